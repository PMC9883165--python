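"""Motif-pair geometry statistics.

Two complementary questions about a pair of motifs co-occurring in open
chromatin:

* colocalization — are hits of motif A accompanied by hits of motif B
  within a short window (50 bp by default) more often than chance?  Tested
  by a bootstrap that re-places B's hits uniformly at random within their
  own peaks, conditioning on accessibility and on the per-peak B-hit
  abundance.
* spacing periodicity — are A-B centre-to-centre distances concentrated on
  multiples of a period (20 bp by default)?  Tested by a permutation that
  resamples the same number of distances uniformly over the distance range.

Empirical p-values use the add-one convention p = (1 + #{null >= obs}) /
(n + 1) so p is never zero.  Distances are centre-to-centre and
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairColocResult",
    "SpacingSpectrum",
    "colocalization_bootstrap",
    "spacing_histogram",
    "periodicity_test",
]


@dataclass
class PairColocResult:
    pwm_a: str
    pwm_b: str
    window_bp: int
    observed: int
    null_counts: np.ndarray
    p_empirical: float
    enrichment: float
    degenerate: bool = False


@dataclass
class SpacingSpectrum:
    pwm_a: str
    pwm_b: str
    max_dist: int
    histogram: np.ndarray  # 1 bp bins over [0, max_dist]
    period_bp: int | None = None
    lattice_statistic: float | None = None
    p: float | None = None
    underpowered: bool = False

    @property
    def n_pairs(self) -> int:
        return int(self.histogram.sum())


def _hits_by_peak(hits: pd.DataFrame) -> dict[str, np.ndarray]:
    return {pid: grp["center"].to_numpy(dtype=float) for pid, grp in hits.groupby("peak_id", sort=False)}


def colocalization_bootstrap(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    peaks: pd.DataFrame,
    window_bp: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
) -> PairColocResult:
    """Bootstrap test of A-hit colocalization with B-hits within a window.

    observed = number of A-hits whose centre lies within ``window_bp`` of
    some B-hit centre in the same peak.  The null re-places each peak's
    B-hits uniformly at random within that peak (its B-hit count is
    preserved), ``n_boot`` times.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    name_a = hits_a["pwm_id"].iloc[0] if len(hits_a) else "a"
    name_b = hits_b["pwm_id"].iloc[0] if len(hits_b) else "b"
    if hits_a.empty or hits_b.empty:
        return PairColocResult(name_a, name_b, window_bp, 0,
                               np.zeros(n_boot, dtype=int), 1.0, float("nan"), degenerate=True)

    peak_len = {r.id: r.end - r.start for r in peaks.itertuples(index=False)}
    universe = set(peak_len)
    for h, lab in ((hits_a, "A"), (hits_b, "B")):
        extra = set(h["peak_id"]) - universe
        if extra:
            raise ValueError(f"{lab}-hits outside the peak universe: {sorted(extra)[:5]}")

    by_a = _hits_by_peak(hits_a)
    by_b = _hits_by_peak(hits_b)
    observed = 0
    for pid, ca in by_a.items():
        cb = by_b.get(pid)
        if cb is None:
            continue
        observed += int((np.abs(ca[:, None] - cb[None, :]) <= window_bp).any(axis=1).sum())

    rng = np.random.default_rng(seed)
    null = np.zeros(n_boot, dtype=int)
    for pid, ca in by_a.items():
        cb = by_b.get(pid)
        if cb is None:
            continue
        length = peak_len[pid]
        # (n_boot, n_b) uniform replacement of B centres within the peak
        rb = rng.uniform(0, length, size=(n_boot, len(cb)))
        close = (np.abs(ca[:, None, None] - rb[None, :, :]) <= window_bp).any(axis=2)
        null += close.sum(axis=0)

    p = (1 + int((null >= observed).sum())) / (n_boot + 1)
    mean_null = float(null.mean())
    enrichment = observed / mean_null if mean_null > 0 else float("inf")
    return PairColocResult(name_a, name_b, window_bp, observed, null, p, enrichment)


def spacing_histogram(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    max_dist: int = 100,
) -> SpacingSpectrum:
    """Centre-to-centre distance histogram of same-peak A-B hit pairs.

    Every (A-hit, B-hit) pair in the same peak with distance <= max_dist
    counts once (all-pairs counting); a hit never pairs with itself when
    the two hit tables share rows.
    """
    name_a = hits_a["pwm_id"].iloc[0] if len(hits_a) else "a"
    name_b = hits_b["pwm_id"].iloc[0] if len(hits_b) else "b"
    hist = np.zeros(max_dist + 1, dtype=int)
    if hits_a.empty or hits_b.empty:
        return SpacingSpectrum(name_a, name_b, max_dist, hist)
    a_keys = {pid: grp for pid, grp in hits_a.groupby("peak_id", sort=False)}
    for pid, gb in hits_b.groupby("peak_id", sort=False):
        ga = a_keys.get(pid)
        if ga is None:
            continue
        ca = ga["center"].to_numpy(dtype=float)
        cb = gb["center"].to_numpy(dtype=float)
        d = np.abs(ca[:, None] - cb[None, :])
        # exclude self-pairs: same PWM and identical (offset, strand)
        same = (
            (ga["pwm_id"].to_numpy()[:, None] == gb["pwm_id"].to_numpy()[None, :])
            & (ga["offset"].to_numpy()[:, None] == gb["offset"].to_numpy()[None, :])
            & (ga["strand"].to_numpy()[:, None] == gb["strand"].to_numpy()[None, :])
        )
        keep = (~same) & (d <= max_dist)
        np.add.at(hist, np.rint(d[keep]).astype(int), 1)
    return SpacingSpectrum(name_a, name_b, max_dist, hist)


def lattice_statistic(hist: np.ndarray, period_bp: int, tol: int = 1) -> float:
    """Mean count on lattice bins (multiples of the period, +/- tol bp) over
    the mean count on all other bins; inf when off-lattice bins are empty
    but lattice bins are not."""
    n_bins = len(hist)
    idx = np.arange(n_bins)
    on = np.zeros(n_bins, dtype=bool)
    for r in range(-tol, tol + 1):
        on |= (idx - r) % period_bp == 0
    mean_on = hist[on].mean()
    mean_off = hist[~on].mean() if (~on).any() else 0.0
    if mean_off == 0:
        return float("inf") if mean_on > 0 else 0.0
    return float(mean_on / mean_off)


def periodicity_test(
    spectrum: SpacingSpectrum,
    period_bp: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
    min_pairs: int = 50,
    tol: int = 1,
) -> SpacingSpectrum:
    """Permutation test for periodic spacing at ``period_bp``.

    The null resamples the same total number of distances uniformly over
    [0, max_dist].  Because the statistic depends on the distances only
    through the number falling on lattice bins, each permutation reduces to
    a binomial draw, which keeps the test cheap at any n_perm.  Histograms
    with fewer than ``min_pairs`` pairs are flagged underpowered (p = NaN).
    """
    if period_bp >= spectrum.max_dist:
        raise ValueError(f"period {period_bp} must be < max_dist {spectrum.max_dist}")
    hist = spectrum.histogram
    total = int(hist.sum())
    out = SpacingSpectrum(spectrum.pwm_a, spectrum.pwm_b, spectrum.max_dist, hist, period_bp)
    if total < min_pairs:
        out.underpowered = True
        out.lattice_statistic = float("nan")
        out.p = float("nan")
        return out
    obs = lattice_statistic(hist, period_bp, tol)

    n_bins = len(hist)
    idx = np.arange(n_bins)
    on = np.zeros(n_bins, dtype=bool)
    for r in range(-tol, tol + 1):
        on |= (idx - r) % period_bp == 0
    n_on = int(on.sum())
    n_off = n_bins - n_on

    rng = np.random.default_rng(seed)
    k_on = rng.binomial(total, n_on / n_bins, size=n_perm)
    with np.errstate(divide="ignore"):
        perm = (k_on / n_on) / ((total - k_on) / n_off)
    perm = np.where((total - k_on) == 0, np.inf, perm)
    n_ge = int((perm >= obs).sum()) if np.isfinite(obs) else int(np.isinf(perm).sum())
    out.lattice_statistic = obs
    out.p = (1 + n_ge) / (n_perm + 1)
    return out
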