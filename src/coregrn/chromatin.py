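"""Open-chromatin peak comparison: merging, normalization, fold-change
ranking, specific-site calling, set overlaps and signal-density matrices.

Conventions fixed here (the field's papers rarely state them):

* normalized tag counts are tags per 10 million (raw x 1e7 / library size);
* a peak's centre is floor((start+end)/2) and ranking windows are
  centre +/- window/2 (200 bp by default, 2 kb for density panels);
* ranking ties break by (log2FC desc, chrom asc, start asc) so outputs are
  deterministic;
* "shared" between two peak sets means >= 1 bp overlap unless a larger
  minimum is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals

__all__ = [
    "RankedContrast",
    "OverlapResult",
    "merge_peak_sets",
    "normalize_counts",
    "rank_by_fold_change",
    "call_specific_peaks",
    "overlap_sets",
    "density_matrix",
]


@dataclass
class RankedContrast:
    """Peaks ordered by accessibility log2 fold-change between conditions."""

    peaks: pd.DataFrame  # id, chrom, start, end, norm_<a>, norm_<b>, log2fc
    cond_a: str
    cond_b: str
    window_bp: int = 200
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        fc = self.peaks["log2fc"].to_numpy()
        if np.any(np.diff(fc) > 1e-12):
            raise ValueError("RankedContrast peaks must be ordered by non-increasing log2fc")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.peaks["id"])


@dataclass
class OverlapResult:
    a_only: int
    shared: int
    b_only: int
    shared_fraction_a: float
    a_shared_mask: np.ndarray
    b_shared_mask: np.ndarray


def merge_peak_sets(sets: list[pd.DataFrame], labels: list[str] | None = None) -> pd.DataFrame:
    """Union of several peak sets; overlapping or book-ended intervals are
    merged and each merged interval records the contributing source sets."""
    if labels is None:
        labels = [f"set{i}" for i in range(len(sets))]
    if len(labels) != len(sets):
        raise ValueError("labels must match sets")
    frames = []
    for df, lab in zip(sets, labels):
        intervals.validate_intervals(df, f"peak set {lab}")
        sub = df.loc[:, ["chrom", "start", "end"]].copy()
        sub["source"] = lab
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "sources"])
    allp = pd.concat(frames, ignore_index=True)
    merged = intervals.merge_intervals(allp, sources=allp["source"])
    merged.insert(3, "id", [f"m{i:05d}" for i in range(len(merged))])
    return merged


def normalize_counts(raw, library_size: int, scale: float = 1e7):
    """Depth normalization to tags per 10 million."""
    raw_arr = np.asarray(raw, dtype=float)
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    if (raw_arr < 0).any():
        raise ValueError("negative raw counts")
    out = raw_arr * scale / library_size
    return float(out) if np.isscalar(raw) or out.ndim == 0 else out


def rank_by_fold_change(
    peaks: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    window_bp: int = 200,
    pseudocount: float = 1.0,
) -> RankedContrast:
    """Rank peaks by log2((a + pc) / (b + pc)) of normalized window counts.

    ``peaks`` must carry ``norm_<cond>`` columns of normalized tag counts
    computed over ``window_bp`` windows on peak centres.  Ordering is
    non-increasing in log2FC with deterministic tie-breaking.
    """
    for cond in (cond_a, cond_b):
        if f"norm_{cond}" not in peaks.columns:
            raise ValueError(f"condition {cond!r} missing: no column norm_{cond}")
    df = peaks.copy()
    a = df[f"norm_{cond_a}"].to_numpy(dtype=float)
    b = df[f"norm_{cond_b}"].to_numpy(dtype=float)
    if pseudocount <= 0 and ((a == 0) | (b == 0)).any():
        raise ValueError("pseudocount must be > 0 when zero counts are present")
    df["log2fc"] = np.log2((a + pseudocount) / (b + pseudocount))
    df = df.sort_values(
        ["log2fc", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return RankedContrast(df, cond_a, cond_b, window_bp, pseudocount)


def call_specific_peaks(
    contrast: RankedContrast, min_abs_log2fc: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition ranked peaks into (A-specific, B-specific, shared).

    Boundary inclusive: log2FC >= threshold is A-specific, <= -threshold is
    B-specific; everything else is shared.  The partition is exhaustive and
    disjoint by construction and asserted on every call.
    """
    df = contrast.peaks
    fc = df["log2fc"].to_numpy()
    a_mask = fc >= min_abs_log2fc
    b_mask = fc <= -min_abs_log2fc
    shared_mask = ~(a_mask | b_mask)
    assert (a_mask.astype(int) + b_mask + shared_mask == 1).all(), "partition violated"
    return (
        df[a_mask].reset_index(drop=True),
        df[b_mask].reset_index(drop=True),
        df[shared_mask].reset_index(drop=True),
    )


def overlap_sets(a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1) -> OverlapResult:
    """Peak-wise overlap between two sets (counts on each set's own
    intervals; asymmetric counts are expected when peaks differ in width)."""
    a_mask = intervals.overlaps_any(a, b, min_overlap_bp) if len(a) else np.zeros(0, bool)
    b_mask = intervals.overlaps_any(b, a, min_overlap_bp) if len(b) else np.zeros(0, bool)
    shared = int(a_mask.sum())
    return OverlapResult(
        a_only=int(len(a) - shared),
        shared=shared,
        b_only=int(len(b) - b_mask.sum()),
        shared_fraction_a=shared / len(a) if len(a) else float("nan"),
        a_shared_mask=a_mask,
        b_shared_mask=b_mask,
    )


def density_matrix(
    regions: pd.DataFrame,
    signal: pd.DataFrame | dict[str, np.ndarray],
    flank_bp: int = 1000,
    bin_bp: int = 10,
) -> np.ndarray:
    """Signal-position counts in fixed bins around region centres.

    Row r, column j counts signal positions in
    [centre_r - flank + j*bin, centre_r - flank + (j+1)*bin); rows keep the
    order of ``regions`` (e.g. a RankedContrast), which is what heat-map
    style density panels plot.  ``signal`` is either a DataFrame with
    chrom/pos columns or a dict chrom -> sorted positions.
    """
    if (2 * flank_bp) % bin_bp != 0:
        raise ValueError(f"bin_bp {bin_bp} must divide the window 2 x {flank_bp}")
    n_bins = (2 * flank_bp) // bin_bp
    if isinstance(signal, pd.DataFrame):
        sig = {c: np.sort(g["pos"].to_numpy()) for c, g in signal.groupby("chrom", sort=False)}
    else:
        sig = {c: np.sort(np.asarray(v)) for c, v in signal.items()}
    mat = np.zeros((len(regions), n_bins), dtype=int)
    ctr = intervals.centers(regions)
    for i, (chrom, c) in enumerate(zip(regions["chrom"], ctr)):
        pos = sig.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        edges = c - flank_bp + bin_bp * np.arange(n_bins + 1)
        mat[i] = np.diff(np.searchsorted(pos, edges, side="left"))
    return mat
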