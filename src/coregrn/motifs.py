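"""PWM motif scanning, projection onto ranked site lists, and enrichment.

A PWM is a per-position base-probability model scored as log-odds (bits)
against a background composition.  Scanning reports every position x strand
whose summed log-odds meets a bit threshold; by default the threshold is
80% of a PWM's maximum achievable score.  Enrichment between a target and a
background site set uses presence/absence per site and a one-sided Fisher
exact test with Benjamini-Hochberg correction across the library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

__all__ = [
    "PWM",
    "read_motif_library",
    "write_motif_library",
    "read_family_map",
    "scan",
    "scan_library",
    "project_hits",
    "enrich",
]


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T}.

    matrix has shape (L, 4), rows summing to 1; background is strictly
    positive and defaults to uniform.
    """

    id: str
    family: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"PWM {self.id}: length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.id}: columns must sum to 1")
        if (self.background <= 0).any():
            raise ValueError(f"PWM {self.id}: background must be strictly positive")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2(p/bg) with a zero column for N (scores as background)."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background)
        lo = np.where(np.isneginf(lo), -1e9, lo)  # zero-probability base: effectively forbidden
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        lo = self.log_odds[:, :4]
        return float(lo.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.family, self.matrix[::-1, ::-1], self.background[::-1])


def encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes A=0 C=1 G=2 T=3, anything else (N) = 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def default_threshold(pwm: PWM, fraction: float = 0.8) -> float:
    """Default scan threshold: a fixed fraction of the PWM's maximum score."""
    return fraction * pwm.max_score


def scan(
    sequences: dict[str, str],
    pwm: PWM,
    min_score_bits: float | None = None,
) -> pd.DataFrame:
    """Scan sequences with one PWM on both strands.

    Returns a DataFrame with columns peak_id, pwm_id, family, offset
    (0-based from sequence start, of the match's leftmost base on the
    forward coordinate system), strand, score, center.  Sequences shorter
    than the motif are skipped (their count is available via the ``attrs``
    dict under ``n_skipped``).
    """
    if min_score_bits is None:
        min_score_bits = default_threshold(pwm)
    L = len(pwm)
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    rows = []
    n_skipped = 0
    for pid in sequences:
        seq = sequences[pid]
        if len(seq) < L:
            n_skipped += 1
            continue
        codes = encode(seq)
        idx = np.lib.stride_tricks.sliding_window_view(codes, L)
        pos = np.arange(L)
        fwd = lo_fwd[pos, idx].sum(axis=1)
        # reverse-strand score at offset o = score of revcomp-PWM on forward window
        rev = lo_rev[pos, idx].sum(axis=1)
        for strand, sc in (("+", fwd), ("-", rev)):
            keep = np.flatnonzero(sc >= min_score_bits - 1e-12)
            for o in keep:
                rows.append((pid, pwm.id, pwm.family, int(o), strand, float(sc[o]), o + L / 2))
    hits = pd.DataFrame(
        rows, columns=["peak_id", "pwm_id", "family", "offset", "strand", "score", "center"]
    )
    hits = hits.sort_values(["peak_id", "offset", "strand"], kind="mergesort").reset_index(drop=True)
    hits.attrs["n_skipped"] = n_skipped
    return hits


def scan_library(
    sequences: dict[str, str],
    library: list[PWM],
    min_score_bits: float | None = None,
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Scan with every PWM in a library; per-PWM default thresholds unless
    a single absolute bit threshold is given."""
    frames = []
    for pwm in library:
        thr = min_score_bits if min_score_bits is not None else default_threshold(pwm, threshold_fraction)
        frames.append(scan(sequences, pwm, thr))
    if not frames:
        return pd.DataFrame(columns=["peak_id", "pwm_id", "family", "offset", "strand", "score", "center"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------- library IO

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def read_motif_library(path, family_map: dict[str, str] | None = None, pseudocount: float = 0.5) -> list[PWM]:
    """Read a JASPAR-2020-style text motif file.

    Records are ``>ID NAME`` headers followed by four base rows like
    ``A  [ 10  0  3 ... ]``.  Counts become probabilities with the given
    per-cell pseudocount.  ``family_map`` (pwm id -> TF family) is required
    for any downstream family aggregation; missing ids raise.
    """
    pwms: list[PWM] = []
    with open(path) as fh:
        header = None
        rows: dict[str, list[float]] = {}
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    pwms.append(_finish_record(header, rows, family_map, pseudocount))
                header = line[1:].split()[0]
                rows = {}
            else:
                m = _JASPAR_ROW.match(line)
                if not m:
                    raise ValueError(f"line {lineno}: unrecognized motif row {line!r}")
                base, values = m.group(1), m.group(2).split()
                rows[base] = [float(v) for v in values]
        if header is not None:
            pwms.append(_finish_record(header, rows, family_map, pseudocount))
    return pwms


def _finish_record(pwm_id, rows, family_map, pseudocount) -> PWM:
    missing = set(BASES) - set(rows)
    if missing:
        raise ValueError(f"PWM {pwm_id}: missing base rows {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"PWM {pwm_id}: ragged matrix, row lengths {sorted(lengths)}")
    counts = np.array([rows[b] for b in BASES], dtype=float).T + pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    if family_map is not None:
        if pwm_id not in family_map:
            raise ValueError(f"PWM {pwm_id}: no family mapping")
        family = family_map[pwm_id]
    else:
        family = pwm_id
    return PWM(pwm_id, family, probs)


def write_motif_library(pwms: list[PWM], path, scale: int = 1000) -> None:
    """Write PWMs in JASPAR text dialect (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id} {p.family}\n")
            counts = np.round(p.matrix * scale).astype(int)
            for j, b in enumerate(BASES):
                vals = "  ".join(str(v) for v in counts[:, j])
                fh.write(f"{b}  [ {vals} ]\n")


def read_family_map(path) -> dict[str, str]:
    """Two-column TSV: pwm id -> family label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pwm_id", "family"], comment="#")
    return dict(zip(df["pwm_id"], df["family"]))


# ---------------------------------------------------------------- projection

def project_hits(ranked_peak_ids: list[str], hits: pd.DataFrame, window: int = 25) -> pd.DataFrame:
    """Per-peak motif presence vectors in ranked order, plus rolling densities.

    Returns a DataFrame indexed by peak id (ranked order) with one boolean
    column per PWM id and one ``<pwm>_density`` column: centred rolling mean
    of the indicator over ``window`` peaks (min_periods=1), the substrate of
    side-panel motif density plots along a ranked site list.
    """
    known = set(ranked_peak_ids)
    unknown = set(hits["peak_id"]) - known
    if unknown:
        raise ValueError(f"hits reference unknown peaks: {sorted(unknown)[:5]}")
    out = pd.DataFrame(index=pd.Index(ranked_peak_ids, name="peak_id"))
    for pwm_id, grp in hits.groupby("pwm_id", sort=True):
        present = out.index.isin(set(grp["peak_id"]))
        out[pwm_id] = present
        out[f"{pwm_id}_density"] = (
            pd.Series(present.astype(float), index=out.index)
            .rolling(window, center=True, min_periods=1)
            .mean()
        )
    return out


# ---------------------------------------------------------------- enrichment

def enrich(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    library: list[PWM],
    min_score_bits: float | None = None,
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Motif enrichment of target vs background sites.

    Presence/absence per site, one-sided (greater) Fisher exact test per
    PWM, BH correction over the library.  Background sites also present in
    the target set are excluded.  Odds ratios use the Haldane-Anscombe
    +0.5 correction when any margin cell is zero.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("target and background site sets must be non-empty")
    background_seqs = {k: v for k, v in background_seqs.items() if k not in target_seqs}
    if not background_seqs:
        raise ValueError("background is empty after excluding target sites")

    rows = []
    for pwm in library:
        thr = min_score_bits if min_score_bits is not None else default_threshold(pwm, threshold_fraction)
        t_hits = scan(target_seqs, pwm, thr)
        b_hits = scan(background_seqs, pwm, thr)
        nt, nb = len(target_seqs), len(background_seqs)
        tw = t_hits["peak_id"].nunique()
        bw = b_hits["peak_id"].nunique()
        table = np.array([[tw, nt - tw], [bw, nb - bw]])
        _, p = stats.fisher_exact(table, alternative="greater")
        if (table == 0).any():
            t2 = table + 0.5
        else:
            t2 = table.astype(float)
        oddsr = (t2[0, 0] * t2[1, 1]) / (t2[0, 1] * t2[1, 0])
        rows.append((pwm.id, pwm.family, tw, nt, bw, nb, oddsr, p))
    res = pd.DataFrame(
        rows,
        columns=["pwm_id", "family", "n_target_with", "n_target_total",
                 "n_bg_with", "n_bg_total", "odds_ratio", "p"],
    )
    res["p_adj"] = stats.false_discovery_control(res["p"], method="bh")
    return res.sort_values(["p_adj", "p", "pwm_id"], kind="mergesort").reset_index(drop=True)
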