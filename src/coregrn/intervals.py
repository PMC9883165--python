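"""Genomic-interval primitives shared across the pipeline.

All coordinates are 0-based half-open (BED convention).  Interval tables are
pandas DataFrames with at least ``chrom``, ``start`` and ``end`` columns;
peak tables additionally carry an ``id`` column.  The operations here are
deliberately small and are tested against per-base boolean-mask oracles.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end", "id", "score", "strand"]


def validate_intervals(df: pd.DataFrame, context: str = "interval table") -> None:
    """Raise ValueError (with offending row index) on malformed intervals."""
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError(f"{context}: requires chrom/start/end columns")
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        raise ValueError(f"{context}: start >= end at row(s) {list(bad[:5])}")
    if (df["start"] < 0).any():
        raise ValueError(f"{context}: negative start coordinate")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, sources: Sequence[str] | None = None) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals.

    Returns a sorted table with columns chrom/start/end plus ``sources``
    (comma-joined, sorted, de-duplicated labels of contributing intervals)
    when a per-row source label column or list is supplied.
    """
    validate_intervals(df, "merge")
    if df.empty:
        out = df.loc[:, ["chrom", "start", "end"]].copy()
        out["sources"] = pd.Series(dtype=str)
        return out
    work = df.loc[:, ["chrom", "start", "end"]].copy()
    if sources is not None:
        work["src"] = list(sources)
    elif "source" in df.columns:
        work["src"] = df["source"].astype(str).to_numpy()
    else:
        work["src"] = ""
    work = sort_intervals(work)

    rows = []
    for chrom, grp in work.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        srcs = grp["src"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        cur_src = {srcs[0]}
        for s, e, sr in zip(starts[1:], ends[1:], srcs[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
                cur_src.add(sr)
            else:
                rows.append((chrom, cur_s, cur_e, ",".join(sorted(x for x in cur_src if x))))
                cur_s, cur_e, cur_src = s, e, {sr}
        rows.append((chrom, cur_s, cur_e, ",".join(sorted(x for x in cur_src if x))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sources"])


def _per_chrom_arrays(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        out[chrom] = (g["start"].to_numpy(), g["end"].to_numpy())
    return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame, min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean per query row: does it overlap >= min_overlap_bp with any subject interval?

    Half-open overlap length of [a,b) and [c,d) is max(0, min(b,d) - max(a,c)).
    """
    validate_intervals(query, "overlap query")
    if subject.empty:
        return np.zeros(len(query), dtype=bool)
    validate_intervals(subject, "overlap subject")
    subj = _per_chrom_arrays(subject)
    hit = np.zeros(len(query), dtype=bool)
    for i, (chrom, s, e) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        if chrom not in subj:
            continue
        ss, se = subj[chrom]
        # candidates: subject start < e and subject end > s
        lo = np.searchsorted(ss, e - min_overlap_bp + 1, side="left")
        ov = np.minimum(se[:lo], e) - np.maximum(ss[:lo], s)
        hit[i] = bool((ov >= min_overlap_bp).any())
    return hit


def overlapping_ids(query: pd.DataFrame, subject: pd.DataFrame, min_overlap_bp: int = 1) -> list[list]:
    """Per query row, list of subject ``id`` values overlapping it."""
    validate_intervals(query, "overlap query")
    result: list[list] = [[] for _ in range(len(query))]
    if subject.empty:
        return result
    validate_intervals(subject, "overlap subject")
    groups = {c: g.sort_values("start") for c, g in subject.groupby("chrom", sort=False)}
    for i, (chrom, s, e) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        g = groups.get(chrom)
        if g is None:
            continue
        ss = g["start"].to_numpy()
        se = g["end"].to_numpy()
        ov = np.minimum(se, e) - np.maximum(ss, s)
        result[i] = list(g["id"].to_numpy()[ov >= min_overlap_bp])
    return result


def centers(df: pd.DataFrame) -> np.ndarray:
    """Interval centers, floor((start+end)/2)."""
    return (df["start"].to_numpy() + df["end"].to_numpy()) // 2


def read_bed(path, n_cols: int | None = None) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame (extra columns preserved as given)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = BED_COLS[: df.shape[1]] if df.shape[1] <= 6 else BED_COLS + [f"extra{i}" for i in range(df.shape[1] - 6)]
    df.columns = cols
    validate_intervals(df, str(path))
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLS if c in df.columns]
    out = df.loc[:, cols].copy()
    if "id" in out.columns and "score" not in out.columns:
        out["score"] = 0
    if "score" in out.columns and "strand" not in out.columns:
        out["strand"] = "."
    out.to_csv(path, sep="\t", header=False, index=False)
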