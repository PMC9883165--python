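"""Promoter-capture interaction handling and element-to-gene assignment.

Interactions pair a promoter-side "bait" anchor with a distal "other end".
Distal open-chromatin elements are assigned to target genes through the
interaction map where possible and otherwise fall back to the nearest TSS;
elements sitting inside a promoter window are assigned to that promoter's
gene directly.  Promoters are TSS +/- 2 kb (strand-agnostic) by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals

BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]

__all__ = [
    "read_bedpe",
    "write_bedpe",
    "classify_cis_trans",
    "share_interactions",
    "specific_elements",
    "assign_elements",
    "promoter_windows",
]


def read_bedpe(path, sample: str = "", chroms: set[str] | None = None) -> pd.DataFrame:
    """Read >= 6-column BEDPE; malformed rows (start >= end, negative
    coordinates) are dropped and counted in ``attrs['n_rejected']``."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(8))
    df = df.iloc[:, :8]
    df.columns = BEDPE_COLS[: df.shape[1]]
    for c in ("name", "score"):
        if c not in df.columns:
            df[c] = "." if c == "name" else 0.0
    ok = (
        (df["start1"] < df["end1"]) & (df["start2"] < df["end2"])
        & (df["start1"] >= 0) & (df["start2"] >= 0)
    )
    n_rejected = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    if chroms is not None:
        bad = (set(df["chrom1"]) | set(df["chrom2"])) - set(chroms)
        if bad:
            raise ValueError(f"BEDPE chromosome names not in annotation: {sorted(bad)}")
    df["sample"] = sample
    df = df.sort_values(["chrom1", "start1", "chrom2", "start2"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_rejected"] = n_rejected
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    df.loc[:, BEDPE_COLS].to_csv(path, sep="\t", header=False, index=False)


def classify_cis_trans(interactions: pd.DataFrame) -> dict:
    """Split interactions into cis (same chromosome) and trans."""
    if interactions.empty:
        return {"cis_fraction": float("nan"), "trans_fraction": float("nan"),
                "cis": interactions, "trans": interactions}
    cis_mask = (interactions["chrom1"] == interactions["chrom2"]).to_numpy()
    return {
        "cis_fraction": float(cis_mask.mean()),
        "trans_fraction": float(1 - cis_mask.mean()),
        "cis": interactions[cis_mask].reset_index(drop=True),
        "trans": interactions[~cis_mask].reset_index(drop=True),
    }


def _anchor(df: pd.DataFrame, which: int) -> pd.DataFrame:
    return df.rename(columns={f"chrom{which}": "chrom", f"start{which}": "start", f"end{which}": "end"})[
        ["chrom", "start", "end"]
    ]


def share_interactions(a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1) -> dict:
    """Fraction of interactions in ``a`` present in ``b``.

    Interaction i in a is "present in b" iff some j in b overlaps it on
    both anchors (bait with bait, other end with other end) by at least
    ``min_overlap_bp``.
    """
    if a.empty:
        return {"fraction": float("nan"), "matched": a, "unmatched": a,
                "present_mask": np.zeros(0, dtype=bool)}
    present = np.zeros(len(a), dtype=bool)
    if not b.empty:
        b_by_chrom = {c: g for c, g in b.groupby("chrom1", sort=False)}
        for i, row in enumerate(a.itertuples(index=False)):
            cand = b_by_chrom.get(row.chrom1)
            if cand is None:
                continue
            ov1 = np.minimum(cand["end1"].to_numpy(), row.end1) - np.maximum(cand["start1"].to_numpy(), row.start1)
            sub = cand[(ov1 >= min_overlap_bp).to_numpy() if hasattr(ov1, "to_numpy") else ov1 >= min_overlap_bp]
            if sub.empty:
                continue
            same2 = sub[sub["chrom2"] == row.chrom2]
            if same2.empty:
                continue
            ov2 = np.minimum(same2["end2"].to_numpy(), row.end2) - np.maximum(same2["start2"].to_numpy(), row.start2)
            present[i] = bool((ov2 >= min_overlap_bp).any())
    return {
        "fraction": float(present.mean()),
        "matched": a[present].reset_index(drop=True),
        "unmatched": a[~present].reset_index(drop=True),
        "present_mask": present,
    }


def specific_elements(
    dhs: pd.DataFrame,
    interactions_a: pd.DataFrame,
    interactions_b: pd.DataFrame,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Open-chromatin sites lying at the other ends of a-specific
    interactions (those absent from b under the both-anchor criterion)."""
    share = share_interactions(interactions_a, interactions_b, min_overlap_bp)
    spec = share["unmatched"]
    if spec.empty or dhs.empty:
        return dhs.iloc[0:0]
    other_ends = _anchor(spec, 2)
    mask = intervals.overlaps_any(dhs, other_ends, min_overlap_bp)
    return dhs[mask].reset_index(drop=True)


def promoter_windows(genes: pd.DataFrame, promoter_window_bp: int = 2000) -> pd.DataFrame:
    """Strand-agnostic TSS +/- window promoter intervals (clipped at 0)."""
    return pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.maximum(0, genes["tss"] - promoter_window_bp),
        "end": genes["tss"] + promoter_window_bp,
        "id": genes["gene_id"],
    })


def assign_elements(
    elements: pd.DataFrame,
    interactions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window_bp: int = 2000,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Assign every element to >= 1 gene: interaction first, nearest TSS as
    fallback.

    * promoter provenance: the element overlaps a promoter window;
    * chic provenance: an interaction whose bait overlaps >= 1 promoter
      window has its other end overlapping the element — every bait gene is
      assigned (capture baits genuinely multi-map);
    * nearest provenance: no interaction support; the gene minimizing
      |element centre - TSS| is chosen, ties broken by lexicographically
      smaller gene id.

    Returns a DataFrame (element_id, gene_id, provenance, distance_bp,
    interaction_id); each element appears with exactly one provenance.
    """
    if genes.empty:
        raise ValueError("gene annotation is empty")
    intervals.validate_intervals(elements, "elements")
    proms = promoter_windows(genes, promoter_window_bp)
    rows: list[tuple] = []

    prom_hits = intervals.overlapping_ids(elements, proms, min_overlap_bp)

    # annotate baits with promoter genes
    chic_by_element: dict[str, list[tuple[str, str]]] = {}
    if not interactions.empty:
        baits = _anchor(interactions, 1)
        bait_genes = intervals.overlapping_ids(baits, proms, min_overlap_bp)
        annotated = interactions.copy()
        keep = [len(g) > 0 for g in bait_genes]
        other = _anchor(annotated, 2).copy()
        other["id"] = [f"__i{k}" for k in range(len(other))]
        elem_hits = intervals.overlapping_ids(other[keep].reset_index(drop=True), elements, min_overlap_bp)
        kept_rows = annotated[keep].reset_index(drop=True)
        kept_genes = [g for g, k in zip(bait_genes, keep) if k]
        for r, (irow, glist) in enumerate(zip(kept_rows.itertuples(index=False), kept_genes)):
            for el in elem_hits[r]:
                chic_by_element.setdefault(el, []).extend((g, str(irow.name)) for g in glist)

    g_chrom = genes["chrom"].to_numpy()
    g_tss = genes["tss"].to_numpy()
    g_ids = genes["gene_id"].to_numpy()
    ctrs = intervals.centers(elements)

    for i, el in enumerate(elements.itertuples(index=False)):
        if prom_hits[i]:
            for g in sorted(set(prom_hits[i])):
                rows.append((el.id, g, "promoter", 0, ""))
            continue
        support = chic_by_element.get(el.id)
        if support:
            seen = {}
            for g, iid in support:
                seen.setdefault(g, iid)
            for g in sorted(seen):
                rows.append((el.id, g, "chic", 0, seen[g]))
            continue
        same = g_chrom == el.chrom
        if not same.any():
            same = np.ones_like(same)  # no gene on this chromosome: fall back genome-wide
        dist = np.abs(g_tss[same] - ctrs[i])
        cand = g_ids[same]
        best = dist.min()
        choice = min(cand[dist == best])
        rows.append((el.id, choice, "nearest", int(best), ""))

    out = pd.DataFrame(rows, columns=["element_id", "gene_id", "provenance", "distance_bp", "interaction_id"])
    # provenance partition sanity: one provenance per element
    per_el = out.groupby("element_id")["provenance"].nunique()
    assert (per_el == 1).all(), "element assigned under multiple provenances"
    return out
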