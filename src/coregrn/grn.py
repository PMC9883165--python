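"""Gene-regulatory-network assembly, module extraction and validation.

Nodes are composite TF families (all TFs binding the same motif form one
node); a directed edge family -> gene exists whenever an element assigned
to the gene carries at least one hit of a PWM of that family.  Edge weight
is the motif count (distinct supporting element/hit pairs); each edge keeps
its supporting elements and the provenance mix (chic / nearest / promoter)
of the assignments behind it.  Modules (per-family target sets) are
validated against ChIP peaks and differential-expression classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import intervals
from .interactome import promoter_windows

__all__ = [
    "GRN",
    "build_network",
    "connectivity",
    "extract_module",
    "validate_with_chip",
    "de_binding_overlap",
    "export_network",
    "read_network",
]


@dataclass
class GRN:
    """Composite-node regulator network over a gene target universe."""

    graph: nx.DiGraph
    families: list[str]

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v in self.graph.edges}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["motif_count"], d["elements"], d["n_chic"], d["n_nearest"], d["n_promoter"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["family", "gene_id", "motif_count", "elements",
                           "n_chic", "n_nearest", "n_promoter"]
        ).sort_values(["family", "gene_id"]).reset_index(drop=True)

    def tf_subgraph(self, tf_gene_ids: set[str]) -> "GRN":
        """Core network view: edges restricted to TF-encoding target genes."""
        keep = [(u, v) for u, v in self.graph.edges if v in tf_gene_ids]
        sub = self.graph.edge_subgraph(keep).copy() if keep else nx.DiGraph()
        for f in self.families:
            if f not in sub:
                sub.add_node(f, **self.graph.nodes[f])
        return GRN(sub, self.families)


def build_network(
    assignments: pd.DataFrame,
    hits: pd.DataFrame,
    family_map: dict[str, str],
    de_results: pd.DataFrame | None = None,
    family_members: dict[str, list[str]] | None = None,
    tf_gene_ids: set[str] | None = None,
) -> GRN:
    """Assemble the GRN from element->gene assignments and motif hits.

    Edge family -> gene iff an element assigned to the gene carries >= 1
    hit of a PWM in that family; motif_count aggregates distinct
    (element, hit) support across all such elements.  Family nodes carry
    member TF genes, their mean AML CPM and DE class when expression
    results are supplied.  ``tf_gene_ids`` restricts which families become
    nodes (the "expressed TFs" list); families without expressed members
    are dropped along with their edges.
    """
    unknown_pwms = set(hits["pwm_id"]) - set(family_map)
    if unknown_pwms:
        raise ValueError(f"PWM(s) without family mapping: {sorted(unknown_pwms)}")
    known_elements = set(assignments["element_id"])
    stray = set(hits["peak_id"]) - known_elements
    # hits on elements that were never assigned indicate inconsistent inputs
    # only when assignments claim full coverage of the scanned universe; the
    # caller scans exactly the assigned elements in the pipeline, so strays
    # are an error
    if stray and len(known_elements) == 0:
        raise ValueError("assignments are empty")

    hits = hits[hits["peak_id"].isin(known_elements)].copy()
    hits["family"] = hits["pwm_id"].map(family_map)

    de_by_gene = de_results.set_index("gene_id") if de_results is not None else None
    family_members = family_members or {}

    g = nx.DiGraph()
    families = sorted(set(family_map.values()))
    if tf_gene_ids is not None:
        families = [
            f for f in families
            if not family_members.get(f) or any(m in tf_gene_ids for m in family_members[f])
        ]
    for fam in families:
        members = family_members.get(fam, [])
        expr = np.nan
        de_class = ""
        if de_by_gene is not None and members:
            present = [m for m in members if m in de_by_gene.index]
            if present:
                expr = float(de_by_gene.loc[present, "mean_cpm_a"].mean())
                de_class = "/".join(sorted(set(de_by_gene.loc[present, "de_class"])))
        g.add_node(fam, kind="family", members=",".join(members),
                   expression_cpm=expr, de_class=de_class)
    fam_set = set(families)

    per_hit = hits.merge(
        assignments[["element_id", "gene_id", "provenance"]],
        left_on="peak_id", right_on="element_id", how="inner",
    )
    for (fam, gene), grp in per_hit.groupby(["family", "gene_id"], sort=True):
        if fam not in fam_set:
            continue
        if not g.has_node(gene):
            target_class = ""
            if de_by_gene is not None and gene in de_by_gene.index:
                target_class = str(de_by_gene.loc[gene, "de_class"])
            g.add_node(gene, kind="gene", de_class=target_class)
        prov = grp.drop_duplicates(["element_id"]).set_index("element_id")["provenance"]
        support = grp.drop_duplicates(["element_id", "offset", "strand", "pwm_id"])
        g.add_edge(
            fam, gene,
            motif_count=int(len(support)),
            elements=",".join(sorted(set(grp["element_id"]))),
            n_chic=int((prov == "chic").sum()),
            n_nearest=int((prov == "nearest").sum()),
            n_promoter=int((prov == "promoter").sum()),
        )
    grn = GRN(g, families)
    _check_integrity(grn, assignments)
    return grn


def _check_integrity(grn: GRN, assignments: pd.DataFrame) -> None:
    assigned = assignments.groupby("element_id")["gene_id"].apply(set)
    for u, v, d in grn.graph.edges(data=True):
        if d["motif_count"] < 1:
            raise AssertionError(f"edge {u}->{v} without motif support")
        for el in d["elements"].split(","):
            if v not in assigned.get(el, set()):
                raise AssertionError(f"edge {u}->{v}: supporting element {el} not assigned to {v}")


def connectivity(grn: GRN) -> pd.DataFrame:
    """Out-degree (distinct target genes) per family, sorted descending."""
    rows = [(f, grn.graph.out_degree(f) if f in grn.graph else 0) for f in grn.families]
    return (
        pd.DataFrame(rows, columns=["family", "n_targets"])
        .sort_values(["n_targets", "family"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def extract_module(grn: GRN, family: str) -> set[str]:
    """Target gene set of one family node."""
    if family not in grn.families:
        raise KeyError(f"unknown family {family!r}")
    if family not in grn.graph:
        return set()
    return set(grn.graph.successors(family))


def validate_with_chip(
    module: set[str],
    chip_peaks: pd.DataFrame,
    assignments: pd.DataFrame,
    elements: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window_bp: int = 2000,
    min_overlap_bp: int = 1,
) -> dict:
    """Fraction of module target genes bound by a ChIP factor.

    A gene is "bound" iff >= 1 of its assigned elements, or its promoter
    window, overlaps >= 1 ChIP peak.
    """
    if not module:
        return {"fraction": float("nan"), "n_bound": 0, "n_targets": 0, "degenerate": True}
    el_lookup = elements.set_index("id")
    by_gene = assignments[assignments["gene_id"].isin(module)].groupby("gene_id")["element_id"].apply(list)
    proms = promoter_windows(genes[genes["gene_id"].isin(module)], promoter_window_bp)

    el_rows = []
    for gene in sorted(module):
        for el in by_gene.get(gene, []):
            if el in el_lookup.index:
                r = el_lookup.loc[el]
                el_rows.append((gene, r.chrom, int(r.start), int(r.end)))
    candidates = pd.DataFrame(el_rows, columns=["gene_id", "chrom", "start", "end"])
    prom_df = proms.rename(columns={"id": "gene_id"})[["gene_id", "chrom", "start", "end"]]
    cand = pd.concat([candidates, prom_df], ignore_index=True)
    hit = intervals.overlaps_any(cand, chip_peaks, min_overlap_bp) if len(cand) else np.zeros(0, bool)
    bound_genes = set(cand["gene_id"].to_numpy()[hit])
    n_bound = len(bound_genes & module)
    return {
        "fraction": n_bound / len(module),
        "n_bound": n_bound,
        "n_targets": len(module),
        "bound_genes": sorted(bound_genes & module),
        "degenerate": False,
    }


def de_binding_overlap(
    de_results: pd.DataFrame,
    chip_by_factor: dict[str, pd.DataFrame],
    assignments: pd.DataFrame,
    elements: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window_bp: int = 2000,
) -> pd.DataFrame:
    """Per ChIP factor, the fraction of up- and down-regulated genes bound
    (same criterion as validate_with_chip); NaN when a class is empty."""
    rows = []
    for factor, chip in chip_by_factor.items():
        entry = {"factor": factor}
        for cls in ("up", "down"):
            genes_in_class = set(de_results.loc[de_results["de_class"] == cls, "gene_id"])
            if not genes_in_class:
                entry[f"frac_{cls}_bound"] = float("nan")
                continue
            res = validate_with_chip(
                genes_in_class, chip, assignments, elements, genes, promoter_window_bp
            )
            entry[f"frac_{cls}_bound"] = res["fraction"]
        rows.append(entry)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- export

def export_network(grn: GRN, path, fmt: str = "graphml") -> None:
    """Write the network; graphml and json round-trip losslessly."""
    g = grn.graph.copy()
    g.graph["families"] = ",".join(grn.families)
    if fmt == "graphml":
        nx.write_graphml(_sanitized(g), str(path))
    elif fmt == "json-graph":
        import json

        data = nx.node_link_data(_sanitized(g), edges="edges")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in g.edges(data=True):
                fh.write(f"{u}\tmotif\t{v}\n")
            for n in nx.isolates(g):
                fh.write(f"{n}\n")
    elif fmt == "tsv-edgelist":
        grn.edge_table().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _sanitized(g: nx.DiGraph) -> nx.DiGraph:
    out = g.copy()
    for _, d in out.nodes(data=True):
        for k, v in list(d.items()):
            if isinstance(v, float) and np.isnan(v):
                d[k] = "nan"
    return out


def read_network(path, fmt: str = "graphml") -> GRN:
    if fmt == "graphml":
        g = nx.read_graphml(str(path))
        g = nx.DiGraph(g)
    elif fmt == "json-graph":
        import json

        with open(path) as fh:
            g = nx.node_link_graph(json.load(fh), directed=True, edges="edges")
    else:
        raise ValueError(f"cannot read format {fmt!r}")
    for _, d in g.nodes(data=True):
        if d.get("expression_cpm") == "nan":
            d["expression_cpm"] = float("nan")
    families = g.graph.get("families", "")
    fams = families.split(",") if families else []
    return GRN(g, fams)
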