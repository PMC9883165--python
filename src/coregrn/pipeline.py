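"""End-to-end driver: simulate -> rank -> specific -> scan -> enrich ->
geometry -> link -> DE -> GRN -> ChIP validation.

`run_pipeline` executes every stage on one synthetic dataset, optionally
writing all tables plus a provenance manifest (config echo, sha256 of every
output, package version).  All randomness derives from the config seed, so
two runs with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chromatin import call_specific_peaks, density_matrix, normalize_counts, rank_by_fold_change
from .config import SyntheticConfig, stream_rng
from .expression import differential_expression
from .geometry import colocalization_bootstrap, periodicity_test, spacing_histogram
from .grn import GRN, build_network, connectivity, export_network, extract_module, validate_with_chip
from .interactome import assign_elements, classify_cis_trans
from .motifs import scan_library
from .synthetic import CONDITION_A, CONDITION_B, SyntheticDataset, extract_peak_sequences, simulate

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    contrast: object
    specific_a: pd.DataFrame
    specific_b: pd.DataFrame
    shared: pd.DataFrame
    hits: pd.DataFrame
    enrichment: pd.DataFrame
    coloc: object
    spacing: object
    assignments: pd.DataFrame
    de: pd.DataFrame
    grn: GRN
    metrics: dict = field(default_factory=dict)


def run_pipeline(
    config: SyntheticConfig,
    outdir: str | Path | None = None,
    n_boot: int = 200,
    n_perm: int = 500,
    enrichment: bool = True,
) -> PipelineResult:
    ds = simulate(config)
    peaks = ds.peak_data.peaks.copy()
    libs = ds.peak_data.library_sizes
    peaks[f"norm_{CONDITION_A}"] = normalize_counts(peaks["count_aml"], libs[CONDITION_A])
    peaks[f"norm_{CONDITION_B}"] = normalize_counts(peaks["count_normal"], libs[CONDITION_B])

    contrast = rank_by_fold_change(peaks, CONDITION_A, CONDITION_B)
    spec_a, spec_b, shared = call_specific_peaks(contrast)

    seqs_a = extract_peak_sequences(ds.genome.sequences, spec_a)
    hits = scan_library(seqs_a, ds.network.pwm_list)

    enr = None
    if enrichment:
        bg = pd.concat([spec_b, shared], ignore_index=True)
        seqs_bg = extract_peak_sequences(ds.genome.sequences, bg)
        from .motifs import enrich

        enr = enrich(seqs_a, seqs_bg, ds.network.pwm_list)

    # geometry of the designated colocalization pair
    coloc = spacing = None
    if ds.network.coloc_pair is not None:
        fam_a, fam_b = ds.network.coloc_pair
        ha = hits[hits["family"] == fam_a].reset_index(drop=True)
        hb = hits[hits["family"] == fam_b].reset_index(drop=True)
        grng = stream_rng(config.seed, "geometry_tests")
        coloc = colocalization_bootstrap(
            ha, hb, spec_a, window_bp=config.coloc_window_bp,
            n_boot=max(100, n_boot), seed=int(grng.integers(2**31)),
        )
        spec = spacing_histogram(ha, hb, spec_a, max_dist=100)
        spacing = periodicity_test(
            spec, period_bp=config.lattice_period_bp, n_perm=n_perm,
            seed=int(grng.integers(2**31)),
        )

    # element -> gene assignment on the called AML-specific elements
    assignments = assign_elements(
        spec_a, ds.interactions, ds.genome.genes, config.promoter_window_bp
    )

    de = differential_expression(ds.counts_a, ds.counts_b)

    tf_genes = {g for mem in ds.network.members.values() for g in mem}
    grn = build_network(
        assignments, hits, ds.network.family_map, de,
        family_members=ds.network.members, tf_gene_ids=tf_genes,
    )

    metrics = _compute_metrics(ds, spec_a, spec_b, assignments, de, grn, coloc, spacing)
    for fam, chip in ds.chip.items():
        module = extract_module(grn, fam) if fam in grn.families else set()
        rep = validate_with_chip(module, chip, assignments, ds.peak_data.peaks,
                                 ds.genome.genes, config.promoter_window_bp)
        metrics[f"chip_bound_fraction_{fam}"] = rep["fraction"]
    result = PipelineResult(
        ds, contrast, spec_a, spec_b, shared, hits, enr, coloc, spacing,
        assignments, de, grn, metrics,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _compute_metrics(ds, spec_a, spec_b, assignments, de, grn, coloc, spacing) -> dict:
    m: dict = {}
    truth = ds.peak_data.peaks
    planted_a = set(truth.loc[truth["peak_class"] == "specific_a", "id"])
    planted_b = set(truth.loc[truth["peak_class"] == "specific_b", "id"])
    called_a, called_b = set(spec_a["id"]), set(spec_b["id"])
    if planted_a:
        m["specific_peak_recall_aml"] = len(planted_a & called_a) / len(planted_a)
    if planted_b:
        m["specific_peak_recall_normal"] = len(planted_b & called_b) / len(planted_b)

    cis = classify_cis_trans(ds.interactions)
    m["interaction_cis_fraction"] = cis["cis_fraction"]

    prov = assignments.drop_duplicates("element_id").groupby("provenance").size().to_dict()
    m["n_elements_chic"] = int(prov.get("chic", 0))
    m["n_elements_nearest"] = int(prov.get("nearest", 0))
    m["n_elements_promoter"] = int(prov.get("promoter", 0))

    planted_edges = ds.network.edges
    recovered = grn.edges
    tp = len(recovered & planted_edges)
    m["grn_edge_precision"] = tp / len(recovered) if recovered else float("nan")
    m["grn_edge_recall"] = tp / len(planted_edges) if planted_edges else float("nan")
    m["grn_n_edges"] = len(recovered)

    truth_expr = ds.expression_truth.set_index("gene_id")["true_class"]
    calls = de.set_index("gene_id")["de_class"]
    is_de_truth = truth_expr != "unchanged"
    correct = (calls[is_de_truth.index] == truth_expr) & is_de_truth
    n_true = int(is_de_truth.sum())
    if n_true:
        m["de_sensitivity"] = float(correct.sum()) / n_true
    called_de = calls != "unchanged"
    if called_de.any():
        m["de_fdr"] = float(((truth_expr == "unchanged") & called_de).sum() / called_de.sum())

    if coloc is not None:
        m["coloc_observed"] = coloc.observed
        m["coloc_p"] = coloc.p_empirical
    if spacing is not None and spacing.p == spacing.p:
        m["spacing_statistic"] = spacing.lattice_statistic
        m["spacing_p"] = spacing.p
    return m


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = result.dataset.write(outdir / "data")

    def _w(name, fn):
        p = outdir / name
        fn(p)
        paths.append(p)

    _w("contrast.tsv", lambda p: result.contrast.peaks.to_csv(p, sep="\t", index=False))
    _w("specific_aml.bed", lambda p: result.specific_a[["chrom", "start", "end", "id"]]
       .to_csv(p, sep="\t", header=False, index=False))
    _w("specific_normal.bed", lambda p: result.specific_b[["chrom", "start", "end", "id"]]
       .to_csv(p, sep="\t", header=False, index=False))
    _w("motif_hits.tsv", lambda p: result.hits.to_csv(p, sep="\t", index=False))
    if result.enrichment is not None:
        _w("enrichment.tsv", lambda p: result.enrichment.to_csv(p, sep="\t", index=False))
    if result.coloc is not None:
        _w("colocalization.tsv", lambda p: pd.DataFrame([{
            "pwm_a": result.coloc.pwm_a, "pwm_b": result.coloc.pwm_b,
            "window_bp": result.coloc.window_bp, "observed": result.coloc.observed,
            "p_empirical": result.coloc.p_empirical, "enrichment": result.coloc.enrichment,
        }]).to_csv(p, sep="\t", index=False))
    if result.spacing is not None:
        _w("spacing_histogram.tsv", lambda p: pd.DataFrame({
            "distance_bp": np.arange(len(result.spacing.histogram)),
            "n_pairs": result.spacing.histogram,
        }).to_csv(p, sep="\t", index=False))
    _w("assignments.tsv", lambda p: result.assignments.to_csv(p, sep="\t", index=False))
    _w("differential_expression.tsv", lambda p: result.de.to_csv(p, sep="\t", index=False))
    _w("grn.graphml", lambda p: export_network(result.grn, p, "graphml"))
    _w("grn_edges.tsv", lambda p: export_network(result.grn, p, "tsv-edgelist"))
    _w("connectivity.tsv", lambda p: connectivity(result.grn).to_csv(p, sep="\t", index=False))

    # ChIP-module validation summary for the simulated factors
    rows = [
        {"family": fam, "chip_bound_fraction": result.metrics.get(f"chip_bound_fraction_{fam}")}
        for fam in result.dataset.chip
    ]
    if rows:
        _w("module_chip_validation.tsv", lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))

    # density panel substrate: ChIP summit positions around ranked peaks
    if result.dataset.chip:
        fam0 = next(iter(result.dataset.chip))
        chip = result.dataset.chip[fam0]
        signal = pd.DataFrame({
            "chrom": chip["chrom"],
            "pos": (chip["start"] + chip["end"]) // 2,
        })
        mat = density_matrix(result.contrast.peaks, signal, flank_bp=1000, bin_bp=10)
        _w(f"density_{fam0}.tsv", lambda p: pd.DataFrame(
            mat, index=result.contrast.peak_ids
        ).to_csv(p, sep="\t", index_label="peak_id"))

    _w("metrics.json", lambda p: p.write_text(json.dumps(result.metrics, indent=1, sort_keys=True)))

    prov = {
        "package_version": __version__,
        "config": result.dataset.config.to_dict(),
        "files": {
            str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(paths)
        },
    }
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
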