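"""Generator contracts: composition, determinism, planted effect sizes,
manifest completeness."""

import numpy as np
import pandas as pd
import pytest

from coregrn.config import SyntheticConfig
from coregrn.synthetic import (
    generate_chip,
    generate_expression,
    generate_genome,
    generate_interactions,
    generate_peaks,
    plant_network,
    simulate,
)


class TestGenome:
    def test_base_composition_matches_gc(self):
        cfg = SyntheticConfig(seed=1, n_chromosomes=1, chrom_length_bp=1_000_000,
                              gc_content=0.5, n_genes=10)
        g = generate_genome(cfg)
        seq = g.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.01

    def test_gc_zero_gives_only_at(self):
        cfg = SyntheticConfig(seed=1, n_chromosomes=1, chrom_length_bp=50_000,
                              gc_content=0.0, n_genes=2)
        g = generate_genome(cfg)
        assert set(g.sequences["chr1"]) <= {"A", "T"}

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=3, n_chromosomes=2, chrom_length_bp=100_000, n_genes=4)
        for i in (1, 2):
            generate_genome(cfg).to_fasta(tmp_path / f"g{i}.fa")
        assert (tmp_path / "g1.fa").read_bytes() == (tmp_path / "g2.fa").read_bytes()

    def test_promoter_overlap_raises_sizing_error(self):
        cfg = SyntheticConfig(seed=1, n_chromosomes=1, chrom_length_bp=40_000, n_genes=30)
        with pytest.raises(ValueError, match="promoter"):
            generate_genome(cfg)

    def test_promoter_windows_disjoint(self, tiny_config):
        genes = generate_genome(tiny_config).genes
        for _, grp in genes.groupby("chrom"):
            tss = np.sort(grp["tss"].to_numpy())
            assert (np.diff(tss) > 2 * tiny_config.promoter_window_bp).all()


class TestPlantNetwork:
    def test_edge_count_binomial_around_expectation(self):
        totals = [
            len(plant_network(SyntheticConfig(seed=s, n_genes=200, n_tf_families=10,
                                              edge_density=0.1)).edges)
            for s in range(100)
        ]
        # 10 x Binomial(200, 0.1): mean 200, sd ~13.4; mean of 100 draws
        assert 195 <= np.mean(totals) <= 205

    def test_density_zero_min_one_target(self):
        net = plant_network(SyntheticConfig(seed=2, edge_density=0.0))
        assert len(net.edges) == 10
        assert {f for f, _ in net.edges} == set(net.families)

    def test_density_one_complete_bipartite(self):
        net = plant_network(SyntheticConfig(seed=2, n_genes=30, n_tf_families=3,
                                            edge_density=1.0))
        assert len(net.edges) == 90

    def test_pwms_mutually_dissimilar(self):
        net = plant_network(SyntheticConfig(seed=5))
        cons = [net.pwms[f].consensus for f in net.families]
        for i in range(len(cons)):
            for j in range(i + 1, len(cons)):
                ham = sum(a != b for a, b in zip(cons[i], cons[j]))
                assert ham >= len(cons[i]) // 2

    def test_too_many_member_genes_raises(self):
        with pytest.raises(ValueError, match="member genes"):
            plant_network(SyntheticConfig(seed=1, n_genes=10, n_tf_families=10,
                                          members_per_family=2))


class TestPeaks:
    def test_lattice_pair_distances_on_period(self):
        cfg = SyntheticConfig(seed=4, n_chromosomes=2, chrom_length_bp=600_000,
                              n_genes=40, n_tf_families=5, n_peaks_per_condition=120,
                              spacing_mode="lattice", lattice_period_bp=20)
        genome = generate_genome(cfg)
        pd_ = generate_peaks(genome, plant_network(cfg), cfg)
        dists = pd_.pair_manifest["distance"].to_numpy()
        assert len(dists) > 0
        assert (dists % 20 == 0).all()

    def test_embed_prob_zero_empty_manifest(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.to_dict(), "motif_embed_prob": 0.0})
        genome = generate_genome(cfg)
        pd_ = generate_peaks(genome, plant_network(cfg), cfg)
        assert pd_.motif_manifest.empty

    def test_planted_accessibility_ratio(self):
        cfg = SyntheticConfig(seed=6, planted_log2fc_accessibility=2.0,
                              n_peaks_per_condition=1000)
        genome = generate_genome(cfg)
        pd_ = generate_peaks(genome, plant_network(cfg), cfg)
        spec = pd_.peaks[pd_.peaks["peak_class"] == "specific_a"]
        assert len(spec) == 500
        ratio = spec["count_aml"].mean() / spec["count_normal"].mean()
        assert 3.5 <= ratio <= 4.6

    def test_embedded_instances_are_scannable_consensus(self, tiny_dataset):
        from coregrn.synthetic import extract_peak_sequences, _revcomp

        seqs = extract_peak_sequences(tiny_dataset.genome.sequences,
                                      tiny_dataset.peak_data.peaks)
        for row in tiny_dataset.peak_data.motif_manifest.itertuples(index=False):
            cons = tiny_dataset.network.pwms[row.family].consensus
            want = cons if row.strand == "+" else _revcomp(cons)
            found = seqs[row.peak_id][row.offset:row.offset + len(cons)]
            assert found == want

    def test_every_planted_edge_has_an_element(self, tiny_dataset):
        manifest = tiny_dataset.peak_data.motif_manifest.merge(
            tiny_dataset.peak_data.peaks[["id", "target_gene"]],
            left_on="peak_id", right_on="id",
        )
        covered = set(zip(manifest["family"], manifest["target_gene"]))
        assert tiny_dataset.network.edges <= covered


class TestInteractions:
    @pytest.mark.parametrize("frac,expect", [(1.0, "all"), (0.0, "none")])
    def test_fraction_extremes(self, tiny_config, frac, expect):
        cfg = SyntheticConfig(**{**tiny_config.to_dict(),
                                 "frac_elements_with_interaction": frac})
        genome = generate_genome(cfg)
        peaks = generate_peaks(genome, plant_network(cfg), cfg)
        inter, manifest = generate_interactions(peaks, genome.genes, cfg)
        if expect == "all":
            assert manifest["linked"].all()
            linked_el = set(inter.loc[~inter["decoy"], "element_id"])
            assert linked_el == set(manifest["element_id"])
        else:
            assert inter.empty
            assert not manifest["linked"].any()

    def test_fraction_is_exact(self, tiny_dataset):
        manifest = tiny_dataset.interaction_manifest
        frac = tiny_dataset.config.frac_elements_with_interaction
        assert manifest["linked"].sum() == round(frac * len(manifest))

    def test_manifest_covers_every_element_once(self, tiny_dataset):
        spec = tiny_dataset.peak_data.peaks.query("peak_class == 'specific_a'")
        m = tiny_dataset.interaction_manifest
        assert sorted(m["element_id"]) == sorted(spec["id"])
        assert m["element_id"].is_unique


class TestExpression:
    def test_zero_dispersion_is_poisson(self):
        cfg = SyntheticConfig(seed=9, n_genes=200, nb_dispersion=0.0,
                              planted_log2fc_expression=0.0, n_replicates=50)
        genes = pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(200)]})
        a, _, _ = generate_expression(genes, None, cfg)
        # per-replicate library scaling varies; compare within-gene var/mean
        # on counts rescaled to a common depth
        scaled = a / a.sum(axis=0) * a.sum(axis=0).mean()
        fano = (scaled.var(axis=1) / scaled.mean(axis=1)).median()
        assert 0.7 < fano < 1.3

    def test_no_planted_effect_all_unchanged(self):
        cfg = SyntheticConfig(seed=9, n_genes=100, planted_log2fc_expression=0.0)
        genes = pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(100)]})
        _, _, truth = generate_expression(genes, None, cfg)
        assert (truth["true_class"] == "unchanged").all()

    def test_planted_ratio_recovered(self):
        cfg = SyntheticConfig(seed=11, n_genes=400, planted_log2fc_expression=2.0,
                              frac_de_genes=0.5, n_replicates=5)
        genes = pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(400)]})
        a, b, truth = generate_expression(genes, None, cfg)
        up = truth.loc[truth["true_class"] == "up", "gene_id"]
        null = truth.loc[truth["true_class"] == "unchanged", "gene_id"]
        cpm_a = a / a.sum(axis=0) * 1e6
        cpm_b = b / b.sum(axis=0) * 1e6
        # ratio of ratios cancels library-composition effects
        r_up = cpm_a.loc[up].mean(axis=1).mean() / cpm_b.loc[up].mean(axis=1).mean()
        r_null = cpm_a.loc[null].mean(axis=1).mean() / cpm_b.loc[null].mean(axis=1).mean()
        assert 3.4 <= r_up / r_null <= 4.7


class TestChip:
    def test_sensitivity_one_no_false(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.to_dict(), "chip_sensitivity": 1.0,
                                 "chip_false_peak_rate": 0.0})
        genome = generate_genome(cfg)
        peaks = generate_peaks(genome, plant_network(cfg), cfg)
        fam = peaks.motif_manifest["family"].iloc[0]
        lengths = {c: len(s) for c, s in genome.sequences.items()}
        chip, truth = generate_chip(peaks, fam, cfg, lengths)
        bearing = set(peaks.motif_manifest.loc[peaks.motif_manifest["family"] == fam, "peak_id"])
        assert set(truth["source_element"]) == bearing
        assert truth["is_true"].all()

    def test_sensitivity_zero_only_false(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.to_dict(), "chip_sensitivity": 0.0,
                                 "chip_false_peak_rate": 0.5})
        genome = generate_genome(cfg)
        peaks = generate_peaks(genome, plant_network(cfg), cfg)
        lengths = {c: len(s) for c, s in genome.sequences.items()}
        chip, truth = generate_chip(peaks, peaks.motif_manifest["family"].iloc[0], cfg, lengths)
        assert not truth["is_true"].any()

    def test_recovery_within_binomial_ci(self):
        cfg = SyntheticConfig(seed=13, n_genes=500, n_tf_families=1, edge_density=1.0,
                              members_per_family=1, motif_embed_prob=1.0,
                              n_peaks_per_condition=1000, n_chromosomes=4,
                              chrom_length_bp=2_600_000, chip_sensitivity=0.8)
        genome = generate_genome(cfg)
        peaks = generate_peaks(genome, plant_network(cfg), cfg)
        lengths = {c: len(s) for c, s in genome.sequences.items()}
        _, truth = generate_chip(peaks, "FAM00", cfg, lengths)
        n_true_sites = peaks.motif_manifest["peak_id"].nunique()
        recovered = truth["is_true"].sum()
        sd = np.sqrt(n_true_sites * 0.8 * 0.2)
        assert abs(recovered - 0.8 * n_true_sites) < 4 * sd


class TestDatasetContracts:
    def test_full_write_deterministic(self, tiny_config, tmp_path):
        import hashlib

        digests = []
        for run in (1, 2):
            out = tmp_path / f"run{run}"
            simulate(tiny_config).write(out)
            digests.append({
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.iterdir())
            })
        assert digests[0] == digests[1]

    def test_motif_manifest_joins_peaks(self, tiny_dataset):
        joined = tiny_dataset.peak_data.motif_manifest.merge(
            tiny_dataset.peak_data.peaks, left_on="peak_id", right_on="id")
        assert len(joined) == len(tiny_dataset.peak_data.motif_manifest)
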