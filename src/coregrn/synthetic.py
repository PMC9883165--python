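"""Planted-truth synthetic data generator.

Emulates the statistical structure of a two-condition regulatory-genomics
study: a random genome with non-overlapping promoter neighbourhoods, a
planted TF-family -> target-gene network, condition-specific open-chromatin
peaks carrying embedded motif instances (including geometry-controlled motif
pairs), promoter-capture interactions linking a stated fraction of distal
elements to their target promoters, negative-binomial expression with
planted log2 fold-changes, and ChIP peaks recovering planted binding at a
stated sensitivity with a stated false-peak rate.

Every record of every output is covered by exactly one manifest row, and a
fixed config + seed reproduces every file byte for byte (one RNG stream per
output file).  Planted motif instances are embedded as the PWM consensus
sequence so that log-odds scanning at the default threshold recovers them
deterministically; column sampling would place a large fraction of planted
instances below any threshold tight enough to keep random sequence quiet.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SyntheticConfig
from .motifs import BASES, PWM, write_motif_library

CONDITION_A = "aml"
CONDITION_B = "normal"

__all__ = [
    "Genome",
    "PlantedNetwork",
    "PeakData",
    "SyntheticDataset",
    "generate_genome",
    "plant_network",
    "generate_peaks",
    "generate_interactions",
    "generate_expression",
    "generate_chip",
    "simulate",
    "extract_peak_sequences",
]


# --------------------------------------------------------------------- types

@dataclass
class Genome:
    sequences: dict[str, str]
    genes: pd.DataFrame  # gene_id, chrom, tss, strand

    def to_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=c, description="") for c, s in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, fasta_path, genes_path) -> "Genome":
        from Bio import SeqIO

        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
        genes = pd.read_csv(genes_path, sep="\t")
        return cls(seqs, genes)


@dataclass
class PlantedNetwork:
    """Ground-truth regulator network: families, their PWMs, members, edges."""

    families: list[str]
    pwms: dict[str, PWM]  # family -> PWM
    members: dict[str, list[str]]  # family -> TF-encoding gene ids
    edges: set[tuple[str, str]]  # (family, target gene id)
    coloc_pair: tuple[str, str] | None = None

    @property
    def pwm_list(self) -> list[PWM]:
        return [self.pwms[f] for f in self.families]

    @property
    def family_map(self) -> dict[str, str]:
        return {p.id: p.family for p in self.pwm_list}

    def edges_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(rows, columns=["family", "gene_id"])


@dataclass
class PeakData:
    """Peaks of both conditions with raw tag counts and the motif manifest."""

    peaks: pd.DataFrame  # id, chrom, start, end, peak_class, target_gene, count_aml, count_normal
    motif_manifest: pd.DataFrame  # peak_id, family, offset, strand, kind
    pair_manifest: pd.DataFrame  # peak_id, family_a, family_b, distance
    library_sizes: dict[str, int]

    def condition_peaks(self, condition: str) -> pd.DataFrame:
        cls_map = {CONDITION_A: ("shared", "specific_a"), CONDITION_B: ("shared", "specific_b")}
        keep = self.peaks["peak_class"].isin(cls_map[condition])
        return self.peaks[keep].reset_index(drop=True)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: Genome
    network: PlantedNetwork
    peak_data: PeakData
    interactions: pd.DataFrame
    interaction_manifest: pd.DataFrame
    counts_a: pd.DataFrame
    counts_b: pd.DataFrame
    expression_truth: pd.DataFrame
    chip: dict[str, pd.DataFrame] = field(default_factory=dict)
    chip_truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def peak_sequences(self) -> dict[str, str]:
        return extract_peak_sequences(self.genome.sequences, self.peak_data.peaks)

    def write(self, outdir) -> list[Path]:
        """Write every component as plain-text files; returns paths written."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []

        def _w(name, fn):
            p = out / name
            fn(p)
            paths.append(p)

        _w("genome.fa", self.genome.to_fasta)
        _w("genes.tsv", lambda p: self.genome.genes.to_csv(p, sep="\t", index=False))
        _w("motifs.jaspar", lambda p: write_motif_library(self.network.pwm_list, p))
        _w("families.tsv", lambda p: pd.DataFrame(
            [(pw.id, pw.family) for pw in self.network.pwm_list]
        ).to_csv(p, sep="\t", index=False, header=False))
        _w("network_edges.tsv", lambda p: self.network.edges_frame().to_csv(p, sep="\t", index=False))
        _w("peaks.tsv", lambda p: self.peak_data.peaks.to_csv(p, sep="\t", index=False))
        for cond in (CONDITION_A, CONDITION_B):
            sub = self.peak_data.condition_peaks(cond)
            _w(f"peaks_{cond}.bed", lambda p, s=sub: s[["chrom", "start", "end", "id"]]
               .to_csv(p, sep="\t", index=False, header=False))
        _w("motif_manifest.tsv", lambda p: self.peak_data.motif_manifest.to_csv(p, sep="\t", index=False))
        _w("pair_manifest.tsv", lambda p: self.peak_data.pair_manifest.to_csv(p, sep="\t", index=False))
        _w("interactions.bedpe", lambda p: self.interactions[
            ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]
        ].to_csv(p, sep="\t", index=False, header=False))
        _w("interaction_manifest.tsv", lambda p: self.interaction_manifest.to_csv(p, sep="\t", index=False))
        counts = pd.concat([self.counts_a, self.counts_b], axis=1)
        _w("expression_counts.tsv", lambda p: counts.to_csv(p, sep="\t", index=True, index_label="gene_id"))
        _w("expression_truth.tsv", lambda p: self.expression_truth.to_csv(p, sep="\t", index=False))
        for fam, df in self.chip.items():
            _w(f"chip_{fam}.bed", lambda p, d=df: d[["chrom", "start", "end", "id"]]
               .to_csv(p, sep="\t", index=False, header=False))
            _w(f"chip_{fam}_truth.tsv", lambda p, f=fam: self.chip_truth[f].to_csv(p, sep="\t", index=False))
        _w("config.yaml", lambda p: p.write_text(yaml.safe_dump(self.config.to_dict(), sort_keys=True)))
        return paths


# ------------------------------------------------------------------- helpers

class _Occupancy:
    """Per-chromosome sorted occupied intervals with O(log n) collision checks."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        ss = self._starts.get(chrom)
        if not ss:
            return False
        i = bisect.bisect_left(ss, end)
        return i > 0 and self._ends[chrom][i - 1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        ss = self._starts.setdefault(chrom, [])
        ee = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(ss, start)
        ss.insert(i, start)
        ee.insert(i, end)


def extract_peak_sequences(sequences: dict[str, str], peaks: pd.DataFrame) -> dict[str, str]:
    return {
        r.id: sequences[r.chrom][r.start:r.end]
        for r in peaks.itertuples(index=False)
    }


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


# ---------------------------------------------------------------- generators

def generate_genome(config: SyntheticConfig) -> Genome:
    """Random genome with i.i.d. bases at the configured GC content and
    gene TSSs placed so that promoter windows never overlap.

    Genes are spread over evenly spaced, jittered slots with a margin wide
    enough to host distal elements on either side of every TSS.
    """
    rng = config.rng("genome")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, str] = {}
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for i in range(config.n_chromosomes):
        codes = rng.choice(4, size=config.chrom_length_bp, p=p)
        sequences[f"chr{i + 1}"] = base_arr[codes].tobytes().decode("ascii")

    margin = config.promoter_window_bp + 12_000
    chroms = list(sequences)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    rows = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        usable = config.chrom_length_bp - 2 * margin
        spacing = usable / n
        jitter_max = max(1, int(spacing / 4))
        if spacing <= 2 * config.promoter_window_bp + 2 * jitter_max:
            raise ValueError(
                "cannot place promoter windows without overlap: "
                f"{n} genes on a {config.chrom_length_bp} bp chromosome leaves "
                f"{spacing:.0f} bp spacing < 2 x (promoter_window_bp + jitter) = "
                f"{2 * (config.promoter_window_bp + jitter_max)} bp; "
                "increase chrom_length_bp or reduce n_genes"
            )
        for k in range(n):
            tss = int(margin + k * spacing + rng.integers(-jitter_max, jitter_max + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid:04d}", chrom, tss, strand))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return Genome(sequences, genes)


def plant_network(config: SyntheticConfig, pwms: list[PWM] | None = None) -> PlantedNetwork:
    """Sample the ground-truth family -> gene edge set and synthesize PWMs.

    PWM columns have one dominant base (probability ``pwm_dominant_prob``)
    and consensus strings are kept at pairwise Hamming distance >= L/2 so
    scanning separates the families.  Each family gets at least one target
    regardless of density; density 1 yields the complete bipartite set.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1 to plant a network")
    if config.members_per_family * config.n_tf_families > config.n_genes:
        raise ValueError(
            f"{config.n_tf_families} families x {config.members_per_family} member genes "
            f"exceed {config.n_genes} available genes"
        )
    rng = config.rng("network")
    families = [f"FAM{i:02d}" for i in range(config.n_tf_families)]
    genes = [f"g{i:04d}" for i in range(config.n_genes)]

    if pwms is None:
        pwms = _synthesize_pwms(families, config, rng)
    elif len(pwms) < config.n_tf_families:
        raise ValueError(f"need {config.n_tf_families} PWMs, got {len(pwms)}")
    else:
        pwms = [PWM(p.id, fam, p.matrix, p.background) for p, fam in zip(pwms, families)]
    pwm_by_family = {p.family: p for p in pwms}

    member_pool = rng.permutation(genes)
    members = {
        fam: sorted(member_pool[i * config.members_per_family:(i + 1) * config.members_per_family])
        for i, fam in enumerate(families)
    }

    edges: set[tuple[str, str]] = set()
    for fam in families:
        mask = rng.random(config.n_genes) < config.edge_density
        targets = [g for g, m in zip(genes, mask) if m]
        if not targets:
            targets = [genes[int(rng.integers(config.n_genes))]]
        edges.update((fam, g) for g in targets)

    pair = (families[0], families[1]) if len(families) >= 2 else None
    return PlantedNetwork(families, pwm_by_family, members, edges, pair)


def _synthesize_pwms(families: list[str], config: SyntheticConfig, rng: np.random.Generator) -> list[PWM]:
    L = config.pwm_length
    dom = config.pwm_dominant_prob
    consensi: list[np.ndarray] = []
    for _ in families:
        for _attempt in range(1000):
            cand = rng.integers(0, 4, size=L)
            if all((cand != c).sum() >= L // 2 for c in consensi):
                consensi.append(cand)
                break
        else:
            raise RuntimeError("could not synthesize mutually dissimilar PWMs")
    pwms = []
    off = (1.0 - dom) / 3.0
    for fam, cons in zip(families, consensi):
        m = np.full((L, 4), off)
        m[np.arange(L), cons] = dom
        pwms.append(PWM(f"PWM_{fam}", fam, m))
    return pwms


def generate_peaks(genome: Genome, network: PlantedNetwork, config: SyntheticConfig) -> PeakData:
    """Place shared and condition-specific peaks, embed planted motif
    instances, and draw negative-binomial tag counts.

    Condition-specific peaks carry the planted accessibility log2
    fold-change in expectation (split symmetrically across conditions).
    AML-specific peaks are placed 2.5-9.5 kb from their intended target
    gene's TSS (outside every promoter window) so the nearest-TSS fallback
    is a meaningful but imperfect assignment route.  Motif instances are
    written into the genome sequence (consensus string, random strand).
    Geometry-controlled pairs of the designated colocalization families are
    additionally embedded with probability ``pair_prob``; the corresponding
    family -> gene edges are added to the planted network so the manifest
    stays the single source of truth.

    Mutates ``genome.sequences`` (embedding) and ``network.edges`` (pair
    edges).
    """
    rng = config.rng("peaks")
    width = config.peak_width_bp
    L = config.pwm_length
    occ = _Occupancy()
    for r in genome.genes.itertuples(index=False):
        occ.add(r.chrom, r.tss - config.promoter_window_bp, r.tss + config.promoter_window_bp)

    n_shared = config.n_peaks_per_condition // 2
    n_spec = config.n_peaks_per_condition - n_shared
    target_genes = sorted({g for _, g in network.edges})
    if n_spec < len(target_genes):
        raise ValueError(
            f"{n_spec} condition-specific peaks cannot host elements for "
            f"{len(target_genes)} distinct planted target genes; increase n_peaks_per_condition"
        )
    gene_pos = genome.genes.set_index("gene_id")

    # assign each AML-specific element an intended target gene: cover every
    # planted target once, then cycle
    order = list(rng.permutation(target_genes))
    assigned = [order[i % len(order)] for i in range(n_spec)]

    peak_rows = []

    def _place_near(gene_id: str) -> tuple[str, int, int]:
        g = gene_pos.loc[gene_id]
        chrom_len = len(genome.sequences[g.chrom])
        for _ in range(200):
            side = -1 if rng.random() < 0.5 else 1
            dist = int(rng.integers(2500, 9500))
            start = int(g.tss + side * dist - width // 2)
            end = start + width
            if start < 0 or end > chrom_len:
                continue
            if not occ.collides(g.chrom, start, end):
                occ.add(g.chrom, start, end)
                return g.chrom, start, end
        raise RuntimeError(f"peak placement collision budget exceeded near gene {gene_id}")

    def _place_anywhere() -> tuple[str, int, int]:
        chroms = list(genome.sequences)
        for _ in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, len(genome.sequences[chrom]) - width))
            end = start + width
            if not occ.collides(chrom, start, end):
                occ.add(chrom, start, end)
                return chrom, start, end
        raise RuntimeError("peak placement collision budget exceeded (genome too crowded)")

    pid = 0
    for gene_id in assigned:
        chrom, start, end = _place_near(gene_id)
        peak_rows.append((f"peak{pid:05d}", chrom, start, end, "specific_a", gene_id))
        pid += 1
    for cls in ["specific_b"] * n_spec + ["shared"] * n_shared:
        chrom, start, end = _place_anywhere()
        peak_rows.append((f"peak{pid:05d}", chrom, start, end, cls, ""))
        pid += 1
    peaks = pd.DataFrame(peak_rows, columns=["id", "chrom", "start", "end", "peak_class", "target_gene"])

    # ---- motif embedding ------------------------------------------------
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    manifest_rows: list[tuple] = []
    pair_rows: list[tuple] = []
    used_offsets: dict[str, list[tuple[int, int]]] = {pr[0]: [] for pr in peak_rows}
    peak_lookup = peaks.set_index("id")

    def _free_offset(peak_id: str, lo: int, hi: int) -> int | None:
        for _ in range(50):
            o = int(rng.integers(lo, hi + 1))
            if all(o + L <= a or o >= b for a, b in used_offsets[peak_id]):
                return o
        return None

    def _embed(peak_id: str, family: str, offset: int, kind: str) -> None:
        row = peak_lookup.loc[peak_id]
        strand = "+" if rng.random() < 0.5 else "-"
        cons = network.pwms[family].consensus
        inst = cons if strand == "+" else _revcomp(cons)
        pos = row.start + offset
        seqs[row.chrom][pos:pos + L] = inst.encode("ascii")
        used_offsets[peak_id].append((offset, offset + L))
        manifest_rows.append((peak_id, family, offset, strand, kind))

    edge_elements: dict[tuple[str, str], list[str]] = {e: [] for e in network.edges}
    spec_a = peaks[peaks["peak_class"] == "specific_a"]
    for r in spec_a.itertuples(index=False):
        fams = [f for f in network.families if (f, r.target_gene) in network.edges]
        for fam in fams:
            edge_elements[(fam, r.target_gene)].append(r.id)
            if config.motif_embed_prob > 0 and rng.random() < config.motif_embed_prob:
                o = _free_offset(r.id, 10, width - L - 10)
                if o is not None:
                    _embed(r.id, fam, o, "edge")

    # enforce the ground-truth invariant: every planted edge has >= 1
    # embedded instance in >= 1 element assigned to its target gene
    if config.motif_embed_prob > 0:
        embedded = {(m[1], peak_lookup.loc[m[0], "target_gene"]) for m in manifest_rows}
        for (fam, gene), elems in edge_elements.items():
            if (fam, gene) not in embedded and elems:
                eid = elems[int(rng.integers(len(elems)))]
                o = _free_offset(eid, 10, width - L - 10)
                if o is None:
                    raise RuntimeError(f"no room to embed {fam} in element {eid}")
                _embed(eid, fam, o, "edge")

    # geometry-controlled pairs of the designated colocalization families
    if network.coloc_pair is not None and config.pair_prob > 0 and config.motif_embed_prob > 0:
        fam_a, fam_b = network.coloc_pair
        max_mult = 5
        for r in spec_a.itertuples(index=False):
            if rng.random() >= config.pair_prob:
                continue
            if config.spacing_mode == "lattice":
                d = config.lattice_period_bp * int(rng.integers(1, max_mult + 1))
            else:
                d = int(rng.integers(0, 2 * config.coloc_window_bp + 1))
            if d < L:  # motifs cannot physically overlap on the sequence
                continue
            lo, hi = 10, width - L - 10 - d
            if hi < lo:
                continue
            o_a = _free_offset(r.id, lo, hi)
            if o_a is None:
                continue
            o_b = o_a + d
            if not all(o_b + L <= a or o_b >= b for a, b in used_offsets[r.id]):
                continue
            _embed(r.id, fam_a, o_a, "pair")
            _embed(r.id, fam_b, o_b, "pair")
            pair_rows.append((r.id, fam_a, fam_b, d))
            for fam in (fam_a, fam_b):
                if (fam, r.target_gene) not in network.edges:
                    network.edges.add((fam, r.target_gene))
                    edge_elements[(fam, r.target_gene)] = [r.id]

    genome.sequences = {c: b.decode("ascii") for c, b in seqs.items()}

    # ---- tag counts -----------------------------------------------------
    crng = config.rng("tag_counts")
    half = config.planted_log2fc_accessibility / 2.0
    mu_a = np.where(
        peaks["peak_class"] == "specific_a", config.tag_mean * 2 ** half,
        np.where(peaks["peak_class"] == "specific_b", config.tag_mean * 2 ** (-half), config.tag_mean),
    )
    mu_b = np.where(
        peaks["peak_class"] == "specific_a", config.tag_mean * 2 ** (-half),
        np.where(peaks["peak_class"] == "specific_b", config.tag_mean * 2 ** half, config.tag_mean),
    )
    peaks["count_aml"] = _nb_draw(crng, mu_a, config.tag_nb_dispersion)
    peaks["count_normal"] = _nb_draw(crng, mu_b, config.tag_nb_dispersion)
    library_sizes = {
        CONDITION_A: int(peaks["count_aml"].sum()),
        CONDITION_B: int(peaks["count_normal"].sum()),
    }

    manifest = pd.DataFrame(manifest_rows, columns=["peak_id", "family", "offset", "strand", "kind"])
    pair_manifest = pd.DataFrame(pair_rows, columns=["peak_id", "family_a", "family_b", "distance"])
    return PeakData(peaks, manifest, pair_manifest, library_sizes)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with var = mu + dispersion * mu^2;
    dispersion 0 degenerates to Poisson."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def generate_interactions(
    peak_data: PeakData, genes: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter-capture interactions for a stated fraction of distal elements.

    Exactly ``round(frac x n)`` AML-specific elements (chosen at random)
    receive a bait/other-end pair: the other end is the element interval,
    the bait a 1 kb window centred on the intended target's TSS.  Decoy
    interactions to a random non-target gene are added for 5% of the true
    links; decoys attach only to already-linked elements so that the
    linked/unlinked manifest partition remains exact.
    """
    if not 0 <= config.frac_elements_with_interaction <= 1:
        raise ValueError("frac_elements_with_interaction must lie in [0, 1]")
    rng = config.rng("interactions")
    distal = peak_data.peaks[peak_data.peaks["peak_class"] == "specific_a"].reset_index(drop=True)
    if distal.empty:
        raise ValueError("no distal condition-specific elements to link")
    gene_pos = genes.set_index("gene_id")
    n_link = int(round(config.frac_elements_with_interaction * len(distal)))
    linked_idx = sorted(rng.choice(len(distal), size=n_link, replace=False)) if n_link else []
    linked_set = set(linked_idx)

    rows = []
    k = 0
    for i in linked_idx:
        el = distal.iloc[i]
        g = gene_pos.loc[el.target_gene]
        rows.append((g.chrom, int(g.tss) - 500, int(g.tss) + 500,
                     el.chrom, int(el.start), int(el.end),
                     f"int{k:05d}", 1.0, el.id, el.target_gene, False))
        k += 1
    n_decoy = int(round(config.decoy_interaction_rate * len(rows)))
    all_genes = list(gene_pos.index)
    for _ in range(n_decoy):
        i = linked_idx[int(rng.integers(len(linked_idx)))]
        el = distal.iloc[i]
        other = el.target_gene
        while other == el.target_gene:
            other = all_genes[int(rng.integers(len(all_genes)))]
        g = gene_pos.loc[other]
        rows.append((g.chrom, int(g.tss) - 500, int(g.tss) + 500,
                     el.chrom, int(el.start), int(el.end),
                     f"int{k:05d}", 1.0, el.id, other, True))
        k += 1
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "element_id", "gene_id", "decoy"]
    interactions = pd.DataFrame(rows, columns=cols)
    manifest = pd.DataFrame({
        "element_id": distal["id"],
        "target_gene": distal["target_gene"],
        "linked": [i in linked_set for i in range(len(distal))],
    })
    return interactions, manifest


def generate_expression(
    genes: pd.DataFrame,
    network: PlantedNetwork | None,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for two conditions with planted log2 FCs.

    The up-regulated set is drawn preferentially from planted-network
    target genes (those families are the dataset's "active" regulators);
    the down-set from the remaining genes.  Per-sample library scale
    factors are uniform on [0.7, 1.4] (within the stated 2x band).
    Dispersion 0 degenerates to Poisson counts.
    """
    if config.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition for differential testing")
    rng = config.rng("expression")
    gene_ids = list(genes["gene_id"])
    n = len(gene_ids)
    n_de = int(round(config.frac_de_genes * n))
    n_up = n_de // 2
    n_down = n_de - n_up

    targets = sorted({g for _, g in network.edges}) if network is not None else []
    target_set = [g for g in targets if g in set(gene_ids)]
    up: list[str] = list(rng.choice(target_set, size=min(n_up, len(target_set)), replace=False)) \
        if target_set and n_up else []
    remaining = [g for g in gene_ids if g not in set(up)]
    extra_up = n_up - len(up)
    if extra_up > 0:
        up += list(rng.choice(remaining, size=extra_up, replace=False))
        remaining = [g for g in remaining if g not in set(up)]
    down = list(rng.choice(remaining, size=n_down, replace=False)) if n_down else []

    lfc = pd.Series(0.0, index=gene_ids)
    if config.planted_log2fc_expression != 0:
        lfc[up] = config.planted_log2fc_expression
        lfc[down] = -config.planted_log2fc_expression
    true_class = pd.Series("unchanged", index=gene_ids)
    if config.planted_log2fc_expression != 0:
        true_class[up] = "up"
        true_class[down] = "down"

    base = np.clip(rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n), 30.0, None)
    mu_a = base * 2.0 ** lfc.to_numpy()
    mu_b = base

    def _cond(mu: np.ndarray, prefix: str) -> pd.DataFrame:
        cols = {}
        for r in range(config.n_replicates):
            scale = rng.uniform(0.7, 1.4)
            cols[f"{prefix}_{r + 1}"] = _nb_draw(rng, mu * scale, config.nb_dispersion)
        return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    counts_a = _cond(mu_a, CONDITION_A)
    counts_b = _cond(mu_b, CONDITION_B)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "true_class": true_class.to_numpy(),
        "true_log2fc": lfc.to_numpy(),
    })
    return counts_a, counts_b, truth


def generate_chip(
    peak_data: PeakData,
    family: str,
    config: SyntheticConfig,
    chrom_lengths: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChIP peaks for one TF family: each motif-bearing element becomes a
    peak with probability ``chip_sensitivity``; false peaks at
    ``chip_false_peak_rate`` x the emitted true count land in motif-free
    (peak-free) regions."""
    fams = set(peak_data.motif_manifest["family"])
    if family not in fams and config.chip_sensitivity > 0:
        fams_str = ", ".join(sorted(fams)) or "(none)"
        raise ValueError(f"family {family!r} has no embedded instances; families present: {fams_str}")
    rng = config.rng(f"chip_{family}")
    bearing = peak_data.motif_manifest.loc[
        peak_data.motif_manifest["family"] == family, "peak_id"
    ].unique()
    peak_lookup = peak_data.peaks.set_index("id")

    rows, truth_rows = [], []
    k = 0
    for pid in bearing:
        if rng.random() < config.chip_sensitivity:
            p = peak_lookup.loc[pid]
            rows.append((f"chip{k:05d}", p.chrom, int(p.start), int(p.end)))
            truth_rows.append((f"chip{k:05d}", True, pid))
            k += 1
    n_false = int(round(config.chip_false_peak_rate * len(rows)))
    occ = _Occupancy()
    for p in peak_data.peaks.itertuples(index=False):
        occ.add(p.chrom, p.start, p.end)
    chroms = list(chrom_lengths)
    width = config.peak_width_bp
    placed = 0
    attempts = 0
    while placed < n_false and attempts < 10000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_lengths[chrom] - width))
        if occ.collides(chrom, start, start + width):
            continue
        occ.add(chrom, start, start + width)
        rows.append((f"chip{k:05d}", chrom, start, start + width))
        truth_rows.append((f"chip{k:05d}", False, ""))
        k += 1
        placed += 1
    chip = pd.DataFrame(rows, columns=["id", "chrom", "start", "end"])
    chip = chip.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["chip_id", "is_true", "source_element"])
    return chip, truth


def simulate(config: SyntheticConfig, chip_families: list[str] | None = None) -> SyntheticDataset:
    """Run every generator stage under one config; the one-call entry point."""
    genome = generate_genome(config)
    network = plant_network(config)
    peak_data = generate_peaks(genome, network, config)
    interactions, int_manifest = generate_interactions(peak_data, genome.genes, config)
    counts_a, counts_b, truth = generate_expression(genome.genes, network, config)
    chrom_lengths = {c: len(s) for c, s in genome.sequences.items()}
    chip, chip_truth = {}, {}
    for fam in chip_families or network.families[:1]:
        chip[fam], chip_truth[fam] = generate_chip(peak_data, fam, config, chrom_lengths)
    return SyntheticDataset(
        config, genome, network, peak_data, interactions, int_manifest,
        counts_a, counts_b, truth, chip, chip_truth,
    )
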