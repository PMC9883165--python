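"""Configuration for the synthetic-data generator.

A single :class:`SyntheticConfig` drives every generator stage so that one
seed reproduces the whole dataset byte-for-byte.  Each output file draws
from its own RNG stream derived from the master seed, which keeps file-level
reproducibility even when only part of the dataset is regenerated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["SyntheticConfig", "stream_rng"]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent RNG stream named ``stream``, derived from the master seed.

    The stream name is hashed with CRC-32 (stable across platforms and
    Python versions) and combined with the seed through a SeedSequence, so
    streams are mutually independent and individually reproducible.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


@dataclass
class SyntheticConfig:
    """Parameters of the planted-truth synthetic dataset.

    Defaults emulate a two-condition (AML blasts vs normal progenitors)
    open-chromatin contrast with an accessibility effect of 2 log2 units on
    condition-specific peaks, a 10-family regulator network wired to 200
    genes, promoter-capture interactions covering 70% of distal elements,
    negative-binomial expression with a 2 log2-unit planted effect, and
    ChIP recovering planted binding at 80% sensitivity.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 4
    chrom_length_bp: int = 1_500_000
    gc_content: float = 0.41
    # genes / network
    n_genes: int = 200
    n_tf_families: int = 10
    edge_density: float = 0.1
    members_per_family: int = 2
    pwm_length: int = 10
    pwm_dominant_prob: float = 0.85
    # peaks
    n_peaks_per_condition: int = 500
    peak_width_bp: int = 300
    planted_log2fc_accessibility: float = 2.0
    tag_mean: float = 200.0
    tag_nb_dispersion: float = 0.05
    motif_embed_prob: float = 0.9
    coloc_window_bp: int = 50
    spacing_mode: str = "uniform"  # or "lattice"
    lattice_period_bp: int = 20
    pair_prob: float = 0.4
    # interactions
    frac_elements_with_interaction: float = 0.7
    decoy_interaction_rate: float = 0.05
    promoter_window_bp: int = 2000
    # expression
    planted_log2fc_expression: float = 2.0
    nb_dispersion: float = 0.1
    n_replicates: int = 5
    frac_de_genes: float = 0.1
    # ChIP
    chip_sensitivity: float = 0.8
    chip_false_peak_rate: float = 0.1

    _fractions: tuple = field(
        default=(
            "gc_content",
            "edge_density",
            "motif_embed_prob",
            "frac_elements_with_interaction",
            "decoy_interaction_rate",
            "frac_de_genes",
            "chip_sensitivity",
            "chip_false_peak_rate",
            "pwm_dominant_prob",
            "pair_prob",
        ),
        repr=False,
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "n_genes",
            "n_tf_families",
            "n_peaks_per_condition",
            "peak_width_bp",
            "pwm_length",
            "coloc_window_bp",
            "lattice_period_bp",
            "promoter_window_bp",
            "members_per_family",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.nb_dispersion < 0 or self.tag_nb_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if self.spacing_mode not in ("uniform", "lattice"):
            raise ValueError(f"spacing_mode must be 'uniform' or 'lattice', got {self.spacing_mode!r}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (differential testing needs within-group variance)")

    def rng(self, stream: str) -> np.random.Generator:
        return stream_rng(self.seed, stream)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_fractions", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__ and k != "_fractions"}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
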