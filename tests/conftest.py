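import numpy as np
import pandas as pd
import pytest

from coregrn.config import SyntheticConfig
from coregrn.motifs import PWM


@pytest.fixture
def tiny_config():
    """Small, fast dataset: 2 chromosomes, 40 genes, 5 families."""
    return SyntheticConfig(
        seed=7, n_chromosomes=2, chrom_length_bp=600_000, n_genes=40,
        n_tf_families=5, n_peaks_per_condition=120,
    )


@pytest.fixture
def tiny_dataset(tiny_config):
    from coregrn.synthetic import simulate

    return simulate(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pwm(consensus: str, pwm_id: str = "P1", family: str = "F1", dominant: float = 0.85) -> PWM:
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    m = np.full((L, 4), (1 - dominant) / 3)
    for i, b in enumerate(consensus):
        m[i, base_idx[b]] = dominant
    return PWM(pwm_id, family, m)


def random_intervals(rng, n, chrom_len=100_000, max_width=400, chrom="chr1"):
    starts = rng.integers(0, chrom_len - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + widths,
        "id": [f"iv{i}" for i in range(n)],
    })


@pytest.fixture
def make_pwm_fixture():
    return make_pwm


@pytest.fixture
def random_intervals_fixture():
    return random_intervals
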