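import numpy as np
import pandas as pd
import pytest

from transheight.panels import HaplotypePanel
from transheight.simulate import (
    SimulationConfig,
    simulate_admixed_cohort,
    simulate_panels,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_variants=800,
        n_haplotypes=200,
        n_studies=2,
        per_study_n=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def panels(small_config):
    return simulate_panels(small_config)


@pytest.fixture(scope="session")
def cohort(panels, small_config):
    return simulate_admixed_cohort(panels, small_config)


def make_panel(matrix, positions=None, chrom="1", population="TEST",
               ref="A", alt="G"):
    """Hand-built panel from an (n_variants, n_haplotypes) 0/1 matrix."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n = matrix.shape[0]
    if positions is None:
        positions = 1 + 1000 * np.arange(n)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"s{i + 1}" for i in range(n)],
            "ref": ref,
            "alt": alt,
        }
    )
    return HaplotypePanel(variants=variants, haplotypes=matrix,
                          population=population)


def brute_d_r2(matrix, i, j):
    """Haplotype-count oracle for D and r^2 between rows i and j."""
    a = np.asarray(matrix[i], dtype=float)
    b = np.asarray(matrix[j], dtype=float)
    p_a, p_b = a.mean(), b.mean()
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    return d, d * d / denom
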