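"""Shared fixtures: small synthetic datasets and hand-built matrices."""

import numpy as np
import pytest
import scipy.sparse as sp

from khmdemux.allele_io import AlleleCountMatrix, VariantSite
from khmdemux.simulate import SimConfig, simulate_dataset


def make_counts(ref_dense, alt_dense, barcodes=None, variants=None) -> AlleleCountMatrix:
    """AlleleCountMatrix from dense cells x variants arrays."""
    ref = np.asarray(ref_dense)
    alt = np.asarray(alt_dense)
    n_cells, n_variants = ref.shape
    if barcodes is None:
        barcodes = [f"CELL{i:04d}" for i in range(n_cells)]
    if variants is None:
        variants = [VariantSite("1", 100 * (v + 1), "A", "C") for v in range(n_variants)]
    return AlleleCountMatrix(sp.csr_matrix(ref), sp.csr_matrix(alt), barcodes, variants)


@pytest.fixture(scope="session")
def two_donor_sim():
    """Well-separated two-donor mixture (deep coverage, no doublets)."""
    cfg = SimConfig(
        n_donors=2, n_cells=200, n_variants=100,
        coverage_density=0.3, depth_mean=4.0, seed=9,
    )
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def four_donor_sim():
    """Four donors at realistic sparsity with 10% doublets."""
    cfg = SimConfig(
        n_donors=4, n_cells=400, n_variants=1200, doublet_rate=0.10, seed=6
    )
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def eight_donor_sim():
    """Eight donors, no doublets, defaults."""
    cfg = SimConfig(n_donors=8, n_cells=640, n_variants=1000, seed=5)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture()
def tiny_counts():
    """2 cells x 3 variants with hand-checkable entries."""
    ref = [[2, 1, 0], [0, 3, 1]]
    alt = [[1, 0, 2], [0, 3, 0]]
    return make_counts(ref, alt)
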