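"""K-harmonic-means core: loss, soft assignments, center updates, fits."""

import numpy as np
import pytest

from khmdemux.count_model import CountModelConfig, distance_matrix
from khmdemux.initialization import ClusterCenters, initialize_10x
from khmdemux.khm import (
    AnnealSchedule,
    KHMConfig,
    SoftAssignment,
    anneal_fit,
    hard_assignment,
    khm_loss,
    khm_soft_assignment,
    update_centers,
)
from khmdemux.metrics import adjusted_rand_index

from conftest import make_counts

CM = CountModelConfig()


def brute_khm_loss(distances, power):
    d = np.atleast_2d(distances)
    total = 0.0
    for row in d:
        denom = sum(1.0 / (x ** power) for x in row)
        total += len(row) / denom
    return total


def brute_soft_assignment(distances, power, temperature):
    d = np.atleast_2d(distances) ** (1.0 / temperature)
    m = np.zeros_like(d)
    w = np.zeros(d.shape[0])
    for i, row in enumerate(d):
        num = row ** (-power - 2)
        m[i] = num / num.sum()
        w[i] = num.sum() / (row ** (-power)).sum() ** 2
    return m, w


class TestKhmLoss:
    def test_hand_values(self):
        assert khm_loss(np.array([[1.0, 1.0]]), 2) == pytest.approx(1.0)
        assert khm_loss(np.array([[1.0, 10.0]]), 2) == pytest.approx(2 / 1.01)

    def test_equidistant_identity(self):
        d = np.full((1, 5), 3.0)
        assert khm_loss(d, 3) == pytest.approx(3.0 ** 3)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            khm_loss(np.array([[1.0, 0.0]]), 2)


class TestSoftAssignment:
    def test_equidistant_uniform(self):
        sa = khm_soft_assignment(np.full((2, 3), 2.0), 2, 1.0)
        np.testing.assert_allclose(sa.memberships, 1 / 3, atol=1e-12)

    def test_contrast_hand_value(self):
        sa = khm_soft_assignment(np.array([[1.0, 10.0]]), 2, 1.0)
        np.testing.assert_allclose(sa.memberships[0], [1 / 1.0001, 1e-4 / 1.0001],
                                   rtol=1e-9)

    def test_high_temperature_flattens(self):
        sa = khm_soft_assignment(np.array([[1.0, 10.0]]), 2, 1e6)
        np.testing.assert_allclose(sa.memberships[0], [0.5, 0.5], atol=1e-4)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.5, 50, (40, 6))
        sa = khm_soft_assignment(d, 3, 1.7)
        np.testing.assert_allclose(sa.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(sa.cell_weights > 0)

    def test_temperature_below_one_rejected(self):
        with pytest.raises(ValueError):
            khm_soft_assignment(np.array([[1.0, 2.0]]), 2, 0.5)


@pytest.mark.parametrize("power,temperature", [(2.0, 1.0), (3.0, 1.0), (3.5, 2.2)])
def test_oracle_equivalence_small_instances(power, temperature):
    """Loss and soft assignment match brute-force loops to 1e-9."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        n, k = rng.integers(1, 7), rng.integers(2, 5)
        d = rng.uniform(0.2, 30.0, (n, k))
        assert khm_loss(d, power) == pytest.approx(brute_khm_loss(d, power), rel=1e-9)
        sa = khm_soft_assignment(d, power, temperature)
        m_ref, w_ref = brute_soft_assignment(d, power, temperature)
        np.testing.assert_allclose(sa.memberships, m_ref, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(sa.cell_weights, w_ref, rtol=1e-9)


class TestUpdateCenters:
    def test_single_contributor_closed_form(self):
        counts = make_counts([[1, 0]], [[3, 0]])
        centers = ClusterCenters(np.array([[0.5, 0.5]]))
        sa = SoftAssignment(np.array([[1.0]]), np.array([1.0]))
        out = update_centers(counts, sa, centers, KHMConfig())
        assert out.fractions[0, 0] == pytest.approx(2 / 3)
        # variant 1 is uncovered: add-one smoothing default (0+1)/(0+2)
        assert out.fractions[0, 1] == pytest.approx(0.5)

    def test_locked_cluster_bit_identical(self, four_donor_sim):
        _, counts, _ = four_donor_sim
        rng = np.random.default_rng(2)
        F = np.clip(rng.random((3, counts.n_variants)), 0.01, 0.99)
        centers = ClusterCenters(F.copy(), np.array([False, True, False]))
        m = rng.dirichlet(np.ones(3), counts.n_cells)
        sa = SoftAssignment(m, np.ones(counts.n_cells))
        out = update_centers(counts, sa, centers, KHMConfig())
        assert np.array_equal(out.fractions[1], F[1])
        assert not np.array_equal(out.fractions[0], F[0])


class TestAnnealFit:
    def test_loss_trace_non_increasing_from_true_centers(self, two_donor_sim):
        """At T=1 from the true donor centers the loss descends."""
        _, counts, truth = two_donor_sim
        tc = ClusterCenters(np.clip(truth.genotypes / 2, 0.01, 0.99))
        cfg = KHMConfig(schedule=AnnealSchedule(t_start=1.0))
        fit = anneal_fit(counts, tc, cfg)
        rel = np.diff(fit.trace) / np.abs(fit.trace[:-1])
        assert rel.max() <= 1e-8
        assert fit.converged

    def test_k1_converges_to_pooled_fractions(self, four_donor_sim):
        _, counts, _ = four_donor_sim
        init = ClusterCenters(np.full((1, counts.n_variants), 0.3))
        fit = anneal_fit(counts, init, KHMConfig())
        alt_tot = np.asarray(counts.alt_counts.sum(axis=0)).ravel()
        tot = np.asarray(counts.depth().sum(axis=0)).ravel()
        pooled = np.clip((alt_tot + 1) / (tot + 2), 0.01, 0.99)
        np.testing.assert_allclose(fit.centers.fractions[0], pooled, atol=1e-6)

    def test_two_donor_recovery_from_initialize_10x(self, two_donor_sim):
        _, counts, truth = two_donor_sim
        init = initialize_10x(counts, 2, CM, seed=3)
        fit = anneal_fit(counts, init, KHMConfig())
        hard = hard_assignment(fit.assignment.memberships)
        singlet = ~truth.is_doublet
        assert adjusted_rand_index(truth.cell_donor[singlet], hard[singlet]) == 1.0

    def test_label_equivariance(self, two_donor_sim):
        _, counts, truth = two_donor_sim
        tc = np.clip(truth.genotypes / 2, 0.01, 0.99)
        fit_a = anneal_fit(counts, ClusterCenters(tc.copy()), KHMConfig())
        fit_b = anneal_fit(counts, ClusterCenters(tc[::-1].copy()), KHMConfig())
        np.testing.assert_allclose(
            fit_a.centers.fractions, fit_b.centers.fractions[::-1], atol=1e-9
        )
        np.testing.assert_allclose(
            fit_a.assignment.memberships, fit_b.assignment.memberships[:, ::-1],
            atol=1e-9,
        )

    def test_zero_coverage_cells_are_uniform_and_finite(self):
        ref = np.zeros((3, 4)); ref[1:, :2] = 2
        alt = np.zeros((3, 4)); alt[1, 2] = 1
        counts = make_counts(ref, alt)
        fit = anneal_fit(counts, ClusterCenters(np.full((2, 4), 0.4)), KHMConfig())
        assert np.all(np.isfinite(fit.centers.fractions))
        np.testing.assert_allclose(fit.assignment.memberships[0], 0.5, atol=1e-12)


def test_schedule_validation():
    with pytest.raises(ValueError):
        AnnealSchedule(t_start=0.5)
    with pytest.raises(ValueError):
        AnnealSchedule(decay=1.0)
    with pytest.raises(ValueError):
        KHMConfig(power=1.5)
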