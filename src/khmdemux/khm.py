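"""K-harmonic-means clustering under the count-likelihood distance,
wrapped in a deterministic-annealing temperature schedule.

KHM minimizes the sum over cells of the harmonic mean of their
distances to all k centers,

    L = sum_i  k / sum_j d_ij^(-p),

which, unlike k-means, keeps every center feeling a pull from every
cell and is far less sensitive to initialization.  The per-sweep update
is soft: memberships m_ij ~ d_ij^(-p-2) and per-cell weights
w_i = (sum_j d_ij^(-p-2)) / (sum_j d_ij^(-p))^2, so poorly explained
cells pull hardest.  Centers are then refit as the weighted binomial
maximum-likelihood allele fractions with add-one smoothing (closed
form, stable on sparse counts); locked clusters are returned
bit-identical.

Annealing raises distances to the power 1/T — equivalently dividing the
negative log likelihoods by the temperature — so early sweeps see a
flattened assignment landscape and late sweeps (T -> 1) the true one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .count_model import CountModelConfig, clamp_fractions, distance_matrix
from .initialization import ClusterCenters


@dataclass(frozen=True)
class AnnealSchedule:
    """Temperature schedule: start at ``t_start``, multiply by ``decay``
    until ``t_min`` (1.0 = no flattening), running ``inner_iters``
    sweeps per temperature, then iterate at ``t_min`` to convergence
    (relative loss change below ``tol``) or ``max_final_sweeps``."""

    t_start: float = 5.0
    t_min: float = 1.0
    decay: float = 0.8
    inner_iters: int = 3
    tol: float = 1e-6
    max_final_sweeps: int = 200

    def __post_init__(self) -> None:
        if not self.t_start >= self.t_min >= 1.0:
            raise ValueError("need t_start >= t_min >= 1")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class KHMConfig:
    """KHM exponent, anneal schedule, count model, and seed.

    ``power`` is the KHM distance exponent p (>= 2).

    ``baseline_offset`` selects how :func:`anneal_fit` composes the
    membership operation.  Log-likelihood distances are sums over a
    cell's covered sites, so their *ratios* barely move (best vs second
    center typically differ by < 2%) while their *differences* carry
    the genotype evidence.  With an offset c, sweeps feed the
    membership op per-cell excess distances d - min_j d + c*T, making
    the power-law membership (x^-(p+2)) behave like an exponential
    posterior with temperature c*T/(p+2); c is therefore a softness
    scale in log-likelihood units and the annealing temperature scales
    it.  ``baseline_offset=None`` feeds raw distances annealed as
    d^(1/T) (the textbook composition), which is only usable at small
    cluster counts.
    """

    power: float = 3.0
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    count_model: CountModelConfig = field(default_factory=CountModelConfig)
    baseline_offset: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.power >= 2.0:
            raise ValueError("power must be >= 2")
        if self.baseline_offset is not None and not self.baseline_offset > 0:
            raise ValueError("baseline_offset must be positive (or None)")


@dataclass
class SoftAssignment:
    """KHM memberships (rows sum to 1) and per-cell update weights."""

    memberships: np.ndarray
    cell_weights: np.ndarray

    def __post_init__(self) -> None:
        self.memberships = np.atleast_2d(np.asarray(self.memberships, dtype=float))
        self.cell_weights = np.asarray(self.cell_weights, dtype=float)
        if self.cell_weights.shape != (self.memberships.shape[0],):
            raise ValueError("one weight per cell required")


@dataclass
class KHMFit:
    """Result of :func:`anneal_fit`: final centers/assignment, the final
    KHM loss, the per-sweep loss trace (always evaluated at T=1
    distances), and whether the final phase converged."""

    centers: ClusterCenters
    assignment: SoftAssignment
    loss: float
    trace: np.ndarray
    converged: bool


def _check_distances(distances) -> np.ndarray:
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be strictly positive and finite")
    return d


def khm_loss(distances, power: float) -> float:
    """KHM objective: sum over cells of k / sum_j d_ij^(-p)."""
    d = _check_distances(distances)
    k = d.shape[1]
    # log-space: log(k) - logsumexp(-p log d) per cell
    per_cell = np.exp(np.log(k) - logsumexp(-power * np.log(d), axis=1))
    return float(per_cell.sum())


def khm_soft_assignment(distances, power: float, temperature: float = 1.0) -> SoftAssignment:
    """Memberships and cell weights from annealed distances d^(1/T).

    m_ij = d'_ij^(-p-2) / sum_l d'_il^(-p-2);
    w_i  = (sum_j d'_ij^(-p-2)) / (sum_j d'_ij^(-p))^2.
    Computed in log space.
    """
    if temperature < 1.0:
        raise ValueError("temperature must be >= 1")
    d = _check_distances(distances)
    ld = np.log(d) / temperature
    m = softmax(-(power + 2.0) * ld, axis=1)
    log_w = logsumexp(-(power + 2.0) * ld, axis=1) - 2.0 * logsumexp(-power * ld, axis=1)
    return SoftAssignment(m, np.exp(log_w))


def update_centers(
    counts, assignment: SoftAssignment, centers: ClusterCenters, config: KHMConfig
) -> ClusterCenters:
    """Weighted binomial MLE center refit with add-one smoothing.

    For each unlocked cluster j and variant v the new fraction is
    (sum_i q_ij a_iv + 1) / (sum_i q_ij (a_iv + r_iv) + 2) with
    q_ij = m_ij w_i; sums implicitly run over cells covering v.  Locked
    clusters are copied through unchanged.
    """
    q = assignment.memberships * assignment.cell_weights[:, None]
    SA = (counts.alt_counts.T @ q).T  # (k, V)
    SN = (counts.depth().T @ q).T
    F = clamp_fractions((SA + 1.0) / (SN + 2.0), config.count_model)
    F = np.asarray(F)
    F[centers.locked] = centers.fractions[centers.locked]
    return ClusterCenters(F, centers.locked.copy())


def hard_assignment(memberships: np.ndarray) -> np.ndarray:
    """Argmax membership per cell; ties go to the lowest cluster id."""
    return np.argmax(np.atleast_2d(memberships), axis=1)


def _sweep_assignment(d: np.ndarray, temperature: float, config: KHMConfig) -> SoftAssignment:
    """Soft assignment for one sweep under the configured composition.

    Baselined mode shifts each cell's distances to start at the offset
    (scaled by temperature) and uses uniform cell weights at magnitude
    k: the KHM w_i would let the worst-fit cells dominate updates, and
    unit-scale weights would let the add-one smoothing overwhelm
    membership-diluted counts.
    """
    if config.baseline_offset is None:
        return khm_soft_assignment(d, config.power, temperature)
    shifted = d - d.min(axis=1, keepdims=True) + config.baseline_offset * temperature
    sa = khm_soft_assignment(shifted, config.power, 1.0)
    k = d.shape[1]
    return SoftAssignment(sa.memberships, np.full(d.shape[0], float(k)))


def anneal_fit(counts, centers: ClusterCenters, config: KHMConfig) -> KHMFit:
    """Run annealed KHM from the given initial centers.

    Sweeps (distance -> soft assignment -> center update) run
    ``inner_iters`` times at each temperature of the decaying schedule,
    then at ``t_min`` until the relative loss change drops below
    ``tol`` or the sweep cap is hit (the latter returns the best state
    with ``converged=False`` and a warning, never an exception).  The
    loss trace is always the KHM objective of the raw T=1 distances.
    """
    sch = config.schedule
    cm = config.count_model
    p = config.power
    temps = []
    T = sch.t_start
    while T > sch.t_min * (1.0 + 1e-12):
        temps.append(T)
        T *= sch.decay
    cur = centers.copy()
    trace: list[float] = []
    for T in temps:
        for _ in range(sch.inner_iters):
            d = distance_matrix(counts, cur.fractions, cm)
            trace.append(khm_loss(d, p))
            sa = _sweep_assignment(d, T, config)
            cur = update_centers(counts, sa, cur, config)
    converged = False
    prev = None
    for _ in range(sch.max_final_sweeps):
        d = distance_matrix(counts, cur.fractions, cm)
        loss = khm_loss(d, p)
        trace.append(loss)
        if prev is not None and abs(prev - loss) <= sch.tol * max(abs(loss), 1.0):
            converged = True
            break
        sa = _sweep_assignment(d, sch.t_min, config)
        cur = update_centers(counts, sa, cur, config)
        prev = loss
    if not converged:
        warnings.warn("KHM final phase hit the sweep cap before converging", RuntimeWarning)
        d = distance_matrix(counts, cur.fractions, cm)
        loss = khm_loss(d, p)
        trace.append(loss)
    final_assignment = _sweep_assignment(d, 1.0, config)
    return KHMFit(cur, final_assignment, float(loss), np.asarray(trace), converged)
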