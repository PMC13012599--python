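"""Allele-count likelihood model and the clustering distance derived from it.

A cluster center assigns every variant an alternate-allele fraction
``p``.  A cell that observes ``alt`` alternate and ``ref`` reference
reads at a variant contributes a binomial (default) or beta-binomial
log pmf term; summing over the variants the cell actually covers gives
the cell-to-center log likelihood.  The K-harmonic-means distance is
that log likelihood negated, plus a small epsilon so the harmonic mean
never divides by zero (cells covering no variants are equidistant from
every center at exactly ``distance_epsilon``).

Allele fractions are clamped into ``[fraction_floor, 1 - fraction_floor]``
before any pmf evaluation: a center must never assign probability zero
to an allele some cell actually carries, or the log likelihood would be
negative infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import betabinom, binom

FAMILIES = ("binomial", "beta_binomial")

# entries per chunk in the beta-binomial matrix path (bounds nnz * k memory)
_BB_CHUNK = 200_000


@dataclass(frozen=True)
class CountModelConfig:
    """Likelihood family and numerical guards.

    Parameters
    ----------
    family
        ``"binomial"`` (alt reads ~ Binomial(alt+ref, p)) or
        ``"beta_binomial"`` with mean ``p`` and concentration
        ``dispersion``; the latter converges to the binomial as the
        concentration grows.
    dispersion
        Beta-binomial concentration (alpha + beta); ignored for the
        binomial family.
    fraction_floor
        Allele fractions are clamped into ``[floor, 1 - floor]``.
    distance_epsilon
        Added to every negated log likelihood so distances are strictly
        positive.
    """

    family: str = "binomial"
    dispersion: float = 100.0
    fraction_floor: float = 0.01
    distance_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not 0.0 < self.fraction_floor < 0.5:
            raise ValueError("fraction_floor must be in (0, 0.5)")
        if not self.distance_epsilon > 0:
            raise ValueError("distance_epsilon must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")


def clamp_fractions(p, config: CountModelConfig):
    """Clamp allele fraction(s) into [fraction_floor, 1 - fraction_floor]."""
    lo = config.fraction_floor
    return np.clip(p, lo, 1.0 - lo)


def _site_log_pmf_vec(alt, ref, p, config: CountModelConfig) -> np.ndarray:
    """Per-site log pmf for aligned vectors of counts and fractions."""
    alt = np.asarray(alt, dtype=np.int64)
    ref = np.asarray(ref, dtype=np.int64)
    if np.any(alt < 0) or np.any(ref < 0):
        raise ValueError("allele counts must be nonnegative")
    p = clamp_fractions(np.asarray(p, dtype=float), config)
    n = alt + ref
    if config.family == "binomial":
        return binom.logpmf(alt, n, p)
    s = config.dispersion
    return betabinom.logpmf(alt, n, p * s, (1.0 - p) * s)


def site_log_pmf(alt: int, ref: int, p: float, config: CountModelConfig) -> float:
    """Log probability of observing ``alt``/``ref`` reads at alt fraction ``p``.

    Requires at least one read; the fraction is clamped before
    evaluation, so the result is always finite.
    """
    if alt < 0 or ref < 0:
        raise ValueError("allele counts must be nonnegative")
    if alt + ref < 1:
        raise ValueError("site_log_pmf needs at least one read")
    return float(_site_log_pmf_vec([alt], [ref], [p], config)[0])


def _observed_triplets(counts):
    """(rows, cols, alt, ref) over all (cell, variant) pairs with >= 1 read."""
    depth = counts.depth().tocoo()
    rows = depth.row
    cols = depth.col
    n = depth.data.astype(np.int64)
    a = np.asarray(counts.alt_counts[rows, cols]).ravel().astype(np.int64)
    return rows, cols, a, n - a


def cell_cluster_loglik(counts, cell: int, center: np.ndarray, config: CountModelConfig) -> float:
    """Sum of per-site log pmfs over the variants one cell covers.

    A cell that covers no variant contributes an empty sum (0.0):
    it carries no evidence for or against any center.
    """
    center = np.asarray(center, dtype=float)
    if center.shape != (counts.n_variants,):
        raise ValueError(
            f"center has length {center.shape[0] if center.ndim == 1 else center.shape}, "
            f"expected {counts.n_variants}"
        )
    row = counts.depth().getrow(cell)
    if row.nnz == 0:
        return 0.0
    idx = row.indices
    n = row.data.astype(np.int64)
    a = counts.alt_counts.getrow(cell).toarray().ravel()[idx].astype(np.int64)
    return float(np.sum(_site_log_pmf_vec(a, n - a, center[idx], config)))


def distance(counts, cell: int, center: np.ndarray, config: CountModelConfig) -> float:
    """KHM distance: negated cell-to-center log likelihood plus epsilon."""
    return -cell_cluster_loglik(counts, cell, center, config) + config.distance_epsilon


def loglik_matrix(counts, fractions: np.ndarray, config: CountModelConfig) -> np.ndarray:
    """Log likelihood of every cell against every center, (n_cells, k).

    The binomial path factors the pmf into a per-cell combinatorial
    constant plus sparse ``alt @ log(p)`` / ``ref @ log(1-p)`` products;
    the beta-binomial path evaluates gammaln terms per stored entry in
    chunks.  Only covered (cell, variant) pairs contribute, matching the
    per-cell sum of :func:`site_log_pmf`.
    """
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    if fractions.shape[1] != counts.n_variants:
        raise ValueError(
            f"centers have {fractions.shape[1]} variants, counts have {counts.n_variants}"
        )
    P = clamp_fractions(fractions, config)
    rows, cols, a, r = _observed_triplets(counts)
    n = a + r
    log_comb = gammaln(n + 1) - gammaln(a + 1) - gammaln(r + 1)
    if config.family == "binomial":
        A = counts.alt_counts.astype(np.float64)
        R = counts.ref_counts.astype(np.float64)
        L = A @ np.log(P).T + R @ np.log1p(-P).T
        L += np.bincount(rows, weights=log_comb, minlength=counts.n_cells)[:, None]
        return np.asarray(L)
    s = config.dispersion
    alpha = P * s  # (k, V)
    beta = (1.0 - P) * s
    base = log_comb + gammaln(s) - gammaln(n + s)  # per-entry, center-independent
    L = np.zeros((counts.n_cells, P.shape[0]))
    for start in range(0, rows.size, _BB_CHUNK):
        sl = slice(start, start + _BB_CHUNK)
        al = alpha[:, cols[sl]]  # (k, m)
        be = beta[:, cols[sl]]
        t = (
            gammaln(a[sl][None, :] + al)
            + gammaln(r[sl][None, :] + be)
            - gammaln(al)
            - gammaln(be)
            + base[sl][None, :]
        )
        np.add.at(L, rows[sl], t.T)
    return L


def distance_matrix(counts, fractions: np.ndarray, config: CountModelConfig) -> np.ndarray:
    """Strictly positive KHM distance of every cell to every center."""
    return -loglik_matrix(counts, fractions, config) + config.distance_epsilon
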