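"""Final per-cell calls: best singlet cluster, best doublet pair, verdict.

A cross-donor doublet contains RNA from two cells, so its expected alt
fraction at each variant is the mean of the two donors' fractions
(equal-contribution assumption).  For every cell the best singlet
log likelihood L_s (over k clusters) competes with the best doublet
log likelihood L_d (exhaustive over all k(k-1)/2 unordered pairs)
through the posterior

    P(singlet) = (1-pi) e^{L_s} / [ (1-pi) e^{L_s} + pi e^{L_d} ],

computed in log space, with pi the doublet prior.  Cells covering fewer
than ``min_coverage`` variants are reported unassigned: calls from a
handful of sites are noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .count_model import (
    CountModelConfig,
    cell_cluster_loglik,
    clamp_fractions,
    loglik_matrix,
)


@dataclass
class CellCall:
    """Verdict for one barcode.

    ``primary_cluster``/``secondary_cluster`` hold the doublet pair in
    ascending order for doublets; singlets set only the primary;
    unassigned cells set neither.
    """

    barcode: str
    status: str  # singlet | doublet | unassigned
    primary_cluster: int | None
    secondary_cluster: int | None
    singlet_logliks: np.ndarray
    best_doublet_loglik: float
    posterior_singlet: float

    def __post_init__(self) -> None:
        if self.status not in ("singlet", "doublet", "unassigned"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "doublet":
            if self.primary_cluster is None or self.secondary_cluster is None:
                raise ValueError("doublet calls need both clusters")
            if self.primary_cluster == self.secondary_cluster:
                raise ValueError("doublet clusters must differ")
        if self.status == "singlet" and self.secondary_cluster is not None:
            raise ValueError("singlet calls carry no secondary cluster")
        if not 0.0 <= self.posterior_singlet <= 1.0:
            raise ValueError("posterior_singlet must be a probability")


def doublet_loglik(
    counts, cell: int, center_a: np.ndarray, center_b: np.ndarray, config: CountModelConfig
) -> float:
    """Cell log likelihood against the synthetic doublet center (a+b)/2."""
    mixed = clamp_fractions(
        0.5 * (np.asarray(center_a, float) + np.asarray(center_b, float)), config
    )
    return cell_cluster_loglik(counts, cell, mixed, config)


def _pair_list(k: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(k) for b in range(a + 1, k)]


def genotype_levels(
    fractions: np.ndarray,
    error: float = 0.02,
    hom_ref_max: float = 0.2,
    hom_alt_min: float = 0.8,
) -> np.ndarray:
    """Snap fitted allele fractions to diploid genotype levels.

    Donors are diploid, so a cluster's true per-site alt fraction is 0,
    1/2, or 1 (up to sequencing error).  Fitted fractions are shrunk
    toward the middle by smoothing and soft-membership contamination,
    which flatters the singlet model when scoring doublets; calling
    works on {error, 0.5, 1 - error} instead.
    """
    f = np.asarray(fractions, dtype=float)
    return np.where(f < hom_ref_max, error, np.where(f > hom_alt_min, 1.0 - error, 0.5))


def call_cells(
    counts,
    centers,
    config: CountModelConfig = CountModelConfig(),
    doublet_prior: float = 0.08,
    min_coverage: int = 10,
    discretize: bool = True,
    genotype_error: float = 0.02,
) -> list[CellCall]:
    """Call every barcode singlet/doublet/unassigned.

    The pair search is exact over all unordered cluster pairs.  With
    ``doublet_prior=0`` the doublet channel is closed and every covered
    cell is a singlet.  The doublet pair reported is the best-scoring
    one, written in ascending cluster order.  By default centers are
    snapped to diploid genotype levels before scoring (see
    :func:`genotype_levels`).
    """
    if not 0.0 <= doublet_prior < 1.0:
        raise ValueError("doublet_prior must be in [0, 1)")
    P = np.asarray(centers.fractions, dtype=float)
    if discretize:
        P = genotype_levels(P, error=genotype_error)
    k = P.shape[0]
    Ls_mat = loglik_matrix(counts, P, config)
    best_j = np.argmax(Ls_mat, axis=1)
    Ls = Ls_mat[np.arange(counts.n_cells), best_j]
    pairs = _pair_list(k)
    if pairs and doublet_prior > 0.0:
        mixed = clamp_fractions(
            np.stack([0.5 * (P[a] + P[b]) for a, b in pairs]), config
        )
        Ld_mat = loglik_matrix(counts, mixed, config)
        best_pair_idx = np.argmax(Ld_mat, axis=1)
        Ld = Ld_mat[np.arange(counts.n_cells), best_pair_idx]
    else:
        best_pair_idx = np.zeros(counts.n_cells, dtype=int)
        Ld = np.full(counts.n_cells, -np.inf)
    with np.errstate(divide="ignore"):
        log_pi = np.log(doublet_prior) if doublet_prior > 0 else -np.inf
    log_1mpi = np.log1p(-doublet_prior)
    ls = log_1mpi + Ls
    ld = log_pi + Ld
    log_post_s = ls - np.logaddexp(ls, ld)
    post_s = np.exp(log_post_s)
    coverage = counts.sites_per_cell()
    calls = []
    for i, bc in enumerate(counts.barcodes):
        if coverage[i] < min_coverage:
            status, primary, secondary = "unassigned", None, None
        elif post_s[i] < 0.5:
            a, b = pairs[best_pair_idx[i]]
            status, primary, secondary = "doublet", a, b
        else:
            status, primary, secondary = "singlet", int(best_j[i]), None
        calls.append(
            CellCall(
                barcode=bc,
                status=status,
                primary_cluster=primary,
                secondary_cluster=secondary,
                singlet_logliks=Ls_mat[i].copy(),
                best_doublet_loglik=float(Ld[i]),
                posterior_singlet=float(post_s[i]),
            )
        )
    return calls
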