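"""10x merge cluster-center initialization.

Sparse allele-count data defeats kmeans++-style seeding: a single cell
covers only ~5% of variants, so most coordinates of a cell-seeded
center are undefined and cell-to-center distances are dominated by
missingness.  The strategy here over-generates centers — ten per
expected donor, each seeded from a random cell with add-one-smoothed
fractions at covered sites and the dataset-wide smoothed fraction
elsewhere — then greedily merges the closest pair (coverage-weighted
squared difference; merged center = the per-variant mean of its two
parents) until k remain.  Surviving centers are pairwise distant,
which protects against splitting one true donor across two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_model import CountModelConfig, clamp_fractions


@dataclass
class ClusterCenters:
    """k x V matrix of per-cluster alt-allele fractions plus lock flags.

    A locked cluster's fractions are held bit-identical through center
    updates (used by the refinement stage).
    """

    fractions: np.ndarray
    locked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fractions = np.atleast_2d(np.asarray(self.fractions, dtype=float))
        if self.locked is None:
            self.locked = np.zeros(self.fractions.shape[0], dtype=bool)
        self.locked = np.asarray(self.locked, dtype=bool)
        if not np.all(np.isfinite(self.fractions)):
            raise ValueError("cluster fractions must be finite")
        if self.locked.shape != (self.fractions.shape[0],):
            raise ValueError("locked flags must have one entry per cluster")

    @property
    def k(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_variants(self) -> int:
        return self.fractions.shape[1]

    def copy(self) -> "ClusterCenters":
        return ClusterCenters(self.fractions.copy(), self.locked.copy())


def variant_weights(counts) -> np.ndarray:
    """Total allele (read) count per variant across all cells."""
    w = np.asarray(counts.depth().sum(axis=0)).ravel().astype(float)
    if not np.any(w > 0):
        raise ValueError("no variant has any reads")
    return w


def dataset_fill_fractions(counts, config: CountModelConfig) -> np.ndarray:
    """Dataset-wide smoothed alt fraction per variant: (alt+1)/(alt+ref+2)."""
    alt_tot = np.asarray(counts.alt_counts.sum(axis=0)).ravel().astype(float)
    tot = np.asarray(counts.depth().sum(axis=0)).ravel().astype(float)
    return clamp_fractions((alt_tot + 1.0) / (tot + 2.0), config)


def centers_from_cells(counts, cell_indices, config: CountModelConfig) -> np.ndarray:
    """One center per listed cell: smoothed fractions where the cell has
    reads, the dataset fill fraction everywhere else."""
    fill = dataset_fill_fractions(counts, config)
    cell_indices = np.asarray(cell_indices, dtype=int)
    F = np.tile(fill, (cell_indices.size, 1))
    depth = counts.depth()
    for out_i, c in enumerate(cell_indices):
        row = depth.getrow(c)
        if row.nnz == 0:
            continue
        idx = row.indices
        n = row.data.astype(float)
        a = counts.alt_counts.getrow(c).toarray().ravel()[idx].astype(float)
        F[out_i, idx] = (a + 1.0) / (n + 2.0)
    return clamp_fractions(F, config)


def random_centers(
    counts, n: int, config: CountModelConfig, seed: int, cell_pool=None
) -> ClusterCenters:
    """``n`` preliminary centers seeded from distinct uniformly sampled cells."""
    pool = np.arange(counts.n_cells) if cell_pool is None else np.asarray(cell_pool, dtype=int)
    if n > pool.size:
        raise ValueError(f"cannot seed {n} centers from {pool.size} cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool, size=n, replace=False)
    return ClusterCenters(centers_from_cells(counts, idx, config))


def merge_distance(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    """Coverage-weighted squared difference between two centers."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(w, dtype=float)
    if a.shape != b.shape or a.shape != w.shape:
        raise ValueError(f"length mismatch: {a.shape}, {b.shape}, weights {w.shape}")
    return float(np.sum(w * (a - b) ** 2))


def merge_to_k(centers: ClusterCenters, k: int, w: np.ndarray, return_trace: bool = False):
    """Greedily merge the closest center pair until exactly ``k`` remain.

    Each merge replaces the closest pair (ties broken by the lowest
    (i, j) index pair) with the per-variant mean of the two parents,
    regardless of how many original centers each parent subsumes.
    Deterministic.  With ``return_trace`` also returns the merged-pair
    distances in merge order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > centers.k:
        raise ValueError(f"cannot merge {centers.k} centers up to {k}")
    if k == centers.k:
        return (centers, []) if return_trace else centers
    w = np.asarray(w, dtype=float)
    X = centers.fractions.copy()
    n = X.shape[0]
    Xw = X * np.sqrt(w)[None, :]
    # full pairwise weighted squared-difference matrix; dead rows/cols -> inf
    sq = np.sum(Xw**2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (Xw @ Xw.T)
    np.clip(D, 0.0, None, out=D)
    np.fill_diagonal(D, np.inf)
    D[np.tril_indices(n)] = np.inf  # keep only i < j; row-major argmin = lex tie-break
    alive = np.ones(n, dtype=bool)
    trace = []
    for _ in range(n - k):
        flat = int(np.argmin(D))
        i, j = divmod(flat, n)
        trace.append(float(D[i, j]))
        X[i] = 0.5 * (X[i] + X[j])
        Xw[i] = X[i] * np.sqrt(w)
        alive[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        d_new = np.sum((Xw[alive] - Xw[i]) ** 2, axis=1)
        ai = np.flatnonzero(alive)
        lo = ai[ai < i]
        hi = ai[ai > i]
        D[lo, i] = d_new[np.searchsorted(ai, lo)]
        D[i, hi] = d_new[np.searchsorted(ai, hi)]
    out = ClusterCenters(X[alive])
    return (out, trace) if return_trace else out


def initialize_10x(counts, k: int, config: CountModelConfig, seed: int) -> ClusterCenters:
    """Full initializer: 10*k random cell-seeded centers merged down to k.

    If the dataset has fewer than 10*k cells, every cell seeds a center.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_prelim = min(10 * k, counts.n_cells)
    if n_prelim < k:
        raise ValueError(f"need at least {k} cells to initialize {k} clusters")
    prelim = random_centers(counts, n_prelim, config, seed)
    return merge_to_k(prelim, k, variant_weights(counts))
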