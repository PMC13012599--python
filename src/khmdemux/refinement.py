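"""Iterative cluster refinement: fix merged and starved clusters.

After a fit, each cluster is scored on two signals — how many cells it
claims and the mean distance of its members to its center.  Robust
z-scores (median/MAD) on either signal flag outliers: starved or empty
clusters, and clusters whose members fit badly (the signature of two
donors sharing one center).

Repair pairs the two failure modes: a flagged high-loss cluster that
still holds plenty of cells is *split* in two by a leave-one-out
reassignment restricted to its members, and the halves take over the
source slot and a flagged starved slot.  Flagged slots with no source
to pair with are reseeded by the 10x merge strategy from the worst-fit
cells.  A random fraction of the healthy clusters is locked, KHM is
rerun, and the new state is kept only if the total best-cluster
distance improves — otherwise the previous state is restored and
refinement stops.  The loop repeats until no outliers remain or the
round cap is hit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .count_model import distance_matrix
from .discover import DiscoverConfig, discover_donors
from .initialization import ClusterCenters, centers_from_cells, merge_to_k, variant_weights
from .khm import KHMConfig, KHMFit, SoftAssignment, anneal_fit, hard_assignment


@dataclass(frozen=True)
class ClusterQuality:
    cluster_id: int
    n_cells: int
    mean_loss: float
    is_outlier: bool


@dataclass(frozen=True)
class RefineConfig:
    """Outlier thresholds and refit policy.

    ``size_z_cut`` / ``loss_z_cut`` are robust z-score cuts on
    log(1 + cluster size) and mean member distance.  ``lock_fraction``
    of the non-outlier clusters is locked each round (resampled every
    round unless ``persist_locks``).  ``reinit_from_worst`` makes the
    fallback reseeding sample from the worst-fit quartile of cells
    instead of uniformly.
    """

    size_z_cut: float = 2.5
    loss_z_cut: float = 2.5
    lock_fraction: float = 0.5
    max_rounds: int = 10
    seed: int = 0
    reinit_from_worst: bool = True
    persist_locks: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.lock_fraction <= 1.0:
            raise ValueError("lock_fraction must be in [0, 1]")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass(frozen=True)
class RoundInfo:
    """Diagnostics for one refinement round."""

    outlier_ids: tuple
    split_pairs: tuple  # ((source, slot), ...)
    n_preliminary: int  # preliminary centers drawn by the fallback reseeder
    locked_ids: tuple
    accepted: bool


@dataclass
class RefineResult:
    centers: ClusterCenters
    assignment: SoftAssignment
    rounds_used: int
    clean: bool
    rounds: list
    fit: KHMFit | None = None


def _robust_z(x: np.ndarray) -> tuple[np.ndarray, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * 1.4826
    if mad == 0.0:
        return np.zeros_like(x), 0.0
    return (x - med) / mad, mad


def score_clusters(
    counts, centers: ClusterCenters, assignment: SoftAssignment,
    khm_config: KHMConfig, refine_config: RefineConfig = RefineConfig(),
) -> list[ClusterQuality]:
    """Size and mean-loss per cluster with robust-z outlier flags.

    Zero-coverage cells are excluded from the mean loss; an empty
    cluster is always a size outlier.  When the MAD of a signal is
    zero (no dispersion across clusters) that signal flags nothing
    beyond empty clusters.
    """
    k = centers.k
    d = distance_matrix(counts, centers.fractions, khm_config.count_model)
    hard = hard_assignment(assignment.memberships)
    covered = counts.sites_per_cell() > 0
    sizes = np.bincount(hard, minlength=k)
    mean_loss = np.zeros(k)
    for j in range(k):
        members = (hard == j) & covered
        if members.any():
            mean_loss[j] = float(d[members, j].mean())
    z_size, mad_size = _robust_z(np.log1p(sizes.astype(float)))
    z_loss, mad_loss = _robust_z(mean_loss)
    size_out = (sizes == 0) | ((mad_size > 0) & (z_size < -refine_config.size_z_cut))
    loss_out = (mad_loss > 0) & (z_loss > refine_config.loss_z_cut)
    flags = size_out | loss_out
    return [
        ClusterQuality(j, int(sizes[j]), float(mean_loss[j]), bool(flags[j]))
        for j in range(k)
    ]


def reinitialize_outliers(
    counts, centers: ClusterCenters, outlier_ids, khm_config: KHMConfig,
    refine_config: RefineConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Fresh fractions for outlier clusters via the 10x merge strategy.

    Draws ten preliminary cell-seeded centers per outlier (capped by
    the candidate pool) and merges them down to one per outlier.
    Candidates are the covered cells with the worst per-site
    best-cluster distance (worst quartile, at least the number of
    preliminary centers) when ``reinit_from_worst`` is set, otherwise
    all covered cells.  Returns the merged fractions and the number of
    preliminary centers drawn.
    """
    m = len(outlier_ids)
    covered = np.flatnonzero(counts.sites_per_cell() > 0)
    if refine_config.reinit_from_worst:
        d = distance_matrix(counts, centers.fractions, khm_config.count_model)
        per_site = d[covered].min(axis=1) / counts.sites_per_cell()[covered]
        order = covered[np.argsort(-per_site, kind="stable")]
        pool = order[: max(10 * m, math.ceil(0.25 * covered.size))]
    else:
        pool = covered
    n_prelim = min(10 * m, pool.size)
    idx = rng.choice(pool, size=n_prelim, replace=False)
    prelim = ClusterCenters(centers_from_cells(counts, idx, khm_config.count_model))
    merged = merge_to_k(prelim, m, variant_weights(counts))
    return merged.fractions, n_prelim


def _split_cluster(counts, members: np.ndarray, khm_config: KHMConfig, seed: int):
    """Two-way leave-one-out split of one cluster's member cells.

    Returns the two half profiles, or None when the membership is too
    small or the split degenerates (one empty half).
    """
    if members.size < 4:
        return None
    from .allele_io import AlleleCountMatrix  # deferred: avoid import cycle at module load

    sub = AlleleCountMatrix(
        counts.ref_counts[members],
        counts.alt_counts[members],
        [counts.barcodes[i] for i in members],
        counts.variants,
    )
    disc = discover_donors(sub, 2, khm_config.count_model, DiscoverConfig(seed=seed))
    n0 = int((disc.labels == 0).sum())
    if min(n0, members.size - n0) < 2:
        return None
    return disc.profiles[0], disc.profiles[1]


def refine(
    counts, centers: ClusterCenters, assignment: SoftAssignment,
    khm_config: KHMConfig, refine_config: RefineConfig = RefineConfig(),
) -> RefineResult:
    """Score -> repair outliers -> lock -> refit, up to ``max_rounds``.

    Returns immediately (rounds_used = 0) when the first scoring finds
    no outliers.  Deterministic given ``refine_config.seed``.  Each
    round's refit is kept only when it lowers the total best-cluster
    distance; a rejected round restores the previous state and ends
    the loop.  Hitting the cap with outliers remaining returns the
    best state with ``clean=False`` and a warning.
    """
    k = centers.k
    cur_c, cur_a = centers, assignment
    cur_score = float(
        distance_matrix(counts, cur_c.fractions, khm_config.count_model).min(axis=1).sum()
    )
    rounds: list[RoundInfo] = []
    last_fit: KHMFit | None = None
    persistent_locks = np.zeros(k, dtype=bool)
    rounds_used = 0
    for r in range(refine_config.max_rounds):
        quality = score_clusters(counts, cur_c, cur_a, khm_config, refine_config)
        outliers = [q for q in quality if q.is_outlier]
        if not outliers:
            return RefineResult(cur_c, cur_a, rounds_used, True, rounds, last_fit)
        rng = np.random.default_rng([refine_config.seed, r])
        hard = hard_assignment(cur_a.memberships)
        median_size = float(np.median([q.n_cells for q in quality]))
        sources = sorted(
            (q for q in outliers if q.n_cells >= 0.5 * median_size and q.n_cells >= 4),
            key=lambda q: -q.mean_loss,
        )
        slots = sorted(
            (q for q in outliers if q.n_cells < 0.5 * median_size or q.n_cells < 4),
            key=lambda q: q.n_cells,
        )
        F = cur_c.fractions.copy()
        split_pairs = []
        unused_slots = []
        si = 0
        for slot in slots:
            done = False
            while si < len(sources):
                src = sources[si]
                si += 1
                halves = _split_cluster(
                    counts, np.flatnonzero(hard == src.cluster_id), khm_config,
                    seed=refine_config.seed * 1000 + r * 10 + si,
                )
                if halves is not None:
                    F[src.cluster_id] = halves[0]
                    F[slot.cluster_id] = halves[1]
                    split_pairs.append((src.cluster_id, slot.cluster_id))
                    done = True
                    break
            if not done:
                unused_slots.append(slot.cluster_id)
        n_prelim = 0
        if unused_slots:
            new_fracs, n_prelim = reinitialize_outliers(
                counts, cur_c, unused_slots, khm_config, refine_config, rng
            )
            F[unused_slots] = new_fracs
        touched = {c for pair in split_pairs for c in pair} | set(unused_slots)
        non_outlier_ids = np.array(
            [q.cluster_id for q in quality if not q.is_outlier], dtype=int
        )
        locked = persistent_locks.copy()
        locked[list(touched)] = False
        locked_ids: tuple = ()
        n_lock = math.ceil(refine_config.lock_fraction * non_outlier_ids.size)
        if n_lock > 0 and non_outlier_ids.size > 0:
            if not refine_config.persist_locks:
                locked[:] = False
            lockable = non_outlier_ids[~locked[non_outlier_ids]]
            n_new = min(n_lock if not refine_config.persist_locks
                        else max(n_lock - int(locked.sum()), 0), lockable.size)
            if n_new > 0:
                chosen = np.sort(rng.choice(lockable, size=n_new, replace=False))
                locked[chosen] = True
                locked_ids = tuple(int(c) for c in chosen)
        fit = anneal_fit(counts, ClusterCenters(F, locked), khm_config)
        new_score = float(
            distance_matrix(counts, fit.centers.fractions, khm_config.count_model)
            .min(axis=1).sum()
        )
        accepted = new_score < cur_score * (1.0 - 1e-12)
        rounds.append(
            RoundInfo(
                tuple(q.cluster_id for q in outliers),
                tuple(split_pairs), n_prelim, locked_ids, accepted,
            )
        )
        rounds_used = r + 1
        if not accepted:
            break
        cur_score = new_score
        last_fit = fit
        if refine_config.persist_locks:
            persistent_locks = locked
            cur_c = ClusterCenters(fit.centers.fractions.copy(), locked.copy())
        else:
            cur_c = ClusterCenters(fit.centers.fractions.copy())
        cur_a = fit.assignment
    quality = score_clusters(counts, cur_c, cur_a, khm_config, refine_config)
    clean = not any(q.is_outlier for q in quality)
    if not clean:
        warnings.warn(
            "refinement stopped with outlier clusters remaining", RuntimeWarning
        )
    return RefineResult(cur_c, cur_a, rounds_used, clean, rounds, last_fit)
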