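"""Library-level orchestration of the full demultiplexing pipeline.

Stages: 10x-merge initialization, a first annealed KHM fit, donor
discovery by leave-one-out reassignment (seeded from the fit's hard
assignment — this is what lets the pipeline scale to high donor
counts), a second annealed KHM fit polishing the discovered profiles,
outlier-cluster refinement, and finally per-cell singlet/doublet calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assignment import CellCall, call_cells
from .count_model import CountModelConfig
from .discover import DiscoverConfig, DiscoveryResult, discover_donors
from .initialization import ClusterCenters, initialize_10x
from .khm import KHMConfig, KHMFit, SoftAssignment, anneal_fit, hard_assignment
from .refinement import RefineConfig, RefineResult, refine


@dataclass
class DemuxResult:
    centers: ClusterCenters
    assignment: SoftAssignment
    calls: list[CellCall]
    initial_fit: KHMFit
    discovery: DiscoveryResult
    polish_fit: KHMFit
    refinement: RefineResult


def demultiplex(
    counts,
    k: int,
    seed: int = 0,
    count_model: CountModelConfig | None = None,
    khm_config: KHMConfig | None = None,
    discover_config: DiscoverConfig | None = None,
    refine_config: RefineConfig | None = None,
    doublet_prior: float = 0.08,
    min_coverage: int = 10,
) -> DemuxResult:
    """Cluster cells by genotype and call each barcode.

    Deterministic given ``seed``; the discovery and refinement stages
    derive their own seeded streams from it unless explicit configs are
    given.
    """
    cm = count_model or CountModelConfig()
    kc = khm_config or KHMConfig(count_model=cm, seed=seed)
    dc = discover_config or DiscoverConfig(seed=seed + 1)
    rc = refine_config or RefineConfig(seed=seed + 2)
    init = initialize_10x(counts, k, kc.count_model, seed)
    fit = anneal_fit(counts, init, kc)
    disc = discover_donors(
        counts, k, kc.count_model, dc, z_init=hard_assignment(fit.assignment.memberships)
    )
    polish = anneal_fit(counts, ClusterCenters(disc.profiles), kc)
    ref = refine(counts, polish.centers, polish.assignment, kc, rc)
    calls = call_cells(
        counts,
        ref.centers,
        config=kc.count_model,
        doublet_prior=doublet_prior,
        min_coverage=min_coverage,
    )
    return DemuxResult(ref.centers, ref.assignment, calls, fit, disc, polish, ref)
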