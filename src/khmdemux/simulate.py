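"""Synthetic pooled-mixture generator with ground truth.

Emulates the statistical structure of a multiplexed scRNA-seq
experiment as seen through SNP allele counts:

* D donor genotypes over V biallelic variants: population alt-allele
  frequency f ~ Beta(maf_alpha, maf_beta) per site, dosages drawn
  Binomial(2, f) per donor (Hardy-Weinberg).
* Each barcode draws its donor(s) from ``donor_proportions``; with
  probability ``doublet_rate`` it is a doublet carrying a second,
  distinct donor.
* Coverage is independent per (cell, variant) pair at probability
  ``coverage_density`` (real SNP count matrices are ~5% dense); covered
  sites draw 1 + Poisson(depth_mean - 1) total reads.
* The expected alt fraction is dosage/2 for singlets and the average of
  the two donors' dosages over 4 for doublets (equal RNA contribution),
  perturbed by a symmetric base-miscall rate:
  p_eff = p (1 - e) + (1 - p) e.  Alt reads ~ Binomial(total, p_eff).

Defaults target the sparse, low-depth regime of real data: 5% density,
mean depth 2, 0.5% error, allele frequencies skewed rare (Beta(1, 3)).
No gene-length, expression, ambient-RNA, or UMI structure is modeled —
the clustering only ever sees counts at SNP sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .allele_io import AlleleCountMatrix, VariantSite, write_variant_sites

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    n_donors: int = 8
    n_cells: int = 800
    n_variants: int = 1000
    maf_alpha: float = 1.0
    maf_beta: float = 3.0
    coverage_density: float = 0.05
    depth_mean: float = 2.0
    error_rate: float = 0.005
    doublet_rate: float = 0.0
    donor_proportions: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("need at least one donor")
        if not 0.0 < self.coverage_density <= 1.0:
            raise ValueError("coverage_density must be in (0, 1]")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.depth_mean < 1.0:
            raise ValueError("depth_mean must be >= 1 (covered sites have >= 1 read)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.donor_proportions is not None:
            p = np.asarray(self.donor_proportions, dtype=float)
            if p.shape != (self.n_donors,):
                raise ValueError("donor_proportions must have one entry per donor")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("donor_proportions must be a simplex")

    def proportions(self) -> np.ndarray:
        if self.donor_proportions is None:
            return np.full(self.n_donors, 1.0 / self.n_donors)
        return np.asarray(self.donor_proportions, dtype=float)


@dataclass
class SimTruth:
    """Ground truth: genotypes (D x V dosages in {0,1,2}), each cell's
    donor(s) (cell_donor2 = -1 for singlets), and doublet flags."""

    genotypes: np.ndarray
    cell_donor: np.ndarray
    cell_donor2: np.ndarray
    is_doublet: np.ndarray


def simulate_genotypes(config: SimConfig) -> np.ndarray:
    """D x V alt-allele dosage matrix under Hardy-Weinberg equilibrium."""
    rng = np.random.default_rng([config.seed, 0])
    f = rng.beta(config.maf_alpha, config.maf_beta, size=config.n_variants)
    return rng.binomial(2, f[None, :], size=(config.n_donors, config.n_variants)).astype(np.int8)


def _barcode(i: int) -> str:
    # deterministic 16-mer (base-4 encoding of the cell index), 10x-style
    return "".join(_BASES[(i >> (2 * j)) & 3] for j in range(16)) + "-1"


def _variant_sites(config: SimConfig, rng: np.random.Generator) -> list[VariantSite]:
    sites = []
    for v in range(config.n_variants):
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(VariantSite("1", 100 * (v + 1), _BASES[ref], _BASES[alt]))
    return sites


def simulate_cells(genotypes: np.ndarray, config: SimConfig) -> tuple[AlleleCountMatrix, SimTruth]:
    """Draw the sparse ref/alt count matrices and ground truth labels."""
    D, V = genotypes.shape
    if D != config.n_donors or V != config.n_variants:
        raise ValueError("genotype matrix does not match config dimensions")
    n = config.n_cells
    rng = np.random.default_rng([config.seed, 1])
    props = config.proportions()
    donor1 = rng.choice(D, size=n, p=props)
    is_doublet = rng.random(n) < config.doublet_rate
    donor2 = np.full(n, -1, dtype=int)
    for i in np.flatnonzero(is_doublet):
        p2 = props.copy()
        p2[donor1[i]] = 0.0
        p2 /= p2.sum()
        donor2[i] = rng.choice(D, p=p2)
    covered = rng.random((n, V)) < config.coverage_density
    rows, cols = np.nonzero(covered)
    total = 1 + rng.poisson(config.depth_mean - 1.0, size=rows.size)
    dose = genotypes[donor1[rows], cols].astype(float)
    p = dose / 2.0
    dbl = is_doublet[rows]
    if dbl.any():
        dose2 = genotypes[donor2[rows[dbl]], cols[dbl]].astype(float)
        p[dbl] = (dose[dbl] + dose2) / 4.0
    e = config.error_rate
    p_eff = p * (1.0 - e) + (1.0 - p) * e
    alt = rng.binomial(total, p_eff)
    ref = total - alt
    shape = (n, V)
    alt_m = sp.coo_matrix((alt, (rows, cols)), shape=shape).tocsr()
    ref_m = sp.coo_matrix((ref, (rows, cols)), shape=shape).tocsr()
    barcodes = [_barcode(i) for i in range(n)]
    sites = _variant_sites(config, np.random.default_rng([config.seed, 2]))
    counts = AlleleCountMatrix(ref_m, alt_m, barcodes, sites)
    truth = SimTruth(genotypes, donor1, donor2, is_doublet)
    return counts, truth


def simulate_dataset(config: SimConfig) -> tuple[AlleleCountMatrix, SimTruth]:
    """Genotypes plus cells in one call."""
    return simulate_cells(simulate_genotypes(config), config)


def write_sim(counts: AlleleCountMatrix, truth: SimTruth, outdir) -> dict:
    """Emit ref.mtx / alt.mtx (variants x cells), barcodes.tsv,
    variants.vcf, and truth.tsv; all readable by allele_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref": outdir / "ref.mtx",
        "alt": outdir / "alt.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "vcf": outdir / "variants.vcf",
        "truth": outdir / "truth.tsv",
    }
    scipy.io.mmwrite(str(paths["ref"]), counts.ref_counts.T.tocoo(), field="integer")
    scipy.io.mmwrite(str(paths["alt"]), counts.alt_counts.T.tocoo(), field="integer")
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(bc + "\n" for bc in counts.barcodes)
    write_variant_sites(counts.variants, paths["vcf"])
    pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "donor": truth.cell_donor,
            "donor2": truth.cell_donor2,
            "is_doublet": truth.is_doublet.astype(int),
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str})
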