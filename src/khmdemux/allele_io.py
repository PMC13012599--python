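"""Readers and writers for the demultiplexing pipeline's file formats.

On disk the ref/alt count matrices follow the vartrix/cellSNP
convention: MatrixMarket coordinate format, variants x cells, 1-based
indices.  In memory everything is cells x variants (cells are the
clustered items) with 0-based indices.  Variant sites come from a VCF;
cell calls go out as TSV; cluster genotypes go out as a per-cluster
sample column in a VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse as sp


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are both {self.ref_allele!r}")


def _as_count_csr(mat, name: str) -> sp.csr_matrix:
    m = sp.csr_matrix(mat)
    m.sum_duplicates()
    if m.nnz:
        data = m.data
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError(f"{name} matrix contains non-integer values")
        if data.min() < 0:
            raise ValueError(f"{name} matrix contains negative counts")
    return m.astype(np.int64)


@dataclass
class AlleleCountMatrix:
    """Sparse per-cell, per-variant ref and alt read counts.

    Entries absent from the sparse matrices mean "no reads"; an
    explicitly stored zero is equivalent except in storage.
    """

    ref_counts: sp.csr_matrix
    alt_counts: sp.csr_matrix
    barcodes: list[str]
    variants: list[VariantSite]
    _depth: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ref_counts = _as_count_csr(self.ref_counts, "ref")
        self.alt_counts = _as_count_csr(self.alt_counts, "alt")
        if self.ref_counts.shape != self.alt_counts.shape:
            raise ValueError(
                f"ref matrix is {self.ref_counts.shape} but alt matrix is "
                f"{self.alt_counts.shape}"
            )
        n_cells, n_variants = self.ref_counts.shape
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix cells"
            )
        if len(self.variants) != n_variants:
            raise ValueError(
                f"{len(self.variants)} variant records for {n_variants} matrix variants"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")

    @property
    def n_cells(self) -> int:
        return self.ref_counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.ref_counts.shape[1]

    def depth(self) -> sp.csr_matrix:
        """Total reads (alt + ref) per (cell, variant); cached."""
        if self._depth is None:
            d = (self.alt_counts + self.ref_counts).tocsr()
            d.sum_duplicates()
            self._depth = d
        return self._depth

    def sites_per_cell(self) -> np.ndarray:
        """Number of variants with >= 1 read, per cell."""
        return np.diff(self.depth().indptr)


def read_barcodes(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_vcf_sites(path) -> list[VariantSite]:
    """Variant records from a VCF; multiallelic records are rejected."""
    sites = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multiallelic or alt-less record at {rec.chrom}:{rec.pos}; "
                    "split multiallelic sites upstream"
                )
            sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    return sites


def read_allele_matrices(ref_path, alt_path, barcodes_path, vcf_path) -> AlleleCountMatrix:
    """Load a vartrix-style triplet (ref.mtx, alt.mtx, barcodes, VCF).

    The on-disk matrices are variants x cells and are transposed to
    cells x variants; duplicate coordinate entries are summed
    (MatrixMarket semantics).
    """
    ref = sp.coo_matrix(scipy.io.mmread(str(ref_path)))
    alt = sp.coo_matrix(scipy.io.mmread(str(alt_path)))
    if ref.shape != alt.shape:
        raise ValueError(
            f"ref matrix declares {ref.shape[0]}x{ref.shape[1]} but alt matrix "
            f"declares {alt.shape[0]}x{alt.shape[1]}"
        )
    barcodes = read_barcodes(barcodes_path)
    variants = read_vcf_sites(vcf_path)
    n_var, n_cells = ref.shape
    if len(variants) != n_var:
        raise ValueError(f"VCF has {len(variants)} records but matrices declare {n_var} variants")
    if len(barcodes) != n_cells:
        raise ValueError(f"{len(barcodes)} barcodes but matrices declare {n_cells} cells")
    return AlleleCountMatrix(ref.T.tocsr(), alt.T.tocsr(), barcodes, variants)


_CALL_FIXED_COLS = ["barcode", "status", "assignment", "log_prob_singlet", "log_prob_doublet"]


def write_cell_calls(calls, path) -> None:
    """Write per-barcode calls as TSV, one row per cell, input order kept.

    Columns: barcode, status (singlet|doublet|unassigned), assignment
    (cluster id, "a/b" for doublets, "NA" for unassigned), log posterior
    probabilities of the singlet and doublet hypotheses, then one
    log-likelihood column per cluster.  Floats are written with full
    ``repr`` precision so a parse reproduces them exactly.
    """
    if not calls:
        raise ValueError("no calls to write")
    k = len(calls[0].singlet_logliks)
    header = _CALL_FIXED_COLS + [f"cluster{j}" for j in range(k)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in calls:
            if c.status == "doublet":
                assignment = f"{c.primary_cluster}/{c.secondary_cluster}"
            elif c.status == "singlet":
                assignment = str(c.primary_cluster)
            else:
                assignment = "NA"
            with np.errstate(divide="ignore"):
                lps = float(np.log(c.posterior_singlet))
                lpd = float(np.log1p(-c.posterior_singlet))
            row = [c.barcode, c.status, assignment, repr(lps), repr(lpd)]
            row += [repr(float(x)) for x in c.singlet_logliks]
            fh.write("\t".join(row) + "\n")


def read_cell_calls(path) -> pd.DataFrame:
    """Parse a cell-calls TSV back into a DataFrame (exact float round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "status": str, "assignment": str})
    return df


def _genotype(fraction: float, hom_ref_max: float, hom_alt_min: float) -> tuple[int, int]:
    if fraction < hom_ref_max:
        return (0, 0)
    if fraction > hom_alt_min:
        return (1, 1)
    return (0, 1)


def _contig_header(variants) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    seen = {}
    for site in variants:
        seen.setdefault(site.chrom, 0)
        seen[site.chrom] = max(seen[site.chrom], site.pos)
    for chrom, maxpos in seen.items():
        header.contigs.add(chrom, length=maxpos + 1000)
    return header


def write_variant_sites(variants, path) -> None:
    """Write a sites-only VCF (no sample columns)."""
    header = _contig_header(variants)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in variants:
            rec = vf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref_allele, site.alt_allele),
            )
            vf.write(rec)


def write_cluster_genotypes(
    centers, variants, path, hom_ref_max: float = 0.2, hom_alt_min: float = 0.8
) -> None:
    """Write per-cluster genotypes as one VCF sample column per cluster.

    A cluster's genotype at a site is called from its alt-allele
    fraction: 0/0 below ``hom_ref_max``, 1/1 above ``hom_alt_min``,
    0/1 in between.
    """
    fractions = np.asarray(centers.fractions, dtype=float)
    if fractions.shape[1] != len(variants):
        raise ValueError(
            f"centers cover {fractions.shape[1]} variants but {len(variants)} sites given"
        )
    header = _contig_header(variants)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = [f"cluster{j}" for j in range(fractions.shape[0])]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v, site in enumerate(variants):
            rec = vf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref_allele, site.alt_allele),
            )
            for j, s in enumerate(samples):
                rec.samples[s]["GT"] = _genotype(fractions[j, v], hom_ref_max, hom_alt_min)
            vf.write(rec)
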