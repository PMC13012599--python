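"""File-format round trips and validation for the allele IO layer."""

import numpy as np
import pytest

from khmdemux import allele_io
from khmdemux.allele_io import AlleleCountMatrix, VariantSite
from khmdemux.assignment import CellCall
from khmdemux.initialization import ClusterCenters
from khmdemux.simulate import SimConfig, simulate_dataset, write_sim

from conftest import make_counts


def _write_triplet(tmp_path, ref_body, alt_body, barcodes, variants):
    (tmp_path / "ref.mtx").write_text(ref_body)
    (tmp_path / "alt.mtx").write_text(alt_body)
    (tmp_path / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))
    allele_io.write_variant_sites(variants, tmp_path / "v.vcf")
    return (tmp_path / "ref.mtx", tmp_path / "alt.mtx",
            tmp_path / "barcodes.tsv", tmp_path / "v.vcf")


MTX_HEADER = "%%MatrixMarket matrix coordinate integer general\n"


class TestReadAlleleMatrices:
    def test_round_trip_via_simulator(self, tmp_path, four_donor_sim):
        _, counts, truth = four_donor_sim
        write_sim(counts, truth, tmp_path)
        back = allele_io.read_allele_matrices(
            tmp_path / "ref.mtx", tmp_path / "alt.mtx",
            tmp_path / "barcodes.tsv", tmp_path / "variants.vcf",
        )
        assert (back.ref_counts != counts.ref_counts).nnz == 0
        assert (back.alt_counts != counts.alt_counts).nnz == 0
        assert back.barcodes == counts.barcodes
        assert back.variants == counts.variants

    def test_disk_orientation_is_variants_by_cells(self, tmp_path):
        # alt entry at (variant 2, cell 1) in 1-based MTX coordinates
        variants = [VariantSite("1", p, "A", "C") for p in (10, 20, 30)]
        ref = MTX_HEADER + "3 2 1\n1 1 5\n"
        alt = MTX_HEADER + "3 2 1\n2 1 3\n"
        paths = _write_triplet(tmp_path, ref, alt, ["B1", "B2"], variants)
        m = allele_io.read_allele_matrices(*paths)
        assert m.n_cells == 2 and m.n_variants == 3
        assert m.alt_counts[0, 1] == 3
        assert m.ref_counts[0, 0] == 5

    def test_dimension_mismatch_names_both_sizes(self, tmp_path):
        variants = [VariantSite("1", 10 * (i + 1), "A", "C") for i in range(5)]
        ref = MTX_HEADER + "5 4 1\n1 1 1\n"
        alt = MTX_HEADER + "5 3 1\n1 1 1\n"
        paths = _write_triplet(tmp_path, ref, alt, ["B1", "B2", "B3", "B4"], variants)
        with pytest.raises(ValueError, match="5x4.*5x3"):
            allele_io.read_allele_matrices(*paths)

    def test_count_mismatch_with_barcodes_and_vcf(self, tmp_path):
        variants = [VariantSite("1", 10, "A", "C")]
        ref = MTX_HEADER + "1 2 1\n1 1 1\n"
        paths = _write_triplet(tmp_path, ref, ref, ["B1", "B2", "B3"], variants)
        with pytest.raises(ValueError, match="3 barcodes.*2 cells"):
            allele_io.read_allele_matrices(*paths)

    def test_duplicate_entries_are_summed_and_order_insensitive(self, tmp_path):
        variants = [VariantSite("1", 10, "A", "C"), VariantSite("1", 20, "A", "C")]
        alt_a = MTX_HEADER + "2 1 3\n1 1 2\n2 1 7\n1 1 3\n"
        alt_b = MTX_HEADER + "2 1 3\n2 1 7\n1 1 3\n1 1 2\n"
        ref = MTX_HEADER + "2 1 1\n1 1 1\n"
        for sub, alt_body in (("a", alt_a), ("b", alt_b)):
            d = tmp_path / sub
            d.mkdir(exist_ok=True)
            paths = _write_triplet(d, ref, alt_body, ["B1"], variants)
            m = allele_io.read_allele_matrices(*paths)
            assert m.alt_counts[0, 0] == 5
            assert m.alt_counts[0, 1] == 7

    def test_negative_counts_rejected(self, tmp_path):
        variants = [VariantSite("1", 10, "A", "C")]
        ref = MTX_HEADER + "1 1 1\n1 1 -2\n"
        paths = _write_triplet(tmp_path, ref, ref, ["B1"], variants)
        with pytest.raises(ValueError, match="negative"):
            allele_io.read_allele_matrices(*paths)


class TestAlleleCountMatrixInvariants:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            make_counts([[1, 0]], [[1, 0, 0]])

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_counts([[1], [1]], [[0], [0]], barcodes=["B", "B"])

    def test_sites_per_cell(self, tiny_counts):
        assert tiny_counts.sites_per_cell().tolist() == [3, 2]


class TestVcf:
    def test_multiallelic_rejected(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t10\t.\tA\tC,G\t.\t.\t.\n"
        )
        with pytest.raises(ValueError, match="multiallelic"):
            allele_io.read_vcf_sites(p)

    def test_variant_site_validation(self):
        with pytest.raises(ValueError):
            VariantSite("1", 0, "A", "C")
        with pytest.raises(ValueError):
            VariantSite("1", 5, "A", "A")


class TestCellCalls:
    def _calls(self):
        ll = np.array([-1.5, -7.25, -3.0])
        return [
            CellCall("BC1", "singlet", 0, None, ll, -9.5, 0.99),
            CellCall("BC2", "doublet", 0, 2, ll + 1, -2.0, 0.25),
            CellCall("BC3", "unassigned", None, None, ll * 0, -np.inf, 0.92),
        ]

    def test_format_contract(self, tmp_path):
        path = tmp_path / "calls.tsv"
        allele_io.write_cell_calls(self._calls(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        header = lines[0].split("\t")
        assert header[:5] == ["barcode", "status", "assignment",
                              "log_prob_singlet", "log_prob_doublet"]
        assert header[5:] == ["cluster0", "cluster1", "cluster2"]
        assert lines[1].split("\t")[2] == "0"
        assert lines[2].split("\t")[2] == "0/2"
        assert lines[3].split("\t")[2] == "NA"

    def test_round_trip_exact(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        allele_io.write_cell_calls(self._calls(), p1)
        df = allele_io.read_cell_calls(p1)
        assert df.loc[0, "cluster1"] == -7.25
        assert np.isclose(np.exp(df.loc[0, "log_prob_singlet"]), 0.99)
        # a second parse of the same bytes is identical field-for-field
        df2 = allele_io.read_cell_calls(p1)
        assert df.equals(df2)

    def test_empty_calls_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            allele_io.write_cell_calls([], tmp_path / "x.tsv")


class TestClusterGenotypes:
    def test_thresholds_and_shape(self, tmp_path):
        fractions = np.array([
            [0.0, 0.5, 0.95, 0.19],
            [0.21, 0.8, 0.81, 0.79],
        ])
        variants = [VariantSite("1", 10 * (i + 1), "A", "G") for i in range(4)]
        path = tmp_path / "geno.vcf"
        allele_io.write_cluster_genotypes(ClusterCenters(fractions), variants, path)
        sites = allele_io.read_vcf_sites(path)
        assert len(sites) == 4
        import pysam
        with pysam.VariantFile(str(path)) as vf:
            assert list(vf.header.samples) == ["cluster0", "cluster1"]
            gts = [
                [rec.samples[s]["GT"] for s in vf.header.samples] for rec in vf
            ]
        assert gts[0] == [(0, 0), (0, 1)]   # 0.0 hom-ref; 0.21 het
        assert gts[1] == [(0, 1), (0, 1)]   # 0.5 and 0.8 are het
        assert gts[2] == [(1, 1), (1, 1)]   # > 0.8 hom-alt
        assert gts[3] == [(0, 0), (0, 1)]   # 0.19 hom-ref; 0.79 het
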