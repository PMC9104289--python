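"""I/O layer: VCF normalization, filters, coordinate conversion, round-trip."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortvar import variant_io
from cohortvar.models import classify_alleles

from conftest import make_site, write_vcf


GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def gt_row(chrom, pos, ref, alt, dosages, info="."):
    cols = [chrom, str(pos), ".", ref, alt, ".", ".", info, "GT"]
    cols += [GT[d] for d in dosages]
    return "\t".join(cols)


class TestReadSmallVariants:
    def test_het_counts_and_annotations(self, tmp_path):
        samples = [f"S{i}" for i in range(10)]
        dosages = [1, 1, 1] + [0] * 7
        body = gt_row(
            "chr1", 100, "A", "T", dosages,
            "IMPACT=HIGH;CLNSIG=Pathogenic;CLNREVSTAT=practice_guideline;"
            "GENE=BRCA1;REF_AF=0.0001",
        ) + "\n"
        path = write_vcf(tmp_path, "a.vcf", body, samples=samples)
        (site,) = variant_io.read_small_variants(path, "pol")
        c = site.cohort("pol")
        assert (c.ac, c.an, c.carriers) == (3, 20, 3)
        assert site.impact == "HIGH"
        assert site.clnsig == "Pathogenic"
        assert site.gene_ids == ["BRCA1"]
        assert site.reference_af == pytest.approx(0.0001)

    def test_low_genotyping_rate_dropped(self, tmp_path):
        samples = [f"S{i}" for i in range(10)]
        # 9 of 10 missing: rate 10% < 90%
        body = gt_row("chr1", 100, "A", "T", [1] + [None] * 9) + "\n"
        body += gt_row("chr1", 200, "A", "T", [1] + [0] * 9) + "\n"
        path = write_vcf(tmp_path, "a.vcf", body, samples=samples)
        sites = variant_io.read_small_variants(path, "pol")
        assert [s.pos for s in sites] == [200]

    def test_invariant_dropped(self, tmp_path):
        samples = [f"S{i}" for i in range(4)]
        body = gt_row("chr1", 100, "A", "T", [0, 0, 0, 0]) + "\n"
        path = write_vcf(tmp_path, "a.vcf", body, samples=samples)
        assert variant_io.read_small_variants(path, "pol") == []

    def test_multiallelic_rejected(self, tmp_path):
        body = "chr1\t100\t.\tA\tT,G\t.\t.\tAC=1,1;AN=4\n"
        path = write_vcf(tmp_path, "a.vcf", body)
        with pytest.raises(variant_io.MultiallelicError, match="decompose"):
            variant_io.read_small_variants(path, "pol")

    def test_frequency_only_cohort(self, tmp_path):
        body = "chr1\t100\t.\tA\tT\t.\t.\tAC=5;AN=2000\n"
        path = write_vcf(tmp_path, "a.vcf", body)
        (site,) = variant_io.read_small_variants(path, "nfe")
        c = site.cohort("nfe")
        assert (c.ac, c.an) == (5, 2000)
        assert c.carriers is None

    def test_hom_alt_fixed_site_retained(self, tmp_path):
        samples = ["S0", "S1"]
        body = gt_row("chr1", 100, "A", "T", [2, 2]) + "\n"
        path = write_vcf(tmp_path, "a.vcf", body, samples=samples)
        (site,) = variant_io.read_small_variants(path, "pol")
        assert site.cohort("pol").af == 1.0


class TestReadStructuralVariants:
    def test_del_length_one_based_inclusive(self, tmp_path):
        body = "chr1\t1000\tsv1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=1500;DHFFC=0.3;MSHQ=10;SR=2;AC=1;AN=100\n"
        path = write_vcf(tmp_path, "sv.vcf", body)
        (sv,) = variant_io.read_structural_variants(path, "pol")
        assert sv.length == 501

    def test_bnd_flagged_excluded(self, tmp_path):
        body = "chr1\t1000\tsv1\tN\t<BND>\t.\t.\tSVTYPE=BND;AC=1;AN=100\n"
        path = write_vcf(tmp_path, "sv.vcf", body)
        (sv,) = variant_io.read_structural_variants(path, "pol")
        assert sv.excluded_bnd

    def test_dup_missing_dhffc_errors(self, tmp_path):
        body = "chr1\t1000\tsv9\tN\t<DUP>\t.\t.\tSVTYPE=DUP;END=2000;MSHQ=10;SR=2;AC=1;AN=100\n"
        path = write_vcf(tmp_path, "sv.vcf", body)
        with pytest.raises(variant_io.VcfFormatError, match="sv9|DHFFC"):
            variant_io.read_structural_variants(path, "pol")

    def test_end_before_pos_errors(self, tmp_path):
        body = "chr1\t1000\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=900;DHFFC=0.3;AC=1;AN=100\n"
        path = write_vcf(tmp_path, "sv.vcf", body)
        with pytest.raises(variant_io.VcfFormatError, match="END"):
            variant_io.read_structural_variants(path, "pol")


class TestGeneModels:
    def test_bed_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t999\t2000\tGENE1\n")
        (g,) = variant_io.read_gene_models(p)
        assert (g.cds_start, g.cds_end) == (1000, 2000)
        assert g.exons == [(1000, 2000)]

    def test_overlapping_exon_rows_merged(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t999\t2000\tGENE1\nchr1\t1500\t2500\tGENE1\n")
        (g,) = variant_io.read_gene_models(p)
        assert g.exons == [(1000, 2500)]

    def test_tsv_inverted_cds_errors(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "gene_id\tchrom\tstrand\tcds_start\tcds_end\texons\n"
            "G1\tchr1\t+\t5000\t4000\t5000-5100\n"
        )
        with pytest.raises(ValueError, match="cds_start"):
            variant_io.read_gene_models(p)

    def test_bed_roundtrip_identity(self, tmp_path):
        p = tmp_path / "g.bed"
        text = "chr1\t999\t2000\tGENE1\nchr1\t2999\t4000\tGENE1\nchr2\t0\t100\tGENE2\n"
        p.write_text(text)
        genes = variant_io.read_gene_models(p)
        assert variant_io.gene_models_to_bed(sorted(genes, key=lambda g: g.gene_id)) == text


class TestFrequencyVcf:
    def test_info_format_contract(self):
        buf = io.StringIO()
        site = make_site(ac=3, an=2152, carriers=3, cohort="pol", pos=100)
        variant_io.write_frequency_vcf([site], "pol", buf)
        assert "AC=3;AN=2152" in buf.getvalue()

    def test_empty_collection_is_valid_header_only_vcf(self, tmp_path):
        out = tmp_path / "f.vcf"
        variant_io.write_frequency_vcf([], "pol", out)
        assert variant_io.read_small_variants(out, "pol") == []

    def test_unsorted_input_rejected(self):
        sites = [make_site(pos=200, cohort="pol"), make_site(pos=100, cohort="pol")]
        with pytest.raises(ValueError, match="unsorted"):
            variant_io.write_frequency_vcf(sites, "pol", io.StringIO())

    @settings(max_examples=20, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(1, 10_000_000),  # pos
                st.integers(1, 500),  # ac
                st.integers(500, 4000),  # an
            ),
            min_size=1,
            max_size=100,
            unique_by=lambda t: t[0],
        )
    )
    def test_roundtrip_identity(self, tmp_path_factory, data):
        """write -> read is the identity on (chrom,pos,ref,alt,ac,an)."""
        tmp = tmp_path_factory.mktemp("rt")
        sites = [
            make_site(pos=pos, ac=min(ac, an), an=an, carriers=None, cohort="pol")
            for pos, ac, an in sorted(data)
        ]
        out = tmp / "f.vcf"
        variant_io.write_frequency_vcf(sites, "pol", out)
        back = variant_io.read_small_variants(out, "pol")
        assert [(s.chrom, s.pos, s.ref, s.alt) for s in back] == [
            (s.chrom, s.pos, s.ref, s.alt) for s in sites
        ]
        assert [(s.cohort("pol").ac, s.cohort("pol").an) for s in back] == [
            (s.cohort("pol").ac, s.cohort("pol").an) for s in sites
        ]


class TestPanelsCoverage:
    def test_panel_rows_grouped_and_deduplicated(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text(
            "panel_id\tpanel_name\tgene_id\n"
            "P1\tskin\tG1\nP1\tskin\tG2\nP1\tskin\tG3\nP1\tskin\tG2\n"
        )
        (panel,) = variant_io.read_panels(p)
        assert panel.n_genes == 3

    def test_coverage_out_of_range_errors(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\tfrac_below_20x\nG1\t1.2\n")
        with pytest.raises(ValueError, match="outside"):
            variant_io.read_coverage(p)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [("A", "T", "SNV"), ("A", "AT", "insertion"), ("AT", "A", "deletion")],
)
def test_variant_class_from_alleles(ref, alt, expected):
    assert classify_alleles(ref, alt) == expected
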