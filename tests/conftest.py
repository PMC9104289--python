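"""Shared fixtures: tiny VCF texts and published worked-example tables."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from cohortvar.models import CohortCounts, GeneModel, VariantSite


def write_vcf(tmp_path, name: str, body: str, fmt: bool = True, samples=()) -> str:
    """Write a minimal VCF with optional genotype columns."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    header = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##INFO=<ID=AC,Number=A,Type=Integer,Description="x">
        ##INFO=<ID=AN,Number=1,Type=Integer,Description="x">
        ##INFO=<ID=IMPACT,Number=1,Type=String,Description="x">
        ##INFO=<ID=CLNSIG,Number=1,Type=String,Description="x">
        ##INFO=<ID=CLNREVSTAT,Number=1,Type=String,Description="x">
        ##INFO=<ID=GENE,Number=1,Type=String,Description="x">
        ##INFO=<ID=REF_AF,Number=1,Type=Float,Description="x">
        ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
        ##INFO=<ID=END,Number=1,Type=Integer,Description="x">
        ##INFO=<ID=MSHQ,Number=1,Type=Float,Description="x">
        ##INFO=<ID=DHFFC,Number=1,Type=Float,Description="x">
        ##INFO=<ID=SR,Number=1,Type=Integer,Description="x">
        ##INFO=<ID=HET,Number=1,Type=Integer,Description="x">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##contig=<ID=chr1>
        ##contig=<ID=chr2>
        """
    )
    path = tmp_path / name
    path.write_text(header + cols + "\n" + body)
    return str(path)


def make_site(
    ac=1,
    an=2152,
    carriers=None,
    cohort="a",
    cohort_size=None,
    pos=100,
    impact="MODERATE",
    clnsig=None,
    clnrevstat=None,
    gene="G1",
    reference_af=None,
    ref="A",
    alt="T",
    chrom="chr1",
):
    if carriers is None and cohort_size is not None:
        carriers = min(ac, cohort_size)
    return VariantSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        counts={
            cohort: CohortCounts(
                ac=ac, an=an, carriers=carriers, cohort_size=cohort_size
            )
        },
        impact=impact,
        clnsig=clnsig,
        clnrevstat=clnrevstat,
        gene_ids=[gene] if gene else [],
        reference_af=reference_af,
    )


@pytest.fixture
def simple_gene():
    return GeneModel(
        gene_id="G1",
        chrom="chr1",
        cds_start=100_000,
        cds_end=120_000,
        exons=[(100_000, 101_000), (110_000, 111_000), (119_000, 120_000)],
    )


#: published cohort summary: variant counts by impact x frequency tier x
#: class for a 1076-individual whole-genome cohort (worked-example input)
TABLE1_CELLS = {
    ("HIGH", ">0.5%", "deletion"): 412,
    ("MODERATE", ">0.5%", "deletion"): 603,
    ("LOW", ">0.5%", "deletion"): 855,
    ("MODIFIER", ">0.5%", "deletion"): 1_208_322,
    ("HIGH", ">0.5%", "insertion"): 260,
    ("MODERATE", ">0.5%", "insertion"): 573,
    ("LOW", ">0.5%", "insertion"): 977,
    ("MODIFIER", ">0.5%", "insertion"): 1_380_654,
    ("HIGH", ">0.5%", "SNV"): 1109,
    ("MODERATE", ">0.5%", "SNV"): 35_717,
    ("LOW", ">0.5%", "SNV"): 41_402,
    ("MODIFIER", ">0.5%", "SNV"): 10_877_171,
    ("HIGH", "0.1-0.5%", "deletion"): 392,
    ("MODERATE", "0.1-0.5%", "deletion"): 492,
    ("LOW", "0.1-0.5%", "deletion"): 316,
    ("MODIFIER", "0.1-0.5%", "deletion"): 433_985,
    ("HIGH", "0.1-0.5%", "insertion"): 197,
    ("MODERATE", "0.1-0.5%", "insertion"): 345,
    ("LOW", "0.1-0.5%", "insertion"): 376,
    ("MODIFIER", "0.1-0.5%", "insertion"): 529_654,
    ("HIGH", "0.1-0.5%", "SNV"): 852,
    ("MODERATE", "0.1-0.5%", "SNV"): 23_682,
    ("LOW", "0.1-0.5%", "SNV"): 18_675,
    ("MODIFIER", "0.1-0.5%", "SNV"): 4_375_036,
    ("HIGH", "<0.1%", "deletion"): 2849,
    ("MODERATE", "<0.1%", "deletion"): 1988,
    ("LOW", "<0.1%", "deletion"): 1003,
    ("MODIFIER", "<0.1%", "deletion"): 1_295_678,
    ("HIGH", "<0.1%", "insertion"): 1382,
    ("MODERATE", "<0.1%", "insertion"): 1144,
    ("LOW", "<0.1%", "insertion"): 826,
    ("MODIFIER", "<0.1%", "insertion"): 1_037_730,
    ("HIGH", "<0.1%", "SNV"): 5432,
    ("MODERATE", "<0.1%", "SNV"): 119_843,
    ("LOW", "<0.1%", "SNV"): 80_467,
    ("MODIFIER", "<0.1%", "SNV"): 17_817_903,
}


@pytest.fixture
def table1_cells():
    return dict(TABLE1_CELLS)


#: published worked-example constants for a 1076-diploid cohort
WORKED = {
    "cohort_size": 1076,
    "tier_counts": {1: 309, 2: 473, 3: 23, 4: 3},
    "n_private_pathogenic": 591,
    "acmg_pathogenic_carriers": 20,
    "acmg_private": 17,
    "acmg_classified": 18,
    "hq_sv_classes": {"DEL": 19_808, "DUP": 2270, "INV": 998},
}


def clinvar_worked_fixture():
    """808 rare pathogenic sites with the published tier mix and 591 of
    them private (single carrier), built as generator input for the
    selection stage."""
    revstat = {
        1: "criteria_provided,_single_submitter",
        2: "criteria_provided,_multiple_submitters,_no_conflicts",
        3: "reviewed_by_expert_panel",
        4: "practice_guideline",
    }
    sites = []
    pos = 1000
    n_private_left = WORKED["n_private_pathogenic"]
    for tier, count in WORKED["tier_counts"].items():
        for _ in range(count):
            private = n_private_left > 0
            if private:
                n_private_left -= 1
            sites.append(
                make_site(
                    ac=1 if private else 4,
                    carriers=1 if private else 4,
                    cohort_size=WORKED["cohort_size"],
                    pos=pos,
                    clnsig="Pathogenic",
                    clnrevstat=revstat[tier],
                    reference_af=0.0005,
                )
            )
            pos += 10
    return sites
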