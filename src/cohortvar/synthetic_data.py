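"""Two-cohort synthetic datasets with recorded ground truth.

The generator emulates the statistical structure the pipeline assumes:
unrelated diploid individuals, per-site Hardy-Weinberg genotypes drawn
binomially at configured allele frequencies, ClinVar/VEP-style
annotations, Smoove-style SV records with quality fields, and
Balding-Nichols allele-frequency draws for population-differentiation
scenarios. Cohort A is emitted with genotypes (the sequenced cohort);
cohort B as a frequency-only comparator (gnomAD-style). Every scenario
writes a truth table sufficient to score the downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fst import FstSiteComponents, wc_site_components
from .models import CohortCounts, GeneModel, Panel, StructuralVariantRecord, VariantSite

#: review-status strings by confidence tier, sampled for pathogenic sites
REVSTAT_BY_TIER = {
    1: "criteria_provided,_single_submitter",
    2: "criteria_provided,_multiple_submitters,_no_conflicts",
    3: "reviewed_by_expert_panel",
    4: "practice_guideline",
}


@dataclass
class SimulationConfig:
    """Study-scale defaults: a sequenced cohort of 1076 unrelated diploids
    against a 16,000-diploid frequency-only comparator, 50 autosomal-
    recessive genes each carrying a small number of rare pathogenic sites
    at a null cumulative frequency of 0.2%."""

    seed: int = 0
    n_a: int = 1076
    n_b: int = 16000
    n_genes: int = 50
    null_freq: float = 0.002
    #: gene index -> (cumulative pathogenic freq in A, in B); unlisted genes
    #: are null (f_A == f_B == null_freq)
    enriched: dict[int, tuple[float, float]] = field(default_factory=dict)
    sites_per_gene: int = 3
    site_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    background_sites_per_gene: int = 2
    missing_rate: float = 0.0
    #: fraction of pathogenic sites per review-status tier (tiers 1..4)
    tier_mix: tuple[float, ...] = (0.38, 0.59, 0.028, 0.002)
    #: fraction of pathogenic sites per impact HIGH/MODERATE/MODIFIER
    impact_mix: tuple[float, ...] = (0.35, 0.55, 0.10)
    # --- SV scenario -------------------------------------------------------
    n_sv: dict[str, int] = field(
        default_factory=lambda: {"DEL": 300, "DUP": 60, "INV": 30}
    )
    #: log-normal length parameters (mean, sigma of log10 length) per type;
    #: modes near the 300 bp (DEL), 200 bp (DUP), 1.5 kb (INV) length peaks
    sv_length_log10: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"DEL": (2.5, 0.5), "DUP": (2.3, 0.6), "INV": (3.2, 0.5)}
    )
    sv_af_log10_range: tuple[float, float] = (-3.3, -1.0)
    #: fractions of records planted to fail each quality gate
    sv_fail_mshq: float = 0.10
    sv_fail_dhffc: float = 0.10
    sv_fail_split_reads: float = 0.05
    #: gene index receiving an overlapping complex-SV pileup (None = off)
    pileup_gene: int | None = None
    pileup_n_sv: int = 15
    pileup_carriers: int = 24
    # --- Fst scenario ------------------------------------------------------
    fst_sites: int = 100_000
    fst_truth: float = 0.0
    fst_n: tuple[int, int] = (500, 500)

    def __post_init__(self) -> None:
        freqs = [self.null_freq] + [f for pair in self.enriched.values() for f in pair]
        if any(not (0 <= f <= 0.5) for f in freqs):
            raise ValueError("pathogenic allele frequencies must lie in [0, 0.5]")
        if len(self.site_weights) != self.sites_per_gene:
            raise ValueError("site_weights length must equal sites_per_gene")


# gene layout constants: evenly spaced genes on one contig
_GENE_SPACING = 1_000_000
_CDS_LEN = 20_000
_EXON_LEN = 2_000
_N_EXONS = 5


def make_gene_models(n_genes: int, chrom: str = "chr1") -> list[GeneModel]:
    """Evenly spaced genes with 5 exons across a 20 kb CDS."""
    genes = []
    for i in range(n_genes):
        cds_start = 100_000 + i * _GENE_SPACING
        cds_end = cds_start + _CDS_LEN - 1
        step = (_CDS_LEN - _EXON_LEN) // (_N_EXONS - 1)
        exons = [
            (cds_start + j * step, cds_start + j * step + _EXON_LEN - 1)
            for j in range(_N_EXONS)
        ]
        genes.append(
            GeneModel(
                gene_id=f"GENE{i:03d}",
                chrom=chrom,
                cds_start=cds_start,
                cds_end=cds_end,
                exons=exons,
            )
        )
    return genes


def make_panels(genes: list[GeneModel], genes_per_panel: int = 5) -> list[Panel]:
    """Consecutive non-overlapping panels over the gene list."""
    panels = []
    ids = [g.gene_id for g in genes]
    for k, start in enumerate(range(0, len(ids), genes_per_panel)):
        chunk = ids[start : start + genes_per_panel]
        panels.append(Panel(panel_id=f"P{k:02d}", name=f"panel {k}", gene_ids=chunk))
    return panels


@dataclass
class SimulatedCohorts:
    sites_a: list[VariantSite]
    sites_b: list[VariantSite]
    genes: list[GeneModel]
    truth: pd.DataFrame
    genotypes_a: dict[tuple, np.ndarray] | None  # site key -> dosage vector
    config: SimulationConfig


def _draw_dosages(rng, n: int, f: float, missing_rate: float) -> np.ndarray:
    d = rng.binomial(2, f, size=n).astype(np.int8)
    if missing_rate > 0:
        d[rng.random(n) < missing_rate] = -1
    return d


def _counts_from_dosages(d: np.ndarray) -> tuple[int, int, int]:
    called = d[d >= 0]
    return int(called.sum()), 2 * called.size, int((called > 0).sum())


def simulate_small_variant_cohorts(
    config: SimulationConfig, keep_genotypes: bool = False
) -> SimulatedCohorts:
    """Draw two-cohort small-variant data with per-gene pathogenic truth.

    Cohort A sites carry carrier counts and cohort size (genotype cohort);
    cohort B sites are frequency-only (ac/an, no carriers). Pathogenic
    sites split the gene's cumulative frequency by ``site_weights`` and
    receive annotations from the configured tier/impact mixes; each gene
    also gets benign and LOW-impact background sites.
    """
    rng = np.random.default_rng(config.seed)
    genes = make_gene_models(config.n_genes)
    tiers = list(REVSTAT_BY_TIER)
    impacts = ("HIGH", "MODERATE", "MODIFIER")

    sites_a: list[VariantSite] = []
    sites_b: list[VariantSite] = []
    genos: dict[tuple, np.ndarray] = {}
    truth_rows = []
    for gi, gene in enumerate(genes):
        f_a, f_b = config.enriched.get(gi, (config.null_freq, config.null_freq))
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "f_a": f_a,
                "f_b": f_b,
                "enriched": gi in config.enriched and f_a != f_b,
            }
        )
        positions = rng.choice(
            np.arange(gene.cds_start, gene.cds_end), size=config.sites_per_gene + config.background_sites_per_gene, replace=False
        )
        positions.sort()
        # pathogenic sites
        for si in range(config.sites_per_gene):
            w = config.site_weights[si]
            pos = int(positions[si])
            tier = tiers[rng.choice(4, p=np.asarray(config.tier_mix) / sum(config.tier_mix))]
            impact = impacts[
                rng.choice(3, p=np.asarray(config.impact_mix) / sum(config.impact_mix))
            ]
            sig = "Pathogenic" if rng.random() < 0.7 else "Likely_pathogenic"
            d_a = _draw_dosages(rng, config.n_a, f_a * w, config.missing_rate)
            d_b = _draw_dosages(rng, config.n_b, f_b * w, config.missing_rate)
            ac_a, an_a, car_a = _counts_from_dosages(d_a)
            ac_b, an_b, _ = _counts_from_dosages(d_b)
            ref_af = ac_b / an_b if an_b else 0.0
            common = dict(
                chrom=gene.chrom,
                pos=pos,
                ref="A",
                alt="T",
                impact=impact,
                clnsig=sig,
                clnrevstat=REVSTAT_BY_TIER[tier],
                gene_ids=[gene.gene_id],
                reference_af=ref_af,
            )
            if ac_a > 0:  # sites invariant in a cohort are not emitted for it
                sa = VariantSite(
                    counts={
                        "a": CohortCounts(
                            ac=ac_a, an=an_a, carriers=car_a, cohort_size=config.n_a
                        )
                    },
                    **common,
                )
                sites_a.append(sa)
                if keep_genotypes:
                    genos[sa.key] = d_a
            if ac_b > 0:
                sites_b.append(
                    VariantSite(
                        counts={"b": CohortCounts(ac=ac_b, an=an_b)}, **common
                    )
                )
        # background benign / LOW-impact sites, common frequencies
        for bi in range(config.background_sites_per_gene):
            pos = int(positions[config.sites_per_gene + bi])
            f = rng.uniform(0.01, 0.3)
            d_a = _draw_dosages(rng, config.n_a, f, config.missing_rate)
            d_b = _draw_dosages(rng, config.n_b, f, config.missing_rate)
            ac_a, an_a, car_a = _counts_from_dosages(d_a)
            ac_b, an_b, _ = _counts_from_dosages(d_b)
            common = dict(
                chrom=gene.chrom,
                pos=pos,
                ref="G",
                alt="C",
                impact="LOW" if bi % 2 else "MODIFIER",
                clnsig="Benign",
                clnrevstat=REVSTAT_BY_TIER[1],
                gene_ids=[gene.gene_id],
                reference_af=ac_b / an_b if an_b else 0.0,
            )
            if ac_a > 0:
                sa = VariantSite(
                    counts={
                        "a": CohortCounts(
                            ac=ac_a, an=an_a, carriers=car_a, cohort_size=config.n_a
                        )
                    },
                    **common,
                )
                sites_a.append(sa)
                if keep_genotypes:
                    genos[sa.key] = d_a
            if ac_b > 0:
                sites_b.append(
                    VariantSite(counts={"b": CohortCounts(ac=ac_b, an=an_b)}, **common)
                )

    sites_a.sort(key=lambda s: (s.chrom, s.pos))
    sites_b.sort(key=lambda s: (s.chrom, s.pos))
    return SimulatedCohorts(
        sites_a=sites_a,
        sites_b=sites_b,
        genes=genes,
        truth=pd.DataFrame(truth_rows),
        genotypes_a=genos if keep_genotypes else None,
        config=config,
    )


def _info_annotations(s: VariantSite) -> str:
    parts = []
    if s.impact:
        parts.append(f"IMPACT={s.impact}")
    if s.clnsig:
        parts.append(f"CLNSIG={s.clnsig}")
    if s.clnrevstat:
        parts.append(f"CLNREVSTAT={s.clnrevstat}")
    if s.gene_ids:
        parts.append("GENE=" + "|".join(s.gene_ids))
    if s.reference_af is not None:
        parts.append(f"REF_AF={s.reference_af:.6g}")
    return ";".join(parts)


_VCF_ANNOT_HEADER = [
    '##INFO=<ID=IMPACT,Number=1,Type=String,Description="VEP-style impact">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">',
    '##INFO=<ID=CLNREVSTAT,Number=1,Type=String,Description="Review status">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene ids (|-sep)">',
    '##INFO=<ID=REF_AF,Number=1,Type=Float,Description="Comparator-database AF">',
]

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_genotype_vcf(sim: SimulatedCohorts, path: str | Path) -> None:
    """Cohort A as a multi-sample genotype VCF."""
    if sim.genotypes_a is None:
        raise ValueError("simulate with keep_genotypes=True to write genotype VCFs")
    samples = [f"S{i:04d}" for i in range(sim.config.n_a)]
    lines = [
        "##fileformat=VCFv4.2",
        "##source=cohortvar synthetic cohort A",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *_VCF_ANNOT_HEADER,
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for s in sim.sites_a:
        gts = "\t".join(_GT_STR[int(g)] for g in sim.genotypes_a[s.key])
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t"
            f"{_info_annotations(s)}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_frequency_only_vcf(
    sites: list[VariantSite], cohort_label: str, path: str | Path
) -> None:
    """Frequency-only comparator VCF (AC/AN INFO, annotations, no samples)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=cohortvar synthetic comparator ({cohort_label})",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Called alleles">',
        *_VCF_ANNOT_HEADER,
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for s in sites:
        c = s.cohort(cohort_label)
        ann = _info_annotations(s)
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t"
            f"AC={c.ac};AN={c.an}" + (";" + ann if ann else "")
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# structural variants
# --------------------------------------------------------------------------


@dataclass
class SimulatedSvs:
    svs_a: list[StructuralVariantRecord]
    svs_b: list[StructuralVariantRecord]
    genes: list[GeneModel]
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_sv_cohorts(config: SimulationConfig) -> SimulatedSvs:
    """Draw SV records for both cohorts with planted quality failures.

    Lengths are log-normal per type (log10 scale); breakpoints are placed
    uniformly over the gene landscape so a realistic share intersects
    exons. Truth records, per SV, which quality gate (if any) it was
    planted to fail and whether it belongs to the complex pileup.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = make_gene_models(config.n_genes)
    span_end = genes[-1].cds_end + 200_000

    def _records(label: str, n_cohort: int, id_prefix: str):
        recs, rows = [], []
        idx = 0
        for svtype, count in config.n_sv.items():
            mu, sigma = config.sv_length_log10[svtype]
            lengths = np.maximum(
                51, np.round(10 ** rng.normal(mu, sigma, size=count))
            ).astype(int)
            starts = rng.integers(1, span_end, size=count)
            lo, hi = config.sv_af_log10_range
            afs = 10 ** rng.uniform(lo, hi, size=count)
            fail_kind = rng.choice(
                ["none", "mshq", "dhffc", "sr"],
                size=count,
                p=[
                    1 - config.sv_fail_mshq - config.sv_fail_dhffc - config.sv_fail_split_reads,
                    config.sv_fail_mshq,
                    config.sv_fail_dhffc,
                    config.sv_fail_split_reads,
                ],
            )
            for k in range(count):
                an = 2 * n_cohort
                ac = max(1, int(round(afs[k] * an)))
                mshq = rng.uniform(0.0, 2.9) if fail_kind[k] == "mshq" else rng.uniform(3.0, 40.0)
                if svtype == "DEL":
                    dhffc = rng.uniform(0.7, 1.2) if fail_kind[k] == "dhffc" else rng.uniform(0.0, 0.69)
                elif svtype == "DUP":
                    dhffc = rng.uniform(0.8, 1.25) if fail_kind[k] == "dhffc" else rng.uniform(1.26, 3.0)
                else:
                    dhffc = rng.uniform(0.8, 1.2)
                    if fail_kind[k] == "dhffc":
                        fail_kind[k] = "none"  # INV carries no depth gate
                sr = 0 if fail_kind[k] == "sr" else int(rng.integers(1, 20))
                recs.append(
                    StructuralVariantRecord(
                        chrom="chr1",
                        start=int(starts[k]),
                        end=int(starts[k]) + int(lengths[k]) - 1,
                        svtype=svtype,
                        mshq=mshq,
                        dhffc=dhffc,
                        split_reads_per_allele=sr,
                        is_het_call=True,
                        counts={label: CohortCounts(ac=ac, an=an)},
                        sv_id=f"{id_prefix}_{svtype}_{idx}",
                    )
                )
                rows.append(
                    {
                        "sv_id": f"{id_prefix}_{svtype}_{idx}",
                        "cohort": label,
                        "svtype": svtype,
                        "length": int(lengths[k]),
                        "planted_fail": fail_kind[k],
                        "pileup": False,
                    }
                )
                idx += 1
        return recs, rows

    svs_a, rows_a = _records("a", config.n_a, "svA")
    svs_b, rows_b = _records("b", config.n_b, "svB")

    if config.pileup_gene is not None:
        gene = genes[config.pileup_gene]
        an = 2 * config.n_a
        # each overlapping SV is het in ~7/8 of the pileup carriers, keeping
        # every individual SV rare while the gene's cumulative frequency
        # piles far beyond any single-variant frequency
        per_sv_ac = max(1, round(config.pileup_carriers * 0.875))
        for k in range(config.pileup_n_sv):
            ex_s, ex_e = gene.exons[int(rng.integers(len(gene.exons)))]
            start = int(rng.integers(ex_s, ex_e))  # anchor in an exon
            length = int(rng.integers(500, 5000))
            ac = per_sv_ac
            svs_a.append(
                StructuralVariantRecord(
                    chrom=gene.chrom,
                    start=start,
                    end=start + length - 1,
                    svtype="DEL",
                    mshq=20.0,
                    dhffc=0.4,
                    split_reads_per_allele=5,
                    counts={"a": CohortCounts(ac=ac, an=an)},
                    sv_id=f"svA_pileup_{k}",
                )
            )
            rows_a.append(
                {
                    "sv_id": f"svA_pileup_{k}",
                    "cohort": "a",
                    "svtype": "DEL",
                    "length": length,
                    "planted_fail": "none",
                    "pileup": True,
                }
            )
    return SimulatedSvs(
        svs_a=svs_a,
        svs_b=svs_b,
        genes=genes,
        truth=pd.DataFrame(rows_a + rows_b),
        config=config,
    )


def write_sv_vcf(
    svs: list[StructuralVariantRecord], cohort_label: str, path: str | Path
) -> None:
    """Site-only SV VCF with SVTYPE/END and Smoove-style quality INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=cohortvar synthetic SVs ({cohort_label})",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##INFO=<ID=MSHQ,Number=1,Type=Float,Description="Mean split-read het quality">',
        '##INFO=<ID=DHFFC,Number=1,Type=Float,Description="Depth fold-change vs flanks">',
        '##INFO=<ID=SR,Number=1,Type=Integer,Description="Split reads per allele">',
        '##INFO=<ID=HET,Number=1,Type=Integer,Description="Has heterozygous calls">',
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Called alleles">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for sv in sorted(svs, key=lambda r: (r.chrom, r.start)):
        c = sv.counts[cohort_label]
        info = [f"SVTYPE={sv.svtype}", f"END={sv.end}"]
        if sv.mshq is not None:
            info.append(f"MSHQ={sv.mshq:.3f}")
        if sv.dhffc is not None:
            info.append(f"DHFFC={sv.dhffc:.3f}")
        if sv.split_reads_per_allele is not None:
            info.append(f"SR={sv.split_reads_per_allele}")
        info.append(f"HET={int(sv.is_het_call)}")
        info.append(f"AC={c.ac};AN={c.an}")
        lines.append(
            f"{sv.chrom}\t{sv.start}\t{sv.sv_id or '.'}\tN\t<{sv.svtype}>\t.\t.\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Fst scenarios
# --------------------------------------------------------------------------


def simulate_fst_sites(config: SimulationConfig) -> list[FstSiteComponents]:
    """Balding-Nichols two-population draws at the configured truth theta.

    Ancestral frequencies are uniform on (0.1, 0.9); each population's
    frequency is Beta-distributed around the ancestral value with variance
    theta * p * (1-p) (independent draws), then genotypes are sampled
    under HWE and summarised into per-site variance components.
    """
    rng = np.random.default_rng(config.seed + 2)
    m = config.fst_sites
    n1, n2 = config.fst_n
    theta = config.fst_truth
    if theta < 0:
        raise ValueError("divergence parameter must be >= 0")
    anc = rng.uniform(0.1, 0.9, size=m)
    if theta == 0:
        p_pop = np.stack([anc, anc])
    else:
        lam = (1 - theta) / theta
        p_pop = np.stack(
            [rng.beta(anc * lam, (1 - anc) * lam) for _ in range(2)]
        )

    comps = []
    for n_i, p_i in ((n1, p_pop[0]), (n2, p_pop[1])):
        hwe = np.stack([(1 - p_i) ** 2, 2 * p_i * (1 - p_i), p_i**2], axis=1)
        g = rng.multinomial(n_i, hwe)  # per-site genotype counts (n0, n1, n2)
        comps.append(g)
    g1, g2 = comps

    out = []
    for k in range(m):
        p1 = (g1[k, 1] + 2 * g1[k, 2]) / (2 * n1)
        p2 = (g2[k, 1] + 2 * g2[k, 2]) / (2 * n2)
        h1 = g1[k, 1] / n1
        h2 = g2[k, 1] / n2
        out.append(wc_site_components([n1, n2], [p1, p2], [h1, h2]))
    return out


# --------------------------------------------------------------------------
# bundle writer (CLI / pipeline entry)
# --------------------------------------------------------------------------


def write_simulation_bundle(config: SimulationConfig, outdir: str | Path) -> dict:
    """Emit VCFs, gene/panel/coverage TSVs, and truth tables to a directory."""
    from .variant_io import gene_models_to_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_small_variant_cohorts(config, keep_genotypes=True)
    svs = simulate_sv_cohorts(config)

    write_genotype_vcf(sim, outdir / "cohort_a.vcf")
    write_frequency_only_vcf(sim.sites_b, "b", outdir / "cohort_b.vcf")
    write_sv_vcf(svs.svs_a, "a", outdir / "sv_a.vcf")
    write_sv_vcf(svs.svs_b, "b", outdir / "sv_b.vcf")
    (outdir / "genes.bed").write_text(gene_models_to_bed(sim.genes))

    panels = make_panels(sim.genes)
    panel_lines = ["panel_id\tpanel_name\tgene_id"]
    for p in panels:
        panel_lines += [f"{p.panel_id}\t{p.name}\t{g}" for g in p.gene_ids]
    (outdir / "panels.tsv").write_text("\n".join(panel_lines) + "\n")

    rng = np.random.default_rng(config.seed + 3)
    cov_lines = ["gene_id\tfrac_below_20x"]
    cov_lines += [
        f"{g.gene_id}\t{rng.uniform(0.0, 0.08):.4f}" for g in sim.genes
    ]
    (outdir / "coverage.tsv").write_text("\n".join(cov_lines) + "\n")

    sim.truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    svs.truth.to_csv(outdir / "truth_svs.tsv", sep="\t", index=False)
    return {
        "cohort_a": outdir / "cohort_a.vcf",
        "cohort_b": outdir / "cohort_b.vcf",
        "sv_a": outdir / "sv_a.vcf",
        "sv_b": outdir / "sv_b.vcf",
        "genes": outdir / "genes.bed",
        "panels": outdir / "panels.tsv",
        "coverage": outdir / "coverage.tsv",
        "n_sites_a": len(sim.sites_a),
        "n_sites_b": len(sim.sites_b),
        "n_sv_a": len(svs.svs_a),
        "n_sv_b": len(svs.svs_b),
    }
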