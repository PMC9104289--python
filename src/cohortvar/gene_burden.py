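"""Per-gene and per-panel cumulative pathogenic allele burden comparison
between two cohorts.

For each autosomal-recessive gene, pathogenic alleles over the CDS plus
a +/- 5 kb flank are summed into a cumulative allele count, compared
between cohorts with a two-sided Fisher exact test on the 2x2 allele
table, and corrected across genes with Benjamini-Hochberg FDR. Panels sum
their member genes' alleles (a site shared by two member genes counts
once), apply a Bonferroni-style factor for the panel's gene count, then
BH across panels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .clinvar_pathogenic import is_pathogenic
from .models import CoverageSummary, GeneModel, Panel, VariantSite

logger = logging.getLogger(__name__)

BURDEN_IMPACTS = frozenset({"HIGH", "MODERATE", "MODIFIER"})  # LOW excluded

RESULT_COLUMNS = [
    "unit_id",
    "ac_a",
    "an_a",
    "ac_b",
    "an_b",
    "cum_freq_a",
    "cum_freq_b",
    "p",
    "q",
    "direction",
]


@dataclass(frozen=True)
class GeneRegion:
    gene_id: str
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def gene_region(gene: GeneModel, flank: int = 5000) -> GeneRegion:
    """CDS bounds extended by ``flank`` bases each side, clipped at 1."""
    return GeneRegion(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=max(1, gene.cds_start - flank),
        end=gene.cds_end + flank,
    )


def assign_variants(
    sites: Iterable[VariantSite], regions: Sequence[GeneRegion]
) -> dict[str, list[VariantSite]]:
    """Map gene_id -> sites whose position falls in the gene region.

    Regions may overlap; a site is assigned to every region containing it.
    """
    by_chrom: dict[str, list[GeneRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: dict[str, list[VariantSite]] = {r.gene_id: [] for r in regions}
    for s in sites:
        for r in by_chrom.get(s.chrom, ()):
            if r.start <= s.pos <= r.end:
                out[r.gene_id].append(s)
    return out


def variant_scope_filter(sites: Iterable[VariantSite]) -> list[VariantSite]:
    """Keep HIGH/MODERATE/MODIFIER pathogenic sites (drop LOW and benign)."""
    return [
        s for s in sites if s.impact in BURDEN_IMPACTS and is_pathogenic(s.clnsig)
    ]


def cumulative_counts(
    gene_sites: Sequence[VariantSite],
    cohort_label: str,
    declared_cohort_size: int | None = None,
) -> tuple[int, int]:
    """Cumulative (ac, an) over a gene's selected pathogenic sites.

    ``an`` is 2 x cohort size when the cohort's size is known (genotype
    cohorts); for frequency-only comparators it is the median per-variant
    an over the gene's sites, falling back to 2 x the declared size.
    """
    ac = sum(s.cohort(cohort_label).ac for s in gene_sites)
    sizes = [
        s.cohort(cohort_label).cohort_size
        for s in gene_sites
        if s.cohort(cohort_label).cohort_size is not None
    ]
    if sizes:
        an = 2 * max(sizes)
    elif gene_sites:
        an = int(median(s.cohort(cohort_label).an for s in gene_sites))
    elif declared_cohort_size is not None:
        an = 2 * declared_cohort_size
    else:
        an = 0
    if declared_cohort_size is not None and not sizes and not gene_sites:
        an = 2 * declared_cohort_size
    return ac, an


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    The two-sided p sums the probabilities of all tables with the same
    margins whose hypergeometric probability does not exceed that of the
    observed table.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError(f"negative cell in 2x2 table: {(a, b, c, d)}")
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exclude_low_coverage_genes(
    genes: Sequence[GeneModel],
    coverage: Iterable[CoverageSummary] | Mapping[str, float] | None,
    depth_frac: float = 0.10,
) -> list[GeneModel]:
    """Drop genes with more than ``depth_frac`` of the canonical transcript
    below 20x depth; genes without coverage data are retained with a
    warning."""
    if coverage is None:
        cov: dict[str, float] = {}
    elif isinstance(coverage, Mapping):
        cov = dict(coverage)
    else:
        cov = {c.gene_id: c.frac_below_20x for c in coverage}
    kept = []
    for g in genes:
        frac = cov.get(g.gene_id)
        if frac is None:
            if cov:
                warnings.warn(
                    f"no coverage summary for {g.gene_id}; retained", stacklevel=2
                )
            kept.append(g)
        elif frac > depth_frac:
            logger.info("gene %s excluded: frac_below_20x=%.3f > %.2f",
                        g.gene_id, frac, depth_frac)
        else:
            kept.append(g)
    return kept


def _direction(freq_a: float, freq_b: float) -> str:
    if freq_a > freq_b:
        return "enriched_in_a"
    if freq_a < freq_b:
        return "enriched_in_b"
    return "none"


@dataclass
class GeneBurdenOutput:
    """Gene-level burden table plus the site assignments panels reuse."""

    results: pd.DataFrame
    assignments_a: dict[str, list[VariantSite]]
    assignments_b: dict[str, list[VariantSite]]
    cohort_size_a: int | None
    cohort_size_b: int | None
    skipped: dict[str, str]


def run_gene_burden(
    sites_a: Iterable[VariantSite],
    sites_b: Iterable[VariantSite],
    genes: Sequence[GeneModel],
    coverage: Iterable[CoverageSummary] | Mapping[str, float] | None = None,
    cohort_label_a: str = "a",
    cohort_label_b: str = "b",
    flank: int = 5000,
    depth_frac: float = 0.10,
    declared_size_a: int | None = None,
    declared_size_b: int | None = None,
) -> GeneBurdenOutput:
    """Full gene-level burden pipeline.

    Stages: coverage exclusion -> gene regions (+/- flank) -> variant
    assignment -> impact/pathogenicity scope filter -> cumulative allele
    counts -> Fisher per gene -> BH across all tested genes. Genes with
    pathogenic variation in neither cohort are not tested.
    """
    tested_genes = exclude_low_coverage_genes(genes, coverage, depth_frac)
    regions = [gene_region(g, flank) for g in tested_genes]
    scoped_a = variant_scope_filter(sites_a)
    scoped_b = variant_scope_filter(sites_b)
    asg_a = assign_variants(scoped_a, regions)
    asg_b = assign_variants(scoped_b, regions)

    rows = []
    skipped: dict[str, str] = {
        g.gene_id: "low_coverage"
        for g in genes
        if g not in tested_genes
    }
    for g in tested_genes:
        ga, gb = asg_a[g.gene_id], asg_b[g.gene_id]
        if not ga and not gb:
            continue  # no pathogenic variation in either cohort
        ac_a, an_a = cumulative_counts(ga, cohort_label_a, declared_size_a)
        ac_b, an_b = cumulative_counts(gb, cohort_label_b, declared_size_b)
        if not ga and declared_size_a is not None:
            an_a = 2 * declared_size_a
        if not gb and declared_size_b is not None:
            an_b = 2 * declared_size_b
        if an_a == 0 or an_b == 0:
            skipped[g.gene_id] = "zero_an"
            logger.warning("gene %s skipped: allele number unavailable", g.gene_id)
            continue
        p = fisher_exact_2x2(ac_a, an_a - ac_a, ac_b, an_b - ac_b)
        rows.append(
            {
                "unit_id": g.gene_id,
                "ac_a": ac_a,
                "an_a": an_a,
                "ac_b": ac_b,
                "an_b": an_b,
                "cum_freq_a": ac_a / an_a,
                "cum_freq_b": ac_b / an_b,
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-2])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["direction"] = [
            _direction(fa, fb) for fa, fb in zip(df["cum_freq_a"], df["cum_freq_b"])
        ]
        df = df.sort_values(["p", "unit_id"], kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    return GeneBurdenOutput(
        results=df,
        assignments_a=asg_a,
        assignments_b=asg_b,
        cohort_size_a=declared_size_a,
        cohort_size_b=declared_size_b,
        skipped=skipped,
    )


def _panel_counts(
    panel: Panel,
    assignments: Mapping[str, list[VariantSite]],
    cohort_label: str,
    declared_size: int | None,
) -> tuple[int, int]:
    uniq: dict[tuple, VariantSite] = {}
    for gid in panel.gene_ids:
        for s in assignments.get(gid, ()):
            uniq[s.key] = s
    sites = list(uniq.values())
    ac = sum(s.cohort(cohort_label).ac for s in sites)
    sizes = [
        s.cohort(cohort_label).cohort_size
        for s in sites
        if s.cohort(cohort_label).cohort_size is not None
    ]
    if sizes:
        an = 2 * max(sizes)
    elif sites:
        an = int(median(s.cohort(cohort_label).an for s in sites))
    elif declared_size is not None:
        an = 2 * declared_size
    else:
        an = 0
    return ac, an


def run_panel_burden(
    panels: Sequence[Panel],
    gene_output: GeneBurdenOutput,
    cohort_label_a: str = "a",
    cohort_label_b: str = "b",
) -> pd.DataFrame:
    """Panel-level burden from gene-level assignments.

    Per panel the member genes' pathogenic alleles are summed (each site
    once, even when shared by several member genes), Fisher is applied to
    the summed table, the p-value is multiplied by the panel's gene count
    (capped at 1), and BH runs across panels on the corrected values.
    """
    tested = set(gene_output.results["unit_id"]) | set(gene_output.skipped)
    rows = []
    for panel in panels:
        if not any(g in gene_output.assignments_a for g in panel.gene_ids):
            logger.warning("panel %s omitted: no tested genes", panel.panel_id)
            continue
        ac_a, an_a = _panel_counts(
            panel, gene_output.assignments_a, cohort_label_a, gene_output.cohort_size_a
        )
        ac_b, an_b = _panel_counts(
            panel, gene_output.assignments_b, cohort_label_b, gene_output.cohort_size_b
        )
        if ac_a == 0 and ac_b == 0:
            continue
        if an_a == 0 or an_b == 0:
            logger.warning("panel %s skipped: allele number unavailable", panel.panel_id)
            continue
        p = fisher_exact_2x2(ac_a, an_a - ac_a, ac_b, an_b - ac_b)
        rows.append(
            {
                "unit_id": panel.panel_id,
                "n_genes": panel.n_genes,
                "ac_a": ac_a,
                "an_a": an_a,
                "ac_b": ac_b,
                "an_b": an_b,
                "cum_freq_a": ac_a / an_a,
                "cum_freq_b": ac_b / an_b,
                "p": p,
                "p_gene_corrected": min(1.0, p * panel.n_genes),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "n_genes", "ac_a", "an_a", "ac_b", "an_b",
            "cum_freq_a", "cum_freq_b", "p", "p_gene_corrected",
        ],
    )
    if len(df):
        df["q"] = bh_fdr(df["p_gene_corrected"].to_numpy())
        df["direction"] = [
            _direction(fa, fb) for fa, fb in zip(df["cum_freq_a"], df["cum_freq_b"])
        ]
        df = df.sort_values(["p_gene_corrected", "unit_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        df["q"] = []
        df["direction"] = []
    return df
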