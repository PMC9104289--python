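"""Structural-variant quality filtering and loss-of-function calling.

Quality gates follow the Smoove author recommendations: heterozygous
calls with mean split-read het quality (MSHQ) < 3, deletions with depth
fold-change (DHFFC) >= 0.7, duplications with DHFFC <= 1.25, and records
without at least one split read per allele are excluded; break-end (BND)
records are dropped as biologically uncertain.

LoF rules (deletion-intolerance convention): a DEL is LoF on any exon
overlap; a DUP additionally requires both breakpoints inside the gene
body (CDS bounds, inclusive); an INV requires exon overlap plus at least
one breakpoint inside the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, StructuralVariantRecord

MIN_MSHQ = 3.0
DEL_MAX_DHFFC = 0.7   # deletions with DHFFC >= this are excluded
DUP_MIN_DHFFC = 1.25  # duplications with DHFFC <= this are excluded


class MissingQualityFieldError(ValueError):
    pass


def _passes_quality(sv: StructuralVariantRecord) -> bool:
    if sv.svtype == "BND" or sv.excluded_bnd:
        return False
    if sv.dhffc is None and sv.svtype in ("DEL", "DUP"):
        raise MissingQualityFieldError(
            f"{sv.chrom}:{sv.start} {sv.svtype}: DHFFC required for quality filter"
        )
    if sv.is_het_call:
        if sv.mshq is None:
            raise MissingQualityFieldError(
                f"{sv.chrom}:{sv.start} {sv.svtype}: MSHQ required for het call"
            )
        if sv.mshq < MIN_MSHQ:
            return False
    if sv.svtype == "DEL" and sv.dhffc >= DEL_MAX_DHFFC:
        return False
    if sv.svtype == "DUP" and sv.dhffc <= DUP_MIN_DHFFC:
        return False
    if sv.split_reads_per_allele is None or sv.split_reads_per_allele < 1:
        return False
    return True


def filter_high_quality(
    svs: Iterable[StructuralVariantRecord],
) -> list[StructuralVariantRecord]:
    """Apply all Smoove-recommended gates; idempotent and order-independent."""
    return [sv for sv in svs if _passes_quality(sv)]


@dataclass(frozen=True)
class LofCall:
    sv: StructuralVariantRecord
    gene_id: str
    rule_fired: str


def _overlaps_exon(sv: StructuralVariantRecord, gene: GeneModel) -> bool:
    return any(sv.start <= e and sv.end >= s for s, e in gene.exons)


def _breakpoints_in_gene(sv: StructuralVariantRecord, gene: GeneModel) -> int:
    if sv.chrom != gene.chrom:
        return 0
    return sum(
        1 for bp in (sv.start, sv.end) if gene.cds_start <= bp <= gene.cds_end
    )


def classify_lof(sv: StructuralVariantRecord, gene: GeneModel) -> LofCall | None:
    """Loss-of-function call for one SV against one gene, or None.

    DEL: any exon overlap. DUP: exon overlap and both breakpoints within
    [cds_start, cds_end]. INV: exon overlap and >=1 breakpoint within the
    gene. BND must be filtered out beforehand.
    """
    if sv.svtype == "BND":
        raise ValueError("BND records must be removed before LoF classification")
    if sv.chrom != gene.chrom or not _overlaps_exon(sv, gene):
        return None
    n_bp = _breakpoints_in_gene(sv, gene)
    if sv.svtype == "DEL":
        return LofCall(sv, gene.gene_id, "del_exon_overlap")
    if sv.svtype == "DUP":
        if n_bp == 2:
            return LofCall(sv, gene.gene_id, "dup_exon_overlap_both_bp_in_gene")
        return None
    if sv.svtype == "INV":
        if n_bp >= 1:
            return LofCall(sv, gene.gene_id, "inv_exon_overlap_bp_in_gene")
        return None
    raise ValueError(f"unexpected SVTYPE {sv.svtype!r}")


def sv_gene_burden(
    svs_a: Iterable[StructuralVariantRecord],
    svs_b: Iterable[StructuralVariantRecord],
    genes: Sequence[GeneModel],
    cohort_label_a: str = "a",
    cohort_label_b: str = "b",
    af_cap: float = 0.01,
) -> pd.DataFrame:
    """Per-gene cumulative LoF SV frequencies and their absolute difference.

    Within each cohort independently, LoF SVs at frequency >= ``af_cap``
    are excluded as likely benign; remaining allele frequencies are summed
    per gene. No significance test is performed — the comparison is purely
    descriptive, and genes whose cumulative frequency is implausibly high
    are flagged as possible overlapping complex-SV artifacts.
    """
    svs_a, svs_b = list(svs_a), list(svs_b)
    rows = []
    for gene in genes:
        sums = {}
        counts = {}
        for label, svs in ((cohort_label_a, svs_a), (cohort_label_b, svs_b)):
            total, n = 0.0, 0
            for sv in svs:
                if classify_lof(sv, gene) is None:
                    continue
                af = sv.af(label) if label in sv.counts else None
                if af is None or af >= af_cap:
                    continue
                total += af
                n += 1
            sums[label], counts[label] = total, n
        fa, fb = sums[cohort_label_a], sums[cohort_label_b]
        rows.append(
            {
                "gene_id": gene.gene_id,
                "cum_freq_a": fa,
                "cum_freq_b": fb,
                "abs_diff": abs(fa - fb),
                "n_sv_a": counts[cohort_label_a],
                "n_sv_b": counts[cohort_label_b],
                # many rare overlapping calls piling far above the per-SV cap
                # suggest one mis-genotyped complex event
                "complex_artifact_flag": fa > 0.10 or fb > 0.10,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "cum_freq_a", "cum_freq_b", "abs_diff",
            "n_sv_a", "n_sv_b", "complex_artifact_flag",
        ],
    )


def sv_length_spectrum(
    svs: Sequence[StructuralVariantRecord],
    bins_per_decade: int = 10,
) -> dict[str, object]:
    """Log10 length histograms per SV type plus per-individual summaries.

    Returns a dict with ``histograms`` (svtype -> (bin_edges, counts) on
    log10 length), and, when genotypes are available, ``per_individual``
    (DataFrame with per-type counts and total affected length) and
    ``median_affected_length``.
    """
    analysed = [sv for sv in svs if sv.svtype != "BND"]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for svtype in ("DEL", "DUP", "INV"):
        lengths = np.array(
            [sv.length for sv in analysed if sv.svtype == svtype], dtype=float
        )
        if lengths.size == 0:
            histograms[svtype] = (np.array([]), np.array([]))
            continue
        logs = np.log10(lengths)
        lo = np.floor(logs.min() * bins_per_decade) / bins_per_decade
        hi = np.ceil(logs.max() * bins_per_decade) / bins_per_decade + 1e-9
        edges = np.arange(lo, hi + 1.0 / bins_per_decade, 1.0 / bins_per_decade)
        counts, edges = np.histogram(logs, bins=edges)
        histograms[svtype] = (edges, counts)

    out: dict[str, object] = {"histograms": histograms}
    with_gt = [sv for sv in analysed if sv.genotypes is not None]
    if with_gt:
        n_samples = len(with_gt[0].genotypes)
        carried = np.zeros(n_samples, dtype=int)
        affected = np.zeros(n_samples, dtype=float)
        per_type = {t: np.zeros(n_samples, dtype=int) for t in ("DEL", "DUP", "INV")}
        for sv in with_gt:
            g = np.asarray(sv.genotypes)
            has = g > 0
            carried += has
            affected += has * sv.length  # overlapping SVs add up, not merged
            per_type[sv.svtype] += has
        df = pd.DataFrame(
            {
                "n_DEL": per_type["DEL"],
                "n_DUP": per_type["DUP"],
                "n_INV": per_type["INV"],
                "n_sv": carried,
                "affected_length": affected,
            }
        )
        out["per_individual"] = df
        out["median_affected_length"] = float(np.median(affected))
    return out
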