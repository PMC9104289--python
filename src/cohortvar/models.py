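"""Core data model shared by all pipeline stages.

Coordinates are 1-based inclusive throughout (VCF convention); BED inputs
are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


VARIANT_CLASSES = ("SNV", "insertion", "deletion")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
SV_TYPES = ("DEL", "DUP", "INV", "BND")


def classify_alleles(ref: str, alt: str) -> str:
    """Classify a normalized monoallelic REF/ALT pair.

    Equal lengths are substitutions (SNV for length 1; longer balanced
    changes are grouped with SNVs), longer ALT is an insertion, longer REF
    a deletion.
    """
    if len(ref) == len(alt):
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass
class CohortCounts:
    """Allele counts for one variant in one cohort.

    ``carriers`` is the number of individuals with at least one alternate
    allele; it is ``None`` for frequency-only cohorts (AC/AN published
    without genotypes), in which case carrier-based operations must raise.
    """

    ac: int
    an: int
    carriers: int | None = None
    cohort_size: int | None = None  # diploid individuals, when known

    def __post_init__(self) -> None:
        if not (0 <= self.ac <= self.an):
            raise ValueError(f"require 0 <= ac <= an, got ac={self.ac} an={self.an}")
        if self.carriers is not None and self.carriers > self.ac:
            raise ValueError(f"carriers ({self.carriers}) > ac ({self.ac})")
        if self.cohort_size is not None and self.an > 2 * self.cohort_size:
            raise ValueError(
                f"an ({self.an}) exceeds 2 x cohort size ({self.cohort_size})"
            )

    @property
    def af(self) -> float:
        if self.an == 0:
            raise ZeroDivisionError("allele frequency undefined when an == 0")
        return self.ac / self.an


@dataclass
class VariantSite:
    """One normalized, left-aligned small-variant allele with annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    counts: dict[str, CohortCounts] = field(default_factory=dict)
    impact: str | None = None
    clnsig: str | None = None
    clnrevstat: str | None = None
    gene_ids: list[str] = field(default_factory=list)
    reference_af: float | None = None  # comparator-database frequency, if annotated

    def __post_init__(self) -> None:
        if self.impact is not None and self.impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")

    @property
    def variant_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    def cohort(self, label: str) -> CohortCounts:
        return self.counts[label]

    def af(self, label: str) -> float:
        return self.counts[label].af

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneModel:
    """Gene with CDS bounds and exon structure (1-based inclusive)."""

    gene_id: str
    chrom: str
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    canonical_tx_length: int = 0
    is_AR: bool = True

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise ValueError(
                f"{self.gene_id}: cds_start {self.cds_start} > cds_end {self.cds_end}"
            )
        self.exons = merge_intervals(self.exons)
        lo, hi = self.cds_start - 1_000_000, self.cds_end + 1_000_000
        for s, e in self.exons:
            if s < lo or e > hi:
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) implausibly far from CDS"
                )
        if not self.canonical_tx_length:
            self.canonical_tx_length = sum(e - s + 1 for s, e in self.exons) or (
                self.cds_end - self.cds_start + 1
            )
        if self.canonical_tx_length <= 0:
            raise ValueError(f"{self.gene_id}: canonical_tx_length must be positive")


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort 1-based inclusive intervals and merge overlapping/adjacent ones."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s > e:
            raise ValueError(f"interval start {s} > end {e}")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class Panel:
    """Gene panel restricted to autosomal-recessive genes."""

    panel_id: str
    name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        # de-duplicate, preserving order
        self.gene_ids = list(dict.fromkeys(self.gene_ids))
        if not self.gene_ids:
            raise ValueError(f"panel {self.panel_id} has no genes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class CoverageSummary:
    """Fraction of a gene's canonical transcript covered below 20x depth."""

    gene_id: str
    frac_below_20x: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_below_20x <= 1.0):
            raise ValueError(
                f"{self.gene_id}: frac_below_20x {self.frac_below_20x} outside [0,1]"
            )


@dataclass
class StructuralVariantRecord:
    """One structural-variant call with Smoove/duphold-style quality fields.

    ``mshq`` is the mean split-read heterozygote genotype quality, ``dhffc``
    the read-depth fold change of the event interval versus its flanks, and
    ``split_reads_per_allele`` the cohort-wide split-read support.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    mshq: float | None = None
    dhffc: float | None = None
    split_reads_per_allele: int | None = None
    is_het_call: bool = True
    counts: dict[str, CohortCounts] = field(default_factory=dict)
    genotypes: list[int] | None = None  # per-sample dosage, optional
    sv_id: str | None = None
    excluded_bnd: bool = False

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype != "BND" and self.end < self.start:
            raise ValueError(
                f"SV at {self.chrom}:{self.start}: END {self.end} < POS {self.start}"
            )
        if self.svtype == "BND":
            self.excluded_bnd = True

    @property
    def length(self) -> int | None:
        if self.svtype == "BND":
            return None
        return self.end - self.start + 1

    def af(self, label: str) -> float:
        return self.counts[label].af
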