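"""Allele-frequency spectrum: per-site counts, frequency tiers, and
impact x tier x class tabulations.

Tier boundaries (alternate-allele frequency ``af``):

* ``">0.5%"``   — af > 0.005 (includes common and fixed alleles)
* ``"0.1-0.5%"`` — 0.001 <= af <= 0.005
* ``"<0.1%"``   — 0 < af < 0.001

Every polymorphic site falls in exactly one tier. "Common" additionally
flags MAF >= 1% and "fixed" af == 1; a singleton is a variant carried by
exactly one individual (a hom-alt carrier still counts as one singleton).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import IMPACTS, VariantSite

TIER_LABELS = (">0.5%", "0.1-0.5%", "<0.1%")

COMMON_MAF = 0.01  # spectrum-reporting threshold (MAF >= 1%)


class CarriersUnavailableError(ValueError):
    """Raised when a carrier-based operation meets a frequency-only cohort."""


def site_counts(dosages: Sequence[int | float]) -> tuple[int, int, int, float]:
    """AC/AN/carriers/AF from a per-sample dosage row.

    Dosages are 0/1/2 with missing encoded as -1 (or NaN).
    """
    arr = np.asarray(dosages, dtype=float)
    called = arr[(~np.isnan(arr)) & (arr >= 0)]
    an = 2 * called.size
    if an == 0:
        raise ZeroDivisionError("allele frequency undefined: no called genotypes")
    ac = int(called.sum())
    carriers = int((called > 0).sum())
    return ac, an, carriers, ac / an


@dataclass(frozen=True)
class TierLabel:
    label: str
    is_singleton: bool = False
    is_common: bool = False
    is_fixed: bool = False


def classify_tier(af: float, *, carriers: int | None = None) -> TierLabel:
    """Assign the frequency tier for a polymorphic site (0 < af <= 1)."""
    if not (0 < af <= 1):
        raise ValueError(f"tier undefined for af={af}; require 0 < af <= 1")
    if af > 0.005:
        label = ">0.5%"
    elif af >= 0.001:
        label = "0.1-0.5%"
    else:
        label = "<0.1%"
    return TierLabel(
        label=label,
        is_singleton=(carriers == 1) if carriers is not None else False,
        is_common=af >= COMMON_MAF,
        is_fixed=af == 1.0,
    )


def is_singleton(site: VariantSite, cohort_label: str) -> bool:
    """True when exactly one individual carries the alternate allele."""
    c = site.cohort(cohort_label)
    if c.carriers is None:
        raise CarriersUnavailableError(
            f"{site.chrom}:{site.pos}: carrier counts unavailable in "
            f"frequency-only cohort {cohort_label!r}"
        )
    return c.carriers == 1


@dataclass
class SpectrumTable:
    """Variant counts indexed by (impact, tier, variant class)."""

    counts: pd.DataFrame  # columns: impact, tier, variant_class, count

    @classmethod
    def from_sites(cls, sites: Iterable[VariantSite], cohort_label: str) -> "SpectrumTable":
        rows = [
            {
                "impact": s.impact or "MODIFIER",
                "tier": classify_tier(s.af(cohort_label)).label,
                "variant_class": s.variant_class,
                "count": 1,
            }
            for s in sites
        ]
        df = (
            pd.DataFrame(rows, columns=["impact", "tier", "variant_class", "count"])
            .groupby(["impact", "tier", "variant_class"], as_index=False)["count"]
            .sum()
        )
        return cls(counts=df)

    @classmethod
    def from_counts(
        cls, cells: Mapping[tuple[str, str, str], int]
    ) -> "SpectrumTable":
        """Build directly from (impact, tier, class) -> count cells."""
        df = pd.DataFrame(
            [
                {"impact": i, "tier": t, "variant_class": c, "count": n}
                for (i, t, c), n in cells.items()
            ]
        )
        if (df["count"] < 0).any():
            raise ValueError("negative cell count")
        return cls(counts=df)

    def marginal(self, by: str) -> pd.Series:
        """Marginal totals over one axis ('impact', 'tier' or 'variant_class')."""
        return self.counts.groupby(by)["count"].sum()

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())

    def to_long_tsv(self) -> str:
        order = {imp: i for i, imp in enumerate(IMPACTS)}
        df = self.counts.sort_values(
            ["tier", "variant_class", "impact"],
            key=lambda s: s.map(order) if s.name == "impact" else s,
        )
        return df.to_csv(sep="\t", index=False)


def spectrum_table(sites: Iterable[VariantSite], cohort_label: str) -> SpectrumTable:
    return SpectrumTable.from_sites(sites, cohort_label)


def singleton_fraction_by_class(
    sites: Iterable[VariantSite], cohort_label: str
) -> dict[str, float]:
    """Fraction of each variant class observed in a single individual.

    Classes with no sites are omitted (fraction undefined).
    """
    totals: dict[str, int] = {}
    singles: dict[str, int] = {}
    for s in sites:
        cls_ = s.variant_class
        totals[cls_] = totals.get(cls_, 0) + 1
        if is_singleton(s, cohort_label):
            singles[cls_] = singles.get(cls_, 0) + 1
    return {c: singles.get(c, 0) / n for c, n in totals.items()}


def per_individual_summary(genotype_matrix: np.ndarray) -> pd.DataFrame:
    """Per-sample het / hom-alt / total counts from a sites x samples
    dosage matrix (0/1/2, missing as -1)."""
    m = np.asarray(genotype_matrix)
    het = (m == 1).sum(axis=0)
    hom = (m == 2).sum(axis=0)
    return pd.DataFrame({"het": het, "hom": hom, "total": het + hom})
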