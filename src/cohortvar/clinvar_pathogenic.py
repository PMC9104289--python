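"""Selection of rare ClinVar pathogenic / likely-pathogenic variants and
confidence grading by review status ("star" scheme).

Confidence tiers follow the standard ClinVar star counts: 0-1 stars ->
tier 1 (low), 2 stars (criteria provided, multiple submitters, no
conflicts) -> tier 2 (moderate), 3 stars (expert panel) -> tier 3,
4 stars (practice guideline) -> tier 4.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .frequency_db import is_singleton
from .models import VariantSite

#: review-status substrings -> star-derived confidence tier
_REVSTAT_TIERS = (
    ("practice_guideline", 4),
    ("reviewed_by_expert_panel", 3),
    ("criteria_provided,_multiple_submitters,_no_conflicts", 2),
)


def is_pathogenic(clnsig: str | None) -> bool:
    """True for Pathogenic / Likely_pathogenic labels without conflicting
    interpretations; unknown or missing labels are not pathogenic."""
    if not clnsig:
        return False
    low = clnsig.strip().lower().replace(" ", "_")
    return "pathogenic" in low and "conflicting" not in low


def confidence_tier(clnrevstat: str | None) -> int:
    """Map a ClinVar review-status string to confidence tier 1-4."""
    if not clnrevstat:
        warnings.warn("missing review status; assigning tier 1", stacklevel=2)
        return 1
    norm = clnrevstat.strip().lower().replace(" ", "_")
    for key, tier in _REVSTAT_TIERS:
        if key in norm:
            return tier
    if "criteria_provided" not in norm and "no_assertion" not in norm:
        warnings.warn(
            f"unknown review status {clnrevstat!r}; assigning tier 1", stacklevel=2
        )
    return 1


@dataclass
class PathogenicCall:
    site: VariantSite
    significance: str  # 'pathogenic' or 'likely_pathogenic'
    confidence_tier: int
    reference_af: float | None
    reference_af_missing: bool


@dataclass
class PathogenicSummary:
    calls: list[PathogenicCall]
    tier_counts: dict[int, int]
    n_private: int | None  # None when carriers unavailable
    n_nonprivate: int | None

    @property
    def total(self) -> int:
        return len(self.calls)


def _significance(clnsig: str) -> str:
    return "likely_pathogenic" if clnsig.lower().startswith("likely") else "pathogenic"


def select_rare_pathogenic(
    sites: Iterable[VariantSite],
    cohort_label: str | None = None,
    threshold: float = 0.001,
) -> PathogenicSummary:
    """Select pathogenic/likely-pathogenic sites rare in the comparator
    database (reference AF < ``threshold``; missing reference AF counts as
    rare) and grade each by review-status confidence tier.

    When ``cohort_label`` names a genotype cohort, the summary also splits
    calls into private (single carrier) and non-private.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"rare threshold must be in (0, 1], got {threshold}")
    calls = [
        PathogenicCall(
            site=s,
            significance=_significance(s.clnsig),
            confidence_tier=confidence_tier(s.clnrevstat),
            reference_af=s.reference_af,
            reference_af_missing=s.reference_af is None,
        )
        for s in sites
        if is_pathogenic(s.clnsig)
        and (s.reference_af is None or s.reference_af < threshold)
    ]
    tier_counts = dict(Counter(c.confidence_tier for c in calls))
    n_private = n_nonprivate = None
    if cohort_label is not None:
        flags = [is_singleton(c.site, cohort_label) for c in calls]
        n_private = sum(flags)
        n_nonprivate = len(flags) - n_private
    return PathogenicSummary(
        calls=calls,
        tier_counts=tier_counts,
        n_private=n_private,
        n_nonprivate=n_nonprivate,
    )


def select_high_impact_in_gene_list(
    sites: Iterable[VariantSite], gene_list: Sequence[str]
) -> list[VariantSite]:
    """HIGH-impact variants in a medically-actionable gene list.

    Returns candidates only; clinical curation of the candidates is a
    human step outside this package.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    wanted = set(gene_list)
    return [
        s
        for s in sites
        if s.impact == "HIGH" and any(g in wanted for g in s.gene_ids)
    ]
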