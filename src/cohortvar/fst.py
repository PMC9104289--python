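"""Weir-Cockerham fixation-index estimation between cohorts.

The two-level variance-components estimator partitions allele-frequency
variance into components among populations (a), among individuals within
populations (b), and within individuals (c). For population i with n_i
diploid individuals, alternate allele frequency p_i, and observed
heterozygote proportion h_i, with r populations:

    n_bar = mean n_i                    n_c = (r*n_bar - sum n_i^2/(r*n_bar)) / (r-1)
    p_bar = sum n_i p_i / (r*n_bar)     s2 = sum n_i (p_i-p_bar)^2 / ((r-1)*n_bar)
    h_bar = sum n_i h_i / (r*n_bar)

    a = (n_bar/n_c) * [ s2 - (p_bar*(1-p_bar) - s2*(r-1)/r - h_bar/4) / (n_bar-1) ]
    b = (n_bar/(n_bar-1)) * [ p_bar*(1-p_bar) - s2*(r-1)/r - h_bar*(2*n_bar-1)/(4*n_bar) ]
    c = h_bar / 2

The multi-site estimate is the ratio of sums, theta = sum(a) / sum(a+b+c),
over sites where the denominator is defined; negative estimates are
reported as computed. Sites monomorphic across all populations are
undefined and excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class FstSiteComponents:
    n: np.ndarray        # per-population diploid sample sizes
    p: np.ndarray        # per-population alternate allele frequencies
    h: np.ndarray        # per-population observed het proportions
    a: float
    b: float
    c: float
    defined: bool

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if not self.defined or denom == 0:
            return float("nan")
        return self.a / denom


def wc_site_components(
    n: Sequence[float],
    p: Sequence[float],
    h: Sequence[float] | None = None,
) -> FstSiteComponents:
    """Variance components for one biallelic site.

    ``h`` defaults to the HWE expectation 2p(1-p) for frequency-only
    cohorts. A site monomorphic in the pooled sample is flagged undefined.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    r = n.size
    if r < 2:
        raise ValueError("need at least two populations")
    if (n < 1).any():
        raise ValueError("every population needs n_i >= 1")
    if h is None:
        h = 2 * p * (1 - p)
    h = np.asarray(h, dtype=float)

    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)

    if p_bar in (0.0, 1.0):
        return FstSiteComponents(n=n, p=p, h=h, a=0.0, b=0.0, c=0.0, defined=False)

    inner = p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return FstSiteComponents(n=n, p=p, h=h, a=a, b=b, c=c, defined=True)


def fst_average(sites: Iterable[FstSiteComponents]) -> float:
    """Ratio-of-sums estimate over defined sites."""
    num = den = 0.0
    any_defined = False
    for s in sites:
        if not s.defined:
            continue
        any_defined = True
        num += s.a
        den += s.a + s.b + s.c
    if not any_defined:
        raise ValueError("no defined (polymorphic) sites")
    if den == 0:
        raise ValueError("total variance is zero; estimate undefined")
    return num / den


def fst_windows(
    sites: Sequence[FstSiteComponents],
    window: int = 1000,
    step: int | None = None,
) -> pd.DataFrame:
    """Window averages over consecutive blocks of ``window`` defined sites.

    With the default ``step == window`` the blocks tile the genome order
    without overlap; a smaller step gives genuinely sliding windows. The
    final partial block is reported with its actual size.
    """
    step = window if step is None else step
    defined = [s for s in sites if s.defined]
    rows = []
    start = 0
    idx = 0
    while start < len(defined):
        block = defined[start : start + window]
        rows.append(
            {
                "window": idx,
                "n_sites": len(block),
                "fst": fst_average(block),
            }
        )
        if start + window >= len(defined):
            break
        start += step
        idx += 1
    return pd.DataFrame(rows, columns=["window", "n_sites", "fst"])


def pooled_maf(n: Sequence[float], p: Sequence[float]) -> float:
    """Sample-size weighted pooled minor allele frequency."""
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    pool = (n * p).sum() / n.sum()
    return min(pool, 1 - pool)


def maf_prune(
    sites: Sequence[FstSiteComponents], threshold: float = 0.01
) -> list[FstSiteComponents]:
    """Keep sites with pooled MAF strictly above ``threshold``."""
    return [s for s in sites if pooled_maf(s.n, s.p) > threshold]
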