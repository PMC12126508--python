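"""Detection/exceedance screening, distributional summaries and the
reported-vs-measured ethanol comparison.

Detection means the instrument saw the element (entry not censored);
exceedance means an observed concentration is strictly above the element's
AMPHORA screening threshold on the mg/l pure-alcohol scale, with censored
entries counted as non-exceeding. Medians and 99th percentiles are computed
after LOD/2 substitution using linear interpolation between closest ranks
(rank position h = (n-1)p + 1), the convention also used by
``numpy.quantile(..., method="linear")``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import ElementReference, SampleRecord
from .preprocess import (
    MG_PER_L_BEVERAGE,
    MG_PER_L_PA,
    ConcentrationVector,
    per_litre_to_per_gram,
    substitute_censored,
    vector_from_samples,
    vector_to_pure_alcohol,
)

__all__ = [
    "percentile",
    "ElementSummary",
    "summarize_element",
    "summarize_samples",
    "PairedEthanolComparison",
    "wilcoxon_signed_rank",
    "ethanol_comparison",
    "PriceSummary",
    "price_summary",
]


def percentile(values: Sequence[float], p: float, *, method: str = "linear") -> float:
    """Percentile of ``values`` at fraction ``p`` in [0, 1].

    The default convention interpolates linearly between closest ranks at
    position h = (n-1)p + 1: p=0 gives the minimum, p=1 the maximum, and
    p=0.5 the usual median (mean of the two middle values for even n).
    Other numpy quantile method names are accepted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of empty sequence")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"percentile fraction must be in [0, 1], got {p}")
    return float(np.quantile(arr, p, method=method))


@dataclass(frozen=True)
class ElementSummary:
    """Per-element screening counts and distribution summaries.

    Concentration statistics are reported on both pure-alcohol scales:
    mg/l p.a. (``*_mg_l``) and mg/g p.a. (``*_mg_g``). Exceedance fields are
    ``None`` when the element has no screening threshold.
    """

    element: str
    n: int
    n_detected: int
    n_exceeding: Optional[int]
    min_mg_l: float
    max_mg_l: float
    median_mg_l: float
    p99_mg_l: float

    @property
    def pct_detected(self) -> float:
        return 100.0 * self.n_detected / self.n

    @property
    def pct_exceeding(self) -> Optional[float]:
        if self.n_exceeding is None:
            return None
        return 100.0 * self.n_exceeding / self.n

    @property
    def min_mg_g(self) -> float:
        return per_litre_to_per_gram(self.min_mg_l)

    @property
    def max_mg_g(self) -> float:
        return per_litre_to_per_gram(self.max_mg_l)

    @property
    def median_mg_g(self) -> float:
        return per_litre_to_per_gram(self.median_mg_l)

    @property
    def p99_mg_g(self) -> float:
        return per_litre_to_per_gram(self.p99_mg_l)


def summarize_element(
    vector: ConcentrationVector,
    ref: ElementReference,
    abvs: Sequence[float] | None = None,
    *,
    percentile_method: str = "linear",
) -> ElementSummary:
    """Screen one element and summarise its concentration distribution.

    Beverage-scale vectors are first normalised to mg/l p.a. with the
    per-sample ABVs. Exceedance is evaluated on observed values only
    (censored entries cannot exceed); the median and 99th percentile are
    computed after LOD/2 substitution.
    """
    if vector.element != ref.element:
        raise ValueError(f"vector is {vector.element!r} but reference is {ref.element!r}")
    if vector.units == MG_PER_L_BEVERAGE:
        if abvs is None:
            raise ValueError("beverage-scale vector needs per-sample ABVs")
        vector = vector_to_pure_alcohol(vector, abvs)
    elif vector.units != MG_PER_L_PA:
        raise ValueError(f"cannot summarise units {vector.units!r}")

    n = len(vector)
    n_detected = n - vector.n_censored
    if ref.amphora_threshold is None:
        n_exceeding = None
    else:
        observed = vector.values[~vector.censored]
        n_exceeding = int(np.sum(observed > ref.amphora_threshold))

    filled = substitute_censored(vector, ref.lod) if vector.n_censored else vector
    values = filled.values
    return ElementSummary(
        element=vector.element,
        n=n,
        n_detected=n_detected,
        n_exceeding=n_exceeding,
        min_mg_l=float(values.min()),
        max_mg_l=float(values.max()),
        median_mg_l=percentile(values, 0.5, method=percentile_method),
        p99_mg_l=percentile(values, 0.99, method=percentile_method),
    )


def summarize_samples(
    samples: Sequence[SampleRecord],
    references: dict[str, ElementReference],
    *,
    elements: Sequence[str] | None = None,
    percentile_method: str = "linear",
) -> list[ElementSummary]:
    """Summarise every element present in the sample table (or a selection)."""
    if elements is None:
        seen: list[str] = []
        for rec in samples:
            for element in rec.concentrations:
                if element not in seen:
                    seen.append(element)
        elements = seen
    abvs = [rec.measured_abv for rec in samples]
    out = []
    for element in elements:
        vector = vector_from_samples(samples, element)
        ref = references.get(element, ElementReference(element=element))
        out.append(
            summarize_element(vector, ref, abvs, percentile_method=percentile_method)
        )
    return out


@dataclass(frozen=True)
class PairedEthanolComparison:
    """Paired comparison of reported vs measured ethanol strength (% v/v)."""

    n_pairs: int
    differences: np.ndarray  # measured - reported, zero differences included
    w_statistic: float  # sum of positive signed ranks (zeros dropped)
    p_value: float
    method: str  # "exact" or "normal"
    alpha: float
    reported_mean: float
    reported_median: float
    reported_iqr: tuple[float, float]
    measured_mean: float
    measured_median: float
    measured_iqr: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _signed_rank_p_exact(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the positive-rank sum, mid-rank ties allowed.

    ``ranks2`` are the doubled (hence integer) ranks of the nonzero |d|;
    the null distribution of the doubled statistic is built by subset-sum
    convolution over all 2^n equiprobable sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    paired: Sequence[tuple[float, float]],
    *,
    exact_max_n: int = 15,
    alpha: float = 0.05,
) -> PairedEthanolComparison:
    """Wilcoxon signed-rank test on (reported, measured) pairs.

    Differences are measured - reported; pairs with a missing reported value
    must be excluded by the caller (see :func:`ethanol_comparison`). Zero
    differences are dropped; tied absolute differences receive mid-ranks.
    The null distribution is exact (full enumeration) for up to
    ``exact_max_n`` nonzero pairs and a tie-corrected normal approximation
    with continuity correction beyond that. The p-value is two-sided.
    """
    paired = list(paired)
    if not paired:
        raise ValueError("need at least one complete pair")
    diffs = np.array([m - r for r, m in paired], dtype=float)
    reported = np.array([r for r, _ in paired], dtype=float)
    measured = np.array([m for _, m in paired], dtype=float)

    nonzero = diffs[diffs != 0.0]
    summary = dict(
        n_pairs=len(paired),
        differences=diffs,
        alpha=alpha,
        reported_mean=float(reported.mean()),
        reported_median=float(np.median(reported)),
        reported_iqr=(percentile(reported, 0.25), percentile(reported, 0.75)),
        measured_mean=float(measured.mean()),
        measured_median=float(np.median(measured)),
        measured_iqr=(percentile(measured, 0.25), percentile(measured, 0.75)),
    )
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return PairedEthanolComparison(
            w_statistic=0.0, p_value=1.0, method="degenerate", **summary
        )

    ranks = stats.rankdata(np.abs(nonzero))
    w_pos = float(ranks[nonzero > 0].sum())
    n = nonzero.size
    if n <= exact_max_n:
        p = _signed_rank_p_exact(ranks * 2.0, w_pos * 2.0)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(np.abs(nonzero), return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        d = w_pos - mu
        # continuity correction pulls the statistic half a unit toward the mean
        d -= 0.5 * math.copysign(1.0, d) if d != 0 else 0.0
        z = d / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return PairedEthanolComparison(
        w_statistic=w_pos, p_value=min(1.0, p), method=method, **summary
    )


def ethanol_comparison(
    samples: Sequence[SampleRecord], **kwargs
) -> PairedEthanolComparison:
    """Reported-vs-measured ethanol test over samples with a reported value."""
    pairs = [
        (rec.reported_abv, rec.measured_abv)
        for rec in samples
        if rec.reported_abv is not None
    ]
    return wilcoxon_signed_rank(pairs, **kwargs)


@dataclass(frozen=True)
class PriceSummary:
    mean: float
    sd: Optional[float]  # sample (n-1) standard deviation; None when n < 2
    n: int


def price_summary(prices: Sequence[Optional[float]]) -> PriceSummary:
    """Mean and sample SD of the known prices (euros/litre)."""
    known = np.array([p for p in prices if p is not None], dtype=float)
    if known.size == 0:
        raise ValueError("no known prices")
    sd = float(known.std(ddof=1)) if known.size >= 2 else None
    return PriceSummary(mean=float(known.mean()), sd=sd, n=int(known.size))
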