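"""Chronic-exposure health-risk assessment: EDI, THQ and MOE.

For each element of concern the pipeline takes a concentration summary
level (median or 99th percentile, after LOD/2 substitution) expressed in
mg per gram of pure alcohol (MCS), and a drinker scenario with daily
ethanol mass MDI (g/day) and body weight BW (kg), and computes

    EDI = MDI * MCS / BW                                  [mg/kg bw/day]
    THQ = (MCS * MDI * EF * ED) / (RfD * BW * AET)        [dimensionless]
    MOE = BMDL_x / EDI                                    [dimensionless]

With the non-carcinogenic averaging time AET = 365 * ED and EF = 365
days/year the THQ reduces to EDI / RfD. A THQ above 1.0 flags an elevated
non-carcinogenic risk; an MOE below 100 flags a public health concern for
a non-genotoxic substance such as lead.

Elements with an oral reference dose are routed to THQ; elements with only
benchmark-dose lower bounds (lead) are routed to MOE, one value per health
endpoint.

:class:`RiskAssessment` packages the whole computation statsmodels-style: a
model object built from sample data, reference constants and scenarios
whose :meth:`~RiskAssessment.fit` returns a :class:`RiskAssessmentResults`
carrying the per-cell results, a tidy DataFrame and a text summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    ConsumptionScenario,
    ElementReference,
    SampleRecord,
    default_reference,
    default_scenarios,
)
from .descriptive import ElementSummary, ethanol_comparison, summarize_samples
from .preprocess import ETHANOL_DENSITY_G_PER_L, per_litre_to_per_gram

__all__ = [
    "THQ_LIMIT",
    "MOE_LIMIT",
    "RiskResult",
    "scenario_from_annual_volume",
    "estimated_daily_intake",
    "target_hazard_quotient",
    "margin_of_exposure",
    "classify_thq",
    "classify_moe",
    "run_assessment",
    "RiskAssessment",
    "RiskAssessmentResults",
]

#: THQ above this is an elevated non-carcinogenic risk.
THQ_LIMIT = 1.0
#: MOE below this is a public health concern (non-genotoxic substances).
MOE_LIMIT = 100.0

SUMMARY_LEVELS = ("median", "p99")


def scenario_from_annual_volume(
    volumes: Sequence[float],
    *,
    name: str = "derived",
    density: float = 0.789,
    bw: float = 73.9,
    ef: float = 365.0,
    ed: float = 65.4,
) -> ConsumptionScenario:
    """Build a scenario from annual per-capita pure-alcohol volumes.

    ``volumes`` are litres of pure alcohol per capita per year (e.g. one
    entry per neighbouring country); their mean, times the mass density of
    ethanol (``density`` g/cm3, i.e. 1000*density g/l), divided by 365,
    gives the daily ethanol mass in g/day. The averaging time is 365 * ed.
    """
    vols = np.asarray(volumes, dtype=float)
    if vols.size == 0:
        raise ValueError("need at least one annual volume")
    if np.any(vols <= 0):
        raise ValueError("annual volumes must be positive")
    annual_g = float(vols.mean()) * density * 1000.0
    return ConsumptionScenario(
        name=name, mdi=annual_g / 365.0, bw=bw, ef=ef, ed=ed, aet=365.0 * ed
    )


def estimated_daily_intake(mcs: float, scenario: ConsumptionScenario) -> float:
    """EDI in mg/kg bw/day from an MCS in mg/g of pure alcohol."""
    if mcs < 0:
        raise ValueError("MCS must be >= 0")
    return scenario.mdi * mcs / scenario.bw


def target_hazard_quotient(
    mcs: float, scenario: ConsumptionScenario, rfd: Optional[float]
) -> float:
    """Five-factor THQ; equals EDI/RfD when AET = EF * ED."""
    if rfd is None:
        raise ValueError(
            "no oral reference dose for this element; use margin_of_exposure"
        )
    if rfd <= 0:
        raise ValueError("RfD must be > 0")
    s = scenario
    return (mcs * s.mdi * s.ef * s.ed) / (rfd * s.bw * s.aet)


def margin_of_exposure(bmdl_x: float, edi: float) -> float:
    """MOE = BMDL_x / EDI; an EDI of zero gives an infinite margin."""
    if bmdl_x <= 0:
        raise ValueError("BMDL must be > 0")
    if edi < 0:
        raise ValueError("EDI must be >= 0")
    if edi == 0:
        return math.inf
    return bmdl_x / edi


def classify_thq(thq: float) -> str:
    return "elevated" if thq > THQ_LIMIT else "negligible"


def classify_moe(moe: float) -> str:
    return "public health concern" if moe < MOE_LIMIT else "no concern"


@dataclass(frozen=True)
class RiskResult:
    """One element x scenario x summary-level cell of the risk tables."""

    element: str
    scenario: str
    summary_level: str  # "median" | "p99"
    mcs_mg_per_g: float
    edi: float
    thq: Optional[float] = None
    moe: Optional[Mapping[str, float]] = None  # endpoint -> ratio

    @property
    def thq_classification(self) -> Optional[str]:
        return None if self.thq is None else classify_thq(self.thq)

    @property
    def moe_classification(self) -> Optional[dict[str, str]]:
        if self.moe is None:
            return None
        return {endpoint: classify_moe(v) for endpoint, v in self.moe.items()}


def _select_elements(
    summaries: Sequence[ElementSummary], references: Mapping[str, ElementReference]
) -> list[str]:
    """Elements of concern: those exceeding their screening threshold at
    least once."""
    return [
        s.element
        for s in summaries
        if s.n_exceeding is not None and s.n_exceeding >= 1
    ]


def run_assessment(
    samples: Sequence[SampleRecord],
    references: Mapping[str, ElementReference] | None = None,
    scenarios: Sequence[ConsumptionScenario] | None = None,
    elements: Sequence[str] | None = None,
    *,
    percentile_method: str = "linear",
) -> list[RiskResult]:
    """Full risk assessment over element x scenario x {median, p99}.

    Elements are selected automatically (at least one sample above the
    screening threshold) unless an explicit list is given. MCS values feed
    the formulas at full precision, not at display rounding.
    """
    references = dict(references) if references is not None else default_reference()
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    summaries = summarize_samples(
        samples, references, elements=elements, percentile_method=percentile_method
    )
    by_element = {s.element: s for s in summaries}
    if elements is None:
        elements = _select_elements(summaries, references)

    results: list[RiskResult] = []
    for element in elements:
        summary = by_element[element]
        ref = references.get(element, ElementReference(element=element))
        if ref.rfd is None and not ref.bmdl:
            warnings.warn(
                f"element {element!r} has neither RfD nor BMDL; reporting EDI only",
                stacklevel=2,
            )
        for scenario in scenarios:
            for level in SUMMARY_LEVELS:
                mcs = summary.median_mg_g if level == "median" else summary.p99_mg_g
                edi = estimated_daily_intake(mcs, scenario)
                thq = (
                    target_hazard_quotient(mcs, scenario, ref.rfd)
                    if ref.rfd is not None
                    else None
                )
                moe = (
                    {ep: margin_of_exposure(b, edi) for ep, b in ref.bmdl.items()}
                    if ref.bmdl
                    else None
                )
                results.append(
                    RiskResult(
                        element=element,
                        scenario=scenario.name,
                        summary_level=level,
                        mcs_mg_per_g=mcs,
                        edi=edi,
                        thq=thq,
                        moe=moe,
                    )
                )
    return results


class RiskAssessment:
    """Heavy-metal exposure model for a table of spirit samples.

    Parameters
    ----------
    samples
        Sample records (see :mod:`spiritrisk.data`).
    references
        Element constants; defaults to the built-in table.
    scenarios
        Drinker scenarios; defaults to the average (1.62 g ethanol/day) and
        heavy (60 g/day) drinker.
    elements
        Explicit element selection; by default every element whose screening
        threshold is exceeded by at least one sample is assessed.
    percentile_method
        numpy quantile method name for the summary levels.

    Examples
    --------
    >>> from spiritrisk import RiskAssessment, datasets
    >>> res = RiskAssessment(datasets.kosovo_rakia()).fit()
    >>> round(res.thq("Cu", "average", "median"), 4)
    0.008
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        references: Mapping[str, ElementReference] | None = None,
        scenarios: Sequence[ConsumptionScenario] | None = None,
        elements: Sequence[str] | None = None,
        *,
        percentile_method: str = "linear",
    ) -> None:
        self.samples = list(samples)
        self.references = dict(references) if references is not None else default_reference()
        self.scenarios = list(scenarios) if scenarios is not None else default_scenarios()
        self.elements = list(elements) if elements is not None else None
        self.percentile_method = percentile_method

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, units: str = "per_litre_pa", **kwargs
    ) -> "RiskAssessment":
        """Build from a DataFrame in the sample-table dialect."""
        from .data import CensoredValue, DEFAULT_SENTINEL, METADATA_COLUMNS

        records = []
        element_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
        for _, row in frame.iterrows():
            conc = {}
            for element in element_cols:
                cell = row[element]
                if isinstance(cell, str) and cell.strip() == DEFAULT_SENTINEL:
                    conc[element] = CensoredValue.below_lod()
                elif cell is not None and not (isinstance(cell, float) and np.isnan(cell)):
                    conc[element] = CensoredValue.of(float(cell))
            meta = {
                k: (None if pd.isna(row.get(k)) else row.get(k))
                for k in METADATA_COLUMNS
                if k in frame.columns
            }
            if meta.get("year") is not None:
                meta["year"] = int(meta["year"])
            records.append(
                SampleRecord(concentrations=conc, concentration_units=units, **meta)
            )
        return cls(records, **kwargs)

    def fit(self) -> "RiskAssessmentResults":
        """Run screening, summarisation and the risk computations."""
        summaries = summarize_samples(
            self.samples, self.references, percentile_method=self.percentile_method
        )
        results = run_assessment(
            self.samples,
            self.references,
            self.scenarios,
            self.elements,
            percentile_method=self.percentile_method,
        )
        return RiskAssessmentResults(self, summaries, results)


class RiskAssessmentResults:
    """Fitted results: element summaries plus the risk table.

    Access the per-cell numbers through :meth:`thq`, :meth:`moe` and
    :meth:`edi`, the tidy table through :meth:`to_frame`, and a
    human-readable report through :meth:`summary`.
    """

    def __init__(
        self,
        model: RiskAssessment,
        element_summaries: Sequence[ElementSummary],
        results: Sequence[RiskResult],
    ) -> None:
        self.model = model
        self.element_summaries = list(element_summaries)
        self.results = list(results)
        self._index = {
            (r.element, r.scenario, r.summary_level): r for r in self.results
        }

    def __getitem__(self, key: tuple[str, str, str]) -> RiskResult:
        return self._index[key]

    def edi(self, element: str, scenario: str, level: str) -> float:
        return self._index[(element, scenario, level)].edi

    def thq(self, element: str, scenario: str, level: str) -> float:
        r = self._index[(element, scenario, level)]
        if r.thq is None:
            raise KeyError(f"{element} has no RfD; no THQ computed")
        return r.thq

    def moe(self, element: str, scenario: str, level: str, endpoint: str) -> float:
        r = self._index[(element, scenario, level)]
        if not r.moe or endpoint not in r.moe:
            raise KeyError(f"no MOE for {element} endpoint {endpoint!r}")
        return r.moe[endpoint]

    def to_frame(self) -> pd.DataFrame:
        """Long-format risk table, one row per element/scenario/level(/endpoint)."""
        rows = []
        for r in self.results:
            base = dict(
                element=r.element,
                scenario=r.scenario,
                summary_level=r.summary_level,
                mcs_mg_per_g=r.mcs_mg_per_g,
                edi=r.edi,
            )
            if r.thq is not None:
                rows.append(
                    dict(
                        base,
                        metric="THQ",
                        endpoint="",
                        value=r.thq,
                        classification=r.thq_classification,
                    )
                )
            if r.moe:
                for endpoint, v in r.moe.items():
                    rows.append(
                        dict(
                            base,
                            metric="MOE",
                            endpoint=endpoint,
                            value=v,
                            classification=classify_moe(v),
                        )
                    )
            if r.thq is None and not r.moe:
                rows.append(
                    dict(base, metric="EDI", endpoint="", value=r.edi, classification="")
                )
        return pd.DataFrame(rows)

    def screening_frame(self) -> pd.DataFrame:
        """Per-element detection/exceedance counts and percentile summaries."""
        rows = []
        for s in self.element_summaries:
            rows.append(
                dict(
                    element=s.element,
                    n=s.n,
                    n_detected=s.n_detected,
                    pct_detected=s.pct_detected,
                    n_exceeding=s.n_exceeding,
                    pct_exceeding=s.pct_exceeding,
                    min_mg_l_pa=s.min_mg_l,
                    max_mg_l_pa=s.max_mg_l,
                    median_mg_l_pa=s.median_mg_l,
                    p99_mg_l_pa=s.p99_mg_l,
                    median_mg_g_pa=s.median_mg_g,
                    p99_mg_g_pa=s.p99_mg_g,
                )
            )
        return pd.DataFrame(rows)

    def ethanol_comparison(self):
        """Wilcoxon signed-rank test of reported vs measured ethanol strength."""
        return ethanol_comparison(self.model.samples)

    def summary(self, *, sig_digits: int = 2) -> str:
        """Plain-text report of screening counts and risk classifications."""
        fmt = f"{{:.{sig_digits - 1}e}}"
        lines = ["Heavy-metal exposure assessment", "=" * 31, ""]
        lines.append(
            f"Samples: {len(self.model.samples)}   Scenarios: "
            + ", ".join(
                f"{s.name} ({s.mdi:g} g ethanol/day)" for s in self.model.scenarios
            )
        )
        lines.append("")
        lines.append("Screening (mg/l pure alcohol)")
        for s in self.element_summaries:
            exc = (
                "no threshold"
                if s.n_exceeding is None
                else f"{s.n_exceeding}/{s.n} above threshold ({s.pct_exceeding:.1f}%)"
            )
            lines.append(
                f"  {s.element:<2} detected {s.n_detected}/{s.n}"
                f" ({s.pct_detected:.1f}%), {exc}"
            )
        lines.append("")
        lines.append("Risk (per element, scenario, summary level)")
        for r in self.results:
            cell = f"  {r.element:<2} {r.scenario:<8} {r.summary_level:<6}"
            if r.thq is not None:
                lines.append(
                    f"{cell} THQ {fmt.format(r.thq)} [{r.thq_classification}]"
                )
            if r.moe:
                for endpoint, v in r.moe.items():
                    lines.append(
                        f"{cell} MOE({endpoint}) {fmt.format(v)} [{classify_moe(v)}]"
                    )
            if r.thq is None and not r.moe:
                lines.append(f"{cell} EDI {fmt.format(r.edi)} mg/kg bw/day")
        return "\n".join(lines)
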