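"""Censoring substitution and unit conversions.

Downstream risk formulas work on two pure-alcohol scales: mg per litre of
pure alcohol (screening against spirit thresholds) and mg per gram of pure
alcohol (intake computation against a g/day ethanol dose). This module moves
concentration vectors between beverage and pure-alcohol scales and performs
the standard LOD/2 substitution for left-censored trace-element data.

By default LOD/2 substitution is applied to the values on whatever scale the
table carries (the study's element table is already per litre of pure
alcohol); callers converting beverage-scale data first should convert the
LOD by the same factor — the substitution and a linear unit change commute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data import PER_LITRE_PA, SampleRecord

__all__ = [
    "ETHANOL_DENSITY_G_PER_L",
    "ConcentrationVector",
    "vector_from_samples",
    "substitute_censored",
    "beverage_to_pure_alcohol",
    "per_litre_to_per_gram",
    "vector_to_pure_alcohol",
    "vector_per_gram",
]

#: grams of ethanol per litre of pure ethanol (density 0.789 g/cm3).
ETHANOL_DENSITY_G_PER_L = 789.0

MG_PER_L_PA = "mg_per_l_pa"
MG_PER_G_PA = "mg_per_g_pa"
MG_PER_L_BEVERAGE = "mg_per_l_beverage"


@dataclass(frozen=True)
class ConcentrationVector:
    """Ordered concentrations of one element across samples, with censor flags."""

    element: str
    values: np.ndarray
    censored: np.ndarray
    units: str = MG_PER_L_PA

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        censored = np.asarray(self.censored, dtype=bool)
        if values.shape != censored.shape:
            raise ValueError("values and censor flags must have the same length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "censored", censored)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


def vector_from_samples(
    samples: Sequence[SampleRecord], element: str
) -> ConcentrationVector:
    """Extract one element's column from sample records.

    Censored entries get a placeholder value of NaN until substitution;
    samples without the element are skipped.
    """
    values, flags = [], []
    for rec in samples:
        cv = rec.concentrations.get(element)
        if cv is None:
            continue
        if cv.censored:
            values.append(np.nan)
            flags.append(True)
        else:
            values.append(cv.value)
            flags.append(False)
    units = MG_PER_L_PA if samples and samples[0].concentration_units == PER_LITRE_PA else MG_PER_L_BEVERAGE
    return ConcentrationVector(element, np.array(values), np.array(flags, dtype=bool), units)


def substitute_censored(vector: ConcentrationVector, lod: float) -> ConcentrationVector:
    """Replace censored entries by LOD/2, keeping the censor flags.

    Flags are retained so detection counts remain computable after
    substitution. Uncensored entries are untouched.
    """
    if vector.n_censored == 0:
        return vector
    if lod is None or lod <= 0:
        raise ValueError(
            f"element {vector.element!r} has censored entries but no positive LOD"
        )
    values = vector.values.copy()
    values[vector.censored] = lod / 2.0
    return replace(vector, values=values)


def beverage_to_pure_alcohol(conc: float, abv: float) -> float:
    """Convert mg/l of beverage to mg/l of pure alcohol at strength ``abv`` % v/v."""
    if abv <= 0 or abv > 100:
        raise ValueError(f"ABV must be in (0, 100], got {abv}")
    return conc / (abv / 100.0)


def per_litre_to_per_gram(conc: float) -> float:
    """Convert mg per litre of pure alcohol to mg per gram of pure alcohol."""
    if np.any(np.asarray(conc) < 0):
        raise ValueError("concentration must be >= 0")
    return conc / ETHANOL_DENSITY_G_PER_L


def vector_to_pure_alcohol(
    vector: ConcentrationVector, abvs: Sequence[float]
) -> ConcentrationVector:
    """Normalise a beverage-scale vector to mg/l p.a. using per-sample ABV."""
    if vector.units != MG_PER_L_BEVERAGE:
        return vector
    abvs = np.asarray(abvs, dtype=float)
    if abvs.shape != vector.values.shape:
        raise ValueError("need one ABV per concentration entry")
    if np.any(abvs <= 0) or np.any(abvs > 100):
        raise ValueError("ABV must be in (0, 100]")
    return replace(vector, values=vector.values / (abvs / 100.0), units=MG_PER_L_PA)


def vector_per_gram(vector: ConcentrationVector) -> ConcentrationVector:
    """Convert a mg/l p.a. vector to mg/g p.a."""
    if vector.units == MG_PER_G_PA:
        return vector
    if vector.units != MG_PER_L_PA:
        raise ValueError("convert to mg/l of pure alcohol first")
    return replace(
        vector, values=vector.values / ETHANOL_DENSITY_G_PER_L, units=MG_PER_G_PA
    )
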