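"""Synthetic sample-table generator.

Emulates the statistical structure of an unrecorded-spirit survey so the
whole pipeline is testable without the packaged dataset: right-skewed
(log-normal) element concentrations with element-specific detection-limit
censoring, ethanol strengths clustered near 40-50% v/v, producer-reported
strengths that track the measured ones with bias and noise, and prices.

Concentrations are drawn on the mg/l pure-alcohol scale. Censoring is
applied after the draw — a value below the element's LOD has its flag set
and its value removed — so the generator can also return the ground-truth
uncensored values for oracle tests.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .data import PER_LITRE_PA, CensoredValue, SampleRecord

__all__ = ["ElementGenSpec", "GeneratorSpec", "generate", "default_generator_spec"]


class ElementGenSpec(BaseModel):
    """Log-normal concentration model for one element.

    ``median_target`` is the log-normal median in mg/l p.a. (exp of the log
    mean); ``gsd`` the geometric standard deviation (> 1, dimensionless);
    ``lod`` the detection limit in mg/l p.a. below which a draw is censored
    (``None`` disables censoring).
    """

    model_config = ConfigDict(frozen=True)

    median_target: float = Field(gt=0)
    gsd: float = Field(gt=1.0)
    lod: Optional[float] = Field(default=None, gt=0)


class GeneratorSpec(BaseModel):
    """Study-design parameters for a synthetic sample table."""

    model_config = ConfigDict(frozen=True)

    n_samples: int = Field(default=30, ge=1)
    elements: Dict[str, ElementGenSpec]
    abv_mean: float = 45.0  # % v/v
    abv_sd: float = Field(default=5.0, ge=0)
    abv_bounds: tuple[float, float] = (30.0, 70.0)
    reported_bias: float = -1.6  # reported minus measured, % v/v
    reported_noise_sd: float = Field(default=3.5, ge=0)
    reported_missing_rate: float = Field(default=0.1, ge=0, le=1)
    price_range: tuple[float, float] = (2.5, 10.0)
    missing_metadata_rate: float = Field(default=0.1, ge=0, le=1)
    seed: int = 0


def default_generator_spec(n_samples: int = 30, seed: int = 0) -> GeneratorSpec:
    """Defaults emulating the Kosovar rakia survey: a dominant copper signal,
    mostly-censored nickel with a heavy tail, partially censored lead."""
    return GeneratorSpec(
        n_samples=n_samples,
        seed=seed,
        elements={
            "Al": ElementGenSpec(median_target=0.08, gsd=2.0),
            "Cu": ElementGenSpec(median_target=11.5, gsd=2.2, lod=1.0e-4),
            "Fe": ElementGenSpec(median_target=0.12, gsd=1.9, lod=2.0e-4),
            "Mn": ElementGenSpec(median_target=0.009, gsd=2.5),
            "Ni": ElementGenSpec(median_target=1.0e-4, gsd=8.0, lod=5.0e-4),
            "Pb": ElementGenSpec(median_target=0.0655, gsd=4.0, lod=2.2e-3),
            "Zn": ElementGenSpec(median_target=0.17, gsd=3.0),
        },
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Normal draws rejected outside (lo, hi); sd=0 degenerates to the mean."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw > lo) & (draw < hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


_RAW_MATERIALS = ("Grape", "Plum", "Pear", "Apple", "Quince")
_PLACES = ("Producer's home", "Flea market")


def generate(
    spec: GeneratorSpec, *, return_truth: bool = False
) -> list[SampleRecord] | tuple[list[SampleRecord], dict[str, np.ndarray]]:
    """Draw a synthetic sample table; deterministic given ``spec.seed``.

    With ``return_truth=True`` also returns the uncensored per-element
    concentration draws (element -> array of length n_samples).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    lo, hi = spec.abv_bounds
    measured = _truncated_normal(rng, spec.abv_mean, spec.abv_sd, lo, hi, n)
    reported = measured + spec.reported_bias + rng.normal(0.0, spec.reported_noise_sd, n) if spec.reported_noise_sd else measured + spec.reported_bias
    reported = np.clip(reported, 1.0, 100.0)
    reported_missing = rng.random(n) < spec.reported_missing_rate
    prices = rng.uniform(*spec.price_range, size=n)
    years = rng.integers(2013, 2023, size=n)
    materials = rng.choice(len(_RAW_MATERIALS), size=n)
    places = rng.choice(len(_PLACES), size=n, p=[0.75, 0.25])
    meta_missing = rng.random((n, 3)) < spec.missing_metadata_rate

    truth: dict[str, np.ndarray] = {}
    draws: dict[str, np.ndarray] = {}
    for element, espec in spec.elements.items():
        mu = np.log(espec.median_target)
        sigma = np.log(espec.gsd)
        draws[element] = rng.lognormal(mean=mu, sigma=sigma, size=n)
        truth[element] = draws[element].copy()

    records: list[SampleRecord] = []
    for i in range(n):
        conc: dict[str, CensoredValue] = {}
        for element, espec in spec.elements.items():
            value = float(draws[element][i])
            if espec.lod is not None and value < espec.lod:
                conc[element] = CensoredValue.below_lod()
            else:
                conc[element] = CensoredValue.of(value)
        records.append(
            SampleRecord(
                sample_id=f"Synthetic {i + 1}",
                place=None if meta_missing[i, 0] else _PLACES[places[i]],
                raw_material=None if meta_missing[i, 1] else _RAW_MATERIALS[materials[i]],
                year=None if meta_missing[i, 2] else int(years[i]),
                reported_abv=None if reported_missing[i] else round(float(reported[i]), 1),
                measured_abv=round(float(measured[i]), 1),
                price_eur_per_l=round(float(prices[i]), 1),
                concentrations=conc,
                concentration_units=PER_LITRE_PA,
            )
        )
    if return_truth:
        return records, truth
    return records
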