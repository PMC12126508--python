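"""Domain types, reference constants and sample-table IO.

The exchange format is a flat CSV with one row per spirit sample: a fixed
block of metadata columns followed by one column per chemical element.
Concentrations below the instrument's limit of detection (LOD) are encoded
with a sentinel string (default ``"<LOD"``) and surface in memory as
:class:`CensoredValue` objects with ``censored=True``, so that censoring
survives a round trip and detection counts stay computable downstream.

Concentration units are a per-file property: either milligrams per litre of
pure alcohol (``"per_litre_pa"``, the scale toxicological thresholds for
spirits are expressed on) or milligrams per litre of beverage
(``"per_litre_beverage"``, the scale an instrument reports before alcohol
normalisation).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "CensoredValue",
    "SampleRecord",
    "ElementReference",
    "ConsumptionScenario",
    "PER_LITRE_PA",
    "PER_LITRE_BEVERAGE",
    "METADATA_COLUMNS",
    "DEFAULT_SENTINEL",
    "default_reference",
    "load_reference",
    "read_samples",
    "write_samples",
    "average_drinker",
    "heavy_drinker",
    "default_scenarios",
]

PER_LITRE_PA = "per_litre_pa"
PER_LITRE_BEVERAGE = "per_litre_beverage"
_UNIT_FLAGS = (PER_LITRE_PA, PER_LITRE_BEVERAGE)

DEFAULT_SENTINEL = "<LOD"

METADATA_COLUMNS = (
    "sample_id",
    "place",
    "raw_material",
    "year",
    "reported_abv",
    "measured_abv",
    "price_eur_per_l",
)


class CensoredValue(BaseModel):
    """A concentration that is either observed (> 0) or left-censored at the LOD."""

    model_config = ConfigDict(frozen=True)

    value: Optional[float] = None
    censored: bool = False

    @model_validator(mode="after")
    def _exactly_one(self) -> "CensoredValue":
        if self.censored:
            if self.value is not None:
                raise ValueError("censored entry must not carry a value")
        else:
            if self.value is None:
                raise ValueError("uncensored entry must carry a value")
            if self.value <= 0:
                raise ValueError(f"concentration must be > 0, got {self.value}")
        return self

    @classmethod
    def of(cls, value: float) -> "CensoredValue":
        return cls(value=value)

    @classmethod
    def below_lod(cls) -> "CensoredValue":
        return cls(censored=True)


class SampleRecord(BaseModel):
    """One spirit sample: provenance metadata, ethanol strengths, price,
    and per-element concentrations with censoring flags."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    place: Optional[str] = None
    raw_material: Optional[str] = None
    year: Optional[int] = None
    reported_abv: Optional[float] = Field(default=None, gt=0, le=100)
    measured_abv: float = Field(gt=0, le=100)
    price_eur_per_l: Optional[float] = Field(default=None, ge=0)
    concentrations: Mapping[str, CensoredValue] = Field(default_factory=dict)
    concentration_units: str = PER_LITRE_PA

    @field_validator("concentration_units")
    @classmethod
    def _known_units(cls, v: str) -> str:
        if v not in _UNIT_FLAGS:
            raise ValueError(f"unknown units flag {v!r}; expected one of {_UNIT_FLAGS}")
        return v


class ElementReference(BaseModel):
    """Per-element toxicological and analytical constants.

    ``amphora_threshold`` is the screening limit for unrecorded alcohol in
    mg/l of pure alcohol; ``lod`` the instrument detection limit in mg/l;
    ``rfd`` the oral reference dose and ``bmdl`` the benchmark-dose lower
    bounds per health endpoint, both in mg per kg body weight per day.
    """

    model_config = ConfigDict(frozen=True)

    element: str
    amphora_threshold: Optional[float] = Field(default=None, gt=0)
    lod: Optional[float] = Field(default=None, gt=0)
    rfd: Optional[float] = Field(default=None, gt=0)
    bmdl: Mapping[str, float] = Field(default_factory=dict)

    @field_validator("bmdl")
    @classmethod
    def _positive_bmdl(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        for endpoint, val in v.items():
            if val <= 0:
                raise ValueError(f"BMDL for {endpoint!r} must be > 0, got {val}")
        return dict(v)


class ConsumptionScenario(BaseModel):
    """A named drinker scenario for chronic-exposure computations.

    mdi    daily ethanol intake from the beverage, g/day
    bw     body weight, kg
    ef     exposure frequency, days/year
    ed     exposure duration, years
    aet    averaging time, days (365 x ed for non-carcinogenic hazard)
    """

    model_config = ConfigDict(frozen=True)

    name: str
    mdi: float = Field(gt=0)
    bw: float = Field(gt=0)
    ef: float = Field(gt=0, le=365)
    ed: float = Field(gt=0)
    aet: float = Field(gt=0)


# Constants of the Kosovar unrecorded-rakia study: AMPHORA screening limits
# (mg/l p.a.), ICP-OES detection limits (mg/l), oral reference doses and
# lead benchmark-dose lower bounds (mg/kg bw/day).
_DEFAULT_REFERENCE: tuple[ElementReference, ...] = (
    ElementReference(element="Al", amphora_threshold=2.0),
    ElementReference(element="Cu", amphora_threshold=2.0, lod=1.0e-4, rfd=0.04),
    ElementReference(element="Fe", amphora_threshold=2.0, lod=2.0e-4, rfd=0.7),
    ElementReference(element="Mn", amphora_threshold=0.5),
    ElementReference(element="Ni", amphora_threshold=0.2, lod=5.0e-4, rfd=0.011),
    ElementReference(
        element="Pb",
        amphora_threshold=0.2,
        lod=2.2e-3,
        bmdl={"cardiovascular": 0.0015, "nephrotoxicity": 0.00063},
    ),
    ElementReference(element="Zn", amphora_threshold=5.0),
)


def default_reference() -> dict[str, ElementReference]:
    """Built-in reference table for the elements screened in rakia."""
    return {ref.element: ref for ref in _DEFAULT_REFERENCE}


def load_reference(path: str | Path | None = None) -> dict[str, ElementReference]:
    """Load element reference constants, optionally overriding the built-ins.

    The YAML/JSON file maps element symbols to partial
    :class:`ElementReference` fields; listed elements replace or extend the
    defaults field-by-field. ``None`` returns the built-in table.
    """
    table = default_reference()
    if path is None:
        return table
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"reference config must map element -> fields, got {type(raw).__name__}")
    for element, fields in raw.items():
        base = table.get(element)
        merged = dict(base.model_dump(exclude_none=True)) if base else {}
        merged.update(fields or {})
        merged["element"] = element
        table[element] = ElementReference(**merged)
    return table


def average_drinker() -> ConsumptionScenario:
    """1.62 g ethanol/day: per-capita unrecorded-spirit intake averaged over
    neighbouring Balkan countries (0.75 l pure alcohol/year x 789 g/l / 365)."""
    return ConsumptionScenario(
        name="average", mdi=1.62, bw=73.9, ef=365.0, ed=65.4, aet=365.0 * 65.4
    )


def heavy_drinker() -> ConsumptionScenario:
    """60 g ethanol/day, all taken as unrecorded spirit."""
    return ConsumptionScenario(
        name="heavy", mdi=60.0, bw=73.9, ef=365.0, ed=65.4, aet=365.0 * 65.4
    )


def default_scenarios() -> list[ConsumptionScenario]:
    return [average_drinker(), heavy_drinker()]


def _parse_optional_str(cell: str) -> Optional[str]:
    cell = cell.strip()
    if cell == "" or cell.lower() == "unknown":
        return None
    return cell


def _parse_optional_float(cell: str, row: int, column: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "" or cell.lower() == "unknown":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"unparseable numeric cell {cell!r} at row {row}, column {column!r}") from None


def read_samples(
    path: str | Path,
    *,
    sentinel: str = DEFAULT_SENTINEL,
    units: str = PER_LITRE_PA,
    known_elements: Iterable[str] | None = None,
) -> list[SampleRecord]:
    """Read a sample table from CSV.

    Columns listed in :data:`METADATA_COLUMNS` are metadata; every other
    column is taken to be an element. Cells equal to ``sentinel`` become
    censored values; empty or ``Unknown`` metadata cells become ``None``.
    Element columns not present in ``known_elements`` (when given) raise a
    warning but are retained.
    """
    if units not in _UNIT_FLAGS:
        raise ValueError(f"unknown units flag {units!r}; expected one of {_UNIT_FLAGS}")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        element_cols = [c for c in reader.fieldnames if c not in METADATA_COLUMNS]
        if known_elements is not None:
            unknown = [c for c in element_cols if c not in set(known_elements)]
            if unknown:
                warnings.warn(
                    f"unknown element columns retained: {', '.join(unknown)}",
                    stacklevel=2,
                )
        records: list[SampleRecord] = []
        for i, row in enumerate(reader, start=2):
            concentrations: dict[str, CensoredValue] = {}
            for element in element_cols:
                cell = (row[element] or "").strip()
                if cell == sentinel:
                    concentrations[element] = CensoredValue.below_lod()
                    continue
                value = _parse_optional_float(cell, i, element)
                if value is None:
                    continue
                if value <= 0:
                    raise ValueError(
                        f"non-positive concentration {value} at row {i}, column {element!r}"
                    )
                concentrations[element] = CensoredValue.of(value)
            year = _parse_optional_float(row.get("year", ""), i, "year")
            records.append(
                SampleRecord(
                    sample_id=(row.get("sample_id") or f"row{i}").strip(),
                    place=_parse_optional_str(row.get("place", "")),
                    raw_material=_parse_optional_str(row.get("raw_material", "")),
                    year=int(year) if year is not None else None,
                    reported_abv=_parse_optional_float(row.get("reported_abv", ""), i, "reported_abv"),
                    measured_abv=_parse_optional_float(row.get("measured_abv", ""), i, "measured_abv"),
                    price_eur_per_l=_parse_optional_float(
                        row.get("price_eur_per_l", ""), i, "price_eur_per_l"
                    ),
                    concentrations=concentrations,
                    concentration_units=units,
                )
            )
    return records


def write_samples(
    records: Iterable[SampleRecord],
    path: str | Path,
    *,
    sentinel: str = DEFAULT_SENTINEL,
) -> None:
    """Write sample records to CSV in the dialect :func:`read_samples` reads.

    The element column set is the union over records, in first-seen order.
    """
    records = list(records)
    elements: list[str] = []
    for rec in records:
        for element in rec.concentrations:
            if element not in elements:
                elements.append(element)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(METADATA_COLUMNS) + elements)
        for rec in records:
            row: list[str] = [
                rec.sample_id,
                rec.place or "",
                rec.raw_material or "",
                "" if rec.year is None else str(rec.year),
                "" if rec.reported_abv is None else repr(rec.reported_abv),
                repr(rec.measured_abv),
                "" if rec.price_eur_per_l is None else repr(rec.price_eur_per_l),
            ]
            for element in elements:
                cv = rec.concentrations.get(element)
                if cv is None:
                    row.append("")
                elif cv.censored:
                    row.append(sentinel)
                else:
                    row.append(repr(cv.value))
            writer.writerow(row)
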