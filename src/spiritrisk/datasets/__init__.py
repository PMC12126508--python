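"""Packaged study data.

``kosovo_rakia()`` returns the 30 unrecorded rakia samples collected in the
Republic of Kosovo, exactly as published: provenance metadata, reported and
measured ethanol strength (% v/v), price per litre, and ICP-OES element
concentrations in mg/l of pure alcohol with below-LOD entries censored.
"""

from importlib import resources
from pathlib import Path

from ..data import PER_LITRE_PA, SampleRecord, read_samples

__all__ = ["kosovo_rakia", "kosovo_rakia_path"]


def kosovo_rakia_path() -> Path:
    """Filesystem path of the packaged sample CSV."""
    return Path(resources.files(__package__) / "kosovo_rakia.csv")


def kosovo_rakia() -> list[SampleRecord]:
    """The 30 in-study rakia samples (concentrations in mg/l p.a.)."""
    return read_samples(kosovo_rakia_path(), units=PER_LITRE_PA)
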