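import pytest

from spiritrisk import datasets
from spiritrisk.data import default_reference, default_scenarios


@pytest.fixture(scope="session")
def kosovo():
    """The packaged 30-sample study table (mg/l p.a.)."""
    return datasets.kosovo_rakia()


@pytest.fixture()
def references():
    return default_reference()


@pytest.fixture()
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def matches_printed():
    """Check a computed value against a printed one to +-1 unit in the last
    printed digit, allowing the printed value to be either rounded or
    truncated (band [printed - ulp, printed + 2*ulp))."""

    def check(value: float, printed: float, ulp: float, label: str = "") -> None:
        assert printed - ulp <= value < printed + 2 * ulp, (
            f"{label}: computed {value!r} not within one last-digit unit "
            f"of printed {printed!r} (ulp {ulp})"
        )

    return check
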