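"""Percentiles, screening summaries, the ethanol comparison and prices."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spiritrisk.data import ElementReference
from spiritrisk.descriptive import (
    ethanol_comparison,
    percentile,
    price_summary,
    summarize_element,
    summarize_samples,
    wilcoxon_signed_rank,
)
from spiritrisk.preprocess import ConcentrationVector, vector_from_samples

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


def oracle_percentile(values, p):
    """Independent sort-and-interpolate oracle: rank position h = (n-1)p + 1."""
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestPercentile:
    def test_even_n_median(self):
        assert percentile([1, 2, 3, 4], 0.5) == 2.5

    def test_errors(self):
        with pytest.raises(ValueError):
            percentile([], 0.5)
        with pytest.raises(ValueError):
            percentile([1.0], 1.5)

    @given(values=st.lists(finite, min_size=1, max_size=50),
           p=st.floats(min_value=0, max_value=1))
    def test_matches_interpolation_oracle(self, values, p):
        assert percentile(values, p) == pytest.approx(
            oracle_percentile(values, p), rel=1e-9, abs=1e-9
        )

    @given(values=st.lists(finite, min_size=1, max_size=50),
           p1=st.floats(min_value=0, max_value=1),
           p2=st.floats(min_value=0, max_value=1))
    def test_monotone_and_bounded(self, values, p1, p2):
        lo, hi = min(p1, p2), max(p1, p2)
        assert min(values) <= percentile(values, lo) <= percentile(values, hi) <= max(values)


class TestStudyPercentiles:
    """Substituted percentile values of the study's Pb and Ni columns."""

    def test_lead_median_and_p99(self, kosovo, references):
        summary = summarize_samples(kosovo, references, elements=["Pb"])[0]
        assert summary.median_mg_l == pytest.approx(0.0655)
        assert summary.p99_mg_l == pytest.approx(2.68207)
        assert summary.median_mg_g == pytest.approx(8.3e-5, rel=2e-3)
        assert summary.p99_mg_g == pytest.approx(3.4e-3, rel=2e-2)

    def test_nickel_percentiles(self, kosovo, references):
        summary = summarize_samples(kosovo, references, elements=["Ni"])[0]
        assert summary.median_mg_l == pytest.approx(2.5e-4)  # LOD/2
        assert summary.p99_mg_l == pytest.approx(3.01213)
        assert summary.median_mg_g == pytest.approx(3.2e-7, rel=2e-2)


class TestScreening:
    @pytest.mark.parametrize(
        "element, n_detected, n_exceeding",
        [("Cu", 30, 29), ("Fe", 30, 1), ("Ni", 4, 1), ("Pb", 23, 8),
         ("Al", 30, 0), ("Mn", 30, 0), ("Zn", 30, 0)],
    )
    def test_detection_and_exceedance_counts(self, kosovo, references, element,
                                             n_detected, n_exceeding):
        summary = summarize_samples(kosovo, references, elements=[element])[0]
        assert summary.n == 30
        assert summary.n_detected == n_detected
        assert summary.n_exceeding == n_exceeding

    def test_percentages(self, kosovo, references):
        by = {s.element: s for s in summarize_samples(kosovo, references)}
        assert by["Cu"].pct_exceeding == pytest.approx(96.7, abs=0.05)
        assert by["Pb"].pct_exceeding == pytest.approx(26.7, abs=0.05)
        assert by["Pb"].pct_detected == pytest.approx(76.7, abs=0.05)

    def test_copper_range(self, kosovo, references):
        summary = summarize_samples(kosovo, references, elements=["Cu"])[0]
        assert summary.min_mg_l == pytest.approx(1.033)
        assert summary.max_mg_l == pytest.approx(36.536)

    def test_missing_threshold_gives_no_exceedance_fields(self):
        vec = ConcentrationVector("Xx", np.array([1.0, 2.0]),
                                  np.array([False, False]))
        summary = summarize_element(vec, ElementReference(element="Xx"))
        assert summary.n_exceeding is None
        assert summary.pct_exceeding is None
        assert summary.median_mg_l == 1.5

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25)
    def test_counts_invariant_under_common_rescaling(self, scale):
        rng = np.random.default_rng(42)
        values = rng.lognormal(0, 1, 40)
        flags = rng.random(40) < 0.2
        base = ConcentrationVector("Pb", values, flags)
        scaled = ConcentrationVector("Pb", values * scale, flags)
        ref = ElementReference(element="Pb", amphora_threshold=1.0, lod=0.05)
        ref_scaled = ElementReference(element="Pb", amphora_threshold=scale,
                                      lod=0.05 * scale)
        a = summarize_element(base, ref)
        b = summarize_element(scaled, ref_scaled)
        assert (a.n_detected, a.n_exceeding) == (b.n_detected, b.n_exceeding)


def brute_force_signed_rank_p(diffs):
    """Two-sided p by enumerating all 2^n equiprobable sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = np.array([
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=n)
    ])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestWilcoxonSignedRank:
    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([(40.0, 40.0), (42.0, 42.0)])
        assert res.p_value == 1.0

    def test_study_comparison_not_significant(self, kosovo):
        res = ethanol_comparison(kosovo)
        assert res.n_pairs == 27  # three samples lack a reported strength
        assert res.method == "normal"  # 25 nonzero pairs
        assert res.p_value > 0.05
        assert not res.significant

    def test_study_comparison_matches_scipy(self, kosovo):
        res = ethanol_comparison(kosovo)
        diffs = [r.measured_abv - r.reported_abv for r in kosovo
                 if r.reported_abv is not None]
        sp = stats.wilcoxon(diffs, zero_method="wilcox", correction=True,
                            method="approx")
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-12)

    @given(data=st.data(), n=st.integers(min_value=2, max_value=10))
    @settings(max_examples=40, deadline=None)
    def test_exact_mode_equals_enumeration_oracle(self, data, n):
        diffs = data.draw(st.lists(
            st.floats(min_value=-9.9, max_value=9.9).map(lambda x: round(x, 1))
                .filter(lambda x: x != 0.0),
            min_size=n, max_size=n))
        pairs = [(0.0, d) for d in diffs]
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(diffs), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n15(self):
        rng = np.random.default_rng(2024)
        gaps = []
        for _ in range(20):
            diffs = np.round(rng.normal(0.5, 2.0, 15), 1)
            diffs[diffs == 0] = 0.3
            pairs = [(0.0, d) for d in diffs]
            p_exact = wilcoxon_signed_rank(pairs).p_value
            p_norm = wilcoxon_signed_rank(pairs, exact_max_n=0).p_value
            gaps.append(abs(p_exact - p_norm))
        assert np.median(gaps) < 0.01
        assert max(gaps) < 0.02

    def test_descriptives_of_both_series(self, kosovo):
        res = ethanol_comparison(kosovo)
        reported = [r.reported_abv for r in kosovo if r.reported_abv is not None]
        assert res.reported_median == pytest.approx(np.median(reported))
        lo, hi = res.measured_iqr
        assert lo <= res.measured_median <= hi


class TestPriceSummary:
    def test_study_prices(self, kosovo):
        res = price_summary([r.price_eur_per_l for r in kosovo])
        assert res.n == 28  # two samples of unknown price
        assert res.mean == pytest.approx(4.196, abs=5e-3)
        assert res.sd == pytest.approx(1.82, abs=5e-3)

    def test_degenerate_inputs(self):
        assert price_summary([2.5, 2.5]).sd == 0.0
        single = price_summary([10.0])
        assert single.mean == 10.0 and single.sd is None
        with pytest.raises(ValueError):
            price_summary([None])
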