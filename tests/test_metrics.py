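import numpy as np
import pytest

from ventmech import (
    SingleCompartmentModel,
    cross_patient_median,
    edrs_area,
    pearson,
    rank_sum_exact,
    summarize_level,
    wob_decomposition,
)
from ventmech.datasets import zeep_edrs_medians
from ventmech.metrics import (
    PEEPLevelSummary,
    TitrationSummary,
    ZeroVarianceError,
)
from ventmech.model import DynamicElastanceResults

from conftest import make_breath


def series_from_values(edrs, window=0.1):
    """Hand-built dynamic series with uniform window cells."""
    edrs = np.asarray(edrs, dtype=float)
    n = edrs.size
    times = (np.arange(n) + 0.5) * window
    return DynamicElastanceResults(
        breath=None,
        times=times,
        edrs=edrs,
        pressures=np.full(n, 15.0),
        durations=np.full(n, window),
        window_slices=[],
        window=window,
    )


class TestEdrsArea:
    def test_constant_elastance_rectangle(self):
        series = series_from_values([30.0] * 10)
        assert edrs_area(series) == pytest.approx(30.0)

    def test_linear_ramp_analytic_integral(self):
        # E(t) = 20 + 10 t over [0, 1]: integral 25.0
        series = series_from_values(20.0 + 10.0 * (np.arange(10) + 0.5) * 0.1)
        assert edrs_area(series) == pytest.approx(25.0, abs=0.1)

    def test_single_window_rectangle_rule(self):
        series = series_from_values([42.0], window=0.8)
        assert edrs_area(series) == pytest.approx(42.0 * 0.8)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            edrs_area(series_from_values([]))

    def test_scales_linearly_with_elastance(self):
        base = series_from_values([20.0, 30.0, 40.0])
        scaled = series_from_values([60.0, 90.0, 120.0])
        assert edrs_area(scaled) == pytest.approx(3.0 * edrs_area(base))

    def test_identified_series_matches_truth_integral(self, noiseless_breath):
        # constant E=30 with the onset window dropped: 30 * retained span
        dyn = SingleCompartmentModel(noiseless_breath).fit_dynamic()
        assert edrs_area(dyn) == pytest.approx(30.0 * dyn.durations.sum(), rel=1e-9)


class TestWOB:
    def test_end_inspiration_elastic_work(self):
        # decelerating flow reaches Q = 0 at end inspiration: with E = 30 and
        # V = 0.5 l, WOB_E = 30 * 0.25 = 7.5 and WOB_R = 0
        breath, _ = make_breath(flow_shape="decelerating")
        fit = SingleCompartmentModel(breath).fit()
        wob = wob_decomposition(breath, fit)
        assert wob.total_wob_e == pytest.approx(7.5, rel=1e-3)
        assert wob.total_wob_r == pytest.approx(0.0, abs=1e-3)

    def test_conservation_identity_per_sample(self):
        breath, _ = make_breath(noise_sd_paw=0.5, seed=3)
        fit = SingleCompartmentModel(breath).fit()
        wob = wob_decomposition(breath, fit)
        np.testing.assert_allclose(wob.wob, wob.wob_e + wob.wob_r, atol=1e-12)

    def test_dynamic_wob_e_recovers_edrs(self, noiseless_breath):
        model = SingleCompartmentModel(noiseless_breath)
        dyn = model.fit_dynamic()
        wob = wob_decomposition(noiseless_breath, dyn)
        v = noiseless_breath.volume_insp
        retained = np.isin(noiseless_breath.time_insp, wob.time)
        # E_drs(t) = WOB_E(t) / V(t)^2 on retained samples
        e_back = wob.wob_e / v[retained] ** 2
        np.testing.assert_allclose(e_back, 30.0, rtol=1e-6)


class TestLevelSummary:
    def test_single_breath_constant_series(self, noiseless_breath):
        model = SingleCompartmentModel(noiseless_breath)
        level = summarize_level([(noiseless_breath, model.fit(), model.fit_dynamic())])
        assert level.edrs_median == pytest.approx(30.0, rel=1e-6)
        assert level.edrs_iqr[0] == pytest.approx(30.0, rel=1e-6)
        assert level.edrs_iqr[1] == pytest.approx(30.0, rel=1e-6)
        assert level.n_breaths == 1

    def test_pooled_median_over_breaths(self):
        s1 = series_from_values([20.0, 30.0])
        s2 = series_from_values([40.0])
        levels = summarize_level(
            [(None, _FakeConst(25.0), s1), (None, _FakeConst(35.0), s2)],
            peep=10.0,
        )
        assert levels.edrs_median == pytest.approx(30.0)
        assert levels.e_lung == pytest.approx(30.0)

    def test_iqr_ordering_enforced(self):
        with pytest.raises(ValueError, match="IQR"):
            PEEPLevelSummary(peep=5, e_lung=30, edrs_median=30, edrs_iqr=(31, 35))


class _FakeConst:
    def __init__(self, e):
        self.e_lung = e


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5, dtype=float)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_against_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 3.5, 3.0, 6.0, 5.5])
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson(x, y) == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCrossPatientMedian:
    def test_reported_zeep_medians(self):
        med, _ = cross_patient_median(zeep_edrs_medians("all"), ndigits=1)
        assert med == 51.9
        med_copd, _ = cross_patient_median(zeep_edrs_medians("copd"), ndigits=1)
        assert med_copd == 63.1
        med_non, _ = cross_patient_median(zeep_edrs_medians("non_copd"), ndigits=1)
        assert med_non == 30.8

    def test_singleton(self):
        med, (q1, q3) = cross_patient_median([7.0])
        assert med == q1 == q3 == 7.0

    def test_hazen_quartiles_match_report_convention(self):
        _, (q1, q3) = cross_patient_median(
            zeep_edrs_medians("all"), ndigits=1, method="hazen"
        )
        assert (q1, q3) == (30.8, 63.1)

    def test_linear_quartiles_interpolate(self):
        _, (q1, q3) = cross_patient_median([1.0, 2.0, 3.0, 4.0])
        assert q1 == pytest.approx(1.75)
        assert q3 == pytest.approx(3.25)


class TestSubgroupComparison:
    def test_exact_rank_sum_on_zeep_medians(self):
        p = rank_sum_exact(zeep_edrs_medians("copd"), zeep_edrs_medians("non_copd"))
        assert p == pytest.approx(2.0 / 252.0, abs=1e-12)


class TestTitrationSummary:
    def test_requires_increasing_peep(self):
        lv = [
            PEEPLevelSummary(peep=p, e_lung=30, edrs_median=30) for p in (5, 5)
        ]
        with pytest.raises(ValueError, match="increasing"):
            TitrationSummary(patient_id="x", levels=lv)

    def test_dataframe_round_trip(self):
        import pandas as pd

        df = pd.DataFrame(
            {"peep": [0, 5], "e_lung": [30.0, 25.0], "edrs_median": [31.0, 26.0],
             "edrs_area": [33.0, 27.0]}
        )
        ts = TitrationSummary.from_dataframe(df, patient_id="p")
        out = ts.to_dataframe()
        assert list(out["peep"]) == [0.0, 5.0]
        assert list(out["e_lung"]) == [30.0, 25.0]
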