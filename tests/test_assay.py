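"""Batch-assay rate fitting, stoichiometric ratios and pH optima."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snadlab import (
    AssayCondition,
    AssaySeries,
    BatchAssayModel,
    fit_rate,
    ph_optimum,
    stoichiometric_ratio,
)
from snadlab.errors import (
    DomainError,
    InsufficientDataError,
    UndefinedRatioError,
)

from conftest import make_linear_series, ols_normal_equations


class TestFitRate:
    def test_exact_line(self):
        series = make_linear_series(slope_per_h=-10.0, intercept=200.0)
        est = fit_rate(series, "TAN")
        assert est.slope == pytest.approx(-10.0)
        assert est.r_squared == pytest.approx(1.0)
        assert est.stderr == pytest.approx(0.0, abs=1e-9)
        assert est.n_points == 7

    def test_noisy_line_within_three_stderr(self):
        series = make_linear_series(slope_per_h=-10.0, noise_sd=1.0, seed=42)
        est = fit_rate(series, "TAN")
        assert abs(est.slope - (-10.0)) < 3 * est.stderr
        # agree with the independently coded normal-equations oracle
        slope, stderr, r2 = ols_normal_equations(
            series.times, series.concentrations["TAN"]
        )
        assert est.slope == pytest.approx(slope * 60.0, rel=1e-10)
        assert est.stderr == pytest.approx(stderr * 60.0, rel=1e-10)
        assert est.r_squared == pytest.approx(r2, rel=1e-10)

    def test_two_points_insufficient(self):
        series = AssaySeries(times=[0, 30], concentrations={"TAN": [100, 95]})
        with pytest.raises(InsufficientDataError):
            fit_rate(series, "TAN")

    def test_window_restricts_points(self):
        series = make_linear_series(slope_per_h=-10.0)
        est = fit_rate(series, "TAN", window=(60, 180))
        assert est.n_points == 5
        assert est.window == (60.0, 180.0)
        with pytest.raises(InsufficientDataError):
            fit_rate(series, "TAN", window=(0, 59))

    @given(
        slope=st.floats(-20, 20),
        intercept=st.floats(50, 300),
        n=st.integers(3, 10),
        noise=st.floats(0, 2),
    )
    @settings(derandomize=True, max_examples=60)
    def test_matches_normal_equations_oracle(self, slope, intercept, n, noise):
        """OLS path equals the hand-coded oracle on any small input."""
        t = np.linspace(0, 180, n)
        rng = np.random.default_rng(abs(hash((slope, intercept, n))) % 2**31)
        c = np.clip(intercept + slope / 60.0 * t + rng.normal(0, noise, n), 0, None)
        series = AssaySeries(times=t, concentrations={"TNN": c})
        est = fit_rate(series, "TNN")
        o_slope, o_stderr, _ = ols_normal_equations(t, c)
        assert est.slope == pytest.approx(o_slope * 60.0, rel=1e-9, abs=1e-9)
        # numerically exact lines: tiny rounding differences around 0
        assert est.stderr == pytest.approx(o_stderr * 60.0, rel=1e-7, abs=1e-6)

    def test_scaling_and_shift_invariance(self):
        """Doubling concentrations doubles |slope|; shifting times changes nothing."""
        t = np.arange(7) * 30.0
        c = 200 - 10.0 / 60.0 * t + np.sin(t / 17.0)  # deterministic wiggle
        s1 = AssaySeries(times=t, concentrations={"TAN": c})
        s2 = AssaySeries(times=t, concentrations={"TAN": 2 * c})
        s3 = AssaySeries(times=t + 500.0, concentrations={"TAN": c})
        r1, r2, r3 = (fit_rate(s, "TAN") for s in (s1, s2, s3))
        assert r2.slope == pytest.approx(2 * r1.slope, rel=1e-12)
        assert r3.slope == pytest.approx(r1.slope, rel=1e-12)

    def test_specific_rates_attached_from_condition(self):
        cond = AssayCondition(protein_conc=2.85, tss=10.0)
        series = make_linear_series(slope_per_h=-3.83, intercept=126.0, condition=cond)
        est = fit_rate(series, "TAN")
        assert est.specific_rate == pytest.approx(1.60, abs=0.005)
        assert est.tss_rate == pytest.approx(0.383, abs=1e-6)


class TestStoichiometricRatio:
    def _est(self, slope, species="TNN", stderr=0.01):
        series = make_linear_series(slope_per_h=slope, species=species)
        return fit_rate(series, species)

    @pytest.mark.parametrize(
        "num_slope, den_slope, expected",
        [(10.0, -10.0, 1.0), (-13.2, -10.0, 1.32), (-14.0, -10.0, 1.4), (-16.0, -10.0, 1.6)],
    )
    def test_reference_ratios(self, num_slope, den_slope, expected):
        ratio = stoichiometric_ratio(
            self._est(num_slope, "TNN"), self._est(den_slope, "TAN")
        )
        assert ratio.ratio == pytest.approx(expected)

    def test_rescaling_invariance(self):
        r1 = stoichiometric_ratio(self._est(-14.0), self._est(-10.0, "TAN"))
        r2 = stoichiometric_ratio(self._est(-14.0 * 3), self._est(-10.0 * 3, "TAN"))
        assert r1.ratio == pytest.approx(r2.ratio, rel=1e-12)

    def test_undetectable_denominator_refused(self):
        num = self._est(-14.0)
        den_series = make_linear_series(slope_per_h=0.0, intercept=100.0,
                                        species="TAN", noise_sd=1.0, seed=3)
        den = fit_rate(den_series, "TAN")
        assert not den.detectable
        with pytest.raises(UndefinedRatioError):
            stoichiometric_ratio(num, den)

    def test_stderr_propagation_first_order(self):
        series = make_linear_series(slope_per_h=-14.0, species="TNN",
                                    noise_sd=1.0, seed=11)
        series2 = make_linear_series(slope_per_h=-10.0, species="TAN",
                                     noise_sd=1.0, seed=12)
        num, den = fit_rate(series, "TNN"), fit_rate(series2, "TAN")
        r = stoichiometric_ratio(num, den)
        expected = r.ratio * np.sqrt(
            (num.stderr / abs(num.slope)) ** 2 + (den.stderr / abs(den.slope)) ** 2
        )
        assert r.stderr == pytest.approx(expected, rel=1e-12)


class TestPhOptimum:
    @pytest.mark.parametrize(
        "profile, best, flag",
        [
            ({6: 0.2, 7: 1.0, 8: 1.86, 9: 0.9}, 8, "interior"),
            ({6: 1, 7: 2, 8: 3}, 8, "boundary"),
            ({7.5: 0.3, 7.8: 0.38, 8.0: 0.38, 8.5: 0.2}, 7.8, "interior"),
        ],
    )
    def test_argmax_and_flag(self, profile, best, flag):
        assert ph_optimum(profile) == (best, flag)

    def test_empty_and_short_profiles(self):
        with pytest.raises(DomainError):
            ph_optimum({})
        with pytest.raises(InsufficientDataError):
            ph_optimum({7.0: 1.0, 8.0: 2.0})


class TestModelObjects:
    def test_fit_returns_rates_for_all_species(self):
        t = np.arange(7) * 30.0
        series = AssaySeries(
            times=t,
            concentrations={"TAN": 126 - 10 / 60 * t, "TNN": 10 / 60 * t,
                            "NO3N": np.zeros(7)},
            condition=AssayCondition(protein_conc=2.85, tss=10.0),
        )
        res = BatchAssayModel(series).fit()
        assert set(res.rates) == {"TAN", "TNN", "NO3N"}
        assert res.headline_ratio.ratio == pytest.approx(1.0)
        text = res.summary()
        assert "TNN_produced/TAN_removed" in text and "1.000" in text
        d = res.to_dict()
        assert d["ratio"]["value"] == pytest.approx(1.0)
        assert 0.0 <= d["rates"]["NO3N"]["r_squared"] <= 1.0

    def test_from_dataframe_csv_roundtrip(self, tmp_path):
        import pandas as pd

        from snadlab import read_assay_csv

        t = np.arange(7) * 30.0
        df = pd.DataFrame({
            "time_min": t,
            "TAN_mgN_L": 126 - 10 / 60 * t,
            "TNN_mgN_L": 10 / 60 * t,
            "NO3_mgN_L": np.zeros(7),
        })
        p = tmp_path / "bottle.csv"
        df.to_csv(p, index=False)
        series = read_assay_csv(p)
        assert set(series.species) == {"TAN", "TNN", "NO3N"}
        res = BatchAssayModel(series).fit()
        assert res.rates["TAN"].slope == pytest.approx(-10.0)

    def test_series_validation(self):
        with pytest.raises(DomainError):
            AssaySeries(times=[0, 30, 20], concentrations={"TAN": [1, 2, 3]})
        with pytest.raises(DomainError):
            AssaySeries(times=[0, 30, 60], concentrations={"TAN": [1, -2, 3]})
        with pytest.raises(DomainError):
            AssaySeries(times=[0, 30, 60], concentrations={"XAN": [1, 2, 3]})
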