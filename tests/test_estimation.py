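"""Parameter recovery from synthetic observations."""

import numpy as np
import pytest

from pukinetics import (
    NoiseModel,
    TimeGrid,
    TimeSeries,
    UptakeParams,
    default_parameter_set,
    fit_first_order_rate,
    fit_internalization,
    fit_langmuir,
    generate_noisy_timeseries,
    internalization_closed_form,
    langmuir_coverage,
)
from pukinetics.errors import DataDomainError, UnidentifiableParametersError


def _decay_series(k, y0=1.0, t_end=500.0, n=50):
    t = np.linspace(0.0, t_end, n)
    return TimeSeries(t, y0 * np.exp(-k * t))


class TestFirstOrderFit:
    @pytest.mark.parametrize("k", [1e-3, 3e-3, 1e-2])
    def test_noiseless_recovery_exact(self, k):
        result = fit_first_order_rate(_decay_series(k))
        assert result.converged
        assert result.estimates["k"] == pytest.approx(k, rel=1e-8)
        assert result.estimates["y0"] == pytest.approx(1.0, rel=1e-8)

    def test_noisy_recovery_rate(self):
        # multiplicative 5% noise, 50 points over 500 h: k within 10%
        params = default_parameter_set()
        hits = 0
        for seed in range(30):
            ts = generate_noisy_timeseries(
                "degradation", params, TimeGrid(0.0, 500.0, 50),
                NoiseModel(sigma=0.05), seed=seed,
            )
            k_hat = fit_first_order_rate(ts).estimates["k"]
            hits += abs(k_hat - params.degradation.k) / params.degradation.k < 0.10
        assert hits >= 29

    def test_constant_series_hits_zero_boundary(self):
        t = np.linspace(0.0, 100.0, 20)
        result = fit_first_order_rate(TimeSeries(t, np.full(20, 2.0)))
        assert result.estimates["k"] == 0.0
        assert not result.converged

    def test_nonpositive_values_rejected(self):
        t = np.linspace(0.0, 10.0, 5)
        with pytest.raises(DataDomainError):
            fit_first_order_rate(TimeSeries(t, np.array([1.0, 0.5, 0.0, 0.2, 0.1])))

    def test_time_unit_equivariance(self):
        # same data with t in days returns a rate exactly 24x per-hour
        series_h = _decay_series(1e-2)
        series_d = TimeSeries(series_h.times / 24.0, series_h.values)
        k_h = fit_first_order_rate(series_h).estimates["k"]
        k_d = fit_first_order_rate(series_d).estimates["k"]
        assert k_d == pytest.approx(24.0 * k_h, rel=1e-9)


class TestLangmuirFit:
    def test_noiseless_recovery_exact(self):
        c = np.logspace(-9, -3, 30)
        result = fit_langmuir(c, langmuir_coverage(c, 1e6))
        assert result.converged
        assert result.estimates["K"] == pytest.approx(1e6, rel=1e-6)
        assert result.warnings == []

    def test_noisy_recovery_rate(self):
        # additive 0.02 coverage noise, 30 log-spaced points: K within 15%
        k_true = 1e6
        c = np.logspace(-3, 3, 30) / k_true
        clean = langmuir_coverage(c, k_true)
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            theta = np.clip(clean + rng.normal(0.0, 0.02, 30), 1e-9, 1 - 1e-9)
            k_hat = fit_langmuir(c, theta).estimates["K"]
            hits += abs(k_hat - k_true) / k_true < 0.15
        assert hits >= 29

    def test_linear_data_flagged_as_misfit(self):
        # a non-saturating linear response cannot be an isotherm
        c = np.linspace(1e-7, 2e-6, 20)
        theta = np.clip(4e5 * c, None, 0.95)
        result = fit_langmuir(c, theta)
        assert result.sse > 20 * 0.05**2 or result.warnings

    def test_coverage_domain_enforced(self):
        c = np.array([1e-7, 1e-6, 1e-5])
        with pytest.raises(DataDomainError):
            fit_langmuir(c, np.array([0.1, 0.5, 1.0]))


class TestInternalizationFit:
    def test_noiseless_recovery_exact(self):
        p = UptakeParams()
        t = np.linspace(0.0, 3000.0, 50)
        series = TimeSeries(t, np.asarray(internalization_closed_form(p, t)))
        result = fit_internalization(series, theta=p.theta, n_max=p.n_max)
        assert result.converged
        assert result.estimates["k_uptake"] == pytest.approx(p.k_uptake, rel=1e-6)
        assert result.estimates["k_degr"] == pytest.approx(p.k_degr, rel=1e-6)

    def test_noisy_recovery_rate(self):
        # multiplicative 5% noise, 50 points over 3/k_degr: both rates within 15%
        params = default_parameter_set()
        u = params.uptake
        hits = 0
        for seed in range(30):
            ts = generate_noisy_timeseries(
                "internalization", params, TimeGrid(0.0, 3000.0, 50),
                NoiseModel(sigma=0.05), seed=seed,
            )
            est = fit_internalization(ts, theta=u.theta, n_max=u.n_max).estimates
            hits += (
                abs(est["k_uptake"] - u.k_uptake) / u.k_uptake < 0.15
                and abs(est["k_degr"] - u.k_degr) / u.k_degr < 0.15
            )
        assert hits >= 27

    def test_truncated_data_warns_on_identifiability(self):
        # a window ending at 0.1/k_degr never sees the saturation knee
        p = UptakeParams()
        t = np.linspace(0.0, 0.1 / p.k_degr, 50)
        series = TimeSeries(t, np.asarray(internalization_closed_form(p, t)))
        result = fit_internalization(series, theta=p.theta, n_max=p.n_max)
        assert result.converged
        assert any("identifiability" in w for w in result.warnings)

    def test_full_window_carries_no_warning(self):
        p = UptakeParams()
        t = np.linspace(0.0, 3000.0, 50)
        series = TimeSeries(t, np.asarray(internalization_closed_form(p, t)))
        assert fit_internalization(series, theta=p.theta, n_max=p.n_max).warnings == []

    def test_all_zero_data_unidentifiable(self):
        t = np.linspace(0.0, 100.0, 10)
        with pytest.raises(UnidentifiableParametersError):
            fit_internalization(TimeSeries(t, np.zeros(10)), theta=0.5, n_max=1000.0)

    def test_time_unit_equivariance(self):
        p = UptakeParams()
        t = np.linspace(0.0, 3000.0, 50)
        values = np.asarray(internalization_closed_form(p, t))
        est_h = fit_internalization(
            TimeSeries(t, values), theta=p.theta, n_max=p.n_max).estimates
        est_d = fit_internalization(
            TimeSeries(t / 24.0, values), theta=p.theta, n_max=p.n_max).estimates
        assert est_d["k_uptake"] == pytest.approx(24.0 * est_h["k_uptake"], rel=1e-5)
        assert est_d["k_degr"] == pytest.approx(24.0 * est_h["k_degr"], rel=1e-5)


class TestSampleSizeScaling:
    def test_recovery_error_decreases_with_n(self):
        params = default_parameter_set()
        k_true = params.degradation.k
        errors = []
        for n in (10, 50, 200):
            errs = []
            for seed in range(20):
                ts = generate_noisy_timeseries(
                    "degradation", params, TimeGrid(0.0, 500.0, n),
                    NoiseModel(sigma=0.05), seed=seed,
                )
                errs.append(abs(fit_first_order_rate(ts).estimates["k"] - k_true))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]
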