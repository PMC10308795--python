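"""Growth-rate, q-rate, and yield estimation."""

import numpy as np
import pytest

from mfa13.physiology import (
    PhysioParams,
    RateFit,
    TimeSeries,
    compute_yields,
    fit_growth,
    fit_physiology,
    fit_qrates,
)

MU, QS, X0 = 0.22, -3.37, 0.025 * 0.563  # reference-culture magnitudes


def make_series(mu=MU, qs=QS, x0=X0, m0=27.1, t=None, products=True):
    if t is None:  # sample the batch until ~95 % substrate consumption
        t_end = np.log(1.0 + 0.95 * m0 * mu / (abs(qs) * x0)) / mu
        t = np.linspace(0.0, t_end, 14)
    x = x0 * np.exp(mu * t)
    growth = (x0 / mu) * (np.exp(mu * t) - 1.0)
    conc = {"glycerol": m0 + qs * growth}
    if products:
        conc["p1"] = 0.4 * abs(qs) * growth
        conc["p2"] = 0.1 * abs(qs) * growth
    return TimeSeries(t, x / 0.563, conc, biomass_unit="od600")


def test_noiseless_growth_recovery():
    g = fit_growth(make_series())
    assert g.mu == pytest.approx(MU, abs=1e-6)
    assert g.x0 == pytest.approx(X0, rel=1e-6)
    assert g.is_growing


def test_noiseless_qrate_recovery():
    ts = make_series()
    g = fit_growth(ts)
    rates = fit_qrates(ts, g)
    assert rates["glycerol"].q == pytest.approx(QS, abs=1e-6)
    assert rates["p1"].q == pytest.approx(0.4 * abs(QS), abs=1e-6)


def test_constant_biomass_flagged_non_growing():
    t = np.arange(0.0, 8.0)
    ts = TimeSeries(t, np.full_like(t, 0.5), {})
    g = fit_growth(ts)
    assert abs(g.mu) < 1e-9
    assert not g.is_growing


def test_flat_metabolite_recovers_zero_rate(rng):
    ts = make_series()
    ts.concentrations["inert"] = 5.0 * (1 + 0.02 * rng.standard_normal(len(ts.time)))
    g = fit_growth(ts)
    q = fit_qrates(ts, g, cv=0.02)["inert"]
    assert abs(q.q) < 3 * q.sd_q + 1e-3


def test_mu_noise_recovery_median_under_2pct():
    errs = []
    for seed in range(200):
        r = np.random.default_rng(seed)
        t = np.linspace(0, 16.5, 12)
        x = X0 * np.exp(MU * t) * r.lognormal(0, 0.05, len(t))
        g = fit_growth(TimeSeries(t, x / 0.563, {}), cv=0.05)
        errs.append(abs(g.mu - MU) / MU)
    assert np.median(errs) <= 0.02


def test_sign_pattern_recovered_under_noise():
    for seed in range(100):
        r = np.random.default_rng(10_000 + seed)
        ts = make_series()
        ts.biomass = ts.biomass * r.lognormal(0, 0.05, len(ts.time))
        ts.concentrations = {
            k: v * r.lognormal(0, 0.05, len(v)) for k, v in ts.concentrations.items()
        }
        g = fit_growth(ts, cv=0.05)
        rates = fit_qrates(ts, g, cv=0.05)
        assert rates["glycerol"].q < 0 < rates["p1"].q
        assert rates["p2"].q > 0


def test_lag_phase_is_trimmed():
    t = np.arange(0.0, 16.0)
    x = np.where(t < 5, X0, X0 * np.exp(MU * (t - 5)))  # 5 h lag
    g = fit_growth(TimeSeries(t, x / 0.563, {}))
    assert g.window[0] >= 4
    assert g.mu == pytest.approx(MU, rel=1e-6)


def test_growth_fit_errors():
    with pytest.raises(ValueError):
        fit_growth(TimeSeries(np.arange(3.0), np.ones(3), {}))
    with pytest.raises(ValueError):
        fit_growth(TimeSeries(np.arange(5.0), np.array([1, 2, 0, 3, 4.0]), {}))


def test_all_missing_metabolite_skipped_with_warning():
    ts = make_series()
    ts.concentrations["ghost"] = np.full(len(ts.time), np.nan)
    g = fit_growth(ts)
    with pytest.warns(UserWarning, match="ghost"):
        rates = fit_qrates(ts, g)
    assert "ghost" not in rates


def _params(mu=0.22, qs=-3.37, qp=0.084 * 3.37):
    return PhysioParams(
        mu=mu, x0=X0, sd_mu=0.001, sd_x0=0.001,
        rates={
            "glycerol": RateFit(qs, 27.1, 0.05, 0.1),
            "hp": RateFit(qp, 0.0, 0.01, 0.1),
        },
    )


MW = {"glycerol": 92.09, "hp": 90.08}
NC = {"glycerol": 3, "hp": 3}


def test_biomass_yield_hand_value():
    y = compute_yields(_params(), "glycerol", MW, NC)
    # mu / (|q_S| MW 1e-3) = 0.22 / (3.37 * 0.09209) = 0.709 g/g
    assert y.loc["biomass", "yield_g_per_g"] == pytest.approx(0.709, abs=0.002)


def test_equal_rates_give_unit_cmol_yield():
    y = compute_yields(_params(qp=3.37), "glycerol", MW, NC)
    assert y.loc["hp", "yield_cmol_per_cmol"] == pytest.approx(1.0, abs=1e-12)


def test_cmol_to_mass_yield_conversion():
    # 0.084 Cmol/Cmol for a C3 product on a C3 substrate -> ~0.082 g/g
    y = compute_yields(_params(), "glycerol", MW, NC)
    assert y.loc["hp", "yield_cmol_per_cmol"] == pytest.approx(0.084, abs=1e-12)
    assert y.loc["hp", "yield_g_per_g"] == pytest.approx(0.081, abs=0.002)


def test_yield_requires_consumed_substrate():
    with pytest.raises(ValueError):
        compute_yields(_params(qs=1.0), "glycerol", MW, NC)


def test_cmol_yield_invariant_to_concentration_units():
    ts_mm = make_series(products=False)
    ts_mm.concentrations["hp"] = 0.084 * abs(QS) * (X0 / MU) * (np.exp(MU * ts_mm.time) - 1)
    p_mm = fit_physiology(ts_mm)
    # same data expressed in g/L; q comes out in g gCDW^-1 h^-1, convert back
    ts_gl = make_series(products=False)
    ts_gl.concentrations = {
        "glycerol": ts_mm.concentrations["glycerol"] * MW["glycerol"] / 1000,
        "hp": ts_mm.concentrations["hp"] * MW["hp"] / 1000,
    }
    p_gl = fit_physiology(ts_gl)
    for name in ("glycerol", "hp"):
        p_gl.rates[name].q *= 1000 / MW[name]
    y1 = compute_yields(p_mm, "glycerol", MW, NC)
    y2 = compute_yields(p_gl, "glycerol", MW, NC)
    assert y1.loc["hp", "yield_cmol_per_cmol"] == pytest.approx(
        y2.loc["hp", "yield_cmol_per_cmol"], rel=1e-9
    )


def test_parameter_bias_and_coverage_grid():
    """Bias of mu and q <= 1 % and ~2 SD coverage >= 90 % over the study grid."""
    hits, mu_bias, q_bias = [], [], []
    for mu in (0.10, 0.13, 0.22):
        for qs in (-2.1, -3.4):
            for cv in (0.02, 0.05):
                mus, qs_hat = [], []
                for seed in range(40):
                    r = np.random.default_rng(hash((mu, qs, cv, seed)) % 2**31)
                    ts = make_series(mu=mu, qs=qs, products=False)
                    n = len(ts.time)
                    ts.biomass = ts.biomass * r.lognormal(0, cv, n)
                    ts.concentrations["glycerol"] = ts.concentrations[
                        "glycerol"
                    ] * r.lognormal(0, cv, n)
                    g = fit_growth(ts, cv=cv)
                    rates = fit_qrates(ts, g, cv=cv)
                    mus.append(g.mu)
                    qs_hat.append(rates["glycerol"].q)
                    hits.append(abs(g.mu - mu) <= 2 * g.sd_mu)
                    hits.append(abs(rates["glycerol"].q - qs) <= 2 * rates["glycerol"].sd_q)
                mu_bias.append(abs(np.mean(mus) - mu) / mu)
                q_bias.append(abs(np.mean(qs_hat) - qs) / abs(qs))
    assert max(mu_bias) <= 0.01
    assert max(q_bias) <= 0.015
    assert np.mean(hits) >= 0.90
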