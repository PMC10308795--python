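"""Validation studies quantifying pipeline performance on synthetic data.

Each function runs one self-contained study at its documented conditions
(noise: MID SD 0.01, rate CV 5 %, physiology CV 5 %; Monte-Carlo n = 100)
and returns plain numbers.  The studies are shared between the test suite
and the reproduction script, so the same computation backs both.
"""

from __future__ import annotations

import numpy as np

from .correction import FragmentFormula, build_correction_matrix, correct_mid
from .design import MeasurementSpec, rank_mixtures, score_mixture
from .emu import TracerMixture, simulate_mids
from .fba import cofactor_balance, fba_max_atpm, pyruvate_partition
from .fitting import FitOptions, Measurements, fit_fluxes, monte_carlo
from .fixtures import toy_energy_model, toy_model, toy_reference_fluxes
from .isotopomer import enumerate_isotopomers_oracle
from .model import FluxVector, sample_feasible_fluxes
from .physiology import compute_yields, fit_physiology
from .synth import ScenarioSpec, generate_labelling_dataset, generate_timeseries

DEFAULT_MIX = {"GLYC": [((1,), 0.2), ((2,), 0.8)]}


def study_mixtures() -> list[TracerMixture]:
    """Three tracer compositions spanning the designs used throughout."""
    return [
        TracerMixture({"GLYC": [((1,), 0.2), ((2,), 0.8)]}),
        TracerMixture.single("GLYC", (1,), purity=0.99),
        TracerMixture({"GLYC": [((1, 3), 0.4), ((1, 2, 3), 0.3), ((), 0.3)]}),
    ]


def random_toy_fluxes(rng: np.random.Generator, n: int, uptake: float = 1.0) -> list[FluxVector]:
    """Random interior steady-state vectors: LP vertex mixtures blended with a
    strictly positive reference so every pathway carries some flux."""
    model = toy_model()
    ref = toy_reference_fluxes(
        uptake=uptake, scramble=0.15 * uptake, cycle=0.2 * uptake,
        pdc=0.2 * uptake, pyr_out=0.12 * uptake,
    )
    out = sample_feasible_fluxes(model, n, rng, uptake=("upt", uptake))
    for fv in out:
        fv.net = 0.8 * fv.net + 0.2 * ref.net
        fv.xch["cleave"] = float(rng.uniform(0.0, 0.8))
    return out


def emu_oracle_deviation(seed: int, n_fluxes: int = 20) -> float:
    """Max |EMU - full-isotopomer oracle| over random feasible flux vectors
    crossed with three tracer mixtures."""
    model = toy_model()
    rng = np.random.default_rng(seed)
    dev = 0.0
    for fv in random_toy_fluxes(rng, n_fluxes):
        for mix in study_mixtures():
            emu = simulate_mids(model, fv, mix)
            orc = enumerate_isotopomers_oracle(model, fv, mix)
            for t in emu:
                dev = max(dev, float(np.max(np.abs(emu[t] - orc[t]))))
    return dev


def _scenario_measurements(model, scenario: ScenarioSpec, rng) -> Measurements:
    """Corrected MIDs + noisy rates for one synthetic labelling experiment.

    The Monte-Carlo resampler re-noises the *raw* isotopologue table and
    re-runs the correction, so replicate errors carry the correlations the
    correction inverse introduces.
    """
    from .pipeline import _correct_raw_table

    raw, _ = generate_labelling_dataset(scenario)
    corrected = _correct_raw_table(model, raw, scenario.inoculum_fraction)
    mids = {sp: (v, sd) for sp, (v, sd, _) in corrected.items()}
    rates = {}
    for rxn in model.measured_rates:
        truth = scenario.truth[rxn]
        sd = max(0.05 * abs(truth), 0.01)
        rates[rxn] = (truth + rng.normal(0, sd), sd)

    def resample(r: np.random.Generator) -> Measurements:
        raw2 = raw.copy()
        raw2["intensity"] = raw2["intensity"] + r.normal(0, raw2["sd"])
        corr2 = _correct_raw_table(model, raw2, scenario.inoculum_fraction)
        mids2 = {sp: (v, sd) for sp, (v, sd, _) in corr2.items()}
        rates2 = {k: (v + r.normal(0, s), s) for k, (v, s) in rates.items()}
        return Measurements(mids2, rates2, scenario.mixture)

    return Measurements(mids, rates, scenario.mixture, resampler=resample)


# public name: building corrected measurements from a scenario is useful
# beyond the studies themselves (examples, user scripts)
scenario_measurements = _scenario_measurements


def coverage_study(seed: int, n_scenarios: int = 20, mc: int = 100) -> dict:
    """End-to-end recovery: do 95 % Monte-Carlo CIs cover the ground truth?

    Returns the coverage fraction over identifiable fluxes pooled across
    scenarios, plus bookkeeping counts.
    """
    model = toy_model()
    root = np.random.default_rng(seed)
    covered = total = 0
    for i in range(n_scenarios):
        rng = np.random.default_rng(seed + 100 + i)
        truth = random_toy_fluxes(rng, 1, uptake=3.37)[0]
        scenario = ScenarioSpec(model=model, truth=truth, seed=seed + 100 + i)
        meas = _scenario_measurements(model, scenario, rng)
        fit = fit_fluxes(model, meas, FitOptions(n_starts=4, seed=seed + i))
        fit = monte_carlo(model, fit, meas, n=mc, seed=seed + 500 + i)
        for j, rid in enumerate(fit.fluxes.reaction_ids):
            if rid in fit.non_identifiable:
                continue
            total += 1
            if fit.ci_low[j] - 1e-9 <= truth.net[j] <= fit.ci_high[j] + 1e-9:
                covered += 1
    return {"coverage": covered / total, "n_checked": total, "n_scenarios": n_scenarios}


def chi2_calibration(seed: int, n_reps: int = 100) -> dict:
    """Empirical pass rate of the 95 % goodness-of-fit test under exactly
    specified Gaussian noise (no truncation or renormalization)."""
    model = toy_model()
    truth = toy_reference_fluxes(uptake=3.37, scramble=0.6, cycle=0.9, pdc=0.8, pyr_out=0.5)
    mix = TracerMixture({k: list(v) for k, v in DEFAULT_MIX.items()})
    sim = simulate_mids(model, truth, mix)
    passed = 0
    for i in range(n_reps):
        rng = np.random.default_rng(seed + i)
        mids = {
            t.species: (sim[t] + rng.normal(0, 0.01, len(sim[t])), np.full(len(sim[t]), 0.01))
            for t in sim
        }
        rates = {}
        for rxn in model.measured_rates:
            sd = max(0.05 * abs(truth[rxn]), 0.01)
            rates[rxn] = (truth[rxn] + rng.normal(0, sd), sd)
        fit = fit_fluxes(model, Measurements(mids, rates, mix), FitOptions(n_starts=3, seed=seed + i))
        passed += fit.chi2_pass
    return {"pass_rate": passed / n_reps, "n_reps": n_reps}


def physiology_recovery(seed: int, n_seeds: int = 200, noise_cv: float = 0.05) -> dict:
    """Median relative recovery error of mu and q_S at the study magnitudes
    (mu 0.13/0.22 h^-1, q_S 2.10/3.37 mmol gCDW^-1 h^-1, 5 % noise)."""
    model = toy_model()
    combos = [(0.13, 2.10), (0.22, 3.37), (0.13, 3.37), (0.22, 2.10)]
    mu_err, q_err = [], []
    for i in range(n_seeds):
        mu, qs = combos[i % len(combos)]
        truth = toy_reference_fluxes(
            uptake=qs, scramble=0.15 * qs, cycle=0.2 * qs, pdc=0.25 * qs, pyr_out=0.15 * qs
        )
        # sampling emulates the batch protocol, scaled to each strain's batch
        # length: 2-hourly early, then ~hourly through the late exponential
        # phase where most of the substrate is consumed (the generator clips
        # at exhaustion, so the last samples sit near full consumption where
        # proportional errors are small in absolute terms)
        x0 = 0.025 * 0.563
        t_end = np.log(1.0 + 0.95 * 27.1 * mu / (qs * x0)) / mu
        late = np.arange(0.6 * t_end, 1.05 * t_end, max(t_end / 30.0, 0.5))
        schedule = np.unique(np.concatenate([np.arange(0.0, 0.6 * t_end, 2.0), late]))
        sc = ScenarioSpec(model=model, truth=truth, mu=mu, od_cv=noise_cv,
                          conc_cv=noise_cv, schedule=schedule, seed=seed + i)
        ts = generate_timeseries(sc)
        physio = fit_physiology(ts, cv=noise_cv)
        mu_err.append(abs(physio.mu - mu) / mu)
        q_err.append(abs(abs(physio.rates["glycerol"].q) - qs) / qs)
    return {
        "mu_median_rel_err": float(np.median(mu_err)),
        "qs_median_rel_err": float(np.median(q_err)),
        "n_seeds": n_seeds,
    }


def correction_roundtrip(seed: int) -> dict:
    """build_correction_matrix then correct_mid must be the identity on
    noiseless data; columns must be probability distributions."""
    rng = np.random.default_rng(seed)
    max_err = col_dev = 0.0
    for formula in ("C3H7NO2", "C5H9NO4", "C2H5NO2"):
        C = build_correction_matrix(FragmentFormula.parse(formula), purity=0.995)
        col_dev = max(col_dev, float(np.max(np.abs(C.sum(axis=0) - 1.0))))
        for _ in range(20):
            x = rng.dirichlet(np.ones(C.shape[1]))
            rec, _ = correct_mid(C @ x, C)
            max_err = max(max_err, float(np.max(np.abs(rec - x))))
    return {"roundtrip_max_err": max_err, "colsum_max_dev": col_dev}


def design_sanity(seed: int) -> dict:
    """Uninformative designs (unlabelled, pure U-13C) must rank strictly below
    informative positional mixtures; ranking must be order-invariant."""
    model = toy_model()
    ref = toy_reference_fluxes()
    uninformative = [TracerMixture.unlabelled("GLYC"), TracerMixture.single("GLYC", (1, 2, 3))]
    informative = [
        TracerMixture.single("GLYC", (1,)),
        TracerMixture({"GLYC": [((1,), 0.2), ((2,), 0.8)]}),
        TracerMixture({"GLYC": [((1,), 0.5), ((2,), 0.5)]}),
        TracerMixture({"GLYC": [((1,), 0.5), ((1, 2, 3), 0.5)]}),
    ]
    spec = MeasurementSpec()
    s_un = [score_mixture(model, ref, m, spec) for m in uninformative]
    s_inf = [score_mixture(model, ref, m, spec) for m in informative]
    gap = min(s.n_precise for s in s_inf) - max(s.n_precise for s in s_un)

    scores = s_un + s_inf
    rng = np.random.default_rng(seed)
    order1 = rank_mixtures(list(scores))
    shuffled = list(scores)
    rng.shuffle(shuffled)
    order2 = rank_mixtures(shuffled)
    deterministic = [s.mixture_key() for s in order1] == [s.mixture_key() for s in order2]
    return {"n_precise_gap": gap, "order_invariant": deterministic,
            "worst_informative": min(s.n_precise for s in s_inf),
            "best_uninformative": max(s.n_precise for s in s_un)}


def fba_checks(seed: int, n_vectors: int = 10) -> dict:
    """Hand-derived LP optimum (ATPM = 2 x uptake on the toy energy network)
    and cofactor-balance closure for random feasible vectors."""
    energy = toy_energy_model()
    res = fba_max_atpm(energy, bounds={"upt": (0.0, 1.0)})
    rng = np.random.default_rng(seed)
    worst = 0.0
    for fv in sample_feasible_fluxes(energy, n_vectors, rng, uptake=("upt", 1.0)):
        for cof in ("ATP", "NADPH"):
            df = cofactor_balance(energy, fv, cof)
            worst = max(worst, abs(df.attrs["net"]))
    return {"atpm_per_uptake": res.objective, "balance_max_abs_net": worst}


def yield_checks(seed: int) -> dict:
    """Yields recomputed through the physiology module.

    Biomass yield for a mu = 0.22 h^-1 / q_S = 3.37 mmol gCDW^-1 h^-1 culture
    (glycerol, MW 92.09) and the g/g equivalent of a 0.084 Cmol/Cmol product
    yield for a C3 product (MW 90.08) on a C3 substrate.
    """
    model = toy_model()
    qs = 3.37
    truth = toy_reference_fluxes(uptake=qs, scramble=0.5, cycle=0.7,
                                 pdc=0.084 * qs, pyr_out=0.3 * qs)
    mu = 0.22
    x0 = 0.025 * 0.563
    t_end = np.log(1.0 + 0.95 * 27.1 * mu / (qs * x0)) / mu
    schedule = np.unique(np.concatenate([
        np.arange(0.0, 0.6 * t_end, 2.0),
        np.arange(0.6 * t_end, 1.05 * t_end, max(t_end / 30.0, 0.5)),
    ]))
    sc = ScenarioSpec(model=model, truth=truth, mu=mu, od_cv=0.03, conc_cv=0.05,
                      product_rxns={"product_3c": "ace_out", "pyruvate": "pyr_out"},
                      schedule=schedule, seed=seed)
    ts = generate_timeseries(sc)
    physio = fit_physiology(ts, cv=0.05)
    yields = compute_yields(
        physio,
        substrate="glycerol",
        molar_masses={"glycerol": 92.09, "product_3c": 90.08, "pyruvate": 88.06},
        carbon_counts={"glycerol": 3, "product_3c": 3, "pyruvate": 3},
    )
    return {
        "biomass_yield_g_per_g": float(yields.loc["biomass", "yield_g_per_g"]),
        "product_yield_cmol_per_cmol": float(yields.loc["product_3c", "yield_cmol_per_cmol"]),
        "product_yield_g_per_g": float(yields.loc["product_3c", "yield_g_per_g"]),
        "mu": physio.mu,
        "qs": physio.rates["glycerol"].q,
    }


def partition_check() -> dict:
    """Max-ATPM FBA with bounds constructed so 47.1 % of cytosolic pyruvate
    enters the mitochondria-like branch; the LP must report it back."""
    energy = toy_energy_model()
    target = 0.471
    t2p = 2.12
    bounds = {
        "upt": (3.37, 3.37),
        "scramble": (0.25, 0.25),
        "t2p": (t2p, t2p),
        "pyr_out": (target * t2p, target * t2p),
    }
    res = fba_max_atpm(energy, bounds)
    return {"partition_pct": pyruvate_partition(res.fluxes, "pyr_out", "t2p")}
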