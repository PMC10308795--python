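"""One-command orchestration: synthetic panel -> physiology -> MID correction
-> flux fit + Monte-Carlo -> normalization/fold-changes -> FBA energy books.

Outputs are plain CSV/JSON tables (flux tables, relative fluxes, log2
fold-change matrix, residual diagnostics, cofactor balances, a summary with
seeds and stage log), deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import FragmentFormula, build_correction_matrix, correct_mid, subtract_inoculum
from .fba import cofactor_balance, fba_max_atpm, maintenance_split, pyruvate_partition
from .fitting import FitOptions, Measurements, fit_fluxes, monte_carlo, normalize_and_compare
from .fixtures import toy_energy_model, toy_model
from .model import ModelError, load_model, sample_feasible_fluxes
from .physiology import fit_physiology
from .synth import ScenarioSpec, generate_labelling_dataset, generate_timeseries

__all__ = ["PipelineConfig", "run_pipeline", "export_heatmap_matrix", "default_panel_config"]


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    model: str = "toy"  # "toy" or a path to an FTBL-subset file
    energy_model: str = "toy_energy"
    reference: str = "reference"
    strains: dict[str, dict[str, float]] = field(default_factory=dict)
    mc_draws: int = 100
    n_starts: int = 5
    mid_sd: float = 0.01
    od_cv: float = 0.03
    conc_cv: float = 0.05
    inoculum_fraction: float = 0.025
    uptake_rxn: str = "upt"
    pdh_like: str = "pyr_out"
    pyk_like: str = "t2p"
    biomass_rxn: str = "bio"
    atpm_rxn: str = "atpm"
    pathway_sets: dict[str, list[str]] = field(
        default_factory=lambda: {"UG": ["upt", "cond"], "PPP": ["cleave", "scramble"]}
    )
    special_baseline: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_panel_config(outdir: str = "pipeline_out", seed: int = 0) -> PipelineConfig:
    """A 3-strain demonstration panel: reference, a doubled PPP-like split,
    and a doubled decarboxylation branch."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        strains={"ppp_up": {"scramble": 2.0}, "pdc_up": {"pdc": 2.0}},
    )


def _load_models(config: PipelineConfig):
    model = toy_model() if config.model == "toy" else load_model(config.model)
    energy = (
        toy_energy_model() if config.energy_model == "toy_energy" else load_model(config.energy_model)
    )
    return model, energy


def _base_scenario(config: PipelineConfig, model, energy) -> ScenarioSpec:
    """Cofactor-consistent reference ground truth for the toy panel, or an LP
    sample for a user-supplied model; restricted to the labelling model."""
    uptake = 3.37  # mmol gCDW^-1 h^-1, fast-growing reference culture
    if config.model == "toy":
        from .fixtures import toy_energy_fluxes

        full = toy_energy_fluxes(uptake=uptake, scramble=0.25, cycle=0.9,
                                 pdc=0.8, pyr_out=0.5)
    else:
        rng = np.random.default_rng(config.seed)
        full = sample_feasible_fluxes(energy, 1, rng, uptake=(config.uptake_rxn, uptake))[0]
    net = {r: full[r] for r in model.reaction_ids}
    truth = model.flux_vector(net, xch={r.id: 0.3 for r in model.reactions if r.reversible})
    return ScenarioSpec(
        model=model,
        truth=truth,
        mid_sd=config.mid_sd,
        od_cv=config.od_cv,
        conc_cv=config.conc_cv,
        inoculum_fraction=config.inoculum_fraction,
        seed=config.seed,
    )


def _correct_raw_table(model, raw: pd.DataFrame, f_inoculum: float) -> dict:
    """Natural-abundance + inoculum correction of a raw isotopologue table.

    Raw-vector SDs are propagated through the (pseudo-)inverse of the
    correction matrix and the inoculum rescaling — inverting the correction
    amplifies MS noise, and downstream weights must reflect that.
    """
    out = {}
    formulas = dict(model.measured_species)
    for sp, grp in raw.groupby("species"):
        grp = grp.sort_values("mass_shift")
        C, Cinv = _correction_matrices(
            formulas[sp] or f"C{model.metabolites[sp].carbon_count}"
        )
        corrected, residual = correct_mid(grp["intensity"].to_numpy(), C)
        unlabelled = np.zeros(len(corrected))
        unlabelled[0] = 1.0
        corrected = subtract_inoculum(corrected, unlabelled, f_inoculum)
        sd = np.sqrt((Cinv**2) @ grp["sd"].to_numpy() ** 2) / (1.0 - f_inoculum)
        out[sp] = (corrected, sd, residual)
    return out


from functools import lru_cache


@lru_cache(maxsize=64)
def _correction_matrices(formula: str) -> tuple[np.ndarray, np.ndarray]:
    C = build_correction_matrix(FragmentFormula.parse(formula))
    return C, np.linalg.pinv(C)


def _fit_one_strain(config, model, scenario, log):
    ts = generate_timeseries(scenario)
    physio = fit_physiology(ts, cv=scenario.conc_cv)
    log.append({"stage": "physiology", "mu": physio.mu, "sd_mu": physio.sd_mu})

    raw, sidecar = generate_labelling_dataset(scenario)
    corrected = _correct_raw_table(model, raw, scenario.inoculum_fraction)
    log.append({"stage": "correction",
                "max_residual": max(r for _, _, r in corrected.values())})

    mids = {sp: (vals, sd) for sp, (vals, sd, _) in corrected.items()}
    rates = {scenario.substrate_rxn: (abs(physio.rates[scenario.substrate].q),
                                      physio.rates[scenario.substrate].sd_q)}
    for name, rxn in scenario.product_rxns.items():
        rf = physio.rates[name]
        rates[rxn] = (rf.q, rf.sd_q)

    def resample(r):
        raw2 = raw.copy()
        raw2["intensity"] = raw2["intensity"] + r.normal(0, raw2["sd"])
        corr2 = _correct_raw_table(model, raw2, scenario.inoculum_fraction)
        return Measurements(
            {sp: (v, sd) for sp, (v, sd, _) in corr2.items()},
            {k: (v + r.normal(0, s), s) for k, (v, s) in rates.items()},
            scenario.mixture,
        )

    meas = Measurements(mids, rates, scenario.mixture, resampler=resample)
    fit = fit_fluxes(model, meas, FitOptions(n_starts=config.n_starts, seed=scenario.seed))
    fit = monte_carlo(model, fit, meas, n=config.mc_draws, seed=scenario.seed + 17)
    log.append({"stage": "fit", "ssr": fit.ssr, "dof": fit.dof, "chi2_pass": fit.chi2_pass})
    return ts, physio, fit, sidecar


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages for the configured strain panel; returns the bundle.

    Stage failures raise ``ModelError`` naming the stage after writing the
    partial results collected so far to the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, energy = _load_models(config)
    log: list[dict] = []
    bundle: dict = {}
    stage = "setup"
    try:
        stage = "scenario"
        base = _base_scenario(config, model, energy)
        from .synth import generate_strain_panel

        panel, truth_fc = generate_strain_panel(base, config.strains)
        bundle["truth_foldchange"] = truth_fc

        fits, physio_rows = {}, []
        for strain, sc in panel.items():
            stage = f"strain:{strain}"
            _, physio, fit, _ = _fit_one_strain(config, model, sc, log)
            fits[strain] = fit
            physio_rows.append({"strain": strain, "mu": physio.mu, "sd_mu": physio.sd_mu,
                                **{f"q_{k}": v.q for k, v in physio.rates.items()}})
        bundle["physiology"] = pd.DataFrame(physio_rows).set_index("strain")
        bundle["fluxes"] = pd.concat(
            {s: f.flux_table(config.uptake_rxn) for s, f in fits.items()}, names=["strain"]
        )
        bundle["residuals"] = pd.concat(
            {s: f.residuals for s, f in fits.items()}, names=["strain"]
        )

        stage = "normalize"
        rel, fc = normalize_and_compare(
            fits, config.reference, config.uptake_rxn, config.special_baseline
        )
        bundle["relative_fluxes"], bundle["foldchange"] = rel, fc

        stage = "fba"
        fba_rows, balances = [], {}
        for strain, fit in fits.items():
            bounds = {
                rid: (float(min(lo, v)), float(max(hi, v)))
                for rid, lo, hi, v in zip(
                    fit.fluxes.reaction_ids, fit.ci_low, fit.ci_high, fit.fluxes.net
                )
                if rid not in fit.non_identifiable
            }
            try:
                res = fba_max_atpm(energy, bounds, objective_id=config.atpm_rxn)
            except ModelError:
                # CI box misses a cofactor-consistent point: keep only the
                # measured exchanges bounded and note the relaxation
                bounds = {r: bounds[r] for r in model.measured_rates if r in bounds}
                res = fba_max_atpm(energy, bounds, objective_id=config.atpm_rxn)
                log.append({"stage": f"fba:{strain}", "note": "relaxed to exchange bounds"})
            split = maintenance_split(energy, res.fluxes, config.biomass_rxn, config.atpm_rxn)
            fba_rows.append({
                "strain": strain,
                "atpm": res.objective,
                "pyruvate_to_mitochondria_pct": pyruvate_partition(
                    res.fluxes, config.pdh_like, config.pyk_like
                ),
                **split,
            })
            for cof in ("ATP", "NADPH"):
                df = cofactor_balance(energy, res.fluxes, cof)
                df.insert(0, "strain", strain)
                balances.setdefault(cof, []).append(df)
        bundle["fba"] = pd.DataFrame(fba_rows).set_index("strain")
        for cof, parts in balances.items():
            bundle[f"balance_{cof}"] = pd.concat(parts, ignore_index=True)

        stage = "export"
        for name, df in bundle.items():
            df.to_csv(outdir / f"{name}.csv")
        export_heatmap_matrix(fc, outdir / "heatmap_log2fc.csv", config)
        summary = {
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "stages": log,
            "strains": list(panel),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        bundle["summary"] = summary
        return bundle
    except Exception as exc:
        for name, df in bundle.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(outdir / f"partial_{name}.csv")
        raise ModelError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def export_heatmap_matrix(fc: pd.DataFrame, path, config: PipelineConfig | None = None,
                          clip: float = 1.0) -> pd.DataFrame:
    """Reactions x strains log2 fold-change matrix for heat-map rendering.

    Values are annotated, not altered: entries beyond +/- clip carry a
    ``clipped`` marker column per strain (the conventional color-scale limit),
    reactions with an alternative baseline keep their own scale, and
    undefined ratios stay as empty cells rather than zeros.
    """
    out = fc.copy()
    for col in fc.columns:
        out[f"{col}_clipped"] = np.where(
            fc[col].abs() > clip, np.sign(fc[col]).map({1.0: "+", -1.0: "-"}), ""
        )
    out.to_csv(path, na_rep="NA")
    return out
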