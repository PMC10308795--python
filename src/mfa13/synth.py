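"""Synthetic datasets with the statistical structure the pipeline assumes.

A :class:`ScenarioSpec` fixes a ground-truth flux map, a tracer mixture, the
batch physiology (mu, inoculum biomass, q-rates implied by the exchange
fluxes) and the noise model; from it the generators emit (a) OD/concentration
time series under exponential batch growth with multiplicative log-normal
noise, and (b) raw isotopologue tables produced by forward label simulation,
convolved with natural abundance, diluted by the unlabelled-inoculum
fraction, and perturbed by Gaussian MS noise.  All randomness flows from one
seed through per-product spawned substreams, so datasets are reproducible
bit-for-bit.

Default conditions: mu = 0.22 h^-1 and glycerol uptake 3.37 mmol gCDW^-1 h^-1
(a fast-growing reference culture), inoculation at OD600 0.025 with a
27-hour sampling schedule (2-hourly early, hourly through the exponential
phase), 2.5 g/L initial glycerol, OD CV 3 %, concentration CV 5 %, MID SD
0.01 — plausible Orbitrap/NMR precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .correction import FragmentFormula, build_correction_matrix
from .emu import TracerMixture, simulate_mids
from .model import FluxVector, ModelError, NetworkModel, steady_state_residual
from .physiology import DEFAULT_OD_TO_CDW, TimeSeries

__all__ = [
    "ScenarioSpec",
    "default_schedule",
    "generate_timeseries",
    "generate_labelling_dataset",
    "generate_strain_panel",
    "DEFAULT_MIXTURE",
]

DEFAULT_MIXTURE = {"GLYC": [((1,), 0.2), ((2,), 0.8)]}  # 20 % 1-13C + 80 % 2-13C glycerol
GLYCEROL_MM = 92.09  # g/mol
GLYCEROL_G_PER_L = 2.5


def default_schedule() -> np.ndarray:
    """OD600 every 2 h to 16 h, hourly 16-24 h, final sample at 27 h."""
    return np.array(sorted(set(range(0, 17, 2)) | set(range(16, 25)) | {27.0}), dtype=float)


@dataclass
class ScenarioSpec:
    model: NetworkModel
    truth: FluxVector
    mixture: TracerMixture = field(
        default_factory=lambda: TracerMixture({k: list(v) for k, v in DEFAULT_MIXTURE.items()})
    )
    mu: float = 0.22  # h^-1
    od0: float = 0.025  # inoculation OD600
    conversion_factor: float = DEFAULT_OD_TO_CDW
    substrate: str = "glycerol"
    substrate_rxn: str = "upt"
    substrate_m0: float = GLYCEROL_G_PER_L / GLYCEROL_MM * 1000.0  # mM
    product_rxns: dict[str, str] = field(
        default_factory=lambda: {"acetate": "ace_out", "pyruvate": "pyr_out"}
    )
    od_cv: float = 0.03
    conc_cv: float = 0.05
    mid_sd: float = 0.01
    inoculum_fraction: float = 0.025
    schedule: np.ndarray = field(default_factory=default_schedule)
    seed: int = 0
    noise_mode: str = "realistic"  # or "gaussian" (no truncation/renormalization)

    def __post_init__(self):
        if min(self.od_cv, self.conc_cv, self.mid_sd) < 0:
            raise ModelError("noise parameters must be >= 0")
        if steady_state_residual(self.model, self.truth) > 1e-6:
            raise ModelError("ground-truth fluxes violate steady state")
        if self.mu <= 0:
            raise ModelError("mu must be positive")

    @property
    def x0(self) -> float:  # gCDW/L
        return self.od0 * self.conversion_factor

    def qrates(self) -> dict[str, float]:
        """q-rates (mmol gCDW^-1 h^-1) implied by the ground-truth fluxes."""
        q = {self.substrate: -abs(self.truth[self.substrate_rxn])}
        for name, rxn in self.product_rxns.items():
            q[name] = self.truth[rxn]
        return q

    def _rngs(self, *labels: str) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(labels))
        return {lab: np.random.default_rng(ss) for lab, ss in zip(labels, children)}


def _lognormal_noise(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values.copy()
    sigma = np.sqrt(np.log1p(cv * cv))
    return values * rng.lognormal(-0.5 * sigma * sigma, sigma, size=values.shape)


def generate_timeseries(spec: ScenarioSpec) -> TimeSeries:
    """Exponential batch trajectories with multiplicative noise.

    The schedule is clipped where the substrate would be exhausted (batch
    growth stops there; later samples would not obey the exponential model).
    """
    rng = spec._rngs("timeseries")["timeseries"]
    t = np.asarray(spec.schedule, dtype=float)
    q = spec.qrates()
    growth = (spec.x0 / spec.mu) * (np.exp(spec.mu * t) - 1.0)
    substrate = spec.substrate_m0 + q[spec.substrate] * growth
    keep = substrate >= 0.05 * spec.substrate_m0
    t = t[keep]
    if len(t) < 4:
        raise ModelError("schedule too short after substrate-exhaustion clipping")
    growth = growth[keep]
    od = (spec.x0 / spec.conversion_factor) * np.exp(spec.mu * t)
    conc = {spec.substrate: spec.substrate_m0 + q[spec.substrate] * growth}
    for name in spec.product_rxns:
        conc[name] = q[name] * growth
    return TimeSeries(
        time=t,
        biomass=_lognormal_noise(od, spec.od_cv, rng),
        concentrations={k: _lognormal_noise(v, spec.conc_cv, rng) for k, v in conc.items()},
        biomass_unit="od600",
    )


def _formula_map(model: NetworkModel) -> dict[str, FragmentFormula]:
    out = {}
    for sp, formula in model.measured_species:
        if formula is None:
            n = model.metabolites[sp].carbon_count
            formula = f"C{n}"
        out[sp] = FragmentFormula.parse(formula)
    return out


def generate_labelling_dataset(
    spec: ScenarioSpec, natural_abundance: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Raw isotopologue table + ground-truth sidecar for one scenario.

    Pipeline: tracer-only MIDs at the ground-truth fluxes -> forward natural-
    abundance convolution (correction matrix columns) -> mixing with the
    unlabelled-inoculum MID -> Gaussian MS noise (truncated at 0 and
    renormalized in "realistic" mode, raw in "gaussian" mode).
    """
    rng = spec._rngs("mids")["mids"]
    sim = simulate_mids(spec.model, spec.truth, spec.mixture)
    formulas = _formula_map(spec.model)
    rows = []
    truth_mids = {}
    for emu, mid in sim.items():
        sp = emu.species
        C = (
            build_correction_matrix(formulas[sp])
            if natural_abundance
            else np.eye(len(mid))
        )
        observed = C @ mid
        unlabelled = C[:, 0]
        raw = (1.0 - spec.inoculum_fraction) * observed + spec.inoculum_fraction * unlabelled
        if spec.mid_sd > 0:
            raw = raw + rng.normal(0.0, spec.mid_sd, size=raw.shape)
            if spec.noise_mode == "realistic":
                raw = np.clip(raw, 0.0, None)
                raw = raw / raw.sum()
        truth_mids[sp] = mid.tolist()
        for i, val in enumerate(raw):
            rows.append(
                {"species": sp, "mass_shift": i, "intensity": float(val), "sd": spec.mid_sd}
            )
    sidecar = {
        "seed": spec.seed,
        "fluxes": spec.truth.as_dict(),
        "xch": dict(spec.truth.xch),
        "tracer_mids": truth_mids,
        "mixture": {
            sp: [[list(p), f] for p, f in comps] for sp, comps in spec.mixture.fractions.items()
        },
        "inoculum_fraction": spec.inoculum_fraction,
        "qrates": spec.qrates(),
        "mu": spec.mu,
    }
    return pd.DataFrame(rows), sidecar


def project_to_steady_state(
    model: NetworkModel, target: dict[str, float], base: FluxVector
) -> FluxVector:
    """Closest (L1) steady-state vector to ``base`` with the listed fluxes
    fixed, keeping irreversible fluxes non-negative.

    Solved as an LP over (v, t) with |v - base| <= t; raises naming the edit
    when no feasible vector exists.
    """
    from scipy.optimize import linprog
    from .model import stoichiometric_matrix

    S, _, rids = stoichiometric_matrix(model)
    nr = len(rids)
    # variables: [v (nr), t (nr)]
    c = np.concatenate([np.zeros(nr), np.ones(nr)])
    A_eq_rows = [np.hstack([S, np.zeros_like(S)])]
    b_eq = [np.zeros(S.shape[0])]
    for rxn, val in target.items():
        row = np.zeros(2 * nr)
        row[rids.index(rxn)] = 1.0
        A_eq_rows.append(row.reshape(1, -1))
        b_eq.append(np.array([float(val)]))
    A_ub = np.vstack([
        np.hstack([np.eye(nr), -np.eye(nr)]),   # v - t <= base
        np.hstack([-np.eye(nr), -np.eye(nr)]),  # -v - t <= -base
    ])
    b_ub = np.concatenate([base.net, -base.net])
    bounds = [
        ((None, None) if r.reversible else (0.0, None)) for r in model.reactions
    ] + [(0.0, None)] * nr
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=np.vstack(A_eq_rows),
                  b_eq=np.concatenate(b_eq), bounds=bounds, method="highs")
    if res.status != 0:
        raise ModelError(f"perturbation {target} breaks feasibility (LP status {res.status})")
    v = res.x[:nr]
    return FluxVector(tuple(rids), v, dict(base.xch))


def generate_strain_panel(
    base: ScenarioSpec, perturbations: dict[str, dict[str, float]]
) -> tuple[dict[str, ScenarioSpec], pd.DataFrame]:
    """One scenario per strain from named multiplicative flux edits.

    ``perturbations`` maps strain -> {reaction: factor}; factors scale the
    base ground truth and the edited vector is re-projected to steady state.
    Returns the panel (reference strain included under "reference") and the
    ground-truth log2 fold-change table of relative (per-unit-uptake) fluxes.
    """
    panel = {"reference": base}
    for k, (strain, edits) in enumerate(perturbations.items()):
        target = {rxn: base.truth[rxn] * factor for rxn, factor in edits.items()}
        # substrate uptake stays at the base value unless explicitly edited,
        # so relative (per-uptake) fold-changes equal the nominal edits
        target.setdefault(base.substrate_rxn, base.truth[base.substrate_rxn])
        truth = project_to_steady_state(base.model, target, base.truth)
        panel[strain] = replace(base, truth=truth, seed=base.seed + 1000 * (k + 1))

    rids = base.model.reaction_ids
    ref_rel = base.truth.normalized(base.substrate_rxn)
    fc = {}
    for strain, sc in panel.items():
        rel = sc.truth.normalized(sc.substrate_rxn)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc[strain] = np.where(
                (ref_rel > 0) & (rel > 0), np.log2(rel / ref_rel), np.nan
            )
        fc[strain][np.isclose(rel, ref_rel)] = 0.0
    return panel, pd.DataFrame(fc, index=rids)
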