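"""In silico ranking of tracer mixtures by the flux precision they buy.

For each candidate mixture the measurements are simulated at a reference
flux map and the linearized flux covariance is computed as the pseudo-inverse
of the Fisher information J^T W J over the free fluxes, propagated to every
net flux (normalized per unit uptake).  Directions the measurements cannot
see yield infinite SDs, not errors.  Mixtures are ranked in two stages:
first by the number of fluxes determined with SD below a threshold (and,
within that, the smallest summed SD of those fluxes); the top tier is then
re-ranked by the summed SD over designated pathway sets (e.g. upper
glycolysis + pentose phosphate pathway).  A Monte-Carlo refit scorer is
available to verify the linearization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .emu import EMU, TracerMixture, simulate_mids
from .fitting import FitOptions, Measurements, _Objective, free_flux_parameterization, monte_carlo, fit_fluxes
from .model import FluxVector, ModelError, NetworkModel

__all__ = ["DesignScore", "mixture_grid", "score_mixture", "rank_mixtures", "mc_score_mixture"]

GLYCEROL_TRACERS: dict[str, tuple[int, ...]] = {
    "1-13C": (1,),
    "2-13C": (2,),
    "1,3-13C": (1, 3),
    "U-13C": (1, 2, 3),
}


@dataclass
class DesignScore:
    mixture: TracerMixture
    flux_sd: dict[str, float]
    n_precise: int
    sum_sd: float
    pathway_sds: dict[str, float] = field(default_factory=dict)

    def mixture_key(self) -> tuple:
        """Deterministic lexicographic key of the mixture composition."""
        items = []
        for sp in sorted(self.mixture.fractions):
            for pattern, frac in sorted(self.mixture.fractions[sp]):
                items.append((sp, pattern, round(frac, 12)))
        return tuple(items)


def mixture_grid(
    species: str,
    tracers: dict[str, tuple[int, ...]] | None = None,
    step: float = 0.1,
    include_unlabelled: bool = False,
    purity: float = 1.0,
) -> list[TracerMixture]:
    """All tracer-fraction vectors on the step lattice summing to 1.

    With t tracers and k = 1/step this enumerates C(k + t - 1, t - 1)
    compositions (stars and bars); ``include_unlabelled`` adds an unlabelled
    component as one more slot.
    """
    if step <= 0:
        raise ModelError("step must be positive")
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9:
        raise ModelError(f"step {step} does not divide 1 evenly")
    tracers = tracers if tracers is not None else dict(GLYCEROL_TRACERS)
    patterns = list(tracers.values()) + ([()] if include_unlabelled else [])
    t = len(patterns)
    out = []
    for cuts in combinations(range(k + t - 1), t - 1):
        counts = []
        prev = -1
        for c in list(cuts) + [k + t - 1]:
            counts.append(c - prev - 1)
            prev = c
        comps = [
            (patterns[i], counts[i] * step) for i in range(t) if counts[i] > 0
        ]
        out.append(TracerMixture({species: comps}, purity=purity))
    return out


@dataclass
class MeasurementSpec:
    """What the instrument would see and how precisely."""

    mid_sd: float = 0.01
    rate_cv: float = 0.05
    rate_floor: float = 0.01


def _simulated_measurements(
    model: NetworkModel, ref: FluxVector, mixture: TracerMixture, spec: MeasurementSpec
) -> Measurements:
    targets = [
        EMU(sp, tuple(range(1, model.metabolites[sp].carbon_count + 1)))
        for sp, _ in model.measured_species
    ]
    sim = simulate_mids(model, ref, mixture, targets)
    mids = {t.species: (sim[t], np.full(len(sim[t]), spec.mid_sd)) for t in targets}
    rates = {
        r: (ref[r], max(spec.rate_cv * abs(ref[r]), spec.rate_floor))
        for r in model.measured_rates
    }
    return Measurements(mids, rates, mixture)


def score_mixture(
    model: NetworkModel,
    ref_fluxes: FluxVector,
    mixture: TracerMixture,
    spec: MeasurementSpec | None = None,
    sd_threshold: float = 1.0,
    pathway_sets: dict[str, list[str]] | None = None,
    uptake_id: str | None = None,
    sv_tol: float = 1e-9,
) -> DesignScore:
    """Linearized per-flux SDs (per unit uptake) for one candidate mixture."""
    spec = spec or MeasurementSpec()
    uptake_id = uptake_id or (model.measured_rates[0] if model.measured_rates else None)
    if uptake_id is None:
        raise ModelError("need an uptake reaction to normalize the SD threshold")
    meas = _simulated_measurements(model, ref_fluxes, mixture, spec)
    basis = free_flux_parameterization(model)
    obj = _Objective(model, basis, meas, FitOptions())
    theta0 = np.concatenate(
        [basis.project(ref_fluxes.net), [ref_fluxes.xch.get(n, 0.0) for n in obj.xch_names]]
    )
    # central-difference Jacobian of the weighted residuals at the reference
    J = np.empty((obj.n_meas, obj.n_params))
    h = 1e-6 * max(1.0, abs(ref_fluxes[uptake_id]))
    for k in range(obj.n_params):
        tp, tm = theta0.copy(), theta0.copy()
        tp[k] += h
        tm[k] = max(tm[k] - h, 0.0) if k >= basis.dim else tm[k] - h
        J[:, k] = (obj(tp)[: obj.n_meas] - obj(tm)[: obj.n_meas]) / (tp[k] - tm[k])

    F = J.T @ J
    lam, Q = np.linalg.eigh(F)
    lmax = max(lam.max(), 1e-300)
    u = abs(ref_fluxes[uptake_id])
    flux_sd: dict[str, float] = {}
    for i, rid in enumerate(basis.reaction_ids):
        row = np.concatenate([basis.N[i, :], np.zeros(len(obj.xch_names))]) / u
        nr = np.linalg.norm(row)
        coeff = Q.T @ row
        weak = lam < sv_tol * lmax
        if nr > 0 and np.any(weak & (np.abs(coeff) > 1e-4 * nr)):
            flux_sd[rid] = np.inf
        else:
            var = float(np.sum(coeff[~weak] ** 2 / lam[~weak]))
            flux_sd[rid] = float(np.sqrt(var))

    precise = {r: s for r, s in flux_sd.items() if s < sd_threshold}
    pathway_sds = {
        name: float(sum(flux_sd[r] for r in rxns if r in flux_sd))
        for name, rxns in (pathway_sets or {}).items()
    }
    return DesignScore(mixture, flux_sd, len(precise), float(sum(precise.values())), pathway_sds)


def mc_score_mixture(
    model: NetworkModel,
    ref_fluxes: FluxVector,
    mixture: TracerMixture,
    spec: MeasurementSpec | None = None,
    n: int = 200,
    seed: int = 0,
    uptake_id: str | None = None,
) -> dict[str, float]:
    """Monte-Carlo verification scorer: per-flux SDs from n noisy refits."""
    spec = spec or MeasurementSpec()
    uptake_id = uptake_id or model.measured_rates[0]
    meas = _simulated_measurements(model, ref_fluxes, mixture, spec)
    fit = fit_fluxes(model, meas, FitOptions(n_starts=3, seed=seed))
    fit = monte_carlo(model, fit, meas, n=n, seed=seed + 1)
    u = abs(ref_fluxes[uptake_id])
    return dict(zip(fit.fluxes.reaction_ids, fit.flux_sd / u))


def rank_mixtures(scores: list[DesignScore], pathway_key: str | None = None) -> list[DesignScore]:
    """Two-stage deterministic ranking of candidate mixtures.

    Stage 1 orders by (n_precise desc, sum_sd asc); stage 2 re-ranks the top
    tier (all mixtures attaining the maximal n_precise) by the summed SD of
    the ``pathway_key`` set.  Ties break on the lexicographic mixture key, so
    the result is invariant to input order.
    """
    if not scores:
        raise ModelError("no scores to rank")
    best_n = max(s.n_precise for s in scores)
    top = [s for s in scores if s.n_precise == best_n]
    rest = [s for s in scores if s.n_precise < best_n]

    def path_sd(s: DesignScore) -> float:
        if pathway_key and pathway_key in s.pathway_sds:
            return s.pathway_sds[pathway_key]
        return s.sum_sd

    top.sort(key=lambda s: (path_sd(s), s.sum_sd, s.mixture_key()))
    rest.sort(key=lambda s: (-s.n_precise, s.sum_sd, s.mixture_key()))
    return top + rest
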