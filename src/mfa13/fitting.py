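"""Flux estimation from corrected MIDs and extracellular rates.

The steady-state constraint S v = 0 (plus any fixed fluxes) is eliminated by
a null-space parameterization, so every candidate during optimization is a
balanced flux map by construction.  The weighted nonlinear least squares

    SSR = sum(((sim - meas) / sd)^2)

over isotopologue fractions and rates is minimized by multi-start
trust-region least squares (Latin-hypercube-free: starts are random feasible
flux vectors from LP sampling).  Goodness of fit is a chi-square test at the
95 % level with dof = (independent measurements) - rank(Jacobian); the rank
accounts for structurally non-identifiable directions (e.g. futile cycles no
measurement can see), which are also reported per flux.  Uncertainty comes
from Monte-Carlo refits on data perturbed at the measurement SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import least_squares
from scipy.stats import chi2

from .emu import EMU, TracerMixture, simulate_mids
from .model import (
    FluxVector,
    ModelError,
    NetworkModel,
    sample_feasible_fluxes,
    stoichiometric_matrix,
)

__all__ = [
    "FreeFluxBasis",
    "Measurements",
    "FitOptions",
    "FitResult",
    "free_flux_parameterization",
    "fit_fluxes",
    "monte_carlo",
    "normalize_and_compare",
    "average_replicates",
]

MID_SD_FLOOR = 0.01  # mass-fraction floor preventing chi-square blow-up


@dataclass
class FreeFluxBasis:
    """Affine map theta -> v with S v = 0 and constrained fluxes honoured."""

    reaction_ids: tuple[str, ...]
    v_particular: np.ndarray
    N: np.ndarray  # (n_reactions, dim), orthonormal columns

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def map(self, theta: np.ndarray) -> np.ndarray:
        return self.v_particular + self.N @ np.asarray(theta, dtype=float)

    def project(self, v: np.ndarray) -> np.ndarray:
        return self.N.T @ (np.asarray(v, dtype=float) - self.v_particular)


def free_flux_parameterization(
    model: NetworkModel, extra_constraints: dict[str, float] | None = None
) -> FreeFluxBasis:
    """Null-space basis of the steady-state + equality constraint system."""
    S, _, rids = stoichiometric_matrix(model)
    rows = [S] if S.size else []
    rhs = [np.zeros(S.shape[0])] if S.size else []
    fixed = dict(model.constrained_fluxes)
    fixed.update(extra_constraints or {})
    for rxn, val in fixed.items():
        row = np.zeros(len(rids))
        row[rids.index(rxn)] = 1.0
        rows.append(row.reshape(1, -1))
        rhs.append(np.array([float(val)]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    v_p, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.max(np.abs(A @ v_p - b)) > 1e-8:
        raise ModelError("inconsistent equality constraints")
    N = null_space(A)
    if N.shape[1] == 0:
        raise ModelError("over-constrained model: steady-state null space is empty")
    return FreeFluxBasis(tuple(rids), v_p, N)


@dataclass
class Measurements:
    """Corrected (tracer-space) MIDs and extracellular rates with SDs.

    ``resampler``, when set, produces a freshly re-noised Measurements for
    Monte-Carlo replicates (e.g. perturbing *raw* isotopologue vectors and
    re-running the natural-abundance correction, which preserves the error
    correlations the correction inverse introduces); otherwise entries are
    perturbed independently at their SDs.
    """

    mids: dict[str, tuple[np.ndarray, np.ndarray]]  # species -> (values, sd)
    rates: dict[str, tuple[float, float]]  # reaction -> (value, sd)
    mixture: TracerMixture | None = None
    resampler: object = None  # Callable[[np.random.Generator], Measurements]

    def n_rows(self) -> int:
        return sum(len(v) for v, _ in self.mids.values()) + len(self.rates)

    def perturbed(self, rng: np.random.Generator) -> "Measurements":
        if self.resampler is not None:
            return self.resampler(rng)
        mids = {
            sp: (v + rng.normal(0, s), s.copy()) for sp, (v, s) in self.mids.items()
        }
        rates = {r: (v + rng.normal(0, s), s) for r, (v, s) in self.rates.items()}
        return Measurements(mids, rates, self.mixture)


@dataclass
class FitOptions:
    n_starts: int = 10
    seed: int = 0
    sd_floor: float = MID_SD_FLOOR
    xch_max: float = 0.95
    penalty_weight: float = 1e3
    # tiny ridge on the free-flux coordinates: gives flat (non-identifiable)
    # directions a deterministic minimum without biasing measured fluxes
    # (contributes ~(1e-3 v/u)^2 to the optimizer objective, excluded from SSR)
    reg_weight: float = 1e-3
    ftol: float = 1e-10
    identifiability_tol: float = 1e-7


@dataclass
class FitResult:
    fluxes: FluxVector
    ssr: float
    dof: int
    chi2_pass: bool
    chi2_critical: float
    theta: np.ndarray
    basis: FreeFluxBasis
    xch_names: tuple[str, ...]
    residuals: pd.DataFrame
    jac_rank: int
    non_identifiable: list[str]
    start_diagnostics: list[dict] = field(default_factory=list)
    mc_samples: np.ndarray | None = None  # (n_kept, n_reactions) net fluxes
    flux_sd: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    mc_failed: int = 0

    def flux_table(self, uptake_id: str | None = None) -> pd.DataFrame:
        rids = self.fluxes.reaction_ids
        df = pd.DataFrame({"reaction": rids, "net": self.fluxes.net})
        if uptake_id:
            df["relative"] = self.fluxes.normalized(uptake_id)
        if self.flux_sd is not None:
            df["sd"] = self.flux_sd
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        df["identifiable"] = [r not in self.non_identifiable for r in rids]
        return df.set_index("reaction")


class _Objective:
    def __init__(self, model, basis, meas, options):
        self.model = model
        self.basis = basis
        self.meas = meas
        self.opt = options
        self.rids = list(basis.reaction_ids)
        self.xch_names = tuple(r.id for r in model.reactions if r.reversible)
        self.irrev_idx = [i for i, r in enumerate(model.reactions) if not r.reversible]
        self.targets = [
            EMU(sp, tuple(range(1, model.metabolites[sp].carbon_count + 1)))
            for sp in meas.mids
        ]
        self.rate_idx = {r: self.rids.index(r) for r in meas.rates}
        self.sds = {
            sp: np.maximum(sd, options.sd_floor) for sp, (_, sd) in meas.mids.items()
        }
        self.n_meas = meas.n_rows()
        self.scale = max((abs(v) for v, _ in meas.rates.values()), default=1.0) or 1.0

    @property
    def n_params(self) -> int:
        return self.basis.dim + len(self.xch_names)

    def split(self, theta):
        d = self.basis.dim
        return np.asarray(theta[:d]), {
            name: float(theta[d + i]) for i, name in enumerate(self.xch_names)
        }

    def flux_vector(self, theta) -> FluxVector:
        th_net, xch = self.split(theta)
        return FluxVector(tuple(self.rids), self.basis.map(th_net), xch)

    def __call__(self, theta) -> np.ndarray:
        fv = self.flux_vector(theta)
        d = self.basis.dim
        out = np.empty(self.n_meas + len(self.irrev_idx) + d)
        out[self.n_meas + len(self.irrev_idx) :] = (
            self.opt.reg_weight * np.asarray(theta[:d]) / self.scale
        )
        try:
            sim = simulate_mids(self.model, fv, self.meas.mixture, self.targets,
                                ss_tol=1e-5, strict=False)
        except (ModelError, np.linalg.LinAlgError):
            out[:] = 1e6
            return out
        k = 0
        for t in self.targets:
            v, _ = self.meas.mids[t.species]
            sd = self.sds[t.species]
            m = len(v)
            out[k : k + m] = (sim[t] - v) / sd
            k += m
        for r, (val, sd) in self.meas.rates.items():
            out[k] = (fv.net[self.rate_idx[r]] - val) / max(sd, 1e-9)
            k += 1
        # smooth one-sided penalty keeping irreversible nets non-negative
        pen = np.minimum(fv.net[self.irrev_idx], 0.0)
        out[self.n_meas : self.n_meas + len(self.irrev_idx)] = self.opt.penalty_weight * pen
        return out

    def residual_table(self, theta) -> pd.DataFrame:
        fv = self.flux_vector(theta)
        sim = simulate_mids(self.model, fv, self.meas.mixture, self.targets,
                            ss_tol=1e-5, strict=False)
        rows = []
        for t in self.targets:
            v, _ = self.meas.mids[t.species]
            sd = self.sds[t.species]
            for i in range(len(v)):
                rows.append(
                    dict(kind="mid", name=f"{t.species} M{i}", measured=v[i],
                         simulated=sim[t][i], sd=sd[i],
                         weighted_residual=(sim[t][i] - v[i]) / sd[i])
                )
        for r, (val, sd) in self.meas.rates.items():
            s = fv.net[self.rate_idx[r]]
            rows.append(dict(kind="rate", name=r, measured=val, simulated=s, sd=sd,
                             weighted_residual=(s - val) / max(sd, 1e-9)))
        return pd.DataFrame(rows)


def _starts(model, basis, meas, options, rng) -> list[np.ndarray]:
    uptake = None
    for r, (val, _) in meas.rates.items():
        uptake = (r, val)
        break
    try:
        samples = sample_feasible_fluxes(
            model, options.n_starts, rng, uptake=uptake,
            scale=10 * max(abs(v) for v, _ in meas.rates.values()) if meas.rates else 10.0,
        )
    except ModelError:
        samples = []
    starts = []
    for s in samples:
        th = basis.project(s.net)
        xch0 = rng.uniform(0.05, 0.7, size=len([r for r in model.reactions if r.reversible]))
        starts.append(np.concatenate([th, xch0]))
    if not starts:
        starts = [rng.normal(size=basis.dim + sum(r.reversible for r in model.reactions))]
    return starts


def fit_fluxes(
    model: NetworkModel,
    measurements: Measurements,
    options: FitOptions | None = None,
) -> FitResult:
    """Weighted least-squares flux fit with multi-start local optimization.

    ``measurements.mixture`` must carry the tracer composition used in the
    experiment.  Raises if no start converges or if dof <= 0.
    """
    options = options or FitOptions()
    if measurements.mixture is None:
        raise ModelError("measurements must carry the tracer mixture")
    basis = free_flux_parameterization(model)
    obj = _Objective(model, basis, measurements, options)
    rng = np.random.default_rng(options.seed)

    lo = np.concatenate([np.full(basis.dim, -np.inf), np.zeros(len(obj.xch_names))])
    hi = np.concatenate([np.full(basis.dim, np.inf), np.full(len(obj.xch_names), options.xch_max)])

    best = None
    diagnostics = []
    for i, x0 in enumerate(_starts(model, basis, measurements, options, rng)):
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(obj, x0, bounds=(lo, hi), method="trf", ftol=options.ftol,
                                xtol=1e-10, max_nfev=150 * obj.n_params)
        except Exception as exc:  # pragma: no cover - diagnostic path
            diagnostics.append({"start": i, "status": "error", "message": str(exc)})
            continue
        ssr = float(np.sum(res.fun[: obj.n_meas] ** 2))
        diagnostics.append({"start": i, "status": int(res.status), "ssr": ssr})
        if not np.isfinite(ssr) or ssr >= 1e11:
            continue
        key = (round(ssr, 6), float(np.linalg.norm(obj.flux_vector(res.x).net)))
        if best is None or key < best[0]:
            best = (key, res, ssr)
    if best is None:
        raise ModelError(f"no converged start; diagnostics: {diagnostics}")

    _, res, ssr = best
    J = res.jac[: obj.n_meas]
    sv = np.linalg.svd(J, compute_uv=False)
    rank = int(np.sum(sv > max(sv) * options.identifiability_tol)) if sv.size else 0
    dof = obj.n_meas - rank
    if dof <= 0:
        raise ModelError(f"non-positive degrees of freedom ({obj.n_meas} meas, rank {rank})")
    crit = float(chi2.ppf(0.95, dof))

    non_ident = _structural_non_identifiable(obj, J, options)

    return FitResult(
        fluxes=obj.flux_vector(res.x),
        ssr=ssr,
        dof=dof,
        chi2_pass=ssr <= crit,
        chi2_critical=crit,
        theta=res.x,
        basis=basis,
        xch_names=obj.xch_names,
        residuals=obj.residual_table(res.x),
        jac_rank=rank,
        non_identifiable=non_ident,
        start_diagnostics=diagnostics,
    )


def _structural_non_identifiable(obj: _Objective, J: np.ndarray, options: FitOptions) -> list[str]:
    """Fluxes with a component along the Jacobian's null directions."""
    U, sv, Vt = np.linalg.svd(J, full_matrices=True)
    null_mask = np.ones(Vt.shape[0], dtype=bool)
    null_mask[: len(sv)] = sv <= max(sv, default=0) * options.identifiability_tol
    V0 = Vt[null_mask].T  # (n_params, n_null)
    out = []
    if V0.shape[1] == 0:
        return out
    d = obj.basis.dim
    for i, rid in enumerate(obj.rids):
        row = np.concatenate([obj.basis.N[i, :], np.zeros(len(obj.xch_names))])
        nr = np.linalg.norm(row)
        if nr > 0 and np.linalg.norm(row @ V0) > 1e-6 * nr:
            out.append(rid)
    for k, name in enumerate(obj.xch_names):
        e = np.zeros(obj.n_params)
        e[d + k] = 1.0
        if np.linalg.norm(e @ V0) > 1e-6:
            out.append(f"{name}.xch")
    return out


def monte_carlo(
    model: NetworkModel,
    fit: FitResult,
    measurements: Measurements,
    n: int = 100,
    seed: int = 0,
    ci_width_factor: float = 10.0,
) -> FitResult:
    """Monte-Carlo uncertainty: n refits on data perturbed at measurement SDs.

    Refits are warm-started at the point estimate.  Per-flux SD and
    percentile CIs [2.5 %, 97.5 %] are stored on the returned FitResult;
    fluxes whose CI width exceeds ``ci_width_factor`` x the median width or
    whose MC SD exceeds 5x the point estimate are added to the
    non-identifiable list (on top of the structural flags).
    """
    rng = np.random.default_rng(seed)
    options = FitOptions(seed=seed)
    basis = fit.basis
    lo = np.concatenate([np.full(basis.dim, -np.inf), np.zeros(len(fit.xch_names))])
    hi = np.concatenate([np.full(basis.dim, np.inf), np.full(len(fit.xch_names), options.xch_max)])

    # pool of alternative starts: warm starts alone never hop between local
    # basins, which under-disperses the MC sample for weakly identified fluxes
    start_pool = _starts(model, basis, measurements, FitOptions(n_starts=6, seed=seed), rng)

    def _refit(obj, x0):
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        res = least_squares(obj, x0, bounds=(lo, hi), method="trf", ftol=1e-9,
                            xtol=1e-9, max_nfev=80 * obj.n_params)
        ssr = float(np.sum(res.fun[: obj.n_meas] ** 2))
        return ssr, res

    samples, failed = [], 0
    for k in range(n):
        pm = measurements.perturbed(rng)
        obj = _Objective(model, basis, pm, options)
        try:
            best = _refit(obj, fit.theta)
            alt = _refit(obj, start_pool[k % len(start_pool)])
            ssr, res = min(best, alt, key=lambda t: t[0])
            if not np.isfinite(ssr) or ssr >= 1e11:
                raise ModelError("diverged")
            samples.append(obj.flux_vector(res.x).net)
        except Exception:
            failed += 1
    if failed > 0.2 * n:
        warnings.warn(f"{failed}/{n} Monte-Carlo replicates did not converge; excluded",
                      stacklevel=2)
    if not samples:
        raise ModelError("all Monte-Carlo replicates failed")
    M = np.array(samples)
    fit.mc_samples = M
    fit.flux_sd = M.std(axis=0, ddof=1) if len(M) > 1 else np.zeros(M.shape[1])
    fit.ci_low = np.percentile(M, 2.5, axis=0)
    fit.ci_high = np.percentile(M, 97.5, axis=0)
    fit.mc_failed = failed

    widths = fit.ci_high - fit.ci_low
    med = np.median(widths[widths > 0]) if np.any(widths > 0) else 0.0
    flagged = set(fit.non_identifiable)
    for i, rid in enumerate(fit.fluxes.reaction_ids):
        wide = med > 0 and widths[i] > ci_width_factor * med
        sd_blown = fit.flux_sd[i] > 5.0 * max(abs(fit.fluxes.net[i]), 1e-12)
        if wide or sd_blown:
            flagged.add(rid)
    fit.non_identifiable = sorted(flagged)
    return fit


def normalize_and_compare(
    fits: dict[str, FitResult],
    reference: str,
    uptake_id: str,
    special_baseline: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit-uptake fluxes and log2 fold-changes against a reference strain.

    ``special_baseline`` maps a reaction to an alternative baseline strain
    (e.g. a heterologous reaction absent from the wild type, compared to the
    first producer strain instead).  Zero-reference fold-changes are NaN,
    never +/-inf.
    """
    if reference not in fits:
        raise ModelError(f"reference strain {reference!r} missing from panel")
    rids = fits[reference].fluxes.reaction_ids
    rel = pd.DataFrame(
        {strain: f.fluxes.normalized(uptake_id) for strain, f in fits.items()}, index=rids
    )
    special_baseline = special_baseline or {}
    fc = pd.DataFrame(index=rids, columns=list(fits), dtype=float)
    for rxn in rids:
        base_strain = special_baseline.get(rxn, reference)
        denom = rel.loc[rxn, base_strain]
        for strain in fits:
            num = rel.loc[rxn, strain]
            if denom == 0 or num <= 0 or denom < 0:
                fc.loc[rxn, strain] = np.nan if not (num == denom) else 0.0
            else:
                fc.loc[rxn, strain] = np.log2(num / denom)
    return rel, fc


def average_replicates(fits: list[FitResult]) -> pd.DataFrame:
    """Mean +/- SD of replicate point estimates, dropping chi-square failures."""
    kept = [f for f in fits if f.chi2_pass]
    if not kept:
        raise ModelError("no replicate passed the chi-square test")
    rids = kept[0].fluxes.reaction_ids
    M = np.array([f.fluxes.net for f in kept])
    return pd.DataFrame(
        {
            "mean": M.mean(axis=0),
            "sd": M.std(axis=0, ddof=1) if len(kept) > 1 else np.zeros(M.shape[1]),
            "n_replicates": len(kept),
        },
        index=rids,
    )
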