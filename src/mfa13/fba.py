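"""Flux balance analysis closing the ATP and NADPH books.

The fitted flux map is checked for energy/redox consistency by a linear
program: maximize the non-growth ATP maintenance flux (ATPM) subject to
steady state and to per-flux bounds taken from the Monte-Carlo confidence
intervals (the objective best describing batch growth on excess substrate).
Cofactor balance tables list every reaction touching ATP or NADPH with its
signed rate; production and consumption must cancel for any feasible vector,
not only at the optimum.  The HiGHS solver is deterministic, so optima are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import FluxVector, ModelError, NetworkModel, stoichiometric_matrix

__all__ = [
    "FBAResult",
    "fba_max_atpm",
    "cofactor_balance",
    "pyruvate_partition",
    "flux_variability",
    "maintenance_split",
]

DEFAULT_BOUND = 1000.0


@dataclass
class FBAResult:
    fluxes: FluxVector
    objective: float
    objective_id: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


def _bound_arrays(
    model: NetworkModel, bounds: dict[str, tuple[float, float]] | None
) -> list[tuple[float, float]]:
    out = []
    for r in model.reactions:
        if bounds and r.id in bounds:
            lo, hi = bounds[r.id]
        else:
            lo = -DEFAULT_BOUND if r.reversible else 0.0
            hi = DEFAULT_BOUND
        if lo > hi:
            raise ModelError(f"bounds for {r.id} reversed ({lo} > {hi})")
        out.append((lo, hi))
    return out


def _diagnose_infeasible(model, S, box, rids) -> list[str]:
    """Greedy minimal set of bounds whose relaxation restores feasibility."""
    relaxed = list(box)
    conflict = []
    order = sorted(range(len(box)), key=lambda i: box[i][1] - box[i][0])
    for i in order:
        trial = list(relaxed)
        trial[i] = (-DEFAULT_BOUND if model.reactions[i].reversible else 0.0, DEFAULT_BOUND)
        res = linprog(np.zeros(len(box)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=trial, method="highs")
        if res.status == 0:
            conflict.append(rids[i])
            return conflict
        relaxed = trial
        conflict.append(rids[i])
    return conflict


def fba_max_atpm(
    model: NetworkModel,
    bounds: dict[str, tuple[float, float]] | None = None,
    objective_id: str = "atpm",
) -> FBAResult:
    """LP maximum of the ATP-maintenance flux within the given flux bounds.

    ``bounds`` maps reactions to (lb, ub), typically Monte-Carlo CIs for the
    fitted fluxes; unlisted reactions default to [0, 1000] (irreversible) or
    [-1000, 1000].  Infeasible bound sets raise with a minimal conflicting
    subset; an unbounded objective raises naming the objective.
    """
    rids = list(model.reaction_ids)
    if objective_id not in rids:
        raise ModelError(f"objective reaction {objective_id!r} not in model")
    S, _, _ = stoichiometric_matrix(model)
    box = _bound_arrays(model, bounds)
    c = np.zeros(len(rids))
    c[rids.index(objective_id)] = -1.0  # maximize
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=box, method="highs")
    if res.status == 2:
        conflict = _diagnose_infeasible(model, S, box, rids)
        raise ModelError(f"infeasible flux bounds; conflicting set: {conflict}")
    if res.status == 3:
        raise ModelError(f"objective {objective_id} is unbounded; missing upper bounds")
    if res.status != 0:
        raise ModelError(f"LP failed: {res.message}")
    fv = FluxVector(tuple(rids), res.x)
    return FBAResult(fv, float(-res.fun), objective_id, dict(bounds or {}))


def cofactor_balance(model: NetworkModel, fluxes: FluxVector, cofactor: str) -> pd.DataFrame:
    """Signed rates of every reaction producing or consuming a cofactor.

    Rate = net stoichiometric coefficient x flux; the table carries totals in
    ``df.attrs`` (production, consumption, net) and net must vanish at steady
    state for balanced cofactors.
    """
    if cofactor not in model.metabolites:
        raise ModelError(f"unknown cofactor {cofactor!r}")
    rows = []
    for j, r in enumerate(model.reactions):
        coeff = sum(c for sp, c, _ in r.products if sp == cofactor) - sum(
            c for sp, c, _ in r.substrates if sp == cofactor
        )
        if coeff != 0:
            rate = coeff * fluxes.net[j]
            rows.append({"reaction": r.id, "coefficient": coeff,
                         "flux": fluxes.net[j], "rate": rate})
    df = pd.DataFrame(rows, columns=["reaction", "coefficient", "flux", "rate"])
    production = float(df.loc[df["rate"] > 0, "rate"].sum()) if len(df) else 0.0
    consumption = float(-df.loc[df["rate"] < 0, "rate"].sum()) if len(df) else 0.0
    df.attrs.update(production=production, consumption=consumption,
                    net=production - consumption)
    return df


def pyruvate_partition(fluxes: FluxVector, pdh_id: str, pyk_id: str) -> float:
    """Percentage of the cytosolic pyruvate flux entering the mitochondria:
    100 x v_PDH / v_PYK."""
    v_pyk = fluxes[pyk_id]
    v_pdh = fluxes[pdh_id]
    if v_pyk <= 0:
        raise ModelError(f"zero or negative flux through {pyk_id}; partition undefined")
    if v_pdh < 0:
        raise ModelError(f"negative flux through {pdh_id}")
    return 100.0 * v_pdh / v_pyk


def flux_variability(
    model: NetworkModel,
    bounds: dict[str, tuple[float, float]] | None,
    reactions: list[str],
    objective_id: str | None = None,
    objective_value: float | None = None,
) -> pd.DataFrame:
    """Min/max of selected fluxes, optionally at a fixed objective value
    (degenerate-optimum reporting for the cofactor tables)."""
    rids = list(model.reaction_ids)
    S, _, _ = stoichiometric_matrix(model)
    box = _bound_arrays(model, bounds)
    A_eq, b_eq = S, np.zeros(S.shape[0])
    if objective_id is not None and objective_value is not None:
        row = np.zeros(len(rids))
        row[rids.index(objective_id)] = 1.0
        A_eq = np.vstack([S, row])
        b_eq = np.concatenate([b_eq, [objective_value]])
    rows = []
    for rxn in reactions:
        c = np.zeros(len(rids))
        c[rids.index(rxn)] = 1.0
        out = {}
        for sign, key in ((1.0, "min"), (-1.0, "max")):
            res = linprog(sign * c, A_eq=A_eq, b_eq=b_eq, bounds=box, method="highs")
            out[key] = float(sign * res.fun) if res.status == 0 else np.nan
        rows.append({"reaction": rxn, **out})
    return pd.DataFrame(rows).set_index("reaction")


def maintenance_split(
    model: NetworkModel,
    fluxes: FluxVector,
    biomass_id: str = "bio",
    atpm_id: str = "atpm",
    atp_id: str = "ATP",
) -> dict[str, float]:
    """Growth-associated vs non-growth ATP maintenance.

    GAME = |ATP coefficient of the biomass reaction| x biomass flux;
    NGAME = the ATPM flux itself.
    """
    r = model.reaction(biomass_id)
    coeff = sum(c for sp, c, _ in r.substrates if sp == atp_id) - sum(
        c for sp, c, _ in r.products if sp == atp_id
    )
    return {"GAME": abs(coeff) * fluxes[biomass_id], "NGAME": fluxes[atpm_id]}
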