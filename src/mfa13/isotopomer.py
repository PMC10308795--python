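"""Exact full-isotopomer oracle via the cumomer cascade.

Independent cross-check for the EMU simulator: enumerates every positional
isotopomer of every carbon-bearing species.  The cumomer of a position set S
is the probability that all positions in S are 13C; cumomer balances of
weight w are *linear* given all weights < w (condensation source terms are
products of strictly lighter cumomers), so the full isotopomer balance
system is solved exactly, weight by weight, with no iteration.  Isotopomer
fractions follow by Moebius inversion over the subset lattice and MIDs by
summing per mass.  Cost is O(2^n) per species, so refuse networks whose
largest molecule exceeds 12 carbons.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .emu import EMU, MIDSet, TracerMixture, default_targets, direction_fluxes, directions
from .model import FluxVector, ModelError, NetworkModel, steady_state_residual

__all__ = ["enumerate_isotopomers_oracle"]

MAX_CARBONS = 12


def _input_cumomer(mixture: TracerMixture, species: str, subset: frozenset) -> float:
    comps = mixture.fractions.get(species)
    if comps is None:
        raise ModelError(f"no tracer composition for input species {species}")
    y = 0.0
    for pattern, frac in comps:
        if subset <= set(pattern):
            y += frac * mixture.purity ** len(subset)
    return y


def enumerate_isotopomers_oracle(
    model: NetworkModel,
    fluxes: FluxVector,
    mixture: TracerMixture,
    targets: list[EMU] | None = None,
    ss_tol: float = 1e-6,
) -> MIDSet:
    """MIDs of the targets from the full cumomer/isotopomer balance system."""
    targets = targets if targets is not None else default_targets(model)
    if steady_state_residual(model, fluxes) > ss_tol:
        raise ModelError("flux vector violates steady state")

    too_big = [
        (m, s.carbon_count) for m, s in model.metabolites.items() if s.carbon_count > MAX_CARBONS
    ]
    if too_big:
        raise ModelError(f"network too large for enumeration (> {MAX_CARBONS} carbons): {too_big}")

    dirs = directions(model)
    u = direction_fluxes(model, fluxes)
    inputs = {m for m, s in model.metabolites.items() if s.role == "input"} | set(
        model.label_inputs
    )
    # balanced carbon species that some transition produces
    produced = {psp for d in dirs for psp, _ in d.products}
    species = sorted(
        m
        for m, s in model.metabolites.items()
        if s.carbon_count > 0 and m not in inputs and m in produced
    )
    ncarbon = {m: model.metabolites[m].carbon_count for m in model.metabolites}

    y: dict[tuple[str, frozenset], float] = {}

    def get_y(sp: str, subset: frozenset) -> float:
        if not subset:
            return 1.0
        if sp in inputs:
            return _input_cumomer(mixture, sp, subset)
        return y[(sp, subset)]

    max_w = max(ncarbon[sp] for sp in species) if species else 0
    for w in range(1, max_w + 1):
        variables = [
            (sp, frozenset(c))
            for sp in species
            for c in combinations(range(1, ncarbon[sp] + 1), w)
        ]
        if not variables:
            continue
        idx = {v: i for i, v in enumerate(variables)}
        n = len(variables)
        A = np.zeros((n, n))
        b = np.zeros(n)
        for (sp, subset), i in idx.items():
            for di, d in enumerate(dirs):
                for psp, pletters in d.products:
                    if psp != sp:
                        continue
                    v = u[di]
                    want = [pletters[p - 1] for p in sorted(subset)]
                    groups: dict[int, set[int]] = {}
                    for si, (ssp, sletters) in enumerate(d.substrates):
                        pos = {sletters.index(ch) + 1 for ch in want if ch in sletters}
                        if pos:
                            groups[si] = pos
                    if sum(len(g) for g in groups.values()) != len(want):
                        raise ModelError(f"reaction {d.rxn}: unmapped carbons for {sp}{set(subset)}")
                    A[i, i] += v
                    if v == 0.0:
                        continue
                    gl = sorted(groups.items())
                    if len(gl) == 1:
                        ssp = d.substrates[gl[0][0]][0]
                        key = (ssp, frozenset(gl[0][1]))
                        if ssp not in inputs and key in idx:  # same weight, unknown
                            A[i, idx[key]] -= v
                        else:
                            b[i] += v * get_y(ssp, frozenset(gl[0][1]))
                    else:  # split across molecules: strictly lighter factors, known
                        prod = 1.0
                        for si, pos in gl:
                            prod *= get_y(d.substrates[si][0], frozenset(pos))
                        b[i] += v * prod
            if A[i, i] <= 0.0:
                raise ModelError(f"zero total inflow to {sp} (cumomer weight {w})")
        sol = np.linalg.solve(A, b)
        for var, val in zip(variables, sol):
            y[var] = float(val)

    # cumomers -> isotopomer fractions -> MIDs, per target EMU
    out = MIDSet()
    for t in targets:
        P = list(t.positions)
        mid = np.zeros(len(P) + 1)
        for r in range(len(P) + 1):
            for A_set in combinations(P, r):
                rest = [p for p in P if p not in A_set]
                p_exact = 0.0
                for k in range(len(rest) + 1):
                    for extra in combinations(rest, k):
                        p_exact += (-1) ** k * get_y(t.species, frozenset(A_set) | frozenset(extra))
                mid[r] += p_exact
        if abs(mid.sum() - 1.0) > 1e-8:
            raise ModelError(f"oracle MID of {t} does not normalize (sum {mid.sum()})")
        out[t] = mid
    return out
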