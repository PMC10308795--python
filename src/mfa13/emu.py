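"""Label propagation at isotopic steady state via elementary metabolite units.

An EMU is a subset of a metabolite's carbon atoms.  Mass isotopologue
distributions (MIDs) of EMUs of size s satisfy linear flux balances once all
EMUs of size < s are known; condensation reactions enter as convolutions of
smaller EMUs.  The network is decomposed backwards from the target EMUs,
stratified by size, and each stratum is solved as one dense linear system —
adequate at core-model scale (~10^2 reactions), so no sparse machinery.

Reversible reactions are expanded into two unidirectional fluxes,
``forward = max(net, 0) + xch_abs`` and ``backward = max(-net, 0) + xch_abs``
with the exchange coordinate x in [0, 1) mapped to an absolute exchange flux
x/(1-x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .model import FluxVector, ModelError, NetworkModel, steady_state_residual

__all__ = ["EMU", "TracerMixture", "MIDSet", "decompose_emu", "simulate_mids", "mean_enrichment"]


def binom_pmf(n: int, p: float) -> np.ndarray:
    """Binomial(n, p) pmf over 0..n (closed form; hot path)."""
    if n == 0:
        return np.array([1.0])
    if p == 1.0:
        out = np.zeros(n + 1)
        out[n] = 1.0
        return out
    k = np.arange(n + 1)
    return np.array([comb(n, int(i)) for i in k]) * p**k * (1.0 - p) ** (n - k)


@dataclass(frozen=True)
class EMU:
    species: str
    positions: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(sorted(self.positions)))
        if not self.positions:
            raise ModelError("EMU with empty position set")
        if len(set(self.positions)) != len(self.positions) or min(self.positions) < 1:
            raise ModelError(f"invalid EMU positions {self.positions}")

    @property
    def size(self) -> int:
        return len(self.positions)

    def __repr__(self):
        return f"{self.species}[{','.join(map(str, self.positions))}]"


@dataclass
class TracerMixture:
    """Isotopic composition of the label inputs, in tracer-only space.

    ``fractions`` maps each input species to a list of
    ``(labelled positions, molar fraction)`` components; e.g. 20 % [1-13C] +
    80 % [2-13C] glycerol is ``{"GLYC": [((1,), 0.2), ((2,), 0.8)]}``.
    ``purity`` is the probability that a nominally labelled position is
    actually 13C; unlabelled positions are 12C here (natural abundance is a
    measurement-space effect handled by the correction module).
    """

    fractions: dict[str, list[tuple[tuple[int, ...], float]]]
    purity: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ModelError(f"tracer purity {self.purity} outside (0, 1]")
        for sp, comps in self.fractions.items():
            fr = [f for _, f in comps]
            if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
                raise ModelError(f"tracer fractions for {sp} must be >= 0 and sum to 1")
            self.fractions[sp] = [(tuple(sorted(p)), f) for p, f in comps]
        self._mid_cache: dict = {}

    @classmethod
    def single(cls, species: str, positions: tuple[int, ...], purity: float = 1.0):
        return cls({species: [(tuple(positions), 1.0)]}, purity)

    @classmethod
    def unlabelled(cls, species: str):
        return cls({species: [((), 1.0)]})

    def input_mid(self, emu: EMU) -> np.ndarray:
        """MID of an input-species EMU under this mixture."""
        cached = self._mid_cache.get(emu)
        if cached is not None:
            return cached
        comps = self.fractions.get(emu.species)
        if comps is None:
            raise ModelError(f"no tracer composition for input species {emu.species}")
        out = np.zeros(emu.size + 1)
        for pattern, frac in comps:
            k = len(set(pattern) & set(emu.positions))
            out[: k + 1] += frac * binom_pmf(k, self.purity)
        self._mid_cache[emu] = out
        return out

    def labelled_fraction(self) -> float:
        """Average fraction of 13C over all input carbons (for monotonicity checks)."""
        tot, lab = 0.0, 0.0
        for sp, comps in self.fractions.items():
            n = max((max(p) for p, _ in comps if p), default=1)
            for p, f in comps:
                tot += f * n
                lab += f * len(p) * self.purity
        return lab / tot if tot else 0.0


class MIDSet(dict):
    """Mapping EMU -> MID vector, with a tidy-table view."""

    def for_species(self, species: str) -> np.ndarray:
        for emu, mid in self.items():
            if emu.species == species and emu.size == len(mid) - 1:
                if emu.positions == tuple(range(1, emu.size + 1)):
                    return mid
        raise KeyError(species)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": emu.species,
                "fragment": ",".join(map(str, emu.positions)),
                "mass_shift": i,
                "fraction": float(f),
            }
            for emu, mid in sorted(self.items(), key=lambda kv: (kv[0].species, kv[0].positions))
            for i, f in enumerate(mid)
        ]
        return pd.DataFrame(rows)


def mean_enrichment(mid: np.ndarray) -> float:
    n = len(mid) - 1
    return float(np.dot(np.arange(n + 1), mid) / n) if n else 0.0


# ---------------------------------------------------------------------------
# directions and decomposition


@dataclass(frozen=True)
class _Direction:
    rxn: str
    forward: bool
    substrates: tuple[tuple[str, str], ...]  # lettered occurrences (species, letters)
    products: tuple[tuple[str, str], ...]


def directions(model: NetworkModel) -> list[_Direction]:
    key = "directions"
    if key in model._caches:
        return model._caches[key]
    out = []
    for r in model.reactions:
        if not r.has_transition:
            continue
        subs = tuple((sp, l) for sp, _, l in r.substrates if l)
        prods = tuple((sp, l) for sp, _, l in r.products if l)
        out.append(_Direction(r.id, True, subs, prods))
        if r.reversible:
            out.append(_Direction(r.id, False, prods, subs))
    model._caches[key] = out
    return out


def direction_fluxes(model: NetworkModel, fluxes: FluxVector, strict: bool = True) -> np.ndarray:
    """Unidirectional fluxes per transition-bearing direction.

    With ``strict`` (the default) a negative net flux through an irreversible
    reaction raises; with ``strict=False`` it is clamped to zero, which keeps
    the EMU balances well defined while an optimizer probes the boundary.
    """
    dirs = directions(model)
    rid = {r: i for i, r in enumerate(fluxes.reaction_ids)}
    rev = {r.id for r in model.reactions if r.reversible}
    u = np.empty(len(dirs))
    for i, d in enumerate(dirs):
        net = fluxes.net[rid[d.rxn]]
        if d.rxn in rev:
            x = fluxes.xch_flux(d.rxn)
            u[i] = (max(net, 0.0) + x) if d.forward else (max(-net, 0.0) + x)
        else:
            if strict and net < -1e-9:
                raise ModelError(f"negative net flux through irreversible reaction {d.rxn}")
            u[i] = max(net, 0.0)
    return u


@dataclass
class EMUNetwork:
    """Size-stratified EMU balance structure for a fixed target set."""

    model: NetworkModel
    targets: tuple[EMU, ...]
    # per size: list of EMUs and, per EMU, its formation terms
    # term = (direction index, sources) with sources a tuple of EMUs
    strata: dict[int, list[EMU]] = field(default_factory=dict)
    terms: dict[EMU, list[tuple[int, tuple[EMU, ...]]]] = field(default_factory=dict)

    @property
    def emu_count(self) -> int:
        return sum(len(v) for v in self.strata.values())


def _trace_back(model: NetworkModel, emu: EMU) -> list[tuple[int, tuple[EMU, ...]]]:
    """Formation terms of a balanced-species EMU: one per producing occurrence."""
    dirs = directions(model)
    terms = []
    for di, d in enumerate(dirs):
        for psp, pletters in d.products:
            if psp != emu.species:
                continue
            want = [pletters[p - 1] for p in emu.positions]
            groups: dict[int, list[int]] = {}
            for si, (ssp, sletters) in enumerate(d.substrates):
                pos = sorted(sletters.index(ch) + 1 for ch in want if ch in sletters)
                if pos:
                    groups[si] = pos
            found = sum(len(v) for v in groups.values())
            if found != len(want):  # letters must map somewhere (bijection)
                raise ModelError(f"reaction {d.rxn}: unmapped carbons for {emu}")
            sources = tuple(EMU(d.substrates[si][0], tuple(p)) for si, p in sorted(groups.items()))
            terms.append((di, sources))
    return terms


def decompose_emu(model: NetworkModel, targets: list[EMU]) -> EMUNetwork:
    """Backward EMU decomposition from the target EMUs.

    Returns the size-stratified system; every size-s EMU depends only on
    EMUs of size < s, tracer inputs, and same-size EMUs within its stratum.
    Raises if a target sits in a species no transition ever produces.
    """
    for t in targets:
        spec = model.metabolites.get(t.species)
        if spec is None:
            raise ModelError(f"unknown species in target {t}")
        if max(t.positions) > spec.carbon_count:
            raise ModelError(f"target {t} exceeds carbon count {spec.carbon_count}")

    cache_key = ("emunet", tuple(targets))
    if cache_key in model._caches:
        return model._caches[cache_key]

    net = EMUNetwork(model, tuple(targets))
    inputs = set(model.label_inputs) | {
        m for m, s in model.metabolites.items() if s.role == "input"
    }
    queue = list(targets)
    seen = set()
    while queue:
        emu = queue.pop()
        if emu in seen:
            continue
        seen.add(emu)
        net.strata.setdefault(emu.size, [])
        if emu not in net.strata[emu.size]:
            net.strata[emu.size].append(emu)
        if emu.species in inputs:
            continue
        terms = _trace_back(model, emu)
        if not terms:
            raise ModelError(
                f"species {emu.species} has no transition-bearing producing reaction "
                f"(target {emu} cannot be simulated)"
            )
        net.terms[emu] = terms
        for _, sources in terms:
            queue.extend(sources)

    for s in net.strata:
        net.strata[s].sort(key=lambda e: (e.species, e.positions))
    model._caches[cache_key] = net
    return net


def default_targets(model: NetworkModel) -> list[EMU]:
    out = []
    for sp, _ in model.measured_species:
        n = model.metabolites[sp].carbon_count
        out.append(EMU(sp, tuple(range(1, n + 1))))
    return out


def simulate_mids(
    model: NetworkModel,
    fluxes: FluxVector,
    mixture: TracerMixture,
    targets: list[EMU] | None = None,
    ss_tol: float = 1e-6,
    strict: bool = True,
) -> MIDSet:
    """Isotopic-steady-state MIDs of the target EMUs for one flux vector.

    Preconditions: ``S v = 0`` within ``ss_tol`` and non-negative
    unidirectional fluxes.  Raises on a singular stratum (an EMU with zero
    total inflow is named in the error).
    """
    targets = targets if targets is not None else default_targets(model)
    resid = steady_state_residual(model, fluxes)
    if resid > ss_tol:
        raise ModelError(f"flux vector violates steady state (max |S v| = {resid:.3g})")

    network = decompose_emu(model, targets)
    u = direction_fluxes(model, fluxes, strict=strict)
    inputs = set(model.label_inputs) | {
        m for m, s in model.metabolites.items() if s.role == "input"
    }

    mids = MIDSet()
    for size in sorted(network.strata):
        emus = network.strata[size]
        internal = [e for e in emus if e.species not in inputs]
        for e in emus:
            if e.species in inputs:
                mids[e] = mixture.input_mid(e)
        if not internal:
            continue
        idx = {e: i for i, e in enumerate(internal)}
        n = len(internal)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e in internal:
            i = idx[e]
            for di, sources in network.terms[e]:
                v = u[di]
                if v == 0.0:
                    continue
                A[i, i] += v
                if len(sources) == 1 and sources[0] in idx:
                    A[i, idx[sources[0]]] -= v
                else:
                    y = mids[sources[0]]
                    for s_emu in sources[1:]:
                        y = np.convolve(y, mids[s_emu])
                    B[i, :] += v * y
        dead = [internal[i] for i in range(n) if A[i, i] <= 0.0]
        if dead:
            raise ModelError(f"zero total inflow to EMU(s) {dead}; balance system singular")
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular EMU system at size {size}: {exc}") from exc
        for e, row in zip(internal, X):
            s = row.sum()
            if not np.isfinite(s) or abs(s - 1.0) > 1e-9:
                raise ModelError(f"MID of {e} does not normalize (sum {s})")
            mids[e] = row

    return MIDSet({t: mids[t] for t in targets})
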