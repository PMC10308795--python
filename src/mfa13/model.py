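"""Atom-transition metabolic network models in a tabular (FTBL-subset) dialect.

The dialect is section-headed, tab/whitespace separated text.  A minimal
document::

    NETWORK
        upt     GLYC#abc -> T#abc
        cond    T#abc + T#def -> H#abcdef
        sink    T -> BIO

    LABEL_INPUT
        GLYC

    MEASUREMENTS
        MID     PYR     C3H4O3
        RATE    upt

``#letters`` attach one carbon letter per atom of that molecule occurrence
(1-based positions map to letters left to right).  A reaction carrying any
letters is transition-bearing and must be carbon balanced: the multiset of
substrate letters must equal the multiset of product letters.  Reactions
without letters (lumped biomass/sink reactions, cofactor-only steps) are
exempt.  ``<->`` marks a reversible reaction.  Stoichiometric coefficients
(``2 ATP``, ``0.5 NADPH``) are allowed only on species without letters;
multiple carbon-bearing copies are written as separate occurrences with
distinct letters.

Metabolite roles are inferred: species appearing only as substrates are
*inputs*, only as products are *outputs*, all others are *balanced* and
subject to steady-state mass balancing.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "MetaboliteSpec",
    "Reaction",
    "NetworkModel",
    "FluxVector",
    "ValidationReport",
    "ModelError",
    "ParseError",
    "parse_model",
    "serialize_model",
    "load_model",
    "validate_model",
    "stoichiometric_matrix",
    "sample_feasible_fluxes",
]

KNOWN_SECTIONS = {"NETWORK", "LABEL_INPUT", "FLUXES", "MEASUREMENTS", "PROJECT"}


class ModelError(ValueError):
    """A structural problem with a network model."""


class ParseError(ModelError):
    """Malformed model document."""


@dataclass
class MetaboliteSpec:
    id: str
    carbon_count: int
    role: str  # "balanced" | "input" | "output"
    compartment: str | None = None

    def __post_init__(self):
        if self.carbon_count < 0:
            raise ModelError(f"{self.id}: negative carbon count")
        if self.role not in ("balanced", "input", "output"):
            raise ModelError(f"{self.id}: unknown role {self.role!r}")


@dataclass
class Reaction:
    """One reaction: occurrences of (species, coefficient, atom letters).

    ``letters`` is ``None`` for occurrences without carbon tracking.  For
    transition-bearing occurrences the coefficient must be 1 (write repeated
    carbon-bearing substrates as separate occurrences).
    """

    id: str
    substrates: list[tuple[str, float, str | None]]
    products: list[tuple[str, float, str | None]]
    reversible: bool = False
    lb: float = 0.0
    ub: float = 1000.0

    def __post_init__(self):
        if self.lb > self.ub:
            raise ModelError(f"{self.id}: lb > ub")
        if not self.reversible and self.lb < 0:
            self.lb = 0.0

    @property
    def has_transition(self) -> bool:
        return any(l is not None for _, _, l in self.substrates + self.products)

    def carbon_delta(self) -> int:
        ns = sum(len(l) for _, _, l in self.substrates if l)
        np_ = sum(len(l) for _, _, l in self.products if l)
        return np_ - ns

    def letter_bijection_ok(self) -> bool:
        sub = "".join(l for _, _, l in self.substrates if l)
        prod = "".join(l for _, _, l in self.products if l)
        return sorted(sub) == sorted(prod) and len(set(sub)) == len(sub) and len(set(prod)) == len(prod)


@dataclass
class FluxVector:
    """Net fluxes (mmol·gCDW^-1·h^-1) aligned with a model's reaction order.

    ``xch`` holds per-reversible-reaction exchange coordinates on [0, 1);
    the corresponding absolute exchange flux is x/(1-x).
    """

    reaction_ids: tuple[str, ...]
    net: np.ndarray
    xch: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.net = np.asarray(self.net, dtype=float)
        if len(self.net) != len(self.reaction_ids):
            raise ModelError("net flux length mismatch")
        for r, x in self.xch.items():
            if not (0.0 <= x < 1.0):
                raise ModelError(f"exchange coordinate for {r} outside [0,1)")

    def __getitem__(self, rid: str) -> float:
        return float(self.net[self.reaction_ids.index(rid)])

    def xch_flux(self, rid: str) -> float:
        x = self.xch.get(rid, 0.0)
        return x / (1.0 - x)

    def normalized(self, uptake_id: str) -> np.ndarray:
        u = abs(self[uptake_id])
        if u == 0:
            raise ModelError("zero uptake flux; cannot normalize")
        return self.net / u

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.reaction_ids, map(float, self.net)))


@dataclass
class ValidationReport:
    carbon_violations: list[str] = field(default_factory=list)
    orphan_metabolites: list[str] = field(default_factory=list)
    dead_end_reactions: list[str] = field(default_factory=list)
    unreachable_measured: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def fatal(self) -> list[str]:
        return (
            [f"carbon balance: {m}" for m in self.carbon_violations]
            + [f"orphan metabolite: {m}" for m in self.orphan_metabolites]
            + [f"unreachable measured species: {m}" for m in self.unreachable_measured]
        )

    @property
    def usable(self) -> bool:
        return not self.fatal


@dataclass
class NetworkModel:
    name: str
    metabolites: dict[str, MetaboliteSpec]
    reactions: list[Reaction]
    label_inputs: list[str]
    measured_species: list[tuple[str, str | None]]  # (species, chemical formula or None)
    measured_rates: list[str]
    constrained_fluxes: dict[str, float] = field(default_factory=dict)
    free_fluxes: list[str] = field(default_factory=list)
    annotations: dict[str, list[str]] = field(default_factory=dict)

    _caches: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def balanced_ids(self) -> list[str]:
        return [m for m, s in self.metabolites.items() if s.role == "balanced"]

    def flux_vector(self, net: dict[str, float], xch: dict[str, float] | None = None) -> FluxVector:
        v = np.array([net.get(r, 0.0) for r in self.reaction_ids])
        return FluxVector(self.reaction_ids, v, dict(xch or {}))

    def summary(self) -> str:
        n_bal = len(self.balanced_ids)
        return (
            f"{self.name}: {len(self.reactions)} reactions, {len(self.metabolites)} species "
            f"({n_bal} balanced), label inputs: {', '.join(self.label_inputs) or '-'}, "
            f"measured MIDs: {', '.join(s for s, _ in self.measured_species) or '-'}, "
            f"measured rates: {', '.join(self.measured_rates) or '-'}"
        )


# ---------------------------------------------------------------------------
# parsing

_TERM_RE = re.compile(
    r"^(?:(?P<coeff>\d+(?:\.\d+)?|\d+/\d+)\s+)?(?P<species>[A-Za-z0-9_]+)(?:#(?P<letters>[A-Za-z]+))?$"
)


def _parse_term(term: str, rid: str) -> tuple[str, float, str | None]:
    m = _TERM_RE.match(term.strip())
    if not m:
        raise ParseError(f"reaction {rid}: cannot parse term {term!r}")
    coeff = m.group("coeff")
    if coeff is None:
        c = 1.0
    elif "/" in coeff:
        a, b = coeff.split("/")
        c = float(a) / float(b)
    else:
        c = float(coeff)
    letters = m.group("letters")
    if letters is not None and c != 1.0:
        raise ParseError(
            f"reaction {rid}: coefficient {c} on carbon-tracked species "
            f"{m.group('species')}; write repeated occurrences with distinct letters"
        )
    return m.group("species"), c, letters


def _parse_equation(rid: str, eq: str) -> tuple[list, list, bool]:
    if "<->" in eq:
        lhs, rhs = eq.split("<->")
        rev = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        rev = False
    else:
        raise ParseError(f"reaction {rid}: missing '->' in {eq!r}")
    subs = [_parse_term(t, rid) for t in lhs.split("+") if t.strip()]
    prods = [_parse_term(t, rid) for t in rhs.split("+") if t.strip()]
    if not subs or not prods:
        raise ParseError(f"reaction {rid}: empty reaction side")
    return subs, prods, rev


def parse_model(document: str, name: str = "model") -> NetworkModel:
    """Parse an FTBL-subset document into a validated :class:`NetworkModel`.

    Unknown sections are preserved verbatim in ``model.annotations`` and
    reported with a warning.  Raises :class:`ParseError` on malformed input
    and :class:`ModelError` on validation failures (carbon imbalance,
    duplicate ids, ...).
    """
    sections: dict[str, list[str]] = {}
    current = None
    for raw in io.StringIO(document):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("//"):
            continue
        if re.fullmatch(r"[A-Z_][A-Z_0-9]*", stripped) and not line[:1].isspace():
            current = stripped
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ParseError(f"content before any section header: {stripped!r}")
        sections[current].append(stripped)

    for sec in sections:
        if sec not in KNOWN_SECTIONS:
            warnings.warn(f"ignoring unknown section {sec!r}", stacklevel=2)

    if "NETWORK" not in sections or not sections["NETWORK"]:
        raise ParseError("empty or missing NETWORK section")

    if "PROJECT" in sections:
        for line in sections["PROJECT"]:
            parts = line.split(None, 1)
            if len(parts) == 2 and parts[0].upper() == "NAME":
                name = parts[1].strip()

    reactions: list[Reaction] = []
    seen = set()
    for line in sections["NETWORK"]:
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"NETWORK line needs 'id equation': {line!r}")
        rid, eq = parts
        if rid in seen:
            raise ParseError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
        subs, prods, rev = _parse_equation(rid, eq)
        reactions.append(Reaction(rid, subs, prods, reversible=rev, lb=-1000.0 if rev else 0.0))

    # infer metabolites: carbon counts from letters, roles from usage sides
    carbons: dict[str, int] = {}
    used_as_sub: set[str] = set()
    used_as_prod: set[str] = set()
    for r in reactions:
        for side, bag in ((r.substrates, used_as_sub), (r.products, used_as_prod)):
            for sp, _, letters in side:
                bag.add(sp)
                if letters is not None:
                    n = len(letters)
                    if sp in carbons and carbons[sp] != n:
                        raise ParseError(
                            f"reaction {r.id}: species {sp} has {n} transition letters, "
                            f"expected {carbons[sp]} (letter count != carbon count)"
                        )
                    carbons[sp] = n

    metabolites: dict[str, MetaboliteSpec] = {}
    for sp in sorted(used_as_sub | used_as_prod):
        if sp in used_as_sub and sp in used_as_prod:
            role = "balanced"
        elif sp in used_as_sub:
            role = "input"
        else:
            role = "output"
        metabolites[sp] = MetaboliteSpec(sp, carbons.get(sp, 0), role)

    label_inputs = []
    for line in sections.get("LABEL_INPUT", []):
        sp = line.split()[0]
        if sp not in metabolites:
            raise ParseError(f"LABEL_INPUT species {sp!r} not in network")
        label_inputs.append(sp)

    constrained: dict[str, float] = {}
    free: list[str] = []
    for line in sections.get("FLUXES", []):
        parts = line.split()
        kind = parts[0].lower()
        if kind == "constrained" and len(parts) == 3:
            constrained[parts[1]] = float(parts[2])
        elif kind == "free" and len(parts) == 2:
            free.append(parts[1])
        elif kind == "bounds" and len(parts) == 4:
            rid, lo, hi = parts[1], float(parts[2]), float(parts[3])
            for r in reactions:
                if r.id == rid:
                    r.lb, r.ub = lo, hi
                    break
            else:
                raise ParseError(f"FLUXES bounds for unknown reaction {rid!r}")
        else:
            raise ParseError(f"cannot parse FLUXES line {line!r}")

    measured_species: list[tuple[str, str | None]] = []
    measured_rates: list[str] = []
    for line in sections.get("MEASUREMENTS", []):
        parts = line.split()
        if parts[0].upper() == "MID" and len(parts) in (2, 3):
            measured_species.append((parts[1], parts[2] if len(parts) == 3 else None))
        elif parts[0].upper() == "RATE" and len(parts) == 2:
            measured_rates.append(parts[1])
        else:
            raise ParseError(f"cannot parse MEASUREMENTS line {line!r}")

    annotations = {s: lines for s, lines in sections.items() if s not in KNOWN_SECTIONS}

    model = NetworkModel(
        name=name,
        metabolites=metabolites,
        reactions=reactions,
        label_inputs=label_inputs,
        measured_species=measured_species,
        measured_rates=measured_rates,
        constrained_fluxes=constrained,
        free_fluxes=free,
        annotations=annotations,
    )

    report = validate_model(model)
    if report.carbon_violations:
        raise ModelError("; ".join("carbon imbalance: " + v for v in report.carbon_violations))
    return model


def serialize_model(model: NetworkModel) -> str:
    """Write a model back to the FTBL-subset dialect (round-trip safe)."""

    def term(sp, c, letters):
        out = sp if c == 1.0 else f"{c:g} {sp}"
        return out + (f"#{letters}" if letters else "")

    lines = ["PROJECT", f"\tNAME\t{model.name}", "", "NETWORK"]
    for r in model.reactions:
        arrow = "<->" if r.reversible else "->"
        eq = " + ".join(term(*t) for t in r.substrates) + f" {arrow} " + " + ".join(
            term(*t) for t in r.products
        )
        lines.append(f"\t{r.id}\t{eq}")
    if model.label_inputs:
        lines += ["", "LABEL_INPUT"] + [f"\t{s}" for s in model.label_inputs]
    flux_lines = [f"\tconstrained\t{r}\t{v:g}" for r, v in model.constrained_fluxes.items()]
    flux_lines += [f"\tfree\t{r}" for r in model.free_fluxes]
    flux_lines += [
        f"\tbounds\t{r.id}\t{r.lb:g}\t{r.ub:g}"
        for r in model.reactions
        if (r.lb, r.ub) != ((-1000.0, 1000.0) if r.reversible else (0.0, 1000.0))
    ]
    if flux_lines:
        lines += ["", "FLUXES"] + flux_lines
    meas = [f"\tMID\t{s}" + (f"\t{f}" if f else "") for s, f in model.measured_species]
    meas += [f"\tRATE\t{r}" for r in model.measured_rates]
    if meas:
        lines += ["", "MEASUREMENTS"] + meas
    for sec, content in model.annotations.items():
        lines += ["", sec] + [f"\t{c}" for c in content]
    return "\n".join(lines) + "\n"


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        return parse_model(fh.read(), name=str(path))


# ---------------------------------------------------------------------------
# validation and stoichiometry


def validate_model(model: NetworkModel) -> ValidationReport:
    """Report-only structural checks; the model is usable iff no fatal item."""
    rep = ValidationReport()
    for r in model.reactions:
        if r.has_transition:
            if not r.letter_bijection_ok() or r.carbon_delta() != 0:
                rep.carbon_violations.append(f"{r.id} (carbon delta {r.carbon_delta():+d})")
            for sp, _, letters in r.substrates + r.products:
                if letters is None and model.metabolites[sp].carbon_count > 0:
                    rep.warnings.append(
                        f"{r.id}: carbon-bearing species {sp} lacks transition letters"
                    )

    produced = {sp for r in model.reactions for sp, _, _ in r.products}
    consumed = {sp for r in model.reactions for sp, _, _ in r.substrates}
    for r in model.reactions:
        if r.reversible:
            produced |= {sp for sp, _, _ in r.substrates}
            consumed |= {sp for sp, _, _ in r.products}
    for m in model.balanced_ids:
        if m not in produced or m not in consumed:
            rep.orphan_metabolites.append(m)

    reachable = _label_reachable(model)
    for sp, _ in model.measured_species:
        if sp not in reachable:
            rep.unreachable_measured.append(sp)

    for r in model.reactions:
        dead = all(
            model.metabolites[sp].role == "output" for sp, _, _ in r.products
        ) and all(model.metabolites[sp].role == "input" for sp, _, _ in r.substrates)
        if dead and len(model.reactions) > 1:
            rep.dead_end_reactions.append(r.id)
    return rep


def _label_reachable(model: NetworkModel) -> set[str]:
    """Species reachable from label inputs through atom transitions."""
    reach = set(model.label_inputs)
    changed = True
    while changed:
        changed = False
        for r in model.reactions:
            if not r.has_transition:
                continue
            sides = [(r.substrates, r.products)]
            if r.reversible:
                sides.append((r.products, r.substrates))
            for src, dst in sides:
                if any(sp in reach for sp, _, l in src if l):
                    for sp, _, l in dst:
                        if l and sp not in reach:
                            reach.add(sp)
                            changed = True
    return reach


def stoichiometric_matrix(model: NetworkModel) -> tuple[np.ndarray, list[str], list[str]]:
    """Net stoichiometric matrix over balanced metabolites.

    Returns ``(S, balanced_metabolite_ids, reaction_ids)`` with
    ``S[i, j]`` the net coefficient of metabolite i in reaction j; input and
    output species are excluded from balancing.
    """
    key = "S"
    if key in model._caches:
        return model._caches[key]
    bal = model.balanced_ids
    idx = {m: i for i, m in enumerate(bal)}
    S = np.zeros((len(bal), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for sp, c, _ in r.substrates:
            if sp in idx:
                S[idx[sp], j] -= c
        for sp, c, _ in r.products:
            if sp in idx:
                S[idx[sp], j] += c
    model._caches[key] = (S, bal, list(model.reaction_ids))
    return model._caches[key]


def steady_state_residual(model: NetworkModel, fluxes: FluxVector) -> float:
    S, _, _ = stoichiometric_matrix(model)
    return float(np.max(np.abs(S @ fluxes.net))) if S.size else 0.0


def sample_feasible_fluxes(
    model: NetworkModel,
    n: int,
    rng: np.random.Generator,
    uptake: tuple[str, float] | None = None,
    scale: float = 10.0,
    interior: bool = True,
) -> list[FluxVector]:
    """Draw random steady-state flux vectors by LP with random objectives.

    Vertices of ``{S v = 0, bounds}`` are sampled with random linear
    objectives; with ``interior=True`` pairs of vertices are averaged with
    Dirichlet weights to move off the boundary.  ``uptake=(rxn, value)``
    pins the uptake reaction.
    """
    S, _, rids = stoichiometric_matrix(model)
    nr = len(rids)
    bounds = []
    for r in model.reactions:
        lo = max(r.lb, -scale) if r.reversible else max(r.lb, 0.0)
        hi = min(r.ub, scale)
        bounds.append((lo, hi))
    A_eq = [S] if S.size else []
    b_eq = [np.zeros(S.shape[0])] if S.size else []
    if uptake is not None:
        row = np.zeros(nr)
        row[rids.index(uptake[0])] = 1.0
        A_eq.append(row.reshape(1, -1))
        b_eq.append(np.array([uptake[1]]))
    A = np.vstack(A_eq)
    b = np.concatenate(b_eq)

    verts = []
    tries = 0
    while len(verts) < max(2 * n, 8) and tries < 50 * n + 100:
        tries += 1
        c = rng.normal(size=nr)
        res = linprog(c, A_eq=A, b_eq=b, bounds=bounds, method="highs")
        if res.status == 0:
            verts.append(res.x)
    if not verts:
        raise ModelError("no feasible flux vector found (model over-constrained?)")
    verts = np.array(verts)
    out = []
    for _ in range(n):
        if interior:
            k = min(4, len(verts))
            pick = rng.choice(len(verts), size=k, replace=False)
            w = rng.dirichlet(np.ones(k))
            v = w @ verts[pick]
        else:
            v = verts[rng.integers(len(verts))]
        out.append(FluxVector(tuple(rids), v))
    return out
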