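"""EMU decomposition and isotopic steady-state simulation vs the isotopomer oracle."""

import numpy as np
import pytest

from mfa13.emu import EMU, TracerMixture, decompose_emu, mean_enrichment, simulate_mids
from mfa13.fixtures import toy_reference_fluxes
from mfa13.isotopomer import enumerate_isotopomers_oracle
from mfa13.model import ModelError, parse_model
from mfa13.studies import random_toy_fluxes, study_mixtures

PYR = EMU("PYR", (1, 2, 3))
ACD = EMU("ACD", (1, 2))


def test_decomposition_contains_identity_chain(toy):
    net = decompose_emu(toy, [PYR])
    emus = {e for stratum in net.strata.values() for e in stratum}
    assert EMU("T", (1, 2, 3)) in emus
    assert EMU("GLYC", (1, 2, 3)) in emus


def test_decarboxylation_reads_transition(toy):
    net = decompose_emu(toy, [ACD])
    emus = {e for stratum in net.strata.values() for e in stratum}
    assert EMU("PYR", (2, 3)) in emus


def test_emu_count_matches_exhaustive_backward_enumeration(toy):
    """Independent oracle: saturate backward reachability over raw transitions."""
    # (species, positions) pairs reachable backwards from the targets
    dirs = []
    for r in toy.reactions:
        if not r.has_transition:
            continue
        subs = [(sp, l) for sp, _, l in r.substrates if l]
        prods = [(sp, l) for sp, _, l in r.products if l]
        dirs.append((subs, prods))
        if r.reversible:
            dirs.append((prods, subs))

    seen = {("PYR", (1, 2, 3)), ("ACD", (1, 2))}
    frontier = list(seen)
    while frontier:
        sp, pos = frontier.pop()
        for subs, prods in dirs:
            for psp, pl in prods:
                if psp != sp:
                    continue
                want = [pl[p - 1] for p in pos]
                for ssp, sl in subs:
                    spos = tuple(sorted(sl.index(ch) + 1 for ch in want if ch in sl))
                    if spos and (ssp, spos) not in seen:
                        seen.add((ssp, spos))
                        frontier.append((ssp, spos))

    net = decompose_emu(toy, [PYR, ACD])
    assert net.emu_count == len(seen)


def test_unlabelled_gives_m0(toy, ref_fluxes):
    mids = simulate_mids(toy, ref_fluxes, TracerMixture.unlabelled("GLYC"))
    for mid in mids.values():
        assert mid[0] == pytest.approx(1.0, abs=1e-12)


def test_uniform_tracer_gives_full_shift(toy, ref_fluxes):
    mids = simulate_mids(toy, ref_fluxes, TracerMixture.single("GLYC", (1, 2, 3)))
    for mid in mids.values():
        assert mid[-1] == pytest.approx(1.0, abs=1e-12)


def test_paper_mixture_matches_oracle_at_even_split(toy, paper_mixture):
    fv = toy_reference_fluxes(toy, scramble=0.2, cycle=0.2)  # scramble:cleave = 1:1
    emu = simulate_mids(toy, fv, paper_mixture)
    orc = enumerate_isotopomers_oracle(toy, fv, paper_mixture)
    for t in emu:
        assert np.max(np.abs(emu[t] - orc[t])) <= 1e-8


def test_emu_oracle_agreement_random_fluxes(toy, rng):
    for fv in random_toy_fluxes(rng, 5):
        for mix in study_mixtures():
            emu = simulate_mids(toy, fv, mix)
            orc = enumerate_isotopomers_oracle(toy, fv, mix)
            for t in emu:
                assert np.max(np.abs(emu[t] - orc[t])) <= 1e-8
                assert emu[t].sum() == pytest.approx(1.0, abs=1e-9)
                assert orc[t].sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all(emu[t] >= -1e-12)


def test_two_carbon_single_reaction_closed_form():
    doc = "NETWORK\n\tr1\tA#ab -> B#ab\n\tout\tB -> SINK\nLABEL_INPUT\n\tA\nMEASUREMENTS\n\tMID\tB"
    model = parse_model(doc)
    fv = model.flux_vector({"r1": 1.0, "out": 1.0})
    mix = TracerMixture({"A": [((1,), 0.5), ((), 0.5)]})
    for sim in (simulate_mids, enumerate_isotopomers_oracle):
        mid = sim(model, fv, mix).for_species("B")
        assert np.allclose(mid, [0.5, 0.5, 0.0], atol=1e-12)


def test_reaction_order_permutation_invariance(toy, ref_fluxes, paper_mixture, rng):
    base = simulate_mids(toy, ref_fluxes, paper_mixture)
    from mfa13.model import serialize_model

    lines = serialize_model(toy).splitlines()
    start = lines.index("NETWORK") + 1
    rxns = lines[start : start + 10]
    order = rng.permutation(10)
    shuffled = lines[:start] + [rxns[i] for i in order] + lines[start + 10 :]
    model2 = parse_model("\n".join(shuffled))
    fv2 = model2.flux_vector(ref_fluxes.as_dict(), xch=dict(ref_fluxes.xch))
    perm = simulate_mids(model2, fv2, paper_mixture)
    for t in base:
        assert np.allclose(base[t], perm[t], atol=1e-12)


def test_enrichment_monotone_in_uniform_fraction(toy, ref_fluxes):
    prev = None
    for p in (0.0, 0.25, 0.5, 0.75, 1.0):
        comps = [((1, 2, 3), p)] + ([((), 1.0 - p)] if p < 1 else [])
        mids = simulate_mids(toy, ref_fluxes, TracerMixture({"GLYC": comps}))
        enr = {t: mean_enrichment(m) for t, m in mids.items()}
        if prev is not None:
            for t in enr:
                assert enr[t] >= prev[t] - 1e-12
        prev = enr


def test_zero_inflow_emu_raises(toy, paper_mixture):
    dead = toy.flux_vector({r: 0.0 for r in toy.reaction_ids})
    with pytest.raises(ModelError, match="zero total inflow"):
        simulate_mids(toy, dead, paper_mixture)


def test_steady_state_violation_raises(toy, ref_fluxes, paper_mixture):
    bad = toy.flux_vector(ref_fluxes.as_dict(), xch=dict(ref_fluxes.xch))
    bad.net[1] += 0.5
    with pytest.raises(ModelError, match="steady state"):
        simulate_mids(toy, bad, paper_mixture)


def test_target_without_producing_transition_raises(toy):
    with pytest.raises(ModelError):
        decompose_emu(toy, [EMU("BIO", (1,))])


def test_oracle_refuses_oversized_molecules():
    doc = "NETWORK\n\tr1\tA#abcdefghijklm -> B#abcdefghijklm\nLABEL_INPUT\n\tA\nMEASUREMENTS\n\tMID\tB"
    model = parse_model(doc)
    fv = model.flux_vector({"r1": 1.0})
    with pytest.raises(ModelError, match="too large"):
        enumerate_isotopomers_oracle(model, fv, TracerMixture.single("A", (1,)))


def test_tracer_mixture_validation():
    with pytest.raises(ModelError):
        TracerMixture({"GLYC": [((1,), 0.4), ((2,), 0.4)]})  # fractions don't sum to 1
    with pytest.raises(ModelError):
        TracerMixture({"GLYC": [((1,), 1.0)]}, purity=0.0)
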