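"""FTBL-subset parsing, validation, and stoichiometry."""

import numpy as np
import pytest

from mfa13.model import (
    ModelError,
    ParseError,
    parse_model,
    sample_feasible_fluxes,
    serialize_model,
    stoichiometric_matrix,
    validate_model,
)

MINI = """
NETWORK
\tr1\tA#ab -> B#ab
"""


def test_toy_counts_and_summary(toy):
    assert len(toy.reactions) == 10
    assert len(toy.metabolites) == 9
    assert "10 reactions" in toy.summary()
    assert toy.label_inputs == ["GLYC"]
    assert [s for s, _ in toy.measured_species] == ["PYR", "ACD"]
    assert toy.measured_rates == ["upt", "ace_out", "pyr_out"]


def test_toy_carbon_balance_hand_count(toy):
    # independent bookkeeping: count letters per side straight off the strings
    for r in toy.reactions:
        sub = "".join(l for _, _, l in r.substrates if l)
        prod = "".join(l for _, _, l in r.products if l)
        assert sorted(sub) == sorted(prod), r.id
        # and letter counts match the inferred carbon inventory
        for sp, _, l in r.substrates + r.products:
            if l:
                assert len(l) == toy.metabolites[sp].carbon_count


def test_roles_inferred(toy):
    assert toy.metabolites["GLYC"].role == "input"
    assert toy.metabolites["CO2"].role == "output"
    assert toy.metabolites["BIO"].role == "output"
    assert toy.metabolites["T"].role == "balanced"


def test_empty_network_is_parse_error():
    with pytest.raises(ParseError):
        parse_model("NETWORK\n")
    with pytest.raises(ParseError):
        parse_model("LABEL_INPUT\n\tA\n")


@pytest.mark.parametrize(
    "doc, fragment",
    [
        ("NETWORK\n\tr1\tA#ab -> B#ab\n\tr1\tB#ab -> C#ab", "duplicate"),
        ("NETWORK\n\tr1\tA#ab -> B#abc\n\tr2\tB#abc -> C#abc", "carbon"),
        ("NETWORK\n\tr1\t2 A#ab -> B#ab", "distinct letters"),
        ("NETWORK\n\tr1\tA#ab B#ab", "->"),
    ],
)
def test_malformed_documents_raise(doc, fragment):
    with pytest.raises(ModelError) as exc:
        parse_model(doc)
    assert fragment.split()[0] in str(exc.value).lower()


def test_unbalanced_transition_names_reaction():
    doc = "NETWORK\n\tok\tA#abc -> B#ab + C#c\n\tbad\tB#ab -> D#a\n\tout\tD#a -> E#a"
    with pytest.raises(ModelError) as exc:
        parse_model(doc)
    assert "bad" in str(exc.value)


def test_unknown_section_preserved_with_warning():
    doc = MINI + "\nEQUALITIES\n\tsomething opaque\n"
    with pytest.warns(UserWarning, match="EQUALITIES"):
        model = parse_model(doc)
    assert model.annotations["EQUALITIES"] == ["something opaque"]


def test_round_trip(toy):
    text = serialize_model(toy)
    again = parse_model(text)
    assert again.reaction_ids == toy.reaction_ids
    for a, b in zip(again.reactions, toy.reactions):
        assert (a.id, a.substrates, a.products, a.reversible, a.lb, a.ub) == (
            b.id, b.substrates, b.products, b.reversible, b.lb, b.ub)
    assert again.metabolites == toy.metabolites
    assert again.label_inputs == toy.label_inputs
    assert again.measured_species == toy.measured_species
    assert again.measured_rates == toy.measured_rates
    assert again.constrained_fluxes == toy.constrained_fluxes


def test_stoichiometric_matrix_single_reaction():
    model = parse_model("NETWORK\n\tr1\tA#a -> B#a\n\tin\tX -> A\n\tout\tB -> Y")
    S, bal, rids = stoichiometric_matrix(model)
    j = rids.index("r1")
    assert S[bal.index("A"), j] == -1 and S[bal.index("B"), j] == 1


def test_stoichiometric_matrix_carbon_weighted_columns(toy):
    S, bal, rids = stoichiometric_matrix(toy)
    carbons = np.array([toy.metabolites[m].carbon_count for m in bal])
    for j, r in enumerate(toy.reactions):
        if not r.has_transition:
            continue
        # carbon leaving through input/output species per column
        boundary = sum(
            c * toy.metabolites[sp].carbon_count
            for sp, c, _ in r.products if toy.metabolites[sp].role == "output"
        ) - sum(
            c * toy.metabolites[sp].carbon_count
            for sp, c, _ in r.substrates if toy.metabolites[sp].role == "input"
        )
        assert carbons @ S[:, j] + boundary == pytest.approx(0.0)


def test_rank_matches_gaussian_elimination_oracle(toy):
    S, _, _ = stoichiometric_matrix(toy)

    def rank_gauss(M, tol=1e-10):
        M = M.astype(float).copy()
        rank = 0
        for col in range(M.shape[1]):
            piv = None
            for row in range(rank, M.shape[0]):
                if abs(M[row, col]) > tol:
                    piv = row
                    break
            if piv is None:
                continue
            M[[rank, piv]] = M[[piv, rank]]
            M[rank] /= M[rank, col]
            for row in range(M.shape[0]):
                if row != rank:
                    M[row] -= M[row, col] * M[rank]
            rank += 1
        return rank

    assert np.linalg.matrix_rank(S) == rank_gauss(S) == len(toy.balanced_ids)


def test_validate_toy_clean(toy):
    rep = validate_model(toy)
    assert rep.usable and rep.fatal == []


def test_validate_flags_deleted_letter():
    doc = (
        "NETWORK\n\tupt\tGLYC#abc -> T#abc\n\tbad\tT#abc -> P#ab\n"
        "\tsink\tP -> OUT\nLABEL_INPUT\n\tGLYC\n"
    )
    with pytest.raises(ModelError, match="bad"):
        parse_model(doc)


def test_validate_flags_unreachable_measured():
    doc = (
        "NETWORK\n\tr1\tA#a -> B#a\n\tiso\tC#a -> D#a\n\tsnk\tB -> OUT\n\tsnk2\tD -> OUT\n"
        "LABEL_INPUT\n\tA\nMEASUREMENTS\n\tMID\tD\n"
    )
    model = parse_model(doc)
    rep = validate_model(model)
    assert "D" in rep.unreachable_measured
    assert not rep.usable


def test_toy_admits_strictly_positive_flux(toy, rng):
    fv = sample_feasible_fluxes(toy, 1, rng, uptake=("upt", 1.0))[0]
    S, _, _ = stoichiometric_matrix(toy)
    assert np.max(np.abs(S @ fv.net)) < 1e-8
    # and a strictly positive distribution exists (blend keeps all >= 0)
    from mfa13.fixtures import toy_reference_fluxes

    pos = toy_reference_fluxes(toy)
    assert np.all(pos.net > 0)
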