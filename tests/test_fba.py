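"""Max-ATPM FBA, cofactor bookkeeping, and pyruvate partitioning."""

import numpy as np
import pytest

from mfa13.fba import (
    cofactor_balance,
    fba_max_atpm,
    flux_variability,
    maintenance_split,
    pyruvate_partition,
)
from mfa13.fixtures import toy_energy_fluxes
from mfa13.model import ModelError, sample_feasible_fluxes


def test_hand_derived_lp_optimum(toy_energy):
    """With uptake <= 1 the books give ATPM = 2: all carbon through t2p
    (1 ATP + 1 NADH -> 2 ATP via resp), nothing to biomass or the PPP-like
    branch, minus 1 ATP for the uptake kinase."""
    res = fba_max_atpm(toy_energy, bounds={"upt": (0.0, 1.0)})
    assert res.objective == pytest.approx(2.0, abs=1e-9)
    assert res.fluxes["t2p"] == pytest.approx(1.0, abs=1e-9)
    assert res.fluxes["bio"] == pytest.approx(0.0, abs=1e-9)


def test_pinned_bounds_return_pinned_objective(toy_energy):
    fv = toy_energy_fluxes()
    bounds = {r: (v, v) for r, v in fv.as_dict().items()}
    res = fba_max_atpm(toy_energy, bounds)
    assert res.objective == pytest.approx(fv["atpm"], abs=1e-8)


def test_lp_deterministic(toy_energy):
    a = fba_max_atpm(toy_energy, bounds={"upt": (0.0, 1.0)})
    b = fba_max_atpm(toy_energy, bounds={"upt": (0.0, 1.0)})
    assert np.array_equal(a.fluxes.net, b.fluxes.net)


def test_cofactor_balances_close_for_feasible_vectors(toy_energy, rng):
    for fv in sample_feasible_fluxes(toy_energy, 8, rng, uptake=("upt", 1.0)):
        for cof in ("ATP", "NADPH", "NADH"):
            df = cofactor_balance(toy_energy, fv, cof)
            assert abs(df.attrs["net"]) <= 1e-6, cof


def test_nadph_production_share_hand_bookkeeping(toy_energy):
    fv = toy_energy_fluxes(scramble=0.05)
    df = cofactor_balance(toy_energy, fv, "NADPH")
    prod = df[df["rate"] > 0]
    # the PPP-like scramble is the sole NADPH source: 2 x 0.05
    assert list(prod["reaction"]) == ["scramble"]
    assert prod["rate"].iloc[0] == pytest.approx(0.1, abs=1e-12)
    assert df.attrs["production"] == pytest.approx(2 * fv["scramble"], abs=1e-12)


def test_cofactor_absent_gives_empty_table(toy_energy):
    fv = toy_energy_fluxes()
    df = cofactor_balance(toy_energy, fv, "GLYC")  # never both produced/consumed
    assert df.attrs["production"] == 0.0 or df.attrs["consumption"] == 0.0
    with pytest.raises(ModelError):
        cofactor_balance(toy_energy, fv, "NOPE")


def test_pyruvate_partition_limits(toy_energy):
    fv = toy_energy_fluxes()
    same = fv.as_dict()
    assert pyruvate_partition(fv, "pyr_out", "t2p") == pytest.approx(
        100 * same["pyr_out"] / same["t2p"]
    )
    zero = toy_energy.flux_vector({**same, "pyr_out": 0.0})
    assert pyruvate_partition(zero, "pyr_out", "t2p") == 0.0
    v_eq = toy_energy.flux_vector({**same, "pyr_out": same["t2p"]})
    assert pyruvate_partition(v_eq, "pyr_out", "t2p") == pytest.approx(100.0)
    dead = toy_energy.flux_vector({**same, "t2p": 0.0})
    with pytest.raises(ModelError):
        pyruvate_partition(dead, "pyr_out", "t2p")


def test_partition_reconstructed_from_bounds(toy_energy):
    """Bounds built for a 47.1 % mitochondrial pyruvate share reproduce it."""
    t2p = 2.12
    bounds = {"upt": (3.37, 3.37), "scramble": (0.25, 0.25),
              "t2p": (t2p, t2p), "pyr_out": (0.471 * t2p, 0.471 * t2p)}
    res = fba_max_atpm(toy_energy, bounds)
    assert pyruvate_partition(res.fluxes, "pyr_out", "t2p") == pytest.approx(47.1, abs=1e-6)


def test_infeasible_bounds_report_conflict(toy_energy):
    with pytest.raises(ModelError, match="conflicting"):
        fba_max_atpm(toy_energy, bounds={"upt": (0, 1.0), "t2p": (0.9, 1.0),
                                         "bio": (0.5, 0.6)})


def test_unknown_objective_raises(toy_energy):
    with pytest.raises(ModelError, match="objective"):
        fba_max_atpm(toy_energy, objective_id="nope")


def test_bound_relaxation_monotonicity(toy_energy):
    base = fba_max_atpm(toy_energy, bounds={"upt": (0.0, 1.0), "bio": (0.0, 0.1)})
    # bio bound is non-binding at the optimum (bio = 0): relaxing it is neutral
    relaxed = fba_max_atpm(toy_energy, bounds={"upt": (0.0, 1.0), "bio": (0.0, 10.0)})
    assert relaxed.objective == pytest.approx(base.objective, abs=1e-9)
    # relaxing the binding uptake bound cannot decrease the optimum
    wider = fba_max_atpm(toy_energy, bounds={"upt": (0.0, 2.0)})
    assert wider.objective >= base.objective - 1e-9


def test_flux_variability_brackets_vertex(toy_energy):
    res = fba_max_atpm(toy_energy, bounds={"upt": (0.0, 1.0)})
    fva = flux_variability(toy_energy, {"upt": (0.0, 1.0)}, ["pdc", "pyr_out"],
                           objective_id="atpm", objective_value=res.objective)
    for rid in ("pdc", "pyr_out"):
        assert fva.loc[rid, "min"] - 1e-9 <= res.fluxes[rid] <= fva.loc[rid, "max"] + 1e-9


def test_maintenance_split(toy_energy):
    fv = toy_energy_fluxes()
    split = maintenance_split(toy_energy, fv)
    assert split["GAME"] == pytest.approx(2 * fv["bio"])
    assert split["NGAME"] == pytest.approx(fv["atpm"])
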