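"""Bundled toy fixtures and reference flux vectors used in docs and tests."""

from __future__ import annotations

from importlib import resources

import numpy as np

from .model import FluxVector, NetworkModel, parse_model

__all__ = ["toy_model", "toy_energy_model", "toy_reference_fluxes"]


def _load(name: str) -> NetworkModel:
    text = resources.files("mfa13.data").joinpath(name).read_text()
    return parse_model(text)


def toy_model() -> NetworkModel:
    """The bundled 10-reaction, 9-species labelling network ("toyglyc")."""
    return _load("toyglyc.ftbl")


def toy_energy_model() -> NetworkModel:
    """toyglyc plus cofactor stoichiometry, respiration, and ATP maintenance."""
    return _load("toyglyc_energy.ftbl")


def toy_reference_fluxes(
    model: NetworkModel | None = None,
    uptake: float = 1.0,
    scramble: float = 0.2,
    cycle: float = 0.3,
    pdc: float = 0.25,
    pyr_out: float = 0.15,
    xch_cleave: float = 0.3,
) -> FluxVector:
    """A steady-state flux vector for toyglyc, parameterized by the free splits.

    Balances (uptake u, scramble s, cleave net c):
      H:   cond = c + s
      T:   bio  = u - s - (pdc + pyr_out)
      P:   p_out = s
      PYR: t2p = pdc + pyr_out;  ACD: ace_out = pdc
    """
    model = model or toy_model()
    u, s, c = uptake, scramble, cycle
    t2p = pdc + pyr_out
    net = {
        "upt": u,
        "cond": c + s,
        "cleave": c,
        "scramble": s,
        "t2p": t2p,
        "pdc": pdc,
        "ace_out": pdc,
        "pyr_out": pyr_out,
        "p_out": s,
        "bio": u - s - t2p,
    }
    if net["bio"] < -1e-12:
        raise ValueError("infeasible parameter choice: negative biomass drain")
    fv = model.flux_vector(net, xch={"cleave": xch_cleave})
    from .model import steady_state_residual

    assert steady_state_residual(model, fv) < 1e-9
    return fv


def toy_energy_fluxes(uptake: float = 1.0, scramble: float = 0.05, **kw) -> FluxVector:
    """Steady-state vector for the energy variant (adds resp/atpm closure)."""
    model = toy_energy_model()
    base = toy_reference_fluxes(uptake=uptake, scramble=scramble, **kw)
    net = base.as_dict()
    # cofactor closure: NADPH pins bio = 4 s, which re-pins t2p and splits
    net["bio"] = 4 * scramble
    net["t2p"] = uptake - scramble - net["bio"]
    net["pdc"] = net["t2p"] * net["pdc"] / max(net["pdc"] + net["pyr_out"], 1e-12)
    net["pyr_out"] = net["t2p"] - net["pdc"]
    net["ace_out"] = net["pdc"]
    net["resp"] = net["t2p"]
    net["atpm"] = -uptake + net["t2p"] + 2 * net["resp"] - 2 * net["bio"]
    if min(net.values()) < -1e-12 or net["atpm"] < 0:
        raise ValueError("infeasible energy-closure parameters")
    fv = model.flux_vector(net, xch=dict(base.xch))
    from .model import steady_state_residual

    assert steady_state_residual(model, fv) < 1e-9
    return fv
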