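"""Estimate growth rate, q-rates, and yields from a batch time series.

Generates a synthetic glycerol batch culture (mu = 0.22 1/h, qS = -3.37
mmol/gCDW/h, 3 % OD and 5 % concentration noise) and recovers the bioprocess
parameters.
"""

from mfa13 import ScenarioSpec, fit_physiology, generate_timeseries, toy_model
from mfa13.fixtures import toy_reference_fluxes
from mfa13.physiology import compute_yields

model = toy_model()
truth = toy_reference_fluxes(model, uptake=3.37, scramble=0.5, cycle=0.7,
                             pdc=0.8, pyr_out=0.5)
scenario = ScenarioSpec(model=model, truth=truth, mu=0.22, seed=4)
ts = generate_timeseries(scenario)

physio = fit_physiology(ts)
print(f"mu   = {physio.mu:.4f} +/- {physio.sd_mu:.4f} 1/h      (truth 0.22)")
q = physio.rates["glycerol"]
print(f"q_S  = {q.q:.3f} +/- {q.sd_q:.3f} mmol/gCDW/h  (truth -3.37)")

yields = compute_yields(physio, "glycerol",
                        molar_masses={"glycerol": 92.09, "acetate": 60.05,
                                      "pyruvate": 88.06},
                        carbon_counts={"glycerol": 3, "acetate": 2, "pyruvate": 3})
print(yields.round(3))
# biomass yield ~0.71 gCDW per g glycerol at these rates
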