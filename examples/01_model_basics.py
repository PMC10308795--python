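"""Load and inspect an atom-transition network model.

The bundled "toyglyc" network is a 10-reaction glycerol-like skeleton with
condensation, reversible cleavage, a PPP-like scrambling split, and a
decarboxylation — the label-routing mechanisms a core yeast model contains.
"""

import numpy as np

from mfa13 import parse_model, serialize_model, stoichiometric_matrix, toy_model, validate_model

model = toy_model()
print(model.summary())
# toyglyc: 10 reactions, 9 species (5 balanced), ...

report = validate_model(model)
print("fatal issues:", report.fatal or "none")

S, balanced, reactions = stoichiometric_matrix(model)
print("stoichiometric matrix:", S.shape, "rank", np.linalg.matrix_rank(S))
# 5 balanced metabolites x 10 reactions, full rank 5 -> 5 free fluxes

# the model round-trips through its tabular text format
assert parse_model(serialize_model(model)).reaction_ids == model.reaction_ids
print("round-trip: ok")
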