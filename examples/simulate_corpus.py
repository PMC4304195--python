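"""Generate a labeled synthetic corpus with a planted hydropathy signal.

The generator tilts a flat residue composition along the planted scale
(+beta for the ordered class, -beta for the disordered class) and adds
an asymmetric K/E enrichment to the disordered class so its net charge
is elevated — the two compositional contrasts the C-H model relies on.
"""

import numpy as np

from idphydro import GeneratorParams, composition, generate, mean_hydropathy
from idphydro import planted_scale, prepare_scale

params = GeneratorParams(n_disordered=50, n_ordered=50, seed=7)
dataset = generate(params)
scale = prepare_scale(planted_scale(params))

stats = {"disordered": ([], []), "ordered": ([], [])}
for rec, label in zip(dataset.records, dataset.labels):
    h_list, r_list = stats[label]
    h_list.append(mean_hydropathy(rec, scale))
    r_list.append(abs(composition(rec).net_charge_signed))

print(f"{len(dataset.records)} proteins, lengths "
      f"{min(len(r) for r in dataset.records)}-"
      f"{max(len(r) for r in dataset.records)}, beta={params.beta}")
for label, (h, r) in stats.items():
    print(f"  {label:10s}: mean H = {np.mean(h):.3f}, mean R = {np.mean(r):.3f}")

print("\nThe ordered class sits higher on the hydropathy axis and lower "
      "on the charge axis, mirroring real structured-vs-disordered "
      "composition differences.")
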