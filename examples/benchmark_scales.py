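"""Benchmark several scales as C-H classifiers on one labeled corpus.

Each scale maps proteins to (H, R); a boundary is fitted per
cross-validation fold (intercept tuned to the F-optimal threshold) and
scored on held-out proteins.  A shuffled copy of the planted scale acts
as a negative control: it should rank clearly below the true scale.
"""

import dataclasses

import numpy as np

from idphydro import GeneratorParams, benchmark_scales, generate, planted_scale
from idphydro.scales import CANONICAL_RESIDUES

params = GeneratorParams(n_disordered=60, n_ordered=60, seed=3)
dataset = generate(params)
truth = planted_scale(params)

rng = np.random.default_rng(0)
shuffled_vals = rng.permutation(truth.as_array())
shuffled = dataclasses.replace(
    truth, id="shuffled_control",
    values=dict(zip(CANONICAL_RESIDUES, map(float, shuffled_vals))),
)

table = benchmark_scales(
    dataset.records, list(dataset.labels),
    {"planted": truth, "shuffled_control": shuffled},
    k=5, repeats=2, seed=3,
)
cols = ["scale", "sens_mean", "spec_mean", "bal_acc_mean", "auc_mean", "f_mean"]
print(table[cols].round(3).to_string(index=False))

print("\nScales are ranked by mean F-score across folds; the shuffled "
      "control destroys the residue-to-hydropathy mapping and should "
      "separate the classes far worse than the planted scale.")
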