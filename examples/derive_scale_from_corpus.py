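"""Derive a hydropathy scale from a labeled corpus and check its quality.

Windows of 41 residues become 21-feature rows (20 composition fractions
plus signed net charge); a class-weighted linear SVM is trained under
protein-level 10-fold cross-validation repeated 5 times, and the fold
weight-vectors are averaged into a scale.  On a synthetic corpus the
planted scale is known, so recovery can be measured directly.
"""

from idphydro import (
    GeneratorParams,
    derive_scale,
    generate,
    pearson_r,
    planted_scale,
    refit_whole_protein_boundary,
)
from idphydro.scales import CANONICAL_RESIDUES

params = GeneratorParams(n_disordered=100, n_ordered=100, seed=11)
dataset = generate(params)

derived = derive_scale(
    dataset.records, list(dataset.labels),
    window=41, k=10, repeats=2, seed=11,
)

truth = planted_scale(params)
r = pearson_r(derived.residue_weights, truth.as_array())
print(f"recovery: Pearson r(derived, planted) = {r:.3f} "
      f"over {len(derived.fold_models)} fold-models")

top = sorted(zip(CANONICAL_RESIDUES, derived.residue_weights),
             key=lambda kv: kv[1])
print("most disorder-promoting (most negative weights):",
      ", ".join(f"{k}={v:.2f}" for k, v in top[:3]))
print("most order-promoting (most positive weights):   ",
      ", ".join(f"{k}={v:.2f}" for k, v in top[-3:]))

boundary, heldout = refit_whole_protein_boundary(
    derived, dataset.records, list(dataset.labels))
print(f"\nwhole-protein boundary: R = {boundary.a:.2f} * H + {boundary.b:.2f}")
print(f"held-out balanced accuracy = {heldout.balanced_acc:.3f}, "
      f"AUC = {heldout.auc:.3f}")
print("\nNegative weights mark residues enriched in disordered sequences; "
      "the refitted line separates whole proteins in the C-H plane.")
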