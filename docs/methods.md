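# Methods

## The charge–hydropathy model

The model assumes two opposing compositional forces decide whether a
protein folds: net charge repulsion favours the unfolded ensemble,
mean hydrophobicity favours a collapsed, folded state.  Both are pure
composition statistics — residue order never enters — so a protein is
a single point (H, R):

* H = c · s, where c is the 20-vector of composition fractions and s a
  hydropathy scale oriented hydrophobic-positive and min–max
  normalized to [0, 1]; hence H ∈ [0, 1].
* R = |(n_R + n_K − n_E − n_D)| / L ∈ [0, 1].  Histidine is treated as
  uncharged: at neutral pH its contribution is small and ambiguous,
  and the charge definition used throughout names only R, K, E, D.

A linear boundary R = a·H + b classifies: strictly above → disordered,
on or below → ordered.  The on-line tie goes to *ordered* because
specificity (correct structured calls) is the dominant behaviour of
C-H classifiers; the choice only matters on a measure-zero set.
Boundaries are stored in explicit line form; a fitted separator whose
charge-axis weight is ~0 (vertical line) or positive (disordered side
below the line) cannot be expressed in this convention and is rejected
with a dedicated error rather than silently re-parameterized.

Bundled scales: Kyte–Doolittle (1982) and IDP-Hydropathy are
hydrophobic-positive; Guy (1985) uses the inverted transfer-free-energy
convention and is negated before normalization.  Orientation is
explicit metadata, not inferred from signs, because scales legitimately
mix signs.  The published IDP-Hydropathy histidine value (+2.18) breaks
the otherwise descending order of the printed scale and may be a sign
typo; the bundled scale keeps the printed value, and
`get_builtin_scale("idp_hydropathy", his_sign_flipped=True)` exposes
the −2.18 variant without asserting either as ground truth.

## Scale derivation

Training examples are uniform 41-residue windows: consecutive
non-overlapping windows from position 0, plus a final window anchored
at the sequence end when the trailing remainder is ≥ width/2 (shorter
remainders are dropped; sequences shorter than the window are used
whole).  The end-anchored rule keeps window length uniform — the point
of windowing is removing length-dependent composition variation —
without discarding large tails.  Each window contributes a row of 21
features: 20 composition fractions and the signed normalized net
charge (the sign carries information during training; only the C-H
plot itself uses |R|).  Disordered windows are labelled −1 so that a
negative learned weight marks a disorder-promoting residue, matching
the hydropathy sign convention.

The classifier is a linear SVM (liblinear, squared hinge, primal) with
per-class misclassification weights.  Default weights are inversely
proportional to class frequency, normalized to mean one over the
samples (w_c = n / (2 n_c)); the per-sample cost is C·w_c with C = 1.0
by default.  This keeps the cost scale of a weighted fit comparable to
an unweighted fit of the same size.  A consequence worth knowing:
duplicating every training row doubles the effective C, so the fitted
direction is only *approximately* duplication-invariant (cosine
> 0.99 in practice).  An exactly invariant alternative — normalizing
the weighted loss to an average — was evaluated and rejected because
the fixed loss-to-regularizer ratio over-regularizes small problems,
most visibly the two-feature boundary fit, where the intercept
collapses (held-out balanced accuracy ≈ 0.58 at AUC ≈ 1.0).

Cross-validation is at the protein level: a protein's windows never
straddle a train/test split.  Proteins are dealt to 10 folds greedily
in descending window count (each to the currently lightest fold), which
bounds the spread of fold window-totals by the largest single protein;
a repair pass swaps closest-sized proteins if a fold ends up without
one of the classes (requires a pathological size distribution).  The
whole procedure is repeated 5 times with fold assignments reseeded from
a master seed (one `SeedSequence` fan-out per repeat), and the final
scale is the plain mean of the 20 composition weights over all 50
fold-models.  All fold-models, their metrics, and the assignments are
retained so the average is auditable.  Averaged weights are reported
raw plus as a [0, 1]-normalized view; no attempt is made to reproduce
any particular published magnitude scaling, which Pearson-based
comparisons ignore anyway.

For whole-protein classification the averaged scale is oriented and
normalized, every protein becomes a C-H point, and a two-feature
weighted SVM is fitted per stored cross-validation split; the reported
boundary is the element-wise mean of the per-fold (a, b) and the
held-out report pools predictions across splits.  Where an F-optimal
operating point is wanted (the benchmark), the intercept is shifted by
the threshold that maximizes F on the training folds, found by an
exhaustive sweep over midpoints of adjacent sorted decision scores
with ties broken toward the higher threshold (higher specificity).

## Evaluation suite

All metrics treat disordered as the positive class.  Any metric with a
zero denominator is reported as an explicit `None`, never silently 0:
degenerate folds should be visible, not averaged away.  Fold-wise
aggregation skips undefined entries and counts them.  The "±" values
reported by the benchmark are sample (n−1) standard deviations across
fold-models; pooled values over all held-out predictions are reported
alongside.  AUC uses the Mann–Whitney rank identity with average ranks
(ties credited 0.5), which equals the trapezoidal area under the
empirical ROC; the test suite verifies this against exhaustive
concordant-pair counting.

## Correlation analysis

Pearson r over the 20 residue values, residue-aligned by one-letter
code.  Constant indices are skipped with a warning (correlation is
undefined).  Cluster summaries of |r| use sample standard deviation;
singleton clusters report it as undefined.  Index collections are read
from a simplified TSV (id, cluster, 20 values) — native AAindex flat
files are out of scope, and the particular index subsets behind any
published cluster table are user-supplied.

## Synthetic corpus generator

The generator emulates the compositional contrast the C-H model
assumes, with a known recovery target.  Let u be the planted scale's
value vector, mean-centered and scaled to unit L2 norm.  Class
composition priors are exponential tilts of a flat background:
log-weights = s·β·u with s = +1 (ordered) / −1 (disordered), plus an
asymmetric charge tilt for the disordered class (+γ on K, +γ/2 on E)
that raises its |net charge|.  Per protein, a composition is drawn
from Dirichlet(α·prior) and residues are sampled i.i.d.; lengths are
uniform on [82, 410] so every sequence yields at least two windows.

Because the planted direction enters the class log-odds linearly in
composition space, it is the Bayes-optimal linear direction there,
giving a principled target for the SVM derivation.  Defaults — 300
proteins per class, β = 2, γ = 1, α = 50 — produce a clear but not
trivial separation: mean H differs by ≈ 0.25 normalized units between
classes and the disordered class carries visibly higher net charge.
At β = γ = 0 the classes are exchangeable and derived weights must not
correlate with the planted scale (the null control).

What the generator does *not* emulate: domain architecture, local
sequence order effects, MoRF-like structure-prone segments inside
disordered regions, length–composition correlations, or database
curation biases.  Passing tests on synthetic corpora therefore
demonstrate that the pipeline recovers a planted compositional signal
and classifies under the stated model — not that any particular
accuracy will be reached on curated disorder databases, which differ
in all the ways above.  Real corpora are supported as FASTA plus a
manifest TSV of labels.

## Numerical and interface choices

* Composition features ignore non-canonical letters (B, J, O, U, X, Z,
  `*`) under the default skip policy, with a hard error when they
  exceed 10% of a sequence of length ≥ 10 (on shorter fragments a
  single odd letter already exceeds 10%, which would make the skip
  policy unusable).
* liblinear runs in the primal with tol = 1e-10 and a high iteration
  cap, making fits deterministic for a fixed seed and data order.
* Problem sizes in tests and the acceptance script (300 + 300 proteins,
  10 × 5 cross-validation; smaller corpora for unit tests) were chosen
  so the full suite completes in well under a minute on one CPU while
  leaving the planted-signal checks comfortably powered.
* Scale TSVs render values with `repr`, so write → read round-trips
  are bit-exact.
* The 21st training feature defaults to *signed* net charge; an
  `abs` option exists because whole-protein C-H plots use |R| and
  either convention is defensible for windows.

## Known limitations

* Only single linear boundaries; no probability calibration, no
  per-residue (sliding-window) disorder profiles.
* Charge model is pH-independent and ignores histidine and termini.
* The derived-scale magnitude is arbitrary up to the SVM's cost
  scaling; only relative values (and the [0, 1] view) are meaningful.
* Duplication of training rows rescales the effective cost (see
  above); exact invariance was deliberately traded away.
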