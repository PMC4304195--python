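"""Deriving a hydropathy scale from labeled sequences with a linear SVM.

The central idea: represent each 41-residue sequence window by its 20
amino-acid composition fractions plus its signed normalized net charge
(21 features), label windows from disordered proteins -1 and windows
from structured proteins +1, and train a class-weighted linear
max-margin classifier.  The 20 composition weights of the fitted
hyperplane, suitably normalized, ARE an amino-acid scale: a negative
weight marks a disorder-promoting residue (the Kyte-Doolittle energy
convention), a positive weight an order-promoting one.

Training uses protein-level 10-fold cross-validation repeated 5 times
(windows of one protein never straddle a train/test split), the weight
vectors of all folds are averaged into the final scale, and a
whole-protein charge-hydropathy boundary is refitted per fold and
averaged.  Class weights default to inverse class frequency so that
misclassifying the under-represented disordered class costs more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chplot import LinearBoundary, _fit_weighted_svc, ch_point, fit_boundary
from .evaluation import (
    MetricsReport,
    aggregate_reports,
    confusion,
    metrics,
    roc_auc,
)
from .features import DEFAULT_WINDOW, SequenceRecord, chop_windows, composition
from .io import DISORDERED, LABELS, ORDERED
from .scales import CANONICAL_RESIDUES, AminoAcidScale, prepare_scale

__all__ = [
    "TrainingMatrix",
    "LinearModel",
    "DerivedScale",
    "build_training_matrix",
    "train_weighted_linear",
    "assign_folds",
    "derive_scale",
    "refit_whole_protein_boundary",
    "optimize_threshold_for_f",
]

Y_DISORDERED = -1
Y_ORDERED = +1


@dataclass(frozen=True)
class TrainingMatrix:
    """n x 21 feature matrix (20 compositions + net charge) with ±1 targets."""

    X: np.ndarray
    Y: np.ndarray
    provenance: tuple[tuple[str, str], ...]  # (protein id, window id) per row

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 21:
            raise ValueError(f"X must be n x 21, got shape {X.shape}")
        if Y.shape != (X.shape[0],):
            raise ValueError("Y must be parallel to X rows")
        if not set(np.unique(Y)) <= {Y_DISORDERED, Y_ORDERED}:
            raise ValueError("Y values must be -1 or +1")
        if not np.allclose(X[:, :20].sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("composition columns of each row must sum to 1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class LinearModel:
    """A fitted 21-weight linear classifier; positive decision => ordered."""

    w: np.ndarray  # shape (21,): 20 residue weights + 1 charge weight
    b: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (21,) or not np.all(np.isfinite(w)):
            raise ValueError("w must be 21 finite weights")
        object.__setattr__(self, "w", w)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict_labels(self, X: np.ndarray) -> list[str]:
        return [ORDERED if d > 0 else DISORDERED for d in self.decision(X)]


@dataclass(frozen=True)
class DerivedScale:
    """The averaged scale plus full per-fold provenance.

    ``residue_weights`` is the mean of the 20 composition weights over
    every fold-model (k folds x repeats), ``charge_weight`` the mean
    21st weight, ``bias`` the mean intercept.  ``fold_models`` keeps all
    the individual models so the averaging is verifiable, and
    ``fold_assignments[r][i]`` gives protein i's fold in repeat r.
    """

    residue_weights: np.ndarray  # (20,), ordered by CANONICAL_RESIDUES
    charge_weight: float
    bias: float
    fold_models: tuple[LinearModel, ...]
    fold_reports: tuple[MetricsReport, ...]
    fold_assignments: tuple[tuple[int, ...], ...]
    pooled_report: MetricsReport
    seed: int

    def to_scale(self, scale_id: str = "derived") -> AminoAcidScale:
        """Raw averaged weights as a hydrophobic-positive scale."""
        return AminoAcidScale(
            id=scale_id,
            values=dict(zip(CANONICAL_RESIDUES, map(float, self.residue_weights))),
            orientation="hydrophobic_positive",
            source="derived from labeled corpus by weighted linear SVM",
        )

    def to_normalized_scale(self, scale_id: str = "derived") -> AminoAcidScale:
        """Unit-normalized [0, 1] view of the averaged weights."""
        return prepare_scale(self.to_scale(scale_id))

    def cv_summary(self) -> dict:
        return {
            "per_fold": aggregate_reports(list(self.fold_reports)),
            "pooled": self.pooled_report.as_dict(),
            "n_models": len(self.fold_models),
        }


def _label_to_y(label: str) -> int:
    if label == DISORDERED:
        return Y_DISORDERED
    if label == ORDERED:
        return Y_ORDERED
    raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")


def build_training_matrix(
    windows: Sequence[SequenceRecord],
    labels: Sequence[str],
    charge_feature: str = "signed",
) -> TrainingMatrix:
    """One 21-feature row per labeled window.

    Column 21 is the signed normalized net charge by default
    (``charge_feature="abs"`` switches to the absolute value).
    Disordered windows get target -1, ordered +1.
    """
    if len(windows) == 0:
        raise ValueError("no windows supplied")
    if len(windows) != len(labels):
        raise ValueError("windows and labels must be parallel")
    if charge_feature not in ("signed", "abs"):
        raise ValueError(f"unknown charge_feature {charge_feature!r}")
    rows = np.empty((len(windows), 21))
    ys = np.empty(len(windows), dtype=int)
    prov = []
    for i, (win, label) in enumerate(zip(windows, labels)):
        cv = composition(win)
        charge = cv.net_charge_signed
        if charge_feature == "abs":
            charge = abs(charge)
        rows[i, :20] = cv.comp
        rows[i, 20] = charge
        ys[i] = _label_to_y(label)
        pid = win.id.split("|w")[0]
        prov.append((pid, win.id))
    return TrainingMatrix(X=rows, Y=ys, provenance=tuple(prov))


def train_weighted_linear(
    X: np.ndarray,
    Y: np.ndarray,
    class_weights: dict[int, float] | None = None,
    regularization: float = 1.0,
    seed: int = 0,
) -> LinearModel:
    """Fit the class-weighted linear max-margin model on 21-feature rows.

    Default class weights are inversely proportional to class frequency
    (the under-represented disordered class is penalised more when
    misclassified), normalized to mean one over the samples.
    Deterministic given the seed.
    """
    model = _fit_weighted_svc(
        np.asarray(X, dtype=float),
        np.asarray(Y, dtype=int),
        class_weights,
        regularization,
        seed,
    )
    return LinearModel(
        w=model.coef_[0].copy(),
        b=float(model.intercept_[0]),
        meta={
            "class_weights": class_weights or "inverse_frequency",
            "regularization": regularization,
            "seed": seed,
        },
    )


def assign_folds(
    labels: Sequence[str],
    window_counts: Sequence[int],
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Protein-level fold assignment balancing window totals.

    Proteins (never their individual windows) are dealt to ``k`` folds
    greedily in descending window count, each to the currently lightest
    fold, so fold window-totals differ by at most the largest single
    protein's window count.  A repair pass then swaps same-sized
    proteins between folds if any fold ended up without one of the two
    classes (rare; it needs a pathological size distribution).  Ties are
    broken by a seeded shuffle, so the assignment is deterministic per
    seed.

    Returns the fold index (0..k-1) of each protein.
    """
    labels = list(labels)
    window_counts = list(window_counts)
    if len(labels) != len(window_counts):
        raise ValueError("labels and window_counts must be parallel")
    for label in LABELS:
        n_class = sum(1 for l in labels if l == label)
        if n_class < k:
            raise ValueError(
                f"need at least k={k} proteins of class {label!r}, "
                f"have {n_class}"
            )
    rng = np.random.default_rng(seed)
    n = len(labels)
    order = rng.permutation(n)  # seeded tie-break among equal counts
    order = sorted(order, key=lambda i: -window_counts[i])
    assignment = np.full(n, -1, dtype=int)
    totals = np.zeros(k, dtype=int)
    for i in order:
        f = int(np.argmin(totals))  # first-lightest fold, stable
        assignment[i] = f
        totals[f] += window_counts[i]
    # coverage repair: every fold must contain both classes.  Swap the
    # closest-sized pair (a protein of the missing class from a fold
    # holding >= 2 of them, against one of the deficient fold's
    # proteins) so totals stay balanced.
    for label in LABELS:
        is_label = np.array([l == label for l in labels])
        for f in range(k):
            if np.any(is_label[assignment == f]):
                continue
            takes = np.flatnonzero(assignment == f)
            best = None
            for d in range(k):
                gives = np.flatnonzero(is_label & (assignment == d))
                if d == f or len(gives) < 2:
                    continue
                for g in gives:
                    if len(takes) < 2:  # cannot swap out f's only protein
                        if best is None or window_counts[g] < best[0]:
                            best = (window_counts[g], g, None, d)
                        continue
                    for t in takes:
                        diff = abs(window_counts[g] - window_counts[t])
                        if best is None or diff < best[0]:
                            best = (diff, g, t, d)
            if best is None:
                raise ValueError(
                    f"cannot place class {label!r} into every fold; "
                    "reduce k or supply more proteins"
                )
            _, g, t, d = best
            assignment[g] = f
            if t is not None:
                assignment[t] = d
    return assignment


def derive_scale(
    records: Sequence[SequenceRecord],
    labels: Sequence[str],
    window: int = DEFAULT_WINDOW,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    class_weights: dict[int, float] | None = None,
    regularization: float = 1.0,
    charge_feature: str = "signed",
) -> DerivedScale:
    """Run the full cross-validated scale derivation.

    For each repeat, proteins are assigned to ``k`` folds; for each
    fold, windows of the remaining k-1 folds train a weighted linear
    model which is then evaluated on the held-out fold's windows.  The
    final scale is the mean of the 20 residue weights over all
    k x repeats fold-models; every fold-model and its metrics are kept
    so the average is auditable.  Bitwise deterministic given the seed.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must be parallel")
    # chop once; windows inherit their protein's label
    per_protein_windows = [chop_windows(rec, width=window) for rec in records]
    window_counts = [len(w) for w in per_protein_windows]

    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) for s in ss.generate_state(2 * repeats) % (2**31)]

    fold_models: list[LinearModel] = []
    fold_reports: list[MetricsReport] = []
    assignments: list[tuple[int, ...]] = []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    pooled_scores: list[float] = []

    for r in range(repeats):
        fold_of = assign_folds(labels, window_counts, k=k, seed=repeat_seeds[r])
        assignments.append(tuple(int(f) for f in fold_of))
        for f in range(k):
            train_wins, train_labels = [], []
            test_wins, test_labels = [], []
            for i, wins in enumerate(per_protein_windows):
                dest = (test_wins, test_labels) if fold_of[i] == f else (
                    train_wins, train_labels)
                dest[0].extend(wins)
                dest[1].extend([labels[i]] * len(wins))
            tm_train = build_training_matrix(
                train_wins, train_labels, charge_feature)
            tm_test = build_training_matrix(
                test_wins, test_labels, charge_feature)
            model = train_weighted_linear(
                tm_train.X, tm_train.Y,
                class_weights=class_weights,
                regularization=regularization,
                seed=repeat_seeds[repeats + r],
            )
            pred = model.predict_labels(tm_test.X)
            # larger score = more disordered, for ROC orientation
            scores = (-model.decision(tm_test.X)).tolist()
            report = metrics(confusion(pred, test_labels))
            try:
                auc = roc_auc(scores, test_labels)
            except ValueError:
                auc = None
            report = _with_auc(report, auc)
            fold_models.append(model)
            fold_reports.append(report)
            pooled_true.extend(test_labels)
            pooled_pred.extend(pred)
            pooled_scores.extend(scores)

    W = np.stack([m.w for m in fold_models])
    pooled = _with_auc(
        metrics(confusion(pooled_pred, pooled_true)),
        roc_auc(pooled_scores, pooled_true),
    )
    return DerivedScale(
        residue_weights=W[:, :20].mean(axis=0),
        charge_weight=float(W[:, 20].mean()),
        bias=float(np.mean([m.b for m in fold_models])),
        fold_models=tuple(fold_models),
        fold_reports=tuple(fold_reports),
        fold_assignments=tuple(assignments),
        pooled_report=pooled,
        seed=seed,
    )


def _with_auc(report: MetricsReport, auc: float | None) -> MetricsReport:
    return MetricsReport(
        acc=report.acc,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        balanced_acc=report.balanced_acc,
        ppv=report.ppv,
        npv=report.npv,
        f=report.f,
        mcc=report.mcc,
        auc=auc,
    )


def refit_whole_protein_boundary(
    derived: DerivedScale,
    records: Sequence[SequenceRecord],
    labels: Sequence[str],
    regularization: float = 1.0,
) -> tuple[LinearBoundary, MetricsReport]:
    """Reassemble windows into whole proteins and fit the C-H boundary.

    The derived residue weights are oriented and unit-normalized into a
    scale; every protein becomes a whole-sequence (H, R) point.  For
    each stored cross-validation split a boundary is fitted on the
    training proteins and evaluated on the held-out proteins; the
    returned boundary is the element-wise mean of all per-fold
    boundaries and the report pools the held-out predictions (with AUC
    from the boundary decision scores).
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must be parallel")
    scale = derived.to_normalized_scale()
    points = [
        ch_point(rec, scale, label=lab)
        for rec, lab in zip(records, labels)
    ]
    from .chplot import classify as classify_point
    from .chplot import decision_score

    slopes, intercepts = [], []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    pooled_scores: list[float] = []
    for fold_of in derived.fold_assignments:
        fold_of = np.asarray(fold_of)
        for f in sorted(set(fold_of.tolist())):
            train_pts = [p for p, g in zip(points, fold_of) if g != f]
            test_idx = [i for i, g in enumerate(fold_of) if g == f]
            boundary = fit_boundary(
                train_pts, regularization=regularization, seed=derived.seed)
            slopes.append(boundary.a)
            intercepts.append(boundary.b)
            for i in test_idx:
                pooled_true.append(labels[i])
                pooled_pred.append(classify_point(points[i], boundary))
                pooled_scores.append(decision_score(points[i], boundary))
    mean_boundary = LinearBoundary(
        a=float(np.mean(slopes)), b=float(np.mean(intercepts)))
    report = _with_auc(
        metrics(confusion(pooled_pred, pooled_true)),
        roc_auc(pooled_scores, pooled_true),
    )
    return mean_boundary, report


def optimize_threshold_for_f(
    scores: Sequence[float], labels: Sequence[str]
) -> float:
    """Decision threshold maximising the F-score (disordered positive).

    ``scores`` must be oriented so larger means more disordered; a point
    is predicted disordered iff its score exceeds the threshold.
    Candidate thresholds are the midpoints between adjacent sorted
    unique scores plus one sentinel below the minimum and one above the
    maximum; ties on F are broken toward the higher threshold (higher
    specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels) or len(scores) == 0:
        raise ValueError("scores and labels must be parallel and non-empty")
    present = set(labels.tolist())
    if not ({DISORDERED, ORDERED} <= present):
        raise ValueError("both classes must be present to optimize F")
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates += [0.5 * (uniq[i] + uniq[i + 1]) for i in range(len(uniq) - 1)]
    candidates.append(uniq[-1] + 1.0)
    is_dis = labels == DISORDERED
    best_t, best_f = None, -1.0
    for t in candidates:  # ascending, so >= keeps the highest tying threshold
        pred_pos = scores > t
        tp = int(np.sum(pred_pos & is_dis))
        fp = int(np.sum(pred_pos & ~is_dis))
        fn = int(np.sum(~pred_pos & is_dis))
        if tp + fp == 0 or tp + fn == 0:
            continue  # F undefined at this cut
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        f = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        if f >= best_f:
            best_f, best_t = f, float(t)
    assert best_t is not None  # all-positive cut always defines F
    return best_t
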