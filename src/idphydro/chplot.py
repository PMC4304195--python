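"""The charge-hydropathy plane: points, linear boundaries, classification.

A protein maps to a point (H, R) where H is its mean normalized
hydropathy and R its absolute normalized net charge.  The model is that
charge repulsion favors unfolding while hydropathy favors folding, so a
straight line <charge> = a * <hydropathy> + b separates intrinsically
disordered proteins (above the line: high charge, low hydropathy) from
structured ones (below).  Published boundaries for the three bundled
scales are available via :func:`builtin_boundary`; new boundaries are
fitted from labeled points with a class-weighted linear max-margin
classifier (liblinear).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .features import SequenceRecord, mean_hydropathy, net_charge_abs
from .io import DISORDERED, ORDERED
from .scales import AminoAcidScale, UnknownScaleError, prepare_scale

__all__ = [
    "CHPoint",
    "LinearBoundary",
    "BoundaryOrientationError",
    "ch_point",
    "builtin_boundary",
    "classify",
    "decision_score",
    "fit_boundary",
    "plot_ch",
]


class BoundaryOrientationError(ValueError):
    """Fitted separator cannot be expressed as 'disordered iff R > aH + b'."""


@dataclass(frozen=True)
class CHPoint:
    """A protein's coordinates in the C-H plane, optionally labeled."""

    H: float
    R: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.H <= 1 + 1e-9):
            raise ValueError(f"H must lie in [0, 1], got {self.H}")
        if not (-1e-9 <= self.R <= 1 + 1e-9):
            raise ValueError(f"R must lie in [0, 1], got {self.R}")
        if self.label is not None and self.label not in (DISORDERED, ORDERED):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class LinearBoundary:
    """The decision line <charge> = a * <hydropathy> + b.

    Convention: a point is predicted disordered iff R > a*H + b; a point
    exactly on the line is predicted ordered.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("boundary coefficients must be finite")


#: Published C-H boundary lines for the bundled scales.
_BUILTIN_BOUNDARIES = {
    "idp_hydropathy": LinearBoundary(a=3.31, b=-0.97),
    "guy": LinearBoundary(a=2.32, b=-0.93),
    "kyte_doolittle": LinearBoundary(a=1.35, b=-0.49),
}


def builtin_boundary(scale_name: str) -> LinearBoundary:
    """Published boundary line for a bundled scale."""
    try:
        return _BUILTIN_BOUNDARIES[scale_name]
    except KeyError:
        raise UnknownScaleError(
            f"no builtin boundary for {scale_name!r}; available: "
            f"{', '.join(sorted(_BUILTIN_BOUNDARIES))}"
        ) from None


def ch_point(
    record: SequenceRecord,
    scale: AminoAcidScale,
    label: str | None = None,
) -> CHPoint:
    """Map a sequence to the C-H plane under a scale.

    The scale is oriented hydrophobic-positive and unit-normalized
    internally if needed, so any valid scale is accepted.
    """
    if scale.orientation != "hydrophobic_positive" or not scale.normalized:
        scale = prepare_scale(scale)
    return CHPoint(
        H=mean_hydropathy(record, scale),
        R=net_charge_abs(record),
        label=label,
    )


def decision_score(point: CHPoint, boundary: LinearBoundary) -> float:
    """Signed distance surrogate R - (a*H + b); positive => disordered.

    Monotone in R at fixed H, so it ranks points for ROC analysis.
    """
    return point.R - (boundary.a * point.H + boundary.b)


def classify(point: CHPoint, boundary: LinearBoundary) -> str:
    """Predict disordered iff the point lies strictly above the line."""
    return DISORDERED if decision_score(point, boundary) > 0 else ORDERED


def fit_boundary(
    points: Sequence[CHPoint],
    class_weights: dict[str, float] | None = None,
    regularization: float = 1.0,
    seed: int = 0,
) -> LinearBoundary:
    """Fit the C-H decision line from labeled points.

    Trains a two-feature linear max-margin classifier (squared-hinge
    liblinear) on (H, R) with targets disordered = -1, ordered = +1 and
    per-class misclassification weights (default: inverse class
    frequency), then converts its weight vector (w_H, w_R, bias) to the
    explicit line a = -w_H / w_R, b = -bias / w_R.

    Raises
    ------
    ValueError
        If fewer than two points or only one class is present.
    BoundaryOrientationError
        If |w_R| is numerically zero (a vertical line, not representable
        as R = aH + b) or w_R > 0 (the disordered half-plane would lie
        below the line, violating the fixed classification convention).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 labeled points to fit a boundary")
    labels = [p.label for p in points]
    if any(l is None for l in labels):
        raise ValueError("all points must carry a label")
    X = np.array([[p.H, p.R] for p in points])
    y = np.array([-1 if l == DISORDERED else 1 for l in labels])
    model = _fit_weighted_svc(X, y, class_weights, regularization, seed)
    w_h, w_r = model.coef_[0]
    bias = float(model.intercept_[0])
    if abs(w_r) <= 1e-12:
        raise BoundaryOrientationError(
            "fitted separator is vertical (charge weight ~ 0); "
            "not representable as R = a*H + b"
        )
    if w_r > 0:
        raise BoundaryOrientationError(
            "fitted separator places the disordered class below the line; "
            "not representable under the 'disordered iff R > a*H + b' "
            "convention"
        )
    return LinearBoundary(a=float(-w_h / w_r), b=float(-bias / w_r))


def _fit_weighted_svc(
    X: np.ndarray,
    y: np.ndarray,
    class_weights: dict | None,
    regularization: float,
    seed: int,
) -> LinearSVC:
    """Shared liblinear fit with per-class misclassification weights.

    Default class weights are inversely proportional to class frequency
    and normalized to mean one over the samples (w_c = n / (K * n_c)),
    so the minority class is up-weighted while the overall cost scale
    matches an unweighted fit of the same size.  The per-sample
    liblinear cost is C * w_c.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for training")
    n = len(y)
    if class_weights is None:
        weight_of = {c: n / (len(classes) * cnt)
                     for c, cnt in zip(classes, counts)}
    else:
        weight_of = dict(class_weights)
        missing = [c for c in classes if c not in weight_of]
        if missing:
            raise ValueError(f"class_weights missing entries for {missing}")
    sample_weight = np.array([weight_of[c] for c in y])
    model = LinearSVC(
        C=regularization,
        loss="squared_hinge",
        dual=False,
        tol=1e-10,
        max_iter=100_000,
        random_state=seed % (2**31),
    )
    model.fit(X, y, sample_weight=sample_weight)
    return model


def plot_ch(
    points: Iterable[CHPoint],
    boundary: LinearBoundary | None = None,
    path: str | None = None,
    title: str = "Charge-Hydropathy plot",
):
    """Scatter labeled/unlabeled C-H points with an optional boundary line.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    pts = list(points)
    groups = {
        DISORDERED: ("red", [p for p in pts if p.label == DISORDERED]),
        ORDERED: ("blue", [p for p in pts if p.label == ORDERED]),
        "unlabeled": ("gray", [p for p in pts if p.label is None]),
    }
    for name, (color, grp) in groups.items():
        if grp:
            ax.scatter(
                [p.H for p in grp], [p.R for p in grp],
                s=12, c=color, alpha=0.6, label=name,
            )
    if boundary is not None:
        h = np.linspace(0, 1, 50)
        r = boundary.a * h + boundary.b
        ax.plot(h, r, "k-", lw=1)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, max(0.6, max((p.R for p in pts), default=0.6) * 1.1))
    ax.set_xlabel("mean normalized hydropathy")
    ax.set_ylabel("absolute normalized net charge")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
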