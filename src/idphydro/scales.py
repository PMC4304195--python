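"""Amino-acid scale representation, orientation, normalization and TSV IO.

A hydropathy scale assigns one real number to each of the 20 canonical
amino acids.  Scales in the literature disagree on sign convention:
Kyte-Doolittle-style scales give hydrophobic residues positive values
("hydrophobic_positive"), while e.g. Guy's transfer-free-energy scale is
inverted ("hydrophilic_positive").  For charge-hydropathy analysis every
scale is first oriented hydrophobic-positive and then min-max normalized
to [0, 1], so that the composition-weighted mean hydropathy of any
sequence lies in [0, 1].

Three scales are bundled: the classic Kyte-Doolittle (1982) scale, the
Guy (1985) transfer-free-energy scale, and the IDP-Hydropathy scale
derived from disordered/structured sequence sets via a linear SVM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

__all__ = [
    "CANONICAL_RESIDUES",
    "AminoAcidScale",
    "DegenerateScaleError",
    "ScaleFormatError",
    "UnknownScaleError",
    "builtin_scale_names",
    "get_builtin_scale",
    "orient_hydrophobic_positive",
    "normalize_unit",
    "read_scale_tsv",
    "write_scale_tsv",
]

#: Canonical one-letter residue codes in alphabetical order.  All
#: composition vectors and scale value arrays in this package follow
#: this ordering.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

HYDROPHOBIC_POSITIVE = "hydrophobic_positive"
HYDROPHILIC_POSITIVE = "hydrophilic_positive"
_ORIENTATIONS = (HYDROPHOBIC_POSITIVE, HYDROPHILIC_POSITIVE)


class UnknownScaleError(KeyError):
    """Requested builtin scale name does not exist."""


class DegenerateScaleError(ValueError):
    """Scale is constant (max == min) and cannot be normalized."""


class ScaleFormatError(ValueError):
    """Scale TSV file is malformed (missing/duplicate/unknown residues)."""


@dataclass(frozen=True)
class AminoAcidScale:
    """A 20-value amino-acid scale with orientation metadata.

    Parameters
    ----------
    id : str
        Short identifier, e.g. ``"kyte_doolittle"``.
    values : Mapping[str, float]
        Value for each of the 20 canonical one-letter residue codes.
    orientation : str
        ``"hydrophobic_positive"`` if larger values mean more hydrophobic
        (Kyte-Doolittle convention), ``"hydrophilic_positive"`` for the
        inverted convention (Guy).
    normalized : bool
        True iff values span exactly [0, 1].
    source : str
        Free-text citation.
    """

    id: str
    values: Mapping[str, float]
    orientation: str = HYDROPHOBIC_POSITIVE
    normalized: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        got = set(self.values)
        if got != _CANONICAL_SET:
            missing = sorted(_CANONICAL_SET - got)
            extra = sorted(got - _CANONICAL_SET)
            raise ScaleFormatError(
                f"scale {self.id!r} must define exactly the 20 canonical "
                f"residues; missing={missing} extra={extra}"
            )
        vals = list(self.values.values())
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"scale {self.id!r} contains non-finite values")
        if max(vals) <= min(vals):
            raise DegenerateScaleError(
                f"scale {self.id!r} is constant (max == min)"
            )
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {_ORIENTATIONS}, "
                f"got {self.orientation!r}"
            )
        if self.normalized:
            if abs(min(vals)) > 1e-12 or abs(max(vals) - 1.0) > 1e-12:
                raise ValueError(
                    f"scale {self.id!r} flagged normalized but spans "
                    f"[{min(vals)}, {max(vals)}]"
                )
        # freeze the mapping so the dataclass is genuinely immutable
        object.__setattr__(self, "values", dict(self.values))

    def as_array(self):
        """Values as a numpy array ordered by :data:`CANONICAL_RESIDUES`."""
        import numpy as np

        return np.array([self.values[r] for r in CANONICAL_RESIDUES])

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


# -- bundled scales ---------------------------------------------------------

_IDP_HYDROPATHY = {
    "W": 10.66, "Y": 6.64, "I": 6.19, "F": 5.79, "C": 5.62,
    "L": 5.17, "V": 4.64, "M": 2.49, "N": 2.06, "T": 1.22,
    "A": 0.91, "R": 0.07, "G": 0.02, "D": -0.48, "Q": -1.23,
    "S": -1.84, "H": 2.18, "E": -2.20, "K": -2.43, "P": -3.89,
}

_GUY = {
    "W": -0.51, "Y": -0.21, "I": -1.13, "F": -2.12, "C": -1.42,
    "L": -1.18, "V": -1.27, "M": -1.59, "N": 0.48, "T": 0.07,
    "A": 0.10, "R": 1.91, "G": 0.33, "D": 0.78, "Q": 0.83,
    "S": 0.52, "H": -0.50, "E": 0.95, "K": 1.40, "P": 0.73,
}

_KYTE_DOOLITTLE = {
    "W": -0.90, "Y": -1.30, "I": 4.50, "F": 2.80, "C": 2.50,
    "L": 3.80, "V": 4.20, "M": 1.90, "N": -3.50, "T": -0.70,
    "A": 1.80, "R": -4.50, "G": -0.40, "D": -3.50, "Q": -3.50,
    "S": -0.80, "H": -3.20, "E": -3.50, "K": -3.90, "P": -1.60,
}

_BUILTINS = {
    "idp_hydropathy": AminoAcidScale(
        id="idp_hydropathy",
        values=_IDP_HYDROPATHY,
        orientation=HYDROPHOBIC_POSITIVE,
        source="IDP-Hydropathy: SVM-derived order/disorder hydropathy scale",
    ),
    "guy": AminoAcidScale(
        id="guy",
        values=_GUY,
        orientation=HYDROPHILIC_POSITIVE,
        source="Guy HR (1985) Biophys J 47:61-70",
    ),
    "kyte_doolittle": AminoAcidScale(
        id="kyte_doolittle",
        values=_KYTE_DOOLITTLE,
        orientation=HYDROPHOBIC_POSITIVE,
        source="Kyte J, Doolittle RF (1982) J Mol Biol 157:105-132",
    ),
}

#: Names of disorder-propensity scales supported as user-supplied TSVs
#: (their full value sets are not bundled).
KNOWN_PROPENSITY_SCALE_NAMES = ("disprot", "top_idp", "fold_unfold", "b_value")


def builtin_scale_names() -> tuple[str, ...]:
    return tuple(_BUILTINS)


def get_builtin_scale(name: str, *, his_sign_flipped: bool = False) -> AminoAcidScale:
    """Return a bundled scale by identifier.

    Parameters
    ----------
    name : str
        One of ``idp_hydropathy``, ``guy``, ``kyte_doolittle``.
    his_sign_flipped : bool
        Only meaningful for ``idp_hydropathy``: the published histidine
        value (+2.18) sits out of the otherwise descending order of the
        scale and may be a sign typo.  Passing True returns the variant
        with H = -2.18.  Neither variant is asserted as ground truth.
    """
    try:
        scale = _BUILTINS[name]
    except KeyError:
        raise UnknownScaleError(
            f"unknown builtin scale {name!r}; available: "
            f"{', '.join(sorted(_BUILTINS))}"
        ) from None
    if his_sign_flipped:
        if name != "idp_hydropathy":
            raise ValueError("his_sign_flipped applies only to idp_hydropathy")
        vals = dict(scale.values)
        vals["H"] = -vals["H"]
        scale = replace(scale, id="idp_hydropathy_hneg", values=vals)
    return scale


# -- transforms -------------------------------------------------------------


def orient_hydrophobic_positive(scale: AminoAcidScale) -> AminoAcidScale:
    """Flip a hydrophilic-positive scale so hydrophobic residues score high.

    Idempotent: an already hydrophobic-positive scale is returned as-is.
    Negation invalidates a ``normalized`` flag, which is cleared.
    """
    if scale.orientation == HYDROPHOBIC_POSITIVE:
        return scale
    return replace(
        scale,
        values={r: -v for r, v in scale.values.items()},
        orientation=HYDROPHOBIC_POSITIVE,
        normalized=False,
    )


def normalize_unit(scale: AminoAcidScale) -> AminoAcidScale:
    """Min-max rescale values to [0, 1].

    Requires a hydrophobic-positive scale (orient first); preserves
    residue ranking.  Idempotent on already-normalized scales up to
    floating-point identity.
    """
    if scale.orientation != HYDROPHOBIC_POSITIVE:
        raise ValueError(
            f"scale {scale.id!r} must be oriented hydrophobic_positive "
            "before normalization"
        )
    lo = min(scale.values.values())
    hi = max(scale.values.values())
    if hi <= lo:  # unreachable for a valid AminoAcidScale; kept as a guard
        raise DegenerateScaleError(f"scale {scale.id!r} is constant")
    span = hi - lo
    return replace(
        scale,
        values={r: (v - lo) / span for r, v in scale.values.items()},
        normalized=True,
    )


def prepare_scale(scale: AminoAcidScale) -> AminoAcidScale:
    """Orient hydrophobic-positive then unit-normalize (the C-H convention)."""
    return normalize_unit(orient_hydrophobic_positive(scale))


# -- TSV IO -----------------------------------------------------------------


def write_scale_tsv(scale: AminoAcidScale, path: str | Path) -> None:
    """Write a scale to TSV with '#'-prefixed metadata lines.

    Values are rendered with :func:`repr`, which round-trips Python
    floats exactly.
    """
    path = Path(path)
    lines = [
        f"# id: {scale.id}",
        f"# orientation: {scale.orientation}",
        f"# normalized: {str(scale.normalized).lower()}",
        f"# source: {scale.source}",
        "residue\tvalue",
    ]
    for r in CANONICAL_RESIDUES:
        lines.append(f"{r}\t{scale.values[r]!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_scale_tsv(path: str | Path) -> AminoAcidScale:
    """Read a scale TSV written by :func:`write_scale_tsv` or hand-authored.

    Format: optional ``#`` metadata lines (``# id:``, ``# orientation:``,
    ``# normalized:``, ``# source:``), a ``residue<TAB>value`` header, then
    exactly one row per canonical residue.
    """
    path = Path(path)
    meta = {"id": path.stem, "orientation": HYDROPHOBIC_POSITIVE,
            "normalized": "false", "source": ""}
    values: dict[str, float] = {}
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key in meta:
                        meta[key] = val.strip()
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                fields = line.split()
            if len(fields) != 2:
                raise ScaleFormatError(f"{path}: malformed row {line!r}")
            residue, text = fields[0].strip(), fields[1].strip()
            if residue.lower() == "residue":
                continue
            if residue not in _CANONICAL_SET:
                raise ScaleFormatError(
                    f"{path}: unknown residue letter {residue!r}"
                )
            if residue in values:
                raise ScaleFormatError(f"{path}: duplicate residue {residue!r}")
            try:
                values[residue] = float(text)
            except ValueError:
                raise ScaleFormatError(
                    f"{path}: non-numeric value {text!r} for residue {residue}"
                ) from None
    missing = sorted(_CANONICAL_SET - set(values))
    if missing:
        raise ScaleFormatError(f"{path}: missing residues {missing}")
    return AminoAcidScale(
        id=meta["id"],
        values=values,
        orientation=meta["orientation"],
        normalized=meta["normalized"].lower() in ("true", "1", "yes"),
        source=meta["source"],
    )
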