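"""Per-sequence composition, net charge, mean hydropathy and windowing.

The charge-hydropathy model summarises a whole protein by two numbers:
its composition-weighted mean hydropathy under a normalized scale and
its normalized net charge |(#Arg + #Lys - #Glu - #Asp)| / length.  Both
depend only on amino-acid composition, never on residue order.
Histidine carries zero charge (charge at neutral pH is taken from R, K,
E, D only).

Training examples for scale derivation are uniform 41-residue windows;
:func:`chop_windows` implements the chopping policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scales import CANONICAL_RESIDUES, HYDROPHOBIC_POSITIVE, AminoAcidScale

__all__ = [
    "SequenceRecord",
    "CompositionVector",
    "composition",
    "net_charge_signed",
    "net_charge_abs",
    "mean_hydropathy",
    "chop_windows",
    "NonCanonicalResidueError",
    "EmptySequenceError",
]

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)
_RESIDUE_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}

#: Letters tolerated (and skipped) under the default non-canonical policy.
NONCANONICAL_LETTERS = frozenset("BJOUXZ*")

#: Hard cap on the tolerated fraction of non-canonical residues.
MAX_NONCANONICAL_FRACTION = 0.10

DEFAULT_WINDOW = 41


class EmptySequenceError(ValueError):
    """Sequence has no canonical residues to compute features from."""


class NonCanonicalResidueError(ValueError):
    """Sequence contains non-canonical residues disallowed by policy."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (uppercase one-letter codes)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CompositionVector:
    """The 21 composition features of a sequence.

    ``comp`` holds the 20 residue fractions (ordered by
    :data:`~idphydro.scales.CANONICAL_RESIDUES`), ``net_charge_signed``
    the signed normalized net charge (R + K - E - D fractions), and
    ``effective_length`` the number of canonical residues used.
    """

    comp: np.ndarray
    net_charge_signed: float
    effective_length: int
    n_noncanonical_skipped: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.comp, dtype=float)
        object.__setattr__(self, "comp", comp)
        comp.setflags(write=False)

    def fraction(self, residue: str) -> float:
        return float(self.comp[_RESIDUE_INDEX[residue]])


def _count_residues(record: SequenceRecord, noncanonical_policy: str):
    if noncanonical_policy not in ("skip", "error"):
        raise ValueError(
            f"noncanonical_policy must be 'skip' or 'error', "
            f"got {noncanonical_policy!r}"
        )
    counts = np.zeros(20, dtype=np.int64)
    n_skipped = 0
    for ch in record.residues:
        idx = _RESIDUE_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
        else:
            if noncanonical_policy == "error":
                raise NonCanonicalResidueError(
                    f"{record.id}: non-canonical residue {ch!r}"
                )
            n_skipped += 1
    total = int(counts.sum())
    if total == 0:
        raise EmptySequenceError(
            f"{record.id}: no canonical residues in sequence"
        )
    # the cap guards bulk composition estimates; on very short sequences a
    # single odd letter already exceeds it, so it only applies from 10 aa up
    if total + n_skipped >= 10 and \
            n_skipped > MAX_NONCANONICAL_FRACTION * (total + n_skipped):
        raise NonCanonicalResidueError(
            f"{record.id}: {n_skipped}/{total + n_skipped} residues "
            f"non-canonical, above the {MAX_NONCANONICAL_FRACTION:.0%} cap"
        )
    return counts, total, n_skipped


def composition(
    record: SequenceRecord, noncanonical_policy: str = "skip"
) -> CompositionVector:
    """Residue-fraction vector plus signed normalized net charge.

    Under the default ``skip`` policy, non-canonical letters (B, J, O,
    U, X, Z, ``*``) are excluded from numerator and denominator and
    tallied in ``n_noncanonical_skipped``; more than 10% non-canonical
    content is an error regardless of policy.
    """
    counts, total, n_skipped = _count_residues(record, noncanonical_policy)
    comp = counts / total
    charge = (
        counts[_RESIDUE_INDEX["R"]] + counts[_RESIDUE_INDEX["K"]]
        - counts[_RESIDUE_INDEX["E"]] - counts[_RESIDUE_INDEX["D"]]
    ) / total
    return CompositionVector(
        comp=comp,
        net_charge_signed=float(charge),
        effective_length=total,
        n_noncanonical_skipped=n_skipped,
    )


def net_charge_signed(
    record: SequenceRecord, noncanonical_policy: str = "skip"
) -> float:
    """(#R + #K - #E - #D) / effective length, in [-1, 1]."""
    return composition(record, noncanonical_policy).net_charge_signed


def net_charge_abs(
    record: SequenceRecord, noncanonical_policy: str = "skip"
) -> float:
    """|(#R + #K - #E - #D)| / effective length, in [0, 1]."""
    return abs(net_charge_signed(record, noncanonical_policy))


def mean_hydropathy(
    record: SequenceRecord,
    scale: AminoAcidScale,
    noncanonical_policy: str = "skip",
) -> float:
    """Composition-weighted mean hydropathy under a normalized scale.

    The scale must already be oriented hydrophobic-positive and
    unit-normalized (see :func:`idphydro.scales.prepare_scale`); the
    result then lies in [0, 1].  Depends only on composition, not on
    residue order.
    """
    if scale.orientation != HYDROPHOBIC_POSITIVE or not scale.normalized:
        raise ValueError(
            f"scale {scale.id!r} must be oriented hydrophobic_positive and "
            "unit-normalized before computing mean hydropathy "
            "(use idphydro.scales.prepare_scale)"
        )
    comp = composition(record, noncanonical_policy).comp
    return float(comp @ scale.as_array())


def chop_windows(
    record: SequenceRecord,
    width: int = DEFAULT_WINDOW,
    remainder_policy: str = "anchor_end",
) -> list[SequenceRecord]:
    """Chop a sequence into uniform windows of ``width`` residues.

    Consecutive non-overlapping windows start at position 0.  A trailing
    remainder of at least ``width/2`` residues is re-emitted as a final
    full-width window anchored at the sequence end (overlapping the
    previous window); shorter remainders are discarded
    (``remainder_policy="anchor_end"``, default) — or always discarded
    (``"discard"``).  A sequence shorter than ``width`` is returned
    whole as a single window.
    """
    if width < 1:
        raise ValueError(f"window width must be >= 1, got {width}")
    if remainder_policy not in ("anchor_end", "discard"):
        raise ValueError(f"unknown remainder_policy {remainder_policy!r}")
    seq = record.residues
    n = len(seq)
    if n <= width:
        return [SequenceRecord(id=f"{record.id}|w0-{n}", residues=seq)]
    windows = []
    full = n // width
    for i in range(full):
        start = i * width
        windows.append(
            SequenceRecord(
                id=f"{record.id}|w{start}-{start + width}",
                residues=seq[start : start + width],
            )
        )
    remainder = n - full * width
    if remainder_policy == "anchor_end" and remainder >= width / 2:
        start = n - width
        windows.append(
            SequenceRecord(id=f"{record.id}|w{start}-{n}", residues=seq[start:])
        )
    return windows
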