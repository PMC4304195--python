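"""Scale-vs-scale Pearson correlation and AAindex-style cluster summaries.

To decide whether a derived amino-acid scale measures hydropathy rather
than some other residue property, it is correlated (Pearson r over the
20 residues) against collections of published amino-acid indices grouped
into property clusters — alpha/turn propensity (A), beta propensity (B),
composition (C), hydropathy (H), physicochemical (P), other (O) — and
the per-cluster distribution of |r| is summarised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .scales import CANONICAL_RESIDUES, AminoAcidScale

__all__ = [
    "IndexEntry",
    "CorrelationRow",
    "ClusterSummary",
    "pearson_r",
    "correlate_scale_vs_collection",
    "cluster_summary",
    "read_index_collection_tsv",
    "ConstantVectorError",
]

logger = logging.getLogger(__name__)

CLUSTERS = ("A", "B", "C", "H", "P", "O")
UNASSIGNED = "unassigned"


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class IndexEntry:
    """One amino-acid index: id, property cluster, 20 residue values."""

    id: str
    cluster: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(CANONICAL_RESIDUES):
            raise ValueError(
                f"index {self.id!r} must define exactly the 20 canonical "
                "residues"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"index {self.id!r} contains non-finite values")
        if self.cluster not in CLUSTERS and self.cluster != UNASSIGNED:
            raise ValueError(
                f"index {self.id!r}: cluster must be one of {CLUSTERS} "
                f"or {UNASSIGNED!r}, got {self.cluster!r}"
            )
        object.__setattr__(self, "values", dict(self.values))

    def as_array(self) -> np.ndarray:
        return np.array([self.values[r] for r in CANONICAL_RESIDUES])


@dataclass(frozen=True)
class CorrelationRow:
    index_id: str
    cluster: str
    r: float

    @property
    def abs_r(self) -> float:
        return abs(self.r)


@dataclass(frozen=True)
class ClusterSummary:
    """Five-number summary of |r| over one cluster's member indices."""

    cluster: str
    n: int
    mean: float
    median: float
    std: float | None  # None for singleton clusters (n-1 undefined)
    max: float
    min: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation over residue-aligned 20-vectors.

    r = sum((x_i - x̄)(y_i - ȳ)) / sqrt(sum((x_i - x̄)²) sum((y_i - ȳ)²)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0 or sy == 0:
        raise ConstantVectorError(
            "Pearson correlation undefined for a constant vector"
        )
    r = float(xd @ yd) / math.sqrt(sx * sy)
    return max(-1.0, min(1.0, r))


def correlate_scale_vs_collection(
    scale: AminoAcidScale, collection: Sequence[IndexEntry]
) -> list[CorrelationRow]:
    """Pearson r of ``scale`` against every index, residue-aligned.

    Constant indices are skipped with a logged warning rather than
    aborting the whole collection.
    """
    if not collection:
        raise ValueError("index collection is empty")
    scale_vec = scale.as_array()
    rows: list[CorrelationRow] = []
    for entry in collection:
        try:
            r = pearson_r(scale_vec, entry.as_array())
        except ConstantVectorError:
            logger.warning(
                "index %s is constant; skipping correlation", entry.id
            )
            continue
        rows.append(CorrelationRow(index_id=entry.id, cluster=entry.cluster, r=r))
    return rows


def cluster_summary(rows: Sequence[CorrelationRow]) -> list[ClusterSummary]:
    """Per-cluster mean/median/std/max/min of |r|, sorted by descending mean.

    Standard deviation is the sample (n-1) convention; a singleton
    cluster reports ``std=None``.
    """
    by_cluster: dict[str, list[float]] = {}
    for row in rows:
        by_cluster.setdefault(row.cluster, []).append(row.abs_r)
    if not by_cluster:
        raise ValueError("no labeled correlation rows to summarise")
    summaries = []
    for cluster, vals in by_cluster.items():
        arr = np.array(vals)
        summaries.append(
            ClusterSummary(
                cluster=cluster,
                n=len(arr),
                mean=float(arr.mean()),
                median=float(np.median(arr)),
                std=float(arr.std(ddof=1)) if len(arr) > 1 else None,
                max=float(arr.max()),
                min=float(arr.min()),
            )
        )
    summaries.sort(key=lambda s: -s.mean)
    return summaries


def read_index_collection_tsv(path: str | Path) -> list[IndexEntry]:
    """Read a simplified index-collection TSV.

    Header: ``id  cluster  A C D E F G H I K L M N P Q R S T V W Y``
    (tab-separated); one row per index.
    """
    path = Path(path)
    entries: list[IndexEntry] = []
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                expected = ["id", "cluster"] + list(CANONICAL_RESIDUES)
                if header != expected:
                    raise ValueError(
                        f"{path}: header must be {' '.join(expected)}"
                    )
                continue
            if len(fields) != 22:
                raise ValueError(f"{path}: expected 22 columns, got "
                                 f"{len(fields)} in row {fields[0]!r}")
            values = {
                r: float(v)
                for r, v in zip(CANONICAL_RESIDUES, fields[2:])
            }
            entries.append(
                IndexEntry(id=fields[0], cluster=fields[1], values=values)
            )
    if header is None:
        raise ValueError(f"{path}: empty index collection file")
    return entries


def write_correlation_tsv(
    rows: Sequence[CorrelationRow], path: str | Path
) -> None:
    lines = ["index_id\tcluster\tr\tabs_r"]
    lines += [
        f"{r.index_id}\t{r.cluster}\t{r.r:.6f}\t{r.abs_r:.6f}" for r in rows
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_summary_tsv(
    summaries: Sequence[ClusterSummary], path: str | Path
) -> None:
    lines = ["cluster\tn\tmean\tmedian\tstd\tmax\tmin"]
    for s in summaries:
        std = "NA" if s.std is None else f"{s.std:.6f}"
        lines.append(
            f"{s.cluster}\t{s.n}\t{s.mean:.6f}\t{s.median:.6f}\t{std}"
            f"\t{s.max:.6f}\t{s.min:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
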