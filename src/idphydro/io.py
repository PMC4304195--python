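"""FASTA and label-manifest IO."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .features import SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "write_manifest",
    "LABELS",
    "DISORDERED",
    "ORDERED",
]

DISORDERED = "disordered"
ORDERED = "ordered"
LABELS = (DISORDERED, ORDERED)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record protein FASTA.

    Wrapping is ignored, ``*`` (stop) characters are stripped, lowercase
    letters are uppercased, duplicate record IDs are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).replace("*", "").upper()
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a TSV manifest mapping sequence id -> {disordered, ordered}.

    A header row ``id<TAB>label`` is optional; '#' lines are ignored.
    """
    labels: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}: malformed manifest row {line!r}")
            key, label = fields[0].strip(), fields[1].strip().lower()
            if key.lower() == "id" and label == "label":
                continue
            if label not in LABELS:
                raise ValueError(
                    f"{path}: unknown label {label!r} for {key!r}; "
                    f"expected one of {LABELS}"
                )
            if key in labels:
                raise ValueError(f"{path}: duplicate manifest id {key!r}")
            labels[key] = label
    if not labels:
        raise ValueError(f"{path}: empty manifest")
    return labels


def write_manifest(
    ids: Sequence[str], labels: Sequence[str], path: str | Path
) -> None:
    lines = ["id\tlabel"]
    lines += [f"{i}\t{l}" for i, l in zip(ids, labels, strict=True)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
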