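"""FASTA / label / feature-table input and output.

Sequences are read with Biopython's SeqIO and kept verbatim (uppercased,
ambiguity codes preserved, no filtering), because downstream statistics are
meant to describe the dataset exactly as deposited. Labels are not part of
the FASTA standard, so they are attached via a pluggable ``label_rule``:

* ``fixed:<label>`` — every record gets the same label (one file per class);
* ``header:<regex>`` — records whose header matches the regex are soluble,
  the rest insoluble;
* ``sidecar:<csv>`` — two-column CSV ``id,label`` mapping every record id.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .residue_tables import AMBIGUOUS_RESIDUES, CANONICAL_RESIDUES

SOLUBLE = "soluble"
INSOLUBLE = "insoluble"
UNLABELED = "unlabeled"
LABELS = (SOLUBLE, INSOLUBLE, UNLABELED)

_VALID_CHARS = frozenset(CANONICAL_RESIDUES) | AMBIGUOUS_RESIDUES


class SequenceParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One identified, labeled amino-acid sequence."""

    id: str
    sequence: str
    label: str = UNLABELED

    def __post_init__(self) -> None:
        seq = "".join(self.sequence.split()).upper()
        if not seq:
            raise SequenceParseError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(seq) - _VALID_CHARS)
        if bad:
            raise SequenceParseError(
                f"record {self.id!r}: invalid residue character(s) {bad}"
            )
        if self.label not in LABELS:
            raise SequenceParseError(
                f"record {self.id!r}: unknown label {self.label!r}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class LabeledDataset:
    """Ordered collection of protein records with label provenance."""

    records: list[ProteinRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups = []
        for r in self.records:
            if r.id in seen:
                dups.append(r.id)
            seen.add(r.id)
        if dups:
            raise SequenceParseError(f"duplicate record id(s): {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for r in self.records:
            counts[r.label] += 1
        return counts


LabelRule = str | Callable[[str, str], str]


def _make_labeler(label_rule: LabelRule, fasta_path: Path) -> Callable[[str, str], str]:
    if callable(label_rule):
        return label_rule
    if ":" not in label_rule:
        raise ValueError(
            f"label_rule {label_rule!r} must be 'fixed:<label>', "
            "'header:<regex>' or 'sidecar:<csv path>'"
        )
    kind, _, arg = label_rule.partition(":")
    if kind == "fixed":
        if arg not in LABELS:
            raise ValueError(f"fixed label must be one of {LABELS}, got {arg!r}")
        return lambda rid, header: arg
    if kind in ("header", "header-token"):
        pattern = re.compile(arg)
        return lambda rid, header: SOLUBLE if pattern.search(header) else INSOLUBLE
    if kind == "sidecar":
        table = read_label_table(arg)

        def from_sidecar(rid: str, header: str) -> str:
            if rid not in table:
                raise SequenceParseError(
                    f"record {rid!r} has no entry in sidecar label table {arg}"
                )
            return table[rid]

        return from_sidecar
    raise ValueError(f"unknown label_rule kind {kind!r}")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id,label`` CSV (header row optional)."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            rid, label = row[0].strip(), row[1].strip().lower()
            if rid == "id" and label == "label":
                continue
            if label not in LABELS:
                raise SequenceParseError(
                    f"sidecar {path}: unknown label {label!r} for id {rid!r}"
                )
            table[rid] = label
    return table


def read_fasta(
    path: str | Path,
    label_rule: LabelRule = f"fixed:{UNLABELED}",
) -> LabeledDataset:
    """Read a FASTA file into a :class:`LabeledDataset`, one record per entry.

    Entries are kept in file order; ambiguous residues (X, B, Z, U, O) are
    preserved in place; no filtering of any kind is applied.
    """
    path = Path(path)
    labeler = _make_labeler(label_rule, path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        label = labeler(entry.id, entry.description)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq), label=label))
    if not records:
        raise SequenceParseError(f"{path}: no FASTA records found")
    rule_repr = label_rule if isinstance(label_rule, str) else "<callable>"
    return LabeledDataset(
        records=records,
        provenance={"sources": [str(path)], "label_rule": rule_repr},
    )


def write_fasta(dataset: LabeledDataset, path: str | Path, wrap: int = 60) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.label) for r in dataset
    ]
    writer_format = "fasta" if wrap else "fasta-2line"
    SeqIO.write(entries, str(path), writer_format)


def merge_datasets(parts: Sequence[LabeledDataset]) -> LabeledDataset:
    """Concatenate datasets preserving part order; record ids must be unique."""
    if not parts:
        raise ValueError("merge_datasets requires at least one dataset")
    records: list[ProteinRecord] = []
    sources: list[str] = []
    for part in parts:
        records.extend(part.records)
        sources.extend(part.provenance.get("sources", []))
    return LabeledDataset(records=records, provenance={"sources": sources, "merged": len(parts)})


def write_feature_table(matrix, path: str | Path) -> None:
    """Write a FeatureMatrix as CSV (id, label, then the 36 canonical columns).

    Floats are serialized with shortest-round-trip repr, so re-reading the
    file reproduces the matrix bit-identically.
    """
    df = matrix.to_dataframe()
    # shortest-round-trip float repr so re-reading is bit-identical
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_feature_table(path: str | Path):
    """Read a feature CSV back into a FeatureMatrix.

    A missing ``label`` column is tolerated (rows become unlabeled); a missing
    feature column or an unknown column is an error naming the column.
    """
    from .features import FEATURE_NAMES, FeatureMatrix

    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns:
        raise SequenceParseError(f"{path}: missing 'id' column")
    if "label" not in df.columns:
        df["label"] = UNLABELED
    expected = {"id", "label", *FEATURE_NAMES}
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SequenceParseError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise SequenceParseError(f"{path}: missing feature column(s) {missing}")
    return FeatureMatrix(
        ids=[str(i) for i in df["id"]],
        labels=np.asarray([str(l) for l in df["label"]], dtype=object),
        values=df[list(FEATURE_NAMES)].to_numpy(dtype=float),
    )
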