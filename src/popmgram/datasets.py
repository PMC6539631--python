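"""Dataset I/O: FASTA sequences, label tables, feature matrices, reports.

On-disk contract
----------------
* sequences: FASTA; the header token before the first whitespace is the
  record id.  If no label file is given, headers of the form
  ``>id|CLASS`` provide a fallback label source.
* labels: two-column TSV ``id <TAB> class``, optional header row.
* feature matrices: CSV with a leading ``sequence_id`` column followed
  by the 1000 named tri-gram columns, plus a sidecar ``.meta.json``
  recording the property-table version and encoder settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .properties import default_property_table

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_STRIPPED = "*-"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str


@dataclass
class LabeledDataset:
    """Validated sequences plus one class label per sequence."""

    records: list[SequenceRecord]
    labels: dict[str, str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            seen: dict[str, None] = {}
            for rec in self.records:
                seen.setdefault(self.labels[rec.id], None)
            self.class_names = list(seen)

    @property
    def n(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for rec in self.records:
            counts[self.labels[rec.id]] += 1
        return counts

    def sequences(self) -> list[tuple[str, str]]:
        return [(rec.id, rec.sequence) for rec in self.records]

    def label_array(self) -> list[str]:
        return [self.labels[rec.id] for rec in self.records]


def _normalize_sequence(raw: str, seq_id: str) -> str:
    seq = raw.upper()
    if any(c in seq for c in _STRIPPED):
        logger.warning(
            "sequence %r: stripped stop/gap characters (*, -)", seq_id
        )
        for c in _STRIPPED:
            seq = seq.replace(c, "")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Ids are the header token before the first whitespace; wrapped
    sequence lines are concatenated and uppercased; ``*``/``-`` are
    stripped with a warning.  Duplicate ids, empty records and text
    before the first header are errors (the last with a line number).
    """
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
        handle.seek(0)
        records: list[SequenceRecord] = []
        seen: set[str] = set()
        for header, seq in SimpleFastaParser(handle):
            seq_id = header.split()[0] if header.split() else ""
            if not seq_id:
                raise ValueError(f"{path}: FASTA record with empty header id")
            if seq_id in seen:
                raise ValueError(f"{path}: duplicate FASTA id {seq_id!r}")
            seen.add(seq_id)
            seq = _normalize_sequence(seq, seq_id)
            if not seq:
                raise ValueError(f"{path}: record {seq_id!r} has an empty sequence")
            if not seq.isalpha():
                bad = sorted({c for c in seq if not c.isalpha()})
                raise ValueError(
                    f"{path}: record {seq_id!r} contains non-alphabetic "
                    f"characters: {bad}"
                )
            records.append(SequenceRecord(id=seq_id, sequence=seq))
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``id <TAB> class`` into a mapping.

    A first row whose id column is ``id`` or ``sequence_id``
    (case-insensitive) is treated as a header and skipped.  Duplicate id
    rows with conflicting classes are errors; consistent duplicates are
    tolerated.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            seq_id, cls = parts[0].strip(), parts[1].strip()
            if lineno == 1 and seq_id.lower() in {"id", "sequence_id"}:
                continue
            if seq_id in labels and labels[seq_id] != cls:
                raise ValueError(
                    f"{path}:{lineno}: conflicting labels for {seq_id!r}: "
                    f"{labels[seq_id]!r} vs {cls!r}"
                )
            labels[seq_id] = cls
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write("id\tlocation\n")
        for seq_id, cls in labels.items():
            handle.write(f"{seq_id}\t{cls}\n")


def labels_from_headers(records: list[SequenceRecord]) -> dict[str, str]:
    """Fallback labels parsed from ``>id|CLASS``-style record ids."""
    labels: dict[str, str] = {}
    for rec in records:
        if "|" not in rec.id:
            raise ValueError(
                f"record {rec.id!r} has no '|CLASS' suffix and no label "
                f"file was provided"
            )
        labels[rec.id] = rec.id.rsplit("|", 1)[1]
    return labels


def assemble_dataset(
    records: list[SequenceRecord], labels: dict[str, str]
) -> LabeledDataset:
    """Validate records against labels and build a dataset.

    Every record must have exactly one label and every label must refer
    to a record; offenders are listed in the error.  Requires >= 2
    distinct classes.
    """
    record_ids = {rec.id for rec in records}
    unlabeled = sorted(record_ids - labels.keys())
    dangling = sorted(labels.keys() - record_ids)
    if unlabeled:
        raise ValueError(f"records without labels: {unlabeled}")
    if dangling:
        raise ValueError(f"labels without records: {dangling}")
    dataset = LabeledDataset(records=list(records), labels=dict(labels))
    if len(dataset.class_names) < 2:
        raise ValueError(
            f"need >= 2 classes, got {dataset.class_names}"
        )
    logger.info("dataset assembled: %s", dataset.class_counts())
    return dataset


def load_dataset(
    fasta_path: str | Path, labels_path: str | Path | None = None
) -> LabeledDataset:
    """Read FASTA (+ optional label TSV) into a validated dataset."""
    records = read_fasta(fasta_path)
    if labels_path is None:
        labels = labels_from_headers(records)
    else:
        labels = read_labels(labels_path)
    return assemble_dataset(records, labels)


def write_feature_matrix(
    features: pd.DataFrame, path: str | Path, settings: dict | None = None
) -> None:
    """Write a feature matrix CSV plus a ``.meta.json`` sidecar.

    Floats are written with ``repr`` precision so a read-back
    round-trips exactly.
    """
    path = Path(path)
    features.to_csv(path, float_format="%.17g")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "property_table_version": default_property_table().version,
        "n_features": features.shape[1],
        "settings": settings or {},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, float_precision="round_trip")


def write_ranking(ranked, path: str | Path) -> None:
    """Two-column TSV (rank, feature name) plus a JSON settings block."""
    path = Path(path)
    frame = ranked.to_frame()
    frame.to_csv(path, sep="\t", index=False)
    settings = {"schema_version": SCHEMA_VERSION, **ranked.settings}
    path.with_suffix(path.suffix + ".settings.json").write_text(
        json.dumps(settings, indent=2)
    )


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
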