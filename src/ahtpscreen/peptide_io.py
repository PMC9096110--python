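"""Peptide records, validation, and FASTA/CSV dataset I/O.

Every downstream descriptor is defined only over the 20 standard residues,
so validation is strict: nonstandard residues (B, J, O, U, X, Z) are
rejected, never imputed. The default minimum length of 5 reflects the
shortest peptides the method is meant for; a hard floor of 4 exists because
the lag-3 sequence-coupling terms need more than 3 residues.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import AA_SET

log = logging.getLogger(__name__)

POSITIVE_LABEL = "AHTP"
NEGATIVE_LABEL = "nonAHTP"
DEFAULT_MIN_LENGTH = 5
HARD_MIN_LENGTH = 4


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an identifier."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        ok, reason = validate_peptide(self.seq)
        if not ok:
            raise ValueError(f"invalid peptide {self.id!r}: {reason}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """Peptides with optional AHTP/nonAHTP labels.

    ``records`` is a list of ``(Peptide, label)`` pairs; label is ``None``
    for prediction-only sets.
    """

    records: list[tuple[Peptide, str | None]] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.id for p, _ in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[Peptide, str | None]]:
        return iter(self.records)

    @property
    def peptides(self) -> list[Peptide]:
        return [p for p, _ in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [y for _, y in self.records]

    def subset(self, labels: Iterable[str]) -> "LabeledDataset":
        want = set(labels)
        return LabeledDataset([(p, y) for p, y in self.records if y in want])


def validate_peptide(seq: str, min_length: int = DEFAULT_MIN_LENGTH) -> tuple[bool, str]:
    """Check the alphabet and length rules; total function.

    Returns ``(verdict, reason)`` where ``reason`` names the first violation
    (empty string when valid).
    """
    if min_length < HARD_MIN_LENGTH:
        min_length = HARD_MIN_LENGTH
    s = seq.upper()
    if len(s) < min_length:
        return False, f"length {len(s)} < minimum {min_length}"
    for i, res in enumerate(s):
        if res not in AA_SET:
            return False, f"nonstandard residue {res!r} at position {i + 1}"
    return True, ""


def read_fasta(path: str | Path, min_length: int = DEFAULT_MIN_LENGTH,
               strict: bool = False) -> list[Peptide]:
    """Read peptides from FASTA; invalid records are reported and excluded.

    In strict mode the first failing record raises instead, naming the
    record and the offending residue or length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peptides: list[Peptide] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        if not seq:
            msg = f"empty record {rec.id!r}"
            if strict:
                raise ValueError(msg)
            log.warning("skipping %s", msg)
            continue
        ok, reason = validate_peptide(seq, min_length)
        if not ok:
            msg = f"record {rec.id!r}: {reason}"
            if strict:
                raise ValueError(msg)
            log.warning("skipping %s", msg)
            continue
        peptides.append(Peptide(rec.id, seq))
    if n_records == 0:
        log.warning("no FASTA records found in %s", path)
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    records = [SeqRecord(Seq(p.seq), id=p.id, description="") for p in peptides]
    SeqIO.write(records, str(path), "fasta")


_LABEL_MAP = {"ahtp": POSITIVE_LABEL, "1": POSITIVE_LABEL,
              "nonahtp": NEGATIVE_LABEL, "0": NEGATIVE_LABEL}


def read_labeled_csv(path: str | Path, min_length: int = DEFAULT_MIN_LENGTH,
                     strict: bool = False) -> LabeledDataset:
    """Read a two-column ``sequence,label`` CSV (header required).

    Labels are case-insensitive ``AHTP``/``nonAHTP`` or ``1``/``0``. Row
    numbers become peptide ids (``row1``, ``row2``, ...).
    """
    records: list[tuple[Peptide, str | None]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.lower() for f in reader.fieldnames[:2]] != ["sequence", "label"]:
            raise ValueError("expected header 'sequence,label'")
        for i, row in enumerate(reader, start=1):
            seq = row[reader.fieldnames[0]].strip()
            raw = row[reader.fieldnames[1]].strip().lower()
            if raw not in _LABEL_MAP:
                raise ValueError(f"row {i}: unknown label {raw!r}")
            ok, reason = validate_peptide(seq, min_length)
            if not ok:
                msg = f"row {i}: {reason}"
                if strict:
                    raise ValueError(msg)
                log.warning("skipping %s", msg)
                continue
            records.append((Peptide(f"row{i}", seq), _LABEL_MAP[raw]))
    return LabeledDataset(records)


def write_labeled_csv(data: LabeledDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence", "label"])
        for p, y in data:
            writer.writerow([p.seq, y if y is not None else ""])


def dataset_from_fasta_pair(pos_path: str | Path, neg_path: str | Path,
                            min_length: int = DEFAULT_MIN_LENGTH,
                            strict: bool = False) -> LabeledDataset:
    """Build a labeled dataset from a positive-FASTA / negative-FASTA pair."""
    pos = read_fasta(pos_path, min_length, strict)
    neg = read_fasta(neg_path, min_length, strict)
    recs = [(p, POSITIVE_LABEL) for p in pos] + [(p, NEGATIVE_LABEL) for p in neg]
    seen: dict[str, int] = {}
    out = []
    for p, y in recs:
        if p.id in seen:
            if strict:
                raise ValueError(f"duplicate id {p.id!r}")
            seen[p.id] += 1
            p = Peptide(f"{p.id}_{seen[p.id]}", p.seq)
        else:
            seen[p.id] = 0
        out.append((p, y))
    return LabeledDataset(out)
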