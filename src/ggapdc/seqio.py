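"""Reading, validating and writing protein sequences in FASTA format.

Sequences are restricted to the 20 standard amino acids. Residues such as
B, J, O, U, X and Z (ambiguity codes, selenocysteine, pyrrolysine) as well
as stop ('*') and gap ('-') characters are treated as illegal because a
dipeptide composition is undefined for them. Input is case-normalized to
upper case before validation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import DataError, SequenceValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically ordered.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

Policy = Literal["reject", "skip", "strip"]


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise DataError("protein record id must be a non-empty string")
        validate_sequence(self.sequence, record_id=self.id)
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str, record_id: str | None = None) -> str:
    """Upper-case *sequence* and verify every character is a standard residue.

    Returns the upper-cased sequence. Raises
    :class:`~ggapdc.exceptions.SequenceValidationError` naming the first
    offending character and its 1-based position.
    """
    if not sequence:
        raise SequenceValidationError(
            f"empty sequence{_in(record_id)}", record_id=record_id
        )
    upper = sequence.upper()
    for pos, ch in enumerate(upper, start=1):
        if ch not in _ALPHABET_SET:
            raise SequenceValidationError(
                f"illegal character {ch!r} at position {pos}{_in(record_id)}; "
                f"allowed alphabet is {ALPHABET}",
                character=ch,
                position=pos,
                record_id=record_id,
            )
    return upper


def _in(record_id: str | None) -> str:
    return f" in record {record_id!r}" if record_id else ""


def _strip_illegal(sequence: str) -> str:
    return "".join(ch for ch in sequence.upper() if ch in _ALPHABET_SET)


def read_fasta(path: str | Path, policy: Policy = "reject") -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Parameters
    ----------
    path
        FASTA file; multi-line sequences and CRLF line endings are accepted.
    policy
        How to treat sequences with characters outside the 20-letter
        alphabet: ``"reject"`` raises on the first invalid record,
        ``"skip"`` drops invalid records, ``"strip"`` removes the invalid
        characters (records left empty are dropped). Skipped/stripped
        records are counted in a log message.

    Raises
    ------
    DataError
        On an empty file, zero valid records, or duplicate ids.
    SequenceValidationError
        Under ``policy="reject"`` for any invalid sequence.
    """
    if policy not in ("reject", "skip", "strip"):
        raise ValueError(f"unknown policy {policy!r}; expected reject|skip|strip")
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise DataError(f"no FASTA records found in {path}")

    ids = [r.id for r in raw]
    dupes = sorted(name for name, cnt in Counter(ids).items() if cnt > 1)
    if dupes:
        raise DataError(f"duplicate sequence ids in {path}: {', '.join(dupes)}")

    records: list[ProteinRecord] = []
    n_skipped = n_stripped = 0
    for rec in raw:
        seq = str(rec.seq)
        try:
            records.append(ProteinRecord(rec.id, seq))
        except SequenceValidationError as err:
            if policy == "reject":
                raise SequenceValidationError(
                    f"{path}: {err}", character=err.character,
                    position=err.position, record_id=rec.id,
                ) from err
            if policy == "skip":
                n_skipped += 1
                continue
            stripped = _strip_illegal(seq)
            if not stripped:
                n_skipped += 1
                continue
            n_stripped += 1
            records.append(ProteinRecord(rec.id, stripped))
    if n_skipped:
        logger.info("read_fasta(%s): dropped %d invalid record(s)", path, n_skipped)
    if n_stripped:
        logger.info(
            "read_fasta(%s): stripped illegal characters from %d record(s)",
            path, n_stripped,
        )
    if not records:
        raise DataError(f"no valid records remain in {path} under policy={policy!r}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to *path* in FASTA format, one line per sequence."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta-2line")


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of (id, label) with label in {1, 0}."""
    labels: dict[str, int] = {}
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rid, lab = parts
            if lab not in ("0", "1"):
                raise DataError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            if rid in labels:
                raise DataError(f"{path}:{lineno}: duplicate id {rid!r}")
            labels[rid] = int(lab)
    if not labels:
        raise DataError(f"no labels found in {path}")
    return labels


def read_two_class_fasta(
    positive_path: str | Path,
    negative_path: str | Path,
    policy: Policy = "reject",
) -> tuple[list[ProteinRecord], list[int]]:
    """Read positive- and negative-class FASTA files into records + 1/0 labels."""
    pos = read_fasta(positive_path, policy=policy)
    neg = read_fasta(negative_path, policy=policy)
    overlap = {r.id for r in pos} & {r.id for r in neg}
    if overlap:
        raise DataError(
            "ids present in both classes: " + ", ".join(sorted(overlap))
        )
    return pos + neg, [1] * len(pos) + [0] * len(neg)
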