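"""Reading, validating and writing DNA sequences, and the G/C/* alphabet reduction.

Candidate replication-origin regions arrive as plain multi-record FASTA.
Sequences are normalised to uppercase A/C/G/T (U is accepted and mapped to T).
The encoder downstream only distinguishes G, C and "other", so ambiguity codes
can be tolerated: in non-strict mode they are replaced by an A-equivalent
wildcard (which becomes ``*`` after alphabet reduction) with a logged warning;
in strict mode they are rejected.

Coordinates in user-facing messages are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
# IUPAC nucleotide ambiguity codes (plus U); everything else is a hard error.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_REDUCE = str.maketrans("ACGT", "*CG*")


class FastaFormatError(ValueError):
    """Raised for empty files, duplicate ids, or invalid characters."""


@dataclass(frozen=True)
class DnaRecord:
    """A single validated DNA sequence.

    ``sequence`` holds only A/C/G/T after normalisation; ``length`` is its
    positive length L.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: non-ACGT characters {sorted(bad)} "
                "after normalisation"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReducedSequence:
    """A sequence over the reduced alphabet {G, C, *}, with * standing for A or T."""

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("empty reduced sequence")
        bad = set(self.symbols) - set("GC*")
        if bad:
            raise ValueError(f"invalid reduced symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.symbols)


def normalize_sequence(raw: str, *, record_id: str = "?", strict: bool = False) -> str:
    """Uppercase, map U->T, and resolve ambiguity codes.

    Non-strict mode replaces IUPAC ambiguity codes with ``A`` (an A/T-equivalent
    wildcard that reduces to ``*``), logging one warning per record. Strict mode
    raises on the first such character, naming its 1-based position. Characters
    outside the IUPAC nucleotide alphabet are always an error.
    """
    seq = raw.upper().replace("U", "T")
    if set(seq) <= _DNA:
        return seq
    out = []
    n_replaced = 0
    for pos, ch in enumerate(seq, start=1):
        if ch in _DNA:
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS:
            if strict:
                raise FastaFormatError(
                    f"record {record_id!r}: ambiguous base {ch!r} at position {pos} "
                    "(strict mode)"
                )
            out.append("A")
            n_replaced += 1
        else:
            raise FastaFormatError(
                f"record {record_id!r}: invalid character {ch!r} at position {pos}"
            )
    if n_replaced:
        logger.warning(
            "record %r: replaced %d ambiguous base(s) with A-equivalent wildcard",
            record_id,
            n_replaced,
        )
    return "".join(out)


def read_fasta(path: str | Path, strict: bool = False) -> list[DnaRecord]:
    """Read a multi-record FASTA file into validated :class:`DnaRecord` objects.

    Records are returned in file order. Raises :class:`FastaFormatError` on an
    empty file, duplicated ids, or (in strict mode) ambiguity codes.
    """
    path = Path(path)
    records: list[DnaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicated record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), record_id=rec.id, strict=strict)
        records.append(DnaRecord(id=rec.id, sequence=seq))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[DnaRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns; round-trips with read_fasta."""
    if not records:
        raise ValueError("refusing to write an empty record list")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def reduce_alphabet(record: DnaRecord | str) -> ReducedSequence:
    """Collapse A and T to ``*``; G and C are kept (positionally, length preserved)."""
    seq = record.sequence if isinstance(record, DnaRecord) else record
    return ReducedSequence(symbols=seq.translate(_REDUCE))


def reverse_complement(record: DnaRecord) -> DnaRecord:
    """Watson-Crick reverse complement."""
    return DnaRecord(
        id=record.id, sequence=record.sequence.translate(_COMPLEMENT)[::-1]
    )


def write_label_table(
    ids: Iterable[str], labels: Iterable[int], path: str | Path
) -> None:
    """Write the two-column (id, label) tab-separated table used for labelled sets."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for i, y in zip(ids, labels):
            fh.write(f"{i}\t{int(y)}\n")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) table; labels must be 0 or 1."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FastaFormatError(f"empty label table {path}")
        for line in fh:
            if not line.strip():
                continue
            ident, value = line.rstrip("\n").split("\t")
            y = int(value)
            if y not in (0, 1):
                raise ValueError(f"label for {ident!r} must be 0 or 1, got {y}")
            labels[ident] = y
    return labels
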