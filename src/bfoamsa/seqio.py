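"""FASTA input/output with alphabet validation.

Sequences are read into light-weight :class:`SequenceRecord` objects (id,
description, residue string), case-folded to upper (substitution tables are
uppercase-keyed) and validated against the declared alphabet.  With
``alphabet="auto"`` a file is classified as DNA iff the pooled residue set
is a subset of ``{A, C, G, T, N, -}``, otherwise protein.

Parsing and serialisation go through Biopython's ``SeqIO``; run traces are
plain CSV (see :class:`~bfoamsa.optimizers.RunTrace`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "FastaFormatError",
    "AlphabetError",
    "read_fasta",
    "write_fasta",
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
]

GAP = "-"
DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX")
_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}


class FastaFormatError(ValueError):
    """The file is not parseable FASTA (or contains no records)."""


class AlphabetError(ValueError):
    """A residue is illegal for the declared alphabet."""


@dataclass
class SequenceRecord:
    """One FASTA entry.

    ``id`` is the first header token; ``description`` is the remainder of
    the header line; ``residues`` may contain gaps.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")


def _validate(records: list[SequenceRecord], alphabet: str) -> None:
    allowed = _ALPHABETS[alphabet] | {GAP}
    for rec in records:
        bad = set(rec.residues) - allowed
        if bad:
            ch = sorted(bad)[0]
            raise AlphabetError(
                f"illegal character {ch!r} for {alphabet} alphabet in record {rec.id!r}"
            )


def read_fasta(path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Parse a FASTA file into validated, upper-cased records.

    Raises :class:`FastaFormatError` for an empty/recordless file,
    :class:`AlphabetError` for residues outside the declared alphabet, and
    ``ValueError`` for duplicate ids.
    """
    if alphabet not in ("auto", "dna", "protein"):
        raise ValueError(f"alphabet must be auto|dna|protein, got {alphabet!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            residues = str(rec.seq).upper().strip()
            records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    except ValueError as exc:
        raise FastaFormatError(f"cannot parse {path} as FASTA: {exc}") from exc
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FastaFormatError(f"duplicate record id {dup!r} in {path}")
    if alphabet == "auto":
        pooled = set().union(*(set(r.residues) for r in records))
        alphabet = "dna" if pooled <= DNA_ALPHABET | {GAP} else "protein"
    _validate(records, alphabet)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA; an empty record list gives an empty file."""
    seqrecords = [
        SeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
        for rec in records
    ]
    path = Path(path)
    if not seqrecords:
        path.write_text("")
        return
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)
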