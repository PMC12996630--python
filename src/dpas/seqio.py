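"""Peptide sequence I/O: FASTA reading/writing, validation, and chunking.

Sequences are restricted to the 20 canonical amino acids. Case is preserved
verbatim in ``raw_sequence`` (some upstream databases print lowercase letters,
e.g. to mark substituted residues) but every downstream feature is computed on
the upper-cased ``sequence``; no feature depends on case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)


class FastaParseError(ValueError):
    """Raised when a file is not parseable as FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains letters outside the 20-letter alphabet."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide sequence.

    ``sequence`` is the upper-cased, validated form used for all feature
    computation; ``raw_sequence`` keeps the original casing.
    """

    id: str
    raw_sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("record id must be non-empty")
        if len(self.raw_sequence) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.raw_sequence.upper()) - _ALPHABET_SET)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-amino-acid character(s) "
                + ", ".join(repr(c) for c in bad)
            )

    @property
    def sequence(self) -> str:
        return self.raw_sequence.upper()

    def __len__(self) -> int:
        return len(self.raw_sequence)


@dataclass
class PeptideSet:
    """An ordered collection of peptides with unique ids."""

    records: list[PeptideRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = []
        for rec in self.records:
            if rec.id in seen:
                dupes.append(rec.id)
            seen.add(rec.id)
        if dupes:
            raise SequenceValidationError(
                "duplicate record id(s): " + ", ".join(sorted(set(dupes)))
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: list[str]) -> "PeptideSet":
        """Records for the given ids, in the given order."""
        by_id = {r.id: r for r in self.records}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"unknown record id(s): {', '.join(missing)}")
        return PeptideSet([by_id[i] for i in ids], source=self.source)


def read_fasta(path, skip_invalid: bool = False) -> PeptideSet:
    """Read a peptide FASTA file into a :class:`PeptideSet`.

    Multi-line sequence entries are accepted. With ``skip_invalid`` records
    containing non-canonical letters are dropped with a warning instead of
    raising.
    """
    import logging

    with open(path) as fh:
        # Bio's FASTA iterator silently skips leading junk; report it instead.
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:40]!r}"
                    )
                break
        fh.seek(0)
        records: list[PeptideRecord] = []
        n_skipped = 0
        for entry in SeqIO.parse(fh, "fasta"):
            try:
                records.append(PeptideRecord(id=entry.id, raw_sequence=str(entry.seq)))
            except SequenceValidationError:
                if not skip_invalid:
                    raise
                n_skipped += 1
        if n_skipped:
            logging.getLogger(__name__).warning(
                "%s: skipped %d record(s) with non-canonical letters", path, n_skipped
            )
    return PeptideSet(records, source=str(path))


def write_fasta(pset: PeptideSet, path) -> None:
    """Write a :class:`PeptideSet` as single-line-per-sequence FASTA.

    Raw (case-preserved) sequences are written, so a read/write round trip
    reproduces ids and raw sequences exactly.
    """
    entries = [
        SeqRecord(Seq(rec.raw_sequence), id=rec.id, description="")
        for rec in pset.records
    ]
    with open(path, "w") as fh:
        SeqIO.write(entries, fh, "fasta-2line")


def chunk_records(pset: PeptideSet, n_chunks: int) -> list[PeptideSet]:
    """Partition a set into ``n_chunks`` contiguous chunks of near-equal size.

    Chunk sizes differ by at most one (larger chunks first); concatenating the
    chunks restores the original order. When ``n_chunks`` exceeds the number of
    records the trailing chunks are empty.
    """
    if n_chunks < 1:
        raise ValueError(f"n_chunks must be >= 1, got {n_chunks}")
    parts = np.array_split(np.arange(len(pset)), n_chunks)
    return [
        PeptideSet([pset.records[i] for i in idx], source=pset.source)
        for idx in parts
    ]
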