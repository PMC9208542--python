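"""Protein sequence records and FASTA input/output.

A :class:`ProteinRecord` is the unit object flowing through the pipeline:
one protein sequence with a stable identifier and the taxon it comes from.
Sequences are restricted to the 20 canonical amino acids plus ``X`` for
unknown residues; gap characters are never part of a record (alignments
keep gapped strings separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)

GAP = "-"


class InputError(ValueError):
    """Malformed user input (bad characters, duplicate ids, missing files)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identifiers and taxon of origin."""

    id: str
    sequence: str
    taxon: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("record id must be non-empty")
        if not self.sequence:
            raise InputError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise InputError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}; "
                f"allowed: 20 amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def _taxon_from_description(rec_id: str, description: str) -> str:
    # convention: "taxon=<name>" key in the description, else empty
    for token in description.split():
        if token.startswith("taxon="):
            return token[len("taxon="):]
    return ""


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Taxon labels are taken from a ``taxon=<name>`` token in the header
    description when present. With ``allow_gaps`` the file is treated as
    aligned FASTA and gap characters are stripped.
    """
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        seq = str(sr.seq).upper()
        if allow_gaps:
            seq = seq.replace(GAP, "").replace(".", "")
        records.append(
            ProteinRecord(
                id=sr.id,
                sequence=seq,
                taxon=_taxon_from_description(sr.id, sr.description),
                description=sr.description,
            )
        )
    check_unique_ids(records)
    return records


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file as (id, gapped sequence) rows."""
    rows = [(sr.id, str(sr.seq).upper().replace(".", GAP)) for sr in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise InputError(f"no sequences in {path}")
    ncol = len(rows[0][1])
    for rid, gapped in rows:
        if len(gapped) != ncol:
            raise InputError(f"unequal row lengths in alignment {path} (row {rid!r})")
    return rows


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns, taxon in the header."""
    seqrecs = []
    for rec in records:
        desc = rec.description
        if rec.taxon and "taxon=" not in desc:
            desc = (desc + " " if desc else "") + f"taxon={rec.taxon}"
        seqrecs.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


def write_aligned_fasta(rows: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, gapped in rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(gapped), 60):
                fh.write(gapped[i : i + 60] + "\n")
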