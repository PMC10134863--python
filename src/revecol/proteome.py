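"""Proteome container and protein-FASTA I/O.

A :class:`Proteome` is the unit every composition trait is computed on: the
set of predicted protein sequences of one genome (typically a MAG).  Records
keep their FASTA ids; sequences are stored upper-case and may contain
ambiguity codes — downstream composition math strips those explicitly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids (one-letter codes), alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-residue codes removed before any composition statistic.
AMBIGUOUS_AA = frozenset("BJOUXZ*")


@dataclass
class Proteome:
    """All protein sequences of one genome.

    Parameters
    ----------
    genome_id:
        Identifier of the source genome (used as the key in trait tables).
    records:
        List of ``(protein_id, sequence)`` tuples.  Protein ids must be
        unique within the proteome.
    """

    genome_id: str
    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(
                f"duplicate protein ids in proteome {self.genome_id!r}"
            )
        self.records = [(pid, seq.upper()) for pid, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


def sanitize(sequence: str) -> str:
    """Strip ambiguity codes and stops; return the canonical-residue string."""
    return "".join(c for c in sequence.upper() if c in CANONICAL_AA)


def read_fasta(path: str | os.PathLike, genome_id: str | None = None) -> Proteome:
    """Read a protein multi-FASTA into a :class:`Proteome`.

    ``genome_id`` defaults to the file stem.
    """
    path = os.fspath(path)
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(path))[0]
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    return Proteome(genome_id=genome_id, records=records)


def write_fasta(proteome: Proteome, path: str | os.PathLike, width: int = 60) -> None:
    """Write a proteome as wrapped protein FASTA."""
    recs = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in proteome.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fasta_dir(directory: str | os.PathLike,
                   extensions: Iterable[str] = (".faa", ".fasta", ".fa")) -> list[Proteome]:
    """Read every protein FASTA in a directory (sorted by filename)."""
    directory = os.fspath(directory)
    out = []
    for name in sorted(os.listdir(directory)):
        if any(name.endswith(ext) for ext in extensions):
            out.append(read_fasta(os.path.join(directory, name)))
    if not out:
        raise FileNotFoundError(f"no protein FASTA files found in {directory}")
    return out
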