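"""Thin FASTQ/FASTA helpers over Biopython.

Writers emit records in input order with no wrapping so that seeded
simulations are byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) tuples; id is the header up to whitespace."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def phred_to_string(scores: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in scores)


def string_to_phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]
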