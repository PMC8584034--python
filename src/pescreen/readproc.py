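"""Demultiplexing and quality triage of screen read pairs.

Each sequencing cluster yields two 8-nt index reads (sample of origin), a
44-nt R1 read covering the CRISPRi sgRNA protospacer, and a 263-nt R2 read of
the editing outcome.  Reads are routed to samples by exact index match, to
sgRNAs by comparing the extracted 20-mer to the library allowing up to one
mismatch, and triaged on R2 quality: reads with less than 60% of base calls at
Q>=30 are discarded.  R2 is reverse-complemented into vector top-strand frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .library import PROTOSPACER_LENGTH, SgRNALibrary
from .seqio import read_fastq
from .vector import reverse_complement

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    index1: str
    index2: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class AssignedRead:
    """Outcome read oriented to the vector top strand, with its sgRNA assignment."""

    read_id: str
    sgrna_id: str            # library id, UNASSIGNED, or AMBIGUOUS
    outcome_seq: str
    outcome_qual: str
    pass_quality: bool


def load_read_pairs(r1_path: str | Path, r2_path: str | Path,
                    i1_path: str | Path | None = None,
                    i2_path: str | Path | None = None) -> Iterator[ReadPair]:
    """Stream read pairs from paired FASTQ, with optional index FASTQs.

    Without index files, indexes are taken from the read id when formatted as
    ``name#index1+index2`` (index-embedded dialect), else left empty.
    """
    r1_iter, r2_iter = read_fastq(r1_path), read_fastq(r2_path)
    i1_iter = read_fastq(i1_path) if i1_path else None
    i2_iter = read_fastq(i2_path) if i2_path else None
    for (rid1, s1, q1), (rid2, s2, q2) in zip(r1_iter, r2_iter):
        if rid1 != rid2:
            raise ValueError(f"R1/R2 out of sync: {rid1} vs {rid2}")
        if i1_iter is not None and i2_iter is not None:
            i1 = next(i1_iter)[1]
            i2 = next(i2_iter)[1]
        elif "#" in rid1:
            # index-embedded dialect: read ids of the form name#index1+index2
            rid1, _, idx = rid1.partition("#")
            i1, _, i2 = idx.partition("+")
        else:
            i1 = i2 = ""
        yield ReadPair(rid1, i1, i2, s1, q1, s2, q2)


def demultiplex_samples(read_pairs: Iterable[ReadPair],
                        sample_sheet) -> dict[str, list[ReadPair]]:
    """Route read pairs to samples by exact (index1, index2) match.

    ``sample_sheet`` is either a {(index1, index2): sample} mapping or an
    iterable of (index1, index2, sample) rows; duplicate index pairs are
    rejected.  Unmatched pairs go to the ``undetermined`` stream; counts are
    conserved.
    """
    if isinstance(sample_sheet, dict):
        rows = [(i1, i2, name) for (i1, i2), name in sample_sheet.items()]
    else:
        rows = list(sample_sheet)
    lookup: dict[tuple[str, str], str] = {}
    for i1, i2, name in rows:
        if (i1, i2) in lookup:
            raise ValueError(f"duplicate index pair {(i1, i2)} in sample sheet")
        lookup[(i1, i2)] = name
    out: dict[str, list[ReadPair]] = {name: [] for _, _, name in rows}
    out[UNDETERMINED] = []
    for rp in read_pairs:
        out[lookup.get((rp.index1, rp.index2), UNDETERMINED)].append(rp)
    return out


def assign_sgrna(r1_seq: str, library: SgRNALibrary, offset: int = 0) -> str:
    """sgRNA id of the unique protospacer within Hamming distance <= 1 of the R1 20-mer.

    Returns UNASSIGNED when nothing is within one mismatch, AMBIGUOUS when two
    or more protospacers are.
    """
    if offset + PROTOSPACER_LENGTH > len(r1_seq):
        raise ValueError("protospacer offset runs past the end of R1")
    observed = r1_seq[offset:offset + PROTOSPACER_LENGTH]
    exact = library.lookup_protospacer(observed)
    hits = []
    for entry in library:
        d = 0
        for a, b in zip(entry.protospacer, observed):
            if a != b:
                d += 1
                if d > 1:
                    break
        if d <= 1:
            hits.append(entry.sgrna_id)
            if len(hits) > 1:
                return AMBIGUOUS
    if not hits:
        return UNASSIGNED
    if exact is not None and hits[0] != exact.sgrna_id:  # pragma: no cover - defensive
        return AMBIGUOUS
    return hits[0]


def quality_filter(qual: str, min_q: int = 30, min_fraction: float = 0.60) -> bool:
    """True (keep) iff at least ``min_fraction`` of base calls have Phred >= ``min_q``.

    A read at exactly the threshold fraction is kept (only reads with *less*
    than the threshold are discarded).
    """
    if not qual:
        raise ValueError("empty quality string")
    cutoff = chr(min_q + 33)
    n_good = sum(1 for c in qual if c >= cutoff)
    return n_good / len(qual) >= min_fraction


def orient_outcome_read(r2_seq: str, r2_qual: str) -> tuple[str, str]:
    """Reverse-complement R2 into vector top-strand frame (applied exactly once)."""
    return reverse_complement(r2_seq), r2_qual[::-1]


def process_read_pairs(read_pairs: Iterable[ReadPair], library: SgRNALibrary,
                       r1_offset: int = 0, min_q: int = 30,
                       min_fraction: float = 0.60) -> list[AssignedRead]:
    """Assign, quality-triage and orient a stream of read pairs."""
    out = []
    for rp in read_pairs:
        seq, qual = orient_outcome_read(rp.r2_seq, rp.r2_qual)
        out.append(AssignedRead(
            read_id=rp.read_id,
            sgrna_id=assign_sgrna(rp.r1_seq, library, r1_offset),
            outcome_seq=seq,
            outcome_qual=qual,
            pass_quality=quality_filter(rp.r2_qual, min_q, min_fraction),
        ))
    return out
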