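"""End-to-end screen processing: FASTQ pairs -> classified outcome records."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .classify import ClassifierConfig, classify_read
from .library import SgRNALibrary
from .outcomes import OutcomeRecord
from .readproc import (AMBIGUOUS, UNASSIGNED, AssignedRead, load_read_pairs,
                       process_read_pairs)
from .vector import ScreenVectorSpec


@dataclass
class ScreenResult:
    records: list[OutcomeRecord]
    n_input: int
    n_quality_discarded: int
    n_unassigned: int
    n_ambiguous: int

    @property
    def n_classified(self) -> int:
        return len(self.records)


def classify_assigned_reads(assigned: list[AssignedRead], spec: ScreenVectorSpec,
                            decoys: dict[str, str] | None = None,
                            config: ClassifierConfig = ClassifierConfig()) -> ScreenResult:
    """Classify quality-passing, sgRNA-assigned reads; tallies exclusions.

    Quality-discarded reads and reads with UNASSIGNED/AMBIGUOUS sgRNA never
    enter per-sgRNA statistics; they are counted separately.
    """
    records: list[OutcomeRecord] = []
    n_q = n_un = n_amb = 0
    for ar in assigned:
        if not ar.pass_quality:
            n_q += 1
            continue
        if ar.sgrna_id == UNASSIGNED:
            n_un += 1
            continue
        if ar.sgrna_id == AMBIGUOUS:
            n_amb += 1
            continue
        records.append(classify_read(ar.outcome_seq, spec, decoys,
                                     read_id=ar.read_id, sgrna_id=ar.sgrna_id,
                                     config=config))
    return ScreenResult(records, len(assigned), n_q, n_un, n_amb)


def run_screen(r1_path: str | Path, r2_path: str | Path, library: SgRNALibrary,
               spec: ScreenVectorSpec, decoys: dict[str, str] | None = None,
               r1_offset: int = 0,
               config: ClassifierConfig = ClassifierConfig()) -> ScreenResult:
    """FASTQ pair -> demultiplexed, triaged, classified outcome records."""
    pairs = load_read_pairs(r1_path, r2_path)
    assigned = process_read_pairs(pairs, library, r1_offset)
    return classify_assigned_reads(assigned, spec, decoys, config)
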