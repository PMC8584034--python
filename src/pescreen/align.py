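"""Local alignment of outcome reads to screen references.

An outcome read may be explained by several alignments to different reference
regions (deletions, tandem duplications, pegRNA-templated junctions), so the
aligner returns a *set* of local alignments per read: the best local alignment
is found (affine-gap Smith-Waterman via Biopython's PairwiseAligner), the
aligned read span is removed, and the flanking read segments are realigned
recursively.  Alignments containing indel gaps longer than ``max_gap`` are
split at those gaps, so large structural events surface as alignment pairs
rather than as single gapped alignments.

Read *coverage* of an alignment is the set of read positions aligned to a
reference base; read bases inside insertions are not covered.  Greedy
parsimony pruning then selects a minimal set of alignments explaining as much
of the read as possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

# op kinds: M = match, X = mismatch, I = insertion (read bases absent from the
# reference), D = deletion (reference bases absent from the read)
Op = tuple[str, int, int, int]  # (kind, ref_start, read_start, length)


@dataclass(frozen=True)
class AlignParams:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5      # additional cost for opening a gap
    gap_extend: int = -1    # per-base cost, including the first gap base
    min_score: int = 10
    min_length: int = 15    # minimum aligned read length (M+X columns)
    max_gap: int = 10       # indel gaps longer than this split the alignment


@dataclass(frozen=True)
class LocalAlignment:
    reference_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    ops: tuple[Op, ...]
    score: float
    strand: str = "+"

    @property
    def aligned_read_length(self) -> int:
        return sum(l for k, _, _, l in self.ops if k in "MX")

    @property
    def n_mismatches(self) -> int:
        return sum(l for k, _, _, l in self.ops if k == "X")

    @property
    def indels(self) -> list[Op]:
        return [op for op in self.ops if op[0] in "ID"]

    @property
    def covered(self) -> frozenset[int]:
        """Read positions aligned to a reference base."""
        out: set[int] = set()
        for k, _, rs, l in self.ops:
            if k in "MX":
                out.update(range(rs, rs + l))
        return frozenset(out)

    def read_pos_of_ref(self, ref_pos: int) -> int | None:
        """Read position aligned to ``ref_pos`` (aligned columns only)."""
        for k, fs, rs, l in self.ops:
            if k in "MX" and fs <= ref_pos < fs + l:
                return rs + (ref_pos - fs)
        return None

    def read_span_of_ref_interval(self, interval: tuple[int, int]) -> tuple[int, int, int] | None:
        """(read_start, read_end, n_aligned_columns) for ref positions in ``interval``.

        Returns None when no column of the interval is aligned.
        """
        s, e = interval
        lo, hi, n = None, None, 0
        for k, fs, rs, l in self.ops:
            if k not in "MX":
                continue
            a, b = max(fs, s), min(fs + l, e)
            if a < b:
                r0 = rs + (a - fs)
                r1 = rs + (b - fs)
                lo = r0 if lo is None else min(lo, r0)
                hi = r1 if hi is None else max(hi, r1)
                n += b - a
        if lo is None:
            return None
        return lo, hi, n

    def edits_in_read_span(self, lo: int, hi: int) -> int:
        """Mismatched, inserted and deleted bases attributable to read span [lo, hi)."""
        n = 0
        for k, fs, rs, l in self.ops:
            if k == "X":
                n += max(0, min(rs + l, hi) - max(rs, lo))
            elif k == "I":
                n += max(0, min(rs + l, hi) - max(rs, lo))
            elif k == "D" and lo <= rs < hi:
                n += l
        return n


@lru_cache(maxsize=8)
def _aligner(params: AlignParams, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    # PairwiseAligner charges open_gap_score for the first gap base; a gap of
    # length L then costs -(gap_open + L * gap_extend) as documented.
    al.open_gap_score = params.gap_open + params.gap_extend
    al.extend_gap_score = params.gap_extend
    return al


def _ops_from_alignment(alignment, ref: str, read: str,
                        ref_offset: int = 0, read_offset: int = 0) -> tuple[Op, ...]:
    t_blocks, q_blocks = alignment.aligned
    ops: list[Op] = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            dt, dq = ts - prev_t, qs - prev_q
            if dt > 0:
                ops.append(("D", prev_t + ref_offset, prev_q + read_offset, dt))
            if dq > 0:
                ops.append(("I", ts + ref_offset, prev_q + read_offset, dq))
        # emit M/X runs within the block
        run_kind, run_start = None, 0
        for i in range(te - ts):
            kind = "M" if ref[ts + i] == read[qs + i] else "X"
            if kind != run_kind:
                if run_kind is not None:
                    ops.append((run_kind, ts + run_start + ref_offset,
                                qs + run_start + read_offset, i - run_start))
                run_kind, run_start = kind, i
        if run_kind is not None:
            ops.append((run_kind, ts + run_start + ref_offset,
                        qs + run_start + read_offset, te - ts - run_start))
        prev_t, prev_q = te, qe
    return tuple(ops)


def _score_ops(ops: tuple[Op, ...], params: AlignParams) -> float:
    s = 0.0
    for k, _, _, l in ops:
        if k == "M":
            s += params.match * l
        elif k == "X":
            s += params.mismatch * l
        else:
            s += params.gap_open + params.gap_extend * l
    return s


def _trim_terminal_mismatches(ops: list[Op]) -> list[Op]:
    while ops and ops[0][0] != "M":
        ops.pop(0)
    while ops and ops[-1][0] != "M":
        ops.pop()
    return ops


def alignment_from_ops(reference_id: str, ops: tuple[Op, ...], params: AlignParams) -> LocalAlignment:
    aligned = [op for op in ops if op[0] in "MX"]
    ref_start = min(op[1] for op in aligned)
    ref_end = max(op[1] + op[3] for op in aligned)
    read_start = min(op[2] for op in aligned)
    read_end = max(op[2] + op[3] for op in aligned)
    return LocalAlignment(reference_id, ref_start, ref_end, read_start, read_end,
                          tuple(ops), _score_ops(ops, params))


def split_long_gaps(aln: LocalAlignment, params: AlignParams) -> list[LocalAlignment]:
    """Split an alignment at indel gaps longer than ``params.max_gap``."""
    pieces: list[list[Op]] = [[]]
    for op in aln.ops:
        if op[0] in "ID" and op[3] > params.max_gap:
            pieces.append([])
        else:
            pieces[-1].append(op)
    if len(pieces) == 1:
        return [aln]
    out = []
    for ops in pieces:
        ops = _trim_terminal_mismatches(ops)
        if not ops:
            continue
        cand = alignment_from_ops(aln.reference_id, tuple(ops), params)
        if cand.score >= params.min_score and cand.aligned_read_length >= params.min_length:
            out.append(cand)
    return out


def best_local(reference_id: str, ref: str, read: str, params: AlignParams,
               ref_offset: int = 0, read_offset: int = 0) -> LocalAlignment | None:
    """Best-scoring local alignment, or None when nothing aligns."""
    if not read or not ref:
        return None
    alns = _aligner(params, "local").align(ref, read)
    if len(alns) == 0 or alns.score <= 0:
        return None
    a = alns[0]
    ops = _ops_from_alignment(a, ref, read, ref_offset, read_offset)
    if not ops:
        return None
    return alignment_from_ops(reference_id, ops, params)


def hamming_alignment(reference_id: str, ref: str, read: str, ref_offset: int,
                      params: AlignParams) -> LocalAlignment | None:
    """Gap-free alignment of ``read`` against ``ref[ref_offset:]`` (fast path).

    Terminal mismatches are trimmed as a score-optimal local alignment would.
    Returns None if the resulting score falls below ``min_score``.
    """
    window = ref[ref_offset:ref_offset + len(read)]
    if len(window) != len(read):
        return None
    ops: list[Op] = []
    run_kind, run_start = None, 0
    for i, (a, b) in enumerate(zip(window, read)):
        kind = "M" if a == b else "X"
        if kind != run_kind:
            if run_kind is not None:
                ops.append((run_kind, ref_offset + run_start, run_start, i - run_start))
            run_kind, run_start = kind, i
    if run_kind is not None:
        ops.append((run_kind, ref_offset + run_start, run_start, len(read) - run_start))
    ops = _trim_terminal_mismatches(ops)
    if not ops:
        return None
    aln = alignment_from_ops(reference_id, tuple(ops), params)
    if aln.score < params.min_score or aln.aligned_read_length < params.min_length:
        return None
    return aln


def align_local(read: str, references: dict[str, str],
                params: AlignParams = AlignParams()) -> list[LocalAlignment]:
    """All qualifying local alignments between read segments and the references.

    For each reference, the best local alignment is found, its read span is
    masked, and the flanking segments are realigned until no segment of at
    least ``min_length`` produces a qualifying alignment.  Alignments are
    post-split at gaps longer than ``max_gap``.  The empty list is a valid
    result.
    """
    results: list[LocalAlignment] = []
    for ref_id, ref_seq in references.items():
        stack = [(0, len(read))]
        while stack:
            a, b = stack.pop()
            if b - a < params.min_length:
                continue
            raw = best_local(ref_id, ref_seq, read[a:b], params,
                             ref_offset=0, read_offset=a)
            if raw is None or raw.score < params.min_score:
                continue
            pieces: list[LocalAlignment] = []
            if raw.aligned_read_length >= params.min_length:
                pieces = split_long_gaps(raw, params)
                results.extend(pieces)
            if not pieces:
                stack.append((a, raw.read_start))
                stack.append((raw.read_end, b))
                continue
            # realign every read segment not claimed by a piece, including
            # segments between pieces (the read side of long insertions)
            prev = a
            for p in sorted(pieces, key=lambda x: x.read_start):
                if p.read_start > prev:
                    stack.append((prev, p.read_start))
                prev = max(prev, p.read_end)
            stack.append((prev, b))
    results.sort(key=lambda x: (x.read_start, x.read_end, x.reference_id, x.ref_start))
    return results


DEFAULT_PRIORITY = ("screen_vector", "pegrna")


def prune_parsimonious(alignments: list[LocalAlignment],
                       ref_priority: tuple[str, ...] = DEFAULT_PRIORITY) -> list[LocalAlignment]:
    """Greedy minimal covering set, ordered by read coordinate.

    Iteratively takes the alignment adding the most uncovered read bases; ties
    broken by higher score, then reference priority (vector before pegRNA
    before decoys), then leftmost read start.  Stops when no alignment adds
    coverage, so the selected set always reaches the coverage of the full
    input union.
    """

    def prio(a: LocalAlignment) -> int:
        try:
            return ref_priority.index(a.reference_id)
        except ValueError:
            return len(ref_priority)

    remaining = list(alignments)
    covered: set[int] = set()
    chosen: list[LocalAlignment] = []
    while remaining:
        best, best_key = None, None
        for a in remaining:
            gain = len(a.covered - covered)
            key = (-gain, -a.score, prio(a), a.read_start, a.ref_start)
            if best_key is None or key < best_key:
                best, best_key = a, key
        if best is None or -best_key[0] == 0:
            break
        chosen.append(best)
        covered |= best.covered
        remaining.remove(best)
    chosen.sort(key=lambda x: (x.read_start, x.read_end))
    return chosen


def total_coverage(alignments: list[LocalAlignment]) -> int:
    cov: set[int] = set()
    for a in alignments:
        cov |= a.covered
    return len(cov)


def explanation_cost(alignments: list[LocalAlignment], lo: int, hi: int) -> int:
    """Read bases in [lo, hi) that no alignment matches exactly.

    Measures how well a set of alignments accounts for a stretch of the read:
    a base is explained when at least one alignment places it in a match
    column; mismatched, inserted and unaligned bases all count one.
    """
    matched: set[int] = set()
    for a in alignments:
        for k, _, rs, l in a.ops:
            if k == "M":
                matched.update(range(rs, rs + l))
    return sum(1 for i in range(lo, hi) if i not in matched)
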