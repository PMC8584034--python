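"""Decision-tree classification of prime-editing outcome reads.

Each quality-passing read (oriented to the vector top strand) is aligned
locally to the screen vector, the pegRNA (in extended-flap sense) and decoy
references; the alignment set is pruned to a parsimonious subset; and the
configuration of that subset is parsed through an ordered decision tree:

1. UNEDITED - one clean full-coverage vector alignment, reference base at the
   programmed-edit position, no indels (1-nt deletions farther than 5 nt from
   every programmed nick are disregarded as sequencing/PCR errors).
2. INTENDED_EDIT - as above but with the programmed substitution installed.
3. SCAFFOLD_EDITS - a pegRNA alignment whose PBS and RTT co-locate on the read
   with a full-coverage vector alignment's PBS/RTT, with fewer edits than the
   vector alignment over the same read span (reverse transcription ran into
   pegRNA scaffold sequence).
4. UNINTENDED_PEGRNA_JOINING - a pegRNA alignment co-locates its PBS with a
   vector alignment's PBS, but no vector alignment places the RTT in its
   native continuation context (the flap rejoined the vector elsewhere).
5. DELETION - vector alignments cover the read but omit a vector segment
   (either an indel gap within one alignment or a junction between two).
6. TANDEM_DUPLICATION - consecutive vector alignments on the read overlap on
   the reference.
7. UNCATEGORIZED - fallback (including decoy-only and unalignable reads).

Deletion and duplication boundaries are reported at their minimal vector
coordinates when microhomology makes them degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .align import (AlignParams, LocalAlignment, align_local, explanation_cost,
                    hamming_alignment, prune_parsimonious, total_coverage)
from .outcomes import Category, OutcomeRecord
from .vector import ScreenVectorSpec, pegrna_feature_intervals


@dataclass(frozen=True)
class ClassifierConfig:
    align: AlignParams = AlignParams()
    terminal_tolerance: int = 2      # unaligned read bases tolerated at each end
    max_mismatches: int = 5          # stray mismatches tolerated in rules 1/2/5a
    junction_slop: int = 2           # uncovered read bases tolerated at a junction
    colocate_frac: float = 0.5       # feature read-span overlap for "co-location"
    rtt_continuation: int = 3        # aligned bases beyond RTT 3' end = native context
    onent_del_window: int = 5        # 1-nt deletions within this of a nick are real
    primer_window: int = 10          # exclusion window around amplicon primers
    decoy_trigger: int = 30          # align decoys when >this many read bases unexplained


def canonical_interval(seq: str, start: int, end: int) -> tuple[int, int]:
    """Slide a half-open interval to minimal coordinates among degenerate placements.

    Removing (or duplicating) ``seq[start:end]`` yields the same product as
    removing ``seq[start-1:end-1]`` whenever ``seq[start-1] == seq[end-1]``
    (microhomology); the minimal-coordinate representative is reported.
    """
    while start > 0 and seq[start - 1] == seq[end - 1]:
        start -= 1
        end -= 1
    return start, end


def deletion_overlaps_primer_window(spec: ScreenVectorSpec, del_start: int, del_end: int,
                                    window: int = 10) -> bool:
    """True when the inclusive deleted interval touches a primer ± ``window`` nt."""
    for ps, pe in (spec.primer_fwd_interval, spec.primer_rev_interval):
        if del_start < pe + window and del_end >= ps - window:
            return True
    return False


def extract_deletion_boundaries(record: OutcomeRecord, spec: ScreenVectorSpec,
                                primer_window: int = 10) -> tuple[int, int]:
    """Canonical inclusive deletion boundaries; flags primer-window exclusion.

    Among microhomology-degenerate boundary pairs the pair with minimal vector
    coordinates is chosen.  The record is flagged ``boundary_excluded`` when
    the deleted region overlaps a ``primer_window``-nt window around either
    amplicon primer (mutated in place); such reads stay DELETION but are
    omitted from boundary statistics.
    """
    if record.category is not Category.DELETION:
        raise ValueError("deletion boundaries are defined only for DELETION records")
    s, e = canonical_interval(spec.sequence, record.del_start, record.del_end + 1)
    record.del_start, record.del_end = s, e - 1
    record.boundary_excluded = deletion_overlaps_primer_window(spec, s, e - 1, primer_window)
    return s, e - 1


def _near_nick(pos: int, nicks: tuple[int, ...], window: int) -> bool:
    # pos is the index of a deleted base; a nick at between-base coordinate n
    # is "within w nt" of bases n-w .. n+w-1
    return any(n - window <= pos <= n + window - 1 for n in nicks)


def _disregardable(op, spec: ScreenVectorSpec, window: int) -> bool:
    kind, fs, _, length = op
    return kind == "D" and length == 1 and not _near_nick(fs, spec.nicks, window)


def _edit_ref_positions(aln: LocalAlignment, lo: int, hi: int, skip_ref_pos: int) -> list[int]:
    """Reference positions of an alignment's edits within read span [lo, hi),
    excluding a mismatch at ``skip_ref_pos`` (the programmed substitution)."""
    positions = []
    for k, fs, rs, l in aln.ops:
        if k == "X":
            positions.extend(fs + i for i in range(l)
                             if lo <= rs + i < hi and fs + i != skip_ref_pos)
        elif k == "I":
            if any(lo <= rs + i < hi for i in range(l)):
                positions.append(fs)
        elif k == "D" and lo <= rs < hi:
            positions.append(fs)
    return positions


def _extend_exact(a: LocalAlignment, read: str, ref: str) -> LocalAlignment:
    """Maximal exact-match extension of both alignment ends.

    The recursive alignment search masks read segments already claimed, so an
    alignment abutting a duplication junction can stop short of read bases it
    matches exactly (they were claimed by the other copy's alignment first).
    Extension restores the full diagonal so junction refinement and
    explanation costs see every placement the reference supports.
    """
    left = 0
    while (a.read_start - left > 0 and a.ref_start - left > 0
           and read[a.read_start - left - 1] == ref[a.ref_start - left - 1]):
        left += 1
    right = 0
    while (a.read_end + right < len(read) and a.ref_end + right < len(ref)
           and read[a.read_end + right] == ref[a.ref_end + right]):
        right += 1
    if not left and not right:
        return a
    ops = list(a.ops)
    if left:
        ops.insert(0, ("M", a.ref_start - left, a.read_start - left, left))
    if right:
        ops.append(("M", a.ref_end, a.read_end, right))
    return replace(a, ref_start=a.ref_start - left, read_start=a.read_start - left,
                   ref_end=a.ref_end + right, read_end=a.read_end + right,
                   ops=tuple(ops), score=a.score + left + right)


def _ref_matched(a: LocalAlignment, ref_pos: int) -> bool:
    """True when ``ref_pos`` is aligned as a match column."""
    return any(k == "M" and fs <= ref_pos < fs + l for k, fs, _, l in a.ops)


def _gapfree_offset(a: LocalAlignment) -> int | None:
    """ref - read diagonal offset for alignments without internal indels."""
    if any(op[0] in "ID" for op in a.ops):
        return None
    return a.ref_start - a.read_start


def _refine_junction(read: str, seq: str, v1: LocalAlignment,
                     v2: LocalAlignment) -> tuple[int, int, int] | None:
    """Optimal junction read position between two gap-free flanking alignments.

    A structural junction (deletion or duplication) splits the read between
    two diagonals; local alignment ends can over- or under-shoot the junction
    by absorbing chance matches.  This rescans every candidate split position
    and returns (t, d1, d2) minimizing total mismatches (leftmost t on ties),
    where d1/d2 are the two diagonal offsets; the event's reference interval
    is then [t + d1, t + d2) for deletions and [t + d2, t + d1) for
    duplications.
    """
    d1, d2 = _gapfree_offset(v1), _gapfree_offset(v2)
    if d1 is None or d2 is None or d1 == d2:
        return None
    lo = max(v1.read_start + 1, -min(d1, d2))
    hi = min(v2.read_end, len(seq) - max(d1, d2))
    if lo >= hi:
        return None
    n = len(seq)

    def mism(i: int, d: int) -> int:
        p = i + d
        return 1 if (p < 0 or p >= n or read[i] != seq[p]) else 0

    total2 = sum(mism(i, d2) for i in range(lo, hi))
    best_t, best_cost = lo, total2
    cost_left = 0
    suffix2 = total2
    for t in range(lo, hi):
        cost = cost_left + suffix2
        if cost < best_cost:
            best_cost, best_t = cost, t
        cost_left += mism(t, d1)
        suffix2 -= mism(t, d2)
    if cost_left + suffix2 < best_cost:
        best_t = hi
    return best_t, d1, d2


def _colocated(span_a, span_b, frac: float) -> bool:
    if span_a is None or span_b is None:
        return False
    lo_a, hi_a, _ = span_a
    lo_b, hi_b, _ = span_b
    overlap = min(hi_a, hi_b) - max(lo_a, lo_b)
    need = frac * min(hi_a - lo_a, hi_b - lo_b)
    return overlap > 0 and overlap >= need


def classify_outcome(alignments: list[LocalAlignment], spec: ScreenVectorSpec, read: str,
                     read_id: str = "", sgrna_id: str = "",
                     all_alignments: list[LocalAlignment] | None = None,
                     config: ClassifierConfig = ClassifierConfig()) -> OutcomeRecord:
    """Assign one outcome category to a read given its parsimonious alignments.

    ``alignments`` is the pruned set; ``all_alignments`` optionally supplies
    the unpruned set so pegRNA evidence pruned for redundancy can still inform
    the scaffold-edit comparison.
    """
    L = len(read)
    tol = config.terminal_tolerance
    peg = [a for a in alignments if a.reference_id == spec.pegrna_id]
    peg_all = list(peg)
    vec_all = [a for a in alignments if a.reference_id == spec.vector_id]
    if all_alignments:
        for a in all_alignments:
            if a.reference_id == spec.pegrna_id and a not in peg_all:
                peg_all.append(a)
            elif a.reference_id == spec.vector_id and a not in vec_all:
                vec_all.append(a)
    vec_all = [_extend_exact(a, read, spec.sequence) for a in vec_all]
    # vector-only parsimony: a pegRNA alignment can outcompete an equally good
    # vector alignment in the mixed pruned set (the pegRNA copies vector
    # sequence around the nick), so structural rules use the best vector-only
    # explanation of the read
    vec = prune_parsimonious(vec_all)
    peg_feats = pegrna_feature_intervals(spec)
    edit_pos, _, alt_base = spec.programmed_edit

    def full_coverage(a: LocalAlignment) -> bool:
        return a.read_start <= tol and a.read_end >= L - tol

    def base_at_edit(v: LocalAlignment) -> str | None:
        rp = v.read_pos_of_ref(edit_pos)
        return read[rp] if rp is not None else None

    def make(category: Category, **detail) -> OutcomeRecord:
        rec = OutcomeRecord(read_id=read_id, sgrna_id=sgrna_id, category=category, **detail)
        if category is Category.DELETION:
            extract_deletion_boundaries(rec, spec, config.primer_window)
        return rec

    # --- rules 1 & 2: single clean vector alignment -------------------------
    if len(vec) == 1 and full_coverage(vec[0]):
        v = vec[0]
        bad_indels = [op for op in v.indels
                      if not _disregardable(op, spec, config.onent_del_window)]
        if not bad_indels:
            base = base_at_edit(v)
            edited = base == alt_base
            stray = v.n_mismatches - (1 if edited else 0)
            if stray <= config.max_mismatches:
                return make(Category.INTENDED_EDIT if edited else Category.UNEDITED)

    # --- rule 3: scaffold-templated edits ------------------------------------
    for v in vec:
        if not full_coverage(v):
            continue
        v_pbs = v.read_span_of_ref_interval(spec.pbs_interval)
        v_rtt = v.read_span_of_ref_interval(spec.rtt_interval)
        for p in peg_all:
            # scaffold-templated edits require pegRNA-only sequence: the
            # alignment must extend past the RTT into the scaffold feature
            if p.read_span_of_ref_interval(peg_feats["scaffold"]) is None:
                continue
            p_pbs = p.read_span_of_ref_interval(peg_feats["pbs"])
            p_rtt = p.read_span_of_ref_interval(peg_feats["rtt"])
            if not (_colocated(p_pbs, v_pbs, config.colocate_frac)
                    and _colocated(p_rtt, v_rtt, config.colocate_frac)):
                continue
            span_lo, span_hi = p.read_start, p.read_end
            if p.edits_in_read_span(span_lo, span_hi) >= v.edits_in_read_span(span_lo, span_hi):
                continue
            # the vector alignment's extra edits (beyond the programmed
            # substitution) must sit 3' of the RTT-templated span and add
            # sequence (insertions/substitutions): scaffold incorporation
            # appends scaffold-templated bases at the RTT 3' junction and
            # cannot remove vector sequence
            has_deletion = any(k == "D" and span_lo <= rs < span_hi
                               and not _disregardable((k, fs, rs, l), spec,
                                                      config.onent_del_window)
                               for k, fs, rs, l in v.ops)
            insert_positions = [fs for k, fs, rs, l in v.ops
                                if k == "I" and span_lo <= rs < span_hi]
            inserts_at_junction = all(fs >= spec.rtt_interval[1] - 1
                                      for fs in insert_positions)
            extra = _edit_ref_positions(v, span_lo, span_hi, edit_pos)
            if extra and not has_deletion and inserts_at_junction:
                return make(Category.SCAFFOLD_EDITS)

    # --- rule 4: reverse-transcribed sequence joined at unintended location --
    for p in peg_all:
        p_pbs = p.read_span_of_ref_interval(peg_feats["pbs"])
        if p_pbs is None:
            continue
        if not any(_colocated(p_pbs, v.read_span_of_ref_interval(spec.pbs_interval),
                              config.colocate_frac) for v in vec):
            continue
        # the pegRNA alignment must explain its read span better than any
        # vector explanation can (a flap product carries pegRNA-only sequence)
        if (explanation_cost([p], p.read_start, p.read_end)
                >= explanation_cost(vec_all, p.read_start, p.read_end)):
            continue
        p_rtt = p.read_span_of_ref_interval(peg_feats["rtt"])
        intended_context = False
        for v in vec:
            v_rtt = v.read_span_of_ref_interval(spec.rtt_interval)
            if not _colocated(p_rtt, v_rtt, config.colocate_frac):
                continue
            # RTT sits at its intended location only when the vector alignment
            # continues past the RTT 3' end into native downstream sequence:
            # the reference bases immediately following the RTT must be
            # present as matched columns (a gapped or mismatched continuation
            # is a junction, not native context)
            rtt_end = spec.rtt_interval[1]
            if all(_ref_matched(v, q) for q in
                   range(rtt_end, rtt_end + config.rtt_continuation)):
                intended_context = True
                break
        if not intended_context:
            # junction = vector position aligned where the pegRNA-explained
            # span ends (approximate under junction microhomology)
            cands = []
            for v in vec:
                for k, fs, rs, l in v.ops:
                    if k not in "MX" or rs + l <= p.read_end:
                        continue
                    rp = max(rs, p.read_end)
                    cands.append((rp, fs + (rp - rs)))
            junction = min(cands)[1] if cands else None
            return make(Category.UNINTENDED_PEGRNA_JOINING, junction=junction)

    # --- rules 5 & 6: deletion / tandem duplication ---------------------------
    # (a) one full-coverage vector alignment whose only structural feature is
    # deletion gaps: a deletion small enough for the affine aligner to bridge
    if len(vec) == 1 and full_coverage(vec[0]) and vec[0].n_mismatches <= config.max_mismatches + 1:
        gaps = [op for op in vec[0].indels
                if op[0] == "D" and not _disregardable(op, spec, config.onent_del_window)]
        inserts = [op for op in vec[0].indels if op[0] == "I"]
        if gaps and not inserts:
            _, fs, _, length = max(gaps, key=lambda op: op[3])
            return make(Category.DELETION, del_start=fs, del_end=fs + length - 1)
    # (b) junctions between consecutive vector alignments that collectively
    # cover the read: reference coordinates jump forward across a junction for
    # deletions and backward for tandem duplications
    if len(vec) >= 2:
        ends_ok = vec[0].read_start <= tol and vec[-1].read_end >= L - tol
        interior_ok = all(b.read_start - a.read_end <= config.junction_slop
                          for a, b in zip(vec, vec[1:]))
        if ends_ok and interior_ok:
            deletions: list[tuple[int, int]] = []
            duplications: list[tuple[int, int]] = []
            for a, b in zip(vec, vec[1:]):
                refined = _refine_junction(read, spec.sequence, a, b)
                if refined is not None:
                    t, d1, d2 = refined
                    if d2 > d1:
                        deletions.append((t + d1, t + d2))
                    else:
                        duplications.append((t + d2, t + d1))
                    continue
                overlap = max(0, a.read_end - b.read_start)
                s, e = a.ref_end - overlap, b.ref_start
                if e > s:
                    deletions.append((s, e))
                elif e < s:
                    duplications.append((e, s))
            if deletions and not duplications:
                s, e = max(deletions, key=lambda x: x[1] - x[0])
                return make(Category.DELETION, del_start=s, del_end=e - 1)
            if duplications:
                s, e = max(duplications, key=lambda x: x[1] - x[0])
                s, e = canonical_interval(spec.sequence, s, e)
                return make(Category.TANDEM_DUPLICATION, dup_start=s, dup_end=e - 1)

    # --- rule 7: fallback ------------------------------------------------------
    if not alignments:
        sublabel = "no_alignment"
    elif not vec and not peg:
        sublabel = "decoy_only"
    else:
        sublabel = ""
    return OutcomeRecord(read_id=read_id, sgrna_id=sgrna_id,
                         category=Category.UNCATEGORIZED, sublabel=sublabel)


def screen_references(spec: ScreenVectorSpec,
                      decoys: dict[str, str] | None = None) -> dict[str, str]:
    """Reference dict for alignment: screen vector, pegRNA (flap sense), decoys."""
    refs = {spec.vector_id: spec.sequence, spec.pegrna_id: spec.pegrna_sequence}
    if decoys:
        refs.update(decoys)
    return refs


def classify_read(read: str, spec: ScreenVectorSpec,
                  decoys: dict[str, str] | None = None,
                  read_id: str = "", sgrna_id: str = "",
                  config: ClassifierConfig = ClassifierConfig()) -> OutcomeRecord:
    """Align one oriented read and classify it (pure function of its inputs).

    Indel-free reads matching the vector tail are recognized by a gap-free
    comparison before invoking the full local-alignment search; decoy
    references are only aligned when vector and pegRNA alignments leave a
    substantial part of the read unexplained.  Both shortcuts reproduce what
    the full search would return for those reads.
    """
    # fast path: read is a gap-free copy of the vector suffix window
    offset = len(spec.sequence) - len(read)
    if offset >= 0:
        window = spec.sequence[offset:]
        mism = sum(a != b for a, b in zip(window, read))
        if mism <= config.max_mismatches + 1:
            fast = hamming_alignment(spec.vector_id, spec.sequence, read, offset, config.align)
            if fast is not None:
                return classify_outcome([fast], spec, read, read_id, sgrna_id, config=config)

    primary = screen_references(spec)
    alns = align_local(read, primary, config.align)
    if decoys and total_coverage(alns) < len(read) - config.decoy_trigger:
        alns = alns + align_local(read, decoys, config.align)
        alns.sort(key=lambda x: (x.read_start, x.read_end, x.reference_id, x.ref_start))
    pruned = prune_parsimonious(alns)
    return classify_outcome(pruned, spec, read, read_id, sgrna_id,
                            all_alignments=alns, config=config)
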