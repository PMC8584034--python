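"""Arrayed amplicon editing quantification.

Quantifies prime-editing outcomes at an endogenous-style amplicon with a
window-based scheme: reads are globally aligned to the reference, a
quantification window spanning the sequence between the pegRNA- and
nicking-sgRNA-directed cut sites plus >=10 nt on both sides is applied, and
the standard frequencies are computed:

* substitution editing = (intended-base frequency among aligned, non-discarded
  reads) x (aligned non-discarded / aligned);
* allele (HDR-style) editing = expected-allele reads / aligned reads;
* indels = indel-containing reads / aligned reads;

where "discarded" reads are those whose alignment has an insertion or deletion
overlapping the window.  The same window is used whether or not a nicking
sgRNA was present.  Heterozygous-sample correction and off-target marker
calling follow the same counting conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import AlignParams, Op, _aligner, _ops_from_alignment, hamming_alignment


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon with edit description and quantification window."""

    sequence: str
    pegrna_nick: int                       # between-base cut position
    nick_sgrna_nick: int | None = None     # complementary-strand cut, if any
    # substitution edit: (position, ref base, alt base); None for allele-style edits
    substitution: tuple[int, str, str] | None = None
    expected_allele: str | None = None     # full edited amplicon for non-SNV edits
    window: tuple[int, int] | None = None  # override; default built by quantification_window
    window_pad: int = 10

    def __post_init__(self) -> None:
        if self.substitution is None and self.expected_allele is None:
            raise ValueError("an edit must be specified (substitution or expected allele)")
        if self.substitution is not None:
            pos, ref, _ = self.substitution
            if not (0 <= pos < len(self.sequence)):
                raise ValueError("edit position outside the amplicon")
            if self.sequence[pos] != ref:
                raise ValueError(
                    f"reference base at {pos} is {self.sequence[pos]!r}, stated {ref!r}"
                )

    @property
    def edited_sequence(self) -> str:
        if self.expected_allele is not None:
            return self.expected_allele
        pos, _, alt = self.substitution
        return self.sequence[:pos] + alt + self.sequence[pos + 1:]


def quantification_window(spec: AmpliconSpec) -> tuple[int, int]:
    """Window spanning the inter-nick sequence plus ``window_pad`` nt beyond both cuts.

    Used identically with and without a nicking sgRNA (a PE2 sample is scored
    in the same window as its PE3/PE5 counterpart).
    """
    if spec.window is not None:
        return spec.window
    cuts = [spec.pegrna_nick]
    if spec.nick_sgrna_nick is not None:
        cuts.append(spec.nick_sgrna_nick)
    lo = max(0, min(cuts) - spec.window_pad)
    hi = min(len(spec.sequence), max(cuts) + spec.window_pad)
    return lo, hi


@dataclass
class ReadCall:
    """Per-read alignment summary used by the frequency formulas."""

    read_id: str
    aligned: bool
    identity: float = 0.0
    indel_in_window: bool = False
    base_at_edit: str | None = None
    window_seq: str | None = None
    ops: tuple[Op, ...] = ()
    read_seq: str = ""

    @property
    def discarded(self) -> bool:
        return self.indel_in_window


def _global_ops(ref: str, read: str, params: AlignParams) -> tuple[tuple[Op, ...], float]:
    if ref == read:
        ops = (("M", 0, 0, len(ref)),)
        return ops, 1.0
    if len(ref) == len(read):
        aln = hamming_alignment("amplicon", ref, read, 0, params)
        if aln is not None and aln.n_mismatches <= 0.35 * len(ref):
            ncols = aln.aligned_read_length
            return aln.ops, (ncols - aln.n_mismatches) / len(ref)
    alns = _aligner(params, "global").align(ref, read)
    ops = _ops_from_alignment(alns[0], ref, read)
    ncols = sum(l for _, _, _, l in ops)
    matches = sum(l for k, _, _, l in ops if k == "M")
    return ops, matches / max(ncols, 1)


def _read_pos_at_or_after(ops: Sequence[Op], ref_pos: int) -> int | None:
    best = None
    for k, fs, rs, l in ops:
        if k not in "MX":
            continue
        if fs + l <= ref_pos:
            continue
        rp = rs + max(0, ref_pos - fs)
        best = rp if best is None else min(best, rp)
    return best


def align_and_window(reads: Iterable[tuple[str, str]], spec: AmpliconSpec,
                     identity_threshold: float = 0.65,
                     params: AlignParams = AlignParams()) -> list[ReadCall]:
    """Globally align reads and extract per-read calls within the quantification window.

    A read is *aligned* when its global identity (matches over alignment
    columns) reaches ``identity_threshold``; *indel-containing* when an
    insertion or deletion overlaps the window.
    """
    ws, we = quantification_window(spec)
    edit_pos = spec.substitution[0] if spec.substitution else None
    calls: list[ReadCall] = []
    for read_id, seq in reads:
        ops, identity = _global_ops(spec.sequence, seq, params)
        if identity < identity_threshold:
            calls.append(ReadCall(read_id, aligned=False, identity=identity, read_seq=seq))
            continue
        indel = False
        for k, fs, rs, l in ops:
            if k == "D" and fs < we and fs + l > ws:
                indel = True
            elif k == "I" and ws < fs < we:
                indel = True
        base = None
        if edit_pos is not None:
            for k, fs, rs, l in ops:
                if k in "MX" and fs <= edit_pos < fs + l:
                    base = seq[rs + (edit_pos - fs)]
                    break
        rp_lo = _read_pos_at_or_after(ops, ws)
        rp_hi = _read_pos_at_or_after(ops, we)
        if rp_hi is None:  # window runs to the end of aligned read
            rp_hi = max((rs + l for k, _, rs, l in ops if k in "MXI"), default=None)
        window_seq = seq[rp_lo:rp_hi] if rp_lo is not None and rp_hi is not None else None
        calls.append(ReadCall(read_id, aligned=True, identity=identity,
                              indel_in_window=indel, base_at_edit=base,
                              window_seq=window_seq, ops=ops, read_seq=seq))
    return calls


def quantify_substitution(calls: list[ReadCall], spec: AmpliconSpec) -> float:
    """Single-base substitution editing frequency, in percent.

    (frequency of the intended base among aligned, non-discarded reads)
    x (aligned non-discarded reads / aligned reads) x 100.
    """
    if spec.substitution is None:
        raise ValueError("substitution quantification requires a substitution edit spec")
    alt = spec.substitution[2]
    aligned = [c for c in calls if c.aligned]
    if not aligned:
        raise ValueError("no aligned reads")
    kept = [c for c in aligned if not c.discarded]
    if not kept:
        return 0.0
    sub_freq = sum(1 for c in kept if c.base_at_edit == alt) / len(kept)
    return 100.0 * sub_freq * (len(kept) / len(aligned))


def quantify_allele_edit(calls: list[ReadCall], spec: AmpliconSpec) -> float:
    """Editing frequency for non-substitution edits: expected-allele reads / aligned reads (%).

    A read matches when its window sequence equals the expected allele's
    window sequence.
    """
    ws, we = quantification_window(spec)
    expected = spec.edited_sequence
    # project the window onto the expected allele via its alignment to the reference
    ops, _ = _global_ops(spec.sequence, expected, AlignParams())
    lo = _read_pos_at_or_after(ops, ws)
    hi = _read_pos_at_or_after(ops, we)
    if hi is None:
        hi = len(expected)
    expected_window = expected[lo:hi]
    aligned = [c for c in calls if c.aligned]
    if not aligned:
        raise ValueError("no aligned reads")
    n_hdr = sum(1 for c in aligned if c.window_seq == expected_window)
    return 100.0 * n_hdr / len(aligned)


def quantify_indels(calls: list[ReadCall]) -> float:
    """Indel frequency: indel-containing reads / aligned reads, in percent."""
    aligned = [c for c in calls if c.aligned]
    if not aligned:
        raise ValueError("no aligned reads")
    return 100.0 * sum(1 for c in aligned if c.indel_in_window) / len(aligned)


def correct_heterozygous(editing_pct: float, mock_pct: float) -> tuple[float, bool]:
    """Editable-allele correction: (editing - mock) / (100 - mock), in percent.

    For a sample heterozygous at the target, mock controls measure the
    pre-existing edited-allele fraction; the corrected value estimates the
    fraction of *editable* alleles converted.  Returns (value, clamped):
    values below zero are clamped to 0 and flagged.
    """
    if mock_pct >= 100.0:
        raise ValueError("mock editing frequency must be below 100%")
    value = 100.0 * (editing_pct - mock_pct) / (100.0 - mock_pct)
    if value < 0:
        return 0.0, True
    return value, False


def derive_offtarget_marker(reference: str, nick: int, flap: str) -> str | None:
    """Shortest flap prefix deviating from the reference 3' of the nick.

    Comparing from the 5' ends of the flap and of the reference sequence 3' of
    the Cas9 nick, returns the minimal flap prefix that differs; None when the
    flap is a prefix of the reference (no deviation, hence no marker).
    """
    if not flap:
        raise ValueError("flap must be non-empty")
    target = reference[nick:]
    for i, base in enumerate(flap):
        if i >= len(target) or base != target[i]:
            return flap[:i + 1]
    return None


def call_offtarget_reads(calls: list[ReadCall], marker: str, nick: int) -> float:
    """Off-target frequency: aligned reads carrying ``marker`` directly 3' of the nick (%).

    Indel-containing reads are included in the numerator.
    """
    if not marker:
        raise ValueError("off-target calling requires a non-empty marker")
    aligned = [c for c in calls if c.aligned]
    if not aligned:
        raise ValueError("no aligned reads")
    n = 0
    for c in aligned:
        rp = _read_pos_at_or_after(c.ops, nick)
        if rp is not None and c.read_seq[rp:rp + len(marker)] == marker:
            n += 1
    return 100.0 * n / len(aligned)


def background_mismatch_rate(calls: list[ReadCall], spec: AmpliconSpec) -> float:
    """Mean per-position mismatch rate at non-edit positions of aligned reads.

    Reported alongside off-target/substitution estimates as a sequencing-error
    context check: an apparent editing rate comparable to this background may
    be overestimated.
    """
    edit_pos = spec.substitution[0] if spec.substitution else -1
    mism = cols = 0
    for c in calls:
        if not c.aligned:
            continue
        for k, fs, _, l in c.ops:
            if k not in "MX":
                continue
            span = l
            hit_edit = fs <= edit_pos < fs + l
            cols += span - (1 if hit_edit else 0)
            if k == "X":
                mism += span - (1 if hit_edit else 0)
    return mism / cols if cols else 0.0


@dataclass
class EditQuantReport:
    """Summary counts and frequencies for one amplicon sample."""

    n_reads: int
    n_aligned: int
    n_discarded: int
    editing_pct: float
    indel_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.editing_pct <= 100 and 0 <= self.indel_pct <= 100):
            raise ValueError("frequencies must be percentages in [0, 100]")
        if self.n_discarded > self.n_aligned:
            raise ValueError("discarded reads cannot exceed aligned reads")


def quantify_amplicon(reads: Iterable[tuple[str, str]], spec: AmpliconSpec,
                      identity_threshold: float = 0.65) -> EditQuantReport:
    """End-to-end quantification of one sample (substitution or allele mode)."""
    calls = align_and_window(reads, spec, identity_threshold)
    if spec.substitution is not None and spec.expected_allele is None:
        editing = quantify_substitution(calls, spec)
    else:
        editing = quantify_allele_edit(calls, spec)
    return EditQuantReport(
        n_reads=len(calls),
        n_aligned=sum(c.aligned for c in calls),
        n_discarded=sum(c.aligned and c.discarded for c in calls),
        editing_pct=editing,
        indel_pct=quantify_indels(calls),
    )
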