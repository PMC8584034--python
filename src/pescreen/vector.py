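"""Screen-vector geometry.

The pooled screen reads out editing outcomes on an integrated lentiviral
cassette: a single amplicon carries a CRISPRi sgRNA (sequenced by a 44-nt
forward read) and a composite prime-edit site (sequenced by a 263-nt reverse
read).  The edit site consists of a pegRNA-directed nick flanked by two
complementary-strand nick targets placed exactly 50 bp upstream and 50 bp
downstream, with a programmed +6 G·C-to-C·G substitution templated by the
pegRNA reverse-transcription template (RTT).

:class:`ScreenVectorSpec` captures that geometry on the vector top strand,
and :func:`build_screen_vector` constructs a concrete, randomized instance
with all invariants enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


class GeometryError(ValueError):
    """Raised when requested vector geometry is internally inconsistent."""


@dataclass(frozen=True)
class ScreenVectorSpec:
    """Top-strand description of the screen vector and its functional features.

    All coordinates are 0-based.  Nick positions are between-base coordinates
    (a nick at ``p`` falls between bases ``p-1`` and ``p``); intervals are
    half-open ``[start, end)``.
    """

    sequence: str
    pegrna_nick: int
    plus50_nick: int
    minus50_nick: int
    programmed_edit: tuple[int, str, str]  # (position, ref base, alt base)
    primer_fwd_interval: tuple[int, int]
    primer_rev_interval: tuple[int, int]
    pbs_interval: tuple[int, int]
    rtt_interval: tuple[int, int]
    scaffold_interval: tuple[int, int]
    r2_window: tuple[int, int]
    pegrna_sequence: str = ""
    scaffold_flap: str = ""
    vector_id: str = "screen_vector"
    pegrna_id: str = "pegrna"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 < self.minus50_nick < self.pegrna_nick < self.plus50_nick < n):
            raise GeometryError("nick positions must be ordered and inside the vector")
        if self.plus50_nick - self.pegrna_nick != 50:
            raise GeometryError("downstream nick must sit exactly 50 bp 3' of the pegRNA nick")
        if self.pegrna_nick - self.minus50_nick != 50:
            raise GeometryError("upstream nick must sit exactly 50 bp 5' of the pegRNA nick")
        pos, ref, alt = self.programmed_edit
        if not (self.rtt_interval[0] <= pos < self.rtt_interval[1]):
            raise GeometryError("programmed edit must fall within the RTT-templated span")
        if self.sequence[pos] != ref:
            raise GeometryError(
                f"vector base at edit position {pos} is {self.sequence[pos]!r}, expected {ref!r}"
            )
        if ref == alt:
            raise GeometryError("programmed edit must change the base")
        for name in ("primer_fwd_interval", "primer_rev_interval", "pbs_interval",
                     "rtt_interval", "scaffold_interval", "r2_window"):
            s, e = getattr(self, name)
            if not (0 <= s <= e <= n):
                raise GeometryError(f"{name} {s, e} outside vector [0, {n})")
        if self.r2_window[1] - self.r2_window[0] != 263:
            raise GeometryError("outcome (R2) window must be exactly 263 nt")

    @property
    def edited_sequence(self) -> str:
        """Vector top strand with the programmed substitution installed."""
        pos, _, alt = self.programmed_edit
        return self.sequence[:pos] + alt + self.sequence[pos + 1:]

    @property
    def rtt_edited(self) -> str:
        """RTT-templated span as written by reverse transcription (edit included)."""
        s, e = self.rtt_interval
        return self.edited_sequence[s:e]

    @property
    def pbs_sequence(self) -> str:
        s, e = self.pbs_interval
        return self.sequence[s:e]

    @property
    def nicks(self) -> tuple[int, int, int]:
        return (self.minus50_nick, self.pegrna_nick, self.plus50_nick)

    def r2_window_sequence(self) -> str:
        s, e = self.r2_window
        return self.sequence[s:e]


@dataclass
class VectorConfig:
    """Parameters for :func:`build_screen_vector`.

    Defaults reproduce the screen amplicon geometry: a 453-bp amplicon, the
    pegRNA nick placed so the composite edit site sits mid-way through the
    263-nt outcome read, complementary-strand nicks at ±50 bp, and a +6
    G-to-C programmed edit.
    """

    length: int = 453
    pegrna_nick: int = 320
    edit_offset: int = 6        # 1-based offset of the edit within the new 3' flap
    edit_ref: str = "G"
    edit_alt: str = "C"
    pbs_length: int = 13
    rtt_length: int = 13
    scaffold_flap_length: int = 20
    primer_length: int = 20
    r2_length: int = 263
    seed: int = 0


def build_screen_vector(config: VectorConfig | None = None, **kwargs) -> ScreenVectorSpec:
    """Construct a randomized screen vector satisfying the composite-site geometry.

    The sequence is random except where features pin bases: the programmed-edit
    position carries ``edit_ref``, and the four vector bases immediately 3' of
    the RTT span are forced to differ base-by-base from the start of the
    pegRNA scaffold flap, so that reverse-transcription products running into
    scaffold sequence are unambiguous against the vector.

    Raises :class:`GeometryError` for inconsistent geometry (nicks outside the
    sequence, edit outside the RTT span, R2 window longer than the amplicon).
    """
    if config is None:
        config = VectorConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a VectorConfig or keyword overrides, not both")
    c = config
    if c.length < c.r2_length:
        raise GeometryError("amplicon must be at least as long as the outcome read")
    if not (1 <= c.edit_offset <= c.rtt_length):
        raise GeometryError("edit offset must lie within the RTT length")
    nick = c.pegrna_nick
    if not (c.pbs_length <= nick - 50 and nick + 50 < c.length):
        raise GeometryError("±50 nicks or PBS fall outside the vector")

    rng = np.random.default_rng(c.seed)
    seq = list(random_dna(rng, c.length))
    edit_pos = nick + c.edit_offset - 1
    seq[edit_pos] = c.edit_ref

    rtt_interval = (nick, nick + c.rtt_length)
    pbs_interval = (nick - c.pbs_length, nick)

    # Scaffold flap: pegRNA-templated sequence 3' of the RTT.  Force the first
    # four flap bases to mismatch the vector continuation so scaffold-derived
    # sequence never silently extends a vector alignment.
    flap = list(random_dna(rng, c.scaffold_flap_length))
    for i in range(min(4, len(flap))):
        vpos = nick + c.rtt_length + i
        choices = [b for b in DNA if b != seq[vpos]]
        flap[i] = choices[int(rng.integers(0, 3))]
    scaffold_flap = "".join(flap)
    sequence = "".join(seq)

    edited_rtt = (sequence[:edit_pos] + c.edit_alt + sequence[edit_pos + 1:])[nick:nick + c.rtt_length]
    pegrna_sequence = sequence[pbs_interval[0]:nick] + edited_rtt + scaffold_flap

    r2_window = (c.length - c.r2_length, c.length)
    return ScreenVectorSpec(
        sequence=sequence,
        pegrna_nick=nick,
        plus50_nick=nick + 50,
        minus50_nick=nick - 50,
        programmed_edit=(edit_pos, c.edit_ref, c.edit_alt),
        primer_fwd_interval=(0, c.primer_length),
        primer_rev_interval=(c.length - c.primer_length, c.length),
        pbs_interval=pbs_interval,
        rtt_interval=rtt_interval,
        # scaffold sequence has no extent on the vector: record its junction
        # (the point where scaffold-templated bases would be inserted)
        scaffold_interval=(nick + c.rtt_length, nick + c.rtt_length),
        r2_window=r2_window,
        pegrna_sequence=pegrna_sequence,
        scaffold_flap=scaffold_flap,
    )


def save_spec(spec: ScreenVectorSpec, path) -> None:
    """Serialize a vector spec to JSON (structured feature description)."""
    import dataclasses
    import json

    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=1)


def load_spec(path) -> ScreenVectorSpec:
    import json

    with open(path) as fh:
        data = json.load(fh)
    for key, value in data.items():
        if isinstance(value, list):
            data[key] = tuple(value)
    return ScreenVectorSpec(**data)


def pegrna_feature_intervals(spec: ScreenVectorSpec) -> dict[str, tuple[int, int]]:
    """Feature intervals on the pegRNA reference (flap sense, 5'→3' on the read).

    The pegRNA reference is stored in the sense of the fully extended 3' flap
    projected onto the vector top strand: PBS-complementary context, then the
    RTT-templated (edited) span, then scaffold-templated sequence.
    """
    pbs_len = spec.pbs_interval[1] - spec.pbs_interval[0]
    rtt_len = spec.rtt_interval[1] - spec.rtt_interval[0]
    return {
        "pbs": (0, pbs_len),
        "rtt": (pbs_len, pbs_len + rtt_len),
        "scaffold": (pbs_len + rtt_len, len(spec.pegrna_sequence)),
    }
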