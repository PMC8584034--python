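"""Microsatellite (homopolymer) length calling.

Sequencing error inside long homopolymers is high, so per-read repeat lengths
are measured *between* the 20-nt sequences expected to flank the homopolymer
rather than by counting repeat bases: for each read, the first window within
Hamming distance 2 of each flank is located, and when both flanks are found in
the expected relative orientation no more than 50 nt apart, the inter-flank
distance is the called length.  Reads are demultiplexed to loci by their first
20 nt.  The method is robust to <=2 substitutions per flank by construction;
it measures the read's apparent homopolymer length, so indel errors inside the
repeat itself are reported as-is, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

FLANK_LENGTH = 20
PREFIX_LENGTH = 20

NO_CALL_LEFT = "left-flank-missing"
NO_CALL_RIGHT = "right-flank-missing"
NO_CALL_ORIENTATION = "orientation"
NO_CALL_SPACING = "spacing>50"


@dataclass(frozen=True)
class MicrosatelliteLocus:
    locus_id: str
    prefix: str       # first 20 nt of the amplicon, used for demultiplexing
    left_flank: str
    right_flank: str
    repeat_unit: str = "A"

    def __post_init__(self) -> None:
        for name in ("left_flank", "right_flank"):
            if len(getattr(self, name)) != FLANK_LENGTH:
                raise ValueError(f"{self.locus_id}: {name} must be {FLANK_LENGTH} nt")
        if len(self.prefix) != PREFIX_LENGTH:
            raise ValueError(f"{self.locus_id}: demux prefix must be {PREFIX_LENGTH} nt")
        if len(self.repeat_unit) != 1:
            raise ValueError("only mononucleotide repeats are supported")
        if self.left_flank.endswith(self.repeat_unit) or self.right_flank.startswith(self.repeat_unit):
            raise ValueError(
                f"{self.locus_id}: flanks must not abut the homopolymer with its own "
                "base, otherwise the repeat boundary is ill-defined"
            )


@dataclass(frozen=True)
class MicrosatelliteCall:
    read_id: str
    locus_id: str
    length: int | None
    no_call_reason: str = ""

    @property
    def called(self) -> bool:
        return self.length is not None


def load_locus_table(path: str | Path) -> list[MicrosatelliteLocus]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    loci = [MicrosatelliteLocus(r.locus_id, r.prefix, r.left_flank, r.right_flank,
                                getattr(r, "repeat_unit", "A"))
            for r in df.itertuples()]
    prefixes = [l.prefix for l in loci]
    if len(set(prefixes)) != len(prefixes):
        raise ValueError("duplicate demultiplexing prefixes in locus table")
    return loci


def write_locus_table(path: str | Path, loci: Iterable[MicrosatelliteLocus]) -> None:
    pd.DataFrame(
        [(l.locus_id, l.prefix, l.left_flank, l.right_flank, l.repeat_unit) for l in loci],
        columns=["locus_id", "prefix", "left_flank", "right_flank", "repeat_unit"],
    ).to_csv(path, sep="\t", index=False)


def demux_msi_reads(reads: Iterable[tuple[str, str]],
                    loci: list[MicrosatelliteLocus]) -> dict[str, list[tuple[str, str]]]:
    """Route reads to loci by exact match of the first 20 nt; rest go to 'undetermined'."""
    by_prefix = {}
    for l in loci:
        if l.prefix in by_prefix:
            raise ValueError(f"duplicate demux prefix {l.prefix}")
        by_prefix[l.prefix] = l.locus_id
    out: dict[str, list[tuple[str, str]]] = {l.locus_id: [] for l in loci}
    out["undetermined"] = []
    for rid, seq in reads:
        out[by_prefix.get(seq[:PREFIX_LENGTH], "undetermined")].append((rid, seq))
    return out


def _first_window(read_arr: np.ndarray, flank_arr: np.ndarray, max_mismatch: int) -> int | None:
    n = read_arr.size - flank_arr.size + 1
    if n <= 0:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(read_arr, flank_arr.size)
    mism = (windows != flank_arr).sum(axis=1)
    idx = np.flatnonzero(mism <= max_mismatch)
    return int(idx[0]) if idx.size else None


def measure_repeat_length(read_id: str, read_seq: str, locus: MicrosatelliteLocus,
                          max_flank_mismatch: int = 2, max_span: int = 50) -> MicrosatelliteCall:
    """Inter-flank distance of the first Hamming-<=2 flank occurrences, or a no-call.

    The left-to-right scan takes the leftmost qualifying window for each flank
    (first occurrence); no-calls record which condition failed: a flank not
    found, flanks out of orientation (right before left), or spacing beyond
    ``max_span`` nt.
    """
    arr = np.frombuffer(read_seq.encode("ascii"), dtype=np.uint8)
    left = np.frombuffer(locus.left_flank.encode("ascii"), dtype=np.uint8)
    right = np.frombuffer(locus.right_flank.encode("ascii"), dtype=np.uint8)
    li = _first_window(arr, left, max_flank_mismatch)
    if li is None:
        return MicrosatelliteCall(read_id, locus.locus_id, None, NO_CALL_LEFT)
    ri = _first_window(arr, right, max_flank_mismatch)
    if ri is None:
        return MicrosatelliteCall(read_id, locus.locus_id, None, NO_CALL_RIGHT)
    left_end = li + FLANK_LENGTH
    if ri < left_end:
        return MicrosatelliteCall(read_id, locus.locus_id, None, NO_CALL_ORIENTATION)
    distance = ri - left_end
    if distance > max_span:
        return MicrosatelliteCall(read_id, locus.locus_id, None, NO_CALL_SPACING)
    return MicrosatelliteCall(read_id, locus.locus_id, distance)


def call_locus(reads: Iterable[tuple[str, str]], locus: MicrosatelliteLocus,
               max_flank_mismatch: int = 2, max_span: int = 50) -> list[MicrosatelliteCall]:
    return [measure_repeat_length(rid, seq, locus, max_flank_mismatch, max_span)
            for rid, seq in reads]


def summarize_msi(calls_by_locus: dict[str, list[MicrosatelliteCall]]) -> pd.DataFrame:
    """Per-locus summary: calls, no-calls, mean length, and the length histogram."""
    rows = []
    for locus_id, calls in calls_by_locus.items():
        lengths = [c.length for c in calls if c.called]
        if not lengths:
            rows.append((locus_id, 0, len(calls), np.nan, {}))
            continue
        values, counts = np.unique(lengths, return_counts=True)
        hist = dict(zip(values.tolist(), counts.tolist()))
        rows.append((locus_id, len(lengths), len(calls) - len(lengths),
                     float(np.mean(lengths)), hist))
    return pd.DataFrame(rows, columns=["locus_id", "n_called", "n_no_call",
                                       "mean_length", "histogram"])


def length_distribution(calls: Iterable[MicrosatelliteCall]) -> pd.DataFrame:
    """Length histogram and cumulative distribution over called reads."""
    lengths = np.array([c.length for c in calls if c.called])
    if lengths.size == 0:
        return pd.DataFrame(columns=["length", "count", "frequency", "cumulative"])
    values, counts = np.unique(lengths, return_counts=True)
    freq = counts / counts.sum()
    return pd.DataFrame({"length": values, "count": counts,
                         "frequency": freq, "cumulative": np.cumsum(freq)})


def mean_length_difference(calls_a: Iterable[MicrosatelliteCall],
                           calls_b: Iterable[MicrosatelliteCall]) -> float:
    """Difference of mean called lengths between two samples (a - b), in nt."""
    a = [c.length for c in calls_a if c.called]
    b = [c.length for c in calls_b if c.called]
    if not a or not b:
        raise ValueError("both samples need at least one called read")
    return float(np.mean(a) - np.mean(b))
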