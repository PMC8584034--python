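"""CRISPRi sgRNA library model.

A screen library is a table of (sgRNA id, gene, 20-nt protospacer) rows, with
non-targeting controls carrying the sentinel gene label ``NON_TARGETING``.
Synthetic libraries are generated with pairwise protospacer Hamming distance
>= 3 so the screen's one-mismatch sgRNA assignment rule is unambiguous by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vector import random_dna

NON_TARGETING = "NON_TARGETING"
PROTOSPACER_LENGTH = 20


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SgRNAEntry:
    sgrna_id: str
    gene: str
    protospacer: str

    @property
    def is_nontargeting(self) -> bool:
        return self.gene == NON_TARGETING


class SgRNALibrary:
    """sgRNA library with protospacer lookup."""

    def __init__(self, entries: list[SgRNAEntry]):
        seen: dict[str, str] = {}
        for e in entries:
            if len(e.protospacer) != PROTOSPACER_LENGTH:
                raise ValueError(f"{e.sgrna_id}: protospacer must be {PROTOSPACER_LENGTH} nt")
            if e.protospacer in seen:
                raise ValueError(
                    f"duplicate protospacer shared by {seen[e.protospacer]} and {e.sgrna_id}"
                )
            seen[e.protospacer] = e.sgrna_id
        self.entries = list(entries)
        self._by_protospacer = {e.protospacer: e for e in self.entries}
        self._by_id = {e.sgrna_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, sgrna_id: str) -> SgRNAEntry:
        return self._by_id[sgrna_id]

    def lookup_protospacer(self, protospacer: str) -> SgRNAEntry | None:
        return self._by_protospacer.get(protospacer)

    @property
    def targeting(self) -> list[SgRNAEntry]:
        return [e for e in self.entries if not e.is_nontargeting]

    @property
    def nontargeting(self) -> list[SgRNAEntry]:
        return [e for e in self.entries if e.is_nontargeting]

    def gene_map(self) -> dict[str, list[str]]:
        """gene -> ordered sgRNA ids, targeting genes only."""
        out: dict[str, list[str]] = {}
        for e in self.targeting:
            out.setdefault(e.gene, []).append(e.sgrna_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.sgrna_id, e.gene, e.protospacer) for e in self.entries],
            columns=["sgrna_id", "gene", "protospacer"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SgRNALibrary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([SgRNAEntry(r.sgrna_id, r.gene, r.protospacer) for r in df.itertuples()])


def generate_sgrna_library(
    n_genes: int,
    sgrnas_per_gene: int,
    n_nontargeting: int,
    seed: int = 0,
    min_distance: int = 3,
    max_attempts_per_entry: int = 2000,
) -> SgRNALibrary:
    """Generate a synthetic library with pairwise protospacer Hamming distance >= ``min_distance``.

    Protospacers are drawn by rejection sampling; raises ``RuntimeError`` if the
    requested count cannot be placed at the requested distance.
    """
    if min(n_genes, sgrnas_per_gene, n_nontargeting) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []

    def draw() -> str:
        for _ in range(max_attempts_per_entry):
            cand = random_dna(rng, PROTOSPACER_LENGTH)
            if all(hamming(cand, p) >= min_distance for p in chosen):
                chosen.append(cand)
                return cand
        raise RuntimeError(
            f"could not place protospacer #{len(chosen) + 1} at Hamming distance "
            f">= {min_distance}; alphabet exhausted for this configuration"
        )

    entries: list[SgRNAEntry] = []
    for g in range(n_genes):
        gene = f"GENE_{g + 1:03d}"
        for k in range(sgrnas_per_gene):
            entries.append(SgRNAEntry(f"{gene}_sg{k + 1}", gene, draw()))
    for k in range(n_nontargeting):
        entries.append(SgRNAEntry(f"NT_{k + 1:03d}", NON_TARGETING, draw()))
    return SgRNALibrary(entries)
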