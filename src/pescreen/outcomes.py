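"""Outcome taxonomy shared by the simulator, classifier and statistics layers."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd


class Category(str, Enum):
    """Editing-outcome categories assigned to each quality-passing read."""

    UNEDITED = "UNEDITED"
    INTENDED_EDIT = "INTENDED_EDIT"
    DELETION = "DELETION"
    TANDEM_DUPLICATION = "TANDEM_DUPLICATION"
    UNINTENDED_PEGRNA_JOINING = "UNINTENDED_PEGRNA_JOINING"
    SCAFFOLD_EDITS = "SCAFFOLD_EDITS"
    UNCATEGORIZED = "UNCATEGORIZED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CATEGORIES: tuple[Category, ...] = tuple(Category)


@dataclass
class OutcomeRecord:
    """One classified read.

    ``del_start``/``del_end`` and ``dup_start``/``dup_end`` are *inclusive*
    first-to-last vector positions (the deletion-boundary convention used for
    position profiles); ``junction`` is the vector position where
    reverse-transcribed sequence rejoined the vector for unintended-joining
    outcomes.  ``boundary_excluded`` marks deletions whose deleted region
    overlaps a 10-nt window around either amplicon primer; such reads keep
    their category but are omitted from boundary statistics.
    """

    read_id: str
    sgrna_id: str
    category: Category
    del_start: int | None = None
    del_end: int | None = None
    dup_start: int | None = None
    dup_end: int | None = None
    junction: int | None = None
    boundary_excluded: bool = False
    sublabel: str = ""

    def __post_init__(self) -> None:
        if self.category is Category.DELETION:
            if self.del_start is None or self.del_end is None:
                raise ValueError("DELETION records require a deletion interval")
            if self.del_end < self.del_start:
                raise ValueError("deletion interval must be non-empty (inclusive coords)")
        if self.category is Category.TANDEM_DUPLICATION and (
            self.dup_start is None or self.dup_end is None
        ):
            raise ValueError("TANDEM_DUPLICATION records require a duplicated interval")


_COLUMNS = [
    "read_id", "sgrna_id", "category", "del_start", "del_end",
    "dup_start", "dup_end", "junction", "boundary_excluded", "sublabel",
]


def records_to_frame(records: list[OutcomeRecord]) -> pd.DataFrame:
    rows = [
        (r.read_id, r.sgrna_id, r.category.value, r.del_start, r.del_end,
         r.dup_start, r.dup_end, r.junction, r.boundary_excluded, r.sublabel)
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[OutcomeRecord]:
    def _opt(v):
        return None if pd.isna(v) else int(v)

    return [
        OutcomeRecord(
            read_id=str(r.read_id),
            sgrna_id=str(r.sgrna_id),
            category=Category(r.category),
            del_start=_opt(r.del_start),
            del_end=_opt(r.del_end),
            dup_start=_opt(r.dup_start),
            dup_end=_opt(r.dup_end),
            junction=_opt(r.junction),
            boundary_excluded=bool(r.boundary_excluded),
            sublabel="" if pd.isna(r.sublabel) else str(r.sublabel),
        )
        for r in df.itertuples()
    ]


def write_records(path: str | Path, records: list[OutcomeRecord]) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[OutcomeRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))
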