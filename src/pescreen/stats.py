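"""Screen statistics: per-sgRNA frequencies, gene-level effects, deletion profiles.

Outcome counts per sgRNA and category are collected into a matrix; baseline
category frequencies come from pooling all non-targeting sgRNAs; per-sgRNA
log2 fold changes are taken against that baseline with pseudocount
regularization; and each gene's effect is the mean of its two sgRNAs with the
most extreme absolute log2 fold changes (a compromise between multi-sgRNA
support and tolerance of inactive sgRNAs).  Random sets of non-targeting
sgRNAs ("quasi-genes") passed through the same selection give the empirical
null.  Deletion outcomes additionally yield per-position frequency profiles
and the fraction of deletions reaching far outside the programmed nicks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .library import SgRNALibrary
from .outcomes import CATEGORIES, Category, OutcomeRecord
from .vector import ScreenVectorSpec

CATEGORY_NAMES = [c.value for c in CATEGORIES]


def tally_outcomes(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    """sgRNA x category count matrix; the per-row denominator is the row sum.

    Reads with sentinel sgRNA assignments (UNASSIGNED/AMBIGUOUS) must be
    removed upstream; they are rejected here to prevent silent leakage.
    """
    counts: dict[str, np.ndarray] = {}
    cat_index = {c.value: i for i, c in enumerate(CATEGORIES)}
    for r in records:
        if r.sgrna_id in ("UNASSIGNED", "AMBIGUOUS", ""):
            raise ValueError(f"record {r.read_id} carries sentinel sgRNA {r.sgrna_id!r}")
        row = counts.setdefault(r.sgrna_id, np.zeros(len(CATEGORIES), dtype=int))
        row[cat_index[r.category.value]] += 1
    if not counts:
        return pd.DataFrame(columns=CATEGORY_NAMES, dtype=int)
    return pd.DataFrame.from_dict(counts, orient="index", columns=CATEGORY_NAMES).sort_index()


class Baseline(NamedTuple):
    """Pooled non-targeting counts; ``frequencies`` sum to 1 over categories."""

    counts: pd.Series
    denominator: int
    frequencies: pd.Series


def nontargeting_baseline(matrix: pd.DataFrame, library: SgRNALibrary,
                          include_uncategorized: bool = True) -> Baseline:
    """Pooled category frequencies across all non-targeting sgRNAs.

    ``include_uncategorized=False`` drops UNCATEGORIZED reads from both counts
    and denominators (both conventions are defensible; the default keeps them,
    treating them as real outcomes of unknown class).
    """
    nt_ids = [e.sgrna_id for e in library.nontargeting if e.sgrna_id in matrix.index]
    if not nt_ids:
        raise ValueError("no non-targeting sgRNA has any reads")
    sub = matrix.loc[nt_ids]
    if not include_uncategorized:
        sub = sub.drop(columns=[Category.UNCATEGORIZED.value])
    counts = sub.sum(axis=0)
    denom = int(counts.sum())
    if denom == 0:
        raise ValueError("zero reads across non-targeting sgRNAs")
    return Baseline(counts, denom, counts / denom)


def sgrna_log2fc(matrix: pd.DataFrame, baseline: Baseline,
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sgRNA, per-category log2 fold change vs the pooled baseline.

    Both the sgRNA and baseline frequencies are regularized identically:
    (count + pc) / (denominator + pc * K) with K the number of categories, so
    zero counts stay finite.
    """
    if pseudocount <= 0 and (baseline.frequencies <= 0).any():
        raise ValueError("zero baseline frequencies require a positive pseudocount")
    K = matrix.shape[1]
    denom = matrix.sum(axis=1).to_numpy()[:, None] + pseudocount * K
    freq = (matrix.to_numpy() + pseudocount) / denom
    base = (baseline.counts.reindex(matrix.columns).to_numpy() + pseudocount) / (
        baseline.denominator + pseudocount * K)
    return pd.DataFrame(np.log2(freq) - np.log2(base),
                        index=matrix.index, columns=matrix.columns)


def extreme_pair_mean(values: Iterable[float], ids: Iterable[str] | None = None,
                      top_k: int = 2) -> float:
    """Mean of the ``top_k`` values with the largest absolute magnitude.

    Ties are broken by id order (stable); with fewer than ``top_k`` values all
    are used.
    """
    vals = list(values)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(vals))]
    order = sorted(range(len(vals)), key=lambda i: (-abs(vals[i]), ids[i]))
    take = order[:top_k]
    return float(np.mean([vals[i] for i in take]))


def gene_effect(log2fc: pd.DataFrame, gene_map: dict[str, list[str]],
                top_k: int = 2) -> pd.DataFrame:
    """Gene x category matrix of two-most-extreme-sgRNA mean log2 fold changes.

    ``gene_map`` maps gene (or quasi-gene) names to their sgRNA ids; ids
    missing from ``log2fc`` are rejected.
    """
    rows = {}
    for gene, ids in gene_map.items():
        missing = [i for i in ids if i not in log2fc.index]
        if missing:
            raise ValueError(f"{gene}: sgRNAs without log2FC values: {missing}")
        sub = log2fc.loc[ids]
        rows[gene] = [extreme_pair_mean(sub[c].tolist(), ids, top_k) for c in log2fc.columns]
    return pd.DataFrame.from_dict(rows, orient="index", columns=log2fc.columns).sort_index()


def quasi_genes(nontargeting_ids: list[str], set_size: int = 3,
                seed: int = 0) -> dict[str, list[str]]:
    """Random partition of non-targeting sgRNAs into quasi-genes of ``set_size``.

    Each id is used exactly once; a remainder not filling a whole set is
    dropped (with a warning).  The default 60 ids / size 3 gives 20 sets.
    """
    import warnings

    rng = np.random.default_rng(seed)
    ids = list(nontargeting_ids)
    order = rng.permutation(len(ids))
    n_sets = len(ids) // set_size
    if len(ids) % set_size:
        warnings.warn(f"dropping {len(ids) % set_size} non-targeting sgRNAs that "
                      f"do not fill a quasi-gene of size {set_size}")
    return {
        f"QUASI_{k + 1:02d}": sorted(ids[i] for i in order[k * set_size:(k + 1) * set_size])
        for k in range(n_sets)
    }


@dataclass
class DeletionProfile:
    """Per-vector-position deletion counts and frequencies for a group of reads."""

    counts: np.ndarray
    frequencies: np.ndarray
    total_outcomes: int
    n_deletions: int


def deletion_position_profile(records: Iterable[OutcomeRecord], spec: ScreenVectorSpec,
                              total_outcomes: int | None = None) -> DeletionProfile:
    """Positionwise deletion frequency profile.

    For every included deletion read the inclusive first-to-last deleted
    interval increments a per-position count array; counts are divided by the
    total number of outcomes in the group (all categories), so the profile is
    a per-position deletion frequency.  Boundary-excluded deletions (primer
    window) are omitted from the counts but retained in the denominator.
    """
    records = list(records)
    counts = np.zeros(len(spec.sequence), dtype=float)
    n_del = 0
    for r in records:
        if r.category is not Category.DELETION or r.boundary_excluded:
            continue
        counts[r.del_start:r.del_end + 1] += 1
        n_del += 1
    total = len(records) if total_outcomes is None else total_outcomes
    freq = counts / total if total > 0 else counts * np.nan
    return DeletionProfile(counts, freq, total, n_del)


def profile_log2fc(profile: DeletionProfile, baseline: DeletionProfile,
                   pseudocount: float = 0.5) -> np.ndarray:
    """Positionwise log2 fold change of deletion frequency vs a baseline profile."""
    f1 = (profile.counts + pseudocount) / (profile.total_outcomes + pseudocount)
    f0 = (baseline.counts + pseudocount) / (baseline.total_outcomes + pseudocount)
    return np.log2(f1) - np.log2(f0)


def is_far_deletion(record: OutcomeRecord, spec: ScreenVectorSpec, margin: int = 25) -> bool:
    """True when the deletion removes sequence >= ``margin`` nt outside the outer nicks.

    With between-base nick coordinates, the k-th base beyond the downstream
    nick is position ``plus50_nick + k - 1`` and beyond the upstream nick
    ``minus50_nick - k``.
    """
    if record.category is not Category.DELETION:
        raise ValueError("far/near classification applies to DELETION records")
    return (record.del_start <= spec.minus50_nick - margin
            or record.del_end >= spec.plus50_nick + margin - 1)


def far_deletion_fraction(records: Iterable[OutcomeRecord], spec: ScreenVectorSpec,
                          margin: int = 25) -> tuple[float, int] | None:
    """(fraction of deletions reaching >= margin nt outside the nicks, n deletions).

    Boundary-excluded deletions are omitted.  Returns None when the group has
    no included deletions (no data).
    """
    dels = [r for r in records
            if r.category is Category.DELETION and not r.boundary_excluded]
    if not dels:
        return None
    far = sum(is_far_deletion(r, spec, margin) for r in dels)
    return far / len(dels), len(dels)
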