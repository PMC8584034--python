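"""Synthetic read generation with known ground truth.

Every analysis stage in this package is validated against reads whose true
outcome is known by construction.  The generators here emulate the structure
the analysis assumes:

* screen read pairs — R1 (44 nt) carrying the CRISPRi protospacer, R2 (263 nt)
  reading the outcome molecule from the reverse-primer end, per-sgRNA
  multinomial mixtures over outcome categories, per-base substitution
  sequencing error, and a two-state (Q37/Q11) quality model;
* arrayed amplicon readsets with planted allele frequencies;
* microsatellite readsets with planted homopolymer lengths.

Identical seeds reproduce byte-identical output files and truth tables.  The
generators do not emulate PCR duplicates, UMIs, indel sequencing errors or
copy-number effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec
from .classify import canonical_interval
from .library import SgRNALibrary
from .msi import FLANK_LENGTH, PREFIX_LENGTH, MicrosatelliteLocus, write_locus_table
from .outcomes import Category
from .seqio import write_fasta, write_fastq
from .vector import DNA, ScreenVectorSpec, random_dna, reverse_complement

R1_LENGTH = 44
R2_LENGTH = 263
# constant R1 filler downstream of the protospacer (vector cassette context)
R1_FILLER = "GTTTAAGAGCTAAGCTGGAAACAG"
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASE_IDX = {b: i for i, b in enumerate(DNA)}


def _draw(rng: np.random.Generator, cum: np.ndarray, items: list):
    """Draw from a discrete distribution given cumulative weights."""
    idx = int(np.searchsorted(cum, rng.random(), side="right"))
    return items[min(idx, len(items) - 1)]


def make_decoy_references(seed: int = 0, n: int = 2, length: int = 300) -> dict[str, str]:
    """Small random sequences standing in for genome references in synthetic runs."""
    # decorrelate from other generators seeded with the same integer
    rng = np.random.default_rng([seed, 0xDEC0])
    return {f"decoy_{i + 1}": random_dna(rng, length) for i in range(n)}


@dataclass(frozen=True)
class OutcomePlan:
    """Mixture over outcome categories plus the sequencing-noise model.

    Default weights emulate a PE3+50-like condition: intended editing in the
    mid-teens of percent, deletions as the dominant byproduct, and low-percent
    duplications, unintended joining and scaffold-derived edits.
    """

    weights: dict[Category, float] = field(default_factory=lambda: {
        Category.UNEDITED: 0.70,
        Category.INTENDED_EDIT: 0.15,
        Category.DELETION: 0.08,
        Category.TANDEM_DUPLICATION: 0.02,
        Category.UNINTENDED_PEGRNA_JOINING: 0.02,
        Category.SCAFFOLD_EDITS: 0.02,
        Category.UNCATEGORIZED: 0.01,
    })
    substitution_error_rate: float = 0.001
    q_good: int = 37
    q_bad: int = 11
    p_bad: float = 0.05
    deletion_length: tuple[int, int] = (2, 60)
    far_deletion_weight: float = 0.4   # fraction of deletions reaching >= far_margin outside nicks
    far_margin: int = 25
    # duplications shorter than the aligner's minimum alignment length (15 nt)
    # are unresolvable by design; defaults stay above that limit
    duplication_length: tuple[int, int] = (18, 60)
    scaffold_insert: int = 4           # scaffold-templated bases inserted at the RTT 3' junction
    joining_scaffold_bases: int = 6    # scaffold-templated bases at an unintended junction
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("mixture weights must be non-negative")
        if not (0 <= self.substitution_error_rate < 1):
            raise ValueError("substitution error rate must be in [0, 1)")

    def with_weights(self, **overrides: float) -> "OutcomePlan":
        """New plan with some category weights replaced; the remainder is
        absorbed into UNEDITED so weights still sum to 1."""
        w = {c: self.weights.get(c, 0.0) for c in Category}
        for name, value in overrides.items():
            w[Category(name)] = value
        if "UNEDITED" not in overrides:
            w[Category.UNEDITED] = 0.0
            remainder = 1.0 - sum(w.values())
            if remainder < -1e-9:
                raise ValueError("override weights exceed 1")
            w[Category.UNEDITED] = max(0.0, remainder)
        return replace(self, weights=w)


def simulate_outcome_molecule(spec: ScreenVectorSpec, category: Category, *,
                              deletion: tuple[int, int] | None = None,
                              duplication: tuple[int, int] | None = None,
                              scaffold_insert: int = 4,
                              junction: int | None = None,
                              joining_scaffold_bases: int = 6,
                              decoy: str | None = None) -> str:
    """Full-length outcome molecule (top strand) for one category.

    Detail parameters use half-open vector intervals.  Category/detail
    mismatches are rejected.
    """
    seq = spec.sequence
    nick = spec.pegrna_nick
    rtt_end = spec.rtt_interval[1]
    if category is Category.UNEDITED:
        return seq
    if category is Category.INTENDED_EDIT:
        return spec.edited_sequence
    if category is Category.DELETION:
        if deletion is None:
            raise ValueError("DELETION requires a deletion interval")
        s, e = deletion
        if not (0 <= s < e <= len(seq)):
            raise ValueError(f"deletion interval {deletion} outside the vector")
        return seq[:s] + seq[e:]
    if category is Category.TANDEM_DUPLICATION:
        if duplication is None:
            raise ValueError("TANDEM_DUPLICATION requires a duplicated interval")
        s, e = duplication
        if not (0 <= s < e <= len(seq)):
            raise ValueError(f"duplication interval {duplication} outside the vector")
        return seq[:e] + seq[s:]
    if category is Category.SCAFFOLD_EDITS:
        if not (1 <= scaffold_insert <= len(spec.scaffold_flap)):
            raise ValueError("scaffold insert length outside the available scaffold flap")
        return seq[:nick] + spec.rtt_edited + spec.scaffold_flap[:scaffold_insert] + seq[rtt_end:]
    if category is Category.UNINTENDED_PEGRNA_JOINING:
        j = spec.plus50_nick if junction is None else junction
        if not (0 <= j <= len(seq)) or j == rtt_end:
            raise ValueError("joining junction must differ from the intended RTT junction")
        if not (1 <= joining_scaffold_bases <= len(spec.scaffold_flap)):
            raise ValueError("joining scaffold bases outside the available scaffold flap")
        return seq[:nick] + spec.rtt_edited + spec.scaffold_flap[:joining_scaffold_bases] + seq[j:]
    if category is Category.UNCATEGORIZED:
        if decoy is None:
            raise ValueError("UNCATEGORIZED molecules are drawn from a decoy sequence")
        return decoy
    raise ValueError(f"unknown category {category}")


def _sample_deletion(rng: np.random.Generator, spec: ScreenVectorSpec,
                     plan: OutcomePlan) -> tuple[int, int]:
    """Deletion interval around the nicks, canonicalized to minimal coordinates.

    Intervals stay inside the region visible to the outcome read and clear of
    the primer exclusion windows; a ``far_deletion_weight`` fraction extends at
    least ``far_margin`` nt beyond an outer nick.
    """
    # keep >=15 nt of left flank inside the read even for the longest deletion,
    # and stay clear of the reverse-primer exclusion window on the right
    lo = spec.r2_window[0] + 40
    hi = spec.primer_rev_interval[0] - 13
    m = plan.far_margin
    for _ in range(200):
        length = int(rng.integers(plan.deletion_length[0], plan.deletion_length[1] + 1))
        far = rng.random() < plan.far_deletion_weight
        if far:
            if rng.random() < 0.5:
                first = int(rng.integers(lo, spec.minus50_nick - m + 1))
            else:
                last = int(rng.integers(spec.plus50_nick + m - 1, hi))
                first = last - length + 1
        else:
            first = int(rng.integers(spec.minus50_nick - m + 1, spec.plus50_nick + m - length))
        s, e = first, first + length
        if s < lo or e > hi:
            continue
        s, e = canonical_interval(spec.sequence, s, e)
        if s < lo:
            continue
        is_far = s <= spec.minus50_nick - m or e - 1 >= spec.plus50_nick + m - 1
        if is_far == far:
            return s, e
    raise RuntimeError("could not sample a deletion interval for this geometry")


def _sample_duplication(rng: np.random.Generator, spec: ScreenVectorSpec,
                        plan: OutcomePlan) -> tuple[int, int]:
    length = int(rng.integers(plan.duplication_length[0], plan.duplication_length[1] + 1))
    start = int(rng.integers(spec.pegrna_nick - 50, spec.pegrna_nick + 11))
    return canonical_interval(spec.sequence, start, start + length)


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, 0
    chars = list(seq)
    shifts = rng.integers(1, 4, size=hits.size)
    for pos, shift in zip(hits, shifts):
        chars[pos] = DNA[(_BASE_IDX[chars[pos]] + shift) % 4]
    return "".join(chars), int(hits.size)


def _qualities(rng: np.random.Generator, n: int, plan: OutcomePlan) -> str:
    bad = rng.random(n) < plan.p_bad
    return (np.where(bad, plan.q_bad, plan.q_good).astype(np.uint8) + 33).tobytes().decode("ascii")


def _r2_from_molecule(molecule: str, adapter: str) -> str:
    raw = reverse_complement(molecule)[:R2_LENGTH]
    while len(raw) < R2_LENGTH:
        raw += adapter[:R2_LENGTH - len(raw)]
    return raw


@dataclass
class ScreenReadset:
    r1_path: Path
    r2_path: Path
    i1_path: Path
    i2_path: Path
    truth_path: Path
    truth: pd.DataFrame
    decoys: dict[str, str]
    sample_indexes: tuple[str, str]


def generate_screen_readset(spec: ScreenVectorSpec, library: SgRNALibrary,
                            plan: OutcomePlan, n_reads: int, out_dir: str | Path,
                            seed: int = 0,
                            sgrna_plans: dict[str, OutcomePlan] | None = None,
                            decoys: dict[str, str] | None = None,
                            sample_indexes: tuple[str, str] = ("ACGTACGT", "TGCATGCA"),
                            prefix: str = "screen") -> ScreenReadset:
    """Emit ``n_reads`` screen read pairs (R1/R2/I1/I2 FASTQ) plus a truth table.

    Each read draws an sgRNA uniformly from the library and an outcome
    category from that sgRNA's plan (``sgrna_plans`` overrides the shared
    plan per sgRNA).  The truth table records the canonical detail coordinates
    the classifier is expected to recover.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if decoys is None:
        decoys = make_decoy_references(seed)
    decoy_seq = next(iter(decoys.values()))
    sgrna_plans = sgrna_plans or {}
    entries = library.entries

    plans: dict[str, tuple[OutcomePlan, list[Category], np.ndarray]] = {}
    for e in entries:
        p = sgrna_plans.get(e.sgrna_id, plan)
        cats = [c for c in Category if p.weights.get(c, 0.0) > 0]
        cum = np.cumsum([p.weights[c] for c in cats])
        plans[e.sgrna_id] = (p, cats, cum)

    r1_records, r2_records, i1_records, i2_records, truth_rows = [], [], [], [], []
    for i in range(n_reads):
        rid = f"{prefix}_{i:07d}"
        entry = entries[int(rng.integers(0, len(entries)))]
        p, cats, cum = plans[entry.sgrna_id]
        cat = _draw(rng, cum, cats)

        detail = dict(del_start=None, del_end=None, dup_start=None, dup_end=None, junction=None)
        kwargs = {}
        if cat is Category.DELETION:
            s, e = _sample_deletion(rng, spec, p)
            kwargs["deletion"] = (s, e)
            detail.update(del_start=s, del_end=e - 1)
        elif cat is Category.TANDEM_DUPLICATION:
            s, e = _sample_duplication(rng, spec, p)
            kwargs["duplication"] = (s, e)
            detail.update(dup_start=s, dup_end=e - 1)
        elif cat is Category.UNINTENDED_PEGRNA_JOINING:
            kwargs["junction"] = spec.plus50_nick
            kwargs["joining_scaffold_bases"] = p.joining_scaffold_bases
            detail.update(junction=spec.plus50_nick)
        elif cat is Category.SCAFFOLD_EDITS:
            kwargs["scaffold_insert"] = p.scaffold_insert
        elif cat is Category.UNCATEGORIZED:
            kwargs["decoy"] = decoy_seq
        molecule = simulate_outcome_molecule(spec, cat, **kwargs)

        r1 = (entry.protospacer + R1_FILLER)[:R1_LENGTH]
        r2 = _r2_from_molecule(molecule, p.adapter)
        r1, _ = _apply_substitutions(rng, r1, p.substitution_error_rate)
        r2, n_err = _apply_substitutions(rng, r2, p.substitution_error_rate)

        r1_records.append((rid, r1, _qualities(rng, R1_LENGTH, p)))
        r2_records.append((rid, r2, _qualities(rng, R2_LENGTH, p)))
        i1_records.append((rid, sample_indexes[0], "I" * 8))
        i2_records.append((rid, sample_indexes[1], "I" * 8))
        truth_rows.append((rid, entry.sgrna_id, cat.value, detail["del_start"],
                           detail["del_end"], detail["dup_start"], detail["dup_end"],
                           detail["junction"], n_err))

    paths = {k: out_dir / f"{prefix}_{k}.fastq" for k in ("R1", "R2", "I1", "I2")}
    write_fastq(paths["R1"], r1_records)
    write_fastq(paths["R2"], r2_records)
    write_fastq(paths["I1"], i1_records)
    write_fastq(paths["I2"], i2_records)
    truth = pd.DataFrame(truth_rows, columns=[
        "read_id", "sgrna_id", "category", "del_start", "del_end",
        "dup_start", "dup_end", "junction", "n_r2_errors"])
    truth_path = out_dir / f"{prefix}_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return ScreenReadset(paths["R1"], paths["R2"], paths["I1"], paths["I2"],
                         truth_path, truth, decoys, sample_indexes)


# ---------------------------------------------------------------------------
# arrayed amplicon fixtures
# ---------------------------------------------------------------------------

@dataclass
class AmpliconFixture:
    fastq_path: Path
    reference_path: Path
    truth_path: Path
    truth: pd.DataFrame
    spec: AmpliconSpec
    alleles: dict[str, str]


def make_amplicon_spec(seed: int = 0, length: int = 240, pegrna_nick: int = 100,
                       nick_sgrna_nick: int | None = 150,
                       edit_offset: int = 5) -> AmpliconSpec:
    """Random endogenous-style amplicon with a G-to-T substitution edit."""
    rng = np.random.default_rng(seed)
    seq = list(random_dna(rng, length))
    pos = pegrna_nick + edit_offset - 1
    seq[pos] = "G"
    return AmpliconSpec(sequence="".join(seq), pegrna_nick=pegrna_nick,
                        nick_sgrna_nick=nick_sgrna_nick, substitution=(pos, "G", "T"))


def amplicon_alleles(spec: AmpliconSpec, indel_size: int = 1) -> dict[str, str]:
    """Standard allele set: unedited, intended, small insertion/deletion at the cut."""
    cut = spec.pegrna_nick
    seq = spec.sequence
    return {
        "unedited": seq,
        "intended": spec.edited_sequence,
        "insertion": seq[:cut] + "T" * indel_size + seq[cut:],
        "deletion": seq[:cut] + seq[cut + max(2, indel_size + 1):],
    }


def generate_amplicon_fixture(spec: AmpliconSpec, frequencies: dict[str, float],
                              n_reads: int, seed: int, out_dir: str | Path,
                              error_rate: float = 0.0,
                              extra_alleles: dict[str, str] | None = None,
                              prefix: str = "amplicon") -> AmpliconFixture:
    """Single-end amplicon readset with planted allele frequencies and truth."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    alleles = amplicon_alleles(spec)
    if extra_alleles:
        alleles.update(extra_alleles)
    unknown = set(frequencies) - set(alleles)
    if unknown:
        raise ValueError(f"frequencies reference unknown alleles: {sorted(unknown)}")
    total = sum(frequencies.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    names = sorted(frequencies)
    cum = np.cumsum([frequencies[n] for n in names])
    records, rows = [], []
    for i in range(n_reads):
        rid = f"{prefix}_{i:06d}"
        name = _draw(rng, cum, names)
        seq, _ = _apply_substitutions(rng, alleles[name], error_rate)
        records.append((rid, seq, "F" * len(seq)))
        rows.append((rid, name))
    fq = out_dir / f"{prefix}.fastq"
    fa = out_dir / f"{prefix}_reference.fasta"
    tp = out_dir / f"{prefix}_truth.tsv"
    write_fastq(fq, records)
    write_fasta(fa, [("amplicon", spec.sequence)])
    truth = pd.DataFrame(rows, columns=["read_id", "allele"])
    truth.to_csv(tp, sep="\t", index=False)
    return AmpliconFixture(fq, fa, tp, truth, spec, alleles)


# ---------------------------------------------------------------------------
# microsatellite fixtures
# ---------------------------------------------------------------------------

@dataclass
class MsiFixture:
    fastq_path: Path
    locus_path: Path
    truth_path: Path
    truth: pd.DataFrame
    loci: list[MicrosatelliteLocus]


def make_msi_loci(n_loci: int, seed: int = 0, repeat_unit: str = "A") -> list[MicrosatelliteLocus]:
    """Valid synthetic loci: flanks avoid the repeat base entirely, prefixes distinct."""
    rng = np.random.default_rng(seed)
    other = [b for b in DNA if b != repeat_unit]
    loci, prefixes = [], set()
    for i in range(n_loci):
        while True:
            prefix = random_dna(rng, PREFIX_LENGTH)
            if prefix not in prefixes:
                prefixes.add(prefix)
                break
        lf = "".join(other[j] for j in rng.integers(0, 3, FLANK_LENGTH))
        rf = "".join(other[j] for j in rng.integers(0, 3, FLANK_LENGTH))
        loci.append(MicrosatelliteLocus(f"MS_{i + 1:02d}", prefix, lf, rf, repeat_unit))
    return loci


def generate_msi_fixture(loci: list[MicrosatelliteLocus],
                         length_distributions: dict[str, dict[int, float]],
                         n_reads_per_locus: int, seed: int, out_dir: str | Path,
                         flank_mismatches: int = 0,
                         prefix: str = "msi") -> MsiFixture:
    """Microsatellite reads: prefix + context + left flank + homopolymer + right flank + tail.

    ``length_distributions`` maps locus id to a {length: probability} table;
    ``flank_mismatches`` substitutions are injected into each flank copy (the
    caller is expected to tolerate up to two).  Truth records the planted
    inter-flank distance per read.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for locus in loci:
        dist = length_distributions[locus.locus_id]
        lengths = sorted(dist)
        cum = np.cumsum([dist[l] for l in lengths])
        if abs(cum[-1] - 1.0) > 1e-9:
            raise ValueError(f"{locus.locus_id}: length distribution must sum to 1")
        mid = random_dna(rng, 10)
        tail = random_dna(rng, 15)
        for i in range(n_reads_per_locus):
            rid = f"{prefix}_{locus.locus_id}_{i:06d}"
            length = _draw(rng, cum, lengths)
            lf, rf = locus.left_flank, locus.right_flank
            for _ in range(flank_mismatches):
                lf = _mutate_one(rng, lf)
                rf = _mutate_one(rng, rf)
            seq = locus.prefix + mid + lf + locus.repeat_unit * length + rf + tail
            records.append((rid, seq, "F" * len(seq)))
            rows.append((rid, locus.locus_id, length))
    fq = out_dir / f"{prefix}.fastq"
    lp = out_dir / f"{prefix}_loci.tsv"
    tp = out_dir / f"{prefix}_truth.tsv"
    write_fastq(fq, records)
    write_locus_table(lp, loci)
    truth = pd.DataFrame(rows, columns=["read_id", "locus_id", "length"])
    truth.to_csv(tp, sep="\t", index=False)
    return MsiFixture(fq, lp, tp, truth, loci)


def _mutate_one(rng: np.random.Generator, seq: str) -> str:
    pos = int(rng.integers(0, len(seq)))
    new = DNA[(_BASE_IDX[seq[pos]] + int(rng.integers(1, 4))) % 4]
    return seq[:pos] + new + seq[pos + 1:]
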