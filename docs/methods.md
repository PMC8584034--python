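# Methods

This note describes the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## The screen readout

A pooled prime-editing screen couples a CRISPRi sgRNA and a composite
prime-edit site on one lentiviral cassette, amplified as a single 453-bp
amplicon. Sequencing yields four reads per cluster: two 8-nt sample indexes,
a 44-nt R1 covering the sgRNA protospacer, and a 263-nt R2 covering the edit
site. The edit site carries a pegRNA-directed nick with complementary-strand
nick targets exactly 50 bp upstream and downstream (the PE3 ±50
configurations) and a programmed +6 G·C-to-C·G substitution templated by the
pegRNA reverse-transcription template (RTT). `ScreenVectorSpec` records this
geometry on the vector top strand: between-base nick coordinates, half-open
feature intervals, and the pegRNA's primer-binding site (PBS), RTT and
scaffold features.

The pegRNA is represented in *extended-flap sense*: the sequence a maximally
extended reverse-transcription product would contribute to the top strand —
PBS-complementary context, then the edited RTT span, then scaffold-templated
sequence. This puts pegRNA alignments in the same coordinate frame as the
oriented outcome read, which is what the decision tree needs.

## Read processing

* Sample demultiplexing is exact on the (index1, index2) pair. Index-hopping
  tolerance is deliberately not modeled; a mismatch budget can be added
  upstream if needed.
* sgRNA assignment extracts the 20-mer at a configurable R1 offset (default
  0) and accepts the unique library protospacer within Hamming distance 1;
  zero hits → `UNASSIGNED`, two or more → `AMBIGUOUS`. Ambiguous reads are
  excluded from all per-sgRNA counts. Synthetic libraries are generated with
  pairwise protospacer distance ≥3 so the rule is unambiguous by construction.
* Quality triage discards a read when fewer than 60% of its base calls are at
  Phred ≥30; a read at exactly 60% is kept (only *less than* 60% is
  discarded).
* R2 is reverse-complemented into vector top-strand frame exactly once; all
  downstream coordinates are top-strand.

## Outcome classification

### Alignment

Reads are aligned with affine-gap local alignment (Biopython's
PairwiseAligner): match +1, mismatch −2, a gap of length L costs 5 + L;
alignments must reach score ≥10 over ≥15 aligned read bases. These values
let 15-nt exact seeds survive while spurious ~8-mers do not; all are
configurable (`AlignParams`). Because one read can be explained by several
alignments to different reference regions, the search is iterative: find the
best local alignment, mask its read span, and realign the remaining segments
(including segments between pieces when an alignment is split). Alignments
containing indel gaps longer than 10 nt are split at those gaps, so large
structural events surface as alignment *pairs* while small indels stay inside
one alignment; both paths feed the same boundary canonicalization. Gap-free
reads matching the vector tail are recognized by a Hamming comparison before
invoking the full search (a pure fast path), and decoy references are only
aligned when vector plus pegRNA alignments leave more than 30 read bases
unexplained.

Read *coverage* of an alignment is the set of read positions aligned to a
reference base; inserted read bases are not covered. Greedy parsimony pruning
then repeatedly takes the alignment adding the most uncovered read bases
(ties: higher score, then vector before pegRNA before decoys, then leftmost
read start) until nothing adds coverage. The greedy set always reaches the
maximal achievable coverage; on random instances it can exceed the minimal
cardinality by at most one alignment (measured, never more on 500 seeded
instances — the "greedy gap").

### Decision tree

Rules are evaluated in order; the first match wins. Structural rules examine
a vector-only parsimonious set (pruning restricted to vector alignments,
each maximally extended by exact matches at both ends), because the pegRNA
reference copies vector sequence around the nick and can otherwise displace a
duplicated vector copy from the mixed pruned set.

1. **UNEDITED** — one clean full-coverage vector alignment (≤2 unaligned
   terminal bases), reference base at the programmed-edit position, no indels.
   1-nt deletions farther than 5 nt from every programmed nick are
   disregarded as sequencing/PCR errors (this prep has no UMIs, so no
   consensus correction is possible); up to 5 stray mismatches are tolerated
   for the same reason.
2. **INTENDED_EDIT** — as above with the programmed substitution installed.
3. **SCAFFOLD_EDITS** — a pegRNA alignment extends past the RTT into the
   scaffold feature, its PBS and RTT co-locate on the read (≥50% span
   overlap) with a full-coverage vector alignment's PBS/RTT placements, and
   the pegRNA alignment has fewer edits over that span than the vector
   alignment, whose extra edits must *add* sequence at the RTT 3′ junction
   (insertions there and/or substitutions; never deletions). Without the
   junction constraints, deletions inside the PBS/RTT masquerade as scaffold
   edits, because pegRNA and vector are nearly identical around the nick.
4. **UNINTENDED_PEGRNA_JOINING** — a pegRNA alignment co-locates its PBS with
   a vector alignment's PBS, explains read bases that no vector alignment
   matches, and no vector alignment places the RTT in *native continuation
   context*: the three reference bases immediately 3′ of the RTT span present
   as matched columns. Any reverse-transcription product copies the RTT
   target, so the RTT read span itself always co-locates somewhere; what
   distinguishes a flap joined at an unintended position is that the vector
   alignment ends at the junction instead of continuing into native
   downstream sequence. A read consistent with both a multi-stage
   deletion+editing event and joining is reported as the pegRNA-based
   category.
5. **DELETION** — vector alignments cover the read but omit a vector
   segment: either a deletion gap inside one full-coverage alignment, or a
   forward reference jump between two consecutive alignments. Junctions
   between gap-free flanking alignments are re-scanned for the
   mismatch-minimizing split position (local alignment ends can overshoot a
   junction by absorbing chance matches), then canonicalized.
6. **TANDEM_DUPLICATION** — consecutive vector alignments whose reference
   intervals overlap (a backward reference jump at the junction), same
   refinement.
7. **UNCATEGORIZED** — everything else, sub-labelled `decoy_only` or
   `no_alignment` where applicable.

Deletion and duplication boundaries are degenerate under junction
microhomology; the representative with minimal vector coordinates is always
reported (slide left while the base before the interval equals the base
before its end). Deletions whose deleted region overlaps a 10-nt window
around either amplicon primer keep their category but are excluded from
boundary statistics, since primer dimers and non-specific products mimic long
deletions.

Classification is a pure function of (read, vector spec, references,
configuration); identical inputs give identical records.

## Screen statistics

Counts per sgRNA and category form the count matrix; row sums are the
denominators. Baseline category frequencies pool all non-targeting sgRNAs.
Per-sgRNA log2 fold changes regularize both sides identically:
log2((c + pc)/(D + pc·K)) − log2((c₀ + pc)/(D₀ + pc·K)) with pseudocount
pc = 0.5 and K the number of categories, so zero counts stay finite. The gene
effect is the mean of the two sgRNAs with the largest |log2FC| (stable ties by
sgRNA id) — a compromise between multi-sgRNA support and tolerance of
low-activity sgRNAs; genes with fewer than two sgRNAs use all available. The
null distribution of this extreme-selecting statistic is estimated by
applying it to quasi-genes: a random partition of the non-targeting sgRNAs
into sets of three (60 → 20 sets).

Deletion position profiles increment a per-vector-position count array over
each included deletion's inclusive first-to-last interval and divide by the
total outcomes in the group, so Σ counts = Σ inclusive deletion lengths
(conserved by construction and asserted in tests). `UNCATEGORIZED` reads stay
in denominators by default (they are real outcomes of unknown class);
both conventions are supported. A deletion is *far* when its boundary extends
at least 25 nt beyond an outer nick — with between-base nick coordinate n,
the k-th base beyond the downstream nick is n + k − 1.

## Amplicon quantification

Reads are globally aligned to the reference amplicon; a read is *aligned*
when its identity (matches over alignment columns) reaches 65% —
approximating the behavior of standard amplicon quantifiers, configurable —
and *indel-containing* (discarded) when an insertion or deletion overlaps the
quantification window. The window spans the sequence between the pegRNA- and
nicking-sgRNA cut sites plus 10 nt beyond both ("≥10 nt" resolved to exactly
10 by default), and the same window is applied whether or not a nicking
sgRNA was used. Frequencies:

* substitution editing % = (intended-base fraction among aligned,
  non-discarded reads) × (non-discarded / aligned) × 100. The per-position
  base is taken from the unmasked alignment column (no quality masking by
  default).
* allele-style editing % = reads whose window sequence equals the expected
  allele's window sequence / aligned reads.
* indel % = indel-containing reads / aligned reads.
* heterozygous editable-allele correction % = (editing − mock)/(100 − mock) ×
  100, clamped at 0 with a flag when editing < mock.
* off-target % = aligned reads (including indel-containing ones) carrying the
  marker directly 3′ of the Cas9 nick / aligned reads, where the marker is
  the shortest flap prefix deviating from the reference 3′ of the nick.
  `background_mismatch_rate` reports the mean mismatch rate at non-edit
  positions alongside, because context-specific sequencing error can
  overestimate apparent off-target editing.

## Microsatellite lengths

For each locus the 20-nt sequences flanking the homopolymer are recorded;
reads demultiplex to loci by exact match of their first 20 nt. Per read, the
first (leftmost) window within Hamming distance 2 of each flank is found; if
both exist, in order, with inter-flank distance ≤50 nt, that distance is the
called length, otherwise an explicit no-call records which condition failed.
The truncated phrase "within 50 nt of each [other]" is read as inter-flank
distance ≤50 nt, which comfortably exceeds human mononucleotide run lengths.
The method measures the read's *apparent* length by design: it is robust to
substitutions (≤2 per flank changes no call; 3 gives a no-call, never a wrong
length) but does not correct indel errors inside the homopolymer itself.

## Synthetic data: what it emulates and what it does not

The generators emulate the structure the analysis assumes: read geometry
(44/263 nt, two 8-nt indexes), per-sgRNA multinomial mixtures over outcome
categories, per-base substitution error with a two-state quality model, and
molecule construction per category (deletion = interval removed; duplication
= interval repeated in place; scaffold = edited RTT plus scaffold-templated
bases inserted at the RTT 3′ junction; joining = edited RTT plus scaffold
bases rejoined at the downstream nick; background = decoy-derived molecules).
R2 is emitted as the reverse-strand read of the molecule's last 263 nt,
padded with a configurable adapter when a large deletion shortens the
molecule below the read length.

Default study conditions (chosen once): outcome weights 0.70 unedited / 0.15
intended / 0.08 deletion / 0.02 duplication / 0.02 joining / 0.02 scaffold /
0.01 background, emulating a PE3+50-like condition where intended editing
sits in the mid-teens of percent and deletions dominate the byproducts;
substitution error 0.1% per base; Q37/Q11 quality states with 5% bad-base
probability (which exercises but rarely triggers the 60%/Q30 filter);
PBS/RTT of 13 nt; scaffold insertions of 4 nt; joining with 6
scaffold-templated junction bases at the +50 nick; deletion lengths 2–60 nt
around the nicks with 40% reaching ≥25 nt outside them; duplication lengths
18–60 nt starting between the nicks.

Not emulated: PCR duplicates and chimeras, UMIs (absent from this prep),
indel sequencing errors, quality-correlated error positions, lentiviral
copy-number effects, and real genome backgrounds (small random decoys stand
in for genome references). Passing the truth-table tests therefore
demonstrates that the algorithms are correct on reads with these structures
and error processes — not that real libraries are free of artifacts the
generator does not model.

Detection limits follow from the alignment parameters: a duplicated segment
shorter than the 15-nt minimum alignment length cannot be attested by any
alignment and is unresolvable in principle; 1-nt deletions far from nicks are
deliberately absorbed as errors; deletions are sampled ≥2 nt accordingly.
With 0.1% substitution error a small number of miscalls is inherent rather
than a defect — a single error at the edit base converts an unedited read
into an exact intended-edit read — so category accuracy at that error rate is
≈99.9%, not 100%.

## Numerical and degenerate-input choices

* Boundary canonicalization: among microhomology-degenerate placements the
  minimal-coordinate pair is reported everywhere (truth tables, classifier,
  profiles), making comparisons exact.
* Junction refinement scans all candidate split positions between two
  gap-free flanking alignments and takes the mismatch-minimizing, leftmost
  split — without it, alignment ends absorb chance matches and shift
  boundaries by 2–3 nt.
* Quality threshold comparison keeps reads at exactly 60% Q≥30; fractions are
  compared in floating point after an integer count.
* Empty inputs: empty alignment sets are valid (`UNCATEGORIZED`), empty count
  matrices are returned as empty frames, zero aligned amplicon reads and
  all-no-call loci raise explicit no-data errors, and a zero-deletion group
  reports "no data" rather than 0 for the far-deletion fraction.
* Determinism: every generator draws from a single `numpy` Generator seeded
  by the caller; repeated runs are byte-identical. The decoy generator
  decorrelates its stream from same-seed vector generation.
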