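"""Microsatellite length calling between Hamming-tolerant flanking sequences.

Simulates two samples at one mononucleotide microsatellite locus: a stable
sample (all repeats 18 nt) and an unstable one in which 24% of reads lost one
repeat unit (the kind of shift MMR deficiency produces). Lengths are measured
as the distance between the first occurrences of the 20-nt flanking sequences
(each tolerated to Hamming distance 2), which is robust to base-call errors
inside the homopolymer itself.
"""

import tempfile
from pathlib import Path

from pescreen.msi import call_locus, length_distribution, mean_length_difference
from pescreen.seqio import read_fastq
from pescreen.simulate import generate_msi_fixture, make_msi_loci

loci = make_msi_loci(n_loci=1, seed=0)
locus = loci[0]
print(f"locus {locus.locus_id}: poly-{locus.repeat_unit} run between 20-nt flanks\n")

calls = {}
with tempfile.TemporaryDirectory() as tmp:
    for name, dist, seed in [("stable", {18: 1.0}, 1),
                             ("unstable", {18: 0.76, 17: 0.24}, 2)]:
        fx = generate_msi_fixture(loci, {locus.locus_id: dist}, 20_000, seed,
                                  Path(tmp) / name)
        reads = [(rid, seq) for rid, seq, _ in read_fastq(fx.fastq_path)]
        calls[name] = call_locus(reads, locus)

for name, cs in calls.items():
    called = [c for c in cs if c.called]
    hist = length_distribution(cs)
    mean = sum(c.length for c in called) / len(called)
    print(f"{name}: {len(called)} calls, mean length {mean:.3f} nt")
    for row in hist.itertuples():
        print(f"   length {row.length:2d}: {row.frequency:6.1%} "
              f"(cumulative {row.cumulative:6.1%})")

shift = mean_length_difference(calls["unstable"], calls["stable"])
print(f"\nmean length difference (unstable - stable): {shift:+.3f} nt")
print("A planted 24% single-unit contraction shifts the mean by -0.24 nt; "
      "the caller recovers it from the inter-flank distances alone.")
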