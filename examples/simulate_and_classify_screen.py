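"""Simulate a small pooled prime-editing screen and classify every outcome read.

Builds the composite-edit-site screen vector (pegRNA nick flanked by ±50-bp
complementary-strand nicks, +6 G·C-to-C·G programmed edit), simulates 2,000
read pairs from a known outcome mixture, runs demultiplexing, quality triage
and decision-tree classification, and compares the calls to the planted truth.
"""

import dataclasses
import tempfile
from collections import Counter
from pathlib import Path

from pescreen import OutcomePlan, build_screen_vector, generate_sgrna_library, run_screen
from pescreen.simulate import generate_screen_readset

spec = build_screen_vector(seed=0)
print(f"screen vector: {len(spec.sequence)} bp, pegRNA nick at {spec.pegrna_nick}, "
      f"complementary-strand nicks at {spec.minus50_nick}/{spec.plus50_nick}, "
      f"programmed edit {spec.programmed_edit}")

library = generate_sgrna_library(n_genes=2, sgrnas_per_gene=3, n_nontargeting=6, seed=0)
plan = dataclasses.replace(OutcomePlan(), substitution_error_rate=0.001)

with tempfile.TemporaryDirectory() as tmp:
    readset = generate_screen_readset(spec, library, plan, n_reads=2000,
                                      out_dir=Path(tmp), seed=1)
    result = run_screen(readset.r1_path, readset.r2_path, library, spec,
                        readset.decoys)

    print(f"\nclassified {result.n_classified}/{result.n_input} read pairs "
          f"(quality-discarded {result.n_quality_discarded}, "
          f"unassigned sgRNA {result.n_unassigned})")

    called = Counter(r.category.value for r in result.records)
    planted = Counter(readset.truth.category)
    truth_by_read = readset.truth.set_index("read_id").category
    agree = sum(r.category.value == truth_by_read[r.read_id] for r in result.records)

    print(f"\n{'category':28s} {'called':>7s} {'planted':>8s}")
    for cat in sorted(set(called) | set(planted)):
        print(f"{cat:28s} {called.get(cat, 0):7d} {planted.get(cat, 0):8d}")
    print(f"\nagreement with planted truth: {agree}/{len(result.records)} "
          f"({100 * agree / len(result.records):.2f}%)")
    print("Each read was assigned one of seven outcome categories from the "
          "configuration of its local alignments; at 0.1% sequencing error a "
          "handful of miscalls (e.g. an error landing exactly on the edited "
          "base) are expected.")
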