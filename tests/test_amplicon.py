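import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pescreen.amplicon import (AmpliconSpec, ReadCall, align_and_window,
                               call_offtarget_reads, correct_heterozygous,
                               derive_offtarget_marker, quantification_window,
                               quantify_allele_edit, quantify_indels,
                               quantify_substitution)
from pescreen.seqio import read_fastq
from pescreen.simulate import generate_amplicon_fixture, make_amplicon_spec


@pytest.fixture(scope="module")
def aspec():
    return make_amplicon_spec(seed=1)


class TestWindow:
    def test_window_spans_both_cuts_plus_pad(self, aspec):
        lo, hi = quantification_window(aspec)
        assert lo == min(aspec.pegrna_nick, aspec.nick_sgrna_nick) - 10
        assert hi == max(aspec.pegrna_nick, aspec.nick_sgrna_nick) + 10

    def test_same_window_without_nicking_sgrna(self, aspec):
        # scoring a PE2-style sample with the PE3 window: pass it explicitly
        import dataclasses
        pe2 = dataclasses.replace(aspec, nick_sgrna_nick=None,
                                  window=quantification_window(aspec))
        assert quantification_window(pe2) == quantification_window(aspec)

    def test_stated_ref_base_must_match(self, aspec):
        with pytest.raises(ValueError, match="stated"):
            AmpliconSpec(aspec.sequence, 100, 150,
                         substitution=(aspec.substitution[0], "N", "T"))


class TestAlignAndWindow:
    def test_reference_read_is_clean(self, aspec):
        calls = align_and_window([("r0", aspec.sequence)], aspec)
        c = calls[0]
        assert c.aligned and not c.indel_in_window
        assert c.base_at_edit == aspec.substitution[1]

    def test_insertion_inside_window_is_indel_containing(self, aspec):
        cut = aspec.pegrna_nick
        read = aspec.sequence[:cut] + "T" + aspec.sequence[cut:]
        c = align_and_window([("r0", read)], aspec)[0]
        assert c.aligned and c.indel_in_window

    def test_deletion_outside_window_is_not_indel_containing(self, aspec):
        lo, hi = quantification_window(aspec)
        read = aspec.sequence[:hi + 20] + aspec.sequence[hi + 25:]
        c = align_and_window([("r0", read)], aspec)[0]
        assert c.aligned and not c.indel_in_window

    def test_garbage_read_not_aligned(self, aspec):
        c = align_and_window([("r0", "ACGT" * 60)], aspec)[0]
        assert not c.aligned


def _call(aligned=True, discard=False, base=None, window_seq=None):
    return ReadCall("r", aligned=aligned, indel_in_window=discard,
                    base_at_edit=base, window_seq=window_seq)


class TestFormulas:
    def test_substitution_formula_printed_example(self, aspec):
        alt = aspec.substitution[2]
        ref = aspec.substitution[1]
        calls = ([_call(base=alt)] * 450 + [_call(base=ref)] * 450
                 + [_call(discard=True, base=ref)] * 100)
        # 1000 aligned, 900 non-discarded, 450 edited: (450/900)*(900/1000)
        assert quantify_substitution(calls, aspec) == pytest.approx(45.0)

    def test_indel_formula(self, aspec):
        calls = [_call(discard=True)] * 50 + [_call()] * 950
        assert quantify_indels(calls) == pytest.approx(5.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_formula_identities_on_random_count_tuples(self, n_edit, n_clean, n_indel):
        aspec = make_amplicon_spec(seed=1)
        alt, ref = aspec.substitution[2], aspec.substitution[1]
        if n_edit + n_clean == 0:
            return
        calls = ([_call(base=alt)] * n_edit + [_call(base=ref)] * n_clean
                 + [_call(discard=True)] * n_indel)
        aligned = n_edit + n_clean + n_indel
        kept = n_edit + n_clean
        expected_sub = 100.0 * (n_edit / kept) * (kept / aligned)
        assert quantify_substitution(calls, aspec) == pytest.approx(expected_sub)
        assert quantify_indels(calls) == pytest.approx(100.0 * n_indel / aligned)

    def test_allele_edit_fraction(self, aspec):
        lo, hi = quantification_window(aspec)
        edited_window = aspec.edited_sequence[lo:hi]
        ref_window = aspec.sequence[lo:hi]
        calls = [_call(window_seq=edited_window)] * 200 + [_call(window_seq=ref_window)] * 800
        assert quantify_allele_edit(calls, aspec) == pytest.approx(20.0)

    def test_zero_aligned_reads_is_no_data(self, aspec):
        with pytest.raises(ValueError, match="no aligned"):
            quantify_substitution([_call(aligned=False)], aspec)


class TestHeterozygousCorrection:
    def test_printed_example(self):
        value, clamped = correct_heterozygous(50.0, 10.0)
        assert value == pytest.approx(100 * 40 / 90)
        assert not clamped

    def test_zero_mock_is_identity(self):
        assert correct_heterozygous(37.5, 0.0) == (37.5, False)

    def test_editing_equal_to_mock_is_zero(self):
        assert correct_heterozygous(10.0, 10.0) == (0.0, False)

    def test_below_mock_clamped_and_flagged(self):
        value, clamped = correct_heterozygous(5.0, 10.0)
        assert value == 0.0 and clamped

    def test_mock_at_100_rejected(self):
        with pytest.raises(ValueError):
            correct_heterozygous(50.0, 100.0)


class TestOffTarget:
    def test_marker_is_shortest_deviating_prefix(self):
        assert derive_offtarget_marker("CTGGA" + "A" * 20, 0, "CTGCA") == "CTGC"

    def test_flap_matching_target_has_no_marker(self):
        ref = "ACGTACGTAA"
        assert derive_offtarget_marker(ref, 2, "GTACG") is None

    def test_first_base_deviation_gives_one_base_marker(self):
        assert derive_offtarget_marker("AAAA", 0, "T") == "T"

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=40),
           st.text(alphabet="ACGT", min_size=1, max_size=12),
           st.integers(0, 10))
    def test_matches_bruteforce_prefix_search(self, ref, flap, nick):
        target = ref[nick:]
        expected = None
        for i in range(1, len(flap) + 1):
            if flap[:i] != target[:i]:
                expected = flap[:i]
                break
        assert derive_offtarget_marker(ref, nick, flap) == expected

    def test_marker_reads_counted_including_indel_reads(self, aspec):
        nick = aspec.pegrna_nick
        first = next(b for b in "ACGT" if b != aspec.sequence[nick])
        marker = derive_offtarget_marker(aspec.sequence, nick, first + "GGG")
        assert marker == first  # flap deviates at its first base
        ot = aspec.sequence[:nick] + marker + aspec.sequence[nick + len(marker):]
        ot_indel = ot[:nick - 30] + ot[nick - 28:]  # extra deletion upstream
        calls = align_and_window([("a", aspec.sequence), ("b", ot), ("c", ot_indel),
                                  ("d", aspec.sequence)], aspec)
        freq = call_offtarget_reads(calls, marker, nick)
        assert freq == pytest.approx(100 * 2 / 4)


class TestFixtureRecovery:
    def test_error_free_planted_frequencies_recovered_exactly(self, tmp_path):
        spec = make_amplicon_spec(seed=3)
        freqs = {"intended": 0.45, "insertion": 0.05, "unedited": 0.5}
        fx = generate_amplicon_fixture(spec, freqs, 4000, 11, tmp_path)
        reads = [(r, s) for r, s, _ in read_fastq(fx.fastq_path)]
        calls = align_and_window(reads, spec)
        counts = fx.truth.allele.value_counts()
        n = len(fx.truth)
        expected_sub = 100.0 * counts.get("intended", 0) / n
        expected_indel = 100.0 * counts.get("insertion", 0) / n
        assert quantify_substitution(calls, spec) == pytest.approx(expected_sub)
        assert quantify_indels(calls) == pytest.approx(expected_indel)
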