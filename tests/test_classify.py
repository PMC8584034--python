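import dataclasses

import pytest

from pescreen.classify import (ClassifierConfig, canonical_interval,
                               classify_read, extract_deletion_boundaries)
from pescreen.library import generate_sgrna_library
from pescreen.outcomes import Category, OutcomeRecord
from pescreen.pipeline import run_screen
from pescreen.simulate import (DEFAULT_ADAPTER, OutcomePlan, _r2_from_molecule,
                               generate_screen_readset, simulate_outcome_molecule)
from pescreen.vector import reverse_complement


def _read_for(spec, category, **kwargs):
    mol = simulate_outcome_molecule(spec, category, **kwargs)
    return reverse_complement(_r2_from_molecule(mol, DEFAULT_ADAPTER))


def _window_read(spec, seq):
    """Last 263 nt of an equal-length molecule, oriented to top strand."""
    return reverse_complement(_r2_from_molecule(seq, DEFAULT_ADAPTER))


class TestDecisionTree:
    def test_exact_vector_window_is_unedited(self, spec, decoys):
        rec = classify_read(_read_for(spec, Category.UNEDITED), spec, decoys)
        assert rec.category is Category.UNEDITED

    def test_programmed_substitution_is_intended_edit(self, spec, decoys):
        rec = classify_read(_read_for(spec, Category.INTENDED_EDIT), spec, decoys)
        assert rec.category is Category.INTENDED_EDIT

    def test_one_nt_deletion_far_from_nicks_is_disregarded(self, spec, decoys):
        pos = spec.minus50_nick - 30  # > 5 nt from every programmed nick
        mol = spec.sequence[:pos] + spec.sequence[pos + 1:]
        rec = classify_read(_window_read(spec, mol), spec, decoys)
        assert rec.category is Category.UNEDITED

    def test_one_nt_deletion_near_pegrna_nick_is_a_deletion(self, spec, decoys):
        pos = spec.pegrna_nick + 3
        mol = spec.sequence[:pos] + spec.sequence[pos + 1:]
        rec = classify_read(_window_read(spec, mol), spec, decoys)
        assert rec.category is Category.DELETION

    @pytest.mark.parametrize("interval", [(300, 330), (250, 260), (340, 400)])
    def test_deletions_recover_their_interval(self, spec, decoys, interval):
        read = _read_for(spec, Category.DELETION, deletion=interval)
        rec = classify_read(read, spec, decoys)
        assert rec.category is Category.DELETION
        s, e = canonical_interval(spec.sequence, *interval)
        assert (rec.del_start, rec.del_end) == (s, e - 1)

    def test_internick_duplication_detected_with_interval(self, spec, decoys):
        interval = (spec.minus50_nick + 5, spec.minus50_nick + 45)
        read = _read_for(spec, Category.TANDEM_DUPLICATION, duplication=interval)
        rec = classify_read(read, spec, decoys)
        assert rec.category is Category.TANDEM_DUPLICATION
        s, e = canonical_interval(spec.sequence, *interval)
        assert (rec.dup_start, rec.dup_end) == (s, e - 1)

    def test_scaffold_templated_insertion_is_scaffold_edits(self, spec, decoys):
        read = _read_for(spec, Category.SCAFFOLD_EDITS, scaffold_insert=4)
        rec = classify_read(read, spec, decoys)
        assert rec.category is Category.SCAFFOLD_EDITS

    def test_flap_joined_at_plus50_nick_is_unintended_joining(self, spec, decoys):
        read = _read_for(spec, Category.UNINTENDED_PEGRNA_JOINING)
        rec = classify_read(read, spec, decoys)
        assert rec.category is Category.UNINTENDED_PEGRNA_JOINING
        assert rec.junction == spec.plus50_nick

    def test_decoy_only_read_is_uncategorized(self, spec, decoys):
        read = _read_for(spec, Category.UNCATEGORIZED, decoy=decoys["decoy_1"])
        rec = classify_read(read, spec, decoys)
        assert rec.category is Category.UNCATEGORIZED
        assert rec.sublabel == "decoy_only"

    def test_classification_is_deterministic(self, spec, decoys):
        read = _read_for(spec, Category.DELETION, deletion=(290, 340))
        recs = [classify_read(read, spec, decoys, read_id="x") for _ in range(3)]
        assert recs[0] == recs[1] == recs[2]


class TestDeletionBoundaries:
    def test_unambiguous_interval_returned_inclusively(self, spec):
        # pick a start with no microhomology so the interval is unique
        seq = spec.sequence
        s = next(p for p in range(300, 320)
                 if seq[p - 1] != seq[p + 10])
        rec = OutcomeRecord("r", "sg", Category.DELETION, del_start=s, del_end=s + 10)
        assert extract_deletion_boundaries(rec, spec) == (s, s + 10)
        assert not rec.boundary_excluded

    def test_microhomology_reports_minimal_coordinates(self):
        seq = "G" + "AT" * 2 + "C" * 40  # deleting either AT gives the same product
        assert canonical_interval(seq, 3, 5) == (1, 3)

    def test_deletion_touching_primer_window_is_flagged(self, spec):
        ps = spec.primer_fwd_interval[1]  # deletion within 10 nt of forward primer
        rec = OutcomeRecord("r", "sg", Category.DELETION,
                            del_start=ps + 5, del_end=ps + 20)
        extract_deletion_boundaries(rec, spec)
        assert rec.boundary_excluded

    def test_requires_deletion_record(self, spec):
        rec = OutcomeRecord("r", "sg", Category.UNEDITED)
        with pytest.raises(ValueError):
            extract_deletion_boundaries(rec, spec)


class TestOracleRoundTrip:
    def test_error_free_readset_classifies_to_truth(self, spec, decoys, tmp_path):
        lib = generate_sgrna_library(2, 2, 4, seed=4)
        plan = dataclasses.replace(OutcomePlan(), substitution_error_rate=0.0, p_bad=0.0)
        rs = generate_screen_readset(spec, lib, plan, 800, tmp_path, seed=6, decoys=decoys)
        res = run_screen(rs.r1_path, rs.r2_path, lib, spec, decoys)
        truth = rs.truth.set_index("read_id")
        assert res.n_classified == 800
        for rec in res.records:
            row = truth.loc[rec.read_id]
            assert rec.category.value == row.category
            assert rec.sgrna_id == row.sgrna_id
            if rec.category is Category.DELETION:
                assert (rec.del_start, rec.del_end) == (row.del_start, row.del_end)
            if rec.category is Category.TANDEM_DUPLICATION:
                assert (rec.dup_start, rec.dup_end) == (row.dup_start, row.dup_end)
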