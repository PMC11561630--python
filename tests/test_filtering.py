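"""Size filter, cysteine-spacing motif scan and secretion gating."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_motif
from csabmine.filtering import (
    DEFAULT_MOTIF,
    ConfigurationError,
    MatureTooShortError,
    MotifSpec,
    extract_mature,
    heuristic_signal_predict,
    motif_scan,
    secretion_gate,
    size_filter,
)
from csabmine.sequence_io import SecretionAnnotation, SequenceRecord
from csabmine.synthetic_data import SyntheticSpec, generate_defensin

MINIMAL_MOTIF = "CAACAAACAACAAAACAC"  # gaps (2,3,2,4,1)


def _rec(rid, residues):
    return SequenceRecord(id=rid, residues=residues)


class TestSizeFilter:
    def test_bounds_inclusive(self):
        records = [_rec(f"l{n}", "A" * n) for n in (29, 30, 130, 131)]
        report = size_filter(records)
        assert report.kept == ["l30", "l130"]
        assert report.removed == {"l29": "TOO_SHORT", "l131": "TOO_LONG"}

    def test_empty_input(self):
        report = size_filter([])
        assert report.kept == [] and report.removed == {}

    def test_uniform_length_all_kept(self):
        records = [_rec(f"r{i}", "A" * 60) for i in range(10)]
        report = size_filter(records)
        assert len(report.kept) == 10 and not report.removed

    def test_partition_invariant(self):
        records = [_rec(f"r{i}", "A" * (20 + 7 * i)) for i in range(25)]
        report = size_filter(records)
        assert set(report.kept) | set(report.removed) == {r.id for r in records}
        assert not set(report.kept) & set(report.removed)


class TestMotifScan:
    def test_minimal_satisfying_gaps(self):
        matched, assignments = motif_scan(MINIMAL_MOTIF)
        assert matched
        assert assignments == [(1, 4, 8, 11, 16, 18)]

    def test_five_cysteines_never_match(self):
        matched, assignments = motif_scan("CAACAAACAACAAAAC")
        assert not matched and assignments == []

    def test_extra_cysteines_inside_gaps_allowed(self):
        # an 8-cysteine sequence: extras flank the framework
        seq = "AAC" + "A" + MINIMAL_MOTIF + "A" + "C" + "AA"
        matched, assignments = motif_scan(seq)
        assert matched
        assert (5, 8, 12, 15, 20, 22) in assignments

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_random_80mers(self, seed):
        rng = random.Random(seed)
        residues = "".join(
            rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(80)
        )
        # force exactly 8 cysteines at random positions
        residues = "".join(a for a in residues if a != "C")
        pos = sorted(rng.sample(range(len(residues)), 8))
        chars = list(residues)
        for p in pos:
            chars[p] = "C"
        residues = "".join(chars)
        matched, assignments = motif_scan(residues)
        oracle = brute_force_motif(residues, DEFAULT_MOTIF.segment_bounds)
        assert sorted(assignments) == sorted(oracle)
        assert matched == bool(oracle)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="AC", min_size=6, max_size=60))
    def test_property_oracle_equivalence_cysteine_rich(self, residues):
        if residues.count("C") > 12:
            return
        matched, assignments = motif_scan(residues)
        oracle = brute_force_motif(residues, DEFAULT_MOTIF.segment_bounds)
        assert sorted(assignments) == sorted(oracle)

    def test_bad_motif_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            MotifSpec(segment_bounds=((5, 2), (3, 3), (2, 12), (4, 17), (1, 1)))


class TestSecretionGate:
    def test_rules(self):
        records = [_rec(i, "A" * 40) for i in ("keep", "tm", "nosig")]
        annotations = {
            "keep": SecretionAnnotation("keep", True, False, 20),
            "tm": SecretionAnnotation("tm", True, True, 20),
            "nosig": SecretionAnnotation("nosig", False, False),
        }
        report = secretion_gate(records, annotations)
        assert report.kept == ["keep"]
        assert report.removed == {"tm": "HAS_TM", "nosig": "NO_SIGNAL"}

    def test_missing_annotation_lists_ids(self):
        with pytest.raises(ConfigurationError, match="orphan"):
            secretion_gate([_rec("orphan", "A" * 40)], {})


class TestHeuristicSignal:
    def test_constructed_signal_detected(self):
        rec = _rec("p", "MKK" + "LLLLLLLL" + "AGA" + "Q" * 40)
        ann = heuristic_signal_predict(rec)
        assert ann.has_signal_peptide and not ann.has_transmembrane
        assert ann.cleavage_site is not None

    def test_poly_serine_has_no_signal(self):
        ann = heuristic_signal_predict(_rec("s", "S" * 60))
        assert not ann.has_signal_peptide and not ann.has_transmembrane

    def test_late_hydrophobic_window_marks_tm(self):
        rec = _rec("t", "MKK" + "LLLLLLLL" + "AGA" + "Q" * 31 + "LLLLLLLLLL" + "Q" * 5)
        ann = heuristic_signal_predict(rec)
        assert ann.has_transmembrane

    def test_deterministic(self):
        rec = _rec("d", "MKR" + "LIVLIVL" + "ASA" + "NDQEGH" * 8)
        assert heuristic_signal_predict(rec) == heuristic_signal_predict(rec)


class TestExtractMature:
    def test_cleavage_arithmetic(self):
        rec = _rec("p", "A" * 70)
        ann = SecretionAnnotation("p", True, False, 22)
        mature = extract_mature(rec, ann)
        assert len(mature) == 48
        assert mature.id == "p|mature"

    def test_mature_too_short(self):
        rec = _rec("p", "A" * 70)
        with pytest.raises(MatureTooShortError):
            extract_mature(rec, SecretionAnnotation("p", True, False, 65))

    def test_generator_round_trip(self):
        labeled = generate_defensin(SyntheticSpec(defensin_class="II", seed=7))
        ann = heuristic_signal_predict(labeled.record)
        assert extract_mature(labeled.record, ann).residues == labeled.mature


def test_cascade_stages_nest():
    """Each stage's kept set is a subset of the previous stage's."""
    from csabmine.filtering import annotate_secretion, motif_filter
    from csabmine.synthetic_data import generate_decoys, generate_defensins

    records = [lr.record for lr in generate_defensins("I", 10, 5)]
    records += [lr.record for lr in generate_decoys("NO_CYS", 5, 5)]
    records += [lr.record for lr in generate_decoys("TOO_SHORT", 5, 5)]
    s1 = size_filter(records)
    kept1 = [r for r in records if r.id in set(s1.kept)]
    s2 = motif_filter(kept1)
    kept2 = [r for r in kept1 if r.id in set(s2.kept)]
    s3 = secretion_gate(kept2, annotate_secretion(kept2))
    assert set(s2.kept) <= set(s1.kept)
    assert set(s3.kept) <= set(s2.kept)
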