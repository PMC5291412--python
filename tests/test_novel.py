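"""Folding, hairpin criteria, mapping, windows and novel-miRNA calling."""

import random

import pytest

import _structures
from _oracles import best_fold_by_enumeration, structure_energy, PAIRS, MIN_LOOP
from mothmir.novel import (ArmAssignmentError, GenomicLocus, HairpinCriteria,
                           NovelMiRNA, PrecursorCandidate, arm_ratio,
                           assign_arm, call_novel, evaluate_criteria,
                           extract_windows, fold, fold_candidate, hairpins,
                           map_exact, pair_table, read_vienna)
from mothmir import tables
from mothmir.readqc import UniqueRead


def _random_seq(rand, n):
    return "".join(rand.choice("ACGT") for _ in range(n))


def _structure_pairs(structure):
    return {(i, j) for i, j in enumerate(pair_table(structure))
            if j is not None and i < j}


class TestFold:
    def test_perfect_gc_stem(self):
        assert fold("GGGGAAAACCCC") == ("((((....))))", -12.0)

    def test_unpairable_sequence_stays_open(self):
        assert fold("A" * 12) == ("." * 12, 0.0)

    def test_planted_20bp_gc_stem_with_8nt_loop(self):
        db, energy = fold("G" * 20 + "A" * 8 + "C" * 20)
        assert db == "(" * 20 + "." * 8 + ")" * 20
        assert energy == -60.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGTACGTA")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGTACGXACGT")

    def test_matches_exhaustive_enumeration(self):
        rand = random.Random(2024)
        for _ in range(60):
            seq = _random_seq(rand, rand.randint(10, 14))
            db, energy = fold(seq)
            best_e, best_np = best_fold_by_enumeration(seq)
            assert energy == pytest.approx(best_e, abs=1e-9)
            pairs = _structure_pairs(db)
            # structure is valid under the model and achieves its energy
            assert all((seq[i], seq[j]) in PAIRS and j - i > MIN_LOOP
                       for i, j in pairs)
            assert structure_energy(seq, pairs) == pytest.approx(energy)
            assert len(pairs) == best_np


class TestMapExact:
    GENOME = {"chr1": "TTTT" + "ACGGATCCATTGACCATGCAGG" + "TTTT"}

    def test_forward_hit(self):
        loci = map_exact("ACGGATCCATTGACCATGCAGG", self.GENOME)
        assert GenomicLocus("chr1", 4, 26, "+") in loci

    def test_reverse_hit(self):
        loci = map_exact("CCTGCATGGTCAATGGATCCGT", self.GENOME)
        assert GenomicLocus("chr1", 4, 26, "-") in loci

    def test_absent_read_maps_nowhere(self):
        assert map_exact("GGGGGGGGGGGGCCCCCCCCCC", self.GENOME) == []

    def test_palindrome_hits_both_strands_at_same_span(self):
        genome = {"c": "TT" + "GGATCC" + "TT"}
        loci = map_exact("GGATCC", genome)
        assert {(l.start, l.end, l.strand) for l in loci} == {(2, 8, "+"), (2, 8, "-")}

    def test_planted_matures_map_to_their_loci(self, study):
        for m in study["truth"].matures:
            loci = map_exact(m.sequence, study["genome"])
            assert m.locus in loci


class TestWindows:
    GENOME = {"chr1": "A" * 300}

    def test_window_sizes_mid_sequence(self):
        locus = GenomicLocus("chr1", 100, 122, "+")
        wins = extract_windows(locus, self.GENOME)
        assert [len(w.sequence) for w in wins] == [102, 102]
        assert wins[0].mature_offset == 20
        assert wins[1].mature_offset == 60

    def test_clipped_at_sequence_start(self):
        locus = GenomicLocus("chr1", 5, 27, "+")
        wins = extract_windows(locus, self.GENOME)
        assert len(wins[0].sequence) == 5 + 22 + 60
        assert wins[0].mature_offset == 5

    def test_minus_strand_window_is_reverse_complement(self):
        genome = {"chr1": "TTTTTTTTTT" + "ACGGATCCAT" + "GGGGGGGGGG"}
        locus = GenomicLocus("chr1", 10, 20, "-")
        win = extract_windows(locus, genome)[0]
        assert "ATGGATCCGT" in win.sequence
        start = win.mature_offset
        assert win.sequence[start:start + 10] == "ATGGATCCGT"


class TestCriteria:
    def test_planted_perfect_hairpin_passes_all_eleven(self):
        report = evaluate_criteria(_structures.perfect_hairpin())
        assert report.overall
        assert all(report.passed.values())

    def test_thirteen_nt_stem_bulge_fails_criterion_one(self):
        report = evaluate_criteria(_structures.violating_candidates()[1])
        assert report.measured[1] == 13
        assert not report.passed[1]
        assert not report.overall

    def test_hairpin_of_total_length_49_fails_criterion_four(self):
        seq = "G" * 16 + "A" * 17 + "C" * 16
        st = "(" * 16 + "." * 17 + ")" * 16
        report = evaluate_criteria(_structures.make(seq, st, 0, 18))
        assert report.measured[4] == 49
        assert not report.passed[4]

    @pytest.mark.parametrize("criterion", sorted(_structures.violating_candidates()))
    def test_single_threshold_violations(self, criterion):
        report = evaluate_criteria(_structures.violating_candidates()[criterion])
        failed = [idx for idx, ok in report.passed.items() if not ok]
        assert failed == [criterion]
        assert not report.overall

    def test_oversized_mature_bulge_fails_bulge_and_error_criteria(self):
        report = evaluate_criteria(_structures.bulge9_candidate())
        failed = {idx for idx, ok in report.passed.items() if not ok}
        assert failed == {6, 7, 9}

    def test_mature_outside_any_stem_fails_with_note(self):
        cand = _structures.make("G" * 20 + "A" * 8 + "C" * 20 + "T" * 22,
                                "(" * 20 + "." * 8 + ")" * 20 + "." * 22,
                                48, 20)
        report = evaluate_criteria(cand)
        assert not report.overall
        assert "no hairpin stem" in report.note

    def test_relaxing_any_threshold_never_flips_pass_to_fail(self):
        rand = random.Random(31)
        crit = HairpinCriteria()
        le_fields = ["max_stem_bulge_nt", "max_free_energy", "max_loop_len",
                     "max_mature_bulge_nt", "max_biased_errors_mature",
                     "max_biased_bulges_mature", "max_mature_errors"]
        ge_fields = ["min_stem_pairs", "min_hairpin_len", "min_mature_pairs",
                     "min_pct_mature_in_stem"]
        candidates = list(_structures.violating_candidates().values())
        candidates.append(_structures.perfect_hairpin())
        for _ in range(20):
            seq = _random_seq(rand, 80)
            cand = PrecursorCandidate(seq, "." * 80, 0.0, 10, 22)
            candidates.append(fold_candidate(cand))
        for cand in candidates:
            base = evaluate_criteria(cand, crit)
            for fname in le_fields:
                relaxed = HairpinCriteria(**{fname: getattr(crit, fname) + 5})
                rep = evaluate_criteria(cand, relaxed)
                for idx in rep.passed:
                    assert base.passed[idx] <= rep.passed[idx]
            for fname in ge_fields:
                relaxed = HairpinCriteria(**{fname: getattr(crit, fname) - 5})
                rep = evaluate_criteria(cand, relaxed)
                for idx in rep.passed:
                    assert base.passed[idx] <= rep.passed[idx]


class TestCallNovel:
    def test_exact_recovery_on_noise_free_library(self, study, qc_result):
        called, skipped = call_novel(qc_result["uniques"], study["genome"])
        assert skipped == []
        planted = {m.sequence for m in study["truth"].matures}
        assert {nv.sequence for nv in called} == planted

    def test_called_arms_match_ground_truth(self, study, qc_result):
        called, _ = call_novel(qc_result["uniques"], study["genome"])
        arm_by_seq = {m.sequence: m.arm for m in study["truth"].matures}
        for nv in called:
            assert nv.arm == arm_by_seq[nv.sequence]

    def test_names_rank_by_descending_count(self, study, qc_result):
        called, _ = call_novel(qc_result["uniques"], study["genome"])
        counts = [nv.count for nv in called]
        assert counts == sorted(counts, reverse=True)
        for rank, nv in enumerate(called, start=1):
            assert nv.name == f"gmo-miR-PC-{nv.arm}-{rank}_{int(round(nv.count))}"

    def test_subthreshold_count_not_called(self, study):
        mature = study["truth"].matures[0]
        reads = [UniqueRead(mature.sequence, 9)]
        called, _ = call_novel(reads, study["genome"])
        assert called == []

    def test_read_on_unstructured_sequence_not_called(self, rng):
        genome = {"flat": "ACGGATTACA" * 40}
        read = UniqueRead("ACGGATTACAACGGATTACAAC", 50)
        called, _ = call_novel([read], genome)
        assert called == []

    def test_both_arm_precursors_flagged(self, study, qc_result):
        both_ids = {hp.hairpin_id for hp in study["truth"].hairpins
                    if hp.arm_mode == "both"}
        if not both_ids:
            pytest.skip("no both-arm hairpin planted under this seed")
        called, _ = call_novel(qc_result["uniques"], study["genome"])
        seq_to_hp = {m.sequence: m.hairpin_id for m in study["truth"].matures}
        for nv in called:
            assert nv.both_arms == (seq_to_hp[nv.sequence] in both_ids)


class TestArms:
    def test_mature_at_window_start_is_5p(self):
        cand = _structures.perfect_hairpin()
        assert assign_arm(cand) == "5p"

    def test_mature_at_window_end_is_3p(self):
        base = _structures.perfect_hairpin()
        cand = _structures.make(base.sequence, base.structure,
                                len(base.sequence) - 22, 22)
        assert assign_arm(cand) == "3p"

    def test_loop_straddling_mature_raises(self):
        base = _structures.perfect_hairpin()
        cand = _structures.make(base.sequence, base.structure, 24, 22)
        with pytest.raises(ArmAssignmentError):
            assign_arm(cand)

    def test_published_identifiers_split_27_to_17(self):
        names = tables.load_novel_mirnas()["mirna"].tolist()
        n5 = sum("-5p-" in n for n in names)
        n3 = sum("-3p-" in n for n in names)
        assert (n5, n3) == (27, 17)
        assert arm_ratio(names) == 1.59

    def test_equal_counts_give_ratio_one(self):
        names = ["x-miR-PC-5p-1_10", "x-miR-PC-3p-2_10"]
        assert arm_ratio(names) == 1.0

    def test_zero_denominator_reported_as_undefined(self):
        assert arm_ratio(["x-miR-PC-5p-1_10"]) is None

    def test_planted_three_to_one_bias_recovered(self):
        cand = _structures.perfect_hairpin()
        report = evaluate_criteria(cand)
        novel = [NovelMiRNA(f"n{i}", "5p" if i < 9 else "3p", "A" * 22,
                            20, cand, report) for i in range(12)]
        assert arm_ratio(novel) == 3.0


class TestVienna:
    def test_round_trip_parse(self, tmp_path):
        path = tmp_path / "folds.vienna"
        path.write_text(">cand1\nGGGGAAAACCCC\n((((....)))) (-12.00)\n"
                        ">cand2\nAAAAAAAAAAAA\n............\n")
        entries = read_vienna(path)
        assert entries[0] == ("cand1", "GGGGAAAACCCC", "((((....))))", -12.0)
        assert entries[1][3] == 0.0

    def test_external_fold_feeds_criteria(self, tmp_path):
        good = _structures.perfect_hairpin()
        path = tmp_path / "ext.vienna"
        path.write_text(f">hp\n{good.sequence}\n{good.structure} (-90.0)\n")
        name, seq, st, energy = read_vienna(path)[0]
        cand = PrecursorCandidate(seq, st, energy, 0, 22)
        assert evaluate_criteria(cand).overall


class TestHairpinParse:
    def test_opportunistic_far_pair_is_trimmed(self):
        # one lone pair encloses a clean stem across a 19-nt gap
        seq = "G" + "A" * 19 + "G" * 16 + "A" * 4 + "C" * 16 + "T"
        st = "(" + "." * 19 + "(" * 16 + "." * 4 + ")" * 16 + ")"
        hp = hairpins(st)[0]
        assert hp.n_pairs == 16
        assert hp.outer == (20, 39 + 16)

    def test_strong_far_arm_is_kept_across_a_wide_bulge(self):
        cand = _structures.violating_candidates()[1]
        hp = hairpins(cand.structure)[0]
        assert hp.n_pairs == 30
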