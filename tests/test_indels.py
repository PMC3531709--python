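import pytest

from igclean import (
    ClonalAlignment,
    IndelConfig,
    classify_sequence,
    count_sharing,
    extract_events,
    find_hpts,
    in_aid_motif,
    is_near_hpt,
    run_indel_identifier,
)
from igclean.indels import HPT, IndelEvent


class TestFindHpts:
    @pytest.mark.parametrize("seq,min_len,expected", [
        ("ACGT", 2, []),
        ("AATCCC", 2, [HPT(0, 2, "A"), HPT(3, 6, "C")]),
        ("AAAA", 5, []),
        ("AAAA", 4, [HPT(0, 4, "A")]),
        ("", 1, []),
    ])
    def test_examples(self, seq, min_len, expected):
        assert find_hpts(seq, min_len) == expected

    def test_matches_exhaustive_scan(self, rng):
        """Agreement with an independent oracle on random strings."""
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 120))))
            for min_len in (1, 2, 3, 5):
                expected = []
                i = 0
                while i < len(seq):
                    j = i
                    while j < len(seq) and seq[j] == seq[i]:
                        j += 1
                    if j - i >= min_len:
                        expected.append((i, j, seq[i]))
                    i = j
                assert [(h.start, h.end, h.base) for h in find_hpts(seq, min_len)] == expected


class TestExtractEvents:
    def test_identical_rows_give_nothing(self):
        assert extract_events("ACGT", "ACGT") == ([], [])

    def test_gap_in_germline_is_insertion(self):
        indels, muts = extract_events("ACTGT", "AC-GT")
        assert muts == []
        (ev,) = indels
        assert (ev.kind, ev.columns, ev.length) == ("insertion", (2, 3), 1)
        assert ev.gl_span == (2, 2)

    def test_gap_run_in_member_is_one_deletion(self):
        indels, _ = extract_events("AC--T", "ACGGT")
        (ev,) = indels
        assert (ev.kind, ev.columns, ev.length) == ("deletion", (2, 4), 2)
        assert ev.gl_span == (2, 4)

    def test_mismatch_is_mutation_with_positions(self):
        _, muts = extract_events("A-CGT", "A-CCT")
        (m,) = muts
        assert (m.column, m.gl_base, m.read_base) == (3, "C", "G")
        assert m.read_position == 2  # member has a gap before it
        assert m.gl_position == 2

    def test_shared_gap_columns_ignored(self):
        indels, muts = extract_events("AC-GT", "AC-GT")
        assert indels == [] and muts == []

    def test_adjacent_opposite_gaps_are_two_events(self):
        indels, _ = extract_events("A-CGT", "AG-GT")
        kinds = sorted(ev.kind for ev in indels)
        assert kinds == ["deletion", "insertion"]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            extract_events("ACGT", "ACG")


class TestNearHpt:
    def _deletion(self, gl_pos):
        return IndelEvent("deletion", (gl_pos, gl_pos + 1), (gl_pos, gl_pos + 1))

    def test_inside_tract(self):
        assert is_near_hpt(self._deletion(2), "CAAAG", 3)

    def test_five_prime_flank(self):
        assert is_near_hpt(self._deletion(0), "CAAAG", 3)

    def test_three_prime_flank(self):
        assert is_near_hpt(self._deletion(4), "CAAAG", 3)

    def test_no_tract_long_enough(self):
        assert not is_near_hpt(self._deletion(1), "CAAAG", 4)

    def test_tract_free_sequence(self):
        for pos in range(8):
            assert not is_near_hpt(self._deletion(pos), "ACGTACGT", 2)

    def test_two_away_is_not_near(self):
        # tract TTT at [2,5); position 0 is two bases 5' of it
        assert not is_near_hpt(self._deletion(0), "ACTTTG", 3)

    def test_insertion_touching_tract(self):
        ins = IndelEvent("insertion", (3, 4), (3, 3))
        assert is_near_hpt(ins, "CATTTG", 3)  # inserting just before the Ts? pos 3 is inside
        before = IndelEvent("insertion", (2, 3), (2, 2))
        assert is_near_hpt(before, "CATTTG", 3)  # insertion point at tract start
        far = IndelEvent("insertion", (1, 2), (1, 1))
        assert not is_near_hpt(far, "CATTTG", 3)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 80))))
            for min_len in (2, 3):
                tracts = find_hpts(seq, min_len)
                for pos in range(len(seq)):
                    expected = any(h.start - 1 <= pos <= h.end for h in tracts)
                    assert is_near_hpt(self._deletion(pos), seq, min_len) == expected


def _clone(gl, rows, clone_id="c1"):
    return ClonalAlignment(clone_id, f"GL_{clone_id}", gl,
                           [(f"m{i}", r) for i, r in enumerate(rows, 1)])


class TestCountSharing:
    def test_unique_deletion(self):
        clone = _clone("CAAAG", ["CA-AG", "CAAAG", "CAAAG"])
        (ev,), _ = extract_events("CA-AG", "CAAAG")
        assert count_sharing(ev, clone) == 1

    def test_shared_by_all(self):
        clone = _clone("CAAAG", ["CA-AG"] * 3)
        (ev,), _ = extract_events("CA-AG", "CAAAG")
        assert count_sharing(ev, clone) == 3

    def test_different_lengths_counted_separately(self):
        clone = _clone("CAAAAG", ["CA--AG", "CA-AAG", "CAAAAG"])
        (ev2,), _ = extract_events("CA--AG", "CAAAAG")
        (ev1,), _ = extract_events("CA-AAG", "CAAAAG")
        assert count_sharing(ev2, clone) == 1
        assert count_sharing(ev1, clone) == 1

    def test_mutation_sharing_requires_same_base(self):
        clone = _clone("ACGT", ["ACTT", "ACAT", "ACTT"])
        _, (m,) = extract_events("ACTT", "ACGT")
        assert count_sharing(m, clone) == 2


class TestAidMotif:
    def test_inside_aaca(self):
        _, (m,) = extract_events("GGATCAGG", "GGAACAGG")
        assert m.gl_position == 3
        assert in_aid_motif(m, "GGAACAGG")

    def test_inside_complementary_tgtt(self):
        _, (m,) = extract_events("GGTGATGG", "GGTGTTGG")
        assert m.gl_position == 4
        assert in_aid_motif(m, "GGTGTTGG")

    def test_absent_motif(self):
        _, (m,) = extract_events("GGGGAGGG", "GGGGGGGG")
        assert not in_aid_motif(m, "GGGGGGGG")


class TestClassify:
    def test_unique_tract_deletion_in_multimember_clone_is_artifact(self):
        clone = _clone("CCAAACC", ["CCA-ACC", "CCAAACC", "CCAAACC"])
        v = classify_sequence("m1", clone, config=IndelConfig(min_share=2, min_hpt_len=2))
        assert v.verdict == "artifact_indel"

    def test_same_deletion_in_singleton_clone_is_uncertain(self):
        clone = _clone("CCAAACC", ["CCA-ACC"])
        v = classify_sequence("m1", clone, config=IndelConfig(min_share=2, min_hpt_len=2))
        assert v.verdict == "uncertain"

    def test_low_quality_mutation_in_aid_motif_is_kept(self):
        clone = _clone("GGAACAGG", ["GGATCAGG", "GGAACAGG", "GGAACAGG"])
        quals = [40, 40, 40, 8, 40, 40, 40, 40]
        v = classify_sequence("m1", clone, quals,
                              IndelConfig(min_share=2, min_hpt_len=2, min_qual=10))
        assert v.verdict == "without_indels"

    def test_low_quality_unshared_mutation_is_discarded(self):
        clone = _clone("GGACTAGG", ["GGACAAGG", "GGACTAGG", "GGACTAGG"])
        quals = [40, 40, 40, 40, 8, 40, 40, 40]
        v = classify_sequence("m1", clone, quals,
                              IndelConfig(min_share=2, min_hpt_len=2, min_qual=10))
        assert v.verdict == "low_qual_mutation"

    def test_mutation_screening_disabled_by_negative_threshold(self):
        clone = _clone("GGACTAGG", ["GGACAAGG", "GGACTAGG", "GGACTAGG"])
        quals = [1] * 8
        v = classify_sequence("m1", clone, quals,
                              IndelConfig(min_share=2, min_hpt_len=2, min_qual=-1))
        assert v.verdict == "without_indels"

    def test_shared_tract_deletion_is_legitimate(self):
        clone = _clone("CCAAACC", ["CCA-ACC", "CCA-ACC", "CCAAACC"])
        v = classify_sequence("m1", clone, config=IndelConfig(min_share=2, min_hpt_len=2))
        assert v.verdict == "with_legitimate_indels"

    def test_deletion_away_from_tracts_is_legitimate(self):
        clone = _clone("ACGTACGTAC", ["ACGT-CGTAC", "ACGTACGTAC"])
        v = classify_sequence("m1", clone, config=IndelConfig(min_share=2, min_hpt_len=2))
        assert v.verdict == "with_legitimate_indels"

    def test_singleton_without_events(self):
        clone = _clone("ACGT", ["ACGT"])
        v = classify_sequence("m1", clone, config=IndelConfig())
        assert v.verdict == "without_indels"


class TestRunIdentifier:
    def test_identical_clones_all_clean(self, tmp_path):
        clones = [_clone("ACGTT", ["ACGTT"] * 3, f"c{i}") for i in range(3)]
        counts = run_indel_identifier(clones, outdir=str(tmp_path), name="demo")
        assert counts["without_indels"] == 9
        assert (tmp_path / "demo-WithoutIndels.txt").read_text().count(">") == 9
        assert (tmp_path / "demo-Ig-Indel-Identifier.log").exists()

    def test_partition_is_disjoint_and_exhaustive(self, tmp_path):
        clones = [
            _clone("CCAAACC", ["CCA-ACC", "CCAAACC", "CCAAACC"], "c1"),
            _clone("CCAAACC", ["CCA-ACC"], "c2"),
            _clone("ACGTACGTAC", ["ACGT-CGTAC", "ACGTACGTAC"], "c3"),
        ]
        counts = run_indel_identifier(clones, outdir=str(tmp_path), name="demo")
        total = sum(counts.values())
        assert total == 6
        files = ["demo-WithoutIndels.txt", "demo-CloneOfSize1WithIndels.txt",
                 "demo-IllegitimateIndels.txt", "demo-SeqsWithLowQualPointMuts.txt"]
        written = sum((tmp_path / f).read_text().count(">") for f in files)
        assert written == total
        assert counts["artifact_indel"] == 1
        assert counts["uncertain"] == 1
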