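"""The merging pipeline: validation, boundaries, splicing, artifacts."""

from datetime import datetime

import pytest

from sangermerge.align import global_align
from sangermerge.errors import (
    InputSetError,
    InsufficientOverlapError,
    ParameterError,
    SangermergeError,
)
from sangermerge.merge import (
    BoundaryPair,
    MergeParams,
    align_to_get_boundaries,
    check_and_convert,
    check_file_list_count,
    forwardize,
    merge_sanger,
    splice,
    write_run_artifacts,
)
from sangermerge.seqio import Direction, Read, Sequence


def make_reads(*pairs):
    return [
        Read(sequence=Sequence(seq), direction=Direction(d), order_index=i)
        for i, (seq, d) in enumerate(pairs)
    ]


class TestInputChecks:
    def test_two_reads_pass(self):
        check_file_list_count(make_reads(("ACGT", "F"), ("ACGT", "F")))

    @pytest.mark.parametrize("count", [0, 1])
    def test_fewer_than_two_rejected(self, count):
        reads = make_reads(*[("ACGT", "F")] * count)
        with pytest.raises(InputSetError, match="at least two"):
            check_file_list_count(reads)

    @pytest.mark.parametrize("raw,expected", [("50", 50), ("35", 35), (" 40 ", 40), (1000, 1000)])
    def test_check_and_convert_accepts(self, raw, expected):
        assert check_and_convert(raw) == expected

    @pytest.mark.parametrize("raw", ["abc", "0", "-5", "9", "1001", "3.5", "", True])
    def test_check_and_convert_rejects(self, raw):
        with pytest.raises(ParameterError):
            check_and_convert(raw)


class TestForwardize:
    def test_f_passes_through_r_flipped(self):
        out = forwardize(make_reads(("ACGT", "F"), ("ACGT", "R"), ("AACC", "R")))
        assert out == ["ACGT", "ACGT", "GGTT"]


class TestBoundaries:
    def test_toy_overlap_pair(self):
        # shared run of 10 C's: prev contributes everything, next from base 10
        prev, nxt = "A" * 10 + "C" * 10, "C" * 10 + "G" * 10
        params = MergeParams(consecutive_matches=10)
        boundary, aln = align_to_get_boundaries(prev, nxt, params)
        assert (boundary.prev_cut, boundary.next_cut) == (20, 10)
        assert splice([Sequence(prev), Sequence(nxt)], [boundary]) == "A" * 10 + "C" * 10 + "G" * 10

    def test_identical_sequences_full_run(self):
        s = "ACGTACGTACGTACG"
        boundary, _ = align_to_get_boundaries(s, s, MergeParams(consecutive_matches=len(s)))
        assert (boundary.prev_cut, boundary.next_cut) == (len(s), len(s))

    def test_insufficient_overlap_error_is_informative(self):
        with pytest.raises(InsufficientOverlapError) as exc:
            align_to_get_boundaries(
                "A" * 60, "T" * 60, MergeParams(consecutive_matches=50),
                pair_index=2, name_prev="r2", name_next="r3",
            )
        msg = str(exc.value)
        assert "r2" in msg and "r3" in msg and "50" in msg
        assert "longest run observed: 0" in msg
        assert "lower" in msg.lower()
        assert exc.value.pair_index == 2


class TestSplice:
    def run_boundary(self, pair_index, prev_cut, next_cut):
        return BoundaryPair(pair_index=pair_index, prev_cut=prev_cut, next_cut=next_cut, run=None)

    def test_two_fragment_concatenation(self):
        merged = splice(
            ["AAAAACCCCC", "CCCCCGGGGG"], [self.run_boundary(0, 10, 5)]
        )
        assert merged == "AAAAACCCCCGGGGG"

    def test_single_pair_identical_sequences(self):
        s = "ACGTACGTAC"
        assert splice([s, s], [self.run_boundary(0, len(s), len(s))]) == s

    def test_three_fragments_reconstruct_reference(self):
        ref = "AAAATTTTCCCCGGGGACGTTGCA"
        frags = [ref[0:12], ref[6:18], ref[12:24]]
        # runs found at the start of each 6-base overlap with n=4
        boundaries = [self.run_boundary(0, 10, 4), self.run_boundary(1, 10, 4)]
        assert splice(frags, boundaries) == ref

    def test_out_of_range_boundary_rejected(self):
        with pytest.raises(SangermergeError, match="out of range"):
            splice(["ACGT", "ACGT"], [self.run_boundary(0, 5, 0)])

    def test_inconsistent_middle_read_cuts_rejected(self):
        with pytest.raises(SangermergeError, match="walking order"):
            splice(
                ["ACGTACGT", "ACGTACGT", "ACGTACGT"],
                [self.run_boundary(0, 4, 6), self.run_boundary(1, 4, 2)],
            )

    def test_boundary_count_mismatch_rejected(self):
        with pytest.raises(SangermergeError, match="boundary count"):
            splice(["ACGT", "ACGT"], [])


class TestMergeSanger:
    def test_reconstructs_reference_from_fixture(self, four_read_set):
        result = merge_sanger(four_read_set.reads, MergeParams())
        assert str(result.merged) == str(four_read_set.spanned_reference)
        assert len(result.boundaries) == len(four_read_set.reads) - 1
        assert len(result.pair_reports) == len(four_read_set.reads) - 1

    def test_two_identical_forward_reads(self):
        s = "ACGT" * 20
        result = merge_sanger(make_reads((s, "F"), (s, "F")), MergeParams(consecutive_matches=50))
        assert result.merged == s

    def test_error_names_failing_pair(self, small_spec):
        rs = small_spec(seed=3)
        # make the final read unrelated to the chain
        bad = Read(sequence=Sequence("T" * 250), direction=Direction.F, order_index=2)
        reads = rs.reads[:2] + [bad]
        with pytest.raises(InsufficientOverlapError) as exc:
            merge_sanger(reads, MergeParams())
        assert exc.value.pair_index == 1

    def test_log_narrates_run(self, four_read_set):
        result = merge_sanger(four_read_set.reads, MergeParams())
        log = result.log_text
        assert "Consecutive Matches = 50" in log
        assert "pair 0" in log and "pair 2" in log
        assert f"merged sequence length: {len(result.merged)}" in log
        assert "reverse-complemented" in log

    def test_direction_required(self):
        reads = make_reads(("ACGT" * 20, "F"), ("ACGT" * 20, "F"))
        reads[1].direction = None
        with pytest.raises(InputSetError, match="direction"):
            merge_sanger(reads, MergeParams())


class TestRunArtifacts:
    def fixed_clock(self):
        return datetime(2024, 9, 12, 8, 26, 41)

    def test_folder_name_matches_timestamp(self, tmp_path, small_spec):
        rs = small_spec(seed=1)
        result = merge_sanger(rs.reads, MergeParams())
        out = write_run_artifacts(result, tmp_path, clock=self.fixed_clock)
        assert out.name == "merged_sequence20240912082641"

    def test_three_read_run_file_inventory(self, tmp_path, small_spec):
        rs = small_spec(seed=2)
        result = merge_sanger(rs.reads, MergeParams())
        out = write_run_artifacts(result, tmp_path, clock=self.fixed_clock)
        files = sorted(p.name for p in out.iterdir())
        assert sum(f == "log.txt" for f in files) == 1
        assert sum(f.endswith("_forwardized.seq") for f in files) == 3
        assert sum(f.endswith(".needle") for f in files) == 2
        assert sum(f == "merged_sequence.seq" for f in files) == 1
        merged_on_disk = (out / "merged_sequence.seq").read_text().strip()
        assert merged_on_disk == str(result.merged)

    def test_collision_gets_suffix(self, tmp_path, small_spec):
        rs = small_spec(seed=1)
        result = merge_sanger(rs.reads, MergeParams())
        first = write_run_artifacts(result, tmp_path, clock=self.fixed_clock)
        second = write_run_artifacts(result, tmp_path, clock=self.fixed_clock)
        assert second.name == first.name + "_1"
        assert first.exists() and second.exists()


class TestPipelineProperties:
    def test_composability_two_stage_equals_one_shot(self, four_read_set):
        reads = four_read_set.reads
        params = MergeParams()
        one_shot = merge_sanger(reads, params).merged

        first = merge_sanger(reads[:2], params).merged
        rest = [Read(sequence=first, direction=Direction.F, order_index=0)] + [
            Read(sequence=r.sequence, direction=r.direction, order_index=i + 1)
            for i, r in enumerate(reads[2:])
        ]
        staged = merge_sanger(rest, params).merged
        assert str(staged) == str(one_shot)

    def test_strand_invariance_single_flip(self, small_spec):
        rs = small_spec(seed=5)
        baseline = merge_sanger(rs.reads, MergeParams()).merged
        flipped = [
            Read(
                sequence=r.sequence,
                direction=r.direction,
                order_index=r.order_index,
            )
            for r in rs.reads
        ]
        from sangermerge.seqio import reverse_complement

        flipped[1] = Read(
            sequence=reverse_complement(flipped[1].sequence),
            direction=Direction.F if flipped[1].direction == Direction.R else Direction.R,
            order_index=1,
        )
        assert str(merge_sanger(flipped, MergeParams()).merged) == str(baseline)

    def test_end_errors_outside_run_do_not_corrupt_merge(self, small_spec):
        rs = small_spec(seed=8, end_error_rate=0.5, error_window=10)
        result = merge_sanger(rs.reads, MergeParams())
        # errors live in the last 10 bases of each forward-oriented read; check
        # that they fall outside every contributed segment before asserting
        excluded = all(
            pos >= result.boundaries[i].prev_cut
            for i in range(len(result.boundaries))
            for pos in rs.error_positions[i]
        )
        assert excluded, "run detection should sit well before the degraded tails"
        # the last read's tail is the merged tail, so its injected errors are
        # the only ones that can surface; everything upstream must be exact
        window = 10
        assert str(result.merged)[:-window] == str(rs.spanned_reference)[:-window]
        assert len(result.merged) == len(rs.spanned_reference)
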