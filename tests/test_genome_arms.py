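"""Arm caller: SEG parsing, arm construction, fraction arithmetic, calls."""

import numpy as np
import pandas as pd
import pytest

from karyoscreen import (
    ArmInterval,
    CallerConfig,
    altered_fraction,
    build_arm_table,
    call_arm,
    call_genome,
    calls_to_matrix,
    read_seg,
)
from karyoscreen.genome_arms import (
    GAIN,
    LOSS,
    NEUTRAL,
    SegFormatError,
    SegmentRecord,
)

from conftest import MB, make_segment


def brute_force_fraction(segments, arm, direction, cfg):
    """Per-base oracle: mark every altered base of the arm, count, divide.

    Intervals are closed-start/open-end; a base is altered when any
    qualifying segment covers it.
    """
    altered = np.zeros(arm.length, dtype=bool)
    t = cfg.seg_mean_threshold
    for seg in segments:
        if seg.chromosome != arm.chromosome:
            continue
        qualifies = seg.seg_mean <= -t if direction == LOSS else seg.seg_mean >= t
        if not qualifies:
            continue
        lo = max(seg.start, arm.start) - arm.start
        hi = min(seg.end, arm.end) - arm.start
        if lo < hi:
            altered[lo:hi] = True
    return altered.sum() / arm.length


# ---------------------------------------------------------------------------
# SEG input
# ---------------------------------------------------------------------------


def write_seg_text(path, rows, header="Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean"):
    path.write_text(header + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")


class TestReadSeg:
    def test_row_count_preserved(self, tmp_path):
        rows = [
            (s, "1", i * MB, (i + 1) * MB, 100, -0.5)
            for s in ("A", "B")
            for i in range(3)
        ]
        f = tmp_path / "toy.seg"
        write_seg_text(f, rows)
        assert len(read_seg(f)) == 6

    def test_chr_prefix_stripped(self, tmp_path):
        f = tmp_path / "toy.seg"
        write_seg_text(f, [("A", "chr17", 0, MB, 10, 0.1)])
        assert read_seg(f)[0].chromosome == "17"

    def test_missing_mean_column_is_format_error(self, tmp_path):
        f = tmp_path / "bad.seg"
        f.write_text("Sample\tChromosome\tStart\tEnd\nA\t1\t0\t100\n")
        with pytest.raises(SegFormatError, match="seg_mean"):
            read_seg(f)

    def test_non_numeric_rows_dropped(self, tmp_path):
        f = tmp_path / "toy.seg"
        write_seg_text(f, [("A", "1", 0, MB, 10, 0.1), ("A", "1", "x", MB, 10, 0.1)])
        assert len(read_seg(f)) == 1

    def test_header_only_file_warns_empty(self, tmp_path, caplog):
        f = tmp_path / "empty.seg"
        f.write_text("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        assert read_seg(f) == []


# ---------------------------------------------------------------------------
# Arm construction
# ---------------------------------------------------------------------------


class TestBuildArmTable:
    def annotation(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chromosome", "arm", "start", "end", "coding"])

    def test_min_max_over_coding_genes(self):
        ann = self.annotation([
            ("g1", "1", "p", 1 * MB, 2 * MB, True),
            ("g2", "1", "p", 40 * MB, 41 * MB, True),
        ])
        (arm,) = build_arm_table(ann)
        assert (arm.start, arm.end, arm.length) == (1 * MB, 41 * MB, 40 * MB)

    def test_noncoding_only_arm_omitted(self):
        ann = self.annotation([
            ("g1", "13", "p", MB, 2 * MB, False),
            ("g2", "13", "q", 20 * MB, 21 * MB, True),
        ])
        arms = build_arm_table(ann)
        assert [a.arm_id for a in arms] == ["13q"]

    def test_ordering_per_chromosome_p_before_q(self):
        ann = self.annotation([
            ("a", "2", "q", 50 * MB, 51 * MB, True),
            ("b", "1", "q", 60 * MB, 61 * MB, True),
            ("c", "2", "p", MB, 2 * MB, True),
            ("d", "1", "p", MB, 2 * MB, True),
        ])
        assert [a.arm_id for a in build_arm_table(ann)] == ["1p", "1q", "2p", "2q"]

    def test_noncoding_genes_do_not_widen_arm(self):
        ann = self.annotation([
            ("g1", "1", "p", 5 * MB, 6 * MB, True),
            ("nc", "1", "p", 1 * MB, 2 * MB, False),
        ])
        (arm,) = build_arm_table(ann)
        assert arm.start == 5 * MB


# ---------------------------------------------------------------------------
# altered_fraction
# ---------------------------------------------------------------------------


class TestAlteredFraction:
    def test_simple_length_ratio(self, arm_100mb, caller_cfg):
        segs = [make_segment(end=70 * MB, mean=-0.8)]
        assert altered_fraction(segs, arm_100mb, LOSS, caller_cfg) == pytest.approx(0.70)

    def test_below_threshold_contributes_nothing(self, arm_100mb, caller_cfg):
        segs = [make_segment(end=70 * MB, mean=-0.2)]
        assert altered_fraction(segs, arm_100mb, LOSS, caller_cfg) == 0.0

    def test_disjoint_segments_sum(self, arm_100mb, caller_cfg):
        segs = [
            make_segment(end=60 * MB, mean=-0.8),
            make_segment(start=90 * MB, end=100 * MB, mean=-0.5),
        ]
        expected = brute_force_fraction(segs, arm_100mb, LOSS, caller_cfg)
        got = altered_fraction(segs, arm_100mb, LOSS, caller_cfg)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.70)

    def test_overlapping_segments_unioned(self, arm_100mb, caller_cfg):
        segs = [
            make_segment(end=50 * MB, mean=-0.8),
            make_segment(start=30 * MB, end=60 * MB, mean=-0.4),
        ]
        assert altered_fraction(segs, arm_100mb, LOSS, caller_cfg) == pytest.approx(0.60)

    def test_threshold_boundary_inclusive(self, arm_100mb, caller_cfg):
        segs = [make_segment(end=100 * MB, mean=-0.3)]
        assert altered_fraction(segs, arm_100mb, LOSS, caller_cfg) == pytest.approx(1.0)

    def test_no_segments_gives_zero(self, arm_100mb, caller_cfg):
        assert altered_fraction([], arm_100mb, LOSS, caller_cfg) == 0.0

    def test_matches_base_by_base_oracle_on_random_fixtures(self, rng, caller_cfg):
        """Randomized small arms: interval-union equals the per-base count."""
        for _ in range(25):
            length = int(rng.integers(10_000, 200_000))
            start = int(rng.integers(0, 50_000))
            arm = ArmInterval("5", "q", start, start + length)
            segs = []
            for _ in range(int(rng.integers(1, 15))):
                lo = int(rng.integers(0, start + length + 10_000))
                hi = lo + int(rng.integers(1, 80_000))
                segs.append(make_segment(chrom="5", start=lo, end=hi,
                                         mean=float(rng.normal(0, 0.6))))
            for direction in (LOSS, GAIN):
                expected = brute_force_fraction(segs, arm, direction, caller_cfg)
                got = altered_fraction(segs, arm, direction, caller_cfg)
                assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_seg_mean_threshold(self, arm_100mb, rng):
        """Raising the qualifying threshold never increases a fraction."""
        segs = [
            make_segment(start=i * 10 * MB, end=(i + 1) * 10 * MB,
                         mean=float(rng.normal(0, 0.5)))
            for i in range(10)
        ]
        thresholds = [0.1, 0.2, 0.3, 0.5, 0.8]
        for direction in (LOSS, GAIN):
            fracs = [
                altered_fraction(segs, arm_100mb, direction, CallerConfig(seg_mean_threshold=t))
                for t in thresholds
            ]
            assert all(a >= b for a, b in zip(fracs, fracs[1:]))


# ---------------------------------------------------------------------------
# call_arm / call_genome
# ---------------------------------------------------------------------------


class TestCallArm:
    @pytest.mark.parametrize(
        "covered_mb, mean, expected",
        [(70, -0.8, LOSS), (50, -0.8, NEUTRAL), (67, -0.8, LOSS), (70, 0.8, GAIN)],
    )
    def test_fraction_rule(self, arm_100mb, caller_cfg, covered_mb, mean, expected):
        segs = [make_segment(end=covered_mb * MB, mean=mean)]
        assert call_arm(segs, arm_100mb, caller_cfg).status == expected

    def test_fractions_reported(self, arm_100mb, caller_cfg):
        segs = [
            make_segment(end=70 * MB, mean=-0.8),
            make_segment(start=80 * MB, end=90 * MB, mean=0.5),
        ]
        call = call_arm(segs, arm_100mb, caller_cfg)
        assert call.fraction_loss == pytest.approx(0.70)
        assert call.fraction_gain == pytest.approx(0.10)

    def test_mixed_sample_segments_rejected(self, arm_100mb):
        segs = [make_segment(sample="A"), make_segment(sample="B")]
        with pytest.raises(ValueError, match="multiple samples"):
            call_arm(segs, arm_100mb)


class TestCallGenome:
    def arms(self):
        return [
            ArmInterval("1", "p", 0, 100 * MB),
            ArmInterval("1", "q", 110 * MB, 200 * MB),
            ArmInterval("2", "q", 10 * MB, 90 * MB),
        ]

    def test_cardinality(self):
        segs = [make_segment(sample=s) for s in ("A", "B", "C")]
        assert len(call_genome(segs, self.arms())) == 9

    def test_sample_without_segments_on_arm_is_neutral(self):
        segs = [make_segment(sample="A", chrom="1", end=100 * MB, mean=-1.0)]
        calls = {c.arm_id: c.status for c in call_genome(segs, self.arms())}
        assert calls == {"1p": LOSS, "1q": NEUTRAL, "2q": NEUTRAL}

    def test_whole_genome_deletion_calls_all_arms(self):
        segs = [
            make_segment(sample="A", chrom=a.chromosome, start=a.start, end=a.end, mean=-1.0)
            for a in self.arms()
        ]
        assert all(c.status == LOSS for c in call_genome(segs, self.arms()))

    def test_sex_chromosomes_excluded_by_default(self):
        arms = self.arms() + [ArmInterval("X", "q", 0, 50 * MB)]
        segs = [make_segment(sample="A", chrom="X", end=50 * MB, mean=-1.0)]
        calls = call_genome(segs, arms)
        assert all(not c.arm_id.startswith("X") for c in calls)
        calls_with_sex = call_genome(
            segs, arms, CallerConfig(autosomes_only=False)
        )
        assert any(c.arm_id == "Xq" and c.status == LOSS for c in calls_with_sex)

    def test_negating_means_swaps_loss_and_gain(self, rng):
        """Symmetry: seg_mean -> -seg_mean exchanges the two call classes."""
        arms = self.arms()
        segs = []
        for s in ("A", "B"):
            for a in arms:
                mid = (a.start + a.end) // 2
                segs.append(make_segment(sample=s, chrom=a.chromosome,
                                         start=a.start, end=mid,
                                         mean=float(rng.normal(0, 0.7))))
                segs.append(make_segment(sample=s, chrom=a.chromosome,
                                         start=mid, end=a.end,
                                         mean=float(rng.normal(0, 0.7))))
        flipped = [
            SegmentRecord(s.sample_id, s.chromosome, s.start, s.end, -s.seg_mean)
            for s in segs
        ]
        swap = {LOSS: GAIN, GAIN: LOSS, NEUTRAL: NEUTRAL}
        for c1, c2 in zip(call_genome(segs, arms), call_genome(flipped, arms)):
            assert c2.status == swap[c1.status]
            assert c2.fraction_loss == pytest.approx(c1.fraction_gain)

    def test_matrix_pivot_codes(self):
        segs = [make_segment(sample="A", chrom="1", end=100 * MB, mean=-1.0)]
        mat = calls_to_matrix(call_genome(segs, self.arms()))
        assert mat.loc["A", "1p"] == -1
        assert mat.loc["A", "1q"] == 0
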