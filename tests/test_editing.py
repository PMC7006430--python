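"""Editing index, FPKM conversion, residual identity, expression filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsrnacensus import (
    DuplexStructure,
    EditingProfile,
    LibraryStats,
    arm_coverage_and_index,
    coverage_to_fpkm,
    expression_filter,
    fpkm_to_coverage,
    read_pileup,
    residual_identity,
    simulate_pileup,
    summarize_structure,
)
from dsrnacensus.editing import write_pileup


def _profile(records, contig="g"):
    pos, a, g = zip(*records)
    return EditingProfile(contig, np.array(pos), np.array(a), np.array(g))


def _structure(arm1=(0, 300), arm2=(400, 700), identity=98.0, seq_id="g"):
    return DuplexStructure(
        seq_id=seq_id,
        arm1=arm1,
        arm2=arm2,
        identity_pct=identity,
        aln_length=arm1[1] - arm1[0],
        orientation="inverted",
        gap_bp=max(0, arm2[0] - arm1[1]),
    )


class TestArmCoverageAndIndex:
    def test_direct_ratio_example(self):
        prof = _profile([(10, 8, 2), (20, 9, 1)])
        mean_cov, index, n = arm_coverage_and_index(prof, (0, 100))
        assert (mean_cov, index, n) == (10.0, 0.15, 2)

    def test_unedited_arm_index_zero(self):
        prof = _profile([(10, 8, 0), (20, 12, 0)])
        assert arm_coverage_and_index(prof, (0, 100))[1] == 0.0

    def test_no_adenosines_is_not_applicable(self):
        prof = _profile([(10, 8, 2)])
        mean_cov, index, n = arm_coverage_and_index(prof, (50, 100))
        assert n == 0 and math.isnan(mean_cov) and math.isnan(index)

    def test_zero_coverage_sites_dilute_mean_but_not_index(self):
        prof = _profile([(10, 8, 2), (20, 0, 0)])
        mean_cov, index, n = arm_coverage_and_index(prof, (0, 100))
        assert mean_cov == 5.0  # zero-coverage adenosine averaged in as zero
        assert index == 0.2  # but absent from the index's denominator
        assert n == 2

    def test_unexpressed_arm_index_undefined(self):
        prof = _profile([(10, 0, 0), (20, 0, 0)])
        mean_cov, index, n = arm_coverage_and_index(prof, (0, 100))
        assert mean_cov == 0.0 and math.isnan(index)

    def test_simulated_rate_recovery(self, rng):
        prof = simulate_pileup((0, 1000), "A" * 1000, 50.0, 0.1, rng)
        _, index, _ = arm_coverage_and_index(prof, (0, 1000))
        sd = math.sqrt(0.1 * 0.9 / prof.coverage.sum())
        assert abs(index - 0.1) < 3 * sd

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 10)), min_size=1, max_size=30))
    def test_index_is_coverage_weighted_mean_of_levels(self, counts):
        records = [(i * 3, a, g) for i, (a, g) in enumerate(counts)]
        prof = _profile(records)
        _, index, _ = arm_coverage_and_index(prof, (0, 1000))
        cov = prof.coverage
        if cov.sum() == 0:
            assert math.isnan(index)
        else:
            levels = np.where(cov > 0, prof.g_counts / np.maximum(cov, 1), 0.0)
            weighted = float((levels * cov).sum() / cov.sum())
            assert index == pytest.approx(weighted, rel=1e-12)


class TestFpkmConversion:
    def test_reference_pool_constants(self):
        lib = LibraryStats(total_mapped_reads=1_343_000_000, read_length=76, trim_bp=5)
        assert lib.effective_length == 66
        assert fpkm_to_coverage(1.0, lib) == pytest.approx(88.64, abs=0.005)
        assert coverage_to_fpkm(88.638, lib) == pytest.approx(1.0, rel=1e-9)

    def test_zero_fpkm(self):
        lib = LibraryStats(10**9, 76)
        assert fpkm_to_coverage(0.0, lib) == 0.0

    def test_round_number_instance(self):
        lib = LibraryStats(total_mapped_reads=10**9, read_length=60, trim_bp=5)
        assert fpkm_to_coverage(2.0, lib) == pytest.approx(100.0, rel=1e-12)

    def test_round_trip_identity(self):
        lib = LibraryStats(1_343_000_000, 76)
        for cov in (0.0017, 1.0, 88.64, 5123.4):
            assert fpkm_to_coverage(coverage_to_fpkm(cov, lib), lib) == pytest.approx(
                cov, rel=1e-10
            )

    def test_nonpositive_effective_length_rejected(self):
        with pytest.raises(ValueError, match="effective"):
            LibraryStats(total_mapped_reads=10**9, read_length=10, trim_bp=5)


class TestResidualIdentity:
    def test_direct_formula(self):
        s = _structure(identity=98.0)
        assert residual_identity(s, 6.0) == pytest.approx(96.0)

    def test_no_editing_preserves_identity(self):
        s = _structure(identity=97.3)
        assert residual_identity(s, 0.0) == 97.3

    def test_unwinding_below_threshold(self):
        s = _structure(identity=97.5)
        resid = residual_identity(s, 9.0)
        assert resid == pytest.approx(94.5)
        assert resid < 96.0

    def test_floor_at_zero(self):
        s = _structure(identity=97.0, arm1=(0, 50), arm2=(100, 150))
        assert residual_identity(s, 50.0) == 0.0

    def test_monotone_in_editing(self):
        s = _structure(identity=98.0)
        values = [residual_identity(s, x) for x in np.linspace(0, 20, 15)]
        assert all(b <= a for a, b in zip(values, values[1:]))


class TestSummaries:
    def test_summary_combines_arms(self, rng):
        seq = "A" * 700
        lib = LibraryStats(10**9, 60, 5)  # 1 FPKM = 50 coverage
        s = _structure(identity=98.0)
        prof_parts = [
            simulate_pileup(s.arm1, seq, 50.0, 0.02, rng),
            simulate_pileup(s.arm2, seq, 50.0, 0.02, rng),
        ]
        prof = EditingProfile(
            "g",
            np.concatenate([p.positions for p in prof_parts]),
            np.concatenate([p.a_counts for p in prof_parts]),
            np.concatenate([p.g_counts for p in prof_parts]),
        )
        summary = summarize_structure(s, prof, lib)
        assert summary.arm1.n_adenosines == 300
        assert summary.arm1.fpkm == pytest.approx(summary.arm1.mean_coverage / 50.0)
        expected_ino = 0.02 * 300
        assert summary.avg_inosines == pytest.approx(expected_ino, rel=0.3)
        assert summary.residual_identity_pct <= s.identity_pct

    def test_pooled_mode_close_to_per_arm_for_balanced_arms(self, rng):
        seq = "A" * 700
        lib = LibraryStats(10**9, 60, 5)
        s = _structure()
        prof = simulate_pileup((0, 700), seq, 40.0, 0.05, rng)
        per_arm = summarize_structure(s, prof, lib, inosine_mode="per_arm")
        pooled = summarize_structure(s, prof, lib, inosine_mode="pooled")
        assert pooled.avg_inosines == pytest.approx(per_arm.avg_inosines, rel=0.05)

    def test_unexpressed_structure_keeps_identity(self, rng):
        seq = "A" * 700
        lib = LibraryStats(10**9, 60, 5)
        s = _structure(identity=97.0)
        prof = simulate_pileup((0, 700), seq, 0.0, 0.5, rng)
        summary = summarize_structure(s, prof, lib)
        assert math.isnan(summary.avg_inosines)
        assert summary.residual_identity_pct == 97.0


class TestExpressionFilter:
    @staticmethod
    def _summary_with_fpkms(f1, f2, lib, rng, seq_id="g"):
        seq = "A" * 700
        s = _structure(seq_id=seq_id)
        cov1, cov2 = fpkm_to_coverage(f1, lib), fpkm_to_coverage(f2, lib)
        parts = [
            simulate_pileup(s.arm1, seq, cov1, 0.0, rng),
            simulate_pileup(s.arm2, seq, cov2, 0.0, rng),
        ]
        prof = EditingProfile(
            seq_id,
            np.concatenate([p.positions for p in parts]),
            np.concatenate([p.a_counts for p in parts]),
            np.concatenate([p.g_counts for p in parts]),
        )
        return summarize_structure(s, prof, lib)

    def test_both_arms_rule(self, rng):
        lib = LibraryStats(10**9, 60, 5)
        fails = self._summary_with_fpkms(0.4, 0.1e-3, lib, rng)
        passes = self._summary_with_fpkms(3.0, 2.4, lib, rng, seq_id="h")
        kept = expression_filter([fails, passes], 0.01)
        assert [s.structure.seq_id for s in kept] == ["h"]

    def test_cutoff_strictness_on_exact_fpkms(self):
        # bypass sampling: construct summaries with exact arm FPKMs
        from dsrnacensus.editing import ArmSummary, StructureEditingSummary

        def mk(f1, f2, sid):
            arm = lambda f: ArmSummary((0, 10), 1.0, f, 0.0, 5)
            return StructureEditingSummary(_structure(seq_id=sid), arm(f1), arm(f2), 0.0, 98.0)

        summaries = [mk(0.02, 0.005, "a"), mk(0.15, 0.12, "b"), mk(0.01, 0.02, "c")]
        assert [s.structure.seq_id for s in expression_filter(summaries, 0.01)] == ["b"]
        assert [s.structure.seq_id for s in expression_filter(summaries, 0.1)] == ["b"]


class TestPileupIO:
    def test_round_trip(self, tmp_path, rng):
        prof = simulate_pileup((0, 300), "A" * 300, 20.0, 0.1, rng, contig="gX")
        path = tmp_path / "p.tsv"
        write_pileup([prof], path)
        back = read_pileup(path)
        assert set(back) == {"gX"}
        assert np.array_equal(back["gX"].positions, prof.positions)
        assert np.array_equal(back["gX"].a_counts, prof.a_counts)
        assert np.array_equal(back["gX"].g_counts, prof.g_counts)
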