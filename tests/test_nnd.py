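"""Cross-channel NND computation, histograms, mode estimation, paired tests."""

import numpy as np
import pytest

from conftest import brute_force_nnd
from nucoloc import (
    CsrSpec,
    NndResult,
    Roi,
    compare_real_vs_random,
    cross_nnd,
    csr_nnd_mode,
    make_table,
    mode_nnd,
    nnd_histogram,
    simulate_csr,
)
from nucoloc.errors import PairingError, ParameterError


def as_result(distances, acq="0"):
    return NndResult(distances_nm=np.asarray(distances, float), acquisition_id=acq)


class TestCrossNnd:
    def test_three_four_five(self):
        a = make_table([0.0], [0.0], roi_bounds=Roi(0, 0, 10, 10))
        b = make_table([3.0], [4.0], roi_bounds=Roi(0, 0, 10, 10))
        np.testing.assert_allclose(cross_nnd(a, b).distances_nm, [5.0])

    def test_identical_channels_give_zero(self, small_table):
        d = cross_nnd(small_table, small_table).distances_nm
        np.testing.assert_allclose(d, 0.0)

    def test_uniform_shift_bounded_by_shift(self, rng):
        roi = Roi(0, 0, 5000, 5000)
        x, y = rng.uniform(0, 5000, 100), rng.uniform(0, 5000, 100)
        a = make_table(x, y, roi_bounds=roi)
        b = make_table(x + 7.0 * np.cos(0.3), y + 7.0 * np.sin(0.3), roi_bounds=Roi(0, 0, 5010, 5010))
        d = cross_nnd(a, b).distances_nm
        assert (d <= 7.0 + 1e-9).all()
        assert mode_nnd([cross_nnd(a, b)], fine_step_nm=1.0) == pytest.approx(7.0, abs=1.0)

    def test_asymmetry(self):
        a = make_table([0.0, 100.0], [0.0, 0.0], roi_bounds=Roi(0, 0, 100, 100))
        b = make_table([0.0], [0.0], roi_bounds=Roi(0, 0, 100, 100))
        assert len(cross_nnd(a, b)) == 2
        assert len(cross_nnd(b, a)) == 1

    def test_empty_target_is_error(self, small_table):
        empty = make_table([], [], roi_bounds=small_table.roi_bounds)
        with pytest.raises(ValueError, match="target"):
            cross_nnd(small_table, empty)

    def test_equals_brute_force_exactly(self, rng):
        """KD-tree result must equal the exhaustive all-pairs search."""
        for _ in range(20):
            n_s = int(rng.integers(1, 501))
            n_t = int(rng.integers(1, 501))
            roi = Roi(0, 0, 1000, 1000)
            a = make_table(rng.uniform(0, 1000, n_s), rng.uniform(0, 1000, n_s), roi_bounds=roi)
            b = make_table(rng.uniform(0, 1000, n_t), rng.uniform(0, 1000, n_t), roi_bounds=roi)
            np.testing.assert_array_equal(
                cross_nnd(a, b).distances_nm, brute_force_nnd(a.xy, b.xy)
            )

    def test_rigid_motion_invariance(self, rng):
        roi = Roi(-5000, -5000, 5000, 5000)
        xa, ya = rng.uniform(0, 1000, 50), rng.uniform(0, 1000, 50)
        xb, yb = rng.uniform(0, 1000, 60), rng.uniform(0, 1000, 60)
        theta, tx, ty = 0.7, 123.0, -45.0
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pa = np.column_stack([xa, ya]) @ rot.T + [tx, ty]
        pb = np.column_stack([xb, yb]) @ rot.T + [tx, ty]
        d0 = cross_nnd(
            make_table(xa, ya, roi_bounds=roi), make_table(xb, yb, roi_bounds=roi)
        ).distances_nm
        d1 = cross_nnd(
            make_table(pa[:, 0], pa[:, 1], roi_bounds=roi),
            make_table(pb[:, 0], pb[:, 1], roi_bounds=roi),
        ).distances_nm
        np.testing.assert_allclose(d0, d1, rtol=1e-9)


class TestNndHistogram:
    def test_default_edges_are_50nm_steps_to_500(self):
        dist = nnd_histogram([as_result([10.0])])
        np.testing.assert_allclose(dist.bin_edges_nm, np.arange(0, 501, 50))

    def test_hand_counted_fractions_and_overflow(self):
        dist = nnd_histogram([as_result([10.0, 20.0, 60.0, 600.0])])
        assert dist.normalized_counts[0] == pytest.approx(0.5)
        assert dist.normalized_counts[1] == pytest.approx(0.25)
        assert dist.overflow == pytest.approx(0.25)

    def test_counts_plus_overflow_sum_to_one_per_acquisition(self, rng):
        results = [as_result(rng.exponential(150, 300), acq=str(i)) for i in range(4)]
        dist = nnd_histogram(results)
        sums = dist.per_acquisition.sum(axis=1)
        overflow = np.array(
            [np.mean(r.distances_nm >= dist.bin_edges_nm[-1]) for r in results]
        )
        np.testing.assert_allclose(sums + overflow, 1.0)

    def test_identical_acquisitions_have_zero_sem(self):
        r = as_result([10.0, 60.0, 120.0])
        dist = nnd_histogram([r, as_result(r.distances_nm.copy(), acq="1")])
        np.testing.assert_allclose(dist.sem, 0.0)
        np.testing.assert_allclose(dist.overflow_sem, 0.0)

    def test_bad_parameters_raise(self):
        with pytest.raises(ParameterError):
            nnd_histogram([as_result([1.0])], step_nm=0.0)
        with pytest.raises(ParameterError):
            nnd_histogram([as_result([1.0])], n_bins=0)
        with pytest.raises(ParameterError):
            nnd_histogram([])


class TestModeNnd:
    def test_point_mass_lands_in_containing_bin(self):
        # all distances exactly 5, step 2 -> bin [4, 6), center 5
        assert mode_nnd([as_result([5.0] * 10)], fine_step_nm=2.0) == pytest.approx(5.0)

    def test_tie_breaks_toward_smaller_distance(self):
        assert mode_nnd([as_result([1.0, 1.0, 9.0, 9.0])], fine_step_nm=2.0) == 1.0

    def test_csr_mode_matches_analytic_law(self):
        lam = 1e-3
        roi = Roi(0, 0, 3162.2777, 3162.2777)
        src = simulate_csr(CsrSpec(roi, n_points=10_000, seed=21))
        tgt = simulate_csr(CsrSpec(roi, n_points=10_000, seed=22))
        m = mode_nnd([cross_nnd(src, tgt)], fine_step_nm=5.0)
        assert m == pytest.approx(csr_nnd_mode(lam), abs=5.0)  # within one fine bin

    def test_mode_monotone_in_planted_distance(self, rng):
        roi = Roi(0, 0, 50_000, 50_000)
        modes = []
        for d in (50.0, 100.0, 200.0):
            x, y = rng.uniform(500, 49_500, 2000), rng.uniform(500, 49_500, 2000)
            theta = rng.uniform(0, 2 * np.pi, 2000)
            a = make_table(x, y, roi_bounds=roi)
            b = make_table(x + d * np.cos(theta), y + d * np.sin(theta), roi_bounds=roi)
            modes.append(mode_nnd([cross_nnd(a, b)], fine_step_nm=2.0))
        assert modes == sorted(modes)


class TestCompareRealVsRandom:
    def test_identical_lists_give_t0_p_half(self):
        rep = compare_real_vs_random([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert rep.statistic == 0.0
        assert rep.p_value == 0.5
        assert rep.significance == "ns"

    def test_strong_uniform_shift_is_highly_significant(self, rng):
        # real 30 nm below random with sd 1: closed-form t = -30*sqrt(10)
        random = 100.0 + rng.normal(0, 1.0, 10)
        real = random - 30.0 + rng.normal(0, 1.0, 10)
        rep = compare_real_vs_random(real, random, tail="one_sided_less")
        assert rep.p_value < 0.005
        assert rep.significance == "***"

    def test_two_sided_tail(self):
        rep = compare_real_vs_random([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0], tail="two_sided")
        assert 0 < rep.p_value <= 1

    def test_length_mismatch_raises(self):
        with pytest.raises(PairingError):
            compare_real_vs_random([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_too_few_pairs_raises(self):
        with pytest.raises(PairingError):
            compare_real_vs_random([1.0, 2.0], [2.0, 3.0])

    def test_type_i_error_rate_near_alpha(self):
        """CSR-vs-CSR paired summaries: ~5% of runs significant at alpha=0.05."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            real = rng.normal(50, 3, 10)
            random = rng.normal(50, 3, 10)
            hits += compare_real_vs_random(real, random).p_value < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.05)
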