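"""Age assignment, volumes, FCPlus, binning, normalization, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from septime import (
    CellRecord,
    assign_ages,
    average_replicates,
    bin_by_age,
    cell_volume,
    concentration_per_volume,
    fcplus,
    midcell_density_per_circumference,
    minmax_normalize,
    molecules_at_midcell,
)
from septime.errors import (
    DegenerateCurveError,
    GeometryError,
    InsufficientDataError,
    ShortCellError,
)
from septime.stats import BinnedCurve, _window_weights


class TestAssignAges:
    def test_two_cell_endpoints(self):
        ages = [a.age for a in assign_ages(np.array([2.0, 3.0]))]
        assert ages == [0.0, 1.0]

    def test_three_cell_middle_age(self):
        # ln(1 - 0.5 * 1/2) / ln 0.5 = ln 0.75 / ln 0.5
        ages = [a.age for a in assign_ages(np.array([2.0, 2.5, 3.0]))]
        assert ages[1] == pytest.approx(0.41504, abs=1e-5)
        assert ages == sorted(ages)

    def test_output_order_matches_input_order(self):
        assignments = assign_ages(np.array([3.0, 2.0]), ["long", "short"])
        assert assignments[0].cell_id == "long" and assignments[0].age == 1.0
        assert assignments[1].cell_id == "short" and assignments[1].age == 0.0

    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, perm):
        lengths = np.array([2.0, 2.1, 2.3, 2.6, 3.0, 3.3, 3.7, 3.9])
        base = {(a_.age) for a_ in assign_ages(lengths)}
        permuted = lengths[np.array(perm)]
        pairs = {(a_.age) for a_ in assign_ages(permuted)}
        assert pairs == base

    def test_ties_keep_distinct_ranks(self):
        assignments = assign_ages(np.array([2.0, 2.0, 3.0]))
        ranks = sorted(a.rank for a in assignments)
        assert ranks == [0, 1, 2]
        # stable: first input tied cell gets the lower rank
        assert assignments[0].rank < assignments[1].rank

    def test_requires_two_cells(self):
        with pytest.raises(InsufficientDataError):
            assign_ages(np.array([2.0]))


class TestCellVolume:
    def test_sphere_limit(self):
        assert cell_volume(1.0, 1.0) == pytest.approx(4 / 3 * math.pi * 0.125, abs=1e-6)

    def test_spherocylinder_hand_value(self):
        assert cell_volume(3.0, 1.0) == pytest.approx(2.0944, abs=1e-4)

    def test_monotone_in_length(self):
        vols = [cell_volume(L, 1.0) for L in np.linspace(1.0, 5.0, 50)]
        assert np.all(np.diff(vols) > 0)

    def test_oblate_rejected(self):
        with pytest.raises(GeometryError):
            cell_volume(0.8, 1.0)

    def test_cylinder_variant(self):
        assert cell_volume(3.0, 1.0, geometry="cylinder") == pytest.approx(
            math.pi * 0.25 * 3.0
        )


def _cell_with_split(F_mid, F_rest, length=3.0, diameter=1.0, pitch=10.0):
    """Cell whose profile puts exactly F_mid in the 0.8 μm window.

    At pitch 10 the window is 8 px wide and lands on whole pixels, so the
    split is exact.
    """
    n = round(length * pitch)
    center = (n - 1) / 2
    w = _window_weights(n, center, 0.8 * pitch / 2)
    inside = w == 1.0
    profile = np.zeros(n)
    profile[inside] = F_mid / inside.sum()
    outside = w == 0.0
    profile[outside] = F_rest / outside.sum()
    assert np.all((w == 0) | (w == 1))  # window aligned to pixel edges
    return CellRecord("c", length, diameter, profile)


class TestFCPlus:
    def test_hand_worked_case(self):
        """L=3, d=1, F_mid=60, F_rest=40 → FCPlus 42.86."""
        res = fcplus(_cell_with_split(60.0, 40.0), pixel_pitch=10.0)
        assert res.V_mid == pytest.approx(0.6283, abs=1e-4)
        assert res.V_rest == pytest.approx(1.4661, abs=1e-4)
        assert res.C_mid == pytest.approx(95.49, abs=0.01)
        assert res.C_rest == pytest.approx(27.28, abs=0.01)
        assert res.fcplus == pytest.approx(42.86, abs=0.005)

    def test_zero_for_volume_uniform_profile(self):
        """Axial density proportional to local cross-section ⇒ equal
        concentrations on both sides ⇒ FCPlus 0."""
        length, diameter, pitch = 4.0, 1.0, 20.0
        r = diameter / 2
        n = round(length * pitch)

        def slab_volume(i):
            # integrate the cross-section over pixel [i-0.5, i+0.5] (μm grid)
            x = np.linspace((i - 0.5) / pitch, (i + 0.5) / pitch, 41)
            area = np.where(
                x < r,
                math.pi * np.maximum(r**2 - (r - x) ** 2, 0.0),
                np.where(
                    x > length - r,
                    math.pi * np.maximum(r**2 - (x - (length - r)) ** 2, 0.0),
                    math.pi * r**2,
                ),
            )
            return np.trapezoid(area, x)

        profile = np.array([slab_volume(i) for i in range(n)]) * 7.5
        cell = CellRecord("u", length, diameter, profile)
        res = fcplus(cell, pixel_pitch=pitch)
        assert abs(res.fcplus) < 1e-3 * res.total_F

    def test_all_signal_inside_window_returns_total(self):
        res = fcplus(_cell_with_split(100.0, 0.0), pixel_pitch=10.0)
        assert res.fcplus == pytest.approx(100.0, rel=1e-9)

    def test_short_cell_excluded(self):
        cell = CellRecord("s", 1.5, 1.0, np.ones(15))
        with pytest.raises(ShortCellError):
            fcplus(cell, pixel_pitch=10.0)

    def test_fractional_edge_pixels_weighted(self):
        # at 15.28 px/μm the window spans 12.224 px: weights must sum to it
        w = _window_weights(46, 22.5, 0.8 * 15.28 / 2)
        assert w.sum() == pytest.approx(12.224, abs=1e-9)
        assert np.all((w >= 0) & (w <= 1))


class TestBinByAge:
    def test_constant_values(self):
        ages = np.linspace(0, 1, 200)
        curve = bin_by_age(np.full(200, 3.5), ages)
        occ = curve.occupied
        np.testing.assert_allclose(curve.means[occ], 3.5)
        np.testing.assert_allclose(curve.ci_halfwidths[occ], 0.0, atol=1e-9)

    def test_single_cell_lands_in_its_bin(self):
        curve = bin_by_age(np.array([7.0]), np.array([0.12]))
        assert curve.counts[2] == 1 and curve.counts.sum() == 1
        assert curve.means[2] == 7.0
        assert curve.ci_halfwidths[2] == 0.0
        assert np.isnan(curve.means[0])  # empty bins are missing, not zero

    def test_age_one_in_last_closed_bin(self):
        curve = bin_by_age(np.array([1.0, 2.0]), np.array([1.0, 0.99]))
        assert curve.counts[19] == 2

    def test_t_quantile_ci(self):
        """CI half-width of one n=100 bin matches 1.984 s/√100."""
        rng = np.random.default_rng(17)
        vals = rng.normal(10.0, 2.0, 100)
        ages = np.full(100, 0.52)
        curve = bin_by_age(vals, ages)
        expected = 1.984 * vals.std(ddof=1) / 10.0
        assert curve.ci_halfwidths[10] == pytest.approx(expected, rel=0.05)

    def test_conserves_cells(self, noisy_population):
        pop, truth = noisy_population
        curve = bin_by_age(truth.true_midcell_fraction.to_numpy(),
                           truth.true_age.to_numpy())
        assert curve.counts.sum() == len(pop)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            bin_by_age(np.ones(3), np.ones(4) * 0.5)


class TestMinmaxNormalize:
    def _curve(self, means):
        means = np.asarray(means, dtype=float)
        return BinnedCurve(
            bin_centers=(np.arange(len(means)) + 0.5) / len(means),
            means=means,
            ci_halfwidths=np.full(len(means), 0.5),
            counts=np.full(len(means), 10),
        )

    def test_maps_to_unit_interval(self):
        out = minmax_normalize(self._curve([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(out.means, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(out.ci_halfwidths, 0.05)
        assert out.value_kind == "normalized"

    def test_idempotent(self):
        once = minmax_normalize(self._curve([2.0, 4.0, 8.0]))
        twice = minmax_normalize(once)
        np.testing.assert_allclose(twice.means, once.means)

    @given(st.floats(0.1, 100.0), st.floats(-50.0, 50.0))
    @settings(max_examples=30)
    def test_commutes_with_positive_affine_maps(self, scale, offset):
        base = np.array([1.0, 3.0, 2.0, 7.0])
        out1 = minmax_normalize(self._curve(base))
        out2 = minmax_normalize(self._curve(scale * base + offset))
        np.testing.assert_allclose(out2.means, out1.means, atol=1e-9)

    def test_constant_curve_rejected(self):
        with pytest.raises(DegenerateCurveError):
            minmax_normalize(self._curve([3.0, 3.0, 3.0]))


class TestAverageReplicates:
    def _curve(self, means, counts=None):
        means = np.asarray(means, dtype=float)
        counts = np.full(len(means), 5) if counts is None else np.asarray(counts)
        return BinnedCurve(
            bin_centers=(np.arange(len(means)) + 0.5) / len(means),
            means=means,
            ci_halfwidths=np.zeros(len(means)),
            counts=counts,
        )

    def test_identical_replicates(self):
        c = self._curve([1.0, 2.0, 3.0])
        out = average_replicates([c, c])
        np.testing.assert_allclose(out.means, c.means)
        np.testing.assert_allclose(out.ci_halfwidths, 0.0, atol=1e-12)

    def test_two_opposite_curves(self):
        out = average_replicates([self._curve([0.0, 1.0]), self._curve([1.0, 0.0])])
        np.testing.assert_allclose(out.means, [0.5, 0.5])

    def test_bin_present_in_one_replicate_only(self):
        a = self._curve([1.0, np.nan], counts=[5, 0])
        b = self._curve([3.0, 7.0], counts=[5, 5])
        out = average_replicates([a, b])
        np.testing.assert_allclose(out.means, [2.0, 7.0])
        assert out.ci_halfwidths[1] == 0.0  # single replicate: no scatter

    def test_mismatched_grids_rejected(self):
        a = self._curve([1.0, 2.0])
        b = self._curve([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            average_replicates([a, b])

    def test_noisy_replicates_recover_truth(self):
        """Mean of three noisy replicate curves sits within its CI of the
        true curve in at least 90% of bins."""
        rng = np.random.default_rng(23)
        truth = np.sin(np.linspace(0, np.pi, 20)) * 10.0
        curves = [self._curve(truth + rng.normal(0, 0.5, 20)) for _ in range(3)]
        out = average_replicates(curves)
        covered = np.abs(out.means - truth) <= np.maximum(out.ci_halfwidths, 1e-12)
        assert covered.mean() >= 0.9


class TestCalibrations:
    def _curve(self, means):
        means = np.asarray(means, dtype=float)
        return BinnedCurve(
            bin_centers=(np.arange(len(means)) + 0.5) / len(means),
            means=means,
            ci_halfwidths=np.zeros(len(means)),
            counts=np.full(len(means), 4),
        )

    def test_unit_ratio_gives_calibration_count(self):
        out = molecules_at_midcell(self._curve([500.0]), mean_total_F=500.0)
        assert out.means[0] == pytest.approx(133.0)

    def test_linear_scaling(self):
        out = molecules_at_midcell(self._curve([0.0, 375.0]), mean_total_F=500.0)
        assert out.means[0] == 0.0
        assert out.means[1] == pytest.approx(99.75)  # ratio 0.75 → about 100

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError):
            molecules_at_midcell(self._curve([1.0]), mean_total_F=0.0)

    def test_density_per_circumference(self):
        res = fcplus(_cell_with_split(60.0, 40.0), pixel_pitch=10.0)
        base = midcell_density_per_circumference(res, diameter=1.0)
        assert base == pytest.approx(res.fcplus / math.pi)
        assert midcell_density_per_circumference(res, 0.5) == pytest.approx(2 * base)

    def test_concentration_per_volume(self):
        n = 30
        cell = CellRecord("c", 3.0, 1.0, np.full(n, 2.0944 / n))
        assert concentration_per_volume(cell) == pytest.approx(1.0, abs=1e-4)
        doubled = CellRecord("c", 3.0, 1.0, np.full(n, 2 * 2.0944 / n))
        assert concentration_per_volume(doubled) == pytest.approx(2.0, abs=1e-3)
        zero = CellRecord("c", 3.0, 1.0, np.zeros(n))
        assert concentration_per_volume(zero) == 0.0


class TestFCPlusDetectionOracle:
    def test_matches_continuous_model_integration(self, growth_law):
        """On noiseless simulated cells, the pixel-level FCPlus matches a
        brute-force integration of the continuous ring + diffuse model to
        1% of the total fluorescence."""
        from scipy.integrate import quad
        from septime import RecruitmentModel, simulate_population
        from tests.conftest import constant_expression

        model = RecruitmentModel(
            t0_true=0.2, rise_width=0.3, plateau_fraction=0.6, ring_sigma=0.12,
            expression_law=constant_expression(1000.0),
        )
        pop, truth = simulate_population(40, growth_law, model, seed=31)
        for cell, frac in zip(pop.cells, truth.true_midcell_fraction):
            L, d = cell.length, cell.diameter
            if L <= 0.8 + d:
                continue
            T = cell.total_fluorescence
            # continuous model: Gaussian ring at L/2 (truncated to the cell,
            # renormalized) plus an axially uniform diffuse component
            sig = 0.12
            dens = lambda x: math.exp(-0.5 * ((x - L / 2) / sig) ** 2)
            norm = quad(dens, 0, L)[0]
            ring_mass, _ = quad(dens, L / 2 - 0.4, L / 2 + 0.4)
            F_mid_cont = T * (frac * ring_mass / norm + (1 - frac) * 0.8 / L)
            V_mid = math.pi * 0.25 * 0.8
            V_rest = cell_volume(L, d) - V_mid
            oracle = (F_mid_cont / V_mid - (T - F_mid_cont) / V_rest) * V_mid
            res = fcplus(cell, pixel_pitch=pop.pixel_pitch)
            assert res.fcplus == pytest.approx(oracle, abs=0.01 * T)
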