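"""phi-XANES pipeline: energy grid, foil calibration, alignment,
normalization, pre-edge fitting and Fe2+ fraction estimation."""

import numpy as np
import pytest

from ironage.simulate import default_endmembers, gen_xanes_stack
from ironage.xanes import (
    SpeciationCalibration,
    SpectrumStack,
    XanesSpectrum,
    align_stack,
    build_energy_grid,
    calibrate_energy_axis,
    compare_groups,
    estimate_fe2_fraction,
    extract_normalized_spectrum,
    fit_pre_edge,
    paper_energy_grid,
)


class TestEnergyGrid:
    def test_acquisition_grid_106_points_with_flags(self):
        grid = paper_energy_grid()
        assert len(grid) == 106
        assert grid.energies[0] == 7000.0
        # the declared step table overshoots by one point and the last
        # segment's span is inconsistent; both must be flagged, not silent
        assert len(grid.discrepancies) == 2
        assert any("107 points" in d for d in grid.discrepancies)

    def test_fine_region_steps_are_0p4_ev(self):
        grid = paper_energy_grid()
        e = grid.energies
        fine = (e > 7105.0) & (e <= 7135.0)
        np.testing.assert_allclose(np.diff(e[(e >= 7105.0) & (e <= 7135.0)]),
                                   0.4, rtol=1e-9)
        assert fine.sum() == 75

    def test_point_counting_convention(self):
        # single segment 0 -> 10 in 10 x 1 steps: 1 + 10 points
        grid = build_energy_grid([(0.0, 10.0, 10, 1.0)])
        assert len(grid) == 11
        assert grid.discrepancies == []

    def test_inconsistent_segment_recorded_not_fatal(self):
        grid = build_energy_grid([(0.0, 50.0, 5, 5.0)])
        assert len(grid) == 6
        assert any("trusting step counts" in d for d in grid.discrepancies)


class TestEnergyCalibration:
    @staticmethod
    def _foil(offset_ev: float) -> XanesSpectrum:
        grid = paper_energy_grid()
        e = grid.energies
        # metallic-edge-like spectrum whose derivative peaks at 7112 - offset
        mu = 0.5 + np.arctan((e - (7112.0 - offset_ev)) / 1.2) / np.pi
        return XanesSpectrum(energies=e, mu=mu)

    def test_known_shift_recovered(self):
        assert calibrate_energy_axis(self._foil(2.0)) == pytest.approx(
            2.0, abs=0.02)

    def test_calibrated_foil_gives_zero_offset(self):
        assert calibrate_energy_axis(self._foil(0.0)) == pytest.approx(
            0.0, abs=0.02)

    def test_no_edge_rejected(self):
        grid = paper_energy_grid()
        flat = XanesSpectrum(energies=grid.energies,
                             mu=np.linspace(0, 1, len(grid)))
        with pytest.raises(ValueError, match="maximum"):
            calibrate_energy_axis(flat)


class TestAlignment:
    def test_jitter_free_stack_zero_shifts(self, xanes_factory):
        stack, _ = xanes_factory(0.5, noise=False)
        _, shifts = align_stack(stack)
        assert np.all(shifts == 0)

    def test_planted_jitter_recovered_exactly(self, xanes_factory):
        stack, truth = xanes_factory(0.5, shape=(24, 24), jitter=2, seed=9)
        aligned, shifts = align_stack(stack)
        planted = np.array(truth["shifts"])
        np.testing.assert_array_equal(shifts, -planted)

    def test_alignment_idempotent(self, xanes_factory):
        stack, _ = xanes_factory(0.5, shape=(24, 24), jitter=2, seed=10)
        aligned, _ = align_stack(stack)
        _, second = align_stack(aligned)
        assert np.all(second == 0)


def _reference_normalize(mu, e, pre_max=7105.0, post_min=7135.0,
                         edge_ref=7112.0):
    """Independent oracle: the same edge-jump normalization written directly."""
    pre = e < pre_max
    post = e > post_min
    line = np.polyval(np.polyfit(e[pre], mu[pre], 1), e)
    sub = mu - line
    jump = np.polyval(np.polyfit(e[post], sub[post], 1), edge_ref)
    return sub / jump


class TestNormalization:
    def test_pure_endmember_matches_oracle(self, xanes_factory):
        stack, _ = xanes_factory(1.0, noise=False)
        spec = extract_normalized_spectrum(
            stack, np.ones(stack.frames.shape[1:], bool))
        fe2, _ = default_endmembers()
        expected = _reference_normalize(fe2.mu(stack.grid.energies),
                                        stack.grid.energies)
        np.testing.assert_allclose(spec.mu, expected, atol=1e-6)

    def test_density_scaling_invariance(self, xanes_factory):
        a, _ = xanes_factory(0.4, noise=False, iron_density=1.0)
        b, _ = xanes_factory(0.4, noise=False, iron_density=2.0)
        mask = np.ones(a.frames.shape[1:], bool)
        np.testing.assert_allclose(
            extract_normalized_spectrum(a, mask).mu,
            extract_normalized_spectrum(b, mask).mu, atol=1e-10)

    def test_5050_mixture_is_average_of_normalized_endmembers(
            self, xanes_factory):
        mask = None
        stacks = {}
        for f in (0.0, 0.5, 1.0):
            stack, _ = xanes_factory(f, noise=False)
            mask = np.ones(stack.frames.shape[1:], bool)
            stacks[f] = extract_normalized_spectrum(stack, mask).mu
        # endmember edge jumps are equal by construction only up to the
        # post-edge line extrapolation, so equality is near-exact
        np.testing.assert_allclose(stacks[0.5],
                                   0.5 * (stacks[0.0] + stacks[1.0]),
                                   atol=1e-3)

    def test_empty_roi_rejected(self, xanes_factory):
        stack, _ = xanes_factory(0.5, noise=False)
        with pytest.raises(ValueError, match="empty"):
            extract_normalized_spectrum(
                stack, np.zeros(stack.frames.shape[1:], bool))


class TestPreEdge:
    def test_pure_endmember_gaussian_centers(self, xanes_spec_factory):
        # single-component spectra: the fitted Gaussian center lands on the
        # generator's pre-edge center
        fit2 = fit_pre_edge(xanes_spec_factory(1.0, noise=False))
        fit3 = fit_pre_edge(xanes_spec_factory(0.0, noise=False))
        assert fit2.gaussian[0] == pytest.approx(7112.1, abs=0.05)
        assert fit3.gaussian[0] == pytest.approx(7113.5, abs=0.05)

    def test_equal_mixture_centroid_at_midpoint(self, xanes_spec_factory):
        # equal feature amplitudes: the 50/50 centroid sits at the midpoint
        # of the endmember centroids measured the same way (the symmetry that
        # makes the linear centroid inversion work)
        c2 = fit_pre_edge(xanes_spec_factory(1.0, noise=False)).centroid
        c3 = fit_pre_edge(xanes_spec_factory(0.0, noise=False)).centroid
        fit = fit_pre_edge(xanes_spec_factory(0.5, noise=False))
        assert fit.centroid == pytest.approx(0.5 * (c2 + c3), abs=0.02)

    def test_mixture_centroids_between_and_monotone(self, xanes_spec_factory):
        cents = [fit_pre_edge(xanes_spec_factory(f, noise=False)).centroid
                 for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(np.diff(cents) < 0)  # more ferrous -> lower centroid
        assert all(cents[-1] <= c <= cents[0] for c in cents)

    def test_ci_contains_centroid(self, xanes_spec_factory):
        fit = fit_pre_edge(xanes_spec_factory(0.3, seed=3))
        assert fit.fit_ci[0] <= fit.centroid <= fit.fit_ci[1]


@pytest.fixture(scope="module")
def calibrations(xanes_spec_factory):
    em2 = xanes_spec_factory(1.0, noise=False)
    em3 = xanes_spec_factory(0.0, noise=False)
    cal_c = SpeciationCalibration.from_endmembers(em2, em3, mode="centroid")
    cal_d = SpeciationCalibration.from_endmembers(em2, em3, mode="derivative")
    return cal_c, cal_d


class TestFractionEstimation:
    def test_centroid_endpoints(self, calibrations):
        cal_c, _ = calibrations
        spec = XanesSpectrum(energies=np.array([7100.0, 7110, 7120]),
                             mu=np.zeros(3))

        class FakeFit:
            pass

        for centroid, expected in ((cal_c.centroid_fe2_ref, 1.0),
                                   (cal_c.centroid_fe3_ref, 0.0)):
            fake = FakeFit()
            fake.centroid = centroid
            res = estimate_fe2_fraction(fake, spec, cal_c, n_boot=0)
            assert res.fe2_fraction == pytest.approx(expected, abs=1e-9)
            assert not res.clipped

    def test_recovery_both_modes(self, calibrations, xanes_spec_factory):
        cal_c, cal_d = calibrations
        for f in (0.1, 0.5, 0.9):
            spec = xanes_spec_factory(f, seed=int(10 * f))
            pre = fit_pre_edge(spec)
            fc = estimate_fe2_fraction(pre, spec, cal_c, n_boot=0).fe2_fraction
            fd = estimate_fe2_fraction(None, spec, cal_d, n_boot=0).fe2_fraction
            assert fc == pytest.approx(f, abs=0.05)
            assert fd == pytest.approx(f, abs=0.05)

    def test_count_scaling_leaves_fraction_unchanged(self, calibrations,
                                                     xanes_spec_factory):
        # multiplying raw counts by a positive constant must not move the
        # centroid or the fraction (noiseless, so scaling is exact)
        cal_c, _ = calibrations
        a = xanes_spec_factory(0.3, noise=False, counts_scale=1e4)
        b = xanes_spec_factory(0.3, noise=False, counts_scale=3e4)
        fa = estimate_fe2_fraction(fit_pre_edge(a), a, cal_c, n_boot=0)
        fb = estimate_fe2_fraction(fit_pre_edge(b), b, cal_c, n_boot=0)
        assert fa.fe2_fraction == pytest.approx(fb.fe2_fraction, abs=1e-9)

    def test_equal_reference_centroids_rejected(self):
        with pytest.raises(ValueError, match="centroid_fe2_ref"):
            SpeciationCalibration(centroid_fe2_ref=7113.0,
                                  centroid_fe3_ref=7113.0)

    def test_clipping_flagged(self, calibrations):
        cal_c, _ = calibrations
        spec = XanesSpectrum(energies=np.array([7100.0, 7110, 7120]),
                             mu=np.zeros(3))

        class FakeFit:
            centroid = cal_c.centroid_fe2_ref - 1.0  # beyond the ferrous ref

        res = estimate_fe2_fraction(FakeFit(), spec, cal_c, n_boot=0)
        assert res.fe2_fraction == 1.0 and res.clipped


class TestGroupComparison:
    @staticmethod
    def _results(values):
        from ironage.xanes import SpeciationResult
        return [SpeciationResult(fe2_fraction=v, ci95=(v, v), mode="centroid")
                for v in values]

    def test_identical_groups_delta_zero(self):
        groups = {"ref": self._results([0.2, 0.25, 0.3]),
                  "same": self._results([0.2, 0.25, 0.3])}
        out = compare_groups(groups, "ref", n_boot=500, seed=1)
        assert out["same"]["delta_vs_reference"] == pytest.approx(0.0)
        lo, hi = out["same"]["delta_ci95"]
        assert lo <= 0.0 <= hi

    def test_planted_difference_recovered(self):
        rng = np.random.default_rng(2)
        ref = 0.30 + rng.normal(0, 0.01, 6)
        trt = 0.20 + rng.normal(0, 0.01, 6)
        out = compare_groups({"ref": self._results(ref),
                              "trt": self._results(trt)}, "ref",
                             n_boot=1000, seed=3)
        # proportional change (0.20 - 0.30) / 0.30 = -1/3
        assert out["trt"]["delta_vs_reference"] == pytest.approx(-1 / 3,
                                                                 abs=0.08)

    def test_single_member_group_ci_flagged(self):
        out = compare_groups({"ref": self._results([0.3, 0.31]),
                              "one": self._results([0.25])}, "ref", seed=4)
        assert not out["one"]["ci_available"]
        assert np.isnan(out["one"]["delta_ci95"][0])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            compare_groups({"ref": []}, "ref")


def test_stack_io_roundtrip(tmp_path, xanes_factory):
    stack, _ = xanes_factory(0.5, shape=(8, 8), seed=1)
    p = tmp_path / "stack.h5"
    stack.to_hdf5(p)
    back = SpectrumStack.from_hdf5(p)
    np.testing.assert_array_equal(back.frames, stack.frames)
    np.testing.assert_allclose(back.grid.energies, stack.grid.energies)
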