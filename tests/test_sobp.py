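import numpy as np
import pytest
from scipy import optimize

from ribpet.microdosimetry import RBEProfile
from ribpet.phantom_beam import SPECIES, DepthDoseProfile, range_from_energy
from ribpet.sobp import (
    BeamSpectrum,
    FlatnessError,
    ProfileSet,
    SOBPPlan,
    biological_dose_profile,
    dense_profile_set,
    interpolate_profiles,
    map_weights_to_radioactive,
    optimize_sobp_weights,
    sobp_flatness,
)

C12, C11 = SPECIES["C12"], SPECIES["C11"]


def gaussian_profile(energy, depth, centre, width=2.0):
    dose = np.exp(-0.5 * ((depth - centre) / width) ** 2)
    return DepthDoseProfile(depth, dose, C12, energy)


class TestInterpolateProfiles:
    depth = np.linspace(0.0, 50.0, 51)

    def anchors(self):
        return [(100.0, gaussian_profile(100.0, self.depth, 20.0), None),
                (200.0, gaussian_profile(200.0, self.depth, 40.0), None)]

    def test_endpoint_reproduced_bit_exactly(self):
        sims = self.anchors()
        ps = interpolate_profiles(sims, step=50.0)
        i = ps.index_of(100.0)
        assert np.array_equal(ps.phys[i], sims[0][1].dose)

    def test_midpoint_is_arithmetic_mean(self):
        sims = self.anchors()
        ps = interpolate_profiles(sims, step=50.0)
        mid = ps.phys[ps.index_of(150.0)]
        assert mid == pytest.approx((sims[0][1].dose + sims[1][1].dose) / 2)

    def test_dense_count_for_five_anchor_oxygen_set(self):
        depth = np.linspace(0.0, 300.0, 31)
        energies = [177.0, 237.0, 297.0, 345.0, 418.0]
        sims = [(e, gaussian_profile(e, depth, 100 + 0.3 * e), None)
                for e in energies]
        ps = interpolate_profiles(sims, step=1.0)
        assert ps.energies.size == (418 - 177) + 1 == 242

    def test_query_outside_hull_rejected(self):
        ps = interpolate_profiles(self.anchors(), step=50.0)
        with pytest.raises(KeyError):
            ps.index_of(250.0)


class TestOptimizeWeights:
    def test_single_flat_profile_scales_to_target(self):
        depth = np.linspace(0.0, 100.0, 101)
        v = 4.0
        flat = np.full_like(depth, v)
        ps = ProfileSet(np.array([100.0]), depth, flat[None, :], flat[None, :])
        plan = SOBPPlan((30.0, 80.0), 5.0, 0.02)
        beam = optimize_sobp_weights(ps, plan, C12)
        assert beam.weights.sum() == pytest.approx(1.0 / v, rel=1e-9)

    def test_two_profile_toy_matches_grid_search(self):
        # 3 depths, 2 energies: exhaustive search over the weight grid
        A = np.array([[1.0, 0.2], [0.6, 0.7], [0.1, 1.1]])
        target = np.ones(3)
        w_nnls, _ = optimize.nnls(A, target)
        grid = np.linspace(0.0, 2.0, 801)
        best, best_obj = None, np.inf
        for w0 in grid:
            resid = target - np.outer(A[:, 0], [1.0])[:, 0] * w0
            # 1-D least squares for the second weight, clipped to >= 0
            w1 = max(float(A[:, 1] @ resid / (A[:, 1] @ A[:, 1])), 0.0)
            obj = np.sum((A @ [w0, w1] - target) ** 2)
            if obj < best_obj:
                best, best_obj = (w0, w1), obj
        assert w_nnls == pytest.approx(best, abs=5e-3)

    def test_matches_bounded_lsq_oracle(self):
        # 5 energies x 20 depths synthetic instance
        rng = np.random.default_rng(0)
        depth = np.linspace(0.0, 19.0, 20)
        centres = np.linspace(4.0, 16.0, 5)
        phys = np.stack([np.exp(-0.5 * ((depth - c) / 2.5) ** 2) for c in centres])
        ps = ProfileSet(np.arange(5, dtype=float), depth, phys, phys)
        plan = SOBPPlan((4.0, 16.0), 5.0, 0.2)
        beam = optimize_sobp_weights(ps, plan, C12)
        w = np.zeros(5)
        for e, wi in beam.components:
            w[int(e)] = wi
        mask = (depth >= 4.0) & (depth <= 16.0)
        oracle = optimize.lsq_linear(phys[:, mask].T, np.ones(mask.sum()),
                                     bounds=(0, np.inf), tol=1e-14)
        assert w == pytest.approx(oracle.x, abs=1e-6)

    def test_infeasible_flatness_reports_achieved(self):
        # one broad Gaussian covers the range but cannot be flattened
        depth = np.linspace(0.0, 40.0, 41)
        phys = np.exp(-0.5 * ((depth - 20.0) / 10.0) ** 2)[None, :]
        ps = ProfileSet(np.array([1.0]), depth, phys, phys)
        plan = SOBPPlan((10.0, 30.0), 5.0, 0.02)
        with pytest.raises(FlatnessError) as err:
            optimize_sobp_weights(ps, plan, C12)
        assert err.value.achieved > 0.02

    def test_uncovered_target_range_rejected(self):
        depth = np.linspace(0.0, 40.0, 41)
        phys = np.stack([np.exp(-0.5 * ((depth - c) / 1.0) ** 2)
                         for c in [10.0, 30.0]])
        ps = ProfileSet(np.array([1.0, 2.0]), depth, phys, phys)
        with pytest.raises(ValueError, match="cover"):
            optimize_sobp_weights(ps, SOBPPlan((8.0, 32.0), 5.0, 0.02), C12)

    def test_nnls_beats_random_nonnegative_vectors(self):
        rng = np.random.default_rng(1)
        depth = np.linspace(0.0, 29.0, 30)
        centres = np.linspace(5.0, 25.0, 8)
        phys = np.stack([np.exp(-0.5 * ((depth - c) / 2.0) ** 2) for c in centres])
        mask = (depth >= 5.0) & (depth <= 25.0)
        A = phys[:, mask].T
        target = np.ones(A.shape[0])
        w_opt, _ = optimize.nnls(A, target)
        obj_opt = np.sum((A @ w_opt - target) ** 2)
        for _ in range(1000):
            w = rng.exponential(0.2, centres.size)
            assert obj_opt <= np.sum((A @ w - target) ** 2) + 1e-12


class TestRadioactiveMapping:
    def _stable_beam(self):
        energies = np.array([190.0, 220.0, 250.0])
        return BeamSpectrum(C12, tuple((float(e), 1.0) for e in energies))

    def test_identity_species_unchanged(self):
        beam = self._stable_beam()
        plan = SOBPPlan((90.0, 115.0))
        mapped = map_weights_to_radioactive(beam, C12, plan)
        assert mapped.energies == pytest.approx(beam.energies, rel=1e-9)
        again = map_weights_to_radioactive(mapped, C12, plan)
        assert again.energies == pytest.approx(mapped.energies, rel=1e-9)

    def test_endpoints_map_to_matching_ranges(self):
        beam = self._stable_beam()
        plan = SOBPPlan((90.0, 115.0))
        mapped = map_weights_to_radioactive(beam, C11, plan)
        for e_s, e_r in [(beam.energies[0], mapped.energies[0]),
                         (beam.energies[-1], mapped.energies[-1])]:
            assert range_from_energy(e_r, C11) == pytest.approx(
                range_from_energy(e_s, C12), rel=1e-8)

    def test_weights_preserved(self):
        beam = BeamSpectrum(C12, ((190.0, 0.5), (220.0, 0.3), (250.0, 0.2)))
        mapped = map_weights_to_radioactive(beam, C11, SOBPPlan((90.0, 115.0)))
        assert mapped.weights == pytest.approx(beam.weights)

    def test_mapped_peak_depths_match_through_profile_peak_finder(self, water):
        """C11 SOBP endpoints hit the C12 peak depths within one grid step."""
        from ribpet.phantom_beam import depth_dose_profile

        beam = self._stable_beam()
        mapped = map_weights_to_radioactive(beam, C11, SOBPPlan((90.0, 115.0)))
        for e_s, e_r in zip([beam.energies[0], beam.energies[-1]],
                            [mapped.energies[0], mapped.energies[-1]]):
            p_s = depth_dose_profile(e_s, C12, water, 0.5).peak_depth
            p_r = depth_dose_profile(e_r, C11, water, 0.5).peak_depth
            assert abs(p_s - p_r) <= 0.5


class TestBiologicalDose:
    def test_unit_rbe_means_bio_equals_phys(self):
        depth = np.linspace(0.0, 100.0, 101)
        phys = np.stack([np.exp(-0.5 * ((depth - c) / 3.0) ** 2)
                         for c in np.linspace(40, 80, 9)])
        ps = ProfileSet(np.arange(9, dtype=float), depth, phys, phys.copy())
        plan = SOBPPlan((40.0, 80.0), 5.0, 0.05)
        beam = optimize_sobp_weights(ps, plan, C12)
        unit_rbe = RBEProfile(depth, np.ones_like(depth), np.zeros_like(depth))
        out = biological_dose_profile(beam, ps, plan, rbe=unit_rbe)
        assert out["biological"] == pytest.approx(out["physical"], rel=1e-12)

    def test_optimized_sobp_flat_within_tolerance(self, designed_sobp):
        profiles, beam, plan = designed_sobp
        out = biological_dose_profile(beam, profiles, plan)
        assert out["report"]["flatness_bio"] <= plan.flatness_tolerance
        assert plan.width == pytest.approx(60.0)  # 60 mm SOBP prescription

    def test_bio_flatter_than_phys_for_optimized_solution(self, designed_sobp):
        profiles, beam, plan = designed_sobp
        out = biological_dose_profile(beam, profiles, plan)
        assert out["report"]["flatness_bio"] <= out["report"]["flatness_phys"]


class TestDenseProfileSet:
    def test_peaks_cover_requested_energies(self, skull):
        energies = np.arange(190.0, 200.0)
        ps = dense_profile_set(energies, C12, skull)
        peaks = ps.depth[np.argmax(ps.phys, axis=1)]
        assert np.all(np.diff(peaks) >= 0) and peaks[-1] > peaks[0]

    def test_flatness_helper_on_constant_curve(self):
        depth = np.linspace(0, 10, 11)
        assert sobp_flatness(depth, np.full(11, 2.0), (2.0, 8.0)) == 0.0
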