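import numpy as np
import pytest

from ribpet.annihilation_sim import (
    AnnihilationEventSet,
    AnnihilationMap,
    SpillSchedule,
    bin_events,
    blur_map,
    estimate_half_life,
    interspill_window,
    simulate_treatment,
)
from ribpet.phantom_beam import SPECIES
from ribpet.sobp import BeamSpectrum

C10_BEAM = BeamSpectrum(SPECIES["C10"], ((220.0, 1.0),))
C12_BEAM = BeamSpectrum(SPECIES["C12"], ((200.0, 1.0),))

#: one short spill so all birth times are ~0 (decay-law tests)
PROMPT = SpillSchedule(n_spills=1, beam_on=1e-4, beam_off=1.0, intensity=1e9)


class TestSpillSchedule:
    def test_defaults_match_treatment_protocol(self):
        s = SpillSchedule()
        assert (s.n_spills, s.beam_on, s.beam_off) == (20, 1.9, 1.4)
        assert s.period == pytest.approx(3.3)
        assert s.total_primaries == pytest.approx(20 * 1.9 * 1e9)

    def test_interspill_window_arithmetic(self):
        s = SpillSchedule()
        assert interspill_window(s, 1) == (pytest.approx(1.9), pytest.approx(3.3))
        assert interspill_window(s, 2) == (pytest.approx(5.2), pytest.approx(6.6))

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            SpillSchedule(beam_off=-1.0)


class TestSimulateTreatment:
    def test_stable_beam_without_fragmentation_gives_no_events(self, water):
        ev = simulate_treatment(C12_BEAM, water, PROMPT, 1000, seed=0,
                                fragmentation_probability=0.0)
        assert len(ev) == 0

    def test_deterministic_for_fixed_seed(self, water):
        a = simulate_treatment(C10_BEAM, water, SpillSchedule(), 5000, seed=42)
        b = simulate_treatment(C10_BEAM, water, SpillSchedule(), 5000, seed=42)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.z, b.z)
        assert np.array_equal(a.species, b.species)

    def test_half_the_primaries_decay_within_one_half_life(self, water):
        n = 40_000
        ev = simulate_treatment(C10_BEAM, water, PROMPT, n, seed=1,
                                fragmentation_probability=0.0)
        n_prim = len(ev)
        T = SPECIES["C10"].half_life
        decayed = np.sum((ev.t - ev.t_birth) < T)
        assert abs(decayed - n_prim / 2) < 4 * np.sqrt(n_prim / 2)

    def test_window_counts_follow_exponential_decay_law(self, water):
        n = 50_000
        ev = simulate_treatment(C10_BEAM, water, PROMPT, n, seed=3,
                                fragmentation_probability=0.0)
        lam = SPECIES["C10"].decay_constant
        n_prim = len(ev)
        for t1, t2 in [(5.0, 15.0), (20.0, 60.0)]:
            expected = n_prim * (np.exp(-lam * t1) - np.exp(-lam * t2))
            got = np.sum((ev.t >= t1) & (ev.t < t2))
            assert abs(got - expected) < 4 * np.sqrt(expected)

    def test_recovered_half_life_within_three_se(self, water):
        for name, beam in [("C10", C10_BEAM),
                           ("O15", BeamSpectrum(SPECIES["O15"], ((250.0, 1.0),))),
                           ("C11", BeamSpectrum(SPECIES["C11"], ((210.0, 1.0),)))]:
            ev = simulate_treatment(beam, water, PROMPT, 30_000,
                                    seed=5, fragmentation_probability=0.0)
            t_half, se = estimate_half_life(ev.t - ev.t_birth)
            assert abs(t_half - SPECIES[name].half_life) < 3 * se

    def test_fragment_fractions_must_sum_to_one(self, water):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_treatment(C12_BEAM, water, PROMPT, 100, seed=0,
                               fragment_fractions={"C11": 0.5, "O15": 0.4})

    def test_short_half_life_gives_more_first_interspill_counts(self, water):
        sched = SpillSchedule()
        win = interspill_window(sched, 1)
        counts = {}
        for name in ("C10", "C11"):
            beam = BeamSpectrum(SPECIES[name], ((220.0, 1.0),))
            ev = simulate_treatment(beam, water, sched, 50_000, seed=9)
            counts[name] = np.sum((ev.t >= win[0]) & (ev.t < win[1]))
        assert counts["C10"] > counts["C11"]

    def test_radioactive_beam_stops_at_range_stable_spreads_fragments(self, water):
        from ribpet.phantom_beam import range_from_energy

        R = range_from_energy(220.0, SPECIES["C10"])
        ev_r = simulate_treatment(C10_BEAM, water, PROMPT, 20_000, seed=11,
                                  fragmentation_probability=0.0)
        # long window: nearly all primaries decayed at their stopping point
        assert np.median(ev_r.z) == pytest.approx(R, abs=2.0)
        ev_s = simulate_treatment(C12_BEAM, water, PROMPT, 20_000, seed=11)
        R_s = range_from_energy(200.0, SPECIES["C12"])
        # fragments populate the whole entrance path
        assert np.mean(ev_s.z < 0.5 * R_s) > 0.2
        assert np.all(ev_s.origin == "fragment")


class TestBinning:
    def _events(self, z, t):
        n = len(z)
        zero = np.zeros(n)
        return AnnihilationEventSet(zero, zero, np.asarray(z, float),
                                    np.asarray(t, float), zero,
                                    np.full(n, "C10"), np.full(n, "primary"))

    def test_empty_events_give_zero_map(self):
        m = bin_events(self._events([], []), (0.0, 1.0), 1.5)
        assert m.total == 0

    def test_single_event_at_voxel_centre(self):
        bounds = ((-3.0, 3.0), (-3.0, 3.0), (0.0, 6.0))
        m = bin_events(self._events([0.75], [0.5]), (0.0, 1.0), 1.5, bounds)
        assert m.total == 1
        assert m.counts[2, 2, 0] == 1

    def test_window_additivity(self):
        z = np.linspace(0.5, 5.5, 30)
        t = np.linspace(0.0, 2.0, 30, endpoint=False)
        ev = self._events(z, t)
        bounds = ((-3.0, 3.0), (-3.0, 3.0), (0.0, 6.0))
        full = bin_events(ev, (0.0, 2.0), 1.5, bounds)
        a = bin_events(ev, (0.0, 1.0), 1.5, bounds)
        b = bin_events(ev, (1.0, 2.0), 1.5, bounds)
        assert np.array_equal(full.counts, a.counts + b.counts)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            bin_events(self._events([], []), (2.0, 1.0), 1.5)


class TestBlur:
    def _impulse(self):
        counts = np.zeros((21, 21, 21), dtype=np.int64)
        counts[10, 10, 10] = 1000
        return AnnihilationMap(counts, 1.5, (0.0, 1.0))

    def test_zero_fwhm_is_identity(self):
        m = self._impulse()
        out = blur_map(m, 0.0)
        assert np.array_equal(out.counts, m.counts)

    def test_total_intensity_conserved(self):
        m = self._impulse()
        out = blur_map(m, 3.5)
        assert out.total == pytest.approx(m.total, rel=1e-6)

    def test_impulse_second_moment_matches_sigma(self):
        m = self._impulse()
        out = blur_map(m, 3.5)
        sigma_mm = 3.5 / 2.3548
        centres = m.voxel_centres(0) - m.voxel_centres(0)[10]
        profile = out.counts.sum(axis=(1, 2))
        var = np.sum(profile * centres**2) / profile.sum()
        assert var == pytest.approx(sigma_mm**2, rel=0.01)
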