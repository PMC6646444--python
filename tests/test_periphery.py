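import numpy as np
import pytest

from efrkit import periphery, population
from efrkit.periphery import (
    DEFAULT_CLASS_PARAMS,
    DEFAULT_TUNING,
    Audiogram,
    FiberClassParams,
    HairCellProfile,
    effective_drive,
    fiber_rate,
    fit_haircell_profile,
    instantaneous_level,
    simulate_population,
    tuning_attenuation,
)
from efrkit.stimuli import make_sam


@pytest.fixture(scope="module")
def stim80():
    return make_sam(2005.0, 93.0, 0.85, 80.0, 1.2, 48000.0)


class TestHairCellProfile:
    def test_normal_audiogram_gives_no_shift(self, grid):
        aud = Audiogram(frequencies=np.array([250.0, 1000.0, 4000.0, 8000.0]),
                        thresholds=np.zeros(4))
        hp = fit_haircell_profile(aud, grid)
        assert np.all(hp.ohc_shift == 0)
        assert np.all(hp.ihc_shift == 0)

    def test_mixed_split_at_anchor(self, grid):
        """30 dB HL at 4 kHz splits 2/3 OHC + 1/3 IHC at the 4-kHz channel."""
        aud = Audiogram(frequencies=np.array([1000.0, 2000.0, 4000.0, 8000.0]),
                        thresholds=np.array([0.0, 0.0, 30.0, 0.0]))
        g = population.build_cf_grid(n_cf=5, f_min=1000.0, f_max=4000.0)
        hp = fit_haircell_profile(aud, g)
        assert hp.ohc_shift[-1] == pytest.approx(20.0, abs=0.1)
        assert hp.ihc_shift[-1] == pytest.approx(10.0, abs=0.1)
        # the split conserves the audiometric shift everywhere
        assert np.allclose(hp.ohc_shift + hp.ihc_shift, 3.0 * hp.ihc_shift, atol=1e-9)

    @pytest.mark.parametrize("mode,ohc,ihc", [("ohc_only", 30.0, 0.0), ("ihc_only", 0.0, 30.0)])
    def test_single_mechanism_modes(self, mode, ohc, ihc):
        aud = Audiogram(frequencies=np.array([1000.0, 4000.0]),
                        thresholds=np.array([30.0, 30.0]))
        g = population.build_cf_grid(n_cf=3, f_min=1000.0, f_max=4000.0)
        hp = fit_haircell_profile(aud, g, mode=mode)
        assert hp.ohc_shift[0] == pytest.approx(ohc, abs=0.1)
        assert hp.ihc_shift[0] == pytest.approx(ihc, abs=0.1)

    def test_sloping_ehf_extension(self):
        """25 dB HL at 8 kHz slopes to ~75 dB HL one octave up."""
        aud = Audiogram(frequencies=np.array([1000.0, 8000.0]),
                        thresholds=np.array([25.0, 25.0]), ehf_mode="sloping")
        g = population.build_cf_grid(n_cf=3, f_min=8000.0, f_max=16000.0)
        hp = fit_haircell_profile(aud, g)
        total = hp.ohc_shift[-1] + hp.ihc_shift[-1]
        assert total == pytest.approx(75.0, abs=1.0)

    def test_flat_ehf_extension(self):
        aud = Audiogram(frequencies=np.array([1000.0, 8000.0]),
                        thresholds=np.array([25.0, 25.0]), ehf_mode="flat")
        g = population.build_cf_grid(n_cf=3, f_min=8000.0, f_max=16000.0)
        hp = fit_haircell_profile(aud, g)
        assert hp.ohc_shift[-1] + hp.ihc_shift[-1] == pytest.approx(25.0, abs=0.5)

    def test_negative_thresholds_clamped_with_warning(self, grid):
        aud = Audiogram(frequencies=np.array([1000.0, 4000.0]),
                        thresholds=np.array([-10.0, -5.0]))
        with pytest.warns(UserWarning, match="clamped"):
            hp = fit_haircell_profile(aud, grid)
        assert np.all(hp.ohc_shift == 0) and np.all(hp.ihc_shift == 0)

    def test_invalid_inputs(self, grid):
        aud = Audiogram(frequencies=np.array([1000.0, 4000.0]),
                        thresholds=np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            fit_haircell_profile(aud, grid, mode="both")
        with pytest.raises(ValueError):
            Audiogram(frequencies=np.array([4000.0, 1000.0]), thresholds=np.zeros(2))
        with pytest.raises(ValueError):
            Audiogram(frequencies=np.array([1000.0, 4000.0]),
                      thresholds=np.array([0.0, np.inf]))
        with pytest.raises(ValueError):
            Audiogram(frequencies=np.array([1000.0, 4000.0]),
                      thresholds=np.zeros(2), ehf_mode="rising")


class TestTuning:
    def test_on_frequency_no_attenuation(self):
        assert tuning_attenuation(2005.0, 2005.0) == pytest.approx(0.0)

    def test_two_octaves_above_carrier_sits_on_tail(self):
        """Tail (plateau + shallow ramp), not the 60-dB/oct flank, applies."""
        a = tuning_attenuation(4 * 2005.0, 2005.0)
        tail = DEFAULT_TUNING.tail_level + DEFAULT_TUNING.tail_slope * (2.0 - 0.75)
        assert a == pytest.approx(tail)  # 60 dB, far below 2 oct * 60 dB/oct

    def test_carrier_above_cf_uses_steep_flank(self):
        assert tuning_attenuation(2005.0 / 2.0, 2005.0) == pytest.approx(120.0)

    def test_ohc_shift_raises_tip_until_tail_takes_over(self):
        # at the tip: 40 dB OHC loss is below the 45-dB tail -> A = 40
        assert tuning_attenuation(2005.0, 2005.0, ohc_shift=40.0) == pytest.approx(40.0)
        # a huge OHC loss is capped by the tail
        assert tuning_attenuation(2005.0, 2005.0, ohc_shift=80.0) == pytest.approx(
            DEFAULT_TUNING.tail_level
        )

    def test_tail_invariance_under_ohc_loss(self):
        """Channels already on their tail are unaffected by any OHC shift."""
        cf = 4 * 2005.0
        assert tuning_attenuation(cf, 2005.0, ohc_shift=0.0) == pytest.approx(
            tuning_attenuation(cf, 2005.0, ohc_shift=55.0)
        )

    def test_drive_tracks_envelope_on_frequency(self, stim80):
        t = np.linspace(0.1, 0.2, 500)
        drive = effective_drive(stim80, 2005.0, t=t)
        assert np.allclose(drive, instantaneous_level(stim80, t))

    def test_ihc_shift_attenuates_tip_and_tail_equally(self, stim80):
        t = np.linspace(0.1, 0.2, 200)
        for cf in (2005.0, 4 * 2005.0):  # tip channel and tail channel
            healthy = effective_drive(stim80, cf, t=t)
            impaired = effective_drive(stim80, cf, ihc_shift=25.0, t=t)
            assert np.allclose(healthy - impaired, 25.0)


class TestFiberRate:
    @pytest.mark.parametrize("cls", ["high", "medium", "low"])
    def test_asymptotes(self, cls):
        p = DEFAULT_CLASS_PARAMS[cls]
        assert fiber_rate(p.threshold - 200.0, p) == pytest.approx(p.spont_rate, rel=1e-6)
        assert fiber_rate(p.threshold + 500.0, p) == pytest.approx(p.max_rate, rel=1e-6)
        drives = np.linspace(-50, 150, 300)
        r = fiber_rate(drives, p)
        assert np.all(r >= p.spont_rate - 1e-9) and np.all(r <= p.max_rate + 1e-9)

    def test_sigmoid_anchor_points(self):
        """sigma(0) = 0.05 and sigma(1) = 0.95 on the normalized drive axis."""
        p = FiberClassParams(spont_rate=0.0, threshold=10.0, dynamic_range=20.0, max_rate=100.0)
        assert fiber_rate(10.0, p) == pytest.approx(5.0, rel=1e-9)
        assert fiber_rate(30.0, p) == pytest.approx(95.0, rel=1e-9)

    def test_modulation_collapses_in_saturation(self):
        """Far above saturation the f_m component of the rate vanishes."""
        p = DEFAULT_CLASS_PARAMS["high"]
        t = np.arange(1000) * 1e-3
        mod = 10.0 * np.sin(2 * np.pi * 93.0 * t)
        r_mid = fiber_rate(p.threshold + p.dynamic_range / 2 + mod, p)
        r_sat = fiber_rate(p.threshold + p.dynamic_range + 200.0 + mod, p)
        amp = lambda r: 2.0 / len(r) * np.abs(np.fft.rfft(r - r.mean())[93])
        assert amp(r_sat) < 1e-3 * amp(r_mid)

    def test_invalid_dynamic_range(self):
        p = FiberClassParams(spont_rate=0.0, threshold=0.0, dynamic_range=0.0, max_rate=100.0)
        with pytest.raises(ValueError):
            fiber_rate(0.0, p)

    @pytest.mark.parametrize("cls", ["high", "medium", "low"])
    @pytest.mark.parametrize("cf", [2005.0, 7000.0])
    def test_synchrony_level_function_is_unimodal(self, cls, cf):
        """The f_m magnitude of the rate over a level sweep is single-peaked."""
        levels = np.arange(10, 101, 5)
        mags = []
        t = (np.arange(1200) + 0.5) * 1e-3
        for lv in levels:
            stim = make_sam(2005.0, 93.0, 0.85, float(lv), 1.2, 48000.0)
            r = fiber_rate(effective_drive(stim, cf, t=t), DEFAULT_CLASS_PARAMS[cls])
            seg = r[100:1100]
            mags.append(2.0 / 1000 * np.abs(np.fft.rfft(seg - seg.mean())[93]))
        s = np.sign(np.diff(mags))
        s = s[s != 0]
        assert np.sum(np.diff(s) != 0) <= 1  # rises then falls (or is monotone)


class TestPopulationResponse:
    def test_analytic_mode_deterministic(self, stim80, healthy_pop):
        a = simulate_population(stim80, healthy_pop)
        b = simulate_population(stim80, healthy_pop)
        assert np.array_equal(a.psth, b.psth)

    def test_psth_nonnegative_and_shaped(self, stim80, healthy_pop):
        r = simulate_population(stim80, healthy_pop)
        assert r.psth.shape == (200, 3, 1200)
        assert np.all(r.psth >= 0)

    def test_analytic_steady_state_is_modulation_periodic(self, healthy_pop):
        # 93 Hz is not periodic in 1-ms bins; use f_m = 100 Hz for an exact check
        stim = make_sam(2005.0, 100.0, 0.85, 70.0, 1.2, 48000.0)
        r = simulate_population(stim, healthy_pop)
        total = r.summed()[r.steady_start_index :]
        period = int(round(1.0 / 100.0 / r.bin_width))
        assert np.allclose(total[:-period], total[period:], rtol=1e-9)

    def test_empty_population_warns_and_is_zero(self, stim80, grid):
        empty = population.FiberPopulation(grid=grid, counts=np.zeros((200, 3), int))
        with pytest.warns(UserWarning, match="no fibers"):
            r = simulate_population(stim80, empty)
        assert np.all(r.psth == 0)

    def test_spiking_mean_converges_to_analytic(self, healthy_pop):
        """Inhomogeneous-Poisson sampling is unbiased around the analytic rate."""
        stim = make_sam(2005.0, 93.0, 0.85, 60.0, 0.4, 48000.0)
        analytic = simulate_population(stim, healthy_pop).summed()
        runs = np.array(
            [
                simulate_population(stim, healthy_pop, mode="spiking", seed=s).summed()
                for s in range(50)
            ]
        )
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(50)
        z = np.abs(mean - analytic) / se
        assert np.mean(z < 2.0) > 0.93  # ~95 % of bins within 2 SE
        assert np.abs(mean.mean() / analytic.mean() - 1.0) < 0.005

    def test_spiking_seeded_reproducible(self, stim80, healthy_pop):
        a = simulate_population(stim80, healthy_pop, mode="spiking", seed=11)
        b = simulate_population(stim80, healthy_pop, mode="spiking", seed=11)
        c = simulate_population(stim80, healthy_pop, mode="spiking", seed=12)
        assert np.array_equal(a.psth, b.psth)
        assert not np.array_equal(a.psth, c.psth)

    def test_ohc_loss_leaves_tail_channels_untouched(self, stim80, healthy_pop):
        """End-to-end tail invariance: uniform OHC loss, basal channels identical."""
        grid = healthy_pop.grid
        shift = np.full(grid.n_cf, 30.0)
        hair = HairCellProfile(grid=grid, ohc_shift=shift, ihc_shift=np.zeros(grid.n_cf))
        healthy = simulate_population(stim80, healthy_pop)
        impaired = simulate_population(stim80, healthy_pop, hair=hair)
        tail = tuning_attenuation(grid.cf, 2005.0)  # healthy attenuation
        on_tail = tuning_attenuation(grid.cf, 2005.0, ohc_shift=30.0) == tail
        assert on_tail.sum() > 50
        assert np.array_equal(healthy.psth[on_tail], impaired.psth[on_tail])
        assert not np.array_equal(healthy.psth[~on_tail], impaired.psth[~on_tail])

    def test_grid_mismatch_rejected(self, stim80, healthy_pop):
        other = population.build_cf_grid(n_cf=50)
        hair = HairCellProfile.healthy(other)
        with pytest.raises(ValueError, match="share the CF grid"):
            simulate_population(stim80, healthy_pop, hair=hair)

    def test_invalid_mode(self, stim80, healthy_pop):
        with pytest.raises(ValueError, match="mode"):
            simulate_population(stim80, healthy_pop, mode="exact")
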