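"""Generator properties: archetype proportions, generative responses,
calcium kinetics, spatial layouts, learning curves."""

import numpy as np
import pytest

from rampasym import stimuli, synth
from rampasym.preprocess import deconvolve
from rampasym.spatial import CellMap, homogeneity_index
from rampasym.stimuli import Quality, RampKind, StimulusSpec

RATE = 31.5


class TestPopulation:
    def test_default_split_of_1000_neurons(self):
        pop = synth.sample_population(synth.PopulationConfig(n_neurons=1000), seed=0)
        n_nonresp = (pop.labels == synth.NONRESPONSIVE).sum()
        assert n_nonresp == 630  # ~63% non-responsive
        resp = pop.labels[pop.labels != synth.NONRESPONSIVE]
        frac_loud_off = (resp == "loud_off").sum() / len(resp)
        assert frac_loud_off == pytest.approx(0.30, abs=0.01)

    def test_same_seed_is_bit_identical(self):
        a = synth.sample_population(seed=42)
        b = synth.sample_population(seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.gains, b.gains)

    def test_bad_proportions_rejected(self):
        cfg = synth.PopulationConfig(proportions={"loud_off": 0.5, "tonic": 0.3})
        with pytest.raises(ValueError):
            synth.sample_population(cfg, seed=0)

    def test_positions_inside_field(self):
        pop = synth.sample_population(seed=1)
        assert pop.positions.min() >= 0
        assert (pop.positions[:, 0] <= 550).all()
        assert (pop.positions[:, 1] <= 540).all()


@pytest.fixture(scope="module")
def family_rates(wn_envs):
    model = synth.archetype_model(rate=RATE)
    fams = synth.ARCHETYPE_FAMILIES + (synth.NONRESPONSIVE,)
    rates = np.stack(
        [np.clip(model.predict(e), 0, None) for e in wn_envs], axis=1
    )
    return dict(zip(fams, rates))


class TestGenerativeRates:
    def _env_index(self, envs, kind, duration, lo):
        for i, e in enumerate(envs):
            s = e.spec
            if (s.kind == kind and s.duration == duration
                    and min(s.level_start, s.level_end) == lo):
                return i
        raise LookupError

    def test_quiet_on_prefers_up_ramp_onset(self, wn_envs, family_rates):
        iu = self._env_index(wn_envs, RampKind.UP_RAMP, 2.0, 60.0)
        idn = self._env_index(wn_envs, RampKind.DOWN_RAMP, 2.0, 60.0)
        up = family_rates["quiet_on"][iu]
        down = family_rates["quiet_on"][idn]
        on = wn_envs[iu].onset_index
        # single transient near the up-ramp onset
        assert up.max() > 1.0
        assert on <= np.argmax(up) <= on + 10
        # the down-ramp starts loud: the quiet channel's onset response is
        # cancelled and no onset transient appears
        assert down[on : on + 10].max() < 0.05 * up.max()

    def test_nonresponsive_is_silent(self, family_rates):
        assert np.all(family_rates[synth.NONRESPONSIVE] == 0)

    def test_loud_off_responds_after_loud_offset_only(self, wn_envs, family_rates):
        i85 = next(
            i for i, e in enumerate(wn_envs)
            if e.spec.kind == RampKind.CONSTANT and e.spec.level_start == 85.0
        )
        r = family_rates["loud_off"][i85]
        off = wn_envs[i85].offset_index
        # the forward-difference derivative places the offset transient at
        # the last stimulus frame, one frame before the offset index
        assert r[: off - 1].max() < 0.05 * r.max()
        assert np.argmax(r) >= off - 1

    def test_population_rates_scale_with_gain(self, wn_envs):
        pop = synth.sample_population(synth.PopulationConfig(n_neurons=50), seed=3)
        rates = synth.generate_rates(pop, wn_envs, rate=RATE)
        assert rates.shape == (50, 23, wn_envs[0].n_frames)
        assert rates.min() >= 0
        resp = pop.labels != synth.NONRESPONSIVE
        assert np.all(rates[~resp] == 0)
        assert np.all(rates[resp].max(axis=(1, 2)) > 0)


class TestFluorescence:
    def test_zero_rate_zero_noise_is_baseline_plus_neuropil(self):
        kin = synth.KineticsConfig(noise_sd=0.0)
        rates = np.zeros((3, 2, 50))
        F, Fnp = synth.rates_to_fluorescence(rates, kin, n_trials=4, seed=0)
        np.testing.assert_allclose(
            F, kin.baseline_F0 + kin.neuropil_weight * Fnp, atol=1e-4
        )

    def test_impulse_decays_with_tau_2s(self):
        kin = synth.KineticsConfig(noise_sd=0.0)
        rates = np.zeros((1, 1, 400))
        rates[0, 0, 30] = 1.0
        F, Fnp = synth.rates_to_fluorescence(rates, kin, n_trials=1, seed=0,
                                             dtype=np.float64)
        f = (F[0, 0, 0] - kin.neuropil_weight * Fnp[0, 0, 0]
             - kin.baseline_F0) / kin.baseline_F0
        peak = np.argmax(f)
        # decay from well past the peak follows exp(-t/2); stop before the
        # truncated kernel support (5 tau) runs out
        seg = f[peak + 60 : 330]
        t = np.arange(len(seg)) / RATE
        ref = seg[0] * np.exp(-t / 2.0)
        np.testing.assert_allclose(seg, ref, rtol=0.02)

    def test_deconvolved_transient_lags_rate_by_rise_time(self):
        """Deconvolution inverts the decay but not the indicator rise: the
        deconvolved trace is the rate filtered by a causal exponential of
        time constant tau_rise, so the peak of a smooth rate transient lags
        the true rate peak by a delay on the order of tau_rise."""
        kin = synth.KineticsConfig(noise_sd=0.0)
        t = np.arange(300) / RATE
        n0 = 100
        rates = np.exp(-0.5 * ((t - t[n0]) / 0.1) ** 2)[None, None, :]
        F, Fnp = synth.rates_to_fluorescence(rates, kin, n_trials=1, seed=0,
                                             dtype=np.float64)
        f = (F[0, 0, 0] - kin.neuropil_weight * Fnp[0, 0, 0]
             - kin.baseline_F0) / kin.baseline_F0
        r = deconvolve(f, RATE, tau=kin.tau_decay)
        lag_s = (np.argmax(r) - n0) / RATE
        assert 0.0 < lag_s < 0.15  # on the order of the 0.1 s rise time


class TestSpatialLayout:
    def test_uniform_layout_gives_chance_homogeneity(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 800)
        pos = synth.spatial_layout(labels, clumping=0.0, seed=1)
        idx = homogeneity_index(CellMap(pos, labels), radius=40.0)
        np.testing.assert_allclose(idx.to_numpy(), 0.25, atol=0.06)

    def test_full_clumping_with_tight_blobs_gives_unity(self):
        labels = np.repeat([0, 1], 60)
        pos = np.vstack(
            [
                np.random.default_rng(0).normal((100, 100), 5, (60, 2)),
                np.random.default_rng(1).normal((450, 450), 5, (60, 2)),
            ]
        )
        idx = homogeneity_index(CellMap(pos, labels), radius=30.0)
        np.testing.assert_allclose(idx.to_numpy(), 1.0)

    def test_seeded_layout_is_reproducible(self):
        labels = np.repeat([0, 1, 2], 50)
        a = synth.spatial_layout(labels, 0.7, seed=9)
        b = synth.spatial_layout(labels, 0.7, seed=9)
        np.testing.assert_array_equal(a, b)


class TestLearningCurves:
    def test_noiseless_rise_time_closed_form(self):
        params = dict(group="up", k=0.01, t0=300, plateau=0.9, noise_sd=0.0,
                      n_trials=1200)
        from rampasym.behavior import rise_duration

        curve = synth.generate_learning_curves(params, 1, seed=0)[0]
        assert rise_duration(curve) == pytest.approx(2 * np.log(4) / 0.01,
                                                     rel=0.02)

    def test_chance_plateau_gives_flat_curve(self):
        params = dict(group="x", k=0.01, t0=300, plateau=0.5, noise_sd=0.0)
        curve = synth.generate_learning_curves(params, 1, seed=0)[0]
        np.testing.assert_allclose(curve.performance, 0.5)

    def test_faster_group_has_stochastically_smaller_rises(self):
        from rampasym.behavior import rise_duration

        fast = dict(group="a", k=0.02, k_sd=0.2, t0=250, plateau=0.9,
                    noise_sd=0.02, n_trials=1000)
        slow = dict(group="b", k=0.008, k_sd=0.2, t0=250, plateau=0.9,
                    noise_sd=0.02, n_trials=1000)
        ra = [rise_duration(c)
              for c in synth.generate_learning_curves(fast, 12, seed=1)]
        rb = [rise_duration(c)
              for c in synth.generate_learning_curves(slow, 12, seed=2)]
        assert np.median(ra) < np.median(rb)


def test_dataset_roundtrip_and_determinism(tmp_path, small_dataset):
    import h5py

    ds = small_dataset
    path = tmp_path / "session.h5"
    ds.save(path)
    with h5py.File(path) as h5:
        assert h5["F"].shape == ds.F.values.shape
        assert h5.attrs["rate"] == RATE
        assert h5["positions"].shape == (120, 2)
    assert path.with_suffix(".json").exists()
    ds2 = synth.generate_dataset(seed=7, n_neurons=120, n_trials=10)
    np.testing.assert_array_equal(ds.F.values, ds2.F.values)
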