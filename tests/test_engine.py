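"""Simulation engine: presentation loop, training, determinism, checkpoints.

The engine's vectorized loop is validated against the pure-Python scalar
replay oracle in conftest, which independently re-implements the documented
per-step contract.
"""

import dataclasses

import numpy as np
import pytest

from spilinc import (EncodedInput, LIFParams, Liquid, LiquidConfig,
                     LiquidEnsemble, STDPParams, TrainingSchedule,
                     build_liquid, load_checkpoint, save_checkpoint,
                     slice_encoded, train)
from spilinc.config import apply_overrides, build_model, encode_sample, load_preset
from spilinc.synthetic import make_image_classes

from conftest import scalar_replay


def tiny_liquid(tiny_topology):
    return Liquid(tiny_topology, LIFParams.excitatory(),
                  LIFParams.inhibitory(), STDPParams.image())


@pytest.fixture()
def tiny(tiny_topology):
    return tiny_liquid(tiny_topology)


def constant_enc(n_inp, p, duration=50.0):
    return EncodedInput(np.full(n_inp, p), duration=duration)


class TestPresent:
    def test_zero_input_drives_no_spikes(self, tiny, rng):
        rec = tiny.present(constant_enc(4, 0.0), "test", rng)
        assert rec.spike_count.sum() == 0

    def test_test_mode_is_deterministic_and_frozen(self, tiny_topology):
        recs, weights = [], []
        for _ in range(2):
            liq = tiny_liquid(tiny_topology)
            rec = liq.present(constant_enc(4, 0.5), "test",
                              np.random.default_rng(11))
            recs.append(rec.raster)
            weights.append(liq.w_inp_e.copy())
        assert np.array_equal(*recs)
        assert np.array_equal(*weights)
        assert np.array_equal(weights[0], tiny_topology.w_inp_e)

    def test_dimension_mismatch_rejected(self, tiny, rng):
        with pytest.raises(ValueError):
            tiny.present(constant_enc(5, 0.1), "test", rng)

    def test_unknown_mode_rejected(self, tiny, rng):
        with pytest.raises(ValueError):
            tiny.present(constant_enc(4, 0.1), "banana", rng)

    def test_refractory_period_separates_spikes(self, rng):
        """A strongly driven neuron fires a regular train whose inter-spike
        intervals never violate the refractory period."""
        cfg = LiquidConfig(n_inp=1, n_e=1, n_i=1, p_inp_e=100, p_ee=0, p_ei=0,
                          p_ie=0, p_ii=0, w_init_min=19.9, w_init_max=20.0,
                          seed=0)
        liq = Liquid(build_liquid(cfg))
        rec = liq.present(constant_enc(1, 1.0, duration=100.0), "test", rng)
        times = rec.spike_times(0)
        assert len(times) > 3
        assert np.all(np.diff(times) >= liq.lif_e.t_refrac)

    def test_driven_neuron_matches_scalar_trace(self, rng):
        """Single input firing every step onto one excitatory neuron with a
        large weight: engine output equals the hand-stepped scalar trace."""
        cfg = LiquidConfig(n_inp=1, n_e=1, n_i=1, p_inp_e=100, p_ee=0, p_ei=0,
                          p_ie=0, p_ii=0, w_init_min=19.9, w_init_max=20.0,
                          seed=0)
        topo = build_liquid(cfg)
        liq = Liquid(topo)
        enc = constant_enc(1, 1.0, duration=10.0)  # 20 steps
        rec = liq.present(enc, "test", np.random.default_rng(4))
        _, _, rasters = scalar_replay(topo, liq.lif_e, liq.lif_i, liq.stdp,
                                      [enc.step_probabilities()], enc.n_steps,
                                      0.5, seed=4, mode="test")
        assert np.array_equal(rec.raster, rasters[0])


class TestTrainingReplay:
    def test_full_training_matches_scalar_replay(self, tiny_topology):
        """Ten training presentations of two patterns on the 7-neuron net:
        final plastic weights and every raster equal the independent scalar
        hand-stepped simulation of the same seed."""
        probs_a = np.zeros((4, 50)); probs_a[:2] = 0.6  # pattern A: inputs 0-1
        probs_b = np.zeros((4, 50)); probs_b[2:] = 0.6  # pattern B: inputs 2-3
        enc_a = EncodedInput(probs_a[:, 0], duration=25.0)
        enc_b = EncodedInput(probs_b[:, 0], duration=25.0)
        dataset = [(enc_a, 0), (enc_b, 1)]

        liq = tiny_liquid(tiny_topology)
        w0 = tiny_topology.w_inp_e.copy()
        schedule = TrainingSchedule(n_examples=10, seed=77)
        train(liq, dataset, schedule)

        topo_copy = dataclasses.replace(tiny_topology, w_inp_e=w0)
        probs_list = [[probs_a, probs_b][k % 2] for k in range(10)]
        w_ref, theta_ref, _ = scalar_replay(topo_copy, liq.lif_e, liq.lif_i,
                                            liq.stdp, probs_list, 50, 0.5,
                                            seed=77, mode="train")
        np.testing.assert_allclose(liq.w_inp_e, w_ref, atol=1e-12)
        np.testing.assert_allclose(liq.theta_adapt, theta_ref, atol=1e-12)

    def test_weights_move_during_training(self, tiny):
        dataset = [(constant_enc(4, 0.5), 0)]
        w0 = tiny.w_inp_e.copy()
        train(tiny, dataset, TrainingSchedule(5, seed=1))
        assert not np.array_equal(tiny.w_inp_e, w0)


class TestTrainingContracts:
    @pytest.fixture()
    def small_run(self):
        cfg = apply_overrides(load_preset("image"),
                              ["liquid.n_e=80", "liquid.n_i=20",
                               "schedule.n_examples=30",
                               "synthetic.samples_per_class=3"])
        imgs, labs = make_image_classes(cfg.synthetic)
        ds = [(encode_sample(cfg, im), int(l)) for im, l in zip(imgs, labs)]
        return cfg, ds

    def test_labels_never_influence_weights(self, small_run):
        """Unsupervised contract: permuting the labels changes only the
        class bookkeeping, never the weight trajectory."""
        cfg, ds = small_run
        finals = []
        for mangle in (False, True):
            liq = build_model(cfg)[0].liquids[0]
            ds_run = [(enc, (lab + 1) % 4 if mangle else lab)
                      for enc, lab in ds]
            train(liq, ds_run, cfg.schedule)
            finals.append(liq.w_inp_e.copy())
        assert np.array_equal(finals[0], finals[1])

    def test_recurrent_weights_stay_frozen(self, small_run):
        cfg, ds = small_run
        liq = build_model(cfg)[0].liquids[0]
        frozen_before = [liq._m_ee.copy(), liq._m_ei.copy(),
                         liq._m_ie.copy(), liq._m_ii.copy()]
        train(liq, ds, cfg.schedule)
        for before, after in zip(frozen_before,
                                 [liq._m_ee, liq._m_ei, liq._m_ie, liq._m_ii]):
            assert np.array_equal(before, after)

    def test_full_runs_are_bit_reproducible(self, small_run):
        cfg, ds = small_run
        outs = []
        for _ in range(2):
            liq = build_model(cfg)[0].liquids[0]
            counts = train(liq, ds, cfg.schedule)
            outs.append((liq.w_inp_e.copy(), liq.theta_adapt.copy(), counts))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])

    def test_mean_rate_stays_below_chaos_bound(self, small_run):
        """Sparse connectivity keeps the excitatory population well below a
        runaway regime (mean rate < 200 spikes/s)."""
        cfg, ds = small_run
        liq = build_model(cfg)[0].liquids[0]
        counts = train(liq, ds, cfg.schedule)
        total_time_s = cfg.schedule.n_examples * cfg.duration / 1000.0
        mean_rate = counts.sum() / liq.n_e / total_time_s
        assert 0 < mean_rate < 200

    def test_raster_respects_refractory_invariant(self, small_run):
        cfg, ds = small_run
        liq = build_model(cfg)[0].liquids[0]
        rec = liq.present(ds[0][0], "train", np.random.default_rng(0))
        for j in range(liq.n_e):
            t = rec.spike_times(j)
            if len(t) > 1:
                assert np.all(np.diff(t) >= liq.lif_e.t_refrac)

    def test_homeostasis_equalizes_firing_rates(self):
        """The adaptive threshold narrows the spread of per-neuron activity:
        the coefficient of variation of per-neuron spike counts in the final
        training quarter is below that of the first quarter."""
        cfg = apply_overrides(load_preset("image"),
                              ["liquid.n_e=160", "liquid.n_i=40",
                               "schedule.n_examples=300"])
        imgs, labs = make_image_classes(cfg.synthetic)
        ds = [(encode_sample(cfg, im), int(l)) for im, l in zip(imgs, labs)]
        liq = build_model(cfg)[0].liquids[0]
        _, per_pres = train(liq, ds, cfg.schedule,
                            record_presentation_counts=True)
        q = cfg.schedule.n_examples // 4
        first, final = per_pres[:q].sum(0), per_pres[-q:].sum(0)
        cv = lambda x: x.std() / x.mean()  # noqa: E731
        assert cv(final) < cv(first)

    def test_empty_dataset_rejected(self, tiny):
        with pytest.raises(ValueError):
            train(tiny, [], TrainingSchedule(1))


class TestEnsemble:
    def test_slice_encoded_picks_rows(self):
        enc = EncodedInput(np.linspace(0, 0.9, 10), duration=10.0)
        sub = slice_encoded(enc, np.array([0, 3, 7]))
        np.testing.assert_allclose(sub.firing_prob, enc.firing_prob[[0, 3, 7]])

    def test_partition_size_mismatch_rejected(self, tiny):
        with pytest.raises(ValueError):
            LiquidEnsemble([tiny], [np.arange(3)])

    def test_no_cross_liquid_coupling(self):
        """Training one ensemble member never touches another member's
        weights (liquids are fully independent)."""
        cfg = apply_overrides(load_preset("image"),
                              ["n_liquids=2", "liquid.n_e=40", "liquid.n_i=10",
                               "schedule.n_examples=10",
                               "synthetic.samples_per_class=2"])
        imgs, labs = make_image_classes(cfg.synthetic)
        ds = [(encode_sample(cfg, im), int(l)) for im, l in zip(imgs, labs)]
        ens, parts = build_model(cfg)
        w1_before = ens.liquids[1].w_inp_e.copy()
        sub0 = [(slice_encoded(enc, parts[0]), lab) for enc, lab in ds]
        train(ens.liquids[0], sub0, cfg.schedule)
        assert np.array_equal(ens.liquids[1].w_inp_e, w1_before)


class TestCheckpoints:
    def test_round_trip_preserves_state(self, tiny, tmp_path, rng):
        dataset = [(constant_enc(4, 0.4), 0)]
        counts = train(tiny, dataset, TrainingSchedule(3, seed=5))
        path = tmp_path / "ckpt.h5"
        sampler = np.random.default_rng(5)
        save_checkpoint(path, tiny, counts, 3, sampler, "echo")
        liq, counts2, seen, rng2, echo = load_checkpoint(path)
        assert seen == 3 and echo == "echo"
        assert np.array_equal(liq.w_inp_e, tiny.w_inp_e)
        assert np.array_equal(liq.theta_adapt, tiny.theta_adapt)
        assert np.array_equal(counts2, counts)
        assert np.array_equal(rng2.random(5), np.random.default_rng(5).random(5))

    def test_resumed_run_matches_uninterrupted_run(self, tiny_topology,
                                                   tmp_path):
        dataset = [(constant_enc(4, 0.5), 0), (constant_enc(4, 0.2), 1)]
        # one shot: 8 presentations
        liq_full = tiny_liquid(build_fresh(tiny_topology))
        rng_full = np.random.default_rng(9)
        c_full = train(liq_full, dataset, TrainingSchedule(8, seed=9),
                       rng=rng_full)
        # split: 4 presentations, checkpoint, resume for 4 more
        liq_a = tiny_liquid(build_fresh(tiny_topology))
        rng_a = np.random.default_rng(9)
        c_a = train(liq_a, dataset, TrainingSchedule(4, seed=9), rng=rng_a)
        path = tmp_path / "half.h5"
        save_checkpoint(path, liq_a, c_a, 4, rng_a)
        liq_b, c_b, seen, rng_b, _ = load_checkpoint(path)
        c_more = train(liq_b, dataset, TrainingSchedule(8, seed=9), rng=rng_b,
                       start_index=seen)
        np.testing.assert_array_equal(liq_b.w_inp_e, liq_full.w_inp_e)
        np.testing.assert_array_equal(c_b + c_more, c_full)


def build_fresh(topo):
    return build_liquid(topo.config)
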