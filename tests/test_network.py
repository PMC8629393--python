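"""Network assembly, kernel correctness, determinism, checkpoints, variants."""

import numpy as np
import pytest

from plasticv1.adex import AdexState
from plasticv1.adex import adex_step
from plasticv1.network import (
    NetworkConfig,
    build_network,
    load_checkpoint,
    present_stimulus,
    save_checkpoint,
    train,
)
from plasticv1.plasticity import ClopathTraces, clopath_update, decay_trace, istdp_update
from plasticv1.stimuli import WhitenedScene, on_off_split
from plasticv1.synthetic import generate_scene_set


def tiny_config(variant="EI2/1", seed=0, **kw):
    return NetworkConfig(variant=variant, seed=seed, n_exc=8, n_inh=2,
                         n_stimuli=10, **kw)


def random_rates(rng, r_max=125.0):
    return on_off_split(rng.uniform(-1, 1, (12, 12)), r_max)


class TestBuild:
    def test_default_sizes_and_projections(self):
        net = build_network(NetworkConfig())
        assert (net.config.n_lgn, net.config.n_exc, net.config.n_inh) == (288, 144, 36)
        assert set(net.weights) == {"lgn_e", "lgn_i", "e_i", "i_e", "i_i"}
        assert np.all(np.diag(net.weights["i_i"]) == 0)  # no self-inhibition
        # inhibitory weights start at zero, excitatory within init bounds
        assert np.all(net.weights["i_e"] == 0)
        lo, hi = net.clopath_params["lgn_e"].w_init
        assert np.all((net.weights["lgn_e"] >= lo) & (net.weights["lgn_e"] <= hi))

    def test_ratio_enforced(self):
        with pytest.raises(ValueError, match="4:1"):
            NetworkConfig(n_exc=10, n_inh=3)

    def test_noinh_has_no_inhibitory_population(self):
        net = build_network(NetworkConfig(variant="noInh"))
        assert net.config.n_inh == 0
        _, tr = present_stimulus(net, random_rates(np.random.default_rng(0)))
        assert np.all(tr["i_inh"] == 0)

    def test_fix_variant_requires_reference(self):
        with pytest.raises(ValueError, match="reference"):
            build_network(tiny_config("fix_fb_inh"))

    def test_shuffled_reference_preserves_multiset(self):
        ref_net = build_network(tiny_config(seed=3))
        ref = {k: v + 0.01 for k, v in ref_net.weights.items()}
        net = build_network(tiny_config("fix_fb_inh", seed=4), reference_weights=ref)
        for key in ("lgn_i", "e_i", "i_e"):
            np.testing.assert_allclose(
                np.sort(net.weights[key].ravel()), np.sort(ref[key].ravel())
            )
        # LGN->E is re-drawn, not shuffled reference
        assert not np.allclose(np.sort(net.weights["lgn_e"].ravel()),
                               np.sort(ref["lgn_e"].ravel()))


class TestKernelAgainstReferenceOps:
    def test_fused_kernel_matches_composed_reference_operations(self):
        """The numba presentation kernel reproduces the step-by-step
        composition of the public lgn/adex/plasticity operations."""
        cfg = tiny_config(seed=7)
        net = build_network(cfg)
        w0 = {k: v.copy() for k, v in net.weights.items()}
        rng = np.random.default_rng(5)
        rates = random_rates(rng)
        r = rates.flat()
        T = cfg.presentation_ms
        n_pres = 3
        uniforms = [net.rng["poisson"].random((T, cfg.n_lgn)) for _ in range(n_pres)]

        # --- reference path: public operations composed in the global order
        C = net.params.C
        nL, nE, nI = cfg.n_lgn, cfg.n_exc, cfg.n_inh
        stE = AdexState(n=nE, params=net.params)
        stI = AdexState(n=nI, params=net.params)
        tr_le = ClopathTraces(n_pre=nL, n_post=nE)
        tr_li = ClopathTraces(n_pre=nL, n_post=nI)
        tr_ei = ClopathTraces(n_pre=nE, n_post=nI)
        xiE, xiI = np.zeros(nE), np.zeros(nI)
        sL_prev = np.zeros(nL)
        sE_prev = np.zeros(nE)
        sI_prev = np.zeros(nI)
        W = {k: v.copy() for k, v in w0.items()}
        ref_spikes_e = []
        for p_idx in range(n_pres):
            for t in range(T):
                sL = (uniforms[p_idx][t] < r * 1e-3).astype(float)
                excE = C * (W["lgn_e"].T @ sL_prev)
                inhE = C * (W["i_e"].T @ sI_prev)
                excI = C * (W["lgn_i"].T @ sL_prev + W["e_i"].T @ sE_prev)
                inhI = C * (W["i_i"].T @ sI_prev)
                sE = adex_step(stE, excE, inhE).astype(float)
                sI = adex_step(stI, excI, inhI).astype(float)
                clopath_update(W["lgn_e"], tr_le, sL, stE.u, net.clopath_params["lgn_e"])
                clopath_update(W["lgn_i"], tr_li, sL, stI.u, net.clopath_params["lgn_i"])
                clopath_update(W["e_i"], tr_ei, sE, stI.u, net.clopath_params["e_i"])
                decay_trace(xiE, sE, 10.0)
                decay_trace(xiI, sI, 10.0)
                istdp_update(W["i_e"], xiI, xiE, sI, sE, net.istdp_params["i_e"])
                istdp_update(W["i_i"], xiI, xiI, sI, sI, net.istdp_params["i_i"])
                np.fill_diagonal(W["i_i"], 0.0)
                sL_prev, sE_prev, sI_prev = sL, sE, sI
                ref_spikes_e.append(sE.copy())

        # --- kernel path on an identically initialized network
        net2 = build_network(tiny_config(seed=7))
        for k in net2.weights:
            np.testing.assert_array_equal(net2.weights[k], w0[k])
        kernel_spikes = []
        for p_idx in range(n_pres):
            net2.rng["poisson"] = _FixedUniforms(uniforms[p_idx])
            _, tr = present_stimulus(net2, rates, plastic=True)
            kernel_spikes.append(tr["spikes_e"])
        kernel_spikes = np.concatenate(kernel_spikes).astype(float)

        np.testing.assert_array_equal(kernel_spikes, np.asarray(ref_spikes_e))
        for k in W:
            np.testing.assert_allclose(net2.weights[k], W[k], rtol=1e-9, atol=1e-12)


class _FixedUniforms:
    """Stands in for the Poisson substream with predetermined uniforms."""

    def __init__(self, values):
        self.values = values

    def random(self, shape):
        assert shape == self.values.shape
        return self.values


class TestPresentStimulus:
    def test_zero_rates_are_silent(self):
        net = build_network(tiny_config())
        rec, tr = present_stimulus(net, np.zeros(288))
        assert rec.time_ms.size == 0
        assert tr["spikes_e"].sum() == 0

    def test_identical_seed_gives_bit_identical_record(self):
        rng = np.random.default_rng(9)
        rates = random_rates(rng)
        records = []
        for _ in range(2):
            net = build_network(tiny_config(seed=31))
            rec, _ = present_stimulus(net, rates, plastic=True)
            records.append(rec)
        np.testing.assert_array_equal(records[0].time_ms, records[1].time_ms)
        np.testing.assert_array_equal(records[0].neuron, records[1].neuron)
        np.testing.assert_array_equal(records[0].population, records[1].population)

    def test_spike_times_inside_window(self):
        net = build_network(tiny_config(seed=2))
        rec, _ = present_stimulus(net, random_rates(np.random.default_rng(1)))
        assert rec.window == (0.0, 125.0)
        if rec.time_ms.size:
            assert rec.time_ms.min() > 0.0
            assert rec.time_ms.max() <= 125.0

    def test_bad_duration_rejected(self):
        net = build_network(tiny_config())
        with pytest.raises(ValueError, match="multiple"):
            present_stimulus(net, np.zeros(288), duration=12.5)


class TestTraining:
    def test_zero_stimuli_is_noop(self):
        net = build_network(tiny_config())
        before = {k: v.copy() for k, v in net.weights.items()}
        scenes = generate_scene_set(2, np.random.default_rng(0), size=32)
        train(net, scenes, n_stimuli=0)
        for k, v in before.items():
            np.testing.assert_array_equal(net.weights[k], v)

    def test_training_log_records_blocks(self):
        net = build_network(tiny_config(seed=5))
        scenes = generate_scene_set(2, np.random.default_rng(0), size=32)
        log = train(net, scenes, n_stimuli=60, log_every=20)
        assert log.block_end == [20, 40, 60]
        assert all(dw >= 0 for dw in log.mean_abs_dw)

    def test_runaway_weight_detector(self):
        net = build_network(tiny_config("noInh", seed=1))
        net.weights["lgn_e"][:] = net.clopath_params["lgn_e"].w_max
        silent = [WhitenedScene(np.zeros((32, 32)))]
        with pytest.raises(RuntimeError, match="runaway"):
            train(net, silent, n_stimuli=1, log_every=1)

    def test_frozen_projection_is_immutable(self):
        ref_net = build_network(tiny_config(seed=3))
        cfg = tiny_config("fix_fb_inh", seed=4)
        net = build_network(cfg, reference_weights=ref_net.weights)
        frozen = net.weights["i_e"].copy()
        scenes = generate_scene_set(2, np.random.default_rng(0), size=32)
        train(net, scenes, n_stimuli=30)
        np.testing.assert_array_equal(net.weights["i_e"], frozen)

    def test_block_inhibition_shares_feedforward_weights(self):
        net = build_network(tiny_config(seed=6))
        scenes = generate_scene_set(2, np.random.default_rng(0), size=32)
        train(net, scenes, n_stimuli=20)
        blocked = net.with_blocked_inhibition()
        np.testing.assert_array_equal(
            blocked.weights["lgn_e"], net.weights["lgn_e"]
        )
        _, tr = present_stimulus(blocked, random_rates(np.random.default_rng(2)))
        assert np.all(tr["i_inh"] == 0)


class TestCheckpoints:
    def test_checkpoint_restore_is_bit_identical(self, tmp_path):
        """Save -> restore -> continue reproduces an uninterrupted run."""
        scenes = generate_scene_set(2, np.random.default_rng(0), size=32)
        path = str(tmp_path / "ckpt.npz")

        net_a = build_network(tiny_config(seed=11))
        train(net_a, scenes, n_stimuli=25)
        save_checkpoint(net_a, path)
        train(net_a, scenes, n_stimuli=25)

        net_b = load_checkpoint(path)
        train(net_b, scenes, n_stimuli=25)

        for k in net_a.weights:
            np.testing.assert_array_equal(net_a.weights[k], net_b.weights[k])
        np.testing.assert_array_equal(net_a.uE, net_b.uE)
        np.testing.assert_array_equal(net_a.xL, net_b.xL)
        assert net_a.t_ms == net_b.t_ms

    def test_checkpoint_roundtrip_preserves_config(self, tmp_path):
        net = build_network(tiny_config("EI3/1", seed=2))
        path = str(tmp_path / "c.npz")
        save_checkpoint(net, path)
        restored = load_checkpoint(path)
        assert restored.config == net.config
        assert restored.istdp_params["i_e"].rho == pytest.approx(0.7)
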