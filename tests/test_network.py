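"""Network structure, forward-pass semantics, gradients, lesions, checkpoints."""

import numpy as np
import pytest

from mscausal import network
from mscausal.network import (
    Architecture,
    FULL_ARCH,
    count_parameters,
    forward,
    init_network,
    lesion_forward,
)


@pytest.fixture(scope="module")
def full_zero_fc_params():
    return init_network(0, "zero_fc", FULL_ARCH)


class TestArchitecture:
    def test_full_scale_layer_parameter_counts(self, full_zero_fc_params):
        counts = count_parameters(full_zero_fc_params)
        assert counts["V1"] == 55_360
        assert counts["MT"] == 2_986_048
        assert counts["PIVC"] == 1_548
        assert counts["MSTd"] == 4_940

    def test_v1_map_geometry(self):
        a = FULL_ARCH
        assert a.conv_out == 53
        assert a.n_kernels * a.conv_out**2 == 179_776
        assert a.pooled == 27  # ceil-mode 2x2 pooling: 53 -> 27
        assert a.mt_in == 46_656

    def test_zero_fc_init_scheme(self, full_zero_fc_params):
        p = full_zero_fc_params
        assert np.all(p.mt_w == 0) and np.all(p.out_w == 0)
        assert np.all(p.mt_b == 0) and np.all(p.mstd_in_offsets == 0)
        assert p.v1_kernels.std() == pytest.approx(0.001, rel=0.05)
        assert abs(p.v1_kernels.mean()) < 1e-4

    def test_init_deterministic_per_seed(self, tiny_arch):
        a = init_network(5, "he", tiny_arch)
        b = init_network(5, "he", tiny_arch)
        for name in a.ARRAY_FIELDS:
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_unknown_scheme_rejected(self, tiny_arch):
        with pytest.raises(ValueError):
            init_network(0, "xavier", tiny_arch)


class TestForward:
    def test_zero_network_outputs(self, tiny_arch, rng):
        p = init_network(0, "zero_fc", tiny_arch)
        p.v1_kernels[:] = 0
        vis = rng.uniform(-1, 1, (tiny_arch.image_size, tiny_arch.image_size, 6))
        vest = rng.uniform(0, 1, (4, tiny_arch.vest_units))
        acts = forward(p, vis, vest)
        np.testing.assert_array_equal(acts.fusion, 0)
        np.testing.assert_array_equal(acts.scission, 0)
        np.testing.assert_array_equal(acts.causal, 0.5)

    def test_delta_kernel_on_constant_input(self, tiny_arch):
        # a single delta kernel with zero offsets copies the (rectified) input
        p = init_network(0, "zero_fc", tiny_arch)
        p.v1_kernels[:] = 0
        p.v1_kernels[0, 2, 3, 1] = 1.0
        for c in (0.7, -0.4):
            vis = np.full((tiny_arch.image_size, tiny_arch.image_size, 6), c)
            vest = np.zeros((4, tiny_arch.vest_units))
            acts = forward(p, vis, vest)
            np.testing.assert_allclose(acts.v1[:, :, 0], max(c, 0.0), atol=1e-6)

    def test_all_preoutput_activations_nonnegative(self, tiny_arch, rng):
        p = init_network(3, "he", tiny_arch)
        vis = rng.uniform(-1, 1, (tiny_arch.image_size, tiny_arch.image_size, 6))
        vest = rng.normal(0.5, 0.3, (4, tiny_arch.vest_units))
        acts = forward(p, vis, vest)
        for name in ("v1", "pooled", "mt", "pivc", "mstd"):
            assert getattr(acts, name).min() >= 0
        assert np.all((acts.causal > 0) & (acts.causal < 1))

    def test_forward_deterministic_and_batched(self, tiny_arch, rng):
        p = init_network(4, "he", tiny_arch)
        vis = rng.uniform(-1, 1, (3, tiny_arch.image_size, tiny_arch.image_size, 6))
        vest = rng.uniform(0, 1, (3, 4 * tiny_arch.vest_units))
        batch = forward(p, vis, vest)
        single = forward(p, vis[1], vest[1].reshape(4, -1))
        np.testing.assert_allclose(batch.fusion[1], single.fusion, rtol=1e-5)
        np.testing.assert_allclose(batch.mstd[1], single.mstd, rtol=1e-5)

    def test_shape_mismatch_raises(self, tiny_arch, rng):
        p = init_network(0, "he", tiny_arch)
        with pytest.raises(ValueError, match="visual input shape"):
            forward(p, rng.uniform(-1, 1, (8, 8, 6)), np.zeros((4, tiny_arch.vest_units)))
        with pytest.raises(ValueError, match="vestibular input"):
            forward(
                p,
                rng.uniform(-1, 1, (tiny_arch.image_size, tiny_arch.image_size, 6)),
                np.zeros(7),
            )

    def test_ceil_mode_pooling_covers_edges(self):
        arch = Architecture(image_size=9, kernel_size=4, n_kernels=1,
                            mt_units=2, pivc_units=2, mstd_units=2, vest_units=2)
        assert arch.conv_out == 6 and arch.pooled == 3
        arch2 = Architecture(image_size=10, kernel_size=4, n_kernels=1,
                             mt_units=2, pivc_units=2, mstd_units=2, vest_units=2)
        assert arch2.conv_out == 7 and arch2.pooled == 4  # 7 -> ceil(7/2)
        p = init_network(0, "he", arch2)
        vis = np.ones((arch2.image_size, arch2.image_size, 6))
        acts = forward(p, vis, np.zeros((4, arch2.vest_units)))
        assert acts.pooled.shape == (4, 4, 1)
        assert np.isfinite(acts.pooled).all()


class TestLesions:
    @pytest.fixture()
    def setup(self, tiny_arch, rng):
        p = init_network(9, "he", tiny_arch)
        vis = rng.uniform(-1, 1, (tiny_arch.image_size, tiny_arch.image_size, 6))
        vest = rng.uniform(0, 1, (4, tiny_arch.vest_units))
        return p, vis, vest

    def test_empty_lesion_is_identity(self, setup):
        p, vis, vest = setup
        a = forward(p, vis, vest)
        b = lesion_forward(p, vis, vest, [])
        np.testing.assert_array_equal(a.fusion, b.fusion)
        np.testing.assert_array_equal(a.causal, b.causal)

    def test_full_lesion_leaves_only_offsets(self, setup):
        p, vis, vest = setup
        acts = lesion_forward(p, vis, vest, range(p.arch.mstd_units))
        np.testing.assert_allclose(acts.fusion, p.out_b[:4], atol=1e-7)
        np.testing.assert_allclose(acts.scission, p.out_b[4:8], atol=1e-7)

    def test_single_lesion_is_linear_in_unit_activity(self, setup):
        p, vis, vest = setup
        intact = forward(p, vis, vest)
        j = 3
        lesioned = lesion_forward(p, vis, vest, [j])
        expected = intact.mstd[j] * p.out_w[j, :8]
        got = np.concatenate(
            [intact.fusion - lesioned.fusion, intact.scission - lesioned.scission]
        )
        np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-7)

    def test_invalid_indices_rejected(self, setup):
        p, vis, vest = setup
        with pytest.raises(ValueError):
            lesion_forward(p, vis, vest, [p.arch.mstd_units])


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_arch, rng):
        from mscausal.training import LabelSet, TrainConfig, composite_loss, _output_grad

        p = init_network(1, "he", tiny_arch)
        for n in p.ARRAY_FIELDS:
            setattr(p, n, getattr(p, n).astype(np.float64))
        vis = rng.uniform(-1, 1, (2, tiny_arch.image_size, tiny_arch.image_size, 6))
        vest = rng.uniform(0, 1, (2, 4 * tiny_arch.vest_units))
        cfg = TrainConfig(arch=tiny_arch)
        labels = LabelSet(
            fusion=rng.uniform(-4, 4, (2, 4)),
            scission=rng.uniform(-8, 8, (2, 4)),
            causal=rng.integers(0, 2, (2, 4)).astype(float),
        )

        def loss_of():
            acts, _ = network._forward_full(p, vis, vest)
            return composite_loss(
                acts.fusion, acts.scission,
                np.clip(acts.causal, 1e-12, 1 - 1e-12), labels, cfg,
            )["total"]

        acts, cache = network._forward_full(p, vis, vest)
        grads = network.backward(p, cache, _output_grad(acts, labels, cfg))
        eps = 1e-6
        for name in p.ARRAY_FIELDS:
            arr = getattr(p, name)
            flat_idx = rng.choice(arr.size, size=min(6, arr.size), replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, arr.shape)
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = loss_of()
                arr[ix] = orig - eps
                lm = loss_of()
                arr[ix] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name][ix]
                assert an == pytest.approx(fd, rel=1e-3, abs=1e-9), name


class TestCheckpoints:
    def test_roundtrip_and_validation(self, tiny_arch, tmp_path):
        p = init_network(2, "he", tiny_arch)
        network.save_params(tmp_path / "ckpt", p, meta={"epoch": 3})
        q = network.load_params(tmp_path / "ckpt")
        assert q.arch == tiny_arch
        for name in p.ARRAY_FIELDS:
            np.testing.assert_array_equal(getattr(p, name), getattr(q, name))

    def test_corrupted_counts_rejected(self, tiny_arch, tmp_path):
        import json

        p = init_network(2, "he", tiny_arch)
        network.save_params(tmp_path / "ckpt", p)
        side = json.loads((tmp_path / "ckpt.json").read_text())
        side["param_counts"]["V1"] += 1
        (tmp_path / "ckpt.json").write_text(json.dumps(side))
        with pytest.raises(ValueError, match="parameter count"):
            network.load_params(tmp_path / "ckpt")
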