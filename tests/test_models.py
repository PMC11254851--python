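"""Architecture construction, forward contracts, and the fine-tuning freeze."""

import numpy as np
import pytest

from ecgage import models, nn
from ecgage.nn import Adam


def _batch(n=3, L=1024, seed=0, scale=0.3):
    return np.random.default_rng(seed).normal(0, scale, (n, 12, L)).astype(np.float32)


class TestBuildAttianet:
    def test_kernel_schedule_boundaries(self):
        cfg = models.ATTIA_DEFAULT
        assert cfg.kernels[0] == 7
        assert cfg.kernels[-1] == 3
        assert set(cfg.kernels[1:-1]) <= {5, 3}
        assert len(cfg.filters) == 8  # eight temporal blocks

    def test_block_operator_order(self):
        g = models.build_attianet(input_len=1024)
        kinds = [d["kind"] for d in g.descriptors()]
        # each temporal block: conv -> batchnorm -> relu -> maxpool
        for i in range(8):
            assert kinds[4 * i:4 * i + 4] == ["conv1d", "batchnorm", "relu",
                                              "maxpool"]
        assert "spatial_conv" in kinds
        assert kinds[-1] == "linear"

    def test_off_grid_input_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            models.build_attianet(input_len=1000)

    def test_input_below_receptive_field_rejected(self):
        cfg = models.AttiaConfig(filters=(4,) * 8, kernels=(7,) + (5,) * 6 + (3,),
                                 pools=(4,) * 8, spatial_filters=4,
                                 spatial_pool=2, head=(4, 4, 4))
        # net reduction 4^8 * 2 = 131072 > 1024
        with pytest.raises(ValueError, match="reduction"):
            models.build_attianet(cfg, input_len=1024)


class TestBuildResnet1d:
    def test_channel_schedule(self):
        g = models.build_resnet1d(input_len=1024)
        convs = [d for d in g.descriptors() if d["kind"] == "conv1d"]
        assert convs[0]["out_ch"] == 64
        mains = [d["out_ch"] for d in convs if d["name"].endswith("conv2")]
        assert mains == [128, 192, 256, 320]

    def test_residual_block_structure_audit(self):
        # automated walker: each block holds exactly the operator sequence
        # main conv->BN->ReLU->dropout->conv, pooled 1x1 skip, merge before
        # the closing BN->ReLU->dropout
        g = models.build_resnet1d(input_len=1024)
        blocks = g.residual_blocks()
        assert len(blocks) == 4
        for blk in blocks:
            descs = blk.descriptors(1024)
            kinds = [d["kind"] for d in descs]
            assert kinds == ["conv1d", "batchnorm", "relu", "dropout",
                             "conv1d", "maxpool", "conv1d", "add",
                             "batchnorm", "relu", "dropout"]
            assert kinds.count("dropout") == 2
            skip = [d for d in descs if d.get("path") == "skip"]
            assert [d["kind"] for d in skip] == ["maxpool", "conv1d"]
            assert skip[1]["kernel"] == 1
            # merge happens before the final batchnorm
            assert kinds.index("add") < len(kinds) - 1 - kinds[::-1].index("batchnorm")

    def test_temporal_reduction_per_block(self):
        g = models.build_resnet1d(input_len=5120)
        lens = [blk.out_len(5120 // 4 ** i)
                for i, blk in enumerate(g.residual_blocks())]
        assert lens == [1280, 320, 80, 20]


class TestParameterLinearity:
    @pytest.mark.parametrize("build,slope", [
        (models.build_attianet, 6144),
        (models.build_resnet1d, 81920),
    ])
    def test_total_params_affine_in_input_len(self, build, slope):
        totals = [build(input_len=L).num_params()
                  for L in (1024, 2048, 3072, 4096, 5120)]
        deltas = set(np.diff(totals).tolist())
        assert deltas == {slope * 1024 // 4096}


class TestForward:
    def test_zero_weights_give_zero_output(self):
        g = models.build_attianet(models.ATTIA_REDUCED, input_len=1024)
        for p in g.parameters():
            p.value[...] = 0.0
        out = g.forward(_batch())
        assert np.all(out == 0.0)

    def test_batch_permutation_equivariance(self):
        g = models.build_resnet1d(models.RESNET_REDUCED, input_len=1024, seed=4)
        x = _batch(n=6)
        out = g.forward(x)
        perm = np.array([3, 1, 5, 0, 2, 4])
        assert np.allclose(g.forward(x[perm]), out[perm], atol=1e-4)

    @pytest.mark.parametrize("seed", range(12))
    def test_outputs_finite_and_nonconstant(self, seed):
        g = models.build_attianet(models.ATTIA_REDUCED, input_len=1024,
                                  seed=seed)
        out = g.forward(_batch(n=5, seed=seed + 100))
        assert np.all(np.isfinite(out))
        assert out.std() > 0.0

    def test_shape_mismatch_names_lengths(self):
        g = models.build_attianet(models.ATTIA_REDUCED, input_len=2048)
        with pytest.raises(ValueError, match="2048"):
            g.forward(_batch(L=1024))

    def test_single_scalar_per_record_on_any_grid_length(self):
        for L in (1024, 3072):
            g = models.build_attianet(models.ATTIA_REDUCED, input_len=L)
            assert g.forward(_batch(n=4, L=L)).shape == (4,)


class TestFreezeScope:
    def test_boundary_none_all_trainable(self):
        g = models.build_resnet1d(models.RESNET_REDUCED, input_len=1024)
        models.freeze_scope(g, "none")
        assert all(p.trainable for p in g.parameters())

    def test_through_resblock3_mask(self):
        g = models.build_resnet1d(input_len=4096)
        mask = models.freeze_scope(g, "through_resblock3")
        assert not any(v for k, v in mask.items() if k.startswith(
            ("initial.", "resblock1.", "resblock2.", "resblock3.")))
        assert all(v for k, v in mask.items() if k.startswith("resblock4."))
        assert mask["head.out.weight"] and mask["head.out.bias"]
        assert g.num_params(trainable_only=True) == 3217901

    def test_unknown_boundary_rejected(self):
        g = models.build_resnet1d(models.RESNET_REDUCED, input_len=1024)
        with pytest.raises(ValueError, match="boundary"):
            models.freeze_scope(g, "through_resblock9")
        g2 = models.build_attianet(models.ATTIA_REDUCED, input_len=1024)
        with pytest.raises(ValueError, match="residual"):
            models.freeze_scope(g2, "through_resblock3")

    def test_frozen_tensors_untouched_by_optimization(self):
        g = models.build_resnet1d(models.RESNET_REDUCED, input_len=1024, seed=1)
        models.freeze_scope(g, "through_resblock3")
        frozen_before = {p.name: p.value.copy() for p in g.parameters()
                         if not p.trainable}
        buffers_before = {k: v.copy() for k, v in g.named_buffers().items()
                          if not k.startswith(("resblock4.", "head.out."))}
        opt = Adam(g.parameters(), lr=1e-2)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(0, 0.3, (4, 12, 1024)).astype(np.float32)
            y = rng.uniform(20, 80, 4)
            pred = g.forward(x, train=True)
            opt.zero_grad()
            g.backward((2 * (pred - y) / 4).astype(np.float32))
            opt.step()
        for p in g.parameters():
            if not p.trainable:
                assert np.array_equal(p.value, frozen_before[p.name]), p.name
        # frozen batch norms hold their running statistics too
        for k, v in g.named_buffers().items():
            if k in buffers_before:
                assert np.array_equal(v, buffers_before[k]), k
        trainable = [p for p in g.parameters() if p.trainable]
        assert any(True for _ in trainable)


class TestSerialization:
    def test_weights_round_trip_and_manifest(self, tmp_path):
        g = models.build_resnet1d(models.RESNET_REDUCED, input_len=1024, seed=5)
        models.save_weights(g, tmp_path / "w")
        g2 = models.build_resnet1d(models.RESNET_REDUCED, input_len=1024, seed=6)
        models.load_weights(g2, tmp_path / "w")
        x = _batch(n=2)
        assert np.allclose(g.forward(x), g2.forward(x))
        # disk size is exactly 4 bytes per parameter (+ buffers)
        n = g.num_params() + sum(b.size for b in g.named_buffers().values())
        assert (tmp_path / "w.bin").stat().st_size == 4 * n

    def test_manifest_mismatch_names_layers(self, tmp_path):
        g = models.build_resnet1d(models.RESNET_REDUCED, input_len=1024)
        models.save_weights(g, tmp_path / "w")
        other = models.build_resnet1d(
            models.ResNetConfig(initial_filters=8, initial_kernel=9,
                                block_channels=(12, 16, 20, 28),
                                block_kernel=9, dropout=0.1, head=(8, 12, 6)),
            input_len=1024)
        with pytest.raises(ValueError, match="resblock4"):
            models.load_weights(other, tmp_path / "w")
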