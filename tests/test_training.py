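"""Five-step update routing, batch pairing, determinism and convergence."""

import hashlib

import numpy as np
import pytest

from ddseg.losses import LossWeights
from ddseg.synthetic_data import make_domain_datasets
from ddseg.training import LOG_COLUMNS, Trainer, TrainConfig, pair_batches, train


def param_hash(params):
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


@pytest.fixture(scope="module")
def small_data():
    return make_domain_datasets(16, 16, seed=100)


def _groups(tr: Trainer):
    g = {
        "encoder": tr.generator.encoder_parameters(),
        "decoder1": tr.generator.decoder1_parameters(),
        "decoder2": tr.generator.decoder2_parameters(),
    }
    if tr.disc_e is not None:
        g["disc_e"] = tr.disc_e.parameters()
    if tr.disc_d is not None:
        g["disc_d"] = tr.disc_d.parameters()
    return g


def hashes(tr):
    return {k: param_hash(v) for k, v in _groups(tr).items()}


class TestGradientRouting:
    """Each of the five steps updates exactly the stated sub-networks."""

    @pytest.fixture()
    def setup(self, small_data):
        src, tgt = small_data
        # learning rates large enough that every touched float32 weight moves
        cfg = TrainConfig(
            mode="dd_uda", epochs=1, seed=3, base_channels=4,
            lr_generator=1e-2, lr_discriminators=1e-2,
            weights=LossWeights(lambda_b=0.2, lambda_adv_e=0.5, lambda_adv_d=0.5),
        )
        tr = Trainer(cfg)
        batch = (src["images"][:4], src["masks"][:4], src["boundaries"][:4])
        return tr, batch, tgt["images"][:4]

    def test_step1_updates_encoder_and_decoder1_only(self, setup):
        tr, (imgs, masks, bnds), tgt = setup
        before = hashes(tr)
        tr.step1_segmentation(imgs, masks)
        after = hashes(tr)
        changed = {k for k in before if before[k] != after[k]}
        assert changed == {"encoder", "decoder1"}

    def test_step2_updates_encoder_and_decoder2_only(self, setup):
        tr, (imgs, masks, bnds), tgt = setup
        before = hashes(tr)
        tr.step2_boundary(imgs, bnds)
        after = hashes(tr)
        assert {k for k in before if before[k] != after[k]} == {"encoder", "decoder2"}

    def test_step3_updates_generator_segmentation_path_only(self, setup):
        tr, (imgs, masks, bnds), tgt = setup
        before = hashes(tr)
        tr.step3_adversarial(tgt)
        after = hashes(tr)
        changed = {k for k in before if before[k] != after[k]}
        assert changed == {"encoder", "decoder1"}

    def test_steps4_and_5_update_their_discriminator_only(self, setup):
        tr, (imgs, masks, bnds), tgt = setup
        _, _, f_t, h_t = tr.step3_adversarial(tgt)
        f_s, h_s = tr.source_outputs_detached(imgs)
        before = hashes(tr)
        tr.step4_classify_features(f_s, f_t)
        mid = hashes(tr)
        assert {k for k in before if before[k] != mid[k]} == {"disc_e"}
        tr.step5_classify_heatmaps(h_s, h_t)
        after = hashes(tr)
        assert {k for k in mid if mid[k] != after[k]} == {"disc_d"}

    def test_full_iteration_leaves_discriminators_changed_only_by_cls_steps(self, setup):
        tr, batch, tgt = setup
        rec = tr.train_iteration(batch, tgt)
        assert rec.l_cls_e > 0 and rec.l_cls_d > 0 and rec.l_seg > 0


class TestModes:
    def test_supervised_has_no_discriminators_and_zero_adv_losses(self, small_data):
        src, _ = small_data
        cfg = TrainConfig(mode="supervised", epochs=1, seed=1, base_channels=4)
        tr = Trainer(cfg)
        assert tr.disc_e is None and tr.disc_d is None
        rec = tr.train_iteration((src["images"][:2], src["masks"][:2], src["boundaries"][:2]))
        assert rec.l_adv_e == rec.l_adv_d == rec.l_cls_e == rec.l_cls_d == 0.0
        assert rec.l_seg > 0 and rec.l_b > 0

    def test_uda_output_has_only_output_discriminator(self, small_data):
        src, tgt = small_data
        cfg = TrainConfig(mode="uda_output", epochs=1, seed=1, base_channels=4)
        tr = Trainer(cfg)
        assert tr.disc_e is None and tr.disc_d is not None
        rec = tr.train_iteration(
            (src["images"][:2], src["masks"][:2], src["boundaries"][:2]), tgt["images"][:2]
        )
        assert rec.l_adv_e == 0.0 and rec.l_adv_d > 0
        assert rec.l_cls_e == 0.0 and rec.l_cls_d > 0

    def test_boundary_disabled_skips_decoder2(self, small_data):
        src, _ = small_data
        cfg = TrainConfig(mode="supervised", boundary_enabled=False, epochs=1, seed=1, base_channels=4)
        tr = Trainer(cfg)
        assert tr.generator.decoder2 is None
        rec = tr.train_iteration((src["images"][:2], src["masks"][:2], src["boundaries"][:2]))
        assert rec.l_b == 0.0

    def test_adaptation_mode_requires_target(self, small_data):
        src, _ = small_data
        cfg = TrainConfig(mode="dd_uda", epochs=1, seed=1, base_channels=4)
        with pytest.raises(ValueError):
            Trainer(cfg).train_iteration((src["images"][:2], src["masks"][:2], src["boundaries"][:2]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(mode="nonsense")
        with pytest.raises(ValueError):
            TrainConfig(lr_generator=0)
        with pytest.raises(ValueError):
            TrainConfig(image_size=40)


class TestPairBatches:
    def test_step_counts(self):
        assert len(list(pair_batches(range(10), range(10), 5, seed=0))) == 2
        assert len(list(pair_batches(range(10), range(4), 2, seed=0))) == 5

    def test_smaller_set_wraps_and_covers(self):
        batches = list(pair_batches(range(10), range(4), 2, seed=0))
        tgt_idx = [i for _, t in batches for i in t]
        assert len(tgt_idx) == 10
        assert set(tgt_idx) == {0, 1, 2, 3}  # every target sample visited

    def test_larger_set_visited_exactly_once(self):
        batches = list(pair_batches(range(10), range(4), 2, seed=0))
        src_idx = [i for s, _ in batches for i in s]
        assert sorted(src_idx) == list(range(10))

    def test_different_seeds_give_different_pairings(self):
        a = list(pair_batches(range(10), range(10), 5, seed=0))
        b = list(pair_batches(range(10), range(10), 5, seed=1))
        assert a != b

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            list(pair_batches([], range(4), 2, seed=0))


class TestTrainLoop:
    def test_epochs_zero_returns_initial_weights(self, small_data):
        src, tgt = small_data
        cfg = TrainConfig(mode="supervised", epochs=0, seed=5, base_channels=4)
        trainer, history = train(cfg, src)
        assert history == []
        assert param_hash(trainer.generator.parameters()) == param_hash(Trainer(cfg).generator.parameters())

    def test_seeded_rerun_reproduces_loss_log(self, small_data, tmp_path):
        src, tgt = small_data
        cfg = TrainConfig(
            mode="dd_uda", epochs=2, seed=7, base_channels=4, batch_size=8,
            lr_generator=1e-3, lr_discriminators=1e-4,
        )
        train(cfg, src, tgt, log_path=tmp_path / "a.csv")
        train(cfg, src, tgt, log_path=tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_loss_log_structure_and_finiteness(self, small_data, tmp_path):
        import csv

        src, tgt = small_data
        cfg = TrainConfig(mode="uda_output", epochs=1, seed=2, base_channels=4, batch_size=8)
        train(cfg, src, tgt, log_path=tmp_path / "log.csv")
        with open(tmp_path / "log.csv") as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == list(LOG_COLUMNS)
        assert len(rows) == 1 + 2  # header + ceil(16/8) iterations
        for row in rows[1:]:
            assert all(np.isfinite(float(v)) for v in row)

    def test_empty_source_rejected(self):
        cfg = TrainConfig(mode="supervised", epochs=1, base_channels=4)
        with pytest.raises(ValueError):
            train(cfg, {"images": np.zeros((0, 64, 64))})

    def test_best_validation_checkpoint_restored(self):
        """With a labelled source validation split, the returned generator is
        the best epoch by validation DC, never worse than the final epoch."""
        from ddseg.evaluation import evaluate_dataset

        src, _ = make_domain_datasets(16, 1, seed=300)
        val, _ = make_domain_datasets(8, 1, seed=301)
        val = {"images": val["images"], "masks": val["masks"]}
        cfg = TrainConfig(mode="supervised", epochs=4, seed=1, base_channels=4,
                          lr_generator=2e-3, batch_size=8)
        t_best, _ = train(cfg, src, val_data=val)
        t_last, _ = train(cfg, src)
        dc_best = evaluate_dataset(t_best.generator, zip(val["images"], val["masks"])).dc
        dc_last = evaluate_dataset(t_last.generator, zip(val["images"], val["masks"])).dc
        assert dc_best >= dc_last - 1e-12

    def test_supervised_loss_decreases(self):
        """Dice loss drops between the first and last training epochs."""
        src, _ = make_domain_datasets(24, 1, seed=200)
        cfg = TrainConfig(
            mode="supervised", epochs=8, seed=0, base_channels=4,
            lr_generator=2e-3, batch_size=8,
        )
        _, history = train(cfg, src)
        per_epoch = np.array([r.l_seg for r in history]).reshape(8, -1).mean(axis=1)
        assert per_epoch[-1] < per_epoch[0]
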