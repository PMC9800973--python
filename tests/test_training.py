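"""Target assignment, loss terms, augmentations, anchor fitting and the
training loop (smoke scale)."""

import numpy as np
import pytest

from pestyolo.data import GroundTruthLabel
from pestyolo.model import AnchorSet, ModelConfig, Detector
from pestyolo.nn import Tensor
from pestyolo.training import (DetectionDataset, TrainConfig, assign_targets,
                               augment_geometric, augment_hsv, compute_loss,
                               cosine_lr, fit_anchors, mosaic, train)

ANC = AnchorSet()


def logit(p):
    return float(np.log(p / (1 - p)))


class TestAssignTargets:
    def test_label_at_cell_center_matching_one_anchor_gets_three_cells(self):
        # a 5x5 box ratio-matches only the smallest stride-8 anchor (10, 13)
        lb = GroundTruthLabel(0, (10.5 * 8) / 640, (10.5 * 8) / 640, 5 / 640, 5 / 640)
        per_scale, skipped = assign_targets([[lb]], ANC, 640)
        assert skipped == 0
        counts = [len(a.img) for a in per_scale]
        assert counts == [3, 0, 0]       # own cell + two nearest neighbours
        assert (per_scale[0].anchor == 0).all()
        assert (per_scale[0].cls == 0).all()

    def test_extreme_size_label_skipped(self):
        lb = GroundTruthLabel(0, 0.5, 0.5, 1000 / 640, 0.3 / 640)
        per_scale, skipped = assign_targets([[lb]], ANC, 640)
        assert skipped == 1
        assert all(len(a.img) == 0 for a in per_scale)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rule_by_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = [GroundTruthLabel(int(rng.integers(3)),
                                   float(rng.uniform(0.1, 0.9)),
                                   float(rng.uniform(0.1, 0.9)),
                                   float(rng.uniform(0.01, 0.4)),
                                   float(rng.uniform(0.01, 0.4)))
                  for _ in range(8)]
        per_scale, _ = assign_targets([labels], ANC, 640, ratio_thr=4.0)
        for level, stride in enumerate((8, 16, 32)):
            g = 640 // stride
            expected = set()
            for lb in labels:
                gx, gy = lb.cx * g, lb.cy * g
                gw, gh = lb.w * 640 / stride, lb.h * 640 / stride
                for ai, (aw, ah) in enumerate(ANC.anchors[level] / stride):
                    if max(gw / aw, aw / gw, gh / ah, ah / gh) >= 4.0:
                        continue
                    cells = {(int(gx), int(gy))}
                    if gx % 1 < 0.5 and gx > 1:
                        cells.add((int(gx) - 1, int(gy)))
                    if gx % 1 >= 0.5 and gx < g - 1:
                        cells.add((int(gx) + 1, int(gy)))
                    if gy % 1 < 0.5 and gy > 1:
                        cells.add((int(gx), int(gy) - 1))
                    if gy % 1 >= 0.5 and gy < g - 1:
                        cells.add((int(gx), int(gy) + 1))
                    for ci, cj in cells:
                        expected.add((ai, cj, ci, lb.class_id))
            got = set(zip(per_scale[level].anchor.tolist(),
                          per_scale[level].gj.tolist(),
                          per_scale[level].gi.tolist(),
                          per_scale[level].cls.tolist()))
            assert got == expected

    def test_empty_labels_valid(self):
        per_scale, skipped = assign_targets([[]], ANC, 640)
        assert skipped == 0 and all(len(a.img) == 0 for a in per_scale)


def make_raw(nc=2, size=64, batch=1, fill=0.0):
    return [Tensor(np.full((batch, 3, size // s, size // s, 5 + nc), fill,
                           dtype=np.float32), requires_grad=True)
            for s in (8, 16, 32)]


class TestComputeLoss:
    def cfg(self):
        return TrainConfig(epochs=1, batch_size=2, input_size=64)

    def test_perfect_prediction_zero_box_loss(self):
        """Logits constructed to decode exactly onto every assigned target
        give GIoU = 1 and hence zero box loss."""
        size = 64
        lb = GroundTruthLabel(1, 0.35, 0.45, 10 / size, 13 / size)
        asg, _ = assign_targets([[lb]], ANC, size)
        raw = make_raw(size=size)
        for level, a in enumerate(asg):
            for m in range(len(a.img)):
                cell = raw[level].data[a.img[m], a.anchor[m], a.gj[m], a.gi[m]]
                cell[0] = logit((a.txy[m, 0] + 0.5) / 2)
                cell[1] = logit((a.txy[m, 1] + 0.5) / 2)
                cell[2] = logit(np.sqrt(a.twh[m, 0] / a.anchor_wh[m, 0]) / 2)
                cell[3] = logit(np.sqrt(a.twh[m, 1] / a.anchor_wh[m, 1]) / 2)
        losses = compute_loss(raw, asg, self.cfg(), ANC)
        assert losses["box"] == pytest.approx(0.0, abs=1e-5)

    def test_no_labels_gives_zero_box_cls_positive_obj(self):
        raw = make_raw()
        asg, _ = assign_targets([[]], ANC, 64)
        losses = compute_loss(raw, asg, self.cfg(), ANC)
        assert losses["box"] == 0.0 and losses["cls"] == 0.0
        assert losses["obj"] > 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_straight_line_oracle(self, seed):
        """Loss recomputed with plain NumPy formulas, no Tensor machinery."""
        rng = np.random.default_rng(seed)
        size, nc = 64, 3
        labels = [GroundTruthLabel(int(rng.integers(nc)),
                                   float(rng.uniform(0.2, 0.8)),
                                   float(rng.uniform(0.2, 0.8)),
                                   float(rng.uniform(0.05, 0.5)),
                                   float(rng.uniform(0.05, 0.5)))
                  for _ in range(5)]
        asg, _ = assign_targets([labels], ANC, size)
        raw = [Tensor(rng.normal(size=(1, 3, size // s, size // s, 5 + nc))
                      .astype(np.float32), requires_grad=True)
               for s in (8, 16, 32)]
        cfg = self.cfg()
        losses = compute_loss(raw, asg, cfg, ANC)

        def sig(v):
            return 1 / (1 + np.exp(-v))

        box_terms, cls_terms, obj_sum = [], [], 0.0
        for level, (r, a) in enumerate(zip(raw, asg)):
            d = r.data[0].astype(np.float64)
            tobj = np.zeros(d.shape[:-1])
            gious = []
            for m in range(len(a.img)):
                p = d[a.anchor[m], a.gj[m], a.gi[m]]
                px, py = sig(p[0]) * 2 - 0.5, sig(p[1]) * 2 - 0.5
                pw = (sig(p[2]) * 2) ** 2 * a.anchor_wh[m, 0]
                ph = (sig(p[3]) * 2) ** 2 * a.anchor_wh[m, 1]
                tx, ty = a.txy[m]
                tw, th = a.twh[m]
                bi = max(min(px + pw / 2, tx + tw / 2) - max(px - pw / 2, tx - tw / 2), 0) \
                    * max(min(py + ph / 2, ty + th / 2) - max(py - ph / 2, ty - th / 2), 0)
                un = pw * ph + tw * th - bi + 1e-9
                cw = max(px + pw / 2, tx + tw / 2) - min(px - pw / 2, tx - tw / 2)
                ch = max(py + ph / 2, ty + th / 2) - min(py - ph / 2, ty - th / 2)
                gi = bi / un - (cw * ch + 1e-9 - un) / (cw * ch + 1e-9)
                gious.append(gi)
                tobj[a.anchor[m], a.gj[m], a.gi[m]] = max(
                    tobj[a.anchor[m], a.gj[m], a.gi[m]], np.clip(gi, 0, 1))
            if gious:
                box_terms.append(np.mean([1 - g for g in gious]))
                tcls = np.zeros((len(a.img), nc))
                tcls[np.arange(len(a.img)), a.cls] = 1
                z = np.array([d[a.anchor[m], a.gj[m], a.gi[m], 5:]
                              for m in range(len(a.img))])
                bce = np.maximum(z, 0) - z * tcls + np.log1p(np.exp(-np.abs(z)))
                cls_terms.append(bce.mean())
            zo = d[..., 4]
            bce_o = np.maximum(zo, 0) - zo * tobj + np.log1p(np.exp(-np.abs(zo)))
            obj_sum += bce_o.mean() * cfg.obj_balance[level]
        box_ref = np.mean(box_terms) if box_terms else 0.0
        cls_ref = np.mean(cls_terms) if cls_terms else 0.0
        assert losses["box"] == pytest.approx(box_ref, rel=2e-4, abs=1e-6)
        assert losses["obj"] == pytest.approx(obj_sum, rel=2e-4)
        assert losses["cls"] == pytest.approx(cls_ref, rel=2e-4)
        total_ref = (cfg.box_weight * box_ref + cfg.obj_weight * obj_sum
                     + cfg.cls_weight * cls_ref) * cfg.nominal_batch
        assert float(losses["total"].data) == pytest.approx(total_ref, rel=2e-4)

    def test_loss_backward_produces_finite_grads(self):
        rng = np.random.default_rng(5)
        labels = [GroundTruthLabel(0, 0.5, 0.5, 0.2, 0.2)]
        asg, _ = assign_targets([labels], ANC, 64)
        raw = [Tensor(rng.normal(size=(1, 3, 64 // s, 64 // s, 7)).astype(np.float32),
                      requires_grad=True) for s in (8, 16, 32)]
        compute_loss(raw, asg, self.cfg(), ANC)["total"].backward()
        for r in raw:
            assert r.grad is not None and np.isfinite(r.grad).all()


class TestAugmentations:
    IMG = np.random.default_rng(0).integers(0, 255, (64, 64, 3), dtype=np.uint8)

    def test_hsv_zero_gains_identity(self):
        np.testing.assert_array_equal(
            augment_hsv(self.IMG, (0, 0, 0), np.random.default_rng(1)), self.IMG)

    def test_hsv_output_valid_uint8_and_seeded(self):
        a = augment_hsv(self.IMG, rng=np.random.default_rng(3))
        b = augment_hsv(self.IMG, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        assert a.dtype == np.uint8

    def test_flip_involution(self):
        labels = [GroundTruthLabel(0, 0.3, 0.4, 0.1, 0.2)]
        img1, lb1 = augment_geometric(self.IMG, labels, translate=0, scale=(1, 1),
                                      rng=np.random.default_rng(0), force_flip=True)
        img2, lb2 = augment_geometric(img1, lb1, translate=0, scale=(1, 1),
                                      rng=np.random.default_rng(0), force_flip=True)
        np.testing.assert_array_equal(img2, self.IMG)
        assert lb2[0].cx == pytest.approx(0.3) and lb2[0].cy == pytest.approx(0.4)

    def test_identity_transform(self):
        labels = [GroundTruthLabel(1, 0.5, 0.5, 0.2, 0.2)]
        img, lbs = augment_geometric(self.IMG, labels, flip_p=0, translate=0,
                                     scale=(1, 1), rng=np.random.default_rng(0))
        np.testing.assert_array_equal(img, self.IMG)
        assert lbs == labels

    def test_labels_match_corner_transform_oracle(self):
        rng = np.random.default_rng(7)
        labels = [GroundTruthLabel(0, 0.5, 0.5, 0.3, 0.2)]
        s_rng = np.random.default_rng(7)
        flip = s_rng.uniform() < 0.5
        s = s_rng.uniform(0.8, 1.2)
        tx = s_rng.uniform(-0.05, 0.05) * 64
        ty = s_rng.uniform(-0.05, 0.05) * 64
        _, lbs = augment_geometric(self.IMG, labels, flip_p=0.5, translate=0.05,
                                   scale=(0.8, 1.2), rng=rng)
        cx = 1 - 0.5 if flip else 0.5
        x1, y1 = (cx - 0.15) * 64, (0.5 - 0.1) * 64
        x2, y2 = (cx + 0.15) * 64, (0.5 + 0.1) * 64
        ex1 = (x1 - 32) * s + 32 + tx
        ex2 = (x2 - 32) * s + 32 + tx
        ey1 = (y1 - 32) * s + 32 + ty
        ey2 = (y2 - 32) * s + 32 + ty
        ex1, ey1 = max(ex1, 0), max(ey1, 0)
        ex2, ey2 = min(ex2, 64), min(ey2, 64)
        got = lbs[0]
        assert got.cx == pytest.approx((ex1 + ex2) / 2 / 64, abs=1e-6)
        assert got.w == pytest.approx((ex2 - ex1) / 64, abs=1e-6)
        assert got.h == pytest.approx((ey2 - ey1) / 64, abs=1e-6)

    def test_labels_remain_valid_under_random_transforms(self):
        rng = np.random.default_rng(11)
        labels = [GroundTruthLabel(int(rng.integers(3)),
                                   float(rng.uniform(0.2, 0.8)),
                                   float(rng.uniform(0.2, 0.8)),
                                   float(rng.uniform(0.05, 0.3)),
                                   float(rng.uniform(0.05, 0.3)))
                  for _ in range(10)]
        for _ in range(10):
            _, lbs = augment_geometric(self.IMG, labels, rng=rng)
            for lb in lbs:
                lb.validate()
                assert lb.cx - lb.w / 2 >= -1e-6 and lb.cx + lb.w / 2 <= 1 + 1e-6


class TestMosaic:
    def solid(self, val):
        return np.full((48, 48, 3), val, dtype=np.uint8), \
            [GroundTruthLabel(0, 0.5, 0.5, 0.4, 0.4)]

    def test_requires_four_samples(self):
        with pytest.raises(ValueError, match="4"):
            mosaic([self.solid(1)] * 3, 64)

    def test_solid_color_mosaic(self):
        img, _ = mosaic([self.solid(77)] * 4, 64, np.random.default_rng(0))
        from pestyolo.data import PAD_VALUE
        assert set(np.unique(img)) <= {77, PAD_VALUE}

    def test_label_count_bounded_and_boxes_in_bounds(self):
        rng = np.random.default_rng(5)
        samples = []
        for v in range(4):
            img = np.full((48, 48, 3), 50 + v, dtype=np.uint8)
            lbs = [GroundTruthLabel(v, float(rng.uniform(0.3, 0.7)),
                                    float(rng.uniform(0.3, 0.7)), 0.2, 0.2)
                   for _ in range(3)]
            samples.append((img, lbs))
        img, labels = mosaic(samples, 64, rng)
        assert len(labels) <= 12
        for lb in labels:
            lb.validate()

    def test_seeded_reproducible(self):
        samples = [self.solid(v) for v in (10, 20, 30, 40)]
        a_img, a_lb = mosaic(samples, 64, np.random.default_rng(9))
        b_img, b_lb = mosaic(samples, 64, np.random.default_rng(9))
        np.testing.assert_array_equal(a_img, b_img)
        assert a_lb == b_lb


class TestFitAnchors:
    def test_identical_labels_degenerate_clustering(self):
        labels = [GroundTruthLabel(0, 0.5, 0.5, 0.1, 0.05)] * 20
        anc = fit_anchors(labels, 640)
        np.testing.assert_allclose(anc.anchors.reshape(-1, 2),
                                   np.tile([64, 32], (9, 1)))

    def test_two_cluster_recovery(self):
        rng = np.random.default_rng(0)
        labels = []
        for _ in range(40):
            labels.append(GroundTruthLabel(0, 0.5, 0.5,
                                           float(rng.uniform(0.02, 0.03)),
                                           float(rng.uniform(0.02, 0.03))))
        for _ in range(40):
            labels.append(GroundTruthLabel(0, 0.5, 0.5,
                                           float(rng.uniform(0.3, 0.4)),
                                           float(rng.uniform(0.3, 0.4))))
        anc = fit_anchors(labels, 640).anchors.reshape(-1, 2)
        small = (anc < 0.05 * 640).all(axis=1) & (anc > 0.01 * 640).all(axis=1)
        large = (anc > 0.25 * 640).all(axis=1) & (anc < 0.45 * 640).all(axis=1)
        assert (small | large).all() and small.any() and large.any()

    def test_sorted_by_area(self):
        rng = np.random.default_rng(1)
        labels = [GroundTruthLabel(0, 0.5, 0.5, float(rng.uniform(0.01, 0.6)),
                                   float(rng.uniform(0.01, 0.6)))
                  for _ in range(30)]
        anc = fit_anchors(labels, 640).anchors.reshape(-1, 2)
        areas = anc[:, 0] * anc[:, 1]
        assert (np.diff(areas) >= -1e-9).all()

    def test_too_few_labels_falls_back_to_preset(self):
        labels = [GroundTruthLabel(0, 0.5, 0.5, 0.1, 0.1)] * 5
        anc = fit_anchors(labels, 640)
        np.testing.assert_array_equal(anc.anchors, AnchorSet().anchors)


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    from pestyolo.synthetic import SceneSpec, generate_dataset
    spec = SceneSpec(image_size=96, n_insects=5, n_classes=2,
                     size_range=(0.15, 0.3), density=0.2, n_clutter=2,
                     n_reflections=1, outlier_prob=0.0)
    return generate_dataset(tmp_path_factory.mktemp("ds") / "d", 10, spec,
                            {"train": 0.8, "val": 0.2}, seed=21)


TINY_MODEL = dict(num_classes=2, width_multiple=0.25, depth_multiple=0.33,
                  input_size=96, cla_reduction=4)


class TestTrainLoop:
    def test_epochs_zero_writes_init_checkpoint(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(epochs=0, batch_size=4, input_size=96, seed=1)
        model, hist = train(tiny_dataset, ModelConfig(**TINY_MODEL), cfg,
                            out_dir=tmp_path / "run")
        assert hist == []
        assert (tmp_path / "run" / "last.npz").is_file()
        assert (tmp_path / "run" / "best.npz").is_file()

    def test_smoke_epoch_runs_and_logs(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(epochs=2, batch_size=4, input_size=96, seed=1,
                          augment=False, mosaic=False)
        model, hist = train(tiny_dataset, ModelConfig(**TINY_MODEL), cfg,
                            out_dir=tmp_path / "run")
        assert len(hist) == 2
        assert all(np.isfinite(h["total"]) for h in hist)
        csv_text = (tmp_path / "run" / "metrics.csv").read_text()
        assert csv_text.splitlines()[0].startswith("epoch,box,obj,cls")
        assert not np.isnan(hist[-1]["mAP50"])

    def test_identical_seed_identical_trajectory(self, tiny_dataset):
        cfg = TrainConfig(epochs=1, batch_size=4, input_size=96, seed=3,
                          augment=False, mosaic=False, eval_interval=10**9)
        _, h1 = train(tiny_dataset, ModelConfig(**TINY_MODEL), cfg, val_split=None)
        _, h2 = train(tiny_dataset, ModelConfig(**TINY_MODEL), cfg, val_split=None)
        assert h1[0]["total"] == h2[0]["total"]


def test_cosine_lr_schedule_bounds():
    assert cosine_lr(0, 100, 0.01, 0.1) == pytest.approx(0.01)
    assert cosine_lr(99, 100, 0.01, 0.1) == pytest.approx(0.001)
    mid = cosine_lr(50, 100, 0.01, 0.1)
    assert 0.001 < mid < 0.01
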