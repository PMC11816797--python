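import numpy as np
import pytest
from scipy import ndimage

from siliquant import (
    InstanceMask,
    average_precision,
    evaluate,
    generate_scene,
    iou,
    match_at_threshold,
)
from siliquant.evaluation import IOU_THRESHOLDS


def _box_instance(iid, bbox, score=1.0, image_id="im", frame=(40, 40)):
    x, y, w, h = bbox
    mask = np.zeros(frame, dtype=bool)
    mask[int(y):int(y + h), int(x):int(x + w)] = True
    return InstanceMask(iid, image_id, mask, bbox=bbox, score=score)


def brute_force_match(preds, gts, thr, mode):
    """Independent oracle: simulate the score-ordered one-to-one rule with
    plain python over explicit candidate lists."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    matched_gt = set()
    pairs = {}
    for pi in order:
        best_gi, best_iou = None, -1.0
        for gi, g in enumerate(gts):
            if gi in matched_gt:
                continue
            v = iou(preds[pi], g, mode)
            if v >= thr and v > best_iou:
                best_gi, best_iou = gi, v
        if best_gi is not None:
            matched_gt.add(best_gi)
            pairs[pi] = best_gi
    tp = len(pairs)
    return tp, len(preds) - tp, len(gts) - tp


class TestIoU:
    def test_identity_and_disjoint(self):
        a = _box_instance("a", (0, 0, 5, 5))
        b = _box_instance("b", (20, 20, 5, 5))
        assert iou(a, a, "bbox") == 1.0 and iou(a, a, "mask") == 1.0
        assert iou(a, b, "bbox") == 0.0 and iou(a, b, "mask") == 0.0

    def test_known_box_overlap(self):
        a = _box_instance("a", (0, 0, 2, 2))
        b = _box_instance("b", (1, 1, 2, 2))
        assert iou(a, b, "bbox") == pytest.approx(1 / 7)

    def test_symmetry(self):
        a = _box_instance("a", (0, 0, 6, 4))
        b = _box_instance("b", (2, 1, 6, 4))
        for mode in ("bbox", "mask"):
            assert iou(a, b, mode) == pytest.approx(iou(b, a, mode))


class TestMatching:
    def test_threshold_crossing(self):
        gt = [_box_instance("g", (0, 0, 10, 10))]
        # overlap 60 of union 100+60-60... build a 6x10 prediction: IoU = 0.6
        pred = [_box_instance("p", (0, 0, 10, 6), score=0.9)]
        assert iou(pred[0], gt[0], "mask") == pytest.approx(0.6)
        tp, fp, fn, _ = match_at_threshold(pred, gt, 0.5, "mask")
        assert (tp, fp, fn) == (1, 0, 0)
        tp, fp, fn, _ = match_at_threshold(pred, gt, 0.75, "mask")
        assert (tp, fp, fn) == (0, 1, 1)

    def test_greedy_one_to_one(self):
        gt = [_box_instance("g", (0, 0, 10, 10))]
        preds = [
            _box_instance("p1", (0, 0, 10, 9), score=0.9),
            _box_instance("p2", (0, 1, 10, 9), score=0.8),
        ]
        tp, fp, fn, assignment = match_at_threshold(preds, gt, 0.5, "mask")
        assert (tp, fp, fn) == (1, 1, 0)
        assert assignment == {0: 0}  # the higher-score prediction wins

    def test_duplicate_lower_score_never_adds_tp(self):
        gt, preds = generate_scene(4, seed=21, image_size=(400, 400))
        tp0, *_ = match_at_threshold(preds, gt, 0.5, "mask")
        dup = InstanceMask("dup", preds[0].image_id, preds[0].mask.copy(), score=0.01)
        tp1, *_ = match_at_threshold(preds + [dup], gt, 0.5, "mask")
        assert tp1 == tp0

    @pytest.mark.parametrize("mode", ["bbox", "mask"])
    def test_agrees_with_brute_force_on_random_scenes(self, mode):
        rng = np.random.default_rng(4242)
        mismatches = 0
        for rep in range(100):
            n = int(rng.integers(1, 7))
            frame = (60, 60)
            gts, preds = [], []
            for i in range(n):
                x, y = rng.integers(0, 40, size=2)
                w, h = rng.integers(3, 18, size=2)
                gts.append(_box_instance(f"g{i}", (x, y, w, h), frame=frame))
            for i in range(int(rng.integers(0, 8))):
                x, y = rng.integers(0, 40, size=2)
                w, h = rng.integers(3, 18, size=2)
                preds.append(
                    _box_instance(f"p{i}", (x, y, w, h),
                                  score=float(rng.uniform(0.1, 1)), frame=frame)
                )
            for thr in IOU_THRESHOLDS:
                tp, fp, fn, _ = match_at_threshold(preds, gts, thr, mode)
                assert (tp, fp, fn) == brute_force_match(preds, gts, thr, mode)


class TestAveragePrecision:
    def _one_gt(self):
        return [_box_instance("g", (5, 5, 10, 10))]

    def test_perfect_prediction(self):
        gt = self._one_gt()
        pred = [_box_instance("p", (5, 5, 10, 10), score=1.0)]
        assert average_precision(pred, gt, 0.5, "mask") == 1.0

    def test_tp_then_fp_ranking(self):
        gt = self._one_gt()
        preds = [
            _box_instance("tp", (5, 5, 10, 10), score=0.9),
            _box_instance("fp", (25, 25, 5, 5), score=0.5),
        ]
        assert average_precision(preds, gt, 0.5, "mask") == pytest.approx(1.0)

    def test_fp_then_tp_ranking(self):
        gt = self._one_gt()
        preds = [
            _box_instance("fp", (25, 25, 5, 5), score=0.9),
            _box_instance("tp", (5, 5, 10, 10), score=0.5),
        ]
        # max precision at every recall level is 1/2
        assert average_precision(preds, gt, 0.5, "mask") == pytest.approx(0.5, abs=0.01)

    def test_order_invariance_at_distinct_scores(self):
        gt, preds = generate_scene(5, seed=31, image_size=(500, 500))
        ap = average_precision(preds, gt, 0.5, "mask")
        shuffled = list(reversed(preds))
        assert average_precision(shuffled, gt, 0.5, "mask") == pytest.approx(ap)


class TestEvaluate:
    def test_perfect_predictions_all_hundred(self):
        gt, preds = generate_scene(6, seed=41, image_size=(500, 500))
        report = evaluate(preds, gt)
        for task in (report.detection, report.segmentation):
            for v in task.values():
                assert v == pytest.approx(100.0)

    def test_erosion_separates_thresholds(self):
        # erode every mask so segmentation IoU lands in (0.5, 0.75):
        # AP@0.5 stays 100, AP@0.75 collapses to 0
        gt, preds = generate_scene(5, seed=51, image_size=(500, 500))
        eroded = []
        for p in preds:
            m = ndimage.binary_erosion(p.mask, iterations=2)
            eroded.append(InstanceMask(p.instance_id, p.image_id, m,
                                       bbox=p.bbox, score=p.score))
        ious = [iou(e, g, "mask") for e, g in zip(eroded, gt)]
        assert all(0.5 < v < 0.75 for v in ious)
        report = evaluate(eroded, gt)
        assert report.segmentation["AP_50"] == pytest.approx(100.0)
        assert report.segmentation["AP_75"] == pytest.approx(0.0)

    def test_detection_ignores_bbox_preserving_mask_changes(self):
        gt, preds = generate_scene(4, seed=61, image_size=(400, 400))
        report_before = evaluate(preds, gt)
        nibbled = []
        for p in preds:
            m = ndimage.binary_erosion(p.mask, iterations=1)
            nibbled.append(InstanceMask(p.instance_id, p.image_id, m,
                                        bbox=p.bbox, score=p.score))
        report_after = evaluate(nibbled, gt)
        assert report_after.detection == pytest.approx(report_before.detection)

    def test_ap50_bounds_ap_range_average(self):
        gt, preds = generate_scene(5, seed=71, image_size=(500, 500),
                                   )
        eroded = [
            InstanceMask(p.instance_id, p.image_id,
                         ndimage.binary_erosion(p.mask), bbox=p.bbox, score=p.score)
            for p in preds
        ]
        report = evaluate(eroded, gt)
        for task in (report.detection, report.segmentation):
            assert task["AP_50"] >= task["AP_50_95"]

    def test_report_table_shape(self, tmp_path):
        gt, preds = generate_scene(3, seed=81, image_size=(400, 400))
        report = evaluate(preds, gt)
        frame = report.to_frame()
        assert list(frame.columns) == ["Metric", "AP_50_95", "AP_50", "AP_75", "AR_50_95"]
        assert list(frame["Metric"]) == ["Detection", "Segmentation"]
        report.to_csv(tmp_path / "report.csv")
        report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.csv").exists() and (tmp_path / "report.json").exists()
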