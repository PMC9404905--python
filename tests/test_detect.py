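"""Detector contracts: NMS, lobe assignment, model shapes, overfit recovery."""

import numpy as np
import pytest

from bronchoscore.ctslice import LobeMask
from bronchoscore.detect import (
    Detection,
    DetectorConfig,
    DilationSchedule,
    assign_detections_to_lobes,
    build_hdc_maskrcnn,
    detect_bronchiectasis,
    load_detector,
    nms,
    save_detector,
    train_detector,
)
from bronchoscore.metrics import box_iou
from bronchoscore.nn import Tensor
from bronchoscore.phantom import PhantomSpec, generate_phantom

from conftest import coco_records


class TestDetectionType:
    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            Detection(bbox=(0, 0, 4, 4), mask=None, severity_class=4, confidence=0.5)

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError):
            Detection(bbox=(0, 0, 4, 4), mask=None, severity_class=1, confidence=1.5)


class TestNMS:
    def test_duplicate_boxes_collapse_to_one(self):
        keep = nms([(0, 0, 10, 10), (0, 0, 10, 10)], [0.9, 0.8], 0.5)
        assert keep == [0]

    def test_disjoint_boxes_all_survive(self):
        keep = nms([(0, 0, 5, 5), (20, 20, 5, 5), (40, 0, 5, 5)], [0.3, 0.9, 0.6], 0.5)
        assert keep == [1, 2, 0]  # ordered by score

    def test_output_never_larger_than_input(self):
        rng = np.random.default_rng(0)
        boxes = [tuple(v) for v in rng.uniform(0, 30, (20, 4))]
        scores = list(rng.uniform(0, 1, 20))
        keep = nms(boxes, scores, 0.3)
        assert len(keep) <= 20
        kept_scores = [scores[i] for i in keep]
        assert kept_scores == sorted(kept_scores, reverse=True)


class TestLobeAssignment:
    def make_mask(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[:32, :32] = 1
        labels[32:, :32] = 2
        labels[:32, 32:] = 3
        labels[32:, 32:] = 4
        return LobeMask(labels=labels, lobe_table={1: "lu", 2: "ll", 3: "ru", 4: "rl"})

    def det(self, y, x, cls, size=6):
        mask = np.zeros((64, 64), dtype=bool)
        mask[y : y + size, x : x + size] = True
        return Detection(bbox=(x, y, size, size), mask=mask,
                         severity_class=cls, confidence=0.9)

    def test_no_detections_all_zero(self):
        findings = assign_detections_to_lobes([], self.make_mask())
        assert all(g == 0 for g in findings.grades.values())

    def test_detection_inside_left_lower_lobe(self):
        findings = assign_detections_to_lobes([self.det(40, 8, 1)], self.make_mask())
        assert findings.grades == {2: 1}

    def test_same_lobe_takes_most_dilated_grade(self):
        dets = [self.det(40, 4, 1), self.det(50, 20, 3)]
        findings = assign_detections_to_lobes(dets, self.make_mask())
        assert findings.grades[2] == 3

    def test_tie_breaks_to_lower_lobe_id(self):
        det = self.det(29, 8, 2)  # straddles lobes 1 and 2 equally
        findings = assign_detections_to_lobes([det], self.make_mask())
        assert det.lobe_id == 1

    def test_no_overlap_left_unassigned(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[:8, :8] = 1
        det = self.det(40, 40, 2)
        findings = assign_detections_to_lobes([det], labels)
        assert det.lobe_id is None
        assert findings.grades == {}

    def test_box_fallback_without_mask(self):
        det = Detection(bbox=(8, 40, 6, 6), mask=None, severity_class=2, confidence=0.8)
        findings = assign_detections_to_lobes([det], self.make_mask())
        assert findings.grades == {2: 2}


class TestModelContracts:
    def test_invalid_schedule_rejected_unless_forced(self):
        with pytest.raises(ValueError):
            build_hdc_maskrcnn(schedule=DilationSchedule((2, 2, 2)))
        model = build_hdc_maskrcnn(schedule=DilationSchedule((2, 2, 2)), force=True)
        assert model.schedule.rates == (2, 2, 2)

    def test_hdc_stage_adds_no_downsampling(self):
        model = build_hdc_maskrcnn(seed=0)
        x = Tensor(np.zeros((1, 1, 64, 64)))
        pre_hdc = model.down2(model.down1(model.stem(x)))
        post = pre_hdc
        for layer in model.hdc_stage:
            post = layer(post)
        assert post.shape[2:] == pre_hdc.shape[2:] == (16, 16)

    def test_untrained_model_on_blank_image_no_crash(self):
        model = build_hdc_maskrcnn(seed=1)
        dets = detect_bronchiectasis(model, np.full((64, 64), 120.0), 0.5)
        for d in dets:
            assert 0.0 <= d.confidence <= 1.0
            assert d.severity_class in (1, 2, 3)

    def test_impossible_threshold_returns_empty(self):
        model = build_hdc_maskrcnn(seed=1)
        assert detect_bronchiectasis(model, np.full((64, 64), 120.0), 1.01) == []


@pytest.fixture(scope="module")
def overfit_run():
    """Train the detector on two small phantoms until it memorizes them."""
    def make(seed, ratio):
        return generate_phantom(
            PhantomSpec(image_size=96, n_lesions=1, severity_ratios=[ratio],
                        vessel_radius_px=3.0, n_distractor_vessels=2, seed=seed)
        )

    samples = [make(1, 1.5), make(2, 2.5)]
    dataset = [{"image": s.image, "annotations": coco_records(s)} for s in samples]
    model = build_hdc_maskrcnn(seed=0)
    model, losses = train_detector(model, dataset, steps=400, lr=2e-3, seed=0)
    return model, losses, samples, dataset


class TestTraining:
    def test_loss_trace_length_and_decrease(self, overfit_run):
        _, losses, _, _ = overfit_run
        assert len(losses) == 400
        assert losses[-1] < 0.5 * losses[0]

    def test_overfit_recovers_planted_lesions(self, overfit_run):
        model, _, samples, _ = overfit_run
        for sample in samples:
            gt = sample.annotations[0]
            dets = detect_bronchiectasis(model, sample.image, 0.5)
            assert dets, "memorized lesion not detected"
            best = max(dets, key=lambda d: box_iou(d.bbox, gt.bbox))
            assert box_iou(best.bbox, gt.bbox) >= 0.5
            assert best.severity_class == gt.severity_class

    def test_short_runs_are_deterministic(self, overfit_run):
        _, _, _, dataset = overfit_run
        _, t1 = train_detector(build_hdc_maskrcnn(seed=0), dataset, steps=5, seed=3)
        _, t2 = train_detector(build_hdc_maskrcnn(seed=0), dataset, steps=5, seed=3)
        assert t1 == t2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_detector(build_hdc_maskrcnn(seed=0), [], steps=1)

    def test_checkpoint_round_trip(self, overfit_run, tmp_path):
        model, _, samples, _ = overfit_run
        save_detector(model, tmp_path / "det.npz")
        back = load_detector(tmp_path / "det.npz")
        a = detect_bronchiectasis(model, samples[0].image, 0.5)
        b = detect_bronchiectasis(back, samples[0].image, 0.5)
        assert [d.bbox for d in a] == [d.bbox for d in b]
        assert back.schedule.rates == (1, 2, 5, 2, 1)

    def test_config_round_trips_through_dict(self):
        cfg = DetectorConfig(channels=(4, 8, 16), anchor_size=16.0)
        assert DetectorConfig.from_dict(cfg.to_dict()) == cfg
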