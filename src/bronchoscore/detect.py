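"""HDC Mask R-CNN: bronchiectasis instance detection with severity classes.

Two parts live here. First, the hybrid-dilated-convolution (HDC) design
machinery: an exact receptive-field dependency oracle that detects the
gridding effect (input pixels that a stack of dilated convolutions can never
see), the design-condition checks (pairwise-coprime distinct rates, a
small-large-small rate cycle, bounded maximum rate), and an enumerator of
valid rate schedules — the 5-layer candidates at maximum rate 5 are
1-2-5-2-1, 1-3-5-3-1 and 2-3-5-3-2.

Second, a compact two-stage detector in the Mask R-CNN mould: a small
residual-free convolutional backbone whose final stage replaces further
downsampling with the HDC schedule's stacked dilated 3x3 convolutions, a
single-anchor region-proposal network, RoIAlign, class/box heads over
severity grades {1, 2, 3} plus background, and a class-agnostic mask head.
It is sized for CPU training on phantom data, not for clinical throughput.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .ctslice import CTSlice, LobeMask, as_labels
from .metrics import box_iou
from .nn import Adam, Conv2d, InstanceNorm2d, Linear, Module, Tensor
from .nn.functional import (
    roi_align,
    sigmoid_bce,
    smooth_l1,
    softmax_cross_entropy,
    softmax_probs,
)
from .score import LOBE_SCHEMES, LobeFindings

__all__ = [
    "DilationSchedule",
    "HDCReport",
    "Detection",
    "DetectorConfig",
    "receptive_field_coverage",
    "enumerate_hdc_schedules",
    "nms",
    "HDCMaskRCNN",
    "build_hdc_maskrcnn",
    "train_detector",
    "detect_bronchiectasis",
    "assign_detections_to_lobes",
    "save_detector",
    "load_detector",
]


# --------------------------------------------------------------------------
# HDC schedule analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DilationSchedule:
    """An ordered stack of dilation rates for 3x3 (or kxk) convolutions."""

    rates: tuple[int, ...]
    kernel: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(int(r) for r in self.rates))
        if not self.rates:
            raise ValueError("schedule needs at least one rate")
        if any(r < 1 for r in self.rates):
            raise ValueError("all dilation rates must be >= 1")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")


@dataclass
class HDCReport:
    """Outcome of the receptive-field and design-condition checks.

    ``coverage_fraction`` is measured over the footprint interior (see
    :func:`receptive_field_coverage`); ``full_coverage_fraction`` over the
    whole square footprint including its truncation-sparse outer band.
    """

    pairwise_coprime: bool
    cyclic_small_large_small: bool
    max_rate: int
    gridding_free: bool
    coverage_fraction: float
    full_coverage_fraction: float
    footprint_radius: int
    interior_radius: int


def _is_unimodal(rates: tuple[int, ...]) -> bool:
    """Non-decreasing up to the (first) maximum, non-increasing after."""
    peak = rates.index(max(rates))
    rising = all(rates[i] <= rates[i + 1] for i in range(peak))
    falling = all(rates[i] >= rates[i + 1] for i in range(peak, len(rates) - 1))
    return rising and falling


def _pairwise_coprime(rates: tuple[int, ...]) -> bool:
    distinct = sorted(set(rates))
    return all(
        math.gcd(a, b) == 1 for i, a in enumerate(distinct) for b in distinct[i + 1 :]
    )


def receptive_field_coverage(schedule: DilationSchedule) -> HDCReport:
    """Exact dependency propagation through the stacked dilated convolutions.

    Starting from a single output position, each layer spreads dependency to
    offsets ``rate * d`` for kernel taps d; the reachable set after all
    layers is the exact receptive-field support. A schedule is gridding-free
    when every pixel of the footprint *interior* — Chebyshev radius
    ``R - (r_max - 1) * (k // 2)`` — is reachable. The excluded outer band
    is sparse for any schedule whose largest rate exceeds 1 (a boundary
    truncation artifact of the longest jump), whereas lattice gridding in
    the sense of stacked rate-2 convolutions shows up as interior holes.
    """
    half = schedule.kernel // 2
    radius = half * sum(schedule.rates)
    side = 2 * radius + 1
    reach = np.zeros((side, side), dtype=bool)
    reach[radius, radius] = True
    taps = [(dy, dx) for dy in range(-half, half + 1) for dx in range(-half, half + 1)]
    for rate in schedule.rates:
        spread = np.zeros_like(reach)
        for dy, dx in taps:
            spread |= np.roll(reach, (dy * rate, dx * rate), axis=(0, 1))
        reach = spread
    full_coverage = float(reach.sum()) / float(side * side)
    interior_radius = radius - (max(schedule.rates) - 1) * half
    lo, hi = radius - interior_radius, radius + interior_radius + 1
    interior = reach[lo:hi, lo:hi]
    coverage = float(interior.sum()) / float(interior.size)
    return HDCReport(
        pairwise_coprime=_pairwise_coprime(schedule.rates),
        cyclic_small_large_small=_is_unimodal(schedule.rates),
        max_rate=max(schedule.rates),
        gridding_free=bool(np.isclose(coverage, 1.0)),
        coverage_fraction=coverage,
        full_coverage_fraction=full_coverage,
        footprint_radius=radius,
        interior_radius=interior_radius,
    )


def enumerate_hdc_schedules(max_rate: int, length: int) -> list[DilationSchedule]:
    """All rate schedules satisfying the three HDC design conditions.

    Conditions: distinct rates pairwise coprime; rates follow a
    small-to-large-to-small cycle; the stack is gridding-free under the
    dependency oracle (and no rate exceeds ``max_rate``).
    """
    if max_rate > 9:
        raise ValueError("max_rate above 9 is outside the supported search range")
    if length % 2 == 0:
        raise ValueError("schedule length must be odd")
    out = []
    for rates in product(range(1, max_rate + 1), repeat=length):
        if not _pairwise_coprime(rates) or not _is_unimodal(rates):
            continue
        schedule = DilationSchedule(rates)
        if receptive_field_coverage(schedule).gridding_free:
            out.append(schedule)
    return out


# --------------------------------------------------------------------------
# Detections and lobe assignment
# --------------------------------------------------------------------------


@dataclass
class Detection:
    """One detected bronchiectasis instance on a parent slice."""

    bbox: tuple[float, float, float, float]  # x, y, w, h (0-based pixels)
    mask: np.ndarray | None
    severity_class: int
    confidence: float
    lobe_id: int | None = None

    def __post_init__(self) -> None:
        if self.severity_class not in (1, 2, 3):
            raise ValueError(f"severity class {self.severity_class} outside {{1,2,3}}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


def nms(
    boxes: list[tuple[float, float, float, float]],
    scores: list[float],
    iou_threshold: float = 0.5,
) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    order = sorted(range(len(boxes)), key=lambda i: -scores[i])
    keep: list[int] = []
    for i in order:
        if all(box_iou(boxes[i], boxes[j]) < iou_threshold for j in keep):
            keep.append(i)
    return keep


def assign_detections_to_lobes(
    detections: list[Detection],
    lobe_mask: LobeMask | np.ndarray,
    scheme: str | None = None,
) -> LobeFindings:
    """Assign each detection to the lobe its mask overlaps most.

    Ties break toward the lower lobe id; a detection overlapping no lobe is
    left unassigned and excluded. Per-lobe grade is the maximum severity
    class among assigned detections (the most dilated finding), 0 if none.
    """
    labels = as_labels(lobe_mask)
    if scheme is None:
        if isinstance(lobe_mask, LobeMask) and lobe_mask.lobe_table:
            n = len(lobe_mask.lobe_table)
            scheme = "lobes6" if n == 6 else "lobes4"
        else:
            scheme = "lobes4"
    grades: dict[int, int] = {}
    for det in detections:
        if det.mask is not None and det.mask.any():
            sel = labels[np.asarray(det.mask, dtype=bool)]
        else:  # fall back to the box footprint
            x, y, w, h = det.bbox
            x0, y0 = max(int(np.floor(x)), 0), max(int(np.floor(y)), 0)
            x1 = min(int(np.ceil(x + w)), labels.shape[1])
            y1 = min(int(np.ceil(y + h)), labels.shape[0])
            sel = labels[y0:y1, x0:x1].ravel()
        counts = np.bincount(sel[sel > 0]) if sel.size else np.array([])
        if counts.size <= 1 or counts[1:].max() == 0:
            det.lobe_id = None
            continue
        lobe_id = int(np.argmax(counts[1:])) + 1  # argmax takes the lowest id on ties
        det.lobe_id = lobe_id
        grades[lobe_id] = max(grades.get(lobe_id, 0), det.severity_class)
    return LobeFindings(grades=grades, scheme=scheme)


# --------------------------------------------------------------------------
# The detector model
# --------------------------------------------------------------------------


@dataclass
class DetectorConfig:
    """Backbone and head sizes for the desk-scale detector.

    ``channels`` are the stem and two stride-2 stage widths; the HDC stage
    keeps the last width. ``anchor_size`` is the single square anchor side
    in image pixels, matched to phantom lesion sizes.
    """

    channels: tuple[int, int, int] = (8, 16, 32)
    n_classes: int = 3
    anchor_size: float = 20.0
    roi_size: int = 7
    mask_size: int = 14
    fc_dim: int = 64

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "n_classes": self.n_classes,
            "anchor_size": self.anchor_size,
            "roi_size": self.roi_size,
            "mask_size": self.mask_size,
            "fc_dim": self.fc_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


class _ConvNormRelu(Module):
    def __init__(self, cin, cout, stride=1, dilation=1, rng=None):
        self.conv = Conv2d(cin, cout, 3, stride=stride, dilation=dilation, rng=rng)
        self.norm = InstanceNorm2d(cout)

    def forward(self, x):
        return self.norm(self.conv(x)).relu()


class HDCMaskRCNN(Module):
    """Two-stage detector with an HDC final backbone stage (output stride 4).

    The stage that would normally downsample once more instead applies the
    schedule's stacked dilated convolutions at constant resolution, so the
    deepest features keep the stride of the preceding stage.
    """

    def __init__(self, config: DetectorConfig, schedule: DilationSchedule, seed: int = 0):
        rng = np.random.default_rng(seed)
        c0, c1, c2 = config.channels
        self.config = config
        self.schedule = schedule
        self.stride = 4  # two stride-2 stages; the HDC stage adds none

        self.stem = _ConvNormRelu(1, c0, rng=rng)
        self.down1 = _ConvNormRelu(c0, c1, stride=2, rng=rng)
        self.down2 = _ConvNormRelu(c1, c2, stride=2, rng=rng)
        self.hdc_stage = [
            _ConvNormRelu(c2, c2, dilation=r, rng=rng) for r in schedule.rates
        ]

        self.rpn_conv = _ConvNormRelu(c2, c2, rng=rng)
        self.rpn_obj = Conv2d(c2, 1, 1, rng=rng)
        self.rpn_box = Conv2d(c2, 4, 1, rng=rng)

        self.roi_fc = Linear(c2 * config.roi_size**2, config.fc_dim, rng=rng)
        self.cls_head = Linear(config.fc_dim, config.n_classes + 1, rng=rng)
        self.box_head = Linear(config.fc_dim, 4, rng=rng)

        self.mask_conv = _ConvNormRelu(c2, 16, rng=rng)
        self.mask_out = Conv2d(16, 1, 1, rng=rng)

    # -- backbone / heads -------------------------------------------------
    def backbone(self, x: Tensor) -> Tensor:
        h = self.down2(self.down1(self.stem(x)))
        for layer in self.hdc_stage:
            h = layer(h)
        return h

    def rpn(self, features: Tensor) -> tuple[Tensor, Tensor]:
        h = self.rpn_conv(features)
        return self.rpn_obj(h), self.rpn_box(h)

    def roi_heads(self, features: Tensor, box) -> tuple[Tensor, Tensor]:
        crop = roi_align(features, box, self.config.roi_size, 1.0 / self.stride)
        flat = crop.reshape(1, -1)
        h = self.roi_fc(flat).relu()
        return self.cls_head(h), self.box_head(h)

    def mask_head(self, features: Tensor, box) -> Tensor:
        crop = roi_align(features, box, self.config.mask_size, 1.0 / self.stride)
        return self.mask_out(self.mask_conv(crop))

    # -- anchors ----------------------------------------------------------
    def anchors(self, image_hw: tuple[int, int]) -> np.ndarray:
        """(K, 4) [x, y, w, h] square anchors, one per feature cell."""
        fh = image_hw[0] // self.stride
        fw = image_hw[1] // self.stride
        a = self.config.anchor_size
        cy = (np.arange(fh) + 0.5) * self.stride
        cx = (np.arange(fw) + 0.5) * self.stride
        cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
        return np.stack(
            [cxx.ravel() - a / 2, cyy.ravel() - a / 2,
             np.full(fh * fw, a), np.full(fh * fw, a)], axis=1
        )


def build_hdc_maskrcnn(
    backbone_config: DetectorConfig | None = None,
    schedule: DilationSchedule = DilationSchedule((1, 2, 5, 2, 1)),
    n_classes: int = 3,
    seed: int = 0,
    force: bool = False,
) -> HDCMaskRCNN:
    """Construct the detector, validating the HDC schedule first."""
    config = backbone_config or DetectorConfig()
    if config.n_classes != n_classes:
        config = DetectorConfig(**{**config.to_dict(), "n_classes": n_classes})
    report = receptive_field_coverage(schedule)
    if not report.gridding_free and not force:
        raise ValueError(
            f"schedule {schedule.rates} is not gridding-free "
            f"(coverage {report.coverage_fraction:.3f}); pass force=True to override"
        )
    return HDCMaskRCNN(config, schedule, seed=seed)


# --------------------------------------------------------------------------
# Box encoding helpers
# --------------------------------------------------------------------------


def _encode_deltas(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Standard (dx, dy, dw, dh) parametrization from src boxes to dst boxes."""
    sx, sy, sw, sh = src[..., 0], src[..., 1], src[..., 2], src[..., 3]
    dx_, dy_, dw_, dh_ = dst[..., 0], dst[..., 1], dst[..., 2], dst[..., 3]
    scx, scy = sx + sw / 2, sy + sh / 2
    dcx, dcy = dx_ + dw_ / 2, dy_ + dh_ / 2
    return np.stack(
        [(dcx - scx) / sw, (dcy - scy) / sh, np.log(dw_ / sw), np.log(dh_ / sh)],
        axis=-1,
    )


def _decode_deltas(src: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    sx, sy, sw, sh = src[..., 0], src[..., 1], src[..., 2], src[..., 3]
    scx, scy = sx + sw / 2, sy + sh / 2
    d = np.clip(deltas, -4.0, 4.0)
    cx = scx + d[..., 0] * sw
    cy = scy + d[..., 1] * sh
    w = sw * np.exp(d[..., 2])
    h = sh * np.exp(d[..., 3])
    return np.stack([cx - w / 2, cy - h / 2, w, h], axis=-1)


def _clip_box(box: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    h, w = hw
    x0 = np.clip(box[0], 0, w - 1)
    y0 = np.clip(box[1], 0, h - 1)
    x1 = np.clip(box[0] + box[2], x0 + 1e-3, w)
    y1 = np.clip(box[1] + box[3], y0 + 1e-3, h)
    return np.array([x0, y0, x1 - x0, y1 - y0])


def _prep_image(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, CTSlice) else np.asarray(image, dtype=np.float64)
    return (arr / 255.0 - 0.5)[None, None]


def _resize_nearest(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = arr.shape
    ys = np.clip((np.arange(shape[0]) + 0.5) * h / shape[0], 0, h - 1).astype(int)
    xs = np.clip((np.arange(shape[1]) + 0.5) * w / shape[1], 0, w - 1).astype(int)
    return arr[ys[:, None], xs[None, :]]


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


def _rpn_targets(anchors, gt_boxes, rng, n_sample=32):
    """Sample anchor indices and objectness/box targets for the RPN."""
    k = anchors.shape[0]
    if len(gt_boxes):
        iou = np.array([[box_iou(tuple(a), tuple(g)) for g in gt_boxes] for a in anchors])
        best_gt = iou.argmax(axis=1)
        best_iou = iou.max(axis=1)
        pos = best_iou >= 0.5
        for gi in range(len(gt_boxes)):
            pos[iou[:, gi].argmax()] = True
        neg = best_iou < 0.3
    else:
        pos = np.zeros(k, dtype=bool)
        neg = np.ones(k, dtype=bool)
        best_gt = np.zeros(k, dtype=int)
    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(neg)
    if pos_idx.size > n_sample // 2:
        pos_idx = rng.choice(pos_idx, n_sample // 2, replace=False)
    n_neg = min(neg_idx.size, n_sample - pos_idx.size)
    if neg_idx.size > n_neg:
        neg_idx = rng.choice(neg_idx, n_neg, replace=False)
    box_targets = None
    if pos_idx.size and len(gt_boxes):
        box_targets = _encode_deltas(
            anchors[pos_idx], np.asarray(gt_boxes)[best_gt[pos_idx]]
        )
    return pos_idx, neg_idx, box_targets


def _training_proposals(gt_boxes, gt_classes, hw, anchor, rng):
    """GT boxes, jittered copies (positives) and random crops (background)."""
    props: list[tuple[np.ndarray, int, int]] = []  # (box, label, gt index)
    for gi, (box, cls) in enumerate(zip(gt_boxes, gt_classes)):
        box = np.asarray(box, dtype=np.float64)
        props.append((box, cls, gi))
        for _ in range(2):
            jitter = rng.normal(0, 0.08, 4) * np.array([box[2], box[3], box[2], box[3]])
            jb = _clip_box(box + jitter, hw)
            props.append((jb, cls, gi))
    for _ in range(4):
        x = rng.uniform(0, hw[1] - anchor)
        y = rng.uniform(0, hw[0] - anchor)
        cand = np.array([x, y, anchor, anchor])
        if all(box_iou(tuple(cand), tuple(g)) < 0.3 for g in gt_boxes):
            props.append((cand, 0, -1))
    return props


def train_detector(
    model: HDCMaskRCNN,
    dataset: list[dict],
    steps: int = 200,
    lr: float = 2e-3,
    seed: int = 0,
) -> tuple[HDCMaskRCNN, list[float]]:
    """Train on phantom-style samples; one image per step, cycled in order.

    ``dataset`` entries are dicts with keys ``image`` (CTSlice or array) and
    ``annotations`` — COCO-style records carrying ``bbox``, ``category_id``
    and a decoded boolean ``mask``. The recorded trace holds the combined
    RPN + class + box + mask loss per step. Deterministic for a fixed seed.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    losses: list[float] = []
    for step in range(steps):
        sample = dataset[step % len(dataset)]
        arr = _prep_image(sample["image"])
        hw = arr.shape[2], arr.shape[3]
        gt_boxes = [tuple(a["bbox"]) for a in sample["annotations"]]
        gt_classes = [int(a["category_id"]) for a in sample["annotations"]]
        gt_masks = [a.get("mask") for a in sample["annotations"]]

        features = model.backbone(Tensor(arr))
        obj_logits, box_deltas = model.rpn(features)
        anchors = model.anchors(hw)

        pos_idx, neg_idx, box_targets = _rpn_targets(anchors, gt_boxes, rng)
        obj_flat = obj_logits.reshape(1, -1)
        sampled = np.concatenate([pos_idx, neg_idx]).astype(int)
        obj_sel = obj_flat[:, sampled]
        obj_tgt = np.concatenate([np.ones(pos_idx.size), np.zeros(neg_idx.size)])[None]
        loss = sigmoid_bce(obj_sel, obj_tgt)
        if box_targets is not None:
            deltas_flat = box_deltas.reshape(1, 4, -1)
            loss = loss + smooth_l1(deltas_flat[:, :, pos_idx.astype(int)],
                                    box_targets.T[None], beta=0.1)

        props = _training_proposals(gt_boxes, gt_classes, hw, model.config.anchor_size, rng)
        for box, label, gi in props:
            cls_logits, roi_deltas = model.roi_heads(features, tuple(box))
            loss = loss + softmax_cross_entropy(cls_logits, np.array([label])) * (
                1.0 / len(props)
            )
            if label > 0:
                tgt = _encode_deltas(box[None], np.asarray(gt_boxes[gi])[None])
                loss = loss + smooth_l1(roi_deltas, tgt, beta=0.1) * (1.0 / len(props))
                if gt_masks[gi] is not None:
                    mlogits = model.mask_head(features, tuple(box))
                    x0, y0 = int(round(box[0])), int(round(box[1]))
                    x1 = max(int(round(box[0] + box[2])), x0 + 1)
                    y1 = max(int(round(box[1] + box[3])), y0 + 1)
                    crop = np.asarray(gt_masks[gi], dtype=float)[y0:y1, x0:x1]
                    if crop.size:
                        tgt_mask = _resize_nearest(
                            crop, (model.config.mask_size, model.config.mask_size)
                        )
                        loss = loss + sigmoid_bce(
                            mlogits.reshape(1, -1), tgt_mask.reshape(1, -1)
                        ) * (1.0 / len(props))

        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return model, losses


# --------------------------------------------------------------------------
# Inference
# --------------------------------------------------------------------------


def detect_bronchiectasis(
    model: HDCMaskRCNN,
    image: CTSlice | np.ndarray,
    confidence_threshold: float = 0.5,
    nms_iou: float = 0.5,
    max_proposals: int = 20,
) -> list[Detection]:
    """Run the two-stage detector on one slice.

    Returns thresholded, NMS-filtered detections sorted by confidence
    descending, each with a full-size binary instance mask.
    """
    arr = _prep_image(image)
    hw = arr.shape[2], arr.shape[3]
    features = model.backbone(Tensor(arr))
    obj_logits, box_deltas = model.rpn(features)
    anchors = model.anchors(hw)
    scores = 1.0 / (1.0 + np.exp(-obj_logits.data.reshape(-1)))
    deltas = box_deltas.data.reshape(4, -1).T
    boxes = np.array([_clip_box(b, hw) for b in _decode_deltas(anchors, deltas)])

    top = np.argsort(-scores)[: max(4 * max_proposals, 50)]
    keep = nms([tuple(boxes[i]) for i in top], [float(scores[i]) for i in top], 0.7)
    proposals = [boxes[top[i]] for i in keep[:max_proposals]]

    raw: list[Detection] = []
    raw_boxes, raw_scores = [], []
    for prop in proposals:
        cls_logits, roi_deltas = model.roi_heads(features, tuple(prop))
        probs = softmax_probs(cls_logits.data[0])
        cls = int(np.argmax(probs))
        if cls == 0:
            continue
        conf = float(probs[cls])
        if conf < confidence_threshold:
            continue
        refined = _clip_box(_decode_deltas(prop[None], roi_deltas.data)[0], hw)
        mlogits = model.mask_head(features, tuple(refined))
        msmall = 1.0 / (1.0 + np.exp(-mlogits.data[0, 0]))
        x0, y0 = int(np.floor(refined[0])), int(np.floor(refined[1]))
        x1 = min(int(np.ceil(refined[0] + refined[2])), hw[1])
        y1 = min(int(np.ceil(refined[1] + refined[3])), hw[0])
        full = np.zeros(hw, dtype=bool)
        if x1 > x0 and y1 > y0:
            full[y0:y1, x0:x1] = _resize_nearest(msmall, (y1 - y0, x1 - x0)) >= 0.5
        raw.append(
            Detection(bbox=tuple(refined), mask=full, severity_class=cls, confidence=conf)
        )
        raw_boxes.append(tuple(refined))
        raw_scores.append(conf)

    if confidence_threshold > 1.0 or not raw:
        return []
    keep = nms(raw_boxes, raw_scores, nms_iou)
    return [raw[i] for i in keep]


def save_detector(model: HDCMaskRCNN, path: str | os.PathLike) -> None:
    """Weights to .npz with a JSON sidecar (config + schedule)."""
    path = os.fspath(path)
    np.savez(path, **model.state_dict())
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(
            {"config": model.config.to_dict(), "schedule": list(model.schedule.rates)}, fh
        )


def load_detector(path: str | os.PathLike) -> HDCMaskRCNN:
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    with open(path[:-4] + ".json") as fh:
        meta = json.load(fh)
    model = build_hdc_maskrcnn(
        DetectorConfig.from_dict(meta["config"]),
        DilationSchedule(tuple(meta["schedule"])),
        n_classes=meta["config"]["n_classes"],
    )
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
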