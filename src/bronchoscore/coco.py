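"""Minimal COCO-style instance-annotation JSON support.

Instance masks are stored as uncompressed run-length encodings in the COCO
convention: column-major (Fortran-order) scan, alternating run lengths
starting with the number of leading zeros. Only the subset of the format the
phantom datasets and detector harness need is implemented: images,
annotations with bbox ``[x, y, w, h]`` (0-based pixel coordinates),
segmentation RLE, and severity-grade categories {1, 2, 3}.
"""

from __future__ import annotations

import json
import os

import numpy as np

__all__ = ["rle_encode", "rle_decode", "bbox_from_mask", "write_coco", "read_coco"]


def rle_encode(mask: np.ndarray) -> dict:
    """Binary mask -> COCO uncompressed RLE dict {'size': [h, w], 'counts': [...]}."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.flatten(order="F").astype(np.int8)
    # run boundaries; counts start with the leading-zero run (possibly 0)
    change = np.flatnonzero(np.diff(flat)) + 1
    idx = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(idx).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    """COCO uncompressed RLE dict -> boolean mask."""
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for count in rle["counts"]:
        if val:
            flat[pos : pos + count] = True
        pos += count
        val = not val
    if pos != h * w:
        raise ValueError("RLE counts do not cover the mask")
    return flat.reshape((h, w), order="F")


def bbox_from_mask(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight [x, y, w, h] bounding box of a nonzero mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    return (x0, y0, x1 - x0 + 1, y1 - y0 + 1)


GRADE_CATEGORIES = [
    {"id": 1, "name": "grade1_mild"},
    {"id": 2, "name": "grade2_moderate"},
    {"id": 3, "name": "grade3_severe"},
]


def write_coco(path: str | os.PathLike, images: list[dict], annotations: list[dict]) -> None:
    doc = {"images": images, "annotations": annotations, "categories": GRADE_CATEGORIES}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_coco(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"not a COCO-style annotation file: missing {key!r}")
    return doc
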