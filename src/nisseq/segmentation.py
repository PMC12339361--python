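"""Object segmentation interface and label-image utilities.

Segmentation is pluggable: the published analysis used a learned segmenter
(Cellpose); here the backend is an interface, with a deterministic built-in
classical backend (Otsu threshold → hole fill → distance-transform
watershed) that all tests use.  The 'cellpose' backend is registered and
delegates to the optional cellpose package when it is importable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.segmentation import watershed


@dataclass
class LabelImage:
    """Labeled objects: 0 = background, k>0 = object k, plus an object table.

    The table has columns label, row, col (centroid, px) and area (px).
    """

    labels: np.ndarray
    table: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return len(self.table)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelImage":
        labels = np.asarray(labels)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if labels.max() == 0:
            table = pd.DataFrame(columns=["label", "row", "col", "area"])
        else:
            props = regionprops_table(
                labels, properties=("label", "centroid", "area")
            )
            table = pd.DataFrame(
                {
                    "label": props["label"],
                    "row": props["centroid-0"],
                    "col": props["centroid-1"],
                    "area": props["area"].astype(int),
                }
            )
        return cls(labels=labels, table=table)


def _watershed_backend(image: np.ndarray, mode: str) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.max() <= image.min():
        return np.zeros(image.shape, dtype=np.int32)
    smooth = ndi.gaussian_filter(image, 2.0)
    thresh = threshold_otsu(smooth)
    mask = smooth > thresh
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    # seed markers: maxima of the smoothed distance map, one per object
    dsm = ndi.gaussian_filter(dist, 2.0)
    peaks = (dsm == ndi.maximum_filter(dsm, size=9)) & (dist > 2)
    markers, _ = ndi.label(peaks)
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    labels = watershed(-dist, markers, mask=mask)
    return labels.astype(np.int32)


def _cellpose_backend(image: np.ndarray, mode: str) -> np.ndarray:
    try:
        from cellpose import models
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "cellpose backend requested but the cellpose package is not "
            "installed; use backend='watershed'"
        ) from exc
    model_type = "nuclei" if mode == "nuclei" else "cyto2"
    model = models.Cellpose(model_type=model_type)  # pragma: no cover
    masks = model.eval(image, channels=[0, 0])[0]  # pragma: no cover
    return masks.astype(np.int32)  # pragma: no cover


BACKENDS = {
    "watershed": _watershed_backend,
    "cellpose": _cellpose_backend,
}


def segment_objects(
    image: np.ndarray, mode: str = "nuclei", backend: str = "watershed"
) -> LabelImage:
    """Segment bright objects (nuclei or cells) from a 2D intensity image."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if backend not in BACKENDS:
        raise ValueError(
            f"unknown backend {backend!r}; available: {sorted(BACKENDS)}"
        )
    labels = BACKENDS[backend](image, mode)
    return LabelImage.from_labels(labels)


def shrink_labels(labels: LabelImage, px: int) -> LabelImage:
    """Erode every object by ``px`` pixels; objects eroded away are dropped.

    Used to predict nucleus locations from membrane-derived cell outlines.
    """
    if px < 0:
        raise ValueError("px must be >= 0")
    if px == 0:
        return LabelImage.from_labels(labels.labels.copy())
    out = np.zeros_like(labels.labels)
    structure = ndi.generate_binary_structure(2, 1)
    for lab in labels.table["label"]:
        mask = labels.labels == lab
        eroded = ndi.binary_erosion(mask, structure=structure, iterations=px)
        out[eroded] = lab
    return LabelImage.from_labels(out)
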