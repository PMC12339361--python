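"""Single-cell phenotype quantification from live-cell images.

Two readouts are implemented.  Nuclear translocation (e.g. of an NF-κB
p65 fluorescent fusion) is the Pearson correlation between the nuclear
stain and the reporter across the pixels of each cell: cytosolic reporter
anticorrelates with the nuclear stain, translocated reporter correlates.
Inflammasome specking (e.g. ASC or C1C puncta) is the ratio of the mean
high-pass-filtered reporter signal to the mean overall reporter signal per
cell, after local background subtraction: a micron-scale punctum survives
the high-pass while diffuse signal does not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .params import PipelineParams
from .segmentation import LabelImage
from .spots import frequency_filter


def collapse_z(zstack: np.ndarray) -> np.ndarray:
    """Collapse a z-stack by pixelwise averaging."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim == 2:
        return zstack
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("z-stack must be (Z, H, W) with Z >= 1")
    return zstack.mean(axis=0)


def local_background_subtract(
    image: np.ndarray, params: PipelineParams | None = None
) -> np.ndarray:
    """Subtract a local-minimum background estimated on a downsampled grid.

    The image is downsampled ``bg_downsample``-fold (8×8 by default); for
    each full-resolution pixel the local minimum across the ``bg_window``
    (9×9) closest downsampled pixels is subtracted, and negatives are set
    to zero.
    """
    params = params or PipelineParams()
    image = np.asarray(image, dtype=float)
    f = params.bg_downsample
    H, W = image.shape
    ph = (-H) % f
    pw = (-W) % f
    padded = np.pad(image, ((0, ph), (0, pw)), mode="edge")
    ds = padded.reshape(padded.shape[0] // f, f, padded.shape[1] // f, f).mean(
        axis=(1, 3)
    )
    local_min = ndi.minimum_filter(ds, size=params.bg_window, mode="nearest")
    bg = np.repeat(np.repeat(local_min, f, axis=0), f, axis=1)[:H, :W]
    return np.clip(image - bg, 0, None)


def translocation_score(
    cells: LabelImage,
    nuclear: np.ndarray,
    reporter: np.ndarray,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Per-cell Pearson correlation between nuclear stain and reporter.

    Raw channels are used (no background subtraction).  Cells with fewer
    than ``min_cell_pixels`` pixels or zero variance in either channel get
    a missing score.
    """
    params = params or PipelineParams()
    nuclear = np.asarray(nuclear, dtype=float)
    reporter = np.asarray(reporter, dtype=float)
    if nuclear.shape != reporter.shape or nuclear.shape != cells.labels.shape:
        raise ValueError("channels and labels must share one frame")
    rows = []
    for _, obj in cells.table.iterrows():
        mask = cells.labels == obj["label"]
        r = np.nan
        x = nuclear[mask]
        y = reporter[mask]
        if mask.sum() >= params.min_cell_pixels and x.std() > 0 and y.std() > 0:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "label": int(obj["label"]),
                "row": obj["row"],
                "col": obj["col"],
                "area": int(obj["area"]),
                "mean_reporter": float(y.mean()),
                "translocation_r": r,
            }
        )
    return pd.DataFrame(rows)


def speck_score(
    cells: LabelImage,
    reporter: np.ndarray,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Per-cell high-pass/total reporter ratio measuring punctate aggregation.

    The reporter is background-subtracted, high-pass filtered with
    negatives zeroed, and the ratio of the per-cell mean after vs before
    filtering is reported.  Cells whose mean reporter falls below the
    expression-gate percentile (or is zero) are flagged excluded.
    """
    params = params or PipelineParams()
    reporter = np.asarray(reporter, dtype=float)
    if reporter.shape != cells.labels.shape:
        raise ValueError("reporter and labels must share one frame")
    bg = local_background_subtract(reporter, params)
    hp = frequency_filter(bg, params.speck_highpass_sigma, "highpass")
    rows = []
    for _, obj in cells.table.iterrows():
        mask = cells.labels == obj["label"]
        denom = float(bg[mask].mean())
        numer = float(hp[mask].mean())
        rows.append(
            {
                "label": int(obj["label"]),
                "row": obj["row"],
                "col": obj["col"],
                "area": int(obj["area"]),
                "mean_reporter": denom,
                "speck_ratio": numer / denom if denom > 0 else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        gate = np.percentile(
            df["mean_reporter"], params.expression_gate_percentile
        )
        df["excluded_low_expression"] = (df["mean_reporter"] <= 0) | (
            df["mean_reporter"] < gate
        )
    else:
        df["excluded_low_expression"] = pd.Series(dtype=bool)
    return df
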