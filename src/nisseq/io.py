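"""TIFF input/output for cycle stacks and label images."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .registration import CycleStack
from .segmentation import LabelImage


def write_stack(stack: CycleStack, out_dir) -> None:
    """Write one TIFF per cycle/channel: cycle{c:02d}_{nuclear|ch1..3}.tif."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in range(stack.n_cycles):
        tifffile.imwrite(
            out / f"cycle{c:02d}_nuclear.tif",
            stack.nuclear[c].astype(np.float32),
        )
        for ch in range(3):
            tifffile.imwrite(
                out / f"cycle{c:02d}_ch{ch + 1}.tif",
                stack.channels[c, ch].astype(np.float32),
            )


def read_stack(in_dir, pixel_size_um: float = 0.65) -> CycleStack:
    """Read a stack written by :func:`write_stack`."""
    d = Path(in_dir)
    nuc_paths = sorted(d.glob("cycle*_nuclear.tif"))
    if not nuc_paths:
        raise FileNotFoundError(f"no cycle*_nuclear.tif files in {d}")
    nuclear = np.stack([tifffile.imread(p).astype(float) for p in nuc_paths])
    channels = np.stack(
        [
            np.stack(
                [
                    tifffile.imread(
                        p.with_name(p.name.replace("_nuclear", f"_ch{ch + 1}"))
                    ).astype(float)
                    for ch in range(3)
                ]
            )
            for p in nuc_paths
        ]
    )
    return CycleStack(nuclear=nuclear, channels=channels, pixel_size_um=pixel_size_um)


def write_labels(labels: LabelImage, path) -> None:
    """Write a label image as 16-bit single-channel TIFF."""
    arr = labels.labels
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many objects for 16-bit labels")
    tifffile.imwrite(path, arr.astype(np.uint16))


def read_labels(path) -> LabelImage:
    return LabelImage.from_labels(tifffile.imread(path).astype(np.int32))
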