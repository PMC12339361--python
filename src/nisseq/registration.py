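"""Cycle-to-cycle image registration by FFT cross-correlation.

Sequencing cycles drift by a few pixels between acquisitions.  Each cycle's
nuclear-stain image is registered to the first cycle by FFT-accelerated
cross-correlation, and the recovered integer shift is applied to that
cycle's three sequencing channels.  Integer shifts suffice because spot
intensities are aggregated over a 5×5-pixel window downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RegistrationError(RuntimeError):
    pass


@dataclass
class Shift:
    """Estimated drift (dy, dx) of a moving image relative to the reference.

    The convention is mov ≈ roll(ref, (dy, dx)); the correction that aligns
    mov onto ref is a translation by (−dy, −dx).
    """

    dy: int
    dx: int
    peak_corr: float = 1.0

    def __iter__(self):
        return iter((self.dy, self.dx))


@dataclass
class CycleStack:
    """Multi-cycle image tensor: per cycle one nuclear + three sequencing channels.

    ``nuclear`` has shape (C, H, W); ``channels`` has shape (C, 3, H, W).
    ``shifts`` records the per-cycle drift estimate (cycle 0 is zero once
    the stack is aligned).
    """

    nuclear: np.ndarray
    channels: np.ndarray
    pixel_size_um: float = 0.65
    shifts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nuclear.ndim != 3 or self.channels.ndim != 4:
            raise ValueError("nuclear must be (C,H,W), channels (C,3,H,W)")
        if self.channels.shape[0] != self.nuclear.shape[0]:
            raise ValueError("cycle count mismatch between nuclear and channels")
        if self.channels.shape[2:] != self.nuclear.shape[1:]:
            raise ValueError("image shape mismatch between nuclear and channels")

    @property
    def n_cycles(self) -> int:
        return self.nuclear.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape[1:]


def filter_edge_fovs(stage_positions_um: dict, n_edge: int = 2) -> list:
    """Names of FOVs at least ``n_edge`` grid rows/cols from the scan border.

    Edge tiles of a plate scan are prone to empty or distorted images;
    excluding the outer rows is an optional quality filter.
    """
    names = list(stage_positions_um)
    ys = sorted({round(stage_positions_um[n][0], 3) for n in names})
    xs = sorted({round(stage_positions_um[n][1], 3) for n in names})
    keep_y = set(ys[n_edge : len(ys) - n_edge])
    keep_x = set(xs[n_edge : len(xs) - n_edge])
    return [
        n
        for n in names
        if round(stage_positions_um[n][0], 3) in keep_y
        and round(stage_positions_um[n][1], 3) in keep_x
    ]


def translate(image: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill for out-of-frame pixels."""
    out = np.roll(np.roll(image, dy, axis=0), dx, axis=1)
    if dy > 0:
        out[:dy, :] = 0
    elif dy < 0:
        out[dy:, :] = 0
    if dx > 0:
        out[:, :dx] = 0
    elif dx < 0:
        out[:, dx:] = 0
    return out


def register_translation(
    ref: np.ndarray,
    mov: np.ndarray,
    max_shift: int = 50,
    min_corr: float | None = None,
) -> Shift:
    """Integer shift maximizing circular normalized cross-correlation.

    The cross-correlation surface is computed in the frequency domain on
    mean-subtracted images and searched over |dy|, |dx| ≤ max_shift.  A peak
    on the search boundary, or (when ``min_corr`` is given) a peak below
    that normalized-correlation floor, raises RegistrationError — both
    indicate the true drift is outside the trusted range.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    a = ref - ref.mean()
    b = mov - mov.mean()
    if not a.any() or not b.any():
        raise RegistrationError("no structure to register (constant image)")
    # corr(dy,dx) = sum_xy a(y,x) * b(y+dy, x+dx)  (circular)
    corr = np.fft.irfft2(np.fft.rfft2(b) * np.conj(np.fft.rfft2(a)), s=a.shape)
    norm = np.sqrt((a * a).sum() * (b * b).sum())
    corr /= norm
    H, W = a.shape
    max_dy = min(max_shift, H // 2)
    max_dx = min(max_shift, W // 2)
    dys = np.concatenate([np.arange(0, max_dy + 1), np.arange(-max_dy, 0)])
    dxs = np.concatenate([np.arange(0, max_dx + 1), np.arange(-max_dx, 0)])
    window = corr[np.ix_(dys % H, dxs % W)]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy, dx = int(dys[iy]), int(dxs[ix])
    peak = float(window[iy, ix])
    if (abs(dy) == max_dy and max_dy > 0) or (abs(dx) == max_dx and max_dx > 0):
        raise RegistrationError(
            f"correlation peak at search boundary ({dy},{dx}); "
            f"drift may exceed max_shift={max_shift}"
        )
    if min_corr is not None and peak < min_corr:
        raise RegistrationError(
            f"peak correlation {peak:.3f} below floor {min_corr}"
        )
    return Shift(dy=dy, dx=dx, peak_corr=peak)


def align_cycles(
    stack: CycleStack, max_shift: int = 50, min_corr: float | None = None
) -> CycleStack:
    """Register every cycle to cycle 0 via the nuclear channel.

    The recovered shift is applied to the cycle's nuclear image and all
    three sequencing channels; out-of-frame pixels are zero-filled.
    """
    C = stack.n_cycles
    nuclear = stack.nuclear.copy()
    channels = stack.channels.copy()
    shifts = [Shift(0, 0, 1.0)]
    for c in range(1, C):
        try:
            s = register_translation(
                nuclear[0], stack.nuclear[c], max_shift=max_shift, min_corr=min_corr
            )
        except RegistrationError as exc:
            raise RegistrationError(f"cycle {c}: {exc}") from exc
        nuclear[c] = translate(stack.nuclear[c], -s.dy, -s.dx)
        for ch in range(channels.shape[1]):
            channels[c, ch] = translate(stack.channels[c, ch], -s.dy, -s.dx)
        shifts.append(s)
    return CycleStack(
        nuclear=nuclear,
        channels=channels,
        pixel_size_um=stack.pixel_size_um,
        shifts=shifts,
    )
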