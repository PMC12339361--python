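"""Rolling-circle-amplification spot detection, crosstalk unmixing and base calling.

Each transduced nucleus carries one dominant amplification spot whose
per-cycle three-channel color encodes one base of the barcode's detect
sequence.  The chemistry is three-color: A, C and T each light up one
channel (with optical crosstalk between them) while G is dark — a G cycle
is recognized by all channels being dim relative to the spot's maximum.

The calling chain is: high-pass filter each channel, aggregate intensities
over a 5×5 window per spot, estimate the 3×3 base→channel crosstalk matrix
from base-wise average channel intensities, multiply each cycle's channel
vector by its inverse, and call the argmax channel (or dark-G).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .params import PipelineParams
from .registration import CycleStack

#: default channel → base mapping for the three-color chemistry:
#: channel 1 (477 nm) = A, channel 2 (546 nm) = C, channel 3 (638 nm) = T,
#: G dark.  Configurable because the mapping is chemistry-dependent.
DEFAULT_CHANNEL_BASES = ("A", "C", "T")


@dataclass
class SpotProfile:
    """Per-spot cycles×3 intensity matrices and the called sequence."""

    spot_id: int
    position: tuple[int, int]
    raw: np.ndarray  # (C, 3), high-pass filtered, negatives removed, window-summed
    unmixed: np.ndarray | None = None  # (C, 3)
    sequence: str = ""
    max_unmixed: float = 0.0
    edge_flag: bool = False

    @property
    def n_cycles(self) -> int:
        return self.raw.shape[0]

    def total_intensity(self) -> float:
        """Sum of positive unmixed entries across cycles and channels."""
        if self.unmixed is None:
            raise ValueError("profile not unmixed yet")
        return float(np.clip(self.unmixed, 0, None).sum())


@dataclass
class CrosstalkMatrix:
    """3×3 base→channel intensity signatures, one column per bright base.

    Columns follow ``channel_bases`` order; each column is scaled so its
    maximum entry is 1.  The inverse converts measured channel vectors into
    base-space intensities.
    """

    M: np.ndarray
    channel_bases: tuple[str, str, str] = DEFAULT_CHANNEL_BASES
    _inv: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (3, 3):
            raise ValueError("crosstalk matrix must be 3×3")
        if (self.M < 0).any():
            raise ValueError("crosstalk matrix entries must be non-negative")

    def inverse(self, max_condition: float = 1e3) -> np.ndarray:
        if self._inv is None:
            cond = np.linalg.cond(self.M)
            if not np.isfinite(cond) or cond > max_condition:
                raise ValueError(
                    f"crosstalk matrix ill-conditioned (cond={cond:.3g})"
                )
            self._inv = np.linalg.inv(self.M)
        return self._inv

    @classmethod
    def identity(cls) -> "CrosstalkMatrix":
        return cls(M=np.eye(3))


def frequency_filter(
    image: np.ndarray, sigma: float, mode: str = "highpass"
) -> np.ndarray:
    """Gaussian frequency filter.

    highpass: image − Gaussian blur, negatives set to zero (removes the
    smooth cellular background under the spots).  lowpass: Gaussian blur
    (used to tolerate imperfect alignment in distorted samples).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    image = np.asarray(image, dtype=float)
    blur = ndi.gaussian_filter(image, sigma)
    if mode == "highpass":
        return np.clip(image - blur, 0, None)
    if mode == "lowpass":
        return blur
    raise ValueError(f"unknown mode {mode!r}")


def _local_maxima(image: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Strict 8-connected local maxima above threshold.

    Equal-valued plateaus that dominate their surroundings keep only the
    first pixel in scan order, giving a deterministic tie-break.
    """
    maxf = ndi.maximum_filter(image, size=3, mode="constant", cval=-np.inf)
    candidates = (image >= maxf) & (image >= threshold)
    if not candidates.any():
        return []
    # group equal-valued candidate plateaus, keep first pixel in scan order
    lab, n = ndi.label(candidates)
    slices = ndi.find_objects(lab)
    out = []
    struct = np.ones((3, 3), bool)
    H, W = image.shape
    for k in range(1, n + 1):
        sl = slices[k - 1]
        # widen the bounding box by 1 px to see the plateau border
        rs = slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, H))
        cs = slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, W))
        sub = image[rs, cs]
        mask = lab[rs, cs] == k
        vals = sub[mask]
        if not np.allclose(vals, vals[0]):
            # mixed-value component: keep strict maxima only
            mask = mask & (sub == vals.max())
        # strictness: plateau must exceed all pixels bordering it
        border = ndi.binary_dilation(mask, structure=struct) & ~mask
        if border.any() and sub[border].max() >= sub[mask].max():
            continue
        rows, cols = np.nonzero(mask)
        i = np.lexsort((cols, rows))[0]
        out.append((int(rows[i]) + rs.start, int(cols[i]) + cs.start))
    out.sort(key=lambda rc: (-image[rc], rc))
    return out


def detect_spots(
    stack: CycleStack, params: PipelineParams | None = None
) -> list[tuple[int, int]]:
    """Detect spot positions on the summed, high-pass-filtered detection image.

    All three sequencing channels are summed across the first
    ``n_detection_cycles`` cycles, high-pass filtered, and strict local
    maxima above the detection threshold are returned sorted by intensity
    descending.  The threshold is max(absolute floor, median + k·MAD) of
    the filtered image.
    """
    params = params or PipelineParams()
    if stack.n_cycles < params.n_detection_cycles:
        raise ValueError(
            f"stack has {stack.n_cycles} cycles, need {params.n_detection_cycles}"
        )
    detection = stack.channels[: params.n_detection_cycles].sum(axis=(0, 1))
    # threshold statistics on the signed high-pass difference; the clipped
    # image has a zero-inflated background that collapses the MAD
    diff = detection - ndi.gaussian_filter(detection, params.highpass_sigma)
    med = float(np.median(diff))
    mad = float(np.median(np.abs(diff - med)))
    threshold = max(
        params.detect_abs_floor, med + params.detect_k_mad * mad
    )
    filtered = np.clip(diff, 0, None)
    return _local_maxima(filtered, threshold)


def extract_profiles(
    stack: CycleStack,
    positions: list[tuple[int, int]],
    params: PipelineParams | None = None,
) -> list[SpotProfile]:
    """Aggregate per-cycle per-channel intensities over each spot's window.

    Each channel image is high-pass filtered with negatives zeroed, then
    summed over the spot_window × spot_window window centered on the spot.
    Windows clipped by the image border set ``edge_flag``.
    """
    params = params or PipelineParams()
    H, W = stack.shape
    half = params.spot_window // 2
    C = stack.n_cycles
    filtered = np.empty_like(stack.channels)
    for c in range(C):
        for ch in range(3):
            filtered[c, ch] = frequency_filter(
                stack.channels[c, ch], params.highpass_sigma, "highpass"
            )
    profiles = []
    for sid, (r, cpos) in enumerate(positions):
        if not (0 <= r < H and 0 <= cpos < W):
            raise ValueError(f"spot position {(r, cpos)} outside image bounds")
        r0, r1 = r - half, r + half + 1
        c0, c1 = cpos - half, cpos + half + 1
        edge = r0 < 0 or c0 < 0 or r1 > H or c1 > W
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, H), min(c1, W)
        raw = filtered[:, :, r0:r1, c0:c1].sum(axis=(2, 3))
        profiles.append(
            SpotProfile(
                spot_id=sid, position=(r, cpos), raw=raw, edge_flag=bool(edge)
            )
        )
    return profiles


def _provisional_calls(
    mat: np.ndarray, g_dark_fraction: float
) -> np.ndarray:
    """Per-cycle provisional class: 0/1/2 = bright channel argmax, -1 = dark."""
    spot_max = mat.max()
    calls = np.argmax(mat, axis=1)
    dark = (mat < g_dark_fraction * spot_max).all(axis=1)
    calls[dark] = -1
    return calls


def estimate_crosstalk(
    profiles: list[SpotProfile],
    params: PipelineParams | None = None,
    channel_bases: tuple[str, str, str] = DEFAULT_CHANNEL_BASES,
    min_per_class: int = 30,
    iterate: bool = True,
) -> CrosstalkMatrix:
    """Self-calibrate the crosstalk matrix from base-wise mean channel vectors.

    Bootstrap: provisionally call each bright (spot, cycle) observation by
    its raw argmax channel, average the 3-channel vectors per provisional
    base, column-normalize to build M, then optionally refine once with
    calls made on unmixed vectors.  Deterministic.
    """
    params = params or PipelineParams()
    raws = np.concatenate([p.raw for p in profiles], axis=0)
    calls = np.concatenate(
        [_provisional_calls(p.raw, params.g_dark_fraction) for p in profiles]
    )

    def build(assignments: np.ndarray) -> np.ndarray:
        M = np.zeros((3, 3))
        for base in range(3):
            sel = assignments == base
            if sel.sum() < min_per_class:
                raise ValueError(
                    "insufficient base diversity: provisional class "
                    f"{channel_bases[base]} has {int(sel.sum())} observations "
                    f"(need {min_per_class})"
                )
            M[:, base] = raws[sel].mean(axis=0)
        return M / M.max(axis=0, keepdims=True)

    M = build(calls)
    if iterate:
        inv = CrosstalkMatrix(M, channel_bases).inverse(
            params.max_crosstalk_condition
        )
        unmixed = raws @ inv.T
        refined = np.argmax(unmixed, axis=1)
        refined[calls == -1] = -1
        M = build(refined)
    return CrosstalkMatrix(M=M, channel_bases=channel_bases)


def unmix(
    profile: SpotProfile,
    M: CrosstalkMatrix,
    max_condition: float = 1e3,
) -> SpotProfile:
    """Multiply each cycle's channel vector by the inverse crosstalk matrix.

    Negative unmixed values are preserved; clamping is deferred to calling.
    """
    inv = M.inverse(max_condition)
    profile.unmixed = profile.raw @ inv.T
    profile.max_unmixed = float(profile.unmixed.max()) if profile.unmixed.size else 0.0
    return profile


def call_bases(
    profile: SpotProfile,
    params: PipelineParams | None = None,
    channel_bases: tuple[str, str, str] = DEFAULT_CHANNEL_BASES,
) -> SpotProfile:
    """Call one base per cycle from the unmixed intensities.

    Bright bases are the argmax unmixed channel; G is called at cycles
    where all three unmixed intensities fall below ``g_dark_fraction`` of
    the spot's maximum unmixed intensity across all cycles.  An exact tie
    between the top two channels yields N; a spot with no positive signal
    is called all-N.
    """
    params = params or PipelineParams()
    if profile.unmixed is None:
        raise ValueError("profile must be unmixed before calling")
    U = profile.unmixed
    if profile.max_unmixed <= 0:
        profile.sequence = "N" * profile.n_cycles
        return profile
    dark_level = params.g_dark_fraction * profile.max_unmixed
    seq = []
    for c in range(profile.n_cycles):
        row = U[c]
        if (row < dark_level).all():
            seq.append("G")
            continue
        order = np.argsort(row)[::-1]
        if row[order[0]] == row[order[1]]:
            seq.append("N")
        else:
            seq.append(channel_bases[order[0]])
    profile.sequence = "".join(seq)
    return profile


def call_stack(
    stack: CycleStack,
    params: PipelineParams | None = None,
    crosstalk: CrosstalkMatrix | None = None,
    channel_bases: tuple[str, str, str] = DEFAULT_CHANNEL_BASES,
) -> tuple[list[SpotProfile], CrosstalkMatrix]:
    """Full calling chain: detect → extract → estimate crosstalk → unmix → call."""
    params = params or PipelineParams()
    positions = detect_spots(stack, params)
    profiles = extract_profiles(stack, positions, params)
    if crosstalk is None:
        crosstalk = estimate_crosstalk(profiles, params, channel_bases)
    for p in profiles:
        unmix(p, crosstalk, params.max_crosstalk_condition)
        call_bases(p, params, channel_bases)
    return profiles, crosstalk
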