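"""Linking live-phenotype and sequencing fields of view and matching nuclei.

Phenotype and sequencing images are acquired in separate sessions, possibly
at different magnifications.  Candidate field-of-view (FOV) pairs are found
from microscope stage positions, the phenotype image is rescaled by the
magnification ratio, pairs are coarsely mapped at 8×8-downsampled
resolution by FFT cross-correlation and refined at 2×2, and finally nuclei
are matched one-to-one by centers of gravity under a maximum movement
distance of 11.1 µm and a two-fold nuclear-area margin, with ambiguous
mappings excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import block_reduce
from skimage.transform import rescale

from .params import PipelineParams
from .registration import RegistrationError, Shift, register_translation
from .segmentation import LabelImage


@dataclass
class FovPair:
    pheno_fov: str
    nis_fov: str
    scale: float  # pheno px per NIS px
    coarse_shift: Shift
    fine_shift: Shift
    corr: float

    @property
    def total_shift(self) -> tuple[int, int]:
        """Drift of the rescaled phenotype image relative to the NIS frame, NIS px."""
        return (
            self.coarse_shift.dy + self.fine_shift.dy,
            self.coarse_shift.dx + self.fine_shift.dx,
        )


@dataclass
class MatchedCell:
    pheno_label: int
    nis_label: int
    distance_um: float
    area_ratio: float
    guide_id: str | None = None
    gene: str | None = None


def _downsample(image: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return image
    return block_reduce(image, (factor, factor), np.mean)


def map_fov(
    pheno_image: np.ndarray,
    nis_image: np.ndarray,
    scale: float,
    params: PipelineParams | None = None,
) -> tuple[Shift, Shift, float]:
    """Coarse-then-fine translation mapping of a phenotype FOV onto a NIS FOV.

    The phenotype image is resampled onto the NIS pixel grid (divide by
    ``scale`` = pheno px per NIS px), correlated at 8×8 downsampling, then
    refined at 2×2 downsampling after applying the coarse shift.  Returned
    shifts are expressed in full-resolution NIS pixels.
    """
    params = params or PipelineParams()
    if scale != 1.0:
        pheno_image = rescale(
            pheno_image.astype(float), 1.0 / scale, anti_aliasing=scale > 1
        )
    H, W = nis_image.shape
    ph = np.zeros((H, W), dtype=float)
    h = min(H, pheno_image.shape[0])
    w = min(W, pheno_image.shape[1])
    ph[:h, :w] = pheno_image[:h, :w]

    cd = params.coarse_downsample
    coarse = register_translation(
        _downsample(nis_image.astype(float), cd),
        _downsample(ph, cd),
        max_shift=max(H, W) // (2 * cd) - 1,
    )
    coarse_full = Shift(coarse.dy * cd, coarse.dx * cd, coarse.peak_corr)

    fd = params.fine_downsample
    from .registration import translate

    aligned = translate(ph, -coarse_full.dy, -coarse_full.dx)
    fine = register_translation(
        _downsample(nis_image.astype(float), fd),
        _downsample(aligned, fd),
        max_shift=2 * cd // fd,
    )
    fine_full = Shift(fine.dy * fd, fine.dx * fd, fine.peak_corr)
    return coarse_full, fine_full, fine.peak_corr


def pair_fovs(
    pheno_fovs: dict,
    nis_fovs: dict,
    stage_positions_um: dict,
    params: PipelineParams | None = None,
    field_width_um: float | None = None,
) -> tuple[list[FovPair], list[str]]:
    """Pair phenotype and NIS FOVs by stage position and image correlation.

    ``pheno_fovs`` and ``nis_fovs`` map FOV name → (image, pixel_size_um);
    ``stage_positions_um`` maps FOV name → (y, x) stage position in a
    shared µm frame.  Candidates within one field width are ranked by
    coarse correlation; the best is fine-mapped.  Phenotype FOVs with no
    candidate, or whose best correlation falls below ``min_pair_corr``,
    are reported unpaired.
    """
    params = params or PipelineParams()
    pairs: list[FovPair] = []
    unpaired: list[str] = []
    for pname, (pimg, p_um) in pheno_fovs.items():
        if field_width_um is None:
            some_nis = next(iter(nis_fovs.values()))
            fw = some_nis[0].shape[1] * some_nis[1]
        else:
            fw = field_width_um
        py, px = stage_positions_um[pname]
        candidates = [
            nname
            for nname in nis_fovs
            if max(
                abs(stage_positions_um[nname][0] - py),
                abs(stage_positions_um[nname][1] - px),
            )
            <= fw
        ]
        if not candidates:
            unpaired.append(pname)
            continue
        best = None
        for nname in sorted(candidates):
            nimg, n_um = nis_fovs[nname]
            scale = n_um / p_um  # pheno px per NIS px
            try:
                coarse, fine, corr = map_fov(pimg, nimg, scale, params)
            except RegistrationError:
                continue
            if best is None or corr > best.corr:
                best = FovPair(pname, nname, scale, coarse, fine, corr)
        if best is None or best.corr < params.min_pair_corr:
            unpaired.append(pname)
        else:
            pairs.append(best)
    return pairs, unpaired


def match_nuclei(
    pheno: LabelImage,
    nis: LabelImage,
    pair: FovPair,
    params: PipelineParams | None = None,
    nis_pixel_size_um: float = 0.65,
) -> list[MatchedCell]:
    """One-to-one nucleus matching by centers of gravity with distance/area gates.

    Phenotype centroids are transformed into the NIS frame (rescale by the
    magnification ratio, then the recovered FOV shift), and each takes the
    nearest NIS centroid.  A match is accepted iff the movement distance is
    ≤ ``max_nucleus_move_um`` and the nuclear areas agree within the
    two-fold margin after magnification (scale²) correction.  Ambiguity —
    two phenotype nuclei claiming the same NIS nucleus, or a second NIS
    candidate inside the distance gate at less than 1.2× the nearest
    distance — excludes all nuclei involved.
    """
    params = params or PipelineParams()
    if len(pheno.table) == 0 or len(nis.table) == 0:
        return []
    dy, dx = pair.total_shift
    p_pos = pheno.table[["row", "col"]].to_numpy(dtype=float) / pair.scale
    p_pos[:, 0] -= dy
    p_pos[:, 1] -= dx
    p_area = pheno.table["area"].to_numpy(dtype=float) / pair.scale**2
    n_pos = nis.table[["row", "col"]].to_numpy(dtype=float)
    n_area = nis.table["area"].to_numpy(dtype=float)
    tree = cKDTree(n_pos)
    k = min(2, len(n_pos))
    dists, idxs = tree.query(p_pos, k=k)
    if k == 1:
        dists = dists[:, None]
        idxs = idxs[:, None]
    gate_px = params.max_nucleus_move_um / nis_pixel_size_um

    candidates = []
    for i in range(len(p_pos)):
        d1 = dists[i, 0]
        if d1 > gate_px:
            continue
        if k == 2 and dists[i, 1] <= gate_px:
            if dists[i, 1] < params.ambiguity_separation_ratio * max(d1, 1e-9):
                continue  # two NIS candidates too close to distinguish
        j = idxs[i, 0]
        ratio = p_area[i] / n_area[j]
        if not (1.0 / params.area_ratio_bound <= ratio <= params.area_ratio_bound):
            continue
        candidates.append((i, j, d1, ratio))

    # duplicate-claim exclusion: a NIS nucleus claimed twice drops all claimants
    claims: dict[int, list] = {}
    for cand in candidates:
        claims.setdefault(cand[1], []).append(cand)
    matched = []
    for j, cands in claims.items():
        if len(cands) != 1:
            continue
        i, j, d, ratio = cands[0]
        matched.append(
            MatchedCell(
                pheno_label=int(pheno.table["label"].iloc[i]),
                nis_label=int(nis.table["label"].iloc[j]),
                distance_um=float(d * nis_pixel_size_um),
                area_ratio=float(ratio),
            )
        )
    return matched
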