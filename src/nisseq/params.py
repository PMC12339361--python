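"""Pipeline-wide tunable parameters.

All image coordinates in this package are (row, col), 0-based, in pixels;
physical distances are converted through a per-modality pixel size in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class PipelineParams:
    """Parameters shared across the genotyping and phenotyping stages.

    The defaults are the published operating point of the method: spot
    information aggregated over 5×5 pixels, dark-G calling at 20% of the
    spot maximum, a two-thirds dominance requirement per nucleus, a
    7×10^5-count intensity gate (2×10^5 preset for low-signal cells),
    an 11.1 µm maximum nucleus movement between modalities with a two-fold
    nuclear-area margin, a minimum of 10 cells per tested gene, 8×8 coarse
    and 2×2 fine field-of-view mapping, 8×8 downsampling with a 9×9
    local-minimum window for background subtraction, and a 5-pixel label
    shrink for membrane-derived nucleus prediction.
    """

    # base calling
    n_detection_cycles: int = 3
    spot_window: int = 5
    g_dark_fraction: float = 0.20
    highpass_sigma: float = 4.0
    detect_k_mad: float = 8.0
    detect_abs_floor: float = 50.0
    max_crosstalk_condition: float = 1e3

    # nucleus assignment
    dominance_fraction: float = 2.0 / 3.0
    nucleus_intensity_threshold: float = 7e5
    low_signal_intensity_threshold: float = 2e5  # preset for low-signal cells

    # modality linking
    max_nucleus_move_um: float = 11.1
    area_ratio_bound: float = 2.0
    ambiguity_separation_ratio: float = 1.2
    coarse_downsample: int = 8
    fine_downsample: int = 2
    min_pair_corr: float = 0.2

    # phenotyping
    bg_downsample: int = 8
    bg_window: int = 9
    speck_highpass_sigma: float = 2.0
    expression_gate_percentile: float = 5.0
    min_cell_pixels: int = 10
    label_shrink_px: int = 5

    # registration
    max_shift: int = 50
    min_registration_corr: float = 0.3

    # screen statistics
    min_cells_per_gene: int = 10

    # per-modality pixel sizes, µm per pixel
    pixel_size_um: dict = field(
        default_factory=lambda: {"nis": 0.65, "pheno": 0.65}
    )

    def __post_init__(self) -> None:
        if not (0.5 < self.dominance_fraction <= 1.0):
            raise ValueError("dominance_fraction must be in (0.5, 1]")
        if not (0.0 < self.g_dark_fraction < 1.0):
            raise ValueError("g_dark_fraction must be in (0, 1)")
        for name in (
            "n_detection_cycles",
            "spot_window",
            "nucleus_intensity_threshold",
            "max_nucleus_move_um",
            "area_ratio_bound",
            "min_cells_per_gene",
            "coarse_downsample",
            "fine_downsample",
            "bg_downsample",
            "bg_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
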