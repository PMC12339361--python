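"""Assignment of matched spots to segmented nuclei.

A nucleus is genotyped when a single guide dominates: the dominant sequence
must make up more than two-thirds of the total intensity of library spots
in that nucleus, and the maximum signal intensity per nucleus across
channels and sequencing cycles must pass a numeric threshold (7×10^5 by
default; a 2×10^5 preset exists for low-signal cell types).  Multi-
integration nuclei fail the dominance gate and are rejected rather than
deconvolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PipelineParams
from .segmentation import LabelImage


@dataclass
class NucleusCall:
    fov: str
    label: int
    centroid: tuple[float, float]
    area: int
    status: str  # assigned | no_spot | below_intensity | not_dominant | ambiguous
    guide_id: str | None = None
    gene: str | None = None
    dominance: float = 0.0
    max_intensity: float = 0.0


def assign_spots_to_nuclei(
    profiles,
    matches,
    labels: LabelImage,
    params: PipelineParams | None = None,
    fov: str = "fov0",
    image_shape: tuple[int, int] | None = None,
) -> list[NucleusCall]:
    """Aggregate matched-spot intensity per nucleus and apply the gates.

    Each library-matched spot (exact or corrected) contributes its total
    positive unmixed intensity to its guide within the nucleus containing
    its center pixel; ambiguous spots contribute to the total (denominator)
    but to no guide.  Spots on background are discarded.  A nucleus is
    assigned iff its dominant guide exceeds the dominance fraction of total
    library-spot intensity and its maximum single-channel single-cycle spot
    intensity passes the threshold.
    """
    params = params or PipelineParams()
    if image_shape is not None and labels.labels.shape != tuple(image_shape):
        raise ValueError(
            f"label image shape {labels.labels.shape} does not match "
            f"image frame {tuple(image_shape)}"
        )
    per_guide: dict[int, dict[str, float]] = {}
    totals: dict[int, float] = {}
    max_int: dict[int, float] = {}
    genes: dict[str, str] = {}
    for prof, match in zip(profiles, matches):
        r, c = prof.position
        lab = int(labels.labels[r, c])
        if lab == 0:
            continue
        if match.status not in ("exact", "corrected", "ambiguous"):
            continue
        intensity = prof.total_intensity()
        totals[lab] = totals.get(lab, 0.0) + intensity
        max_int[lab] = max(max_int.get(lab, 0.0), prof.max_unmixed)
        if match.matched:
            d = per_guide.setdefault(lab, {})
            d[match.guide_id] = d.get(match.guide_id, 0.0) + intensity
            genes[match.guide_id] = match.gene
    calls = []
    for _, row in labels.table.iterrows():
        lab = int(row["label"])
        base = dict(
            fov=fov,
            label=lab,
            centroid=(float(row["row"]), float(row["col"])),
            area=int(row["area"]),
        )
        total = totals.get(lab, 0.0)
        if total <= 0:
            calls.append(NucleusCall(status="no_spot", **base))
            continue
        mx = max_int.get(lab, 0.0)
        guides = per_guide.get(lab, {})
        if mx < params.nucleus_intensity_threshold:
            calls.append(
                NucleusCall(status="below_intensity", max_intensity=mx, **base)
            )
            continue
        if not guides:
            # only ambiguous spots: signal present but no attributable guide
            calls.append(
                NucleusCall(status="ambiguous", max_intensity=mx, **base)
            )
            continue
        top_guide, top_val = max(guides.items(), key=lambda kv: (kv[1], kv[0]))
        ties = [g for g, v in guides.items() if v == top_val]
        dominance = top_val / total
        if len(ties) > 1:
            calls.append(
                NucleusCall(
                    status="ambiguous",
                    dominance=dominance,
                    max_intensity=mx,
                    **base,
                )
            )
            continue
        if dominance > params.dominance_fraction:
            calls.append(
                NucleusCall(
                    status="assigned",
                    guide_id=top_guide,
                    gene=genes.get(top_guide),
                    dominance=dominance,
                    max_intensity=mx,
                    **base,
                )
            )
        else:
            calls.append(
                NucleusCall(
                    status="not_dominant",
                    dominance=dominance,
                    max_intensity=mx,
                    **base,
                )
            )
    return calls


def mapping_summary(calls: list[NucleusCall], lib=None) -> dict:
    """Status fractions, library-mapped fraction, and per-guide nucleus counts."""
    n = len(calls)
    statuses = pd.Series([c.status for c in calls])
    fractions = (
        (statuses.value_counts() / n).to_dict() if n else {}
    )
    assigned = [c for c in calls if c.status == "assigned"]
    per_guide = pd.Series([c.guide_id for c in assigned]).value_counts()
    if lib is not None:
        per_guide = per_guide.reindex(
            lib.entries["guide_id"], fill_value=0
        )
    return {
        "n_nuclei": n,
        "status_fractions": fractions,
        "mapped_fraction": len(assigned) / n if n else float("nan"),
        "per_guide_counts": per_guide.astype(int).to_dict(),
    }


def calls_to_frame(calls: list[NucleusCall]) -> pd.DataFrame:
    """Tabulate nucleus calls for CSV output."""
    return pd.DataFrame(
        {
            "fov": [c.fov for c in calls],
            "label": [c.label for c in calls],
            "row": [c.centroid[0] for c in calls],
            "col": [c.centroid[1] for c in calls],
            "area": [c.area for c in calls],
            "status": [c.status for c in calls],
            "guide_id": [c.guide_id for c in calls],
            "gene": [c.gene for c in calls],
            "dominance": [c.dominance for c in calls],
            "max_intensity": [c.max_intensity for c in calls],
        }
    )
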