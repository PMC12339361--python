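"""Per-gene screen statistics.

Cells are pooled per targeted gene and compared against the non-targeting
(NT) control pool: fold change of the gene mean over the NT mean, a
two-sided Wilcoxon–Mann–Whitney test per gene, and Benjamini–Hochberg
adjustment across all tested genes.  Genes are tested only when covered by
at least ``min_cells_per_gene`` cells (default 10).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .params import PipelineParams


def mann_whitney_two_sided(x, y) -> float:
    """Two-sided Wilcoxon–Mann–Whitney p-value.

    Exact null enumeration is used for tie-free samples with pooled size
    ≤ 12; larger or tied samples use the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_test(
    cells: pd.DataFrame,
    metric: str,
    nt_label: str = "NT",
    params: PipelineParams | None = None,
    metric_shift: float = 0.0,
) -> pd.DataFrame:
    """Per-gene Mann–Whitney tests and fold changes against the NT pool.

    ``cells`` needs a ``gene`` column and the metric column; rows with a
    missing metric are dropped.  ``metric_shift`` is added to the metric
    before computing the fold change of means — used for metrics that can
    be negative, such as a Pearson correlation shifted to [0, 2].  The
    rank-based test is unaffected by the shift.
    """
    params = params or PipelineParams()
    df = cells.dropna(subset=[metric])
    nt = df.loc[df["gene"] == nt_label, metric].to_numpy() + metric_shift
    if nt.size == 0:
        raise ValueError(f"no non-targeting cells with label {nt_label!r}")
    nt_mean = float(nt.mean())
    rows = []
    for gene, grp in df[df["gene"] != nt_label].groupby("gene", sort=True):
        vals = grp[metric].to_numpy() + metric_shift
        n = vals.size
        mean = float(vals.mean())
        tested = n >= params.min_cells_per_gene
        log2_fc = (
            float(np.log2(mean / nt_mean)) if mean > 0 and nt_mean > 0 else np.nan
        )
        rows.append(
            {
                "gene": gene,
                "n_cells": n,
                "mean_metric": mean,
                "nt_mean_metric": nt_mean,
                "log2_fc": log2_fc,
                "p_value": mann_whitney_two_sided(vals, nt) if tested else np.nan,
                "tested": tested,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    mask = out["tested"].to_numpy(dtype=bool) if len(out) else np.array([], bool)
    if mask.any():
        out.loc[mask, "fdr"] = benjamini_hochberg(out.loc[mask, "p_value"])
    return out.sort_values(
        ["fdr", "p_value", "gene"], na_position="last"
    ).reset_index(drop=True)


def downsample_power(
    cells: pd.DataFrame,
    metric: str,
    grid,
    reps: int,
    seed: int,
    hit_genes,
    nt_label: str = "NT",
    params: PipelineParams | None = None,
    metric_shift: float = 0.0,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Hit-detection fraction as a function of cells per gene.

    For each grid value k, targeting genes are subsampled (without
    replacement) to k cells, the screen test is re-run, and the fraction
    of ``hit_genes`` recovered at fdr < ``fdr_threshold`` with
    |log2 fold change| > ``lfc_threshold`` is recorded, averaged over
    ``reps`` seeded replicates.  Genes with fewer than k cells are skipped
    for that k.  Screens approach saturation near 100 cells per gene for
    hits with an effect size of |log2 fc| > 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    params = params or PipelineParams()
    hit_genes = list(hit_genes)
    rng = np.random.default_rng(seed)
    rows = []
    for k in grid:
        fractions = []
        for rep in range(reps):
            parts = [cells[cells["gene"] == nt_label]]
            for gene, grp in cells[cells["gene"] != nt_label].groupby("gene"):
                if len(grp) < k:
                    continue
                idx = rng.choice(len(grp), size=k, replace=False)
                parts.append(grp.iloc[idx])
            sub = pd.concat(parts, ignore_index=True)
            res = screen_test(
                sub, metric, nt_label, params, metric_shift=metric_shift
            )
            hits = res[
                (res["gene"].isin(hit_genes))
                & (res["fdr"] < fdr_threshold)
                & (res["log2_fc"].abs() > lfc_threshold)
            ]
            fractions.append(len(hits) / len(hit_genes))
        rows.append(
            {
                "cells_per_gene": k,
                "detection_fraction": float(np.mean(fractions)),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
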