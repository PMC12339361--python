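"""Synthetic-scene benchmarks for every pipeline stage.

Each function builds ground-truthed synthetic inputs at a fixed, seeded
operating point, runs the corresponding stage(s) of the pipeline, and
returns measured quantities (accuracies, error bounds, calibration
statistics).  They double as an executable characterization of what the
method achieves under its stated imaging model.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assign import assign_spots_to_nuclei
from .library import BarcodeLibrary, scramble_library
from .linking import FovPair, match_nuclei
from .matching import build_index, match_profiles, match_sequence
from .params import PipelineParams
from .registration import Shift, register_translation
from .segmentation import segment_objects
from .simulate import (
    SimConfig,
    labels_from_truth,
    render_nis_scene,
    simulate_library,
    simulate_profiles,
    simulate_screen_metrics,
)
from .spots import call_stack
from .stats import benjamini_hochberg, downsample_power, mann_whitney_two_sided, screen_test


def _match_detections_to_truth(profiles, truth_spots, tol_px: float = 1.5):
    """Pair each planted spot with its nearest detection within ``tol_px``."""
    out = []
    det = np.array([p.position for p in profiles], dtype=float)
    if len(det) == 0:
        return out
    for t in truth_spots.itertuples():
        d = np.abs(det - np.array([t.row, t.col])).max(axis=1)
        j = int(np.argmin(d))
        if d[j] <= tol_px:
            out.append((profiles[j], t))
    return out


def base_calling_accuracy(
    n_spots_target: int = 1000,
    n_cycles: int = 6,
    crosstalk_bleed: float = 0.0,
    snr: float | None = None,
    seed: int = 0,
) -> dict:
    """End-to-end base-calling accuracy on rendered scenes.

    Renders fields until ``n_spots_target`` planted spots are covered, runs
    detection → crosstalk estimation → unmixing → calling, and scores
    called sequences against the planted detect sequences.  ``snr`` is the
    ratio of spot peak amplitude to per-pixel noise standard deviation
    (None = noiseless).
    """
    lib = simulate_library(60, 2, 8, seed=seed)
    M = np.eye(3) + crosstalk_bleed * (np.ones((3, 3)) - np.eye(3))
    amp = 2e5
    noise = amp / snr if snr else 0.0
    n_seen = n_exact = n_cyc = n_cyc_ok = 0
    field = 0
    while n_seen < n_spots_target:
        cfg = SimConfig(
            shape=(512, 512),
            n_nuclei=120,
            n_cycles=n_cycles,
            crosstalk=M,
            spot_amplitude=(amp, amp / 10),
            noise_sd=noise,
            seed=seed * 1000 + field,
        )
        stack, truth = render_nis_scene(lib, cfg)
        profiles, _ = call_stack(stack)
        for prof, t in _match_detections_to_truth(profiles, truth.spots):
            n_seen += 1
            n_exact += prof.sequence == t.detect_seq
            n_cyc += len(t.detect_seq)
            n_cyc_ok += sum(a == b for a, b in zip(prof.sequence, t.detect_seq))
        field += 1
    return {
        "n_spots": n_seen,
        "exact_sequence_fraction": n_exact / n_seen,
        "per_cycle_accuracy": n_cyc_ok / n_cyc,
    }


def crosstalk_recovery_error(
    bleed: float = 0.25, n_spots: int = 600, seed: int = 0
) -> dict:
    """Max per-entry error of the self-calibrated crosstalk matrix."""
    from .spots import estimate_crosstalk

    planted = np.eye(3) + bleed * (np.ones((3, 3)) - np.eye(3))
    planted = planted / planted.max(axis=0)
    lib = simulate_library(60, 2, 8, seed=seed)
    profiles, _ = simulate_profiles(
        lib, n_spots, n_cycles=8, crosstalk=planted, amplitude=1000.0,
        noise_sd=20.0, seed=seed,
    )
    est = estimate_crosstalk(profiles)
    return {
        "n_spots": n_spots,
        "max_abs_error": float(np.abs(est.M - planted).max()),
    }


def _brute_force_scan(query: str, seqs: np.ndarray):
    """Exhaustive Hamming scan over an encoded library, tiered like matching."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    dists = (seqs != q).sum(axis=1)
    for tier in (0, 1):
        hits = np.nonzero(dists == tier)[0]
        if len(hits):
            if len(hits) > 1:
                return ("ambiguous", None)
            return ("exact" if tier == 0 else "corrected", int(hits[0]))
    return ("unmatched", None)


def matching_oracle_discrepancies(
    n_queries: int = 10_000, lib_size: int = 1000, read_len: int = 14, seed: int = 0
) -> dict:
    """Count disagreements between indexed matching and an exhaustive scan."""
    lib = simulate_library(lib_size // 2 - 5, 2, 10, L=read_len, seed=seed)
    idx = build_index(lib, read_len)
    detect = lib.entries["detect_seq"].str[:read_len]
    seqs = np.frombuffer("".join(detect).encode(), dtype=np.uint8).reshape(
        len(detect), read_len
    )
    guides = lib.entries["guide_id"].tolist()
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGTN", dtype=np.uint8)
    n_bad = 0
    for i in range(n_queries):
        if i % 2 == 0:
            q = seqs[rng.integers(len(seqs))].copy()
            for _ in range(rng.integers(0, 3)):
                q[rng.integers(read_len)] = bases[rng.integers(5)]
            query = q.tobytes().decode()
        else:
            query = "".join(rng.choice(list("ACGT"), read_len))
        got = match_sequence(query, idx)
        status, hit = _brute_force_scan(query, seqs)
        ok = got.status == status and (
            not got.matched or got.guide_id == guides[hit]
        )
        n_bad += not ok
    return {"n_queries": n_queries, "n_discrepancies": n_bad}


def registration_recovery(max_drift: int = 20, seed: int = 0) -> dict:
    """Shift-recovery error for planted drifts, noiseless and at 10% noise."""
    lib = simulate_library(10, 2, 4, seed=seed)
    cfg = SimConfig(shape=(512, 512), n_nuclei=60, n_cycles=1, seed=seed)
    stack, _ = render_nis_scene(lib, cfg)
    ref = stack.nuclear[0]
    rng = np.random.default_rng(seed)
    drifts = [
        (int(d), int(e))
        for d, e in rng.integers(-max_drift, max_drift + 1, size=(10, 2))
    ]
    dyn = ref.max() - ref.min()
    err_clean = err_noisy = 0
    for dy, dx in drifts:
        mov = np.roll(np.roll(ref, dy, axis=0), dx, axis=1)
        s = register_translation(ref, mov, max_shift=2 * max_drift)
        err_clean = max(err_clean, abs(s.dy - dy), abs(s.dx - dx))
        noisy = mov + rng.normal(0, 0.1 * dyn, mov.shape)
        s = register_translation(ref, noisy, max_shift=2 * max_drift)
        err_noisy = max(err_noisy, abs(s.dy - dy), abs(s.dx - dx))
    return {
        "n_drifts": len(drifts),
        "noiseless_max_error_px": err_clean,
        "noisy_max_error_px": err_noisy,
    }


def hamming1_chance_bound(n_members: int, read_len: int) -> float:
    """Union bound on the probability that a random read falls within
    Hamming distance 1 of any library member: N·(1+3L)/4^L."""
    return n_members * (1 + 3 * read_len) / 4**read_len


def end_to_end_genotyping(
    n_fields: int = 6,
    n_nuclei: int = 200,
    frac_unbarcoded: float = 0.3,
    n_cycles: int = 8,
    seed: int = 0,
) -> dict:
    """Whole-pipeline genotyping on clean fields, plus the scrambled-library control.

    Measures the fraction of barcoded nuclei assigned their planted guide,
    the wrong-guide rate, and the fraction of nuclei that still map when
    the dictionary is replaced by a per-sequence scramble of itself.
    """
    lib = simulate_library(20, 2, 8, seed=seed)
    params = PipelineParams()
    index = build_index(lib, n_cycles)
    scrambled = scramble_library(lib, seed=seed + 99)
    scr_index = build_index(scrambled, n_cycles)

    n_barcoded = n_correct = n_wrong = n_total = n_scr_assigned = 0
    for field in range(n_fields):
        cfg = SimConfig(
            shape=(768, 768),
            n_nuclei=n_nuclei,
            n_cycles=n_cycles,
            frac_unbarcoded=frac_unbarcoded,
            seed=seed * 1000 + 500 + field,
        )
        stack, truth = render_nis_scene(lib, cfg)
        labels = segment_objects(stack.nuclear[0], mode="nuclei")
        profiles, _ = call_stack(stack, params)
        matches = match_profiles(profiles, index)
        calls = assign_spots_to_nuclei(profiles, matches, labels, params)
        call_by_label = {c.label: c for c in calls}
        truth_guide = dict(
            zip(truth.spots["nucleus_id"], truth.spots["guide_id"])
        )
        n_total += len(truth.nuclei)
        for nuc in truth.nuclei.itertuples():
            lab = int(labels.labels[int(round(nuc.row)), int(round(nuc.col))])
            call = call_by_label.get(lab)
            if not nuc.barcoded:
                continue
            n_barcoded += 1
            if call is None or call.status != "assigned":
                continue
            if call.guide_id == truth_guide[nuc.nucleus_id]:
                n_correct += 1
            else:
                n_wrong += 1
        scr_matches = match_profiles(profiles, scr_index)
        scr_calls = assign_spots_to_nuclei(profiles, scr_matches, labels, params)
        n_scr_assigned += sum(c.status == "assigned" for c in scr_calls)
    return {
        "n_nuclei": n_total,
        "n_barcoded": n_barcoded,
        "correct_assignment_fraction": n_correct / n_barcoded,
        "wrong_assignment_fraction": n_wrong / n_barcoded,
        "scrambled_assigned_fraction": n_scr_assigned / n_total,
        "scrambled_chance_bound": hamming1_chance_bound(len(lib), n_cycles),
    }


def nucleus_matching_benchmark(
    jitter_um: float = 5.0, n_nuclei: int = 200, seed: int = 0
) -> dict:
    """Cross-modality nucleus matching under jitter and a planted violation."""
    lib = simulate_library(10, 2, 4, seed=seed)
    cfg = SimConfig(shape=(768, 768), n_nuclei=n_nuclei, n_cycles=1, seed=seed + 7)
    _, truth = render_nis_scene(lib, cfg)
    rng = np.random.default_rng(seed)
    jit_px = jitter_um / cfg.pixel_size_um / np.sqrt(2)
    jitter = rng.uniform(-jit_px, jit_px, size=(n_nuclei, 2))
    nis = labels_from_truth(truth.nuclei, cfg.shape)
    pheno = labels_from_truth(truth.nuclei, cfg.shape, jitter=jitter)
    pair = FovPair("p", "n", 1.0, Shift(0, 0), Shift(0, 0), 1.0)
    matched = match_nuclei(pheno, nis, pair, nis_pixel_size_um=cfg.pixel_size_um)
    n_false = sum(m.pheno_label != m.nis_label for m in matched)

    # planted 12 µm displacement of one nucleus must fail the 11.1 µm gate
    jitter12 = np.zeros((n_nuclei, 2))
    jitter12[0] = (12.0 / cfg.pixel_size_um, 0.0)
    pheno12 = labels_from_truth(truth.nuclei, cfg.shape, jitter=jitter12)
    matched12 = match_nuclei(pheno12, nis, pair, nis_pixel_size_um=cfg.pixel_size_um)
    moved = int(truth.nuclei["nucleus_id"].iloc[0])
    displaced_matched = any(m.pheno_label == moved for m in matched12)
    n_true = sum(m.pheno_label == m.nis_label for m in matched)
    return {
        "n_nuclei": n_nuclei,
        "recall": n_true / n_nuclei,
        "n_false_pairs": n_false,
        "displaced_12um_matched": displaced_matched,
    }


def _enumeration_p(x, y) -> float:
    pooled = np.concatenate([x, y])
    n, nm = len(x), len(x) * len(y)
    ranks = sps.rankdata(pooled)
    us = np.array(
        [
            ranks[list(c)].sum() - n * (n + 1) / 2
            for c in itertools.combinations(range(len(pooled)), n)
        ]
    )
    u = ranks[:n].sum() - n * (n + 1) / 2
    lo, hi = min(u, nm - u), max(u, nm - u)
    return min(1.0, float(((us <= lo).sum() + (us >= hi).sum()) / len(us)))


def statistics_oracle_errors(seed: int = 0) -> dict:
    """Mann–Whitney vs exhaustive enumeration over all partitions with
    pooled n ≤ 12, plus the hand-computed Benjamini–Hochberg step-up case."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_66 = 0.0
    n_partitions = 0
    for n1 in range(1, 12):
        for n2 in range(1, 13 - n1):
            x = rng.normal(size=n1)
            y = rng.normal(0.3, 1, size=n2)
            d = abs(mann_whitney_two_sided(x, y) - _enumeration_p(x, y))
            worst = max(worst, d)
            if n1 == n2 == 6:
                worst_66 = max(worst_66, d)
            n_partitions += 1
    q = benjamini_hochberg([0.01, 0.04, 0.03, 0.02])
    bh_err = float(np.abs(q - 0.04).max())
    return {
        "n_partitions": n_partitions,
        "mw_max_abs_diff": worst,
        "mw_max_abs_diff_6_6": worst_66,
        "bh_step_up_max_abs_error": bh_err,
    }


def screen_calibration(
    n_genes: int = 200, cells_per_gene: int = 100, seed: int = 0
) -> dict:
    """Null-screen false-discovery behavior and p-value uniformity."""
    cells = simulate_screen_metrics(
        n_genes=n_genes,
        cells_per_gene=cells_per_gene,
        n_nt_cells=2000,
        effects={},
        seed=seed,
    )
    res = screen_test(cells, "metric")
    p = res.loc[res["tested"], "p_value"].to_numpy()
    ks = sps.kstest(p, "uniform")
    return {
        "n_genes": n_genes,
        "n_fdr_below_05": int((res["fdr"] < 0.05).sum()),
        "ks_uniformity_p": float(ks.pvalue),
    }


def planted_hit_power(
    n_replicates: int = 20,
    cells_per_gene: int = 100,
    effect: float = 2.0,
    seed: int = 0,
) -> dict:
    """Fraction of seeded replicates in which a 2× mean-shift hit reaches
    FDR < 0.05 at the given coverage."""
    n_detected = 0
    for rep in range(n_replicates):
        cells = simulate_screen_metrics(
            n_genes=50,
            cells_per_gene=cells_per_gene,
            n_nt_cells=1000,
            effects={"G0001": effect},
            seed=seed * 1000 + rep,
        )
        res = screen_test(cells, "metric")
        row = res[res["gene"] == "G0001"].iloc[0]
        n_detected += bool(row["fdr"] < 0.05)
    return {"n_replicates": n_replicates, "n_detected": n_detected}


def coverage_saturation(
    grid=(10, 30, 100), reps: int = 5, effect: float = 0.4, seed: int = 0
) -> dict:
    """Hit-detection fraction (FDR < 0.05, |log2 fc| > 1) vs cells per gene.

    Ten planted hits among 200 genes, with a mean shift placing them past
    the |log2 fc| > 1 reporting threshold (planting exactly at the
    threshold would make the reported fraction a coin toss on estimator
    sign rather than a power measure).  Detection saturates as coverage
    approaches 100 cells per gene.
    """
    hit_genes = [f"G{i:04d}" for i in range(1, 11)]
    cells = simulate_screen_metrics(
        n_genes=200,
        cells_per_gene=max(grid),
        n_nt_cells=2000,
        effects={g: effect for g in hit_genes},
        seed=seed,
    )
    pw = downsample_power(
        cells,
        "metric",
        grid=list(grid),
        reps=reps,
        seed=seed,
        hit_genes=hit_genes,
    )
    return {
        "grid": list(grid),
        "detection_fraction": pw["detection_fraction"].tolist(),
        "reps": reps,
    }
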