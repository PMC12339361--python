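import numpy as np
import pytest

from nisseq import SimConfig, render_nis_scene, simulate_library


@pytest.fixture(scope="session")
def small_library():
    return simulate_library(n_genes=6, guides_per_gene=2, n_nt=4, seed=11)


@pytest.fixture(scope="session")
def clean_scene(small_library):
    """Noiseless scene, identity crosstalk, no phasing or drift."""
    cfg = SimConfig(n_nuclei=60, n_cycles=6, seed=21)
    return render_nis_scene(small_library, cfg)


def hamming(a: str, b: str) -> int:
    """N counts as a mismatch at its position."""
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_match(seq, detect_seqs, guide_ids, genes, ambiguous_flags):
    """Exhaustive-scan oracle for dictionary matching (≤1 mismatch, tiered)."""
    dists = [hamming(seq, d) for d in detect_seqs]
    for tier in (0, 1):
        hits = [i for i, d in enumerate(dists) if d == tier]
        if not hits:
            continue
        distinct = {detect_seqs[i] for i in hits}
        if (
            len(distinct) > 1
            or len(hits) > 1
            or any(ambiguous_flags[i] for i in hits)
        ):
            return ("ambiguous", None, tier)
        i = hits[0]
        status = "exact" if tier == 0 else "corrected"
        return (status, guide_ids[i], tier)
    return ("unmatched", None, None)
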