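import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nisseq import (
    PipelineParams,
    benjamini_hochberg,
    downsample_power,
    mann_whitney_two_sided,
    screen_test,
    simulate_screen_metrics,
)


def enumeration_p(x, y):
    """Independent oracle: exact two-sided p by enumerating all pooled
    arrangements (tie-free samples only)."""
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
    return min(1.0, ((us <= lo).sum() + (us >= hi).sum()) / len(us))


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        # U = 0; 2 of the C(6,3)=20 arrangements are as extreme → p = 0.1
        assert mann_whitney_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_p_1(self):
        p = mann_whitney_two_sided([1.0, 2.0, 3.5], [1.1, 2.1, 3.4])
        assert p == pytest.approx(1.0, abs=0.01)

    def test_matches_enumeration_oracle_in_exact_regime(self):
        rng = np.random.default_rng(1)
        for n1 in range(1, 7):
            for n2 in range(1, 13 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                assert mann_whitney_two_sided(x, y) == pytest.approx(
                    enumeration_p(x, y), abs=1e-12
                )

    def test_normal_approximation_close_to_enumeration(self):
        # the asymptotic branch (engaged above pooled n = 12) stays within
        # 0.02 of exhaustive enumeration already at 8+8
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(0.5, 1, size=8)
            exact = enumeration_p(x, y)
            approx = mann_whitney_two_sided(x, y)
            assert abs(approx - exact) < 0.02

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(1, 1, size=20)
        assert mann_whitney_two_sided(x, y) == pytest.approx(
            mann_whitney_two_sided(y, x)
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_sided([], [1, 2])


class TestBenjaminiHochberg:
    def test_hand_computed_step_up_example(self):
        q = benjamini_hochberg([0.01, 0.04, 0.03, 0.02])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_p_values_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(benjamini_hochberg([0.037]), [0.037])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestScreenTest:
    def test_planted_half_mean_shift_detected(self):
        cells = simulate_screen_metrics(
            n_genes=20,
            cells_per_gene=100,
            n_nt_cells=500,
            effects={"G0001": 0.5},
            seed=5,
        )
        res = screen_test(cells, "metric")
        hit = res[res["gene"] == "G0001"].iloc[0]
        assert hit["log2_fc"] == pytest.approx(-1.0, abs=0.25)
        assert hit["fdr"] < 0.01
        assert res.iloc[0]["gene"] == "G0001"  # ranked first

    def test_gene_below_min_cells_not_tested(self):
        cells = pd.DataFrame(
            {
                "gene": ["G1"] * 9 + ["NT"] * 50,
                "metric": np.arange(59, dtype=float),
            }
        )
        res = screen_test(cells, "metric")
        row = res[res["gene"] == "G1"].iloc[0]
        assert not row["tested"]
        assert np.isnan(row["p_value"]) and np.isnan(row["fdr"])

    def test_missing_nt_pool_is_error(self):
        cells = pd.DataFrame({"gene": ["G1"] * 10, "metric": np.ones(10)})
        with pytest.raises(ValueError, match="non-targeting"):
            screen_test(cells, "metric")

    def test_metric_shift_changes_fc_not_p(self):
        rng = np.random.default_rng(6)
        cells = pd.DataFrame(
            {
                "gene": ["G1"] * 50 + ["NT"] * 100,
                "metric": np.concatenate(
                    [rng.normal(0.3, 0.2, 50), rng.normal(-0.1, 0.2, 100)]
                ),
            }
        )
        shifted = screen_test(cells, "metric", metric_shift=1.0)
        res_row = shifted[shifted["gene"] == "G1"].iloc[0]
        assert np.isfinite(res_row["log2_fc"])
        # rank-based p is unaffected by the shift
        raw = screen_test(cells, "metric")
        assert res_row["p_value"] == pytest.approx(
            raw[raw["gene"] == "G1"]["p_value"].iloc[0]
        )


class TestDownsamplePower:
    def test_full_data_reproduces_screen_test(self):
        cells = simulate_screen_metrics(
            n_genes=10,
            cells_per_gene=50,
            n_nt_cells=300,
            effects={"G0001": 0.4},
            seed=7,
        )
        full = screen_test(cells, "metric")
        pw = downsample_power(
            cells, "metric", grid=[50], reps=1, seed=7, hit_genes=["G0001"]
        )
        detected = bool(
            (full[full["gene"] == "G0001"]["fdr"] < 0.05).iloc[0]
            and abs(full[full["gene"] == "G0001"]["log2_fc"].iloc[0]) > 1
        )
        assert pw["detection_fraction"].iloc[0] == float(detected)

    def test_detection_improves_with_cell_count(self):
        cells = simulate_screen_metrics(
            n_genes=10,
            cells_per_gene=120,
            n_nt_cells=600,
            effects={"G0001": 0.5},
            seed=8,
        )
        pw = downsample_power(
            cells,
            "metric",
            grid=[5, 120],
            reps=5,
            seed=8,
            hit_genes=["G0001"],
        )
        assert (
            pw["detection_fraction"].iloc[1] >= pw["detection_fraction"].iloc[0]
        )

    def test_reps_validated(self):
        with pytest.raises(ValueError):
            downsample_power(
                pd.DataFrame({"gene": [], "metric": []}),
                "metric",
                [10],
                0,
                1,
                [],
            )
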