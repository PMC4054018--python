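"""Sample-level enrichment: standardization, z-scores and rank comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crfdrivers.simulate import generate_expression
from crfdrivers.slea import (
    compare_groups,
    normalize_expression,
    run_slea,
    slea_group_comparison,
    slea_zscores,
)


class TestNormalize:
    def test_median_center_and_sd_scale(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = normalize_expression(df)
        assert out.loc["g"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_dropped_or_zeroed(self, caplog):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "var"], columns=list("abc")
        )
        with caplog.at_level("WARNING"):
            dropped = normalize_expression(df)
        assert list(dropped.index) == ["var"]
        assert "zero-variance" in caplog.text
        kept = normalize_expression(df, zero_variance="zero")
        assert kept.loc["flat"].tolist() == [0.0, 0.0, 0.0]

    def test_idempotent(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(30, 11)), index=[f"g{i}" for i in range(30)]
        )
        once = normalize_expression(df)
        twice = normalize_expression(once)
        assert np.max(np.abs(twice.to_numpy() - once.to_numpy())) < 1e-9


class TestZScores:
    def test_observed_at_null_mean_gives_near_zero_z(self):
        # rows alternate +/-1; a balanced module's statistic sits at the null mean
        rows = np.tile(np.array([[1.0, -1.0], [-1.0, 1.0]]), (10, 1))
        df = pd.DataFrame(rows, index=[f"g{i}" for i in range(20)], columns=["s1", "s2"])
        z = slea_zscores(df, {"M": {"g0", "g1", "g2", "g3", "g4", "g5"}},
                         n_random=10_000, seed=0, min_module_size=5)
        assert np.all(np.abs(z.to_numpy()) < 0.05)

    def test_zero_null_sd_flagged_as_nan(self, caplog):
        # constant standardized matrix: every draw has the same statistic
        df = pd.DataFrame(
            np.tile(np.array([[1.0, -1.0]]), (20, 1)),
            index=[f"g{i}" for i in range(20)],
            columns=["s1", "s2"],
        )
        with caplog.at_level("WARNING"):
            z = slea_zscores(df, {"M": {f"g{i}" for i in range(6)}}, n_random=200, seed=0)
        assert np.isnan(z.to_numpy()).all()
        assert "zero null SD" in caplog.text

    def test_small_modules_skipped(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 6)), index=[f"g{i}" for i in range(30)])
        z = slea_zscores(df, {"tiny": {"g0", "g1"}, "ok": {f"g{i}" for i in range(8)}},
                         n_random=100, seed=0, min_module_size=5)
        assert list(z.index) == ["ok"]

    def test_z_invariant_under_relabeling_nonmember_genes(self, rng):
        values = rng.normal(size=(40, 8))
        genes = [f"g{i}" for i in range(40)]
        df = pd.DataFrame(values, index=genes)
        module = {"M": set(genes[:6])}
        z1 = slea_zscores(df, module, n_random=500, seed=7)
        relabeled = df.copy()
        relabeled.index = genes[:6] + [f"x{i}" for i in range(34)]
        z2 = slea_zscores(relabeled, module, n_random=500, seed=7)
        assert np.allclose(z1.to_numpy(), z2.to_numpy())

    def test_deterministic_given_seed(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 10)), index=[f"g{i}" for i in range(50)])
        modules = {"A": {f"g{i}" for i in range(10)}, "B": {f"g{i}" for i in range(10, 25)}}
        z1 = slea_zscores(df, modules, n_random=300, seed=3)
        z2 = slea_zscores(df, modules, n_random=300, seed=3)
        assert z1.equals(z2)

    def test_per_sample_null_redraw_agrees_with_shared_null(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 5)), index=[f"g{i}" for i in range(60)])
        module = {"M": {f"g{i}" for i in range(12)}}
        shared = slea_zscores(df, module, n_random=4000, seed=2)
        per_sample = slea_zscores(df, module, n_random=4000, seed=2,
                                  share_null_across_samples=False)
        assert np.max(np.abs(shared.to_numpy() - per_sample.to_numpy())) < 0.2

    def test_median_statistic_supported(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)), index=[f"g{i}" for i in range(40)])
        z = slea_zscores(df, {"M": {f"g{i}" for i in range(8)}}, statistic="median",
                         n_random=300, seed=1)
        assert z.shape == (1, 6) and np.isfinite(z.to_numpy()).all()


class TestCompareGroups:
    def test_exact_three_vs_three_complete_separation(self):
        """Mutant {3,4,5} vs WT {0,1,2}: right-tail P = 1/C(6,3) = 0.05."""
        z = [3.0, 4.0, 5.0, 0.0, 1.0, 2.0]
        right, left = compare_groups(z, [0, 1, 2], [3, 4, 5])
        assert right == pytest.approx(1 / 20)
        assert left == pytest.approx(1.0)

    def test_exact_matches_enumeration_of_rank_assignments(self):
        z = [0.3, 1.1, 2.0, 0.9, -0.5, 0.1, 1.4]
        mutant_idx = [0, 1, 2]
        right, _ = compare_groups(z, mutant_idx)
        # oracle: permutation distribution of the rank-sum over all label splits
        z = np.asarray(z)
        observed = z[mutant_idx].sum()
        stats = [
            sum(combo)
            for combo in itertools.combinations(z, 3)
        ]
        exact = np.mean([s >= observed - 1e-12 for s in stats])
        assert right == pytest.approx(exact)

    def test_all_tied_values_give_no_separation(self):
        z = [1.0] * 6
        right, left = compare_groups(z, [0, 1, 2])
        assert right >= 0.5 and left >= 0.5

    def test_label_swap_exchanges_tails(self):
        z = [0.2, 1.5, -0.3, 0.8, 2.2, -1.0]
        right, left = compare_groups(z, [0, 1], [2, 3, 4, 5])
        right2, left2 = compare_groups(z, [2, 3, 4, 5], [0, 1])
        assert right == pytest.approx(left2) and left == pytest.approx(right2)

    def test_overlap_and_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [0], [0, 1])
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [], [0, 1])


def test_group_comparison_bh_per_tail(rng):
    z = pd.DataFrame(
        rng.normal(size=(6, 20)),
        index=[f"M{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(20)],
    )
    table = slea_group_comparison(z, mutant_samples=[f"s{i}" for i in range(8)])
    assert set(table.columns) == {"p_right", "p_left", "q_right", "q_left", "n_mutant", "n_wt"}
    assert (table["q_right"] >= table["p_right"] - 1e-12).all()
    assert (table["n_mutant"] == 8).all() and (table["n_wt"] == 12).all()


def test_run_slea_recovers_injected_module_shift():
    samples = [f"s{i}" for i in range(40)]
    genes = [f"g{i:03d}" for i in range(200)]
    mutant = samples[:12]
    modules = {"linked": set(genes[:20]), "null1": set(genes[20:40]), "null2": set(genes[40:60])}
    expression = generate_expression(
        genes, samples, modules={"linked": modules["linked"]},
        mutant_samples=mutant, effect_size=2.0, noise_sd=1.0, seed=13,
    )
    result = run_slea(expression, modules, mutant, n_random=1000, seed=5)
    mean_mut = result.z.loc["linked", mutant].mean()
    mean_wt = result.z.loc["linked", samples[12:]].mean()
    assert mean_mut > mean_wt + 2
    table = result.group_comparison
    assert table.loc["linked", "q_right"] < 0.05
    assert table.loc["null1", "p_right"] > 0.01
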