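"""CF ratios, mutated fractions, enrichment and exclusivity statistics."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from crfdrivers.catalog import Consequence, MutationCatalog
from crfdrivers.cohort import (
    alteration_matrix,
    driver_enrichment_test,
    exclusivity_sort,
    pairwise_exclusivity_test,
    sample_profiles,
    site_mutated_fraction,
)

from conftest import make_record


def _catalog(sample_genes, roster=None, consequence=Consequence.MISSENSE):
    records = [
        make_record(sample=s, gene=g, consequence=consequence, pos=10)
        for s, genes in sample_genes.items()
        for g in genes
    ]
    samples = tuple(roster or sample_genes)
    return MutationCatalog("d", "site", samples, records)


class TestSampleProfiles:
    def test_cf_ratio_arithmetic(self):
        catalog = _catalog({"S1": ["D1", "D2", "D3", "D4", "D5"]})
        (profile,) = sample_profiles(catalog, set("D1 D2 D3 D4 D5".split()), {"D1", "D2"})
        assert profile.n_driver_pam == 5 and profile.n_crf_driver_pam == 2
        assert profile.cf_ratio == pytest.approx(0.4)

    def test_zero_driver_sample_undefined_ratio(self):
        catalog = _catalog({"S1": ["X"]}, roster=["S1", "S2"])
        profiles = sample_profiles(catalog, {"D1"}, set())
        assert all(p.cf_ratio is None for p in profiles)

    def test_all_crf_drivers_ratio_one(self):
        catalog = _catalog({"S1": ["C1", "C2"]})
        (profile,) = sample_profiles(catalog, {"C1", "C2", "D9"}, {"C1", "C2"})
        assert profile.cf_ratio == 1.0

    def test_gene_mutated_twice_counts_once(self):
        records = [
            make_record(sample="S1", gene="D1", pos=5),
            make_record(sample="S1", gene="D1", pos=90),
        ]
        catalog = MutationCatalog("d", "s", ("S1",), records)
        (profile,) = sample_profiles(catalog, {"D1"}, {"D1"})
        assert profile.n_driver_pam == 1

    def test_non_pam_mutations_ignored(self):
        catalog = _catalog({"S1": ["D1"]}, consequence=Consequence.SYNONYMOUS)
        (profile,) = sample_profiles(catalog, {"D1"}, set())
        assert profile.n_driver_pam == 0

    def test_crf_subset_enforced(self):
        catalog = _catalog({"S1": ["D1"]})
        with pytest.raises(ValueError):
            sample_profiles(catalog, {"D1"}, {"OTHER"})


class TestSiteFraction:
    def test_extremes_and_simple_count(self):
        catalog = _catalog(
            {f"S{i}": (["CRF1"] if i < 3 else ["D1"]) for i in range(10)}
        )
        profiles = sample_profiles(catalog, {"CRF1", "D1"}, {"CRF1"})
        assert site_mutated_fraction(profiles) == pytest.approx(0.3)
        none = sample_profiles(catalog, {"D1"}, set())
        assert site_mutated_fraction(none) == 0.0
        all_profiles = sample_profiles(catalog, {"CRF1", "D1"}, {"CRF1", "D1"})
        assert site_mutated_fraction(all_profiles) == 1.0

    def test_indicator_sum_identity(self, small_null_catalog):
        genes = sorted(small_null_catalog.genes())
        drivers, crfs = set(genes[:30]), set(genes[:10])
        profiles = sample_profiles(small_null_catalog, drivers, crfs)
        manual = sum(p.n_crf_driver_pam >= 1 for p in profiles) / len(profiles)
        assert site_mutated_fraction(profiles) == manual


class TestDriverEnrichment:
    def test_tiny_table_brute_force(self):
        # (2,3,3,10): C(3,2)C(7,1)+C(3,3)C(7,0) over C(10,3)
        expected = (comb(3, 2) * comb(7, 1) + comb(3, 3) * comb(7, 0)) / comb(10, 3)
        assert driver_enrichment_test(2, 3, 3, 10) == pytest.approx(expected)

    def test_empty_upper_tail_is_one(self):
        assert driver_enrichment_test(0, 50, 0, 100) == 1.0
        assert driver_enrichment_test(0, 50, 10, 100) == 1.0

    def test_matches_exhaustive_sum_for_small_universes(self, rng):
        for _ in range(50):
            N = int(rng.integers(10, 100))
            n = int(rng.integers(1, N))
            K = int(rng.integers(1, N))
            lo = max(0, K + n - N)
            k = int(rng.integers(lo, min(K, n) + 1))
            exact = sum(
                comb(n, i) * comb(N - n, K - i) / comb(N, K)
                for i in range(k, min(K, n) + 1)
            )
            got = driver_enrichment_test(k, K, n, N)
            assert got == pytest.approx(exact, rel=1e-10)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            driver_enrichment_test(5, 3, 10, 100)  # k > set size
        with pytest.raises(ValueError):
            driver_enrichment_test(1, 90, 5, 20)  # set larger than universe


class TestExclusivitySort:
    @staticmethod
    def brute_force_sort(matrix):
        row_order = sorted(matrix.index, key=lambda g: (-matrix.loc[g].sum(), str(g)))
        ordered = matrix.loc[row_order]

        def column_key(col):
            return (tuple(-int(v) for v in ordered[col]), str(col))

        best = min(
            itertools.permutations(matrix.columns),
            key=lambda perm: [column_key(c) for c in perm],
        )
        return row_order, list(best)

    def test_matches_brute_force_on_3x4_matrices(self, rng):
        for _ in range(60):
            values = rng.integers(0, 2, size=(3, 4))
            matrix = pd.DataFrame(values, index=list("ABC"), columns=list("wxyz"))
            assert exclusivity_sort(matrix) == self.brute_force_sort(matrix)

    def test_perfectly_exclusive_staircase(self):
        matrix = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"], columns=list("abcd")
        )
        rows, cols = exclusivity_sort(matrix)
        ordered = matrix.loc[rows, cols].to_numpy()
        assert ordered.tolist() == [[1, 1, 0, 0], [0, 0, 1, 1]]
        assert not np.any(ordered.sum(axis=0) > 1)

    def test_idempotent(self, rng):
        matrix = pd.DataFrame(
            rng.integers(0, 2, size=(4, 6)),
            index=list("ABCD"),
            columns=[f"s{i}" for i in range(6)],
        )
        rows, cols = exclusivity_sort(matrix)
        sorted_matrix = matrix.loc[rows, cols]
        assert exclusivity_sort(sorted_matrix) == (rows, cols)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            exclusivity_sort(pd.DataFrame([[0, 2]], index=["A"], columns=["s", "t"]))


class TestPairwiseExclusivity:
    def test_worked_under_overlap(self):
        a = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1, 0, 0]
        assert pairwise_exclusivity_test(a, b) == pytest.approx(15 / 210)

    def test_disjoint_covering_margins_minimal(self):
        a = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
        assert pairwise_exclusivity_test(a, b) == pytest.approx(1 / comb(10, 4))

    def test_identical_vectors_p_one(self):
        a = [1, 0, 1, 0, 1]
        assert pairwise_exclusivity_test(a, a) == pytest.approx(1.0)

    def test_matches_brute_force_hypergeometric_sum(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            a = rng.integers(0, 2, size=n)
            b = rng.integers(0, 2, size=n)
            ka, kb, overlap = int(a.sum()), int(b.sum()), int((a & b).sum())
            exact = sum(
                comb(ka, i) * comb(n - ka, kb - i) / comb(n, kb)
                for i in range(max(0, ka + kb - n), overlap + 1)
                if kb - i <= n - ka
            )
            assert pairwise_exclusivity_test(a, b) == pytest.approx(exact, rel=1e-10)


def test_alteration_matrix_counts_pams_only(small_null_catalog):
    genes = sorted(small_null_catalog.genes())[:10]
    matrix = alteration_matrix(small_null_catalog, genes)
    assert matrix.shape == (10, len(small_null_catalog.samples))
    mutated = {
        (r.gene_id, r.sample_id)
        for r in small_null_catalog.pam_records()
        if r.gene_id in set(genes)
    }
    assert int(matrix.to_numpy().sum()) == len(mutated)
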