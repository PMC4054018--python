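"""FM bias: empirical functional-impact test against the exhaustive oracle."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from crfdrivers.catalog import Consequence, MutationCatalog
from crfdrivers.fm import (
    dataset_fm_bias,
    gene_fm_pvalue,
    group_fm_bias,
    prepare_background,
)
from crfdrivers.simulate import DriverSpec, SimulationConfig, generate_catalog

from conftest import make_record


def exhaustive_fm_pvalue(pool, gene_values):
    """Oracle: exact upper-tail probability of the mean of n independent
    draws (with replacement) from the pool, by full enumeration."""
    n = len(gene_values)
    observed = sum(gene_values) / n
    hits = total = 0
    for draw in itertools.product(pool, repeat=n):
        total += 1
        if sum(draw) / n >= observed - 1e-12:
            hits += 1
    return hits / total


def test_single_pam_toy_matches_single_draw_enumeration(toy_catalog):
    """Pool {0.1,0.2,0.3,0.4,0.9}, gene PAM at 0.9: exact P = 1/5."""
    exact = exhaustive_fm_pvalue([0.1, 0.2, 0.3, 0.4, 0.9], [0.9])
    assert exact == pytest.approx(0.2)
    n_samplings = 20_000
    result = gene_fm_pvalue(toy_catalog, "E", n_samplings=n_samplings, seed=0, min_pams=1)
    se = np.sqrt(exact * (1 - exact) / n_samplings)
    assert result.per_predictor_p["ma"] == pytest.approx(exact, abs=3 * se + 1 / n_samplings)


def test_multi_pam_toy_matches_enumeration():
    """Catalogs with <= 8 PAMs: sampling matches enumeration within 3 MC SE."""
    scores = {"A": [0.15, 0.7], "B": [0.3], "C": [0.5, 0.95, 0.05]}
    records = [
        make_record(sample=f"S{i}", gene=g, pos=5 + i, fis={"ma": s})
        for i, (g, vals) in enumerate(sorted(scores.items()))
        for s in vals
    ]
    catalog = MutationCatalog(
        "toy", "site", tuple(r.sample_id for r in records), records
    )
    pool = [s for vals in scores.values() for s in vals]
    n_samplings = 20_000
    for gene, vals in scores.items():
        exact = exhaustive_fm_pvalue(pool, vals)
        result = gene_fm_pvalue(catalog, gene, n_samplings=n_samplings, seed=3, min_pams=1)
        se = np.sqrt(exact * (1 - exact) / n_samplings)
        assert result.per_predictor_p["ma"] == pytest.approx(
            exact, abs=3 * se + 2 / n_samplings
        ), gene


def test_identical_fis_gives_p_one():
    records = [
        make_record(sample=f"S{i}", gene=g, pos=10, fis={"ma": 0.3})
        for i, g in enumerate(["A", "A", "A", "B", "B", "B"])
    ]
    catalog = MutationCatalog("d", "s", tuple(r.sample_id for r in records), records)
    result = gene_fm_pvalue(catalog, "A", n_samplings=2000, seed=1)
    assert result.p_fm == pytest.approx(1.0)


def test_strict_maximum_attains_add_one_floor():
    """A gene whose PAMs all carry the catalog's strict maximum FIS reaches
    the attainable minimum 1/(N+1)."""
    records = [
        make_record(sample=f"S{i}", gene="HI", pos=7, fis={"ma": 0.99})
        for i in range(3)
    ] + [
        make_record(sample=f"T{i}", gene="LO", pos=8, fis={"ma": 0.01})
        for i in range(50)
    ]
    catalog = MutationCatalog("d", "s", tuple(r.sample_id for r in records), records)
    n = 2000
    result = gene_fm_pvalue(catalog, "HI", n_samplings=n, seed=5)
    # null mean >= 0.99 requires all three draws to hit a 0.99 (p ~ (3/53)^3)
    assert result.per_predictor_p["ma"] <= 5 / (n + 1)


def test_truncating_mutations_score_one_and_missense_imputed():
    records = [
        make_record(sample="S1", gene="A", consequence=Consequence.STOP_GAINED, pos=5),
        make_record(sample="S2", gene="A", consequence=Consequence.MISSENSE, pos=6),
        make_record(sample="S3", gene="B", consequence=Consequence.MISSENSE, pos=7,
                    fis={"ma": 0.4}),
        make_record(sample="S4", gene="B", consequence=Consequence.MISSENSE, pos=8,
                    fis={"ma": 0.6}),
    ]
    catalog = MutationCatalog("d", "s", ("S1", "S2", "S3", "S4"), records)
    bg = prepare_background(catalog)
    assert bg.per_gene["A"]["ma"].tolist() == [1.0, 0.5]  # stop -> 1; imputed median 0.5
    dropped = prepare_background(catalog, missing_missense="drop")
    assert dropped.per_gene["A"]["ma"].tolist() == [1.0]


def test_positioned_pool_excludes_unpositioned_pams():
    records = [
        make_record(sample="S1", gene="A", consequence=Consequence.FRAMESHIFT_INDEL,
                    pos=None),
        make_record(sample="S2", gene="A", pos=5, fis={"ma": 0.4}),
        make_record(sample="S3", gene="B", pos=6, fis={"ma": 0.9}),
    ]
    catalog = MutationCatalog("d", "s", ("S1", "S2", "S3"), records)
    full = prepare_background(catalog)
    positioned = prepare_background(catalog, pool="positioned_pams")
    assert len(full.pools["ma"]) == 3  # unpositioned frameshift scored 1.0
    assert len(positioned.pools["ma"]) == 2
    assert positioned.per_gene["A"]["ma"].tolist() == [0.4]


def test_untested_gene_has_absent_p_not_one(toy_catalog):
    result = gene_fm_pvalue(toy_catalog, "A", min_pams=3)
    assert result.p_fm is None and not result.tested
    assert result.n_pam == 1


def test_monotonicity_raising_fis_never_increases_p():
    """Raising every FIS of a gene by a constant (no clipping) cannot make
    its empirical P larger at the same seed."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(40):
        records.append(
            make_record(sample=f"S{i}", gene=f"G{i % 8}", pos=3 + i,
                        fis={"ma": float(rng.uniform(0.05, 0.55))})
        )
    catalog = MutationCatalog("d", "s", tuple(r.sample_id for r in records), records)
    for shift in (0.1, 0.3):
        lifted_records = [
            replace(r, fis={"ma": r.fis["ma"] + shift}) if r.gene_id == "G0" else r
            for r in records
        ]
        lifted = MutationCatalog("d", "s", catalog.samples, lifted_records)
        p0 = gene_fm_pvalue(catalog, "G0", n_samplings=4000, seed=11).p_fm
        p1 = gene_fm_pvalue(lifted, "G0", n_samplings=4000, seed=11).p_fm
        assert p1 <= p0 + 1e-12


def test_dataset_fm_bias_bh_and_ordering(small_null_catalog):
    results = dataset_fm_bias(small_null_catalog, n_samplings=500, seed=4)
    tested = [r for r in results if r.tested]
    assert tested, "no testable genes in the fixture"
    for r in tested:
        assert 1 / 501 <= r.p_fm <= 1
        assert r.q_fm >= r.p_fm - 1e-12
    ps = [r.p_fm for r in tested]
    assert ps == sorted(ps)
    untested = [r for r in results if not r.tested]
    for r in untested:
        assert r.q_fm is None


def test_bh_on_single_tested_gene_equals_p():
    records = [
        make_record(sample=f"S{i}", gene="ONLY", pos=4, fis={"ma": 0.5})
        for i in range(3)
    ]
    catalog = MutationCatalog("d", "s", ("S0", "S1", "S2"), records)
    (result,) = dataset_fm_bias(catalog, n_samplings=500, seed=0)
    assert result.q_fm == pytest.approx(result.p_fm)


def test_group_singleton_identity(small_null_catalog):
    gene = max(
        small_null_catalog.genes(),
        key=lambda g: len([r for r in small_null_catalog.records_for_gene(g) if r.is_pam]),
    )
    alone = gene_fm_pvalue(small_null_catalog, gene, n_samplings=1000, seed=9)
    grouped = group_fm_bias(small_null_catalog, {gene}, "grp", n_samplings=1000, seed=9)
    assert grouped.p_fm == pytest.approx(alone.p_fm, rel=0, abs=0)
    assert grouped.n_pam == alone.n_pam


def test_group_with_zero_pams_untested():
    records = [make_record(sample="S1", gene="A", consequence=Consequence.SYNONYMOUS, pos=5),
               make_record(sample="S1", gene="B", pos=5, fis={"ma": 0.5}),
               make_record(sample="S2", gene="B", pos=6, fis={"ma": 0.5}),
               make_record(sample="S3", gene="B", pos=7, fis={"ma": 0.5})]
    catalog = MutationCatalog("d", "s", ("S1", "S2", "S3"), records)
    result = group_fm_bias(catalog, {"A"}, "empty-group", n_samplings=100, seed=0)
    assert result.p_fm is None and result.n_pam == 0


def test_pooled_complex_detected_when_members_are_untested():
    """Five genes with 2 high-FIS PAMs each sit below min_pams=5 singly but
    reach significance pooled — the complex-level rationale."""
    config = SimulationConfig(n_samples=100, n_genes=60, mutations_per_sample=6.0, seed=21)
    specs = tuple(
        DriverSpec(f"G{i:04d}", "fis_shift", {"shift": 0.6, "n_add": 2})
        for i in range(1, 6)
    )
    catalog = generate_catalog(replace(config, driver_specs=specs))
    members = {s.gene for s in specs}
    pooled = group_fm_bias(catalog, members, "complex", n_samplings=2000, seed=2, min_pams=5)
    assert pooled.tested and pooled.p_fm < 0.05
    assert pooled.n_samples_with_pam >= 5
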