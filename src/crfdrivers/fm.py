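"""Functional-impact (FM) bias: genes accumulating high-impact mutations.

A gene is FM biased when the functional impact scores (FIS) of its
protein-affecting mutations (PAMs) are higher than expected from the cohort
background — a signal of positive selection.  The test statistic is the mean
FIS of the gene's PAMs per predictor; the null is built by resampling
same-size FIS sets with replacement from the pooled PAM background of the
whole cohort, and the empirical P value uses the add-one convention
``(1 + #{null >= observed}) / (N + 1)``.  Per-predictor P values are combined
(Fisher by default) into one gene-level P; Benjamini–Hochberg runs over the
tested genes of a dataset.

Truncating mutations (stop gains, frameshift indels) carry no predictor
score and are assigned the maximal impact 1.0; missense mutations missing a
predictor score are imputed at the cohort median of that predictor
(configurable to drop).  The same machinery tests pooled gene groups
(multiprotein complexes, the whole CRF catalog) as meta-genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import (
    Consequence,
    GeneUniverse,
    MutationCatalog,
    TRUNCATING_CONSEQUENCES,
)
from .combine import bh_adjust, combine_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "DriverResult",
    "FMBackground",
    "prepare_background",
    "gene_fm_pvalue",
    "dataset_fm_bias",
    "group_fm_bias",
]

#: Score assigned to truncating PAMs for every predictor.
TRUNCATING_SCORE = 1.0

#: Comparison tolerance for "null mean >= observed mean" (absorbs float
#: round-off when all scores are identical; real FIS differences are >> 1e-9).
_GE_TOL = 1e-9


@dataclass
class DriverResult:
    """Per gene (or gene group) per dataset driver statistics."""

    gene_or_group: str
    dataset_id: str
    n_pam: int
    n_samples_with_pam: int = 0
    per_predictor_p: dict[str, float] = field(default_factory=dict)
    p_fm: float | None = None
    q_fm: float | None = None
    p_clust: float | None = None
    q_clust: float | None = None
    driver_flag: bool = False

    @property
    def tested(self) -> bool:
        return self.p_fm is not None


@dataclass
class FMBackground:
    """Effective per-PAM FIS of a catalog, ready for resampling.

    ``pools`` maps predictor -> FIS array over every PAM of the cohort (the
    resampling background); ``per_gene`` maps gene -> (predictor -> FIS array
    of that gene's PAMs); ``samples_with_pam`` maps gene -> number of distinct
    samples bearing >= 1 PAM.
    """

    predictors: tuple[str, ...]
    pools: dict[str, np.ndarray]
    per_gene: dict[str, dict[str, np.ndarray]]
    samples_with_pam: dict[str, int]


def prepare_background(
    catalog: MutationCatalog,
    missing_missense: str = "impute_median",
    predictors: Sequence[str] | None = None,
    pool: str = "all_pams",
) -> FMBackground:
    """Build effective FIS pools for the FM test.

    ``missing_missense`` is ``"impute_median"`` (cohort median of the
    predictor over scored missense PAMs) or ``"drop"`` (unscored missense
    PAMs leave the analysis for that predictor... dropped entirely).
    ``pool`` selects which PAMs enter the analysis: ``"all_pams"`` (default)
    or ``"positioned_pams"`` (only PAMs with a protein position, excluding
    e.g. indels recorded without a residue index).
    """
    if missing_missense not in ("impute_median", "drop"):
        raise ValueError(f"unknown missing-score policy {missing_missense!r}")
    if pool not in ("all_pams", "positioned_pams"):
        raise ValueError(f"unknown background pool {pool!r}")
    preds = tuple(predictors) if predictors is not None else catalog.predictors()
    if not preds:
        preds = ("fis",)

    pams = catalog.pam_records()
    if pool == "positioned_pams":
        pams = [r for r in pams if r.protein_pos is not None]
    medians: dict[str, float] = {}
    for pred in preds:
        observed = [
            r.fis[pred]
            for r in pams
            if r.consequence is Consequence.MISSENSE and pred in r.fis
        ]
        medians[pred] = float(np.median(observed)) if observed else 0.5

    per_gene: dict[str, list[dict[str, float]]] = {}
    gene_samples: dict[str, set[str]] = {}
    for rec in pams:
        if rec.consequence in TRUNCATING_CONSEQUENCES:
            effective = {pred: TRUNCATING_SCORE for pred in preds}
        else:
            effective = {}
            complete = True
            for pred in preds:
                if pred in rec.fis:
                    effective[pred] = float(rec.fis[pred])
                elif missing_missense == "impute_median":
                    effective[pred] = medians[pred]
                else:
                    complete = False
            if not complete:
                continue
        per_gene.setdefault(rec.gene_id, []).append(effective)
        gene_samples.setdefault(rec.gene_id, set()).add(rec.sample_id)

    gene_arrays = {
        gene: {
            pred: np.array([e[pred] for e in entries], dtype=float)
            for pred in preds
        }
        for gene, entries in per_gene.items()
    }
    pools = {
        pred: (
            np.concatenate([arr[pred] for arr in gene_arrays.values()])
            if gene_arrays
            else np.empty(0)
        )
        for pred in preds
    }
    return FMBackground(
        predictors=preds,
        pools=pools,
        per_gene=gene_arrays,
        samples_with_pam={g: len(s) for g, s in gene_samples.items()},
    )


def _empirical_p(
    observed_mean: float,
    pool: np.ndarray,
    n: int,
    n_samplings: int,
    rng: np.random.Generator,
) -> float:
    """Add-one empirical upper-tail P of a mean of n draws from the pool."""
    exceed = 0
    chunk = max(1, min(n_samplings, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_samplings:
        size = min(chunk, n_samplings - done)
        null_means = rng.choice(pool, size=(size, n), replace=True).mean(axis=1)
        exceed += int(np.count_nonzero(null_means >= observed_mean - _GE_TOL))
        done += size
    return (1 + exceed) / (n_samplings + 1)


def _test_pool(
    arrays: Mapping[str, np.ndarray],
    background: FMBackground,
    n_samplings: int,
    rng: np.random.Generator,
    method: str,
) -> tuple[dict[str, float], float]:
    per_predictor: dict[str, float] = {}
    for pred in background.predictors:
        values = arrays[pred]
        pool = background.pools[pred]
        if pool.size == 0:
            raise ValueError("empty cohort background pool")
        observed = float(values.mean())
        per_predictor[pred] = _empirical_p(
            observed, pool, len(values), n_samplings, rng
        )
    combined = combine_pvalues(
        [per_predictor[p] for p in background.predictors], method=method
    )
    return per_predictor, combined


def gene_fm_pvalue(
    catalog: MutationCatalog,
    gene: str,
    n_samplings: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    min_pams: int = 3,
    method: str = "fisher",
    background: FMBackground | None = None,
) -> DriverResult:
    """FM-bias test for one gene.

    Returns a :class:`DriverResult`; a gene with fewer than ``min_pams``
    scored PAMs is untested (``p_fm`` is ``None``, never 1).
    """
    bg = background if background is not None else prepare_background(catalog)
    arrays = bg.per_gene.get(gene)
    n_pam = 0 if arrays is None else len(next(iter(arrays.values())))
    result = DriverResult(
        gene_or_group=gene,
        dataset_id=catalog.dataset_id,
        n_pam=n_pam,
        n_samples_with_pam=bg.samples_with_pam.get(gene, 0),
    )
    if arrays is None or n_pam < min_pams:
        return result
    rng = np.random.default_rng(seed)
    result.per_predictor_p, result.p_fm = _test_pool(
        arrays, bg, n_samplings, rng, method
    )
    return result


def dataset_fm_bias(
    catalog: MutationCatalog,
    universe: GeneUniverse | None = None,
    min_pams: int = 3,
    n_samplings: int = 10_000,
    seed: int = 0,
    method: str = "fisher",
    missing_missense: str = "impute_median",
) -> list[DriverResult]:
    """FM-bias test of every testable gene of one dataset, with BH q values.

    Genes are processed in lexicographic order with per-gene seeds spawned
    from ``seed``, so results do not depend on record order.  Untested genes
    are reported but excluded from the BH denominator.  Results are sorted by
    ``p_fm`` with lexicographic gene symbol as tie-break.
    """
    bg = prepare_background(catalog, missing_missense=missing_missense)
    genes = sorted(bg.per_gene)
    if universe is not None:
        genes = [g for g in genes if g in universe.genes]
    if not genes:
        logger.warning("dataset %s: no testable gene", catalog.dataset_id)
        return []
    seeds = np.random.SeedSequence(seed).spawn(len(genes))
    results = [
        gene_fm_pvalue(
            catalog,
            gene,
            n_samplings=n_samplings,
            seed=child,
            min_pams=min_pams,
            method=method,
            background=bg,
        )
        for gene, child in zip(genes, seeds)
    ]
    tested = [r for r in results if r.tested]
    if not tested:
        logger.warning("dataset %s: no gene reached min_pams=%d", catalog.dataset_id, min_pams)
    else:
        qs = bh_adjust([r.p_fm for r in tested])
        for r, q in zip(tested, qs):
            r.q_fm = float(q)
    results.sort(key=lambda r: (r.p_fm if r.p_fm is not None else 2.0, r.gene_or_group))
    return results


def group_fm_bias(
    catalog: MutationCatalog,
    gene_set: Iterable[str],
    label: str,
    n_samplings: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    min_pams: int = 3,
    method: str = "fisher",
    background: FMBackground | None = None,
) -> DriverResult:
    """FM-bias test of a pooled gene group (complex, CRF catalog) as one
    meta-gene.

    The PAMs of all member genes are pooled; the background is still the full
    cohort.  For a singleton group this reduces exactly to the member gene's
    own test at the same seed.
    """
    members = sorted(set(gene_set))
    if not members:
        raise ValueError("gene_set is empty")
    bg = background if background is not None else prepare_background(catalog)
    member_arrays = [bg.per_gene[g] for g in members if g in bg.per_gene]
    pooled = {
        pred: (
            np.concatenate([arr[pred] for arr in member_arrays])
            if member_arrays
            else np.empty(0)
        )
        for pred in bg.predictors
    }
    n_pam = len(next(iter(pooled.values()))) if bg.predictors else 0
    sample_sets = [
        {r.sample_id for r in catalog.pam_records() if r.gene_id in set(members)}
    ]
    result = DriverResult(
        gene_or_group=label,
        dataset_id=catalog.dataset_id,
        n_pam=n_pam,
        n_samples_with_pam=len(sample_sets[0]),
    )
    if n_pam < min_pams:
        return result
    rng = np.random.default_rng(seed)
    result.per_predictor_p, result.p_fm = _test_pool(
        pooled, bg, n_samplings, rng, method
    )
    return result
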