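"""Cross-dataset P-value combination and false-discovery-rate control.

Gene-wise P values from several cohorts of the same anatomical site are
combined into a single site-level P value (Fisher's method by default,
Stouffer's weighted z as an alternative), and Benjamini–Hochberg adjustment
is applied within each analysis unit (dataset or site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["combine_pvalues", "bh_adjust", "combine_site", "SiteResult"]

_TINY = float(np.finfo(float).tiny)


def combine_pvalues(
    pvalues: Sequence[float],
    method: str = "fisher",
    weights: Sequence[float] | None = None,
) -> float:
    """Combine independent P values into one.

    Fisher: X = -2 sum(ln p) ~ chi2 with 2k df.  Stouffer: weighted inverse
    normal.  A singleton list returns its element unchanged; zeros are
    clipped to the smallest positive float with a warning.
    """
    if len(pvalues) == 0:
        raise ValueError("cannot combine an empty list of P values")
    ps = np.asarray(pvalues, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("P values must lie in [0, 1]")
    if np.any(ps == 0):
        logger.warning("P value of 0 clipped to %.3g before combination", _TINY)
        ps = np.maximum(ps, _TINY)
    if len(ps) == 1:
        return float(ps[0])
    if method == "fisher":
        if weights is not None:
            raise ValueError("Fisher's method does not take weights")
        return float(stats.combine_pvalues(ps, method="fisher").pvalue)
    if method == "stouffer":
        w = None
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if len(w) != len(ps):
                raise ValueError("weights length must match P values")
            if np.any(w <= 0):
                raise ValueError("Stouffer weights must be positive")
        return float(stats.combine_pvalues(ps, method="stouffer", weights=w).pvalue)
    raise ValueError(f"unknown combination method {method!r}")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values, in the input order."""
    ps = np.asarray(pvalues, dtype=float)
    if ps.size == 0:
        return ps.copy()
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1]


@dataclass
class SiteResult:
    """Site-level combined result for one gene."""

    gene: str
    site: str
    p_fm: float | None
    q_fm: float | None
    p_clust: float | None
    q_clust: float | None
    datasets: tuple[str, ...]
    driver_flag: bool = False


def combine_site(
    dataset_results: Mapping[str, Mapping[str, tuple[float | None, float | None]]],
    site: str,
    method: str = "fisher",
    dataset_weights: Mapping[str, float] | None = None,
    q_threshold: float = 0.05,
) -> list[SiteResult]:
    """Combine per-dataset gene results into site-level calls.

    Parameters
    ----------
    dataset_results
        Mapping dataset_id -> {gene -> (p_fm, p_clust)}; either P may be
        ``None`` for a gene untested in that dataset.
    dataset_weights
        Optional per-dataset Stouffer weights (e.g. cohort sizes).

    A gene tested in a single dataset keeps that dataset's P unchanged.  BH
    runs across the site's tested genes, separately per statistic; the driver
    flag is ``min(q_fm, q_clust) < q_threshold`` over the defined q values.
    """
    if not dataset_results:
        raise ValueError(f"no dataset results supplied for site {site!r}")
    per_gene: dict[str, dict[str, tuple[float | None, float | None]]] = {}
    for dataset_id, gene_map in dataset_results.items():
        for gene, (p_fm, p_clust) in gene_map.items():
            per_gene.setdefault(gene, {})[dataset_id] = (p_fm, p_clust)

    results: list[SiteResult] = []
    for gene in sorted(per_gene):
        entries = per_gene[gene]
        contributing = tuple(sorted(entries))
        fm_items = [(d, p) for d, (p, _) in entries.items() if p is not None]
        clust_items = [(d, p) for d, (_, p) in entries.items() if p is not None]

        def _combine(items: list[tuple[str, float]]) -> float | None:
            if not items:
                return None
            items = sorted(items)
            ps = [p for _, p in items]
            weights = None
            if method == "stouffer" and dataset_weights is not None:
                weights = [float(dataset_weights[d]) for d, _ in items]
            return combine_pvalues(ps, method=method, weights=weights)

        results.append(
            SiteResult(
                gene=gene,
                site=site,
                p_fm=_combine(fm_items),
                q_fm=None,
                p_clust=_combine(clust_items),
                q_clust=None,
                datasets=contributing,
            )
        )

    for attr_p, attr_q in (("p_fm", "q_fm"), ("p_clust", "q_clust")):
        tested = [r for r in results if getattr(r, attr_p) is not None]
        if tested:
            qs = bh_adjust([getattr(r, attr_p) for r in tested])
            for r, q in zip(tested, qs):
                setattr(r, attr_q, float(q))
    for r in results:
        qs = [q for q in (r.q_fm, r.q_clust) if q is not None]
        r.driver_flag = bool(qs) and min(qs) < q_threshold
    results.sort(key=lambda r: (r.p_fm if r.p_fm is not None else 2.0, r.gene))
    return results
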