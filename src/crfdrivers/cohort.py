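"""Per-sample driver profiles, CF ratios, exclusivity and enrichment tests.

The CF ratio of a tumor sample is the fraction of its PAM-bearing likely
driver genes that are chromatin regulatory factors (CRFs): 0 when no mutated
driver is a CRF, 1 when all of them are.  Counting is over distinct genes
with at least one protein-affecting mutation, so the ratio is bounded in
[0, 1] by construction.  The module also provides the per-site fraction of
samples with a mutated driver CRF, a log-space hypergeometric
overrepresentation test (are drivers enriched among CRFs?), a deterministic
oncoprint "memo sort" of binary alteration matrices, and a pairwise
hypergeometric test for mutual exclusivity (under-overlap) of two genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MutationCatalog

__all__ = [
    "SampleDriverProfile",
    "sample_profiles",
    "site_mutated_fraction",
    "driver_enrichment_test",
    "alteration_matrix",
    "exclusivity_sort",
    "pairwise_exclusivity_test",
]


@dataclass(frozen=True)
class SampleDriverProfile:
    """Driver-mutation profile of one tumor sample.

    ``cf_ratio`` is ``None`` (undefined) for samples without any mutated
    driver gene; such samples are excluded from CF-ratio distributions but
    kept in mutated-fraction denominators.
    """

    sample_id: str
    site: str
    n_driver_pam: int
    n_crf_driver_pam: int
    cf_ratio: float | None

    def __post_init__(self) -> None:
        if self.n_crf_driver_pam > self.n_driver_pam:
            raise ValueError("CRF driver count exceeds driver count")


def sample_profiles(
    catalog: MutationCatalog,
    driver_genes: Iterable[str],
    crf_driver_genes: Iterable[str],
) -> list[SampleDriverProfile]:
    """One profile per roster sample (zero-mutation samples included).

    Counts are of distinct driver genes bearing >= 1 PAM in the sample; a
    gene mutated twice counts once.
    """
    drivers = set(driver_genes)
    crf_drivers = set(crf_driver_genes)
    if not crf_drivers <= drivers:
        raise ValueError("crf_driver_genes must be a subset of driver_genes")
    mutated: dict[str, set[str]] = {sample: set() for sample in catalog.samples}
    for rec in catalog.pam_records():
        if rec.gene_id in drivers:
            mutated[rec.sample_id].add(rec.gene_id)
    profiles = []
    for sample in catalog.samples:
        genes = mutated[sample]
        n_driver = len(genes)
        n_crf = len(genes & crf_drivers)
        profiles.append(
            SampleDriverProfile(
                sample_id=sample,
                site=catalog.site,
                n_driver_pam=n_driver,
                n_crf_driver_pam=n_crf,
                cf_ratio=(n_crf / n_driver) if n_driver else None,
            )
        )
    return profiles


def site_mutated_fraction(profiles: Sequence[SampleDriverProfile]) -> float:
    """Fraction of roster samples with >= 1 PAM-bearing driver CRF."""
    if not profiles:
        raise ValueError("no profiles supplied")
    hits = sum(1 for p in profiles if p.n_crf_driver_pam >= 1)
    return hits / len(profiles)


def driver_enrichment_test(
    k_drivers_in_set: int, set_size: int, n_drivers: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric P(X >= k) of driver overrepresentation.

    Population ``universe_size`` genes of which ``n_drivers`` are drivers;
    ``set_size`` genes drawn (the catalog, e.g. the CRF list), ``k`` of them
    drivers.  Computed in log space to survive extreme tails.
    """
    k, K, n, N = k_drivers_in_set, set_size, n_drivers, universe_size
    if not (0 <= k <= min(K, n) and 0 <= n <= N and 0 < K <= N):
        raise ValueError(f"inconsistent 2x2 margins: k={k}, set={K}, drivers={n}, universe={N}")
    if K - k > N - n:
        raise ValueError("inconsistent 2x2 margins: too many non-drivers in the set")
    if k == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, n, K)))


def alteration_matrix(
    catalog: MutationCatalog, genes: Iterable[str]
) -> pd.DataFrame:
    """Binary genes x samples matrix: 1 iff the gene has a PAM in the sample."""
    gene_list = sorted(set(genes))
    df = pd.DataFrame(
        0, index=gene_list, columns=list(catalog.samples), dtype=int
    )
    wanted = set(gene_list)
    for rec in catalog.pam_records():
        if rec.gene_id in wanted:
            df.loc[rec.gene_id, rec.sample_id] = 1
    return df


def exclusivity_sort(matrix: pd.DataFrame) -> tuple[list, list]:
    """Oncoprint memo sort of a binary genes x samples alteration matrix.

    Rows (genes) are ordered by descending mutation count, ties broken
    lexicographically.  Columns (samples) are ordered by descending binary
    weight, reading the sorted rows as bits with the most-mutated gene as the
    most significant; ties broken lexicographically by sample id.  The
    resulting staircase exposes mutual exclusivity.  Idempotent.
    """
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("alteration matrix must be binary")
    row_order = sorted(
        matrix.index, key=lambda g: (-int(matrix.loc[g].sum()), str(g))
    )
    ordered = matrix.loc[row_order]
    col_order = sorted(
        matrix.columns,
        key=lambda s: (tuple(-int(v) for v in ordered[s]), str(s)),
    )
    return row_order, col_order


def pairwise_exclusivity_test(
    gene_a: Sequence[int], gene_b: Sequence[int]
) -> float:
    """Lower-tail hypergeometric P of observing <= the seen co-mutation count.

    Small P means the two genes share fewer mutated samples than expected
    from their margins — mutual exclusivity.
    """
    a = np.asarray(gene_a, dtype=int)
    b = np.asarray(gene_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("gene vectors must be equal-length 1-D")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("gene vectors must be binary")
    n = len(a)
    overlap = int(np.sum(a & b))
    return float(stats.hypergeom.cdf(overlap, n, int(a.sum()), int(b.sum())))
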