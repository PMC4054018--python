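"""Positional clustering (CLUST) bias: mutation hotspots along the protein.

Genes under positive selection often concentrate their protein-affecting
mutations (PAMs) in a few residues or short regions.  The detector works in
three steps: (1) *seed* residues whose mutation count exceeds the uniform
expectation (and is at least 2 — a singleton mutation is never evidence of
clustering); (2) seeds within ``gap`` residues of each other are *merged*;
(3) each cluster is *extended* to mutated positions within ``gap`` of its
boundary while they add mutation mass.  The gene score

    score = sum over clusters of (cluster count / positioned PAMs) * w,
    w = 1 - (cluster span - 1) / protein length

is 1 when every positioned PAM sits in one residue and 0 without clusters.

Calibration uses synonymous mutations of the same dataset: their scores (for
genes with enough synonymous events) form the null sample, a normal law is
moment-fitted to them, and each gene's PAM-based score gets a one-sided P
from that fitted null.  These scoring and extension rules are a
reconstruction: the constants (``gap``, seed rule, weight) are exposed and
documented rather than inherited from any released tool.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .catalog import Consequence, GeneUniverse, MutationCatalog
from .combine import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "ClusterCall",
    "CalibrationError",
    "find_clusters",
    "gene_clust_score",
    "dataset_clust_bias",
]

#: Floor for the fitted null standard deviation.  At realistic synonymous
#: counts most background scores are exactly 0 and the moment fit can
#: degenerate; the floor keeps one-sided P values defined.
SIGMA_FLOOR = 0.01


class CalibrationError(RuntimeError):
    """The synonymous background is too small to estimate the null."""


@dataclass(frozen=True)
class Cluster:
    start: int
    end: int
    count: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class ClusterCall:
    """Clustering result for one gene in one dataset."""

    gene: str
    dataset_id: str
    clusters: list[Cluster] = field(default_factory=list)
    gene_score: float = 0.0
    n_pam_positioned: int = 0
    p_clust: float | None = None
    q_clust: float | None = None

    @property
    def tested(self) -> bool:
        return self.p_clust is not None


def find_clusters(
    positions: Iterable[int], protein_length: int, gap: int = 5
) -> list[Cluster]:
    """Seed-merge-extend hotspot detection on a multiset of residue indices.

    Seed residues must carry more mutations than the uniform expectation
    ``n / protein_length`` and at least 2.  Seeds within ``gap`` residues are
    merged; clusters then absorb mutated positions within ``gap`` of their
    boundary (any mutation adds mass) until stable.  Deterministic; clusters
    are returned left to right and never overlap.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    counts = Counter(int(p) for p in positions)
    if not counts:
        return []
    n = sum(counts.values())
    threshold = max(n / protein_length, 1.0)
    seeds = sorted(pos for pos, c in counts.items() if c > threshold)
    if not seeds:
        return []

    # merge seeds within gap
    intervals: list[list[int]] = [[seeds[0], seeds[0]]]
    for pos in seeds[1:]:
        if pos - intervals[-1][1] <= gap:
            intervals[-1][1] = pos
        else:
            intervals.append([pos, pos])

    # extend boundaries toward nearby mutated positions
    mutated = sorted(counts)
    changed = True
    while changed:
        changed = False
        for interval in intervals:
            left = [p for p in mutated if interval[0] - gap <= p < interval[0]]
            if left:
                interval[0] = min(left)
                changed = True
            right = [p for p in mutated if interval[1] < p <= interval[1] + gap]
            if right:
                interval[1] = max(right)
                changed = True
        # re-merge intervals that touched or overlapped after extension
        intervals.sort()
        merged: list[list[int]] = [intervals[0]]
        for interval in intervals[1:]:
            if interval[0] <= merged[-1][1] + gap:
                merged[-1][1] = max(merged[-1][1], interval[1])
            else:
                merged.append(interval)
        intervals = merged

    return [
        Cluster(
            start=start,
            end=end,
            count=sum(c for p, c in counts.items() if start <= p <= end),
        )
        for start, end in intervals
    ]


def gene_clust_score(
    clusters: Sequence[Cluster], n_pam_positioned: int, protein_length: int
) -> float:
    """Concentration score in [0, 1] of a gene's cluster set."""
    if n_pam_positioned < 1:
        raise ValueError("n_pam_positioned must be >= 1")
    score = 0.0
    for cluster in clusters:
        weight = 1.0 - (cluster.span - 1) / protein_length
        score += (cluster.count / n_pam_positioned) * weight
    return float(score)


def _score_positions(
    positions: list[int], protein_length: int, gap: int
) -> tuple[list[Cluster], float]:
    clusters = find_clusters(positions, protein_length, gap=gap)
    return clusters, gene_clust_score(clusters, len(positions), protein_length)


def dataset_clust_bias(
    catalog: MutationCatalog,
    universe: GeneUniverse | None = None,
    min_pams: int = 3,
    gap: int = 5,
    min_background: int = 10,
) -> list[ClusterCall]:
    """CLUST-bias test of every testable gene of one dataset.

    The null is calibrated on clustering scores of synonymous mutations:
    every gene with >= ``min_pams`` positioned synonymous events contributes
    one background score; a normal law is moment-fitted to those scores (SD
    floored at :data:`SIGMA_FLOOR`); each gene with >= ``min_pams``
    positioned PAMs gets a one-sided P for its PAM score under that null.
    BH runs over tested genes.  Deterministic given the catalog.
    """
    syn_positions: dict[str, list[int]] = {}
    pam_positions: dict[str, list[int]] = {}
    for rec in catalog.records:
        if rec.protein_pos is None:
            continue
        if rec.consequence is Consequence.SYNONYMOUS:
            syn_positions.setdefault(rec.gene_id, []).append(rec.protein_pos)
        elif rec.is_pam:
            pam_positions.setdefault(rec.gene_id, []).append(rec.protein_pos)

    background_scores = []
    for gene in sorted(syn_positions):
        positions = syn_positions[gene]
        if len(positions) < min_pams:
            continue
        length = catalog.protein_length(gene)
        if length is None:
            continue
        _, score = _score_positions(positions, length, gap)
        background_scores.append(score)
    if len(background_scores) < min_background:
        raise CalibrationError(
            f"only {len(background_scores)} genes with >= {min_pams} positioned "
            f"synonymous mutations (need {min_background}): null unestimable"
        )
    mu = float(np.mean(background_scores))
    sigma = max(float(np.std(background_scores, ddof=1)), SIGMA_FLOOR)

    genes = sorted(pam_positions)
    if universe is not None:
        genes = [g for g in genes if g in universe.genes]
    calls: list[ClusterCall] = []
    for gene in genes:
        positions = pam_positions[gene]
        call = ClusterCall(
            gene=gene,
            dataset_id=catalog.dataset_id,
            n_pam_positioned=len(positions),
        )
        length = catalog.protein_length(gene)
        if len(positions) >= min_pams and length is not None:
            call.clusters, call.gene_score = _score_positions(positions, length, gap)
            # keep P in (0, 1]: the survival function underflows for extreme scores
            call.p_clust = float(
                max(stats.norm.sf(call.gene_score, loc=mu, scale=sigma),
                    np.finfo(float).tiny)
            )
        calls.append(call)

    tested = [c for c in calls if c.tested]
    if tested:
        qs = bh_adjust([c.p_clust for c in tested])
        for c, q in zip(tested, qs):
            c.q_clust = float(q)
    calls.sort(key=lambda c: (c.p_clust if c.p_clust is not None else 2.0, c.gene))
    return calls
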