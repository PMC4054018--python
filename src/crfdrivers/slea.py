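"""Sample-level enrichment analysis (SLEA) of gene modules.

Expression is first standardized per gene (median-centered, scaled by the
pre-centering standard deviation) so values measure a gene's level in one
sample relative to the whole panel.  For each module and sample, the mean (or
median) standardized expression of the module's genes is compared to the same
statistic over 10,000 random gene sets of identical size; the result is a
z-score per (module, sample).  Random sets are drawn once per module size and
shared across samples, which keeps z columns comparable across samples and
the runtime proportional to the number of distinct sizes.

To link mutations to expression, the z-scores of samples that carry a
mutation in a gene of interest are compared to wild-type samples with the
Wilcoxon–Mann–Whitney rank test, one-sided in both directions, and each tail
is Benjamini–Hochberg-adjusted across modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .combine import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SLEAResult",
    "normalize_expression",
    "slea_zscores",
    "compare_groups",
    "slea_group_comparison",
    "run_slea",
]


@dataclass
class SLEAResult:
    """Module x sample z matrix plus the mutant-vs-WT group comparison."""

    z: pd.DataFrame
    group_comparison: pd.DataFrame | None = None


def normalize_expression(
    matrix: pd.DataFrame, zero_variance: str = "drop"
) -> pd.DataFrame:
    """Per-gene standardization: (x - median) / SD (SD before centering).

    ``zero_variance``: ``"drop"`` removes constant rows with a warning,
    ``"zero"`` keeps them as all-zero rows.  Idempotent up to round-off.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to standardize")
    if zero_variance not in ("drop", "zero"):
        raise ValueError(f"unknown zero_variance policy {zero_variance!r}")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    median = np.median(values, axis=1)
    constant = sd == 0
    if constant.any():
        if zero_variance == "drop":
            logger.warning(
                "dropping %d zero-variance gene(s)", int(constant.sum())
            )
        sd = np.where(constant, 1.0, sd)
    out = (values - median[:, None]) / sd[:, None]
    if zero_variance == "zero":
        out[constant] = 0.0
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return pd.DataFrame(
        out[~constant], index=matrix.index[~constant], columns=matrix.columns
    )


def _random_index_sets(
    rng: np.random.Generator, n_genes: int, size: int, n_random: int
) -> np.ndarray:
    """(n_random, size) row indices, sampled without replacement per set."""
    out = np.empty((n_random, size), dtype=np.intp)
    chunk = max(1, min(n_random, 20_000_000 // max(n_genes, 1)))
    done = 0
    while done < n_random:
        m = min(chunk, n_random - done)
        keys = rng.random((m, n_genes))
        out[done : done + m] = np.argpartition(keys, size - 1, axis=1)[:, :size]
        done += m
    return out


def slea_zscores(
    standardized: pd.DataFrame,
    modules: Mapping[str, set[str]],
    statistic: str = "mean",
    n_random: int = 10_000,
    seed: int = 0,
    min_module_size: int = 5,
    share_null_across_samples: bool = True,
) -> pd.DataFrame:
    """Per-sample enrichment z-scores of each module.

    Modules with fewer than ``min_module_size`` measured genes are skipped
    (absent rows).  Null sets are drawn from measured genes only, without
    replacement within a set, once per distinct module size; by default the
    same draws serve every sample (comparable z columns, runtime
    proportional to the number of distinct sizes).  With
    ``share_null_across_samples=False`` each sample gets independent draws.
    A zero null SD yields NaN with a warning.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    values = standardized.to_numpy(dtype=float)
    n_genes = values.shape[0]
    index = {g: i for i, g in enumerate(standardized.index)}

    member_rows: dict[str, np.ndarray] = {}
    for name in sorted(modules):
        rows = np.array(
            sorted(index[g] for g in modules[name] if g in index), dtype=np.intp
        )
        if len(rows) >= min_module_size:
            member_rows[name] = rows
        else:
            logger.warning(
                "module %s skipped: %d measured gene(s) < min size %d",
                name, len(rows), min_module_size,
            )

    stat = np.mean if statistic == "mean" else np.median
    sizes = sorted({len(rows) for rows in member_rows.values()})
    null_moments: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    rng = np.random.default_rng(seed)
    n_samples = values.shape[1]
    for size in sizes:
        if share_null_across_samples:
            idx = _random_index_sets(rng, n_genes, size, n_random)
            sums = np.empty((n_random, n_samples))
            chunk = max(1, 4_000_000 // max(size * n_samples, 1))
            for start in range(0, n_random, chunk):
                block = idx[start : start + chunk]
                sums[start : start + len(block)] = stat(values[block], axis=1)
            null_moments[size] = (sums.mean(axis=0), sums.std(axis=0, ddof=1))
        else:
            mu = np.empty(n_samples)
            sd = np.empty(n_samples)
            for j in range(n_samples):
                idx = _random_index_sets(rng, n_genes, size, n_random)
                col = stat(values[:, j][idx], axis=1)
                mu[j], sd[j] = col.mean(), col.std(ddof=1)
            null_moments[size] = (mu, sd)

    rows = []
    names = []
    for name, member in member_rows.items():
        observed = stat(values[member], axis=0)
        mu, sd = null_moments[len(member)]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (observed - mu) / np.where(sd > 0, sd, 1.0), np.nan)
        if np.any(sd == 0):
            logger.warning("module %s: zero null SD in some sample(s); z set to NaN", name)
        rows.append(z)
        names.append(name)
    return pd.DataFrame(rows, index=names, columns=standardized.columns)


def compare_groups(
    z_row: Sequence[float],
    mutant: Sequence[int] | Sequence[bool],
    wt: Sequence[int] | Sequence[bool] | None = None,
) -> tuple[float, float]:
    """One-sided Wilcoxon–Mann–Whitney P values (right: mutant > WT; left:
    mutant < WT) for one module's z-scores.

    ``mutant``/``wt`` are index arrays or boolean masks over ``z_row``; when
    ``wt`` is omitted it is the complement of ``mutant``.  The exact
    small-sample distribution is used when the pooled size is <= 20 and there
    are no ties, the tie-corrected normal approximation otherwise.
    """
    z = np.asarray(z_row, dtype=float)
    mutant_mask = np.zeros(len(z), dtype=bool)
    mutant_idx = np.asarray(mutant)
    if mutant_idx.dtype == bool:
        mutant_mask = mutant_idx
    elif mutant_idx.size:
        mutant_mask[mutant_idx.astype(int)] = True
    if wt is None:
        wt_mask = ~mutant_mask
    else:
        wt_idx = np.asarray(wt)
        wt_mask = wt_idx if wt_idx.dtype == bool else np.isin(np.arange(len(z)), wt_idx)
    if (mutant_mask & wt_mask).any():
        raise ValueError("mutant and WT groups overlap")
    x, y = z[mutant_mask], z[wt_mask]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    right = stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    left = stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue
    return float(right), float(left)


def slea_group_comparison(
    z: pd.DataFrame,
    mutant_samples: Sequence[str],
    wt_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mutant-vs-WT rank test per module with per-tail BH adjustment.

    Returns a DataFrame indexed by module with columns ``p_right``,
    ``p_left``, ``q_right``, ``q_left``, ``n_mutant``, ``n_wt``.  Modules
    whose z row is all-NaN in either group are skipped with a warning.
    """
    mutant = [s for s in z.columns if s in set(mutant_samples)]
    if wt_samples is None:
        wt = [s for s in z.columns if s not in set(mutant_samples)]
    else:
        wt = [s for s in z.columns if s in set(wt_samples)]
    if not mutant or not wt:
        raise ValueError("both sample groups must be non-empty")
    records = []
    for module in z.index:
        x = z.loc[module, mutant].to_numpy(dtype=float)
        y = z.loc[module, wt].to_numpy(dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0:
            logger.warning("module %s skipped: empty group after NaN removal", module)
            continue
        mask = np.concatenate([np.ones(len(x), bool), np.zeros(len(y), bool)])
        right, left = compare_groups(np.concatenate([x, y]), mask)
        records.append(
            {
                "module": module,
                "p_right": right,
                "p_left": left,
                "n_mutant": len(x),
                "n_wt": len(y),
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["p_right", "p_left", "q_right", "q_left", "n_mutant", "n_wt"]
        )
    df = pd.DataFrame.from_records(records).set_index("module")
    df["q_right"] = bh_adjust(df["p_right"].to_numpy())
    df["q_left"] = bh_adjust(df["p_left"].to_numpy())
    return df[["p_right", "p_left", "q_right", "q_left", "n_mutant", "n_wt"]]


def run_slea(
    expression: pd.DataFrame,
    modules: Mapping[str, set[str]],
    mutant_samples: Sequence[str],
    statistic: str = "mean",
    n_random: int = 10_000,
    seed: int = 0,
    min_module_size: int = 5,
    already_standardized: bool = False,
) -> SLEAResult:
    """Full SLEA: standardize, z-score all modules, compare mutant vs WT."""
    standardized = (
        expression if already_standardized else normalize_expression(expression)
    )
    z = slea_zscores(
        standardized,
        modules,
        statistic=statistic,
        n_random=n_random,
        seed=seed,
        min_module_size=min_module_size,
    )
    comparison = slea_group_comparison(z, mutant_samples) if len(z) else None
    return SLEAResult(z=z, group_comparison=comparison)
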