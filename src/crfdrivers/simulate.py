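"""Synthetic tumor cohorts, gene universes and expression matrices.

The generator emulates the statistical structure the driver analyses assume:
per-sample mutation counts (Poisson), a consequence-type mix, uniform protein
positions within log-normal gene lengths, right-skewed Beta functional impact
scores for passengers, and injectable driver effects — a functional-impact
shift (FM-bias ground truth), a positional hotspot (CLUST-bias ground truth),
and mutation-status-linked expression shifts of gene modules (SLEA ground
truth).  Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    Consequence,
    GeneUniverse,
    MutationCatalog,
    MutationRecord,
    PAM_CONSEQUENCES,
    TRUNCATING_CONSEQUENCES,
)

__all__ = [
    "DriverSpec",
    "SimulationConfig",
    "generate_gene_universe",
    "generate_null_catalog",
    "inject_driver",
    "generate_catalog",
    "generate_expression",
]

#: Default consequence-type mix of a passenger-dominated exome cohort.
DEFAULT_CONSEQUENCE_MIX: dict[Consequence, float] = {
    Consequence.MISSENSE: 0.50,
    Consequence.SYNONYMOUS: 0.25,
    Consequence.STOP_GAINED: 0.05,
    Consequence.FRAMESHIFT_INDEL: 0.05,
    Consequence.INFRAME_INDEL: 0.04,
    Consequence.SPLICE: 0.06,
    Consequence.OTHER: 0.05,
}

#: Functional classes cycled over the CRF portion of a synthetic universe.
CRF_CLASSES = (
    "HDAC",
    "histone_acetyltransferase",
    "histone_methyltransferase",
    "histone_demethylase",
    "DNA_methyltransferase",
    "chromatin_remodeler",
)


@dataclass(frozen=True)
class DriverSpec:
    """A driver effect to inject into a null catalog.

    ``effect_type`` is one of ``fis_shift`` (functional-impact shift),
    ``hotspot`` (positional clustering) or ``module_link`` (expression shift
    of a module in mutated samples; consumed by the pipeline's expression
    stage, not by the catalog generator).
    """

    gene: str
    effect_type: str
    params: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_type not in ("fis_shift", "hotspot", "module_link"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    Defaults describe a mid-size exome cohort: 200 samples, a 500-gene
    universe, 10 somatic coding mutations per sample on average, passenger
    impact scores from the right-skewed Beta(2, 5), and log-normal protein
    lengths (median ~450 residues).  ``driver_n_add`` is the number of extra
    PAMs an injected driver receives by default — drivers are recurrently
    mutated, which is what makes them detectable in cohorts of this size.
    """

    n_samples: int = 200
    n_genes: int = 500
    mutations_per_sample: float = 10.0
    background_fis: tuple[float, float] = (2.0, 5.0)  # Beta(a, b) on [0, 1]
    consequence_mix: Mapping[Consequence, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    predictors: tuple[str, ...] = ("ma", "pp2")
    seed: int = 0
    driver_specs: tuple[DriverSpec, ...] = ()
    crf_fraction: float = 0.10
    n_complexes: int = 6
    complex_size: int = 5
    length_log_median: float = float(np.log(450.0))
    length_log_sigma: float = 0.6
    gene_weights: tuple[float, ...] | None = None
    dataset_id: str = "SIM"
    site: str = "synthetic"
    driver_n_add: int = 10
    driver_fis_shift: float = 0.6
    driver_hotspot_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.mutations_per_sample < 0:
            raise ValueError("mutations_per_sample must be >= 0")
        total = float(sum(self.consequence_mix.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"consequence_mix sums to {total}, expected 1")
        if self.gene_weights is not None and len(self.gene_weights) != self.n_genes:
            raise ValueError("gene_weights length must equal n_genes")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_gene_universe(config: SimulationConfig) -> GeneUniverse:
    """Deterministic universe: first ``crf_fraction`` of genes are CRFs,
    grouped into complexes of ``complex_size``; classes cycle over
    :data:`CRF_CLASSES`."""
    genes = _gene_names(config.n_genes)
    n_crf = int(round(config.crf_fraction * config.n_genes))
    crfs = genes[:n_crf]
    crf_flag = {g: g in set(crfs) for g in genes}
    functional_class = {
        g: CRF_CLASSES[i % len(CRF_CLASSES)] if g in set(crfs) else "non_CRF"
        for i, g in enumerate(genes)
    }
    complexes: dict[str, set[str]] = {}
    idx = 0
    for c in range(config.n_complexes):
        members = crfs[idx : idx + config.complex_size]
        if not members:
            break
        complexes[f"complex{c + 1}"] = set(members)
        idx += config.complex_size
    return GeneUniverse(
        genes=set(genes),
        crf_flag=crf_flag,
        functional_class=functional_class,
        complexes=complexes,
    )


def _protein_lengths(config: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    lengths = np.exp(
        rng.normal(config.length_log_median, config.length_log_sigma, config.n_genes)
    )
    lengths = np.clip(np.round(lengths), 50, 5000).astype(int)
    return dict(zip(_gene_names(config.n_genes), lengths.tolist()))


def generate_null_catalog(config: SimulationConfig) -> MutationCatalog:
    """Generate a passenger-only cohort (no driver effects).

    Per sample, a Poisson(``mutations_per_sample``) count of mutations; each
    mutation hits a gene uniformly (or by ``gene_weights``), draws a
    consequence from ``consequence_mix``, a uniform residue within the gene's
    protein length, and i.i.d. Beta background FIS per predictor (missense
    only — truncating mutations carry no predictor score and are scored
    downstream; synonymous/other carry none by definition).
    """
    if config.driver_specs:
        raise ValueError("generate_null_catalog requires empty driver_specs")
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    samples = _sample_names(config.n_samples)
    lengths = _protein_lengths(config, rng)

    weights = None
    if config.gene_weights is not None:
        weights = np.asarray(config.gene_weights, dtype=float)
        weights = weights / weights.sum()

    mix_keys = list(config.consequence_mix)
    mix_p = np.array([config.consequence_mix[k] for k in mix_keys], dtype=float)
    mix_p = mix_p / mix_p.sum()
    a, b = config.background_fis

    counts = rng.poisson(config.mutations_per_sample, size=config.n_samples)
    records: list[MutationRecord] = []
    for sample, count in zip(samples, counts):
        if count == 0:
            continue
        gene_idx = rng.choice(config.n_genes, size=count, p=weights)
        cons_idx = rng.choice(len(mix_keys), size=count, p=mix_p)
        for gi, ci in zip(gene_idx, cons_idx):
            gene = genes[gi]
            consequence = mix_keys[ci]
            length = lengths[gene]
            protein_pos: int | None = None
            if consequence not in (Consequence.SPLICE, Consequence.OTHER):
                protein_pos = int(rng.integers(1, length + 1))
            fis: dict[str, float] = {}
            if consequence is Consequence.MISSENSE:
                fis = {
                    pred: float(rng.beta(a, b)) for pred in config.predictors
                }
            records.append(
                MutationRecord(
                    sample_id=sample,
                    gene_id=gene,
                    consequence=consequence,
                    protein_pos=protein_pos,
                    fis=fis,
                )
            )
    return MutationCatalog(
        dataset_id=config.dataset_id,
        site=config.site,
        samples=tuple(samples),
        records=records,
        protein_lengths=lengths,
    )


def _shifted_fis(rng: np.random.Generator, a: float, b: float, shift: float,
                 predictors: Sequence[str]) -> dict[str, float]:
    # Background draw plus a location shift, clipped at 1: stochastically
    # larger than background by `shift`; shift 0 reproduces the background law.
    return {
        pred: float(min(1.0, rng.beta(a, b) + shift)) for pred in predictors
    }


def inject_driver(
    catalog: MutationCatalog,
    gene: str,
    effect_type: str,
    params: Mapping[str, float | str] | None = None,
    seed: int = 0,
) -> MutationCatalog:
    """Return a new catalog with a driver effect injected into *gene*.

    ``fis_shift``: redraw the gene's missense FIS from the background law
    shifted up by ``params['shift']`` (clipped at 1).  ``hotspot``: move a
    fraction ``params['fraction']`` of the gene's positioned PAMs onto one
    randomly chosen residue.  Either effect optionally adds
    ``params['n_add']`` extra missense PAMs in randomly chosen samples
    (recurrence); otherwise the gene's mutation count is unchanged.
    """
    params = dict(params or {})
    if effect_type not in ("fis_shift", "hotspot"):
        raise ValueError(f"inject_driver cannot apply effect_type {effect_type!r}")
    known = catalog.genes() | set(catalog.protein_lengths)
    if gene not in known:
        raise ValueError(f"gene {gene!r} absent from the catalog universe")

    rng = np.random.default_rng(seed)
    predictors = catalog.predictors() or ("ma",)
    a = float(params.get("beta_a", 2.0))
    b = float(params.get("beta_b", 5.0))
    n_add = int(params.get("n_add", 0))
    length = catalog.protein_length(gene) or 500
    records = list(catalog.records)

    if effect_type == "fis_shift":
        shift = float(params.get("shift", 0.0))
        if shift < 0:
            raise ValueError("shift must be >= 0")
        new_records = []
        for rec in records:
            if rec.gene_id == gene and rec.consequence is Consequence.MISSENSE:
                rec = replace(rec, fis=_shifted_fis(rng, a, b, shift, predictors))
            new_records.append(rec)
        records = new_records
        if n_add:
            add_samples = rng.choice(len(catalog.samples), size=n_add, replace=True)
            for si in add_samples:
                records.append(
                    MutationRecord(
                        sample_id=catalog.samples[int(si)],
                        gene_id=gene,
                        consequence=Consequence.MISSENSE,
                        protein_pos=int(rng.integers(1, length + 1)),
                        fis=_shifted_fis(rng, a, b, shift, predictors),
                    )
                )
    else:  # hotspot
        fraction = float(params.get("fraction", 1.0))
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"hotspot fraction {fraction} outside [0, 1]")
        hotspot = int(rng.integers(1, length + 1))
        positioned = [
            i
            for i, rec in enumerate(records)
            if rec.gene_id == gene and rec.is_pam and rec.protein_pos is not None
        ]
        n_move = int(round(fraction * len(positioned)))
        move = set(
            rng.choice(positioned, size=n_move, replace=False).tolist()
        ) if n_move else set()
        records = [
            replace(rec, protein_pos=hotspot) if i in move else rec
            for i, rec in enumerate(records)
        ]
        if n_add:
            add_samples = rng.choice(len(catalog.samples), size=n_add, replace=True)
            for si in add_samples:
                records.append(
                    MutationRecord(
                        sample_id=catalog.samples[int(si)],
                        gene_id=gene,
                        consequence=Consequence.MISSENSE,
                        protein_pos=hotspot,
                        fis={p: float(rng.beta(a, b)) for p in predictors},
                    )
                )

    lengths = dict(catalog.protein_lengths)
    if gene not in lengths:
        lengths[gene] = length
    return replace(catalog, records=records, protein_lengths=lengths)


def generate_catalog(config: SimulationConfig) -> MutationCatalog:
    """Null catalog plus all catalog-level driver effects of ``driver_specs``.

    Injection seeds are derived from the config seed and the spec index, so a
    catalog is a pure function of its configuration.  ``module_link`` specs
    are ignored here (they shape expression, not mutations).
    """
    null_config = replace(config, driver_specs=())
    catalog = generate_null_catalog(null_config)
    for i, spec in enumerate(config.driver_specs):
        if spec.effect_type == "module_link":
            continue
        params = dict(spec.params)
        if spec.effect_type == "fis_shift":
            params.setdefault("shift", config.driver_fis_shift)
        else:
            params.setdefault("fraction", config.driver_hotspot_fraction)
        params.setdefault("n_add", config.driver_n_add)
        params.setdefault("beta_a", config.background_fis[0])
        params.setdefault("beta_b", config.background_fis[1])
        catalog = inject_driver(
            catalog,
            spec.gene,
            spec.effect_type,
            params,
            seed=int(np.random.SeedSequence([config.seed, 7919 + i]).generate_state(1)[0] % (2**31)),
        )
    return catalog


def generate_expression(
    genes: int | Sequence[str],
    samples: Sequence[str],
    modules: Mapping[str, set[str]] | None = None,
    mutant_samples: Sequence[str] = (),
    effect_size: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    directions: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Genes x samples expression matrix with module shifts in mutant samples.

    Baseline is i.i.d. Normal(0, ``noise_sd``).  For each module, member genes
    in ``mutant_samples`` receive an additive shift of
    ``directions[module] * effect_size`` (direction defaults to +1).
    """
    if isinstance(genes, int):
        gene_names = _gene_names(genes)
    else:
        gene_names = list(genes)
    modules = modules or {}
    mutant = [s for s in samples if s in set(mutant_samples)]
    missing = set(mutant_samples) - set(samples)
    if missing:
        raise ValueError(f"mutant samples outside the sample list: {sorted(missing)}")
    gene_set = set(gene_names)
    for name, members in modules.items():
        if not members:
            raise ValueError(f"module {name!r} is empty")
        if not set(members) <= gene_set:
            raise ValueError(f"module {name!r} has genes outside the generated set")

    rng = np.random.default_rng(seed)
    matrix = rng.normal(0.0, noise_sd, size=(len(gene_names), len(samples)))
    df = pd.DataFrame(matrix, index=gene_names, columns=list(samples))
    if effect_size and mutant:
        for name, members in modules.items():
            direction = float((directions or {}).get(name, 1.0))
            rows = [g for g in gene_names if g in members]
            df.loc[rows, mutant] += direction * effect_size
    return df
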