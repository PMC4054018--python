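"""End-to-end orchestration: simulate -> drivers -> combine -> profile -> slea.

Each stage reads and writes the plain-text formats of :mod:`crfdrivers.catalog`
and records what it did in a JSON run manifest (inputs, parameters, seeds and
SHA-256 checksums of text outputs), so a run can be reproduced bit-identically
from its manifest.  Stages never mutate their inputs; all randomness flows
through named seeds derived from the run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import catalog as cio
from . import clust, cohort, combine, fm, simulate, slea

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DependencyError", "run", "STAGES"]

STAGES = ("simulate", "drivers", "combine", "profile", "slea", "all")


class ConfigError(ValueError):
    """The run configuration violates the schema."""


class DependencyError(RuntimeError):
    """A staged run is missing an upstream output."""


@dataclass
class RunConfig:
    """Flat per-stage configuration of a pipeline run."""

    outdir: str = "results"
    seed: int = 0
    # simulate
    n_samples: int = 200
    n_genes: int = 500
    mutations_per_sample: float = 10.0
    n_fis_drivers: int = 10
    n_hotspot_drivers: int = 10
    driver_fis_shift: float = 0.4
    driver_n_add: int = 10
    n_modules: int = 20
    module_size: int = 20
    expression_effect_size: float = 2.0
    expression_noise_sd: float = 1.0
    slea_gene: str = ""  # default: first fis-shift driver CRF
    # drivers
    min_pams: int = 3
    n_samplings: int = 10_000
    gap: int = 5
    combination_method: str = "fisher"
    # combine / flags
    q_threshold: float = 0.05
    # slea
    n_random: int = 10_000
    slea_statistic: str = "mean"
    min_module_size: int = 5
    # inputs for non-simulated runs
    mutations_path: str = ""
    roster_path: str = ""
    universe_path: str = ""
    expressed_path: str = ""
    lengths_path: str = ""
    modules_path: str = ""
    expression_path: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        flat: dict[str, Any] = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # per-stage section
                flat.update(value)
            else:
                flat[key] = value
        flat.update({k: v for k, v in overrides.items() if v is not None})
        valid = {f for f in cls.__dataclass_fields__}
        for key in flat:
            if key not in valid:
                raise ConfigError(f"unknown configuration key {key!r}")
        config = cls(**flat)
        config.validate()
        return config

    def validate(self) -> None:
        for key in ("n_samples", "n_genes", "n_samplings", "n_random", "min_pams"):
            if int(getattr(self, key)) <= 0:
                raise ConfigError(f"{key} must be positive, got {getattr(self, key)}")
        if not 0 < self.q_threshold < 1:
            raise ConfigError(f"q_threshold must be in (0, 1), got {self.q_threshold}")
        if self.combination_method not in ("fisher", "stouffer"):
            raise ConfigError(f"unknown combination_method {self.combination_method!r}")
        if self.slea_statistic not in ("mean", "median"):
            raise ConfigError(f"unknown slea_statistic {self.slea_statistic!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(config: RunConfig, stage: str) -> int:
    mix = {"simulate": 11, "drivers": 13, "slea": 17}[stage]
    return int(np.random.SeedSequence([config.seed, mix]).generate_state(1)[0] % (2**31))


def _require(outdir: Path, name: str, override: str, stage: str) -> Path:
    path = Path(override) if override else outdir / name
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} needs input {path} (run 'simulate' first or set the path)"
        )
    return path


def _write_driver_table(results: list[fm.DriverResult], path: Path) -> None:
    rows = []
    for r in results:
        row: dict[str, Any] = {
            "gene": r.gene_or_group,
            "dataset": r.dataset_id,
            "n_pam": r.n_pam,
            "n_samples_with_pam": r.n_samples_with_pam,
        }
        for pred, p in sorted(r.per_predictor_p.items()):
            row[f"p_{pred}"] = p
        row["p_fm"] = r.p_fm
        row["q_fm"] = r.q_fm
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_clust_table(calls: list[clust.ClusterCall], path: Path) -> None:
    rows = [
        {
            "gene": c.gene,
            "dataset": c.dataset_id,
            "n_pam_positioned": c.n_pam_positioned,
            "clusters": ";".join(f"{cl.start}-{cl.end}:{cl.count}" for cl in c.clusters),
            "gene_score": c.gene_score,
            "p_clust": c.p_clust,
            "q_clust": c.q_clust,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def stage_simulate(config: RunConfig, outdir: Path) -> dict[str, Any]:
    """Generate and write a full synthetic study (cohort + expression)."""
    seed = _stage_seed(config, "simulate")
    sim = simulate.SimulationConfig(
        n_samples=config.n_samples,
        n_genes=config.n_genes,
        mutations_per_sample=config.mutations_per_sample,
        seed=seed,
        driver_n_add=config.driver_n_add,
        driver_fis_shift=config.driver_fis_shift,
    )
    universe = simulate.generate_gene_universe(sim)
    genes = sorted(universe.genes)
    crfs = sorted(universe.crf_genes)
    non_crfs = [g for g in genes if g not in set(crfs)]
    # half of each driver kind among CRFs, half among the rest
    k_fis_crf = config.n_fis_drivers // 2
    fis_drivers = crfs[:k_fis_crf] + non_crfs[: config.n_fis_drivers - k_fis_crf]
    k_hot_crf = config.n_hotspot_drivers // 2
    hot_drivers = (
        crfs[k_fis_crf : k_fis_crf + k_hot_crf]
        + non_crfs[
            config.n_fis_drivers - k_fis_crf : config.n_fis_drivers - k_fis_crf
            + config.n_hotspot_drivers - k_hot_crf
        ]
    )
    specs = tuple(
        [simulate.DriverSpec(g, "fis_shift") for g in fis_drivers]
        + [simulate.DriverSpec(g, "hotspot") for g in hot_drivers]
    )
    sim = replace(sim, driver_specs=specs)
    catalog = simulate.generate_catalog(sim)

    slea_gene = config.slea_gene or (fis_drivers[0] if fis_drivers else genes[0])
    mutant = sorted(
        {r.sample_id for r in catalog.pam_records() if r.gene_id == slea_gene}
    )
    rng = np.random.default_rng(seed + 1)
    modules: dict[str, set[str]] = {}
    for i in range(config.n_modules):
        members = rng.choice(genes, size=min(config.module_size, len(genes)), replace=False)
        modules[f"M{i + 1:03d}"] = set(members.tolist())
    linked = "M_linked"
    modules[linked] = set(
        rng.choice(genes, size=min(config.module_size, len(genes)), replace=False).tolist()
    )
    expression = simulate.generate_expression(
        genes,
        list(catalog.samples),
        modules={linked: modules[linked]},
        mutant_samples=mutant,
        effect_size=config.expression_effect_size * config.expression_noise_sd,
        noise_sd=config.expression_noise_sd,
        seed=seed + 2,
    )

    cio.write_mutations(catalog, outdir / "mutations.tsv")
    cio.write_gene_list(catalog.samples, outdir / "roster.txt")
    cio.write_universe(universe, outdir / "universe.tsv")
    cio.write_protein_lengths(catalog.protein_lengths, outdir / "protein_lengths.tsv")
    cio.write_gene_list(genes, outdir / "expressed.txt")
    cio.write_gmt(modules, outdir / "modules.gmt")
    cio.write_expression(expression, outdir / "expression.tsv")
    truth = {
        "fis_drivers": fis_drivers,
        "hotspot_drivers": hot_drivers,
        "slea_gene": slea_gene,
        "linked_module": linked,
        "mutant_samples": mutant,
        "seed": seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"seed": seed, "n_records": len(catalog.records), "slea_gene": slea_gene}


def _load_catalog(config: RunConfig, outdir: Path, stage: str) -> cio.MutationCatalog:
    mut_path = _require(outdir, "mutations.tsv", config.mutations_path, stage)
    roster_path = Path(config.roster_path) if config.roster_path else outdir / "roster.txt"
    lengths_path = Path(config.lengths_path) if config.lengths_path else outdir / "protein_lengths.tsv"
    roster = cio.read_gene_list(roster_path) if roster_path.exists() else None
    lengths = cio.read_protein_lengths(lengths_path) if lengths_path.exists() else None
    return cio.read_mutations(
        mut_path, dataset_id="SIM", site="synthetic", roster=roster, protein_lengths=lengths
    )


def stage_drivers(config: RunConfig, outdir: Path) -> dict[str, Any]:
    """FM- and CLUST-bias tests on one dataset; writes two TSVs."""
    seed = _stage_seed(config, "drivers")
    catalog = _load_catalog(config, outdir, "drivers")
    expressed_path = Path(config.expressed_path) if config.expressed_path else outdir / "expressed.txt"
    if expressed_path.exists():
        catalog = cio.filter_expressed(catalog, cio.read_gene_list(expressed_path))
    fm_results = fm.dataset_fm_bias(
        catalog,
        min_pams=config.min_pams,
        n_samplings=config.n_samplings,
        seed=seed,
        method=config.combination_method,
    )
    _write_driver_table(fm_results, outdir / "drivers_fm.tsv")
    clust_calls = clust.dataset_clust_bias(
        catalog, min_pams=config.min_pams, gap=config.gap
    )
    _write_clust_table(clust_calls, outdir / "drivers_clust.tsv")
    return {
        "seed": seed,
        "n_tested_fm": sum(r.tested for r in fm_results),
        "n_tested_clust": sum(c.tested for c in clust_calls),
    }


def stage_combine(config: RunConfig, outdir: Path) -> dict[str, Any]:
    """Combine per-dataset P values into site-level driver calls."""
    fm_path = _require(outdir, "drivers_fm.tsv", "", "combine")
    clust_path = _require(outdir, "drivers_clust.tsv", "", "combine")
    fm_df = pd.read_csv(fm_path, sep="\t")
    clust_df = pd.read_csv(clust_path, sep="\t")
    dataset_results: dict[str, dict[str, tuple[float | None, float | None]]] = {}
    for _, row in fm_df.iterrows():
        d = dataset_results.setdefault(str(row["dataset"]), {})
        p_fm = None if pd.isna(row["p_fm"]) else float(row["p_fm"])
        d[str(row["gene"])] = (p_fm, None)
    for _, row in clust_df.iterrows():
        d = dataset_results.setdefault(str(row["dataset"]), {})
        p_clust = None if pd.isna(row["p_clust"]) else float(row["p_clust"])
        prev = d.get(str(row["gene"]), (None, None))
        d[str(row["gene"])] = (prev[0], p_clust)
    site_results = combine.combine_site(
        dataset_results,
        site="synthetic",
        method=config.combination_method,
        q_threshold=config.q_threshold,
    )
    rows = [
        {
            "gene": r.gene,
            "site": r.site,
            "p_fm": r.p_fm,
            "q_fm": r.q_fm,
            "p_clust": r.p_clust,
            "q_clust": r.q_clust,
            "datasets": ",".join(r.datasets),
            "driver_flag": int(r.driver_flag),
        }
        for r in site_results
    ]
    pd.DataFrame(rows).to_csv(outdir / "site_results.tsv", sep="\t", index=False)
    return {"n_drivers": sum(r.driver_flag for r in site_results)}


def stage_profile(config: RunConfig, outdir: Path) -> dict[str, Any]:
    """Per-sample CF-ratio profiles, site summary, exclusivity analysis."""
    site_path = _require(outdir, "site_results.tsv", "", "profile")
    universe_path = _require(outdir, "universe.tsv", config.universe_path, "profile")
    catalog = _load_catalog(config, outdir, "profile")
    universe = cio.read_universe(universe_path)
    site_df = pd.read_csv(site_path, sep="\t")
    driver_genes = set(site_df.loc[site_df["driver_flag"] == 1, "gene"].astype(str))
    crf_driver_genes = driver_genes & universe.crf_genes

    profiles = cohort.sample_profiles(catalog, driver_genes, crf_driver_genes)
    pd.DataFrame(
        [
            {
                "sample": p.sample_id,
                "site": p.site,
                "n_driver_pam": p.n_driver_pam,
                "n_crf_driver_pam": p.n_crf_driver_pam,
                "cf_ratio": p.cf_ratio,
            }
            for p in profiles
        ]
    ).to_csv(outdir / "sample_profiles.tsv", sep="\t", index=False)

    ratios = [p.cf_ratio for p in profiles if p.cf_ratio is not None]
    summary = {
        "site": catalog.site,
        "n_samples": len(profiles),
        "n_driver_genes": len(driver_genes),
        "n_crf_driver_genes": len(crf_driver_genes),
        "fraction_with_crf_driver": cohort.site_mutated_fraction(profiles),
        "median_cf_ratio": float(np.median(ratios)) if ratios else float("nan"),
    }
    pd.DataFrame([summary]).to_csv(outdir / "site_summary.tsv", sep="\t", index=False)

    # mutual exclusivity within each complex; memo-sorted alteration matrix
    pair_rows = []
    for name in sorted(universe.complexes):
        members = sorted(universe.complexes[name] & catalog.genes())
        if len(members) < 2:
            continue
        matrix = cohort.alteration_matrix(catalog, members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                p = cohort.pairwise_exclusivity_test(
                    matrix.loc[a].to_numpy(), matrix.loc[b].to_numpy()
                )
                pair_rows.append(
                    {
                        "complex": name,
                        "gene_a": a,
                        "gene_b": b,
                        "n_a": int(matrix.loc[a].sum()),
                        "n_b": int(matrix.loc[b].sum()),
                        "n_overlap": int((matrix.loc[a] & matrix.loc[b]).sum()),
                        "p_exclusive": p,
                    }
                )
    pd.DataFrame(
        pair_rows,
        columns=["complex", "gene_a", "gene_b", "n_a", "n_b", "n_overlap", "p_exclusive"],
    ).to_csv(outdir / "exclusivity_pairs.tsv", sep="\t", index=False)

    if driver_genes:
        matrix = cohort.alteration_matrix(catalog, driver_genes)
        row_order, col_order = cohort.exclusivity_sort(matrix)
        matrix.loc[row_order, col_order].to_csv(
            outdir / "alteration_matrix.tsv", sep="\t", index_label="gene"
        )
    _profile_plots(profiles, outdir)
    return summary


def _profile_plots(profiles, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fraction = cohort.site_mutated_fraction(profiles)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].bar(["mutated CRF driver", "none"], [fraction, 1 - fraction], color=["firebrick", "seagreen"])
    axes[0].set_ylabel("fraction of samples")
    axes[0].set_title("Samples with a PAM in a driver CRF")
    ratios = [p.cf_ratio for p in profiles if p.cf_ratio is not None]
    if ratios:
        axes[1].boxplot([ratios], tick_labels=["cohort"])
    axes[1].set_ylabel("CF ratio")
    axes[1].set_title("CRFs-to-drivers ratio per sample")
    fig.tight_layout()
    fig.savefig(outdir / "cohort_overview.png", dpi=120)
    plt.close(fig)


def stage_slea(config: RunConfig, outdir: Path) -> dict[str, Any]:
    """Sample-level enrichment analysis against the simulated expression."""
    seed = _stage_seed(config, "slea")
    expr_path = _require(outdir, "expression.tsv", config.expression_path, "slea")
    modules_path = _require(outdir, "modules.gmt", config.modules_path, "slea")
    catalog = _load_catalog(config, outdir, "slea")
    expression = cio.read_expression(expr_path)
    modules = cio.read_gmt(modules_path)
    slea_gene = config.slea_gene
    if not slea_gene:
        truth_path = outdir / "truth.json"
        if truth_path.exists():
            slea_gene = json.loads(truth_path.read_text())["slea_gene"]
        else:
            raise DependencyError("slea stage needs slea_gene (or a truth.json)")
    mutant = sorted(
        {r.sample_id for r in catalog.pam_records() if r.gene_id == slea_gene}
    )
    result = slea.run_slea(
        expression,
        modules,
        mutant,
        statistic=config.slea_statistic,
        n_random=config.n_random,
        seed=seed,
        min_module_size=config.min_module_size,
    )
    result.z.to_csv(outdir / "slea_z.tsv", sep="\t", index_label="module")
    if result.group_comparison is not None:
        result.group_comparison.to_csv(
            outdir / "slea_groups.tsv", sep="\t", index_label="module"
        )
    _slea_heatmap(result.z, mutant, outdir)
    n_sig = (
        int((result.group_comparison["q_right"] < config.q_threshold).sum())
        if result.group_comparison is not None
        else 0
    )
    return {"seed": seed, "gene": slea_gene, "n_mutant": len(mutant), "n_sig_right": n_sig}


def _slea_heatmap(z: pd.DataFrame, mutant: list[str], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = mutant + [s for s in z.columns if s not in set(mutant)]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(z))))
    im = ax.imshow(z[order], aspect="auto", cmap="RdBu_r", vmin=-4, vmax=4)
    ax.set_yticks(range(len(z)), z.index, fontsize=6)
    ax.axvline(len(mutant) - 0.5, color="black", lw=1)
    ax.set_xlabel(f"samples (mutant left of bar, n={len(mutant)})")
    fig.colorbar(im, ax=ax, label="enrichment z")
    fig.tight_layout()
    fig.savefig(outdir / "slea_heatmap.png", dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "drivers": stage_drivers,
    "combine": stage_combine,
    "profile": stage_profile,
    "slea": stage_slea,
}

#: Text outputs covered by manifest checksums (PNG exports are excluded:
#: image encoding is not part of the determinism contract).
_TEXT_OUTPUTS = (
    "mutations.tsv",
    "roster.txt",
    "universe.tsv",
    "protein_lengths.tsv",
    "expressed.txt",
    "modules.gmt",
    "expression.tsv",
    "truth.json",
    "drivers_fm.tsv",
    "drivers_clust.tsv",
    "site_results.tsv",
    "sample_profiles.tsv",
    "site_summary.tsv",
    "exclusivity_pairs.tsv",
    "alteration_matrix.tsv",
    "slea_z.tsv",
    "slea_groups.tsv",
)


def run(subcommand: str, config: RunConfig) -> dict[str, Any]:
    """Execute one stage (or ``all``) and write/refresh the run manifest."""
    if subcommand not in STAGES:
        raise ConfigError(f"unknown subcommand {subcommand!r}")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES[:-1]) if subcommand == "all" else [subcommand]
    stage_info: dict[str, Any] = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        stage_info[stage] = _STAGE_FUNCS[stage](config, outdir)
    manifest = {
        "config": asdict(config),
        "stages": stage_info,
        "outputs": {
            name: _sha256(outdir / name)
            for name in _TEXT_OUTPUTS
            if (outdir / name).exists()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
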