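"""Domain types and I/O for somatic mutation catalogs and gene annotations.

The central objects are :class:`MutationRecord` (one somatic mutation with its
consequence type, protein position and functional impact scores),
:class:`MutationCatalog` (one tumor cohort) and :class:`GeneUniverse` (the gene
annotation: chromatin-regulatory-factor flags, functional classes and complex
membership).  Mutations are read from MAF-like tab-separated tables whose
column names and consequence vocabulary are configurable through
:class:`MafDialect`.

All downstream statistics operate at the protein level: positions are 1-based
residue indices and functional impact scores (FIS) live on the canonical
[0, 1] scale (higher = more damaging).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "PAM_CONSEQUENCES",
    "classify_pam",
    "MutationRecord",
    "MutationCatalog",
    "GeneUniverse",
    "MafDialect",
    "FormatError",
    "read_mutations",
    "write_mutations",
    "filter_expressed",
    "read_gmt",
    "write_gmt",
    "read_universe",
    "write_universe",
    "read_expression",
    "write_expression",
    "read_gene_list",
    "write_gene_list",
    "read_protein_lengths",
    "write_protein_lengths",
]


class FormatError(ValueError):
    """An input file does not conform to its declared dialect/format."""


class Consequence(str, Enum):
    """Canonical broad consequence types of a somatic coding mutation."""

    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    SPLICE = "splice"
    OTHER = "other"


#: Protein-affecting mutations (PAMs): non-synonymous, stop-gain and
#: frameshift indels.  Everything else (including in-frame indels and splice
#: variants, which lack a residue-level interpretation here) is non-PAM.
PAM_CONSEQUENCES = frozenset(
    {Consequence.MISSENSE, Consequence.STOP_GAINED, Consequence.FRAMESHIFT_INDEL}
)

#: Truncating consequences carry no predictor score of their own; the FM-bias
#: analysis assigns them maximal impact (see fm.py).
TRUNCATING_CONSEQUENCES = frozenset(
    {Consequence.STOP_GAINED, Consequence.FRAMESHIFT_INDEL}
)


def classify_pam(consequence: Consequence) -> bool:
    """Return True iff *consequence* is protein-affecting (PAM)."""
    if not isinstance(consequence, Consequence):
        raise TypeError(f"expected Consequence, got {type(consequence).__name__}")
    return consequence in PAM_CONSEQUENCES


#: Default alias table covering common MAF spellings.  Lookup is
#: case-insensitive; unknown labels map to OTHER with a logged warning.
DEFAULT_CONSEQUENCE_ALIASES: dict[str, Consequence] = {
    "missense": Consequence.MISSENSE,
    "missense_mutation": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "nonsynonymous": Consequence.MISSENSE,
    "nonsynonymous_snv": Consequence.MISSENSE,
    "stop_gained": Consequence.STOP_GAINED,
    "nonsense_mutation": Consequence.STOP_GAINED,
    "stopgain": Consequence.STOP_GAINED,
    "nonstop_mutation": Consequence.OTHER,
    "frameshift_indel": Consequence.FRAMESHIFT_INDEL,
    "frame_shift_del": Consequence.FRAMESHIFT_INDEL,
    "frame_shift_ins": Consequence.FRAMESHIFT_INDEL,
    "frameshift_variant": Consequence.FRAMESHIFT_INDEL,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "in_frame_del": Consequence.INFRAME_INDEL,
    "in_frame_ins": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "silent": Consequence.SYNONYMOUS,
    "splice": Consequence.SPLICE,
    "splice_site": Consequence.SPLICE,
    "splice_region_variant": Consequence.SPLICE,
    "other": Consequence.OTHER,
}


def normalize_consequence(
    label: str, aliases: Mapping[str, Consequence] | None = None
) -> Consequence:
    """Map a raw consequence label to the canonical enumeration.

    Unrecognized labels become :attr:`Consequence.OTHER` with a warning —
    never silently PAM.
    """
    table = DEFAULT_CONSEQUENCE_ALIASES if aliases is None else aliases
    key = label.strip().lower()
    try:
        return table[key]
    except KeyError:
        logger.warning("unrecognized consequence label %r mapped to 'other'", label)
        return Consequence.OTHER


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation.

    Parameters
    ----------
    sample_id, gene_id
        Opaque sample identifier and gene symbol.
    consequence
        Canonical broad consequence type.
    protein_pos
        1-based residue index of the affected residue, or ``None`` when the
        mutation has no residue-level position (splice, some indels).
    fis
        Mapping predictor name -> functional impact score in [0, 1].  May be
        empty (e.g. truncating mutations, which are scored downstream).
    """

    sample_id: str
    gene_id: str
    consequence: Consequence
    protein_pos: int | None = None
    fis: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        for name, score in self.fis.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"FIS {name}={score} outside [0, 1]")

    @property
    def is_pam(self) -> bool:
        return self.consequence in PAM_CONSEQUENCES


@dataclass
class MutationCatalog:
    """A cohort of tumor samples with their somatic mutations.

    ``samples`` is the full sample roster; samples with zero mutations are
    legal members (true denominators for per-site mutated fractions need
    them).  ``protein_lengths`` maps gene symbol -> residue count where known.
    """

    dataset_id: str
    site: str
    samples: tuple[str, ...]
    records: list[MutationRecord]
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roster = set(self.samples)
        for rec in self.records:
            if rec.sample_id not in roster:
                raise ValueError(
                    f"record sample {rec.sample_id!r} not in the sample roster"
                )
            length = self.protein_lengths.get(rec.gene_id)
            if (
                length is not None
                and rec.protein_pos is not None
                and rec.protein_pos > length
            ):
                raise ValueError(
                    f"{rec.gene_id}: protein_pos {rec.protein_pos} exceeds "
                    f"protein length {length}"
                )

    def genes(self) -> set[str]:
        return {rec.gene_id for rec in self.records}

    def pam_records(self) -> list[MutationRecord]:
        return [rec for rec in self.records if rec.is_pam]

    def records_for_gene(self, gene: str) -> list[MutationRecord]:
        return [rec for rec in self.records if rec.gene_id == gene]

    def predictors(self) -> tuple[str, ...]:
        names: set[str] = set()
        for rec in self.records:
            names.update(rec.fis)
        return tuple(sorted(names))

    def protein_length(self, gene: str) -> int | None:
        """Known residue count, falling back to 1.1x the max observed position."""
        length = self.protein_lengths.get(gene)
        if length is not None:
            return length
        positions = [
            r.protein_pos for r in self.records_for_gene(gene) if r.protein_pos
        ]
        if not positions:
            return None
        return int(max(positions) * 1.1) + 1


@dataclass
class GeneUniverse:
    """Gene annotation: CRF flags, functional classes and complex membership."""

    genes: set[str]
    crf_flag: dict[str, bool] = field(default_factory=dict)
    functional_class: dict[str, str] = field(default_factory=dict)
    complexes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            extra = members - self.genes
            if extra:
                raise ValueError(f"complex {name!r} has members outside the universe: {sorted(extra)}")
        extra = {g for g, flag in self.crf_flag.items() if flag} - self.genes
        if extra:
            raise ValueError(f"CRF genes outside the universe: {sorted(extra)}")

    @property
    def crf_genes(self) -> set[str]:
        return {g for g, flag in self.crf_flag.items() if flag}


@dataclass
class MafDialect:
    """Column and vocabulary mapping for MAF-like mutation tables.

    ``score_columns`` maps predictor name -> input column; ``score_ranges``
    optionally declares a per-predictor input range (lo, hi) that is linearly
    rescaled to the canonical [0, 1] at read time.
    """

    sample_column: str = "sample"
    gene_column: str = "gene"
    consequence_column: str = "consequence"
    position_column: str = "protein_pos"
    score_columns: dict[str, str] = field(default_factory=dict)
    score_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    consequence_aliases: dict[str, Consequence] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_ALIASES)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MafDialect":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("sample_column", "gene_column", "consequence_column", "position_column"):
            if key in raw:
                kwargs[key] = str(raw.pop(key))
        if "score_columns" in raw:
            kwargs["score_columns"] = {str(k): str(v) for k, v in raw.pop("score_columns").items()}
        if "score_ranges" in raw:
            kwargs["score_ranges"] = {
                str(k): (float(v[0]), float(v[1])) for k, v in raw.pop("score_ranges").items()
            }
        if "consequence_aliases" in raw:
            aliases = dict(DEFAULT_CONSEQUENCE_ALIASES)
            for k, v in raw.pop("consequence_aliases").items():
                aliases[str(k).lower()] = Consequence(str(v))
            kwargs["consequence_aliases"] = aliases
        if raw:
            raise FormatError(f"unknown dialect keys: {sorted(raw)}")
        return cls(**kwargs)


def _rescale_score(value: float, predictor: str, dialect: MafDialect) -> float:
    lo, hi = dialect.score_ranges.get(predictor, (0.0, 1.0))
    if hi <= lo:
        raise FormatError(f"degenerate declared range for {predictor!r}: ({lo}, {hi})")
    if not lo <= value <= hi:
        raise FormatError(
            f"score {value} for predictor {predictor!r} outside declared range [{lo}, {hi}]"
        )
    return (value - lo) / (hi - lo)


def read_mutations(
    path: str | Path,
    dialect: MafDialect | None = None,
    *,
    dataset_id: str | None = None,
    site: str = "",
    roster: Iterable[str] | None = None,
    protein_lengths: Mapping[str, int] | None = None,
) -> MutationCatalog:
    """Read a MAF-like TSV into a :class:`MutationCatalog`.

    The sample roster is the union of observed sample ids and the optional
    supplied *roster* (zero-mutation samples enter through the latter).
    """
    path = Path(path)
    dialect = dialect or MafDialect()
    records: list[MutationRecord] = []
    observed_samples: list[str] = []
    seen: set[str] = set()

    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        required = [dialect.sample_column, dialect.gene_column, dialect.consequence_column]
        for column in required:
            if column not in header:
                raise FormatError(f"missing required column {column!r} in {path.name}")
        have_pos = dialect.position_column in header
        if dialect.score_columns:
            score_cols = {
                pred: col for pred, col in dialect.score_columns.items() if col in header
            }
        else:
            # undeclared dialect: every extra column is a predictor score
            known = {
                dialect.sample_column,
                dialect.gene_column,
                dialect.consequence_column,
                dialect.position_column,
            }
            score_cols = {col: col for col in header if col not in known}
        for row in reader:
            consequence = normalize_consequence(
                row[dialect.consequence_column], dialect.consequence_aliases
            )
            pos_raw = row.get(dialect.position_column, "") if have_pos else ""
            protein_pos = None
            if pos_raw not in ("", None, "NA", ".", "-"):
                protein_pos = int(float(pos_raw))
            fis: dict[str, float] = {}
            for pred, col in score_cols.items():
                raw = row.get(col, "")
                if raw in ("", None, "NA", ".", "-"):
                    continue
                fis[pred] = _rescale_score(float(raw), pred, dialect)
            sample = row[dialect.sample_column]
            if sample not in seen:
                seen.add(sample)
                observed_samples.append(sample)
            records.append(
                MutationRecord(
                    sample_id=sample,
                    gene_id=row[dialect.gene_column],
                    consequence=consequence,
                    protein_pos=protein_pos,
                    fis=fis,
                )
            )

    all_samples = list(observed_samples)
    if roster is not None:
        for sample in roster:
            if sample not in seen:
                seen.add(sample)
                all_samples.append(sample)
    return MutationCatalog(
        dataset_id=dataset_id or path.stem,
        site=site,
        samples=tuple(all_samples),
        records=records,
        protein_lengths=dict(protein_lengths or {}),
    )


def write_mutations(
    catalog: MutationCatalog, path: str | Path, dialect: MafDialect | None = None
) -> None:
    """Write a catalog as MAF-like TSV (inverse of :func:`read_mutations`)."""
    dialect = dialect or MafDialect()
    predictors = catalog.predictors()
    score_cols = {p: dialect.score_columns.get(p, p) for p in predictors}
    header = [
        dialect.sample_column,
        dialect.gene_column,
        dialect.consequence_column,
        dialect.position_column,
        *score_cols.values(),
    ]
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rec in catalog.records:
            row = [
                rec.sample_id,
                rec.gene_id,
                rec.consequence.value,
                "" if rec.protein_pos is None else str(rec.protein_pos),
            ]
            for pred in predictors:
                row.append("" if pred not in rec.fis else repr(float(rec.fis[pred])))
            writer.writerow(row)


def filter_expressed(catalog: MutationCatalog, expressed: Iterable[str]) -> MutationCatalog:
    """Restrict the catalog to mutations in expressed genes.

    The sample roster is unchanged; the input catalog is not modified.
    """
    keep = set(expressed)
    if not keep:
        raise ValueError("expressed gene set is empty")
    return replace(
        catalog,
        records=[rec for rec in catalog.records if rec.gene_id in keep],
        protein_lengths=dict(catalog.protein_lengths),
    )


# ---------------------------------------------------------------------------
# Gene sets, universes and expression matrices


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one gene set per line (name, description, members...)."""
    modules: dict[str, set[str]] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            modules[name] = {g for g in fields[2:] if g}
    return modules


def write_gmt(modules: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for name in modules:
            members = sorted(set(modules[name]))
            handle.write("\t".join([name, name, *members]) + "\n")


def read_universe(path: str | Path) -> GeneUniverse:
    """Read a gene-universe TSV: columns gene, is_crf, class, complex.

    ``complex`` may list several comma-separated complex names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for column in ("gene", "is_crf"):
        if column not in df.columns:
            raise FormatError(f"universe file missing column {column!r}")
    genes = set(df["gene"])
    crf_flag = {
        row.gene: str(row.is_crf).strip().lower() in ("1", "true", "yes")
        for row in df.itertuples()
    }
    functional_class = (
        {row.gene: getattr(row, "_3", "") for row in df.itertuples()}
        if "class" in df.columns
        else {}
    )
    if "class" in df.columns:
        functional_class = dict(zip(df["gene"], df["class"]))
    complexes: dict[str, set[str]] = {}
    if "complex" in df.columns:
        for gene, cell in zip(df["gene"], df["complex"]):
            for name in str(cell).split(","):
                name = name.strip()
                if name:
                    complexes.setdefault(name, set()).add(gene)
    return GeneUniverse(
        genes=genes,
        crf_flag=crf_flag,
        functional_class=functional_class,
        complexes=complexes,
    )


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    member_of: dict[str, list[str]] = {}
    for name in sorted(universe.complexes):
        for gene in universe.complexes[name]:
            member_of.setdefault(gene, []).append(name)
    rows = [
        {
            "gene": gene,
            "is_crf": int(universe.crf_flag.get(gene, False)),
            "class": universe.functional_class.get(gene, ""),
            "complex": ",".join(sorted(member_of.get(gene, []))),
        }
        for gene in sorted(universe.genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines ignored; order preserved."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_protein_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "length"} <= set(df.columns):
        raise FormatError("protein length file needs columns 'gene' and 'length'")
    return dict(zip(df["gene"].astype(str), df["length"].astype(int)))


def write_protein_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": sorted(lengths), "length": [lengths[g] for g in sorted(lengths)]}
    ).to_csv(path, sep="\t", index=False)
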