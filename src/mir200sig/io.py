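"""Data model, file formats and configuration.

Containers used throughout the package:

* :class:`ExpressionMatrix` -- genes x samples logCPM (or raw counts) grid.
* :class:`SampleAnnotations` -- per-sample clinical/molecular record,
  including the anchor microRNA value and survival endpoints.
* :class:`GeneSetCollection` -- named gene sets (GMT semantics).
* :class:`ClassCentroids` -- reference per-class expression profiles.
* :class:`AnalysisConfig` -- all tunable parameters of the pipeline.

All on-disk formats are plain tab-delimited text (UTF-8, '.' decimal point).
Tables written by the pipeline carry a ``# mir200sig config_hash=... seed=...``
comment line so that an output file identifies the run that produced it;
readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mir200sig")

UNITS = ("counts", "logCPM")
STAGES = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV", "unknown")
MUTATION_STATES = ("mutant", "wild-type", "unknown")

#: deconvolution class names used across the package
CLASS_DOWN = "miR-200-sign-down"
CLASS_UP = "miR-200-sign-up"


class DataFormatError(ValueError):
    """Malformed or invariant-violating input data."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples numeric grid with a unit tag.

    ``values`` is a DataFrame indexed by gene symbol with sample identifiers
    as columns.  ``unit`` is ``"counts"`` (non-negative integral) or
    ``"logCPM"`` (log2 counts per million).
    """

    values: pd.DataFrame
    unit: str = "logCPM"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise DataFormatError(f"unknown expression unit {self.unit!r}")
        # identifiers are positional labels; axis names (e.g. "gene" from a
        # file header) would shadow columns of the same name in sorts
        self.values.index.name = None
        self.values.columns.name = None
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise DataFormatError(f"duplicate gene identifier {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise DataFormatError(f"duplicate sample identifier {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataFormatError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise DataFormatError(
                f"missing expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.unit == "counts":
            if (arr < 0).any():
                raise DataFormatError("counts matrix contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise DataFormatError("counts matrix contains non-integral values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise DataFormatError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise DataFormatError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(samples)], self.unit)


def _read_header(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                return line.rstrip("\n").split("\t")
    raise DataFormatError(f"{path}: no header line found")


def read_expression(path: str | Path, unit: str = "logCPM") -> ExpressionMatrix:
    """Read a tab-delimited expression table (first column = gene symbols).

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean value (logged).  Duplicate sample columns or non-numeric cells are
    rejected with their location.
    """
    header = _read_header(path)
    if len(header) < 2:
        raise DataFormatError(f"{path}: header must name at least one sample")
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise DataFormatError(f"{path}: duplicate sample identifier {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.columns = sample_ids
    df.index = df.index.astype(str)
    num = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric value {df.iat[g, s]!r} at gene "
            f"{df.index[g]!r}, sample {sample_ids[s]!r}"
        )
    if num.isna().to_numpy().any():
        g, s = np.argwhere(num.isna().to_numpy())[0]
        raise DataFormatError(
            f"{path}: missing value at gene {df.index[g]!r}, sample {sample_ids[s]!r}"
        )
    if num.index.duplicated().any():
        n_dup = int(num.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows (keep highest mean)", n_dup)
        means = num.mean(axis=1)
        order = num.index[~num.index.duplicated()]  # first-occurrence order
        keep = (
            pd.DataFrame({"mean": means})
            .assign(pos=np.arange(len(num)))
            .sort_values(["mean", "pos"], ascending=[False, True])
            .groupby(level=0, sort=False)
            .head(1)["pos"]
        )
        num = num.iloc[sorted(keep)].loc[order]
    return ExpressionMatrix(num, unit)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    config: "AnalysisConfig | None" = None,
    decimals: int = 6,
) -> None:
    """Write a tab-delimited expression table (values at ``decimals`` places)."""
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(table_header(config) + "\n")
        matrix.values.to_csv(
            fh, sep="\t", index_label="gene", float_format=f"%.{decimals}f",
            lineterminator="\n",
        )


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

_REQUIRED_ANNOT = ("sample_id", "anchor_value", "dfs_time", "dfs_event")
_MUT_PREFIX = "mut_"


def _normalize_mutation(v: object) -> str:
    if pd.isna(v) or v == "":
        return "unknown"
    s = str(v).strip().lower()
    if s in ("mutant", "mut", "1", "1.0", "true"):
        return "mutant"
    if s in ("wild-type", "wildtype", "wt", "0", "0.0", "false"):
        return "wild-type"
    if s in ("unknown", "na", "nan"):
        return "unknown"
    raise DataFormatError(f"unrecognized mutation state {v!r}")


@dataclass
class SampleAnnotations:
    """Per-sample clinical and molecular record.

    Wraps a DataFrame indexed by sample_id with columns ``anchor_value``,
    ``dfs_time``/``dfs_event`` (months, 0/1), optional ``os_time``/``os_event``,
    ``stage`` (IA..IV or "unknown"), ``tumor_content`` (fraction or NaN for
    unknown) and any number of ``mut_<GENE>`` flags with values
    mutant / wild-type / unknown.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise DataFormatError(f"duplicate sample identifier {dup!r}")
        for col in ("anchor_value", "dfs_time", "dfs_event"):
            if col not in df.columns:
                raise DataFormatError(f"annotations missing required column {col!r}")
        for t_col, e_col in (("dfs_time", "dfs_event"), ("os_time", "os_event")):
            if t_col not in df.columns:
                continue
            t = pd.to_numeric(df[t_col], errors="raise")
            if (t.dropna() < 0).any():
                raise DataFormatError(f"negative {t_col}")
            e = df[e_col].dropna()
            if not e.isin([0, 1, 0.0, 1.0]).all():
                bad = e[~e.isin([0, 1, 0.0, 1.0])].iloc[0]
                raise DataFormatError(f"{e_col} must be 0/1, got {bad!r}")
        if "stage" not in df.columns:
            df["stage"] = "unknown"
        df["stage"] = df["stage"].fillna("unknown").astype(str)
        bad_stage = set(df["stage"]) - set(STAGES)
        if bad_stage:
            raise DataFormatError(f"unknown stage value(s): {sorted(bad_stage)}")
        if "tumor_content" not in df.columns:
            df["tumor_content"] = np.nan
        tc = pd.to_numeric(df["tumor_content"], errors="raise")
        if ((tc.dropna() < 0) | (tc.dropna() > 1)).any():
            raise DataFormatError("tumor_content must lie in [0, 1]")
        df["tumor_content"] = tc
        for col in df.columns:
            if col.startswith(_MUT_PREFIX):
                df[col] = df[col].map(_normalize_mutation)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def anchor(self) -> pd.Series:
        return pd.to_numeric(self.df["anchor_value"], errors="coerce")

    @property
    def mutation_genes(self) -> list[str]:
        return [c[len(_MUT_PREFIX):] for c in self.df.columns if c.startswith(_MUT_PREFIX)]

    def mutation_flags(self, gene: str) -> pd.Series:
        col = _MUT_PREFIX + gene
        if col not in self.df.columns:
            raise DataFormatError(f"no mutation flags for gene {gene!r}")
        return self.df[col]

    def survival(self, endpoint: str = "dfs") -> tuple[pd.Series, pd.Series]:
        """Return (times, events) for ``endpoint`` in {dfs, os}, dropping unknowns."""
        t_col, e_col = f"{endpoint}_time", f"{endpoint}_event"
        if t_col not in self.df.columns:
            raise DataFormatError(f"no {endpoint} survival columns")
        sub = self.df[[t_col, e_col]].dropna()
        return sub[t_col].astype(float), sub[e_col].astype(int)

    def subset(self, samples: Sequence[str]) -> "SampleAnnotations":
        return SampleAnnotations(self.df.loc[list(samples)].copy())


def read_annotations(path: str | Path) -> SampleAnnotations:
    """Read the tab-delimited per-sample annotation table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in _REQUIRED_ANNOT:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    df = df.set_index("sample_id")
    return SampleAnnotations(df)


def write_annotations(
    ann: SampleAnnotations, path: str | Path, config: "AnalysisConfig | None" = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(table_header(config) + "\n")
        ann.df.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataFormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise DataFormatError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{i}: GMT line needs name, description and >=1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped: list[str] = []
            seen: set[str] = set()
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                deduped.append(m)
            if len(deduped) < len(members):
                warnings.warn(f"gene set {name!r}: duplicate members collapsed")
            if not deduped:
                raise DataFormatError(f"{path}:{i}: gene set {name!r} has no members")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Class centroids
# ---------------------------------------------------------------------------

@dataclass
class ClassCentroids:
    """Reference per-class expression profiles (genes x classes).

    Optional per-gene non-negative ``weights`` modulate the deconvolution
    objective (defaults to 1 for every gene when absent).
    """

    profiles: pd.DataFrame
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.profiles.index.duplicated().any():
            dup = self.profiles.index[self.profiles.index.duplicated()][0]
            raise DataFormatError(f"duplicate centroid gene {dup!r}")
        if self.profiles.columns.duplicated().any():
            raise DataFormatError("duplicate class name in centroids")
        if self.weights is not None:
            w = self.weights.reindex(self.profiles.index)
            if w.isna().any():
                raise DataFormatError("centroid weights must cover all genes")
            if (w < 0).any():
                raise DataFormatError("centroid weights must be non-negative")
            if not (w > 0).any():
                raise DataFormatError("at least one centroid weight must be positive")
            self.weights = w.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def class_names(self) -> list[str]:
        return list(self.profiles.columns)


def read_centroids(path: str | Path) -> ClassCentroids:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    weights = None
    if "weight" in df.columns:
        weights = df.pop("weight").astype(float)
    return ClassCentroids(df.astype(float), weights)


def write_centroids(
    centroids: ClassCentroids, path: str | Path, config: "AnalysisConfig | None" = None
) -> None:
    df = centroids.profiles.copy()
    if centroids.weights is not None:
        df["weight"] = centroids.weights
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(table_header(config) + "\n")
        df.to_csv(fh, sep="\t", index_label="gene", float_format="%.6f",
                  lineterminator="\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline.

    Counts mirror the study design: 15 extreme tumors per anchor tail, 1500
    differentially expressed genes, 1500 most-variable genes, a 150-gene
    centroid panel, and a 0.5 cutoff on the up-weight for class assignment.
    """

    # signature derivation
    n_extreme: int = 15
    n_de_genes: int = 1500
    n_variable_genes: int = 1500
    n_centroid_genes: int = 150
    # deconvolution
    purity_threshold: float = 0.95
    max_iterations: int = 10
    class_cutoff: float = 0.5
    # preprocessing
    prior_count: float = 0.5
    min_tumor_content: float = 0.20
    variable_statistic: str = "variance"  # or "mad"
    # clustering
    k_subtypes: int = 3
    distance: str = "pearson"  # or "euclidean"
    linkage: str = "ward"  # or "average", "complete"
    # anchor: annotations column by default; set anchor_rows to use matrix rows
    anchor_rows: tuple[str, ...] | None = None
    # scoring / enrichment
    emt_anchor_gene: str = "CDH1"
    epithelial_set: str = "EMT_EPITHELIAL"
    mesenchymal_set: str = "EMT_MESENCHYMAL"
    emt7_epithelial_genes: tuple[str, ...] = ()
    emt7_mesenchymal_genes: tuple[str, ...] = ()
    marker_set_prefix: str = "MARKERS_"
    checkpoint_gene: str = "CD274"
    gsea_permutations: int = 1000
    gsea_exponent: float = 1.0
    # survival
    ties: str = "breslow"  # or "efron"
    min_stratum_size: int = 5
    # reproducibility and paths
    seed: int = 0
    expression_unit: str = "logCPM"
    expression_path: str | None = None
    annotations_path: str | None = None
    gene_sets_path: str | None = None
    centroids_path: str | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_extreme", "n_de_genes", "n_variable_genes",
                     "n_centroid_genes", "max_iterations", "k_subtypes",
                     "gsea_permutations", "min_stratum_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise DataFormatError(f"{name} must be a positive integer, got {v!r}")
        if not 0 < self.class_cutoff < 1:
            raise DataFormatError("class_cutoff must lie in (0, 1)")
        if not 0 < self.purity_threshold <= 1:
            raise DataFormatError("purity_threshold must lie in (0, 1]")
        if not 0 <= self.min_tumor_content <= 1:
            raise DataFormatError("min_tumor_content must lie in [0, 1]")
        if self.expression_unit not in UNITS:
            raise DataFormatError(f"unknown expression unit {self.expression_unit!r}")
        if self.anchor_rows is not None:
            self.anchor_rows = tuple(self.anchor_rows)
        self.emt7_epithelial_genes = tuple(self.emt7_epithelial_genes)
        self.emt7_mesenchymal_genes = tuple(self.emt7_mesenchymal_genes)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def table_header(config: AnalysisConfig) -> str:
    """Comment line stamped on every output table."""
    return f"# mir200sig config_hash={config.config_hash} seed={config.seed}"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: AnalysisConfig | None = None,
    index_label: str = "id",
    decimals: int = 6,
) -> None:
    """Write a generic output table with the run-identity header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(table_header(config) + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label,
                  float_format=f"%.{decimals}f", lineterminator="\n")
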