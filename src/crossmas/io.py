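"""Tabular I/O and configuration for the dosage-imbalance DE pipeline.

The pipeline starts from a raw gene x sample count matrix and a sample
metadata table assigning each sample to one of three roles: a reference
condition ("WT"), a low-dosage condition ("KD", driver knocked down) and a
high-dosage condition ("OE", driver overexpressed). All artifacts are plain
TSV/CSV; gene sets use the GMT format; configuration is YAML or JSON.

Floating-point columns are serialized with 17 significant digits so that a
write/read round trip is bit-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crossmas")

#: float format used by every writer (round-trips float64 exactly)
FLOAT_FMT = "%.17g"

DEFAULT_CONDITION_LABELS = ("WT", "KD", "OE")


class ValidationError(ValueError):
    """An input artifact violates a structural invariant."""


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer RNA-seq counts, genes in rows, samples in columns."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # (n_genes, n_samples), non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise ValidationError("a count matrix needs at least 2 samples")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} identifiers: {sorted(dupes)}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            counts=frame.to_numpy(),
        )


@dataclass(frozen=True)
class SampleTable:
    """Sample -> condition assignment for the three-group design.

    ``labels`` gives the (reference, low-dosage, high-dosage) condition
    names in that order; each condition must have at least 2 replicates so
    the GLM has positive residual degrees of freedom.
    """

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    labels: tuple[str, str, str] = DEFAULT_CONDITION_LABELS

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.conditions):
            raise ValidationError("sample_ids and conditions differ in length")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValidationError(f"duplicate sample identifiers: {sorted(dupes)}")
        if len(set(self.labels)) != 3:
            raise ValidationError("exactly three distinct condition labels required")
        unknown = set(self.conditions) - set(self.labels)
        if unknown:
            raise ValidationError(
                f"unknown condition labels {sorted(unknown)}; "
                f"allowed labels are {list(self.labels)}"
            )
        for label in self.labels:
            n = sum(c == label for c in self.conditions)
            if n < 2:
                raise ValidationError(
                    f"condition {label!r} has {n} sample(s); at least 2 replicates "
                    "per condition are required"
                )

    @property
    def reference(self) -> str:
        return self.labels[0]

    @property
    def low(self) -> str:
        return self.labels[1]

    @property
    def high(self) -> str:
        return self.labels[2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.sample_ids), "condition": list(self.conditions)}
        )

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.conditions) if c == condition]


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the full pipeline.

    Defaults follow the published analysis: DEGs at BH-adjusted p < 0.05 and
    |log2FC| > 1, MAS exponents M = A = 1, top-10 genes per unique set,
    Spearman |rho| > 0.2 against the dosage driver, PCA to 2 components.
    """

    lfc_threshold: float = 1.0
    alpha: float = 0.05
    mas_M: float = 1.0
    mas_A: float = 1.0
    top_k_per_set: int = 10
    rho_threshold: float = 0.2
    driver_gene: str = "Mecp2"
    n_components: int = 2
    random_seed: int = 0
    log_prior_count: float = 1.0
    condition_labels: tuple[str, str, str] = DEFAULT_CONDITION_LABELS
    # TMM trim fractions (each tail), following the published method defaults
    trim_m: float = 0.30
    trim_a: float = 0.05
    # "nested": full model over all samples vs reduced model dropping the
    # tested condition indicator. "subset": two-group fit on the tested
    # condition plus reference only.
    contrast_mode: str = "nested"
    require_positive_rho: bool = False

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValidationError("lfc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.mas_M < 0 or self.mas_A < 0:
            raise ValidationError("MAS exponents must be >= 0")
        if self.top_k_per_set < 0:
            raise ValidationError("top_k_per_set must be >= 0")
        if self.rho_threshold < 0:
            raise ValidationError("rho_threshold must be >= 0")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.log_prior_count <= 0:
            raise ValidationError("log_prior_count must be positive")
        if self.contrast_mode not in ("nested", "subset"):
            raise ValidationError("contrast_mode must be 'nested' or 'subset'")
        self.condition_labels = tuple(self.condition_labels)  # type: ignore[assignment]


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# count matrix


def read_counts(
    path: str | Path, dialect: str | None = None, transpose: bool = False
) -> CountMatrix:
    """Read a count matrix (first column gene ids, header row sample ids).

    ``transpose`` handles files stored samples-in-rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    except ValueError as exc:  # non-numeric cells surface here
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    if transpose:
        frame = frame.T
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame[col][~frame[col].astype(str).str.fullmatch(r"-?\d+(\.\d+)?")]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}"
            )
    return CountMatrix.from_frame(frame)


def write_counts(matrix: CountMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=_sep_for(path, dialect))


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(
    path: str | Path,
    labels: tuple[str, str, str] = DEFAULT_CONDITION_LABELS,
    dialect: str | None = None,
) -> SampleTable:
    """Read a two-column (sample_id, condition) table."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    required = {"sample_id", "condition"}
    if not required.issubset(frame.columns):
        raise ValidationError(
            f"metadata {path} must have columns {sorted(required)}; "
            f"found {list(frame.columns)}"
        )
    return SampleTable(
        sample_ids=tuple(frame["sample_id"]),
        conditions=tuple(frame["condition"]),
        labels=labels,
    )


def write_metadata(table: SampleTable, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path, dialect), index=False)


def check_consistency(counts: CountMatrix, samples: SampleTable) -> None:
    """Ensure metadata covers exactly the samples of the count matrix."""
    a, b = set(counts.sample_ids), set(samples.sample_ids)
    if a != b:
        missing = sorted(a - b)
        extra = sorted(b - a)
        raise ValidationError(
            f"sample mismatch between counts and metadata; "
            f"missing from metadata: {missing}; not in counts: {extra}"
        )


# ---------------------------------------------------------------------------
# DEG tables and other pipeline artifacts

DEG_COLUMNS = [
    "gene_id",
    "log2fc",
    "p_raw",
    "p_bh",
    "mas",
    "rank",
    "significant",
    "direction",
]


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.loc[:, DEG_COLUMNS].copy()
    out.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def read_deg_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so 17-significant-digit output reloads bit-exactly
    table = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = set(DEG_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"DEG table {path} missing columns {sorted(missing)}")
    table["gene_id"] = table["gene_id"].astype(str)
    table["rank"] = table["rank"].astype("Int64")
    table["significant"] = table["significant"].astype(bool)
    return table


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(Path(path), sep="\t", index=index, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into {term: member set}; empty sets are dropped."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"malformed GMT line {lineno} in {path}: expected "
                    f">= 3 tab-separated fields, found {len(fields)}"
                )
            name = fields[0]
            members = {g for g in fields[2:] if g}
            if not members:
                logger.warning("GMT term %r has no members; dropped", name)
                continue
            if name in sets:
                raise ValidationError(f"duplicate GMT term {name!r} at line {lineno}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + sorted(set(members))) + "\n")


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    raw = raw or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "condition_labels" in raw:
        raw["condition_labels"] = tuple(raw["condition_labels"])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    raw = dataclasses.asdict(config)
    raw["condition_labels"] = list(raw["condition_labels"])
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
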