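"""CSV readers/writers and run configuration.

Marker CSV: header row, first column ``line_id``, remaining columns numeric
marker codes; empty cells or ``NA`` are mean-imputed per column (upstream
marker imputation is out of scope, so this is a logged fallback only).

Phenotype CSV: columns ``line_id``, ``env_id``, then one column per trait;
empty/``NA`` cells become masked entries.  Rows are canonicalized internally
to environment-major order (sorted environment labels, then sorted line
labels), so input row order is irrelevant.

Kernel matrices round-trip as square labelled CSV for interchange with
GBLUP-style software.  Run configuration round-trips through YAML.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernels import InvalidInputError, KernelMatrix, MarkerMatrix
from .model import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "RunConfig",
    "read_marker_csv",
    "write_marker_csv",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "read_kernel_csv",
    "write_kernel_csv",
]

NA_VALUES = ["", "NA"]


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_marker_csv(path) -> MarkerMatrix:
    """Read a marker matrix; duplicate line ids or non-numeric cells are errors."""
    df = pd.read_csv(path, dtype={0: str}, na_values=NA_VALUES, keep_default_na=False)
    if df.columns[0] != "line_id":
        raise FormatError(f"first column must be 'line_id', got {df.columns[0]!r}")
    ids = df["line_id"].tolist()
    dupes = df["line_id"][df["line_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"duplicate line id(s): {', '.join(map(str, dupes))}")
    values = np.empty((len(df), df.shape[1] - 1))
    for j, col in enumerate(df.columns[1:]):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            i = int(np.where(bad)[0][0])
            raise FormatError(
                f"non-numeric marker value {df[col].iloc[i]!r} at row {i + 2}, column {col!r}"
            )
        values[:, j] = numeric.to_numpy()
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        col_means = np.nanmean(values, axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        idx = np.where(np.isnan(values))
        values[idx] = col_means[idx[1]]
        logger.info("mean-imputed %d missing marker cell(s) in %s", n_missing, path)
    return MarkerMatrix(values=values, line_ids=ids, scaled=False)


def write_marker_csv(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(markers.values, columns=[f"m{j + 1}" for j in range(markers.n_markers)])
    df.insert(0, "line_id", markers.line_ids)
    df.to_csv(path, index=False)


def read_phenotype_csv(path) -> PhenotypeTable:
    """Read a line x environment phenotype table into canonical env-major order."""
    df = pd.read_csv(path, dtype={"line_id": str, "env_id": str},
                     na_values=NA_VALUES, keep_default_na=False)
    for col in ("line_id", "env_id"):
        if col not in df.columns[:2].tolist():
            raise FormatError(f"phenotype CSV must start with line_id, env_id columns")
    trait_names = [c for c in df.columns if c not in ("line_id", "env_id")]
    if not trait_names:
        raise FormatError("phenotype CSV has no trait columns")
    dup = df.duplicated(subset=["line_id", "env_id"])
    if dup.any():
        pair = df.loc[dup, ["line_id", "env_id"]].iloc[0].tolist()
        raise FormatError(f"duplicate (line, environment) pair: {tuple(pair)}")
    for col in trait_names:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            i = int(np.where(bad)[0][0])
            raise FormatError(
                f"non-numeric phenotype value {df[col].iloc[i]!r} at row {i + 2}, column {col!r}"
            )
        df[col] = numeric
    env_ids = sorted(df["env_id"].unique())
    line_ids = sorted(df["line_id"].unique())
    df = df.sort_values(["env_id", "line_id"], kind="mergesort").reset_index(drop=True)
    env_index = {e: i for i, e in enumerate(env_ids)}
    line_index = {l: i for i, l in enumerate(line_ids)}
    values = df[trait_names].to_numpy(dtype=float)
    mask = ~np.isnan(values)
    values = np.nan_to_num(values)
    return PhenotypeTable(
        values=values,
        mask=mask,
        line_of_cell=df["line_id"].map(line_index).to_numpy(),
        env_of_cell=df["env_id"].map(env_index).to_numpy(),
        trait_names=trait_names,
        line_ids=line_ids,
        env_ids=env_ids,
    )


def write_phenotype_csv(data: PhenotypeTable, path) -> None:
    values = np.where(data.mask, data.values, np.nan)
    df = pd.DataFrame(values, columns=data.trait_names)
    df.insert(0, "env_id", [data.env_ids[e] for e in data.env_of_cell])
    df.insert(0, "line_id", [data.line_ids[l] for l in data.line_of_cell])
    df.to_csv(path, index=False, na_rep="NA")


def read_kernel_csv(path) -> KernelMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise FormatError("kernel CSV row labels must equal column labels")
    return KernelMatrix(values=df.to_numpy(dtype=float), row_ids=list(df.columns))


def write_kernel_csv(K: KernelMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.row_ids, columns=K.row_ids).to_csv(path)


@dataclass
class RunConfig:
    """Flat run configuration mirroring the CLI flags; YAML round-trippable."""

    markers: str = ""
    phenotypes: str = ""
    out_dir: str = "."
    kernel: str = "linear"
    gamma: float = 1.0
    offset: float = 0.0
    degree: int = 3
    gxe: bool = False
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    scenario: str = "MT"
    target_traits: list = field(default_factory=list)
    observed_traits: list = field(default_factory=list)
    folds: int = 5
    seed: int = 0
    verbosity: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
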