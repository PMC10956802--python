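"""Delimited-text I/O for expression matrices, target-pair databases and result tables.

Expression matrices are features x samples: first column holds feature IDs,
the header row holds sample IDs.  Empty cells and ``NA`` denote missing
values; ``NA`` is written on output.  Target databases are two-column
(mirna_id, gene_id) files; the real miRDB/TargetScan/miRTarBase
distribution formats are deliberately not parsed — convert them to the
pair format first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: accepted missing-value sentinels on read; the first one is written
MISSING_SENTINELS = ("NA", "")

LAYERS = ("mrna", "protein", "mirna")


@dataclass
class ExpressionMatrix:
    """A features x samples real matrix with missing entries as NaN.

    Parameters
    ----------
    data
        DataFrame indexed by feature ID with sample IDs as columns,
        dtype float, NaN marking missing values.
    layer
        One of ``mrna``, ``protein``, ``mirna``.
    """

    data: pd.DataFrame
    layer: str = field(default="mrna")

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy_with(self, data: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, layer=self.layer)


@dataclass(frozen=True)
class TargetDatabase:
    """A named set of known or predicted (mirna_id, gene_id) pairs."""

    name: str
    pairs: frozenset[tuple[str, str]]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def read_expression_matrix(
    path: str | Path,
    layer: str,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a features x samples delimited-text matrix.

    Empty cells and ``NA`` become NaN.  Duplicate feature or sample IDs,
    ragged rows and non-numeric cells raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # pre-validate structure: pandas silently mangles duplicate header IDs
    # and pads ragged rows, so check the raw lines first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        n_fields = len(header)
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"{path}: duplicate sample IDs in header")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split(sep)) != n_fields:
                raise ValueError(f"{path}:{lineno}: ragged row "
                                 f"(expected {n_fields} fields)")
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        header=0,
        dtype=str,
        keep_default_na=False,
    )
    df = df.replace(list(MISSING_SENTINELS), np.nan)
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell that is not a missing sentinel: {exc}") from exc
    numeric.index = numeric.index.astype(str)
    numeric.index.name = None
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(data=numeric, layer=layer)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix back to delimited text; NaN is written as ``NA``."""
    m.data.to_csv(path, sep=sep, na_rep="NA", index_label="feature_id")


_HEADER_WORDS = {"mirna", "mirna_id", "gene", "gene_id", "target", "target_id", "mir"}


def read_target_database(path: str | Path, name: str, sep: str = "\t") -> TargetDatabase:
    """Read a two-column (mirna_id, gene_id) pair file into a :class:`TargetDatabase`.

    A first line whose fields look like column labels (``mirna``, ``gene`` ...)
    or that starts with ``#`` is treated as a header.  Duplicate pairs are
    dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (a.lower() in _HEADER_WORDS or b.lower() in _HEADER_WORDS):
                continue
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            pairs.append((a, b))
    unique = frozenset(pairs)
    dropped = len(pairs) - len(unique)
    if dropped:
        logger.info("%s: dropped %d duplicate pairs", name, dropped)
    if not unique:
        logger.warning("%s: empty target database", name)
    return TargetDatabase(name=name, pairs=unique)


def write_interaction_table(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write the selected-interaction table as delimited text.

    The table comes from :func:`mirparc.core.select_interactions`, optionally
    annotated with per-database validation flags.  An empty table yields a
    header-only file.
    """
    table.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_interaction_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a previously written interaction table."""
    df = pd.read_csv(path, sep=sep)
    for col in df.columns:
        if col.startswith("in_") or col == "validated_any":
            df[col] = df[col].astype(bool)
    return df


def read_id_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read an optional two-column (from_id, to_id) identifier-mapping file.

    Used to reconcile miRNA naming conventions (``hsa-`` prefixes, arm
    suffixes) between expression matrices and target databases; matching is
    otherwise exact string equality.
    """
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
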