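"""Preprocessing of matched mRNA/protein/miRNA matrices.

Pipeline order: missingness filter -> per-feature median imputation ->
log2 (mRNA and miRNA layers) -> top-variance selection (protein layer)
-> alignment of the triple on shared samples and shared gene IDs.
Running the pipeline twice equals running it once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_matrices import ExpressionMatrix

logger = logging.getLogger(__name__)

#: minimum sample count: the partial-correlation t-test needs n-3 >= 1 df
MIN_SAMPLES = 4


@dataclass
class OmicsDataset:
    """Aligned (M, P, MI) triple: shared samples, M/P share gene IDs, no missing values."""

    M: ExpressionMatrix
    P: ExpressionMatrix
    MI: ExpressionMatrix

    def __post_init__(self) -> None:
        if not (self.M.sample_ids == self.P.sample_ids == self.MI.sample_ids):
            raise ValueError("M, P, MI must share identical sample IDs in identical order")
        if self.M.feature_ids != self.P.feature_ids:
            raise ValueError("M and P must share identical feature IDs in identical order")
        for name, m in (("M", self.M), ("P", self.P), ("MI", self.MI)):
            if m.n_missing:
                raise ValueError(f"{name} still contains {m.n_missing} missing values")
        if self.n < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples, got {self.n}")

    @property
    def n(self) -> int:
        return len(self.M.sample_ids)

    @property
    def genes(self) -> list[str]:
        return self.M.feature_ids

    @property
    def mirnas(self) -> list[str]:
        return self.MI.feature_ids


def filter_by_missingness(
    m: ExpressionMatrix, max_missing_fraction: float = 0.10
) -> ExpressionMatrix:
    """Keep features whose missing fraction is strictly below the threshold.

    A feature missing exactly 10% of samples is dropped at the default
    threshold; order is preserved.
    """
    frac = m.data.isna().mean(axis=1)
    keep = frac < max_missing_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d/%d features with >= %.0f%% missing",
                    m.layer, dropped, len(keep), 100 * max_missing_fraction)
    out = m.copy_with(m.data.loc[keep])
    if out.data.empty:
        logger.warning("%s: missingness filter left no features", m.layer)
    return out


def impute_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing entry by the median of its feature's observed values."""
    all_missing = m.data.isna().all(axis=1)
    if all_missing.any():
        bad = m.data.index[all_missing].tolist()
        raise ValueError(f"features with all values missing: {bad[:5]}")
    medians = m.data.median(axis=1)
    return m.copy_with(m.data.apply(lambda row: row.fillna(medians[row.name]), axis=1))


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Entrywise ``log2(x + pseudocount)``; requires ``x + pseudocount > 0``."""
    shifted = m.data + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("log2 transform: non-positive value after pseudocount")
    return m.copy_with(np.log2(shifted))


def select_top_variance(
    m: ExpressionMatrix, keep_fraction: float = 0.5, statistic: str = "variance"
) -> ExpressionMatrix:
    """Keep the ``ceil(keep_fraction * n_features)`` most variable features.

    Ties are broken by feature ID (lexicographic); the original relative
    order is preserved among survivors.  ``statistic`` may be ``variance``,
    ``sd`` or ``mad``.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return m.copy_with(m.data.copy())
    if statistic == "variance":
        score = m.data.var(axis=1, ddof=1)
    elif statistic == "sd":
        score = m.data.std(axis=1, ddof=1)
    elif statistic == "mad":
        score = (m.data.sub(m.data.median(axis=1), axis=0)).abs().median(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    k = math.ceil(keep_fraction * len(score))
    ranked = sorted(score.index, key=lambda fid: (-score[fid], fid))
    chosen = set(ranked[:k])
    keep = [fid in chosen for fid in m.data.index]
    return m.copy_with(m.data.loc[keep])


def align_dataset(
    M: ExpressionMatrix, P: ExpressionMatrix, MI: ExpressionMatrix
) -> OmicsDataset:
    """Align the triple on the shared samples and the M/P shared genes.

    Samples are the three-way intersection in a canonical sorted order;
    genes are the M/P intersection (canonical sorted order).  Discard
    counts are logged.
    """
    samples = sorted(set(M.sample_ids) & set(P.sample_ids) & set(MI.sample_ids))
    if not samples:
        raise ValueError("empty sample intersection between M, P and MI")
    if len(samples) < MIN_SAMPLES:
        raise ValueError(f"only {len(samples)} shared samples; need >= {MIN_SAMPLES}")
    genes = sorted(set(M.feature_ids) & set(P.feature_ids))
    if not genes:
        raise ValueError("empty gene intersection between M and P")
    for name, m in (("M", M), ("P", P), ("MI", MI)):
        ds = len(m.sample_ids) - len(samples)
        if ds:
            logger.info("align: %s loses %d samples", name, ds)
    logger.info("align: %d shared genes (M had %d, P had %d), %d samples",
                len(genes), len(M.feature_ids), len(P.feature_ids), len(samples))
    return OmicsDataset(
        M=M.copy_with(M.data.loc[genes, samples]),
        P=P.copy_with(P.data.loc[genes, samples]),
        MI=MI.copy_with(MI.data.loc[:, samples]),
    )


def preprocess(
    M: ExpressionMatrix,
    P: ExpressionMatrix,
    MI: ExpressionMatrix,
    max_missing_fraction: float = 0.10,
    keep_fraction: float = 0.5,
    pseudocount: float = 1.0,
    log2_layers: tuple[str, ...] = ("mrna", "mirna"),
) -> OmicsDataset:
    """Full preprocessing pipeline for the (M, P, MI) triple.

    The protein matrix is variance-filtered but, by default, not
    log2-transformed; gene intersection with M is taken after the variance
    filter, so M is subset to the surviving proteins' genes.
    """
    out = {}
    for m in (M, P, MI):
        x = filter_by_missingness(m, max_missing_fraction)
        x = impute_median(x)
        if x.layer in log2_layers:
            x = log2_transform(x, pseudocount)
        if x.layer == "protein":
            x = select_top_variance(x, keep_fraction)
        out[m.layer] = x
    return align_dataset(out["mrna"], out["protein"], out["mirna"])
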