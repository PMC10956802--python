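"""Database annotation, hypergeometric enrichment and bivariate baselines.

Predictions are compared against named sets of known/predicted
(miRNA, gene) pairs.  Enrichment uses the upper-tail (inclusive)
hypergeometric test over the universe of all computable grid cells;
database pairs are intersected with that universe first so the
partial-correlation method and the two bivariate baselines are tested
under identical conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CorrelationGrid, _t_pvalue, benjamini_hochberg, correlation_matrix
from .io_matrices import ExpressionMatrix, TargetDatabase

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of a target database in a prediction set."""

    database_name: str
    universe_size: int
    database_in_universe: int
    predicted: int
    overlap: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.database_in_universe, self.predicted):
            raise ValueError("overlap exceeds its bounds")
        if self.predicted > self.universe_size:
            raise ValueError("predicted exceeds universe")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of range")


def annotate_validated(
    table: pd.DataFrame, dbs: list[TargetDatabase]
) -> pd.DataFrame:
    """Add one boolean membership column per database plus ``validated_any``.

    Membership is exact string equality on (mirna, gene); use an ID map at
    load time if naming conventions differ.
    """
    out = table.copy()
    flags = []
    for db in dbs:
        col = f"in_{db.name}"
        out[col] = [
            (mi, g) in db.pairs for mi, g in zip(out["mirna"], out["gene"])
        ]
        flags.append(col)
    if flags:
        out["validated_any"] = out[flags].any(axis=1)
    return out


def build_universe(grid: CorrelationGrid) -> set[Pair]:
    """All computable (mirna, gene) cells of the grid — the enrichment universe."""
    gi, mj = np.nonzero(grid.mask)
    return {(grid.mirnas[j], grid.genes[i]) for i, j in zip(gi, mj)}


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); inclusive upper tail."""
    if N == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def hypergeometric_enrichment(
    predicted: set[Pair], db: TargetDatabase, universe: set[Pair]
) -> EnrichmentResult:
    """Upper-tail inclusive hypergeometric test, P(X >= overlap).

    X ~ Hypergeometric(N=|universe|, K=|db ∩ universe|, n=|predicted|).
    ``predicted`` must be a subset of the universe.
    """
    if not predicted <= universe:
        raise ValueError("predicted pairs must be a subset of the universe")
    N = len(universe)
    K = len(db.pairs & universe)
    n = len(predicted)
    k = len(predicted & db.pairs)
    p = hypergeom_upper_tail(N, K, n, k)
    return EnrichmentResult(
        database_name=db.name,
        universe_size=N,
        database_in_universe=K,
        predicted=n,
        overlap=k,
        p_value=p,
    )


def bivariate_baseline(
    expr: ExpressionMatrix,
    MI: ExpressionMatrix,
    alpha: float = 0.05,
    negative_only: bool = False,
) -> tuple[set[Pair], float]:
    """miRNA-target calling by direct feature-miRNA correlation significance.

    Pearson r and its t-test p-value are computed for every
    (feature, miRNA) pair, Benjamini-Hochberg is applied across all pairs,
    and pairs with adjusted p strictly below ``alpha`` are selected
    (optionally restricted to negative correlations).  Returns the selected
    pair set and the selected fraction among all computable pairs.
    """
    if expr.sample_ids != MI.sample_ids:
        raise ValueError("matrices must be aligned on samples")
    r = correlation_matrix(expr.values, MI.values)  # features x mirnas
    mask = ~np.isnan(r)
    n = len(expr.sample_ids)
    p = np.full(r.shape, np.nan)
    p[mask] = _t_pvalue(r[mask], n - 2)
    adj = np.full(r.shape, np.nan)
    adj[mask] = benjamini_hochberg(p[mask])
    hit = mask & (adj < alpha)
    if negative_only:
        hit &= r < 0
    fi, mj = np.nonzero(hit)
    pairs = {(MI.feature_ids[j], expr.feature_ids[i]) for i, j in zip(fi, mj)}
    tested = int(mask.sum())
    fraction = len(pairs) / tested if tested else 0.0
    return pairs, fraction


def summarize_validation(
    method_results: dict[str, list[EnrichmentResult]],
    fractions: dict[str, float],
) -> pd.DataFrame:
    """Tabulate selected fractions and per-database enrichment p across methods.

    One column per method (the two bivariate baselines then the
    partial-correlation method), one row for the percentage of pairs called
    significant and one row per database's enrichment p-value.
    """
    methods = list(method_results)
    rows: dict[str, list] = {
        "% predicted": [f"{100 * fractions[m]:.2f}" for m in methods]
    }
    db_names: list[str] = []
    for m in methods:
        for res in method_results[m]:
            if res.database_name not in db_names:
                db_names.append(res.database_name)
    for name in db_names:
        row = []
        for m in methods:
            match = [r for r in method_results[m] if r.database_name == name]
            row.append(f"{match[0].p_value:.3g}" if match else "NA")
        rows[f"{name} enrichment p"] = row
    return pd.DataFrame(rows, index=methods).T
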