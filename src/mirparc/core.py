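"""Bivariate and miRNA-conditioned partial Pearson correlation, the
improvement matrix, FDR adjustment and top-quartile interaction selection.

For a gene with mRNA profile x and protein profile y, and a miRNA profile z,
the first-order partial correlation is

    r_yx.z = (r_yx - r_yz * r_xz) / (sqrt(1 - r_yz^2) * sqrt(1 - r_xz^2))

with a two-sided p-value from t = r * sqrt((n - 3) / (1 - r^2)) on n - 3
degrees of freedom (n - 2 for the bivariate case).  The improvement for a
(gene, miRNA) cell is bivariate_p - partial_p: a positive value means
conditioning on the miRNA made the mRNA-protein association more
significant, the signature of miRNA-mediated repression at the protein
level.  Candidate interactions are the top quartile of positive
improvements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import OmicsDataset

logger = logging.getLogger(__name__)


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if np.ptp(v) == 0:
        raise ValueError(f"{name} is constant; correlation undefined")
    return v


def _t_pvalue(r: float | np.ndarray, df: int) -> float | np.ndarray:
    """Two-sided p-value for a (partial) correlation via the t transform."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    # |r| == 1 -> infinite t -> p = 0
    t = np.where(np.isfinite(t), t, np.inf * np.sign(r))
    return 2.0 * stats.t.sf(np.abs(t), df)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value (df = n - 2)."""
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    return r, float(_t_pvalue(r, n - 2))


def partial_correlation(r_yx: float, r_yz: float, r_xz: float) -> float:
    """First-order partial correlation from the three pairwise estimates."""
    if abs(r_yz) >= 1.0 or abs(r_xz) >= 1.0:
        raise ValueError("|r_yz| or |r_xz| at 1: partial correlation undefined")
    r = (r_yx - r_yz * r_xz) / (np.sqrt(1.0 - r_yz**2) * np.sqrt(1.0 - r_xz**2))
    return float(np.clip(r, -1.0, 1.0))


def partial_with_p(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """Partial correlation of (x, y) given z, with its t-test p-value (df = n - 3)."""
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    z = _check_vector(z, "z")
    if not (len(x) == len(y) == len(z)):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations for a conditioned test")
    r_yx, _ = pearson_with_p(y, x)
    r_yz, _ = pearson_with_p(y, z)
    r_xz, _ = pearson_with_p(x, z)
    r = partial_correlation(r_yx, r_yz, r_xz)
    return r, float(_t_pvalue(r, n - 3))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationGrid:
    """Per-(gene, miRNA) partial correlations next to per-gene bivariate ones.

    ``partial_r``/``partial_p``/``improvement`` are (R_m x R_mi); the
    bivariate vectors have length R_m.  Degenerate cells (constant profile,
    |r| = 1 in a conditioning pair) are NaN and excluded downstream.
    improvement[g, mi] = bivariate_p[g] - partial_p[g, mi].
    """

    genes: list[str]
    mirnas: list[str]
    partial_r: np.ndarray
    partial_p: np.ndarray
    bivariate_r: np.ndarray
    bivariate_p: np.ndarray
    n: int
    improvement: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        shape = (len(self.genes), len(self.mirnas))
        if self.partial_r.shape != shape or self.partial_p.shape != shape:
            raise ValueError("partial matrices must be (genes x mirnas)")
        if self.bivariate_r.shape != (shape[0],) or self.bivariate_p.shape != (shape[0],):
            raise ValueError("bivariate vectors must have one entry per gene")
        self.improvement = self.bivariate_p[:, None] - self.partial_p

    @property
    def mask(self) -> np.ndarray:
        """Boolean (genes x mirnas): True where the cell was computable."""
        return ~np.isnan(self.partial_p) & ~np.isnan(self.bivariate_p)[:, None]

    def n_tested(self) -> int:
        return int(self.mask.sum())


def _row_standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; flag constant rows."""
    c = a - a.mean(axis=1, keepdims=True)
    norm = np.sqrt((c * c).sum(axis=1))
    constant = norm == 0
    norm[constant] = 1.0
    return c / norm[:, None], constant


def correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Rows are profiles over the same samples; constant rows give NaN.
    """
    sa, ca = _row_standardize(np.asarray(a, float))
    sb, cb = _row_standardize(np.asarray(b, float))
    r = np.clip(sa @ sb.T, -1.0, 1.0)
    r[ca, :] = np.nan
    r[:, cb] = np.nan
    return r


def compute_grid(ds: OmicsDataset) -> CorrelationGrid:
    """Compute the full bivariate + partial correlation grid for a dataset.

    Vectorized over the (genes x mirnas) grid: the three pairwise
    correlation families r_yx (per gene), r_xz and r_yz (gene x miRNA) are
    assembled once, then combined cell-wise by the partial-correlation
    formula.  Cells where a conditioning correlation hits |r| = 1, or any
    profile is constant, are NaN-masked with a logged count.
    """
    M, P, MI = ds.M.values, ds.P.values, ds.MI.values
    n = ds.n
    # r_yx: per-gene mRNA-protein correlation (diagonal of the cross matrix)
    sm, cm = _row_standardize(M)
    sp, cp = _row_standardize(P)
    r_yx = np.clip((sm * sp).sum(axis=1), -1.0, 1.0)
    r_yx[cm | cp] = np.nan
    r_xz = correlation_matrix(M, MI)   # genes x mirnas
    r_yz = correlation_matrix(P, MI)

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((1.0 - r_yz**2) * (1.0 - r_xz**2))
        partial_r = (r_yx[:, None] - r_yz * r_xz) / denom
    degenerate = np.isclose(np.abs(r_yz), 1.0) | np.isclose(np.abs(r_xz), 1.0)
    partial_r[degenerate] = np.nan
    partial_r = np.clip(partial_r, -1.0, 1.0)
    partial_p = np.where(
        np.isnan(partial_r), np.nan, _t_pvalue(np.nan_to_num(partial_r), n - 3)
    )
    bivariate_p = np.where(
        np.isnan(r_yx), np.nan, _t_pvalue(np.nan_to_num(r_yx), n - 2)
    )
    grid = CorrelationGrid(
        genes=list(ds.genes),
        mirnas=list(ds.mirnas),
        partial_r=partial_r,
        partial_p=partial_p,
        bivariate_r=r_yx,
        bivariate_p=bivariate_p,
        n=n,
    )
    n_bad = partial_r.size - grid.n_tested()
    if n_bad:
        logger.info("grid: %d degenerate cells excluded", n_bad)
    return grid


def select_interactions(grid: CorrelationGrid, quartile: float = 0.75) -> pd.DataFrame:
    """Select candidate interactions: top quartile of positive improvements.

    Candidates are cells with improvement > 0; the threshold is the
    ``quartile``-th empirical quantile (linear interpolation) of the
    candidates' improvements, and cells at or above it are returned.
    FDR adjustment (Benjamini-Hochberg) runs over the partial p-values of
    every computable grid cell, not only the selected subset.
    """
    if not 0 < quartile < 1:
        raise ValueError("quartile must be in (0, 1)")
    mask = grid.mask
    columns = [
        "gene", "mirna", "partial_estimate", "partial_p",
        "partial_p_fdr", "bivariate_p", "improvement",
    ]
    empty = pd.DataFrame(columns=columns)
    if not mask.any():
        logger.warning("selection: no computable grid cells")
        return empty

    # BH over all tested cells, mapped back onto the grid
    fdr = np.full(grid.partial_p.shape, np.nan)
    fdr[mask] = benjamini_hochberg(grid.partial_p[mask])

    positive = mask & (grid.improvement > 0)
    if not positive.any():
        logger.warning("selection: no positive-improvement cells; empty table")
        return empty
    candidates = grid.improvement[positive]
    threshold = float(np.quantile(candidates, quartile))
    selected = positive & (grid.improvement >= threshold)
    gi, mi = np.nonzero(selected)
    table = pd.DataFrame(
        {
            "gene": [grid.genes[i] for i in gi],
            "mirna": [grid.mirnas[j] for j in mi],
            "partial_estimate": grid.partial_r[gi, mi],
            "partial_p": grid.partial_p[gi, mi],
            "partial_p_fdr": fdr[gi, mi],
            "bivariate_p": grid.bivariate_p[gi],
            "improvement": grid.improvement[gi, mi],
        }
    )
    table = table.sort_values("partial_p", kind="mergesort", ignore_index=True)
    logger.info(
        "selection: %d/%d positive-improvement candidates at threshold %.3g",
        len(table), int(positive.sum()), threshold,
    )
    return table
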