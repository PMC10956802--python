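import numpy as np
import pandas as pd
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirparc.core import (
    CorrelationGrid,
    benjamini_hochberg,
    compute_grid,
    partial_correlation,
    partial_with_p,
    pearson_with_p,
    select_interactions,
)
from mirparc.preprocess import OmicsDataset
from mirparc.synth import generate_dataset, make_spec

from conftest import make_matrix


def residual_partial_oracle(x, y, z):
    """Partial correlation as the Pearson correlation of OLS residuals on z."""
    zc = np.column_stack([np.ones_like(z), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    return stats.pearsonr(rx, ry)[0]


def test_pearson_matches_scipy_and_hand_value():
    x = np.array([1.0, 2, 3, 4])
    y = np.array([1.0, 3, 2, 4])
    r, p = pearson_with_p(x, y)
    assert r == pytest.approx(0.8, abs=1e-15)
    t = 0.8 * np.sqrt(2 / (1 - 0.64))
    assert p == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-15)
    ref = stats.pearsonr(x, y)
    assert p == pytest.approx(ref.pvalue, abs=1e-12)

    assert pearson_with_p([1, 2, 3], [2, 4, 6])[0] == 1.0
    assert pearson_with_p([1, 2, 3], [3, 2, 1])[0] == -1.0
    with pytest.raises(ValueError):
        pearson_with_p([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_with_p([1, 2], [1, 2, 3])


@pytest.mark.parametrize(
    "ryx,ryz,rxz,expected",
    [
        (0.5, 0.0, 0.0, 0.5),
        (0.5, 0.5, 0.5, 1 / 3),
        (0.0, 0.6, -0.6, 0.5625),
    ],
)
def test_partial_correlation_formula_hand_values(ryx, ryz, rxz, expected):
    assert partial_correlation(ryx, ryz, rxz) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    ryx=st.floats(-1, 1),
    ryz=st.floats(-0.99, 0.99),
    rxz=st.floats(-0.99, 0.99),
)
def test_partial_correlation_properties(ryx, ryz, rxz):
    """Range, identity under uncorrelated conditioning, and antisymmetry."""
    r = partial_correlation(ryx, ryz, rxz)
    assert -1.0 <= r <= 1.0
    assert partial_correlation(ryx, 0.0, 0.0) == pytest.approx(ryx)
    # negating y flips every correlation involving y, hence the partial
    assert partial_correlation(-ryx, -ryz, rxz) == pytest.approx(-r, abs=1e-12)


def test_partial_correlation_degenerate_conditioning():
    with pytest.raises(ValueError):
        partial_correlation(0.5, 1.0, 0.0)


def test_partial_with_p_matches_residual_oracle_and_pingouin():
    rng = np.random.default_rng(42)
    for _ in range(25):
        x, y, z = rng.standard_normal((3, 30))
        r, p = partial_with_p(x, y, z)
        assert r == pytest.approx(residual_partial_oracle(x, y, z), abs=1e-10)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-4)


def test_partial_perfect_after_conditioning():
    rng = np.random.default_rng(7)
    x, z = rng.standard_normal((2, 50))
    y = x + z
    r, p = partial_with_p(x, y, z)
    assert r == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.9], [0.01, 0.9]),
        ([0.7], [0.7]),
    ],
)
def test_benjamini_hochberg_hand_values(raw, expected):
    np.testing.assert_allclose(benjamini_hochberg(np.array(raw)), expected,
                               atol=1e-12)


def test_benjamini_hochberg_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg(np.array([0.5, 1.2]))


def _tiny_dataset(rng_seed=0, n=20, genes=3, mirnas=2):
    spec = make_spec(n_samples=n, n_genes=genes, n_mirnas=mirnas,
                     n_planted=1, missing_rate=0.0, rng_seed=rng_seed)
    M, P, MI, _ = generate_dataset(spec)
    from mirparc.preprocess import preprocess
    return preprocess(M, P, MI, keep_fraction=1.0)


def test_grid_shapes_and_cellwise_agreement():
    ds = _tiny_dataset()
    grid = compute_grid(ds)
    assert grid.partial_r.shape == (3, 2)
    assert grid.bivariate_p.shape == (3,)
    # every cell equals the scalar-path computation
    for i, g in enumerate(grid.genes):
        r, p = pearson_with_p(ds.M.data.loc[g], ds.P.data.loc[g])
        assert grid.bivariate_r[i] == pytest.approx(r, abs=1e-12)
        assert grid.bivariate_p[i] == pytest.approx(p, abs=1e-12)
        for j, m in enumerate(grid.mirnas):
            r, p = partial_with_p(
                ds.M.data.loc[g], ds.P.data.loc[g], ds.MI.data.loc[m]
            )
            assert grid.partial_r[i, j] == pytest.approx(r, abs=1e-12)
            assert grid.partial_p[i, j] == pytest.approx(p, abs=1e-12)
    np.testing.assert_allclose(
        grid.improvement, grid.bivariate_p[:, None] - grid.partial_p, atol=0
    )


def test_duplicated_mirna_row_duplicates_grid_column():
    ds = _tiny_dataset()
    mi2 = ds.MI.data.copy()
    mi2.loc["mir-dup"] = mi2.iloc[0]
    ds2 = OmicsDataset(M=ds.M, P=ds.P,
                       MI=make_matrix(mi2.values, features=list(mi2.index),
                                      samples=list(mi2.columns), layer="mirna"))
    grid = compute_grid(ds2)
    np.testing.assert_allclose(grid.partial_r[:, 0], grid.partial_r[:, -1],
                               atol=1e-14)


def _grid_from_improvements(biv_p, partial_p):
    biv_p = np.asarray(biv_p, float)
    partial_p = np.asarray(partial_p, float)
    g, m = partial_p.shape
    return CorrelationGrid(
        genes=[f"G{i}" for i in range(g)],
        mirnas=[f"m{j}" for j in range(m)],
        partial_r=np.zeros((g, m)),
        partial_p=partial_p,
        bivariate_r=np.zeros(g),
        bivariate_p=biv_p,
        n=30,
    )


def test_selection_threshold_by_linear_interpolation():
    # positive improvements 0.1..0.4; the 0.75 empirical quantile (linear
    # interpolation between order statistics) is 0.325, so one row survives
    grid = _grid_from_improvements(
        biv_p=[0.5, 0.5, 0.5, 0.5],
        partial_p=np.array([[0.4], [0.3], [0.2], [0.1]]),
    )
    table = select_interactions(grid, quartile=0.75)
    assert len(table) == 1
    assert table["improvement"].iloc[0] == pytest.approx(0.4)
    assert table["gene"].iloc[0] == "G3"


def test_selection_empty_when_no_positive_improvement():
    grid = _grid_from_improvements(biv_p=[0.1, 0.1], partial_p=np.array([[0.5], [0.9]]))
    assert select_interactions(grid).empty


def test_selection_fdr_over_all_cells_and_row_invariants():
    rng = np.random.default_rng(11)
    partial_p = rng.random((6, 4))
    grid = _grid_from_improvements(biv_p=rng.random(6), partial_p=partial_p)
    table = select_interactions(grid)
    assert (table["improvement"] > 0).all()
    assert (table["partial_p_fdr"] >= table["partial_p"] - 1e-15).all()
    assert not table.duplicated(["gene", "mirna"]).any()
    adj = benjamini_hochberg(partial_p.ravel()).reshape(partial_p.shape)
    for _, row in table.iterrows():
        i, j = int(row["gene"][1:]), int(row["mirna"][1:])
        assert row["partial_p_fdr"] == pytest.approx(adj[i, j], abs=1e-12)
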