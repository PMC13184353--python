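"""EFA: adequacy statistics, ML extraction, rotation, factor purity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import apathynet as an
from apathynet import efa
from apathynet.efa import (
    compare_purity,
    factor_purity,
    match_factors,
    ml_df,
    sampling_adequacy_label,
    varimax,
)


@pytest.mark.parametrize("r", [0.5, 0.3, -0.7])
def test_kmo_is_half_for_any_two_items(r):
    # p = 2: the partial correlation magnitude equals |r|, so KMO = r^2/(2 r^2)
    R = np.array([[1.0, r], [r, 1.0]])
    assert an.kmo_overall(R) == pytest.approx(0.5, abs=1e-12)


def test_kmo_high_for_strong_one_factor_model():
    lam = np.full((9, 1), 0.8)
    R = lam @ lam.T
    np.fill_diagonal(R, 1.0)
    assert an.kmo_overall(R) > 0.9


def test_kmo_near_identity_is_half_and_unsuitable():
    R = np.full((10, 10), 1e-6)
    np.fill_diagonal(R, 1.0)
    kmo = an.kmo_overall(R)
    assert kmo == pytest.approx(0.5, abs=1e-3)
    assert sampling_adequacy_label(kmo - 0.01) == "unsuitable"


def test_bartlett_df_and_identity_null(spec5_60):
    R = an.implied_correlation(spec5_60)
    chi2, df, p = an.bartlett_sphericity(R, 479)
    assert df == 1770  # p = 60 items
    assert chi2 > 0 and p < 1e-10
    chi2_id, df_id, p_id = an.bartlett_sphericity(np.eye(18), 479)
    assert chi2_id == pytest.approx(0.0, abs=1e-10)
    assert df_id == 153  # p = 18
    assert p_id == pytest.approx(1.0)


def test_kaiser_counts_strictly_above_one(spec5_60):
    assert an.kaiser_nfactors([3.2, 1.5, 1.0, 0.3]) == 2
    assert an.kaiser_nfactors(np.ones(12)) == 0
    eig = np.sort(np.linalg.eigvalsh(an.implied_correlation(spec5_60)))[::-1]
    assert an.kaiser_nfactors(eig) == 5


@pytest.mark.parametrize("p, k, expected", [(60, 5, 1480), (18, 3, 102), (6, 1, 9)])
def test_ml_model_test_df_identity(p, k, expected):
    assert ml_df(p, k) == ((p - k) ** 2 - (p + k)) // 2 == expected


def test_extract_ml_recovers_one_factor_model_exactly():
    lam = np.full((6, 1), 0.7)
    R = lam @ lam.T
    np.fill_diagonal(R, 1.0)
    sol = an.extract_ml(R, 1, 1000)
    assert sol.fit[0] == pytest.approx(0.0, abs=1e-6)  # model-implied input
    assert np.allclose(np.abs(sol.pattern[:, 0]), 0.7, atol=1e-4)


def test_extract_ml_agrees_with_statsmodels_oracle(planted3):
    from statsmodels.multivariate.factor import Factor

    ds = an.simulate_cohort(an.CohortSimSpec(n=2000, model=planted3, seed=61))
    X = ds.responses.to_numpy()
    R = np.corrcoef(X, rowvar=False)
    mine = an.extract_ml(R, 3, X.shape[0])
    sm_res = Factor(corr=R, n_factor=3, method="ml", nobs=X.shape[0]).fit()
    assert np.allclose(mine.uniqueness, sm_res.uniqueness, atol=2e-3)
    # same common part regardless of factor orientation
    common_mine = mine.pattern @ mine.pattern.T
    common_sm = np.asarray(sm_res.loadings) @ np.asarray(sm_res.loadings).T
    assert np.allclose(common_mine, common_sm, atol=2e-3)


def test_varimax_is_fixed_point_on_simple_structure(spec5_60):
    L = spec5_60.loadings
    rotated, _ = varimax(L)
    _, _, congr = match_factors(rotated, L)
    assert np.all(congr > 1 - 1e-8)


def test_promax_recovers_interfactor_correlation(cohort5_5000, spec5_60):
    rep = an.run_efa(cohort5_5000, k=5, rotation="promax")
    phi = rep.solution.factor_corr
    off = phi[np.triu_indices(5, 1)]
    assert np.all(np.abs(off - 0.3) < 0.1)
    _, _, congr = match_factors(rep.solution.pattern, spec5_60.loadings)
    assert np.all(congr >= 0.95)


def test_promax_on_orthogonal_structure_leaves_phi_identity():
    spec = an.planted_module_spec(3, 6, 0.7, 0.0)
    R = an.implied_correlation(spec)
    rot = an.rotate(an.extract_ml(R, 3, 5000), "promax")
    off = rot.factor_corr[np.triu_indices(3, 1)]
    assert np.all(np.abs(off) < 0.05)


def test_communalities_invariant_under_varimax(cohort5_5000):
    rep = an.run_efa(cohort5_5000, k=5, rotation="varimax")
    X = rep  # rotated solution
    unrot = an.extract_ml(
        np.corrcoef(cohort5_5000.responses.to_numpy(), rowvar=False), 5, 5000
    )
    assert np.allclose(X.solution.communality, unrot.communality, atol=1e-8)


@pytest.mark.parametrize(
    "row, designated, expected",
    [
        ((0.8, 0.0, 0.0, 0.0, 0.0), 0, 1.0),
        ((0.6, 0.6), 0, 0.5),
        ((0.5, 0.3, 0.2), 0, 0.25 / 0.38),
    ],
)
def test_factor_purity_examples(row, designated, expected):
    table = factor_purity(np.array([row]), assignment=[designated])
    assert table.per_item["purity"].iloc[0] == pytest.approx(expected, abs=1e-12)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.lists(st.floats(-1, 1, allow_nan=False), min_size=3, max_size=3),
        min_size=2,
        max_size=8,
    )
)
def test_purity_bounded_and_one_iff_single_loading(rows):
    L = np.array(rows)
    table = factor_purity(L)
    vals = table.per_item["purity"].dropna()
    assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()
    for i, v in table.per_item["purity"].items():
        if np.isnan(v):
            continue
        secondary = np.delete(L[i] ** 2, table.per_item["primary_factor"].iloc[i])
        if v == pytest.approx(1.0, abs=1e-12):
            assert np.all(secondary <= 1e-10 * max(L[i] ** 2))


def test_compare_purity_degenerate_equal_groups():
    L = np.array([[0.7, 0.0]] * 3 + [[0.0, 0.7]] * 3)
    table = factor_purity(L)
    out = compare_purity(table, focal_factor=0)
    assert out["anova"]["F"] == 0.0
    assert out["welch"]["t"] == pytest.approx(0.0)
    assert out["welch"]["p"] == pytest.approx(0.5)


def test_compare_purity_zero_variance_guard():
    table = factor_purity(
        np.array([[1.0, 0.0]] * 3 + [[0.5, 0.5]] * 3), assignment=[0] * 3 + [1] * 3
    )
    out = compare_purity(table, focal_factor=0)
    assert out["welch"]["t"] > 1e4  # variance floor keeps t finite but huge
    assert out["welch"]["p"] < 1e-6


def test_welch_statistic_matches_textbook_formula():
    rng = np.random.default_rng(7)
    x = np.clip(rng.normal(0.88, 0.05, size=12), 0.01, 0.99)
    y = np.clip(rng.normal(0.74, 0.12, size=48), 0.01, 0.99)
    # loadings (sqrt(v), sqrt(1-v)) give purity exactly v on the designated factor
    on_designated = np.concatenate([x, y])
    first = np.concatenate([x, 1 - y])  # designated factor differs per group
    L = np.column_stack([np.sqrt(first), np.sqrt(1 - first)])
    table = factor_purity(L, assignment=[0] * 12 + [1] * 48)
    got = table.per_item["purity"].to_numpy()
    assert np.allclose(got, on_designated, atol=1e-12)
    out = compare_purity(table, focal_factor=0)
    # independent hand-coded Welch formula
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / 12 + vy / 48
    t_ref = (x.mean() - y.mean()) / np.sqrt(se2)
    df_ref = se2**2 / ((vx / 12) ** 2 / 11 + (vy / 48) ** 2 / 47)
    assert out["welch"]["t"] == pytest.approx(t_ref, abs=1e-6)
    assert out["welch"]["df"] == pytest.approx(df_ref, abs=1e-6)
    sp = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    assert out["welch"]["t"] == pytest.approx(sp.statistic, abs=1e-6)
    assert out["welch"]["p"] == pytest.approx(sp.pvalue, abs=1e-6)


def test_run_efa_reports_adequacy_on_battery(cohort5_5000):
    rep = an.run_efa(cohort5_5000, k=5)
    assert rep.kmo > 0.9
    assert rep.bartlett[1] == 1770
    assert rep.solution.fit[1] == 1480
    assert rep.n_factors == 5
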