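"""Lifespan scan: kernel windows, ESS gate, weighted networks, purity ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import apathynet as an
from apathynet.lifespan import (
    WindowSpec,
    effective_n,
    mode_sensitivity,
    purity_anova,
    weighted_spearman_network,
    window_weights,
)


@pytest.fixture()
def spec_default():
    return WindowSpec(centers=np.arange(16, 91))


def test_window_weights_kernel_and_truncation(spec_default):
    ages = np.array([50.0, 55.0, 55.01, 44.99, 48.0])
    w = window_weights(ages, 50.0, spec_default)
    assert w[0] == pytest.approx(1.0)
    assert w[1] == pytest.approx(np.exp(-0.5))  # edge of the 10-year window
    assert w[2] == 0.0 and w[3] == 0.0  # truncated just outside
    assert np.all(window_weights(np.array([10.0, 90.0]), 50.0, spec_default) == 0.0)


@pytest.mark.parametrize(
    "weights, expected",
    [(np.ones(50), 50.0), (np.array([1.0, 1.0, 0.0, 0.0]), 2.0), (np.array([1.0, 0.5]), 1.8)],
)
def test_effective_n_kish(weights, expected):
    assert effective_n(weights) == pytest.approx(expected)


def test_uniform_weights_reduce_to_unweighted_network(cohort3_4000):
    unweighted = an.spearman_network(cohort3_4000)
    weighted = weighted_spearman_network(cohort3_4000, np.ones(4000))
    assert np.max(np.abs(weighted.signed_R - unweighted.signed_R)) < 1e-12
    assert np.max(np.abs(weighted.W - unweighted.W)) < 1e-12
    # and the unweighted network agrees with the reference Spearman routine
    ref = stats.spearmanr(cohort3_4000.responses.to_numpy()).statistic
    assert np.max(np.abs(unweighted.signed_R - ref)) < 1e-12


def test_too_small_window_rejected(cohort3_4000):
    w = np.zeros(4000)
    w[:2] = 1.0
    with pytest.raises(ValueError, match="effective sample size"):
        weighted_spearman_network(cohort3_4000, w)


def test_scan_includes_only_centers_near_the_data(planted3):
    spec = an.CohortSimSpec(n=40, model=planted3, age_min=70, age_max=70.0001, seed=91)
    ds = an.simulate_cohort(spec)
    wspec = WindowSpec(centers=np.arange(16, 91))
    traj = an.lifespan_scan(ds, wspec, n_restarts=20, seed=1)
    included = set(traj.included_centers())
    # ages sit just above 70, so centers 66..75 are within the +/- 5 window
    assert included == set(range(66, 76))
    excluded = traj.table[~traj.table["included"]]
    assert excluded["modal_domain"].isna().all()
    assert (traj.table.loc[traj.table["included"], "ess"] >= 30).all()


def test_purity_anova_constant_response_gives_zero_f():
    records = pd.DataFrame({
        "group": ["HC", "HC", "Dep", "Dep"] * 3,
        "domain": ["Social", "Behavioural"] * 6,
        "purity": 0.9,
    })
    table = purity_anova(records)
    assert (table["F"] == 0.0).all()
    assert (table["p"] == 1.0).all()


def test_purity_anova_matches_hand_coded_balanced_two_way():
    rng = np.random.default_rng(19)
    groups, domains, reps = ["HC", "Dep", "NCD"], ["B", "S", "E"], 6
    rows = []
    for g in groups:
        for d in domains:
            for _ in range(reps):
                rows.append({"group": g, "domain": d, "purity": rng.normal(0.8, 0.1)})
    df = pd.DataFrame(rows)
    table = purity_anova(df)

    # independent textbook computation (balanced design: classical = Type II)
    y = df["purity"].to_numpy()
    grand = y.mean()
    a, b, n = len(groups), len(domains), reps
    mg = df.groupby("group")["purity"].mean()
    md = df.groupby("domain")["purity"].mean()
    mgd = df.groupby(["group", "domain"])["purity"].mean()
    ss_a = b * n * sum((mg[g] - grand) ** 2 for g in groups)
    ss_b = a * n * sum((md[d] - grand) ** 2 for d in domains)
    ss_ab = n * sum(
        (mgd[(g, d)] - mg[g] - md[d] + grand) ** 2 for g in groups for d in domains
    )
    ss_err = sum(
        (row["purity"] - mgd[(row["group"], row["domain"])]) ** 2
        for _, row in df.iterrows()
    )
    ms_err = ss_err / (a * b * (n - 1))
    f_a = (ss_a / (a - 1)) / ms_err
    f_b = (ss_b / (b - 1)) / ms_err
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / ms_err
    assert table.loc["C(group)", "F"] == pytest.approx(f_a, abs=1e-8)
    assert table.loc["C(domain)", "F"] == pytest.approx(f_b, abs=1e-8)
    assert table.loc["C(group):C(domain)", "F"] == pytest.approx(f_ab, abs=1e-8)


def test_purity_anova_drops_interaction_for_empty_cells():
    records = pd.DataFrame({
        "group": ["HC"] * 6 + ["Dep"] * 3,
        "domain": ["B", "S", "E"] * 2 + ["B"] * 3,  # Dep x S and Dep x E empty
        "purity": np.linspace(0.5, 1.0, 9),
    })
    with pytest.warns(UserWarning, match="interaction"):
        table = purity_anova(records)
    assert not any("C(group):C(domain)" in str(ix) for ix in table.index)


def test_mode_split_same_generator_agrees(planted3):
    ds = an.simulate_cohort(
        an.CohortSimSpec(
            n=1200, model=planted3, seed=95,
            mode_probs={"online": 0.5, "in_person": 0.5},
        )
    )
    report = mode_sensitivity(ds, n_restarts=100, seed=2)
    agr = report["agreement"]
    assert agr["identical"] and agr["ari"] == pytest.approx(1.0)
    assert agr["per_item"]["concordant"].all()
    for r in report["modes"].values():
        assert {m.modal_domain for m in r["modules"]} == {"Behavioural", "Social", "Emotional"}


def test_mode_split_localises_single_rewired_item(ami_scale):
    from apathynet.simulate import stack_cohorts

    base = an.scale_factor_spec(ami_scale, 0.7, 0.3)
    rewired = base.loadings.copy()
    items = list(base.item_ids)
    i6 = items.index("AMI-6")
    # AMI-6 leaves its Emotional factor and joins the Behavioural one
    emo_col = np.argmax(base.loadings[i6])
    beh_col = np.argmax(base.loadings[items.index("AMI-9")])
    rewired[i6, emo_col] = 0.0
    rewired[i6, beh_col] = 0.7
    from apathynet.simulate import FactorModelSpec

    model_b = FactorModelSpec(rewired, base.factor_corr, base.thresholds,
                              base.item_ids, base.domain_of)
    ds_a = an.simulate_cohort(an.CohortSimSpec(n=1500, model=base, seed=96,
                                               mode_probs={"online": 1.0}))
    ds_b = an.simulate_cohort(an.CohortSimSpec(n=1500, model=model_b, seed=97,
                                               mode_probs={"in_person": 1.0}))
    report = mode_sensitivity(stack_cohorts([ds_a, ds_b]), n_restarts=100, seed=3)
    per_item = report["agreement"]["per_item"].set_index("item")
    assert not per_item.loc["AMI-6", "concordant"]
    assert per_item.drop("AMI-6")["concordant"].all()


def test_missing_mode_metadata_rejected(cohort3_4000):
    with pytest.raises(ValueError, match="mode metadata"):
        mode_sensitivity(cohort3_4000, n_restarts=5)
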