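"""Survival pipeline: censoring, splitting, Cox screening, CV, risk score."""

import itertools

import numpy as np
import pandas as pd
import pytest

from immunogradient import (
    CohortSpec,
    censor_rfs,
    cross_validate,
    enumerate_models,
    fit_and_filter,
    harrell_c,
    km_logrank,
    risk_score,
    select_features,
    simulate_cohort,
    split_cohort,
    tertile_stratify,
    univariable_cox,
)
from immunogradient.survival import CoxModelResult, rank_models_by_cv

from ._oracles import brute_force_concordance


# ---------------------------------------------------------------------------
# censoring and splitting
# ---------------------------------------------------------------------------

def test_censor_rfs_rules():
    df = pd.DataFrame({"rfs_months": [72.0, 16.6, 60.0], "event": [1, 1, 1]})
    out = censor_rfs(df, 60.0)
    assert out.loc[0, "rfs_months"] == 60.0 and out.loc[0, "event"] == 0
    assert out.loc[1, "rfs_months"] == 16.6 and out.loc[1, "event"] == 1
    assert out.loc[2, "event"] == 1  # exactly at horizon: unchanged
    # infinite horizon is the identity
    pd.testing.assert_frame_equal(censor_rfs(df, np.inf), df)
    with pytest.raises(ValueError):
        censor_rfs(df, 0.0)


def test_censoring_horizon_invariant():
    cohort = simulate_cohort(CohortSpec(n=300, seed=5))
    out = censor_rfs(cohort, 60.0)
    assert (out.loc[out["event"] == 1, "rfs_months"] <= 60.0).all()
    assert (out["rfs_months"] <= 60.0).all()


def test_split_cohort_stratification_and_determinism():
    cohort = simulate_cohort(CohortSpec(n=157, seed=11))
    train, test = split_cohort(cohort, 117, 40, seed=3)
    assert len(train) == 117 and len(test) == 40
    # event proportions within one event's worth
    assert abs(train["event"].mean() - test["event"].mean()) < 1 / 40
    train2, test2 = split_cohort(cohort, 117, 40, seed=3)
    pd.testing.assert_frame_equal(train, train2)
    with pytest.raises(ValueError):
        split_cohort(cohort, 100, 40, seed=3)


def test_split_all_event_cohort():
    df = pd.DataFrame({"rfs_months": np.arange(1, 11.0), "event": 1})
    train, test = split_cohort(df, 7, 3, seed=0)
    assert train["event"].all() and test["event"].all()


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def test_concordance_trivial_cases():
    assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0
    assert harrell_c([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5
    with pytest.raises(ValueError):
        harrell_c([1.0], [1.0], [1])
    with pytest.raises(ValueError):
        harrell_c([1, 2], [1, 2], [0, 0])  # all censored: no comparable pairs


def test_concordance_equals_brute_force_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        n = rng.integers(5, 51)
        times = rng.random(n) * 60
        events = rng.random(n) < 0.6
        risks = rng.random(n)
        if events.sum() == 0:
            continue
        assert harrell_c(risks, times, events) == pytest.approx(
            brute_force_concordance(risks, times, events), abs=1e-12
        )


# ---------------------------------------------------------------------------
# univariable screening
# ---------------------------------------------------------------------------

def test_univariable_cox_recovers_binary_effect():
    rng = np.random.default_rng(1)
    n = 2000
    x = (rng.random(n) < 0.5).astype(int)
    t = rng.exponential(1 / (0.02 * np.exp(np.log(2) * x)))
    df = pd.DataFrame(
        {"rfs_months": np.minimum(t, 60), "event": (t <= 60).astype(int), "x": x}
    )
    res = univariable_cox(df, "x")
    assert res.hr["x"] == pytest.approx(2.0, rel=0.15)
    assert res.p["x"] < 0.001
    assert res.aic == pytest.approx(2 * 1 - 2 * res.log_likelihood)


def test_univariable_cox_constant_covariate_raises():
    df = pd.DataFrame({"rfs_months": [1.0, 2, 3, 4], "event": [1, 0, 1, 0], "x": 1})
    with pytest.raises(ValueError):
        univariable_cox(df, "x")


def test_select_features_strict_inequality():
    def res(feature, p):
        return CoxModelResult(
            covariates=(feature,), hr={feature: 1.5}, p={feature: p},
            coef={feature: 0.4}, se={feature: 0.1},
            ci_lower={feature: 1.0}, ci_upper={feature: 2.0},
            log_likelihood=-10.0, aic=22.0, n=100, n_events=20,
        )

    results = {"a": res("a", 0.003), "b": res("b", 0.0126), "c": res("c", 0.051)}
    assert select_features(results, 0.05) == ["a", "b"]
    assert select_features({}, 0.05) == []


# ---------------------------------------------------------------------------
# enumeration, filtering, cross-validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k,expected", [(3, 4), (1, 0), (6, 57)])
def test_enumerate_models_counts(k, expected):
    feats = [f"f{i}" for i in range(k)]
    assert len(enumerate_models(feats)) == expected


def test_fit_and_filter_keeps_generating_model_drops_noise():
    cohort = simulate_cohort(CohortSpec(n=400, seed=21))
    combos = [
        ("retur_or_recurrent", "g3", "id_value"),
        ("retur_or_recurrent", "g3", "id_value", "cis"),
    ]
    kept = fit_and_filter(cohort, combos, alpha=0.05)
    names = {tuple(m.covariates) for m in kept}
    assert ("retur_or_recurrent", "g3", "id_value") in names
    for m in kept:
        assert all(p < 0.05 for p in m.p.values())
        assert m.aic == pytest.approx(
            2 * len(m.covariates) - 2 * m.log_likelihood
        )


def test_collinear_duplicate_covariates_filtered():
    cohort = simulate_cohort(CohortSpec(n=300, seed=8)).copy()
    cohort["id_copy"] = cohort["id_value"]
    kept = fit_and_filter(cohort, [("id_value", "id_copy")], alpha=0.05)
    assert kept == []  # dropped via convergence flag or significance filter
    assert fit_and_filter(cohort, []) == []


def test_cross_validation_perfect_and_degenerate():
    n = 60
    rng = np.random.default_rng(4)
    risk = np.linspace(3, 0.2, n)
    df = pd.DataFrame(
        {
            "rfs_months": np.exp(-risk) * 50 + rng.random(n) * 1e-6,
            "event": 1,
            "x": risk,
        }
    )
    mean_c, fold_cs = cross_validate(df, ("x",), k=5, seed=0)
    assert mean_c == 1.0
    assert len(fold_cs) == 5
    with pytest.raises(ValueError):
        cross_validate(df, ("x",), k=n, seed=0)


def test_random_risk_score_has_chance_concordance():
    rng = np.random.default_rng(9)
    n = 2000
    df = pd.DataFrame(
        {
            "rfs_months": rng.exponential(30, n),
            "event": (rng.random(n) < 0.7).astype(int),
            "x": rng.random(n),
        }
    )
    c = harrell_c(df["x"], df["rfs_months"], df["event"])
    assert c == pytest.approx(0.5, abs=0.05)


def test_rank_models_by_cv_orders_best_first():
    cohort = simulate_cohort(CohortSpec(n=400, seed=33))
    combos = [("retur_or_recurrent", "g3"), ("retur_or_recurrent", "g3", "id_value")]
    kept = fit_and_filter(cohort, combos)
    ranked = rank_models_by_cv(cohort, kept, k=5, seed=1)
    cs = [m.mean_validation_c for m in ranked]
    assert cs == sorted(cs, reverse=True)
    assert all(0 <= c <= 1 for c in cs)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def test_km_no_censoring_equals_empirical_survival():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    df = pd.DataFrame({"rfs_months": times, "event": 1})
    curves, _ = km_logrank(df, np.zeros(5, dtype=int))
    curve = curves["0"]
    # step function dropping 1/n per event
    surv = dict(zip(curve["time"], curve["survival"]))
    for k, t in enumerate(times, start=1):
        assert surv[t] == pytest.approx(1 - k / 5)


def test_logrank_detects_strong_hazard_ratio():
    rng = np.random.default_rng(10)
    n = 200
    group = np.repeat([0, 1], n // 2)
    t = rng.exponential(1 / (0.02 * np.exp(np.log(4) * group)))
    df = pd.DataFrame(
        {"rfs_months": np.minimum(t, 60), "event": (t <= 60).astype(int)}
    )
    _, pvals = km_logrank(df, group)
    assert pvals.loc[0, "p"] < 0.05


# ---------------------------------------------------------------------------
# tertiles and risk score
# ---------------------------------------------------------------------------

def test_tertile_sizes():
    labels9 = tertile_stratify(np.arange(9.0))
    assert [list(labels9).count(g) for g in ("low", "medium", "high")] == [3, 3, 3]
    labels10 = tertile_stratify(np.arange(10.0))
    assert [list(labels10).count(g) for g in ("low", "medium", "high")] == [4, 3, 3]
    # ordering respected
    v = np.array([5.0, 1.0, 9.0, 2.0, 8.0, 3.0])
    lab = tertile_stratify(v)
    assert set(v[lab == "low"]) == {1.0, 2.0}
    assert set(v[lab == "high"]) == {8.0, 9.0}


def test_tertile_degenerate_flagged():
    with pytest.warns(UserWarning, match="degenerate"):
        tertile_stratify(np.ones(9))


def test_risk_score_full_mapping():
    for g3, hist, tert in itertools.product(
        (False, True), (False, True), ("low", "medium", "high")
    ):
        rs = risk_score(
            {"grade": "G3" if g3 else "G2", "retur_or_recurrent": hist, "id_tertile": tert}
        )
        expected_points = int(g3) + int(hist) + int(tert != "low")
        assert rs.points == expected_points
        assert rs.category == {0: "low", 1: "low", 2: "intermediate", 3: "high"}[
            expected_points
        ]
    with pytest.raises(ValueError):
        risk_score({"grade": "G3", "retur_or_recurrent": 1, "id_tertile": "mid"})
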