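"""Survival pipeline: events, KM, Cox partial likelihood, stepwise selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from karyolgf.survival import (
    SIX_ABNORMALITIES,
    ClinicalValidationError,
    SurvivalInput,
    build_six_covariates,
    chi2_yates,
    compare_clinical,
    cox_fit,
    cox_univariate,
    derive_event,
    km_estimate,
    read_clinical,
    stepwise_aic,
    summarize_cohort,
)


# ---------------------------------------------------------------------------
# clinical table and event derivation

def test_published_clinical_table(clinical):
    assert len(clinical) == 37
    assert sum(r.gender == "M" for r in clinical) == 24


def test_missing_interval_is_none_not_zero(clinical):
    by_id = {r.case_id: r for r in clinical}
    assert by_id["17"].interval_months is None
    assert by_id["30"].interval_months is None
    assert by_id["1"].interval_months == 0


def test_negative_os_rejected(tmp_path):
    src = read_clinical.__module__  # noqa: F841  (documented schema below)
    p = tmp_path / "bad.tsv"
    p.write_text(
        "case_id\tage_years\tgender\tinterval_months\tdiagnosis\tprior_treatment\t"
        "treatment\ttnt_clone_size_pct\ttnt_persistence\tos_months\toutcome\n"
        "1\t60\tM\t0\tAML\tNo\tChemo\t50\tNo\t-1\tDOD\n"
    )
    with pytest.raises(ClinicalValidationError, match="case 1"):
        read_clinical(p)


def test_event_derivation(clinical):
    by_id = {r.case_id: r for r in clinical}
    assert derive_event(by_id["22"]) == SurvivalInput(146.0, 0)  # ANED censors
    assert derive_event(by_id["1"]) == SurvivalInput(2.5, 1)  # DOD is the event
    assert derive_event(by_id["10"]) == SurvivalInput(3.0, 0)  # hospice censors


def test_published_cohort_has_25_events(clinical):
    assert sum(derive_event(r).event for r in clinical) == 25


def test_cohort_summary_published_values(clinical):
    s = summarize_cohort(clinical)
    assert s["age_mean"] == pytest.approx(66.7, abs=0.05)
    assert s["age_range"] == (24, 89)
    assert s["clone_size_mean"] == pytest.approx(52, abs=0.5)
    assert s["clone_size_range"] == (5, 100)
    assert s["interval_mean"] == pytest.approx(5.36, abs=0.01)
    assert s["dod_median_os"] == 4
    assert s["dod_os_range"] == (1, 27)
    assert s["n_presented_at_diagnosis"] == 27


def test_clinical_comparison_tests():
    # published 2x2 tables: prior treatment and gender between the two cohorts
    chi2, p = chi2_yates([[27, 8], [19, 19]])
    assert p == pytest.approx(0.03, abs=0.005)
    _, p = chi2_yates([[13, 24], [12, 26]])
    assert p == pytest.approx(0.93, abs=0.01)


def test_compare_clinical_identical_cohorts(clinical):
    out = compare_clinical(clinical, clinical)
    tested = out[out.test != "skipped (constant)"]
    assert (tested.p_value > 0.9).all()


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_reduces_to_empirical_survivor_without_censoring():
    times = [1.0, 2.0, 3.0, 4.0, 5.0]
    inputs = [SurvivalInput(t, 1) for t in times]
    km = km_estimate(inputs)["all"]
    # step curve dropping 1/n at each event
    for t, s in zip(km["timeline"], km["survival"]):
        assert s == pytest.approx(np.mean([x > t for x in times]))
    assert km["median"] == 3.0


def test_km_flat_until_first_event():
    inputs = [SurvivalInput(1, 0), SurvivalInput(2, 0), SurvivalInput(5, 1),
              SurvivalInput(6, 1)]
    km = km_estimate(inputs)["all"]
    s = dict(zip(km["timeline"], km["survival"]))
    assert all(v == 1.0 for t, v in s.items() if t < 5)


def test_km_median_matches_exponential_closed_form():
    rng = np.random.default_rng(42)
    lam = 0.2
    t = rng.exponential(1 / lam, size=500)
    km = km_estimate([SurvivalInput(x, 1) for x in t])["all"]
    assert abs(km["median"] - math.log(2) / lam) / (math.log(2) / lam) < 0.10


def test_km_requires_an_event():
    with pytest.raises(ValueError):
        km_estimate([SurvivalInput(3, 0)])


# ---------------------------------------------------------------------------
# Cox partial likelihood

def brute_force_efron_loglik(beta, x, time, event):
    """Textbook Efron partial log-likelihood, written independently."""
    ll = 0.0
    for t in sorted({ti for ti, e in zip(time, event) if e}):
        risk = [i for i in range(len(time)) if time[i] >= t]
        deaths = [i for i in range(len(time)) if time[i] == t and event[i]]
        d = len(deaths)
        s_r = sum(math.exp(beta * x[i]) for i in risk)
        s_d = sum(math.exp(beta * x[i]) for i in deaths)
        ll += sum(beta * x[i] for i in deaths)
        for l in range(d):
            ll -= math.log(s_r - (l / d) * s_d)
    return ll


@pytest.mark.parametrize(
    "x,time,event",
    [
        ([1, 0, 1, 0, 1], [2, 3, 5, 7, 11], [1, 1, 1, 1, 1]),
        ([1, 0, 1, 0, 1], [2, 2, 5, 5, 7], [1, 1, 0, 1, 1]),  # ties + censoring
        ([0, 0, 1, 1, 1, 0], [1, 4, 4, 4, 6, 9], [1, 1, 1, 0, 1, 1]),
    ],
)
def test_cox_matches_brute_force_partial_likelihood(x, time, event):
    x = np.array(x, float)
    time = np.array(time, float)
    event = np.array(event, int)
    fit = cox_fit(x[:, None], time, event)
    # the likelihood function itself agrees to 4 significant figures
    for beta in (-1.0, -0.3, 0.0, 0.4, 1.2):
        from karyolgf.survival import _cox_quantities

        mine = _cox_quantities(np.array([beta]), x[:, None], time, event)[0]
        oracle = brute_force_efron_loglik(beta, x, time, event)
        assert mine == pytest.approx(oracle, rel=1e-9)
    # and the fitted coefficient maximizes the oracle on a fine grid
    grid = np.linspace(-3, 3, 1201)
    best = grid[np.argmax([brute_force_efron_loglik(b, x, time, event) for b in grid])]
    assert fit["beta"][0] == pytest.approx(best, abs=0.01)


def test_cox_matches_lifelines_on_tied_data():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(7)
    n = 150
    x = rng.binomial(1, 0.4, n).astype(float)
    t = np.ceil(rng.exponential(1 / (0.1 * np.exp(0.6 * x))))
    c = np.ceil(rng.exponential(25, n))
    time, event = np.minimum(t, c), (t <= c).astype(int)
    fit = cox_fit(x[:, None], time, event)
    cph = CoxPHFitter().fit(
        pd.DataFrame({"x": x, "T": time, "E": event}), "T", "E"
    )
    assert fit["beta"][0] == pytest.approx(cph.params_["x"], abs=1e-5)
    assert fit["loglik"] == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_cox_score_test_equals_logrank_for_binary_covariate():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(13)
    n = 120
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))  # continuous: no ties
    time, event = t, np.ones(n, int)
    fit = cox_fit(x[:, None], time, event, ties="breslow")
    lr = logrank_test(time[x == 1], time[x == 0], event[x == 1], event[x == 0])
    assert fit["score_statistic"] == pytest.approx(lr.test_statistic, rel=1e-6)


def test_cox_constant_covariate_errors():
    with pytest.raises(ValueError, match="constant"):
        cox_fit(np.ones((10, 1)), np.arange(1, 11, dtype=float), np.ones(10, int))


def test_cox_monotone_likelihood_flagged():
    # perfect separation: all deaths in one arm, far earlier
    time = np.array([1, 2, 3, 100, 110, 120], float)
    event = np.array([1, 1, 1, 0, 0, 0], int)
    x = np.array([1, 1, 1, 0, 0, 0], float)
    r = cox_univariate([SurvivalInput(t, e) for t, e in zip(time, event)], x)
    assert r.flagged


def test_cox_null_coverage_over_replicates():
    """Independent covariate: fitted HR lands in [0.8, 1.25] in >=90% of
    100 seeded replicates at n=300."""
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(3000 + rep)
        n = 300
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(10, n)
        fit = cox_fit(x[:, None], t, np.ones(n, dtype=int))
        hr = math.exp(fit["beta"][0])
        hits += 0.8 <= hr <= 1.25
    assert hits >= 90


def test_planted_hazard_ratios_recovered_on_average():
    """log-HR estimates average within 10% of truth for HR in {1.5, 2, 3}."""
    for hr in (1.5, 2.0, 3.0):
        logs = []
        for rep in range(200):
            rng = np.random.default_rng(int(hr * 1000) + rep)
            n = 400
            x = rng.binomial(1, 0.4, n).astype(float)
            t = rng.exponential(1 / (0.08 * np.exp(math.log(hr) * x)))
            c = rng.exponential(1 / 0.035, n)  # ~30% censoring
            time, event = np.minimum(t, c), (t <= c).astype(int)
            logs.append(cox_fit(x[:, None], time, event)["beta"][0])
        assert abs(np.mean(logs) - math.log(hr)) / math.log(hr) < 0.10, hr


# ---------------------------------------------------------------------------
# six-abnormality covariates

def test_six_covariates_on_published_cohort(osu_matrix, ref):
    six = build_six_covariates(osu_matrix, ref)
    assert list(six.columns[:6]) == list(SIX_ABNORMALITIES)
    assert six.loc["6", "minus5"] == 1  # "idem,-2,-5,-5,-7" sideline
    assert six.loc["27", "any_of_six"] == 0  # balanced tetraploid
    assert (six.any_of_six == (six.count_of_six > 0).astype(int)).all()


def test_six_covariates_all_zero_and_all_planted(ref, records_by_id):
    from karyolgf.lgf import build_matrix
    from karyolgf import parse_karyotype

    balanced = parse_karyotype("z", "92<4n>,XXYY[10]")
    planted = parse_karyotype(
        "p",
        "40,XY,-5,-16,-18,+8,del(11)(p15.1p15.4),del(13)(q12.11q22.3)[10]",
    )
    m = build_matrix([balanced, planted], ref=ref)
    six = build_six_covariates(m, ref)
    assert six.loc["z", "count_of_six"] == 0 and six.loc["z", "any_of_six"] == 0
    assert six.loc["p", "count_of_six"] == 6


# ---------------------------------------------------------------------------
# stepwise AIC

def _sim_survival(rng, X, betas, base=0.08, censor=0.03):
    eta = X @ betas
    t = rng.exponential(1 / (base * np.exp(eta)))
    c = rng.exponential(1 / censor, len(t))
    return np.minimum(t, c), (t <= c).astype(int)


def test_stepwise_empty_candidates_returns_null_model():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"x": rng.binomial(1, 0.5, 50).astype(float)})
    time, event = _sim_survival(rng, X.to_numpy(), np.array([0.0]))
    out = stepwise_aic(
        [SurvivalInput(t, e) for t, e in zip(time, event)], X, candidates=[]
    )
    assert out["selected"] == [] and out["trace"][0]["move"] == "start"


def test_stepwise_duplicate_covariate_keeps_first():
    rng = np.random.default_rng(1)
    x = rng.binomial(1, 0.5, 300).astype(float)
    X = pd.DataFrame({"first_copy": x, "second_copy": x})
    time, event = _sim_survival(rng, x[:, None], np.array([1.0]))
    out = stepwise_aic(
        [SurvivalInput(t, e) for t, e in zip(time, event)], X
    )
    assert out["selected"] == ["first_copy"]


def test_stepwise_deterministic():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(
        {f"x{i}": rng.binomial(1, 0.5, 200).astype(float) for i in range(4)}
    )
    time, event = _sim_survival(rng, X.to_numpy(), np.array([0.9, 0, 0, 0]))
    inputs = [SurvivalInput(t, e) for t, e in zip(time, event)]
    a = stepwise_aic(inputs, X)
    b = stepwise_aic(inputs, X)
    assert a["selected"] == b["selected"]
    assert [t["aic"] for t in a["trace"]] == [t["aic"] for t in b["trace"]]


def test_stepwise_recovers_true_covariate():
    """One planted covariate (log-HR 1.0) among five noise covariates is
    retained in >=90% of 100 seeded replicates at n=400."""
    retained = 0
    for rep in range(100):
        rng = np.random.default_rng(7000 + rep)
        n = 400
        X = pd.DataFrame(
            {"true_factor": rng.binomial(1, 0.5, n).astype(float)}
            | {f"noise{i}": rng.binomial(1, 0.5, n).astype(float) for i in range(5)}
        )
        betas = np.array([1.0, 0, 0, 0, 0, 0])
        time, event = _sim_survival(rng, X.to_numpy(), betas)
        out = stepwise_aic(
            [SurvivalInput(t, e) for t, e in zip(time, event)], X
        )
        retained += "true_factor" in out["selected"]
    assert retained >= 90
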