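"""Clinical data model and overall-survival analysis.

Implements the survival pipeline used on the T/NT cohort: outcome-code event
derivation (death of disease = event, everything else censored at last
follow-up), Kaplan-Meier estimation, univariate Cox proportional-hazards
screening with the partial-likelihood score (log-rank) test, bidirectional
stepwise model selection by AIC, the six-abnormality combined covariates
(-5, -16, -18, del(11)(p15.1p15.4), del(13)(q12.11q22.3), +8), and the
standard clinical covariate comparisons (Welch t-test; chi-squared with Yates
continuity correction for 2x2 tables).

The Cox fitter is a Newton-Raphson maximizer of the Efron-tie partial
likelihood written here in numpy (months-resolution survival times are
heavily tied); the Breslow approximation is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cytoband import CytobandReference, bands_in_interval
from .lgf import LGFMatrix

OUTCOME_CODES = ("DOD", "ANED", "AWD", "LFU", "LFU_hospice")

SIX_ABNORMALITIES = ("minus5", "minus16", "minus18", "del11p", "del13q", "plus8")


class ClinicalValidationError(ValueError):
    pass


@dataclass
class ClinicalRecord:
    case_id: str
    age_years: float
    gender: str  # "M" | "F"
    interval_months: float | None
    diagnosis: str
    prior_treatment: str | None  # "yes" | "no" | None
    treatment: frozenset  # subset of {"chemo", "sct", "none"}
    tnt_clone_size_pct: float
    tnt_persistence: str | None
    os_months: float
    outcome_code: str
    cohort: str = "OSU"


@dataclass
class SurvivalInput:
    time: float
    event: int  # 1 = death from disease observed, 0 = censored


@dataclass
class UnivariateResult:
    factor: str
    n: int
    deaths: int
    coefficient: float
    hazard_ratio: float
    score_statistic: float
    p_value: float
    levels: dict = field(default_factory=dict)  # label -> {n, deaths, median_survival}
    flagged: bool = False  # monotone likelihood / non-convergence


# ---------------------------------------------------------------------------
# clinical table IO

def _norm_outcome(raw: str) -> str:
    s = str(raw).strip().replace("—", "-")  # em-dash
    if s.lower().startswith("lfu") and "hospice" in s.lower():
        return "LFU_hospice"
    s = s.upper()
    if s not in OUTCOME_CODES:
        raise ClinicalValidationError(f"unknown outcome code {raw!r}")
    return s


def _norm_treatment(raw: str) -> frozenset:
    s = str(raw).strip().lower()
    if s in ("no", "none", ""):
        return frozenset({"none"})
    parts = {p.strip() for p in s.split(",")}
    out = set()
    for p in parts:
        if p == "chemo":
            out.add("chemo")
        elif p == "sct":
            out.add("sct")
        elif p:
            raise ClinicalValidationError(f"unknown treatment {raw!r}")
    return frozenset(out)


def read_clinical(source: str | Path | None = None) -> list[ClinicalRecord]:
    """Read a clinical table (packaged cohort table when source is None).

    "NA" fields parse as missing, never as zero. Malformed rows raise a
    row-level error naming the case.
    """
    if source is None:
        source = Path(str(resources.files("karyolgf.data").joinpath("table1_clinical.tsv")))
    sep = "," if str(source).endswith(".csv") else "\t"
    df = pd.read_csv(source, sep=sep, comment="#", dtype={"case_id": str})
    required = [
        "case_id", "age_years", "gender", "interval_months", "diagnosis",
        "prior_treatment", "treatment", "tnt_clone_size_pct", "tnt_persistence",
        "os_months", "outcome",
    ]
    for col in required:
        if col not in df.columns:
            raise ClinicalValidationError(f"clinical table missing column {col!r}")
    records = []
    for row in df.itertuples():
        cid = str(row.case_id)
        try:
            age = float(row.age_years)
            os_months = float(row.os_months)
            clone = float(row.tnt_clone_size_pct)
            if age <= 0:
                raise ClinicalValidationError("age must be positive")
            if os_months < 0:
                raise ClinicalValidationError("os_months must be >= 0")
            if not 0 <= clone <= 100:
                raise ClinicalValidationError("tnt_clone_size_pct must be in [0, 100]")
            gender = str(row.gender).strip().upper()
            if gender not in ("M", "F"):
                raise ClinicalValidationError(f"unknown gender {row.gender!r}")
            interval = None if pd.isna(row.interval_months) else float(row.interval_months)
            prior = (
                None
                if pd.isna(row.prior_treatment)
                else {"yes": "yes", "no": "no"}[str(row.prior_treatment).strip().lower()]
            )
            persist = (
                None
                if pd.isna(row.tnt_persistence)
                else str(row.tnt_persistence).strip().lower()
            )
            records.append(
                ClinicalRecord(
                    case_id=cid,
                    age_years=age,
                    gender=gender,
                    interval_months=interval,
                    diagnosis=str(row.diagnosis),
                    prior_treatment=prior,
                    treatment=_norm_treatment(row.treatment),
                    tnt_clone_size_pct=clone,
                    tnt_persistence=persist,
                    os_months=os_months,
                    outcome_code=_norm_outcome(row.outcome),
                    cohort=str(getattr(row, "cohort", "OSU")),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ClinicalValidationError(f"case {cid}: {exc}") from exc
    return records


def derive_event(record: ClinicalRecord) -> SurvivalInput:
    """Death of disease is the event; all other outcomes censor at os_months."""
    return SurvivalInput(time=record.os_months, event=1 if record.outcome_code == "DOD" else 0)


# ---------------------------------------------------------------------------
# cohort summaries and clinical comparisons

def summarize_cohort(records: list[ClinicalRecord]) -> dict:
    if not records:
        raise ValueError("no clinical records")
    ages = [r.age_years for r in records]
    sizes = [r.tnt_clone_size_pct for r in records]
    intervals = [r.interval_months for r in records if r.interval_months is not None]
    dod_os = [r.os_months for r in records if r.outcome_code == "DOD"]
    out = {
        "n": len(records),
        "n_male": sum(r.gender == "M" for r in records),
        "n_female": sum(r.gender == "F" for r in records),
        "age_mean": float(np.mean(ages)),
        "age_range": (min(ages), max(ages)),
        "interval_mean": float(np.mean(intervals)) if intervals else None,
        "interval_range": (min(intervals), max(intervals)) if intervals else None,
        "interval_n": len(intervals),
        "clone_size_mean": float(np.mean(sizes)),
        "clone_size_range": (min(sizes), max(sizes)),
        "outcome_counts": {
            code: sum(r.outcome_code == code for r in records) for code in OUTCOME_CODES
        },
        "dod_median_os": float(np.median(dod_os)) if dod_os else None,
        "dod_os_range": (min(dod_os), max(dod_os)) if dod_os else None,
        "n_presented_at_diagnosis": sum(
            r.interval_months == 0 and r.prior_treatment == "no" for r in records
        ),
        "diagnosis_counts": {},
        "treatment_counts": {
            "chemo": sum("chemo" in r.treatment for r in records),
            "sct": sum("sct" in r.treatment for r in records),
            "none": sum(r.treatment == frozenset({"none"}) for r in records),
        },
    }
    for r in records:
        out["diagnosis_counts"][r.diagnosis] = out["diagnosis_counts"].get(r.diagnosis, 0) + 1
    return out


def welch_t(a, b) -> tuple[float, float]:
    t, p = stats.ttest_ind(list(a), list(b), equal_var=False)
    return float(t), float(p)


def chi2_yates(table) -> tuple[float, float]:
    """Chi-squared test with Yates continuity correction (2x2) or Pearson otherwise."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=True)
    return float(chi2), float(p)


def compare_clinical(
    records_a: list[ClinicalRecord], records_b: list[ClinicalRecord]
) -> pd.DataFrame:
    """Per-covariate cohort comparison; missing values dropped pairwise."""
    rows = []

    def cont(name, getter):
        a = [getter(r) for r in records_a if getter(r) is not None]
        b = [getter(r) for r in records_b if getter(r) is not None]
        if len(set(a + b)) < 2:
            rows.append({"covariate": name, "test": "skipped (constant)", "n_a": len(a),
                         "n_b": len(b), "statistic": np.nan, "p_value": np.nan})
            return
        t, p = welch_t(a, b)
        rows.append({"covariate": name, "test": "welch_t", "n_a": len(a), "n_b": len(b),
                     "statistic": t, "p_value": p})

    def cat(name, getter, positive):
        a = [getter(r) for r in records_a if getter(r) is not None]
        b = [getter(r) for r in records_b if getter(r) is not None]
        table = [
            [sum(v == positive for v in a), sum(v != positive for v in a)],
            [sum(v == positive for v in b), sum(v != positive for v in b)],
        ]
        if 0 in [sum(col) for col in zip(*table)]:
            rows.append({"covariate": name, "test": "skipped (constant)", "n_a": len(a),
                         "n_b": len(b), "statistic": np.nan, "p_value": np.nan})
            return
        chi2, p = chi2_yates(table)
        rows.append({"covariate": name, "test": "chi2_yates", "n_a": len(a),
                     "n_b": len(b), "statistic": chi2, "p_value": p})

    cont("age_years", lambda r: r.age_years)
    cont("interval_months", lambda r: r.interval_months)
    cont("tnt_clone_size_pct", lambda r: r.tnt_clone_size_pct)
    cat("gender", lambda r: r.gender, "F")
    cat("prior_treatment", lambda r: r.prior_treatment, "yes")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_estimate(inputs: list[SurvivalInput], groups=None) -> dict:
    """Product-limit curves and median survival, overall or per group label.

    The median is the earliest time with S(t) <= 0.5 (inf if never reached).
    """
    from lifelines import KaplanMeierFitter

    if not any(si.event for si in inputs):
        raise ValueError("Kaplan-Meier estimation needs at least one event")
    times = np.array([si.time for si in inputs], dtype=float)
    events = np.array([si.event for si in inputs], dtype=int)
    if groups is None:
        groups = ["all"] * len(inputs)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        sf = kmf.survival_function_.iloc[:, 0]
        out[g] = {
            "timeline": sf.index.to_numpy(dtype=float),
            "survival": sf.to_numpy(dtype=float),
            "median": float(kmf.median_survival_time_),
            "n": int(mask.sum()),
            "deaths": int(events[mask].sum()),
        }
    return out


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties) and the score test

def _cox_quantities(beta, X, time, event, ties: str = "efron"):
    """Efron/Breslow partial log-likelihood, gradient and information.

    Vectorized over tied-time groups: risk-set sums are suffix sums over the
    groups, and the Efron within-tie corrections are expanded to one row per
    death so every quantity reduces to array operations.
    """
    beta = np.asarray(beta, dtype=float)
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)

    order = np.argsort(time, kind="stable")  # ascending time
    Xo, to, eo, wo, etao = X[order], time[order], event[order], w[order], eta[order]

    # group rows by tied time
    starts = np.flatnonzero(np.r_[True, to[1:] != to[:-1]])
    wX = wo[:, None] * Xo
    wXX = wo[:, None, None] * (Xo[:, :, None] * Xo[:, None, :])

    gs = np.add.reduceat(wo, starts)
    gG = np.add.reduceat(wX, starts, axis=0)
    gH = np.add.reduceat(wXX, starts, axis=0)
    # suffix sums: risk set at each group's time
    S_r = np.cumsum(gs[::-1])[::-1]
    G_r = np.cumsum(gG[::-1], axis=0)[::-1]
    H_r = np.cumsum(gH[::-1], axis=0)[::-1]

    we = wo * eo
    wXe = wX * eo[:, None]
    wXXe = wXX * eo[:, None, None]
    d_g = np.add.reduceat(eo, starts)
    S_d = np.add.reduceat(we, starts)
    G_d = np.add.reduceat(wXe, starts, axis=0)
    H_d = np.add.reduceat(wXXe, starts, axis=0)
    eta_d = np.add.reduceat(etao * eo, starts)
    x_d = np.add.reduceat(Xo * eo[:, None], starts, axis=0)

    ev = d_g > 0
    d_ev = d_g[ev]
    # one row per death within each tied event group
    gi = np.repeat(np.flatnonzero(ev), d_ev)
    if ties == "efron":
        frac = np.concatenate([np.arange(d) / d for d in d_ev]) if len(d_ev) else np.zeros(0)
    else:
        frac = np.zeros(int(d_ev.sum()))

    denom = S_r[gi] - frac * S_d[gi]
    Gl = G_r[gi] - frac[:, None] * G_d[gi]
    Hl = H_r[gi] - frac[:, None, None] * H_d[gi]
    mu = Gl / denom[:, None]

    ll = float(eta_d[ev].sum() - np.log(denom).sum())
    grad = x_d[ev].sum(axis=0) - mu.sum(axis=0)
    info = (Hl / denom[:, None, None]).sum(axis=0) - np.einsum("ti,tj->ij", mu, mu)
    return ll, grad, info


def cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> dict:
    """Newton-Raphson maximum partial-likelihood fit.

    Returns coefficients, loglik, the score statistic at beta=0, AIC, and a
    `flagged` bool for monotone-likelihood / non-convergence.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events")
    if any(np.ptp(X[:, k]) == 0 for k in range(p)):
        raise ValueError("constant covariate")

    # score test at beta = 0
    ll0, grad0, info0 = _cox_quantities(np.zeros(p), X, time, event, ties)
    try:
        score_stat = float(grad0 @ np.linalg.solve(info0, grad0))
    except np.linalg.LinAlgError:
        score_stat = float("nan")
    score_p = float(stats.chi2.sf(score_stat, df=p)) if np.isfinite(score_stat) else float("nan")

    beta = np.zeros(p)
    ll = ll0
    flagged = False
    for _ in range(max_iter):
        ll, grad, info = _cox_quantities(beta, X, time, event, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flagged = True
            break
        # step-halving to keep the likelihood non-decreasing
        alpha = 1.0
        for _h in range(30):
            cand = beta + alpha * step
            ll_new = _cox_quantities(cand, X, time, event, ties)[0]
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2
        beta = beta + alpha * step
        if np.max(np.abs(alpha * step)) < tol:
            break
        if np.max(np.abs(beta)) > 20:
            flagged = True  # monotone likelihood: coefficient runs away
            break
    ll = _cox_quantities(beta, X, time, event, ties)[0]
    return {
        "beta": beta,
        "loglik": float(ll),
        "loglik_null": float(ll0),
        "score_statistic": score_stat,
        "score_p": score_p,
        "aic": float(-2 * ll + 2 * p),
        "n": n,
        "events": int(event.sum()),
        "flagged": flagged,
    }


def cox_univariate(
    inputs: list[SurvivalInput],
    covariate,
    name: str = "covariate",
    ties: str = "efron",
) -> UnivariateResult:
    """One-covariate Cox screen with the score (log-rank) test at beta=0."""
    time = np.array([si.time for si in inputs], dtype=float)
    event = np.array([si.event for si in inputs], dtype=int)
    x = np.asarray(covariate, dtype=float)
    fit = cox_fit(x[:, None], time, event, ties=ties)
    beta = float(fit["beta"][0])
    levels = {}
    if set(np.unique(x)) <= {0.0, 1.0}:
        for val, label in ((0.0, "absent"), (1.0, "present")):
            mask = x == val
            med = float("inf")
            if event[mask].sum():
                km = km_estimate(
                    [SurvivalInput(t, e) for t, e in zip(time[mask], event[mask])]
                )["all"]
                med = km["median"]
            levels[label] = {
                "n": int(mask.sum()),
                "deaths": int(event[mask].sum()),
                "median_survival": med,
            }
    return UnivariateResult(
        factor=name,
        n=len(inputs),
        deaths=int(event.sum()),
        coefficient=beta,
        hazard_ratio=float(np.exp(beta)),
        score_statistic=float(fit["score_statistic"]),
        p_value=float(fit["score_p"]),
        levels=levels,
        flagged=bool(fit["flagged"]),
    )


# ---------------------------------------------------------------------------
# six-abnormality covariates

def build_six_covariates(matrix: LGFMatrix, ref: CytobandReference | None = None) -> pd.DataFrame:
    """Per-case indicators for -5, -16, -18, del(11)(p15.1p15.4),
    del(13)(q12.11q22.3) and +8, plus their count and any-of-six flag.

    Whole-chromosome losses/gains require the flag on *every* band of the
    chromosome; the interval deletions require loss on every band of the
    interval.
    """
    ref = ref or matrix.reference
    pos_all = {
        c: np.array([ref.position(b.chromosome, b.band_label) for b in ref.chromosome_bands(c)])
        for c in ("5", "16", "18", "8")
    }
    del11 = np.array(ref.positions(bands_in_interval(ref, "11", "p15.1", "p15.4")))
    del13 = np.array(ref.positions(bands_in_interval(ref, "13", "q12.11", "q22.3")))

    data = {
        "minus5": matrix.loss[:, pos_all["5"]].all(axis=1),
        "minus16": matrix.loss[:, pos_all["16"]].all(axis=1),
        "minus18": matrix.loss[:, pos_all["18"]].all(axis=1),
        "del11p": matrix.loss[:, del11].all(axis=1),
        "del13q": matrix.loss[:, del13].all(axis=1),
        "plus8": matrix.gain[:, pos_all["8"]].all(axis=1),
    }
    df = pd.DataFrame({k: v.astype(int) for k, v in data.items()}, index=matrix.cases)
    df.index.name = "case_id"
    df["count_of_six"] = df[list(SIX_ABNORMALITIES)].sum(axis=1)
    df["any_of_six"] = (df["count_of_six"] > 0).astype(int)
    return df


# ---------------------------------------------------------------------------
# stepwise AIC selection

def stepwise_aic(
    inputs: list[SurvivalInput],
    covariates: pd.DataFrame,
    candidates: list[str] | None = None,
    direction: str = "both",
    ties: str = "efron",
) -> dict:
    """Deterministic bidirectional stepwise Cox selection by AIC.

    Starts from the full candidate set; at each step evaluates every single
    removal (and, for direction="both", every re-addition) and takes the move
    with the lowest AIC, ties broken by candidate order; stops when no move
    lowers the AIC.  Returns the retained covariates, the final fit and the
    AIC trace.
    """
    time = np.array([si.time for si in inputs], dtype=float)
    event = np.array([si.event for si in inputs], dtype=int)
    candidates = list(candidates if candidates is not None else covariates.columns)

    def fit_of(current: list[str]) -> dict:
        if not current:
            ll0 = _cox_quantities(np.zeros(1), np.zeros((len(time), 1)), time, event, ties)[0]
            return {"beta": np.array([]), "loglik": float(ll0), "aic": float(-2 * ll0),
                    "flagged": False}
        return cox_fit(covariates[current].to_numpy(dtype=float), time, event, ties=ties)

    # drop duplicated columns up front (keep the first in declared order)
    seen = {}
    uniq = []
    for c in candidates:
        key = tuple(covariates[c].to_numpy(dtype=float))
        if key in seen:
            continue
        seen[key] = c
        uniq.append(c)
    current = list(uniq)
    best = fit_of(current)
    trace = [{"step": 0, "move": "start", "model": tuple(current), "aic": best["aic"]}]

    step = 0
    while True:
        step += 1
        moves = []
        for c in list(current):
            moves.append(("remove", c, [x for x in current if x != c]))
        if direction == "both":
            for c in uniq:
                if c not in current:
                    moves.append(("add", c, current + [c]))
        best_move = None
        for kind, c, model in moves:
            try:
                f = fit_of(model)
            except ValueError:
                continue
            if f["aic"] < best["aic"] - 1e-10 and (
                best_move is None or f["aic"] < best_move[3]["aic"] - 1e-10
            ):
                best_move = (kind, c, model, f)
        if best_move is None:
            break
        kind, c, model, f = best_move
        current, best = model, f
        trace.append({"step": step, "move": f"{kind} {c}", "model": tuple(current),
                      "aic": best["aic"]})
    return {
        "selected": current,
        "fit": best,
        "coefficients": dict(zip(current, np.atleast_1d(best.get("beta", [])))),
        "trace": trace,
    }
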