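#!/usr/bin/env python
"""Overall-survival models on the packaged cohort: univariate Cox screens of
clinical and cytogenetic factors, and the three stepwise-AIC multivariate
presets (clinical-only, cytogenetic-only, combined).

Writes the univariate table (factor, coefficient, hazard ratio, score test,
p), Kaplan-Meier curve data by any-of-six status, and the selection traces.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from karyolgf import classify_complexity
from karyolgf.io import read_karyotypes
from karyolgf.lgf import build_matrix
from karyolgf.survival import (
    build_six_covariates,
    cox_univariate,
    derive_event,
    km_estimate,
    read_clinical,
    stepwise_aic,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main():
    records = read_karyotypes()
    clinical = {r.case_id: r for r in read_clinical()}
    matrix = build_matrix(records)
    six = build_six_covariates(matrix)
    inputs = [derive_event(clinical[c]) for c in matrix.cases]

    cov = pd.DataFrame(index=pd.Index(matrix.cases, name="case_id"))
    cov["age"] = [clinical[c].age_years for c in matrix.cases]
    cov["age_ge_60"] = (cov["age"] >= 60).astype(float)
    cov["male"] = [1.0 if clinical[c].gender == "M" else 0.0 for c in matrix.cases]
    cov["prior_treatment"] = [
        1.0 if clinical[c].prior_treatment == "yes" else 0.0 for c in matrix.cases
    ]
    cov["complex_karyotype"] = [
        1.0 if classify_complexity(rec) == "complex" else 0.0 for rec in records
    ]
    for col in six.columns:
        cov[col] = six[col].to_numpy(dtype=float)

    rows = []
    for name in cov.columns:
        x = cov[name].to_numpy()
        if np.ptp(x) == 0:
            continue
        r = cox_univariate(inputs, x, name=name)
        rows.append({
            "factor": name, "n": r.n, "deaths": r.deaths,
            "coefficient": round(r.coefficient, 4),
            "hazard_ratio": round(r.hazard_ratio, 4),
            "score_statistic": round(r.score_statistic, 4),
            "p_value": round(r.p_value, 4), "flagged": r.flagged,
        })
    uni = pd.DataFrame(rows)
    uni.to_csv(OUT / "04_univariate.tsv", sep="\t", index=False)

    km = km_estimate(inputs, groups=six["any_of_six"].map({0: "none", 1: "any_of_six"}))
    km_rows = [
        {"group": g, "time": t, "survival": s}
        for g, d in km.items()
        for t, s in zip(d["timeline"], d["survival"])
    ]
    pd.DataFrame(km_rows).to_csv(OUT / "04_km_any_of_six.tsv", sep="\t", index=False)

    presets = {
        "clinical": ["age", "prior_treatment", "complex_karyotype"],
        "cytogenetic": list(six.columns[:6]),
        "combined": ["age", "prior_treatment", "complex_karyotype", *six.columns[:6]],
    }
    models = {}
    for name, cands in presets.items():
        cands = [c for c in cands if np.ptp(cov[c].to_numpy()) > 0]
        sel = stepwise_aic(inputs, cov, cands)
        models[name] = {
            "selected": sel["selected"],
            "coefficients": {k: round(float(v), 4) for k, v in sel["coefficients"].items()},
            "aic": round(sel["fit"]["aic"], 2),
            "steps": len(sel["trace"]) - 1,
        }
    (OUT / "04_stepwise_models.json").write_text(json.dumps(models, indent=2))

    sig = uni[uni.p_value < 0.05].factor.tolist()
    print("univariate p<0.05:", sig)
    for name, m in models.items():
        print(f"model {name}: retained {m['selected']} (AIC {m['aic']})")
    print("KM medians:", {g: d["median"] for g, d in km.items()})


if __name__ == "__main__":
    main()
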