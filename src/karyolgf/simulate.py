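"""Synthetic T/NT karyotype cohorts with planted statistical structure.

Generates syntactically valid short-form ISCN strings plus linked clinical
rows so that every downstream stage (parser, LGF mapper, cohort statistics,
survival models) can be exercised end to end without external data.

What is emulated: multi-clone karyotypes with a diploid/tetraploid ploidy
mix, an optional related pseudodiploid stemline doubled via ``slx2``,
independent per-abnormality event draws at configurable frequencies, and
exponential survival whose hazard is multiplied by a planted hazard ratio for
each of the six prognostic abnormalities present (-5, -16, -18,
del(11)(p15.1p15.4), del(13)(q12.11q22.3), +8).  Co-occurrence structure
beyond independent draws is not modelled.

The rendered grammar subset is deliberately small: whole-chromosome gains
and losses, one- and two-breakpoint deletions, i(17)(q10), balanced
translocations, and ``slx2`` stemline doubling -- the constructs the analysis
depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import SIX_ABNORMALITIES

# token -> six-covariate name (the planted prognostic abnormalities)
SIX_TOKENS = {
    "-5": "minus5",
    "-16": "minus16",
    "-18": "minus18",
    "del(11)(p15.1p15.4)": "del11p",
    "del(13)(q12.11q22.3)": "del13q",
    "+8": "plus8",
}

# chromosome-count delta of each rendered token (per diploid genome)
_COUNT_DELTA = {"-": -1, "+": +1}


def _token_delta(token: str) -> int:
    if token[0] in _COUNT_DELTA and "(" not in token:
        return _COUNT_DELTA[token[0]]
    return 0


# default event frequencies: the recurrent OSU-cohort abnormality classes at
# roughly their observed rates (whole-chromosome losses ~0.2-0.27, +8 ~0.22,
# the interval deletions ~0.1-0.24)
DEFAULT_FREQUENCIES = {
    "-5": 0.24,
    "-7": 0.24,
    "-16": 0.27,
    "-17": 0.27,
    "-2": 0.22,
    "-18": 0.11,
    "+8": 0.22,
    "+13": 0.14,
    "del(11)(p15.1p15.4)": 0.24,
    "del(13)(q12.11q22.3)": 0.14,
    "del(9)(q13q34.3)": 0.20,
    "del(5)(q13q33)": 0.14,
    "i(17)(q10)": 0.08,
    "t(8;21)(q22;q22)": 0.03,
}

# planted log hazard ratios for the six prognostic abnormalities (HR ~ 2)
DEFAULT_LOG_HRS = {name: 0.7 for name in SIX_ABNORMALITIES}


@dataclass
class SimulationConfig:
    n_cases: int
    seed: int
    tnt_fraction: float = 1.0  # fraction of cases rendered tetraploid/near-tetraploid
    related_stemline_prob: float = 0.46  # P(T/NT case shows a doubled pseudodiploid stemline)
    band_event_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_FREQUENCIES))
    six_abnormality_log_hrs: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HRS))
    any_of_six_log_hr: float | None = None  # plant the hazard on the any-of-six indicator
    baseline_hazard: float = 0.12  # deaths per month (median OS ~ 6 months at baseline)
    censoring_rate: float = 0.05  # independent exponential censoring per month
    age_mean: float = 66.0
    age_sd: float = 13.0
    male_prob: float = 0.65
    prior_treatment_prob: float = 0.22
    cohort_label: str = "SIM"

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for tok, p in self.band_event_frequencies.items():
            if not 0 <= p <= 1:
                raise ValueError(f"frequency for {tok!r} outside [0, 1]")


def _render_karyotype(tokens: list[str], tnt: bool, related: bool, male: bool,
                      rng: np.random.Generator) -> str:
    sex2 = "XY" if male else "XX"
    sex4 = "XXYY" if male else "XXXX"
    delta = sum(_token_delta(t) for t in tokens)
    body = ("," + ",".join(tokens)) if tokens else ""
    if not tnt:
        cells = int(rng.integers(10, 21))
        return f"{46 + delta},{sex2}{body}[{cells}]"
    if related and tokens:
        stem_cells = int(rng.integers(5, 16))
        dbl_cells = int(rng.integers(2, 11))
        normal_cells = int(rng.integers(1, 6))
        stem = f"{46 + delta},{sex2}{body}[cp{stem_cells}]"
        doubled = f"{2 * (46 + delta)},slx2[{dbl_cells}]"
        return f"{stem}/{doubled}/46,{sex2}[{normal_cells}]"
    count = 92 + delta
    cells = int(rng.integers(5, 21))
    tag = "<4n>" if 81 <= count <= 103 else ""
    normal_cells = int(rng.integers(1, 6))
    return f"{count}{tag},{sex4}{body}[cp{cells}]/46,{sex2}[{normal_cells}]"


def simulate_case(cfg: SimulationConfig, rng: np.random.Generator, case_id: str):
    """Draw one case: (karyotype string, clinical row dict)."""
    tokens = [tok for tok, p in cfg.band_event_frequencies.items() if rng.random() < p]
    tnt = rng.random() < cfg.tnt_fraction
    related = rng.random() < cfg.related_stemline_prob
    male = rng.random() < cfg.male_prob
    karyotype = _render_karyotype(tokens, tnt, related, male, rng)

    present = [cov for tok, cov in SIX_TOKENS.items() if tok in tokens]
    if cfg.any_of_six_log_hr is not None:
        log_hr = cfg.any_of_six_log_hr if present else 0.0
    else:
        log_hr = sum(cfg.six_abnormality_log_hrs.get(cov, 0.0) for cov in present)
    hazard = cfg.baseline_hazard * np.exp(log_hr)
    t_death = rng.exponential(1.0 / hazard)
    t_censor = (
        rng.exponential(1.0 / cfg.censoring_rate) if cfg.censoring_rate > 0 else np.inf
    )
    observed = min(t_death, t_censor)
    event = t_death <= t_censor

    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18, 95))
    prior = rng.random() < cfg.prior_treatment_prob
    clinical = {
        "case_id": case_id,
        "age_years": round(age, 1),
        "gender": "M" if male else "F",
        "interval_months": 0,
        "diagnosis": "AML-MRC",
        "prior_treatment": "Yes" if prior else "No",
        "treatment": "Chemo",
        "tnt_clone_size_pct": int(rng.integers(5, 101)),
        "tnt_persistence": "NA",
        "os_months": round(max(observed, 0.1), 1),
        "outcome": "DOD" if event else "ANED",
        "cohort": cfg.cohort_label,
    }
    return karyotype, clinical


def simulate_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate n_cases; deterministic given cfg.seed (per-case substreams).

    Returns (karyotype table, clinical table) in the package's input schemas;
    both round-trip through karyolgf.io.read_karyotypes / survival.read_clinical.
    """
    kary_rows, clin_rows = [], []
    for i in range(cfg.n_cases):
        rng = np.random.default_rng([cfg.seed, i])  # order-independent substream
        case_id = f"S{i + 1}"
        karyotype, clinical = simulate_case(cfg, rng, case_id)
        kary_rows.append(
            {"case_id": case_id, "karyotype": karyotype, "cohort": cfg.cohort_label}
        )
        clin_rows.append(clinical)
    return pd.DataFrame(kary_rows), pd.DataFrame(clin_rows)


def write_cohort(cfg: SimulationConfig, karyotype_path, clinical_path) -> None:
    kary, clin = simulate_cohort(cfg)
    kary.to_csv(karyotype_path, sep="\t", index=False)
    clin.to_csv(clinical_path, sep="\t", index=False)
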