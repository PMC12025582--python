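"""Cohort-level recurrence calling and two-cohort per-band comparison.

Frequencies are exact per-band fractions of cases flagged in each of the
three LGF channels.  Recurrent abnormalities are bands at or above a minimum
frequency (default 20%).  Two cohorts are compared with the pooled two-sample
z-test of proportions at every band x channel, followed by multiple-testing
correction (Bonferroni by default; Benjamini-Hochberg and Holm selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lgf import CHANNELS, LGFMatrix

_MT_METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh", "holm": "holm"}


@dataclass
class AnalysisConfig:
    recurrence_threshold: float = 0.20
    nominal_alpha: float = 0.05
    mt_method: str = "bonferroni"
    channels: tuple = CHANNELS

    def __post_init__(self):
        if not 0 < self.recurrence_threshold <= 1:
            raise ValueError("recurrence_threshold must be in (0, 1]")
        if self.mt_method not in _MT_METHODS:
            raise ValueError(f"mt_method must be one of {sorted(_MT_METHODS)}")


def band_frequencies(matrix: LGFMatrix) -> pd.DataFrame:
    """Per (band, channel) counts and fractions of flagged cases."""
    if matrix.n_cases == 0:
        raise ValueError("empty LGF matrix")
    rows = []
    n = matrix.n_cases
    for ch in CHANNELS:
        counts = matrix.channel(ch).sum(axis=0)
        for pos, (band, c) in enumerate(zip(matrix.reference.bands, counts)):
            rows.append(
                {
                    "chromosome": band.chromosome,
                    "band": str(band),
                    "genome_order": pos,
                    "channel": ch,
                    "count": int(c),
                    "n": n,
                    "fraction": float(c) / n,
                }
            )
    return pd.DataFrame(rows)


def recurrent_bands(freqs: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Bands at or above the recurrence threshold, in genome order then channel."""
    cfg = cfg or AnalysisConfig()
    out = freqs[
        (freqs.fraction >= cfg.recurrence_threshold) & freqs.channel.isin(cfg.channels)
    ].copy()
    return out.sort_values(["genome_order", "channel"]).reset_index(drop=True)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z-test of proportions; two-sided normal p.

    Degenerate pooled proportions (0 or 1) return (0.0, 1.0) so correction
    procedures stay well-defined.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, p))


def compare_cohorts(
    m1: LGFMatrix, m2: LGFMatrix, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per band x channel z-tests between two cohorts with adjusted p-values."""
    cfg = cfg or AnalysisConfig()
    if len(m1.reference) != len(m2.reference) or [str(b) for b in m1.reference.bands] != [
        str(b) for b in m2.reference.bands
    ]:
        raise ValueError("cohort matrices must share one cytoband reference")
    rows = []
    for ch in cfg.channels:
        c1 = m1.channel(ch).sum(axis=0)
        c2 = m2.channel(ch).sum(axis=0)
        for band, x1, x2 in zip(m1.reference.bands, c1, c2):
            z, p = two_proportion_z(int(x1), m1.n_cases, int(x2), m2.n_cases)
            rows.append(
                {
                    "chromosome": band.chromosome,
                    "band": str(band),
                    "channel": ch,
                    "x1": int(x1),
                    "n1": m1.n_cases,
                    "x2": int(x2),
                    "n2": m2.n_cases,
                    "z_statistic": z,
                    "p_value": p,
                }
            )
    df = pd.DataFrame(rows)
    # correction across all tested band x channel hypotheses
    _, adj, _, _ = multipletests(df.p_value.values, method=_MT_METHODS[cfg.mt_method])
    df["adjusted_p"] = np.minimum(1.0, np.maximum(adj, df.p_value.values))
    df["method"] = cfg.mt_method
    return df


def comparison_summary(results: pd.DataFrame, cfg: AnalysisConfig | None = None) -> dict:
    """Counts of hypotheses below the nominal alpha, unadjusted and adjusted."""
    cfg = cfg or AnalysisConfig()
    return {
        "n_tests": len(results),
        "n_nominal": int((results.p_value < cfg.nominal_alpha).sum()),
        "n_adjusted": int((results.adjusted_p < cfg.nominal_alpha).sum()),
    }
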