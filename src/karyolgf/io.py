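"""Readers for the packaged case tables and for user-supplied cohorts.

Karyotype tables are delimited text (TSV/CSV autodetected by extension) with
columns ``case_id`` and ``karyotype`` and an optional ``cohort`` column.
"#"-prefixed lines are comments.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .parser import KaryotypeRecord, parse_karyotype


def _read_table(source: str | Path) -> pd.DataFrame:
    source = Path(source)
    sep = "," if source.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(source, sep=sep, comment="#", dtype={"case_id": str})


def _packaged(name: str) -> Path:
    return Path(str(resources.files("karyolgf.data").joinpath(name)))


def packaged_karyotype_table() -> pd.DataFrame:
    """The 37 published OSU T/NT karyotypes (case_id, complexity_printed, karyotype, cohort)."""
    return _read_table(_packaged("table2_karyotypes.tsv"))


def packaged_clinical_table() -> pd.DataFrame:
    """The 37 published OSU T/NT clinical rows."""
    return _read_table(_packaged("table1_clinical.tsv"))


def read_karyotypes(source: str | Path | None = None) -> list[KaryotypeRecord]:
    """Parse a karyotype table into records (packaged table when source is None)."""
    df = packaged_karyotype_table() if source is None else _read_table(source)
    for col in ("case_id", "karyotype"):
        if col not in df.columns:
            raise ValueError(f"karyotype table missing column {col!r}")
    return [parse_karyotype(str(r.case_id), r.karyotype) for r in df.itertuples()]
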