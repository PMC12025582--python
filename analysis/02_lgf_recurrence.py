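#!/usr/bin/env python
"""Encode the cohort as a Loss-Gain-Fusion matrix and call recurrent
abnormalities at the 20% frequency threshold.

Finding: recurrent losses of chromosomes 2, 5, 7, 16 and 17 and of the
intervals 3p13-p26.3, 9q13-q34.3, 11p15.1-p15.5 and 12q24.31-q24.33;
recurrent gains of chromosome 8 and of most of chromosome 1; no recurrent
fusion. Writes the matrix, per-band frequencies and the recurrence calls.
"""

from pathlib import Path

from karyolgf import load_reference
from karyolgf.cohort import AnalysisConfig, band_frequencies, recurrent_bands
from karyolgf.io import read_karyotypes
from karyolgf.lgf import build_matrix, write_matrix_tsv

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main():
    ref = load_reference()
    matrix = build_matrix(read_karyotypes(), ref=ref, cohort_label="OSU")
    write_matrix_tsv(matrix, OUT / "02_lgf_matrix.tsv")
    freqs = band_frequencies(matrix)
    freqs.to_csv(OUT / "02_band_frequencies.tsv", sep="\t", index=False)
    calls = recurrent_bands(freqs, AnalysisConfig(recurrence_threshold=0.20))
    calls.to_csv(OUT / "02_recurrent_bands.tsv", sep="\t", index=False)

    for ch, label in (("L", "loss"), ("G", "gain"), ("F", "fusion")):
        sub = calls[calls.channel == ch]
        chroms = sorted(sub.chromosome.unique(), key=lambda c: (len(c), c))
        print(f"recurrent {label}: {len(sub)} band calls on chromosomes {chroms}")


if __name__ == "__main__":
    main()
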