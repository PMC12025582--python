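# Methods

## The data model

A karyotype is short-form ISCN text: `/`-separated clones, each with a
chromosome count (possibly a `~` range), an optional ploidy tag (`<4n>`), a
sex complement, and comma-separated abnormality tokens, ending in a
cell-count bracket (`[cp18]` marks a composite clone). Later clones may
inherit an earlier clone's abnormalities through `sl` (stemline), `sdl k`
(k-th sideline, numbered by listing order of abnormal clones after the
stemline) or `idem`, with `x2` denoting doubling of the inherited genome.
`//` separates recipient from donor cells in transplanted patients; donor
clones are excluded from all statistics. `nonclonal[...]` entries and bare
`4n[1]` cells are counted and skipped. `.ish ...` suffixes (FISH results) are
stripped and flagged, never interpreted. Constitutional abnormalities
(trailing `c`) are parsed but excluded from counts and from the LGF encoding.

Only the short form is supported. A karyotype written in long-form segment
notation (`::`) raises an unsupported-dialect error — with one exception:
individual derivative tokens that embed segment notation (e.g.
`der(20)(20pter->20q13.1::?::5p15.2->5p15.2::?)`) are retained as *opaque*
derivatives. They count toward complexity but contribute no band content;
this keeps every case of the packaged cohort parseable while refusing to
guess at unreconstructable material. Per-abnormality cell annotations such
as `-7(6)` are stripped with a logged warning. The token `(?:q21)` in the
packaged corpus uses `:` where ISCN wants `;`; band-group separators accept
both.

## Ploidy, complexity, relatedness

* **Ploidy**: a clone is T/NT if it carries a `4n` tag or its count interval
  intersects 81–103; pseudodiploid/diploid-range if the interval lies within
  35–57. Count ranges use interval overlap, not midpoints, so `87~113` is
  T/NT. The clone's *ploidy baseline* (2 or 4 copies per autosome) comes
  from the tag, from lineage doubling (`slx2` of a diploid stemline gives 4),
  or failing both from the count midpoint's nearest of {46, 92}; other
  implied baselines (a `<3n>` clone, `idemx3`) are mapped to the nearest of
  {2, 4} with a logged diagnostic.
* **Complexity**: a karyotype is complex when any single clone carries ≥ 3
  unrelated abnormality events relative to its ploidy baseline. Every event
  counts at its written multiplicity: `add(7)(q36)x2` counts two, each
  written numerical token counts one (so `-Y,-Y` is two events while the
  balanced tetraploid `92<4n>,XXYY` is zero). The alternative convention —
  one count per distinct event regardless of multiplicity — fails to
  reproduce the published per-case labels of this cohort (it undercounts the
  two `90<4n>,XX,-Y,-Y,…` cases); the multiplicity convention reproduces all
  35 evaluable labels and is locked by that test. Clones marked `inc`
  (incomplete) still contribute parsed abnormalities to the encoding but
  make complexity *not evaluable* unless another clone reaches 3.
* **Relatedness**: a pseudodiploid clone (diploid-range count, ≥ 1 acquired
  abnormality) is related to the T/NT clone(s) when a T/NT-side clone is a
  lineage doubling of it, or shares at least one identical acquired
  abnormality (same kind, chromosomes, breakpoints). T/NT-side clones
  include clones on a tetraploid baseline whose losses pushed the count
  below 81 (a doubled stemline at 77–79 chromosomes is still a doubling
  event). Removal tokens (`-del(20)`, `-mar1`) subtract inherited
  multiplicity only; subtracting an event that was never inherited logs a
  warning and is ignored.

## The Loss–Gain–Fusion encoding

The cytoband reference is an ordered, ordinal (no base pairs) table of 868
bands over chromosomes 1–22, X, Y at the ~850-band ISCN resolution. The
classical ideogram enumerates 862 named bands; this table splits the
centromeric q11 band of chromosomes 1, 4, 9, 12, 13 and 19 into q11.1/q11.2,
a documented tuning that fixes the genome-wide total at 868
(`scripts/build_cytoband_fixture.py` regenerates it). Coarse breakpoints
expand hierarchically by digit-prefix: `q13` covers q13.1–q13.3, `q11.2`
covers q11.21–q11.23 but not q11.1.

Each abnormality unit is mapped **independently** to binary loss/gain/fusion
flags; a clone's calls are the union over its events and a case's vector the
union over its non-donor clones. The encoding therefore records the presence
of each kind of abnormality, not a net copy number — doubling a
multiplicity never changes a flag, and a clone that both gains a chromosome
and deletes part of it flags both channels. We validated this choice against
the alternative (per-clone copy-count arithmetic against the ploidy
baseline): net arithmetic lets a `+9` cancel a `del(9)` within one clone and
fails to reproduce the cohort's recurrent 9q13–q34.3 deletion and
chromosome-1 gain regions; per-event flags reproduce both.

Per-kind semantics: whole-chromosome `±N` flag every band of the chromosome
(sex chromosomes included); one-breakpoint deletions run from the breakpoint
to its arm's telomere and two-breakpoint deletions cover the enclosed
interval, breakpoint bands included; `add` marks distal loss and no gain
(the replacing material is of unknown origin), while a supernumerary `+add`
gains the retained proximal segment; `dup` gains its interval; `i(q10)`
gains the q arm and loses the p arm; balanced `t`/`inv` set fusion at every
expanded breakpoint band with no copy change; `dic`/`idic`/`psu dic` add
distal loss at each breakpoint; derivatives lose recipient material distal
to the breakpoint (inclusive) and gain translocated donor segments with the
donor breakpoint band *excluded* — only material unambiguously distal is
called; whole-arm `der(13;14)(q10;q10)` loses the complementary arms;
`hsr` gains its band; markers, rings without content, `dmin`, `?` sides and
opaque derivatives contribute nothing.

Two conventions were fixed by the cohort's printed recurrence boundaries:
breakpoint-band-inclusive distal loss (an `add(12)(q24.3)` must reach
12q24.31–q24.33) and donor-breakpoint-exclusive gain. Two residual
discrepancies against the published region lists are consequences of these
rules and are asserted as such in the tests: `add(11)(p15)` reaches the
telomeric band, so the recurrent 11p loss is called p15.1–p15.5 rather than
p15.1–p15.4; and `i(1)(q10)` gains the entire 1q arm, which lifts proximal
1q to 8/37 cases (≥ 20%) and leaves proximal 1p at 7/37, so the ~6-band
exception region on chromosome 1 falls on p13.3–p11.1 instead of
1q11.1–q21.3. Both calls describe "almost all of chromosome 1" minus six
bands; the per-case figure-level data needed to arbitrate further is not
published.

## Cohort statistics

Band frequencies are exact fractions of flagged cases. Recurrence uses a
minimum frequency threshold, default 0.20 — low enough to catch common
abnormalities hidden in complex karyotypes, high enough to suppress
sporadic events; calls are monotone in the threshold. Cohort comparison
applies the pooled two-proportion z-test per band × channel with a two-sided
normal p-value; degenerate bands (pooled proportion 0 or 1) return p = 1 so
correction stays well defined. Multiple-testing correction defaults to
Bonferroni across **all** tested band × channel hypotheses (the most
conservative reading; per-channel totals would be less so), with BH and Holm
selectable; the method is recorded in every result row. The test's type-I
error is calibrated by simulation in the suite (2000 null replicates at
n = 50 per arm, rejection rate within ±1.5 points of 5% for pooled
frequencies 0.1–0.9).

## Survival analysis

Overall survival runs from T/NT identification. The event is death of
disease (outcome `DOD`); `ANED`, `AWD`, `LFU` and hospice discharge censor
at last follow-up — the only rule consistent with the cohort's 25 recorded
deaths. Kaplan–Meier estimation uses the product-limit estimator (lifelines)
with the median as the earliest time S(t) ≤ 0.5.

Cox proportional-hazards models maximize the Efron-tie partial likelihood
(survival times are month-resolution and heavily tied; Breslow available by
flag) by Newton–Raphson with step-halving, written in numpy for speed —
the replicate-based tests run thousands of fits. The implementation is
cross-checked in the suite against lifelines (coefficients and
log-likelihood), against a brute-force evaluation of the Efron likelihood on
small datasets, and against the log-rank statistic, with which the score
test at β = 0 coincides for a binary covariate without ties. Monotone
likelihood (perfect separation) is flagged rather than hidden.

Stepwise selection is bidirectional from the full candidate set, scored by
AIC = −2ℓ + 2p, taking the best admissible move each step, ties broken by
declared candidate order, stopping when no move lowers the AIC —
deterministic by construction; duplicated covariates are dropped up front
(first kept). Three presets mirror the study design: clinical (age, prior
treatment, complexity — cohort is constant in the packaged single-cohort
data and is dropped automatically), cytogenetic (the six abnormalities), and
combined. The six-abnormality covariates require the flag on *every* band of
the region (whole chromosome for −5/−16/−18/+8; the 11p15.1–p15.4 and
13q12.11–q22.3 intervals for the deletions); `count_of_six` and `any_of_six`
derive from them. Clinical covariate comparisons use Welch's t-test for
continuous variables and chi-squared with Yates continuity correction for
2×2 tables (the correction is required to reproduce the cohort-difference
p ≈ 0.03 for prior treatment); age dichotomizes at ≥ 60 years.

## Synthetic cohorts

The generator emulates the study's data shape: T/NT karyotypes (optionally
with a related pseudodiploid stemline doubled via `slx2`, probability 0.46
as observed), independent per-abnormality draws at the cohort's observed
frequencies (whole-chromosome losses ≈ 0.2–0.27, +8 ≈ 0.22, interval
deletions ≈ 0.1–0.24), and exponential survival with baseline hazard
0.12/month (median ≈ 6 months at baseline, matching the dismal T/NT course)
multiplied by exp(0.7) ≈ 2 per planted prognostic abnormality, with
independent exponential censoring (0.05/month, ≈ 30% censored). Rendering
covers only the constructs the analysis depends on (±N, del, add, i(q10),
balanced t, slx2). It does **not** model co-occurrence among abnormalities,
clone-size dynamics, non-exponential hazards or cohort effects — so passing
recovery tests demonstrates correctness of the machinery on known truth, not
realism of real cohorts. Cohorts are deterministic given the seed (per-case
counter-derived substreams, order-independent).

## Problem sizes in the test suite

The suite's simulation scales were chosen to give tight Monte-Carlo error at
interactive runtimes: 100 seeded replicates for null-coverage and
stepwise-retention properties, 200 per hazard-ratio level for the direct
recovery invariant, 50 full-pipeline replicates (n = 400 cases each) for
end-to-end hazard recovery, 2000 replicates for z-test calibration, and 1000
generated karyotypes for parser closure.

## Known limitations

* Band-level, ordinal coordinates only; no base pairs, liftover or gene
  annotation.
* The LGF grammar subset covers the constructs present in the packaged
  corpus plus the common core; exotic nomenclature (insertions with
  directionality, complex three-way translocations) maps only its
  resolvable breakpoints.
* Marker chromosomes, double minutes and contentless rings count toward
  complexity but are invisible to the encoding (unknown material).
* The second institution's per-case tables are an optional external input
  (same TSV schemas, `cohort` column); no such data are packaged, so
  combined-cohort survival numbers are exercised by property-based tests and
  synthetic cohorts instead.
* No proportional-hazards diagnostics, competing risks or imputation beyond
  listwise exclusion with reported n.
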