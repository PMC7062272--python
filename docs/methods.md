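# Methods

## The detection procedure

A sudden gain is declared for the interval between sessions N and N+1
of one subject's outcome series when three criteria hold
simultaneously. Criterion 1 demands an absolute drop of at least a
user-chosen cutoff (score units; inclusive, so a drop exactly equal to
the cutoff counts). Criterion 2 demands a drop of at least a fraction
`crit2_pct` (default 0.25) of the pregain score, again inclusive.
Criterion 3 demands that the difference in means between the up-to-three
observed scores before the interval and the up-to-three after it
*strictly* exceeds a critical multiple of their pooled sample standard
deviation,

    M_pre − M_post > c · sqrt(((n_pre−1)·SD_pre² + (n_post−1)·SD_post²) / (n_pre+n_post−2)),

with SDs computed with the n−1 denominator. Note this is the historical
form of the stability test: the mean difference is compared against
c·s_p directly, *not* against c·s_p·√(1/n_pre+1/n_post) as in the
classical two-sample t test; the two are related by that fixed factor
and the test suite cross-checks the implementation against both an
independent brute-force evaluation of the inequality and the rescaled
classical statistic. The inclusive/strict distinctions (≥ for criteria
1–2 and the reversal rule, > for criterion 3) are the only boundary
semantics; comparisons are done in double precision with no epsilon.

Sudden losses apply the same machinery with the direction of change
inverted (criterion 2's threshold remains proportional to the pregain
score, so losses are not a pure mirror image of gains unless criterion
2 is disabled; the literature sometimes also raises the percentage to
33% for losses, which `crit2_pct` accommodates).

## Missing data

No imputation is performed. Each criterion returns a tri-state verdict
(met / not met / indeterminate). An interval is structurally evaluable
only when the pregain and postgain points are present and at least two
of three points exist on each side of the interval — at minimum four of
the six window points, in one of four canonical arrangements (or any
superset). When points are missing but the window is still evaluable,
the criterion-3 critical value is adjusted to the available degrees of
freedom (df = n_pre + n_post − 2): 2.776 / 3.182 / 4.303 at α = 0.05
for df 4 / 3 / 2. Setting `crit3_adjust=False` instead applies a single
fixed critical value (default 2.776) to every interval, reproducing the
unadjusted variant used in part of the literature. Sessions before the
first or after the last measurement count as missing when forming the
window, so the first evaluable pregain session is 2 and the last is
S−2; the flag table omits the structurally impossible interval columns
rather than emitting all-NA columns.

The combined flag is indeterminate whenever the window is not
evaluable, even if criterion 1 or 2 individually failed — an interval
that cannot be fully tested is reported as NA, not as a definite
non-gain. When the window is evaluable, any definitely failed criterion
makes the combined flag 0. When criterion 3 is disabled by
configuration, the evaluability gate is dropped and only the presence
of the pregain/postgain pair matters; this choice (the narrowest
missing-data requirement consistent with the applied criteria) is a
design decision of this package.

Criterion 2 with a non-positive pregain score returns "not met" with a
logged warning: a percentage drop from a non-positive score is
undefined, and symptom scales are non-negative.

## Reliable-change cutoffs

`define_crit1_cutoff` computes the chain S_E = SD·√(1−r),
S_diff = √(2·S_E²), reliable change = 1.96·S_diff, and recommends
either S_diff or 1.96·S_diff according to the convention flag — both
conventions appear in published studies, so the result object carries
every intermediate quantity and the convention used. The 1.96
multiplier (two-tailed z at 5%) is fixed by the reliable-change
definition. Whether SD/r are a normal population's SD with test–retest
reliability or the clinical baseline SD with internal consistency is
recorded as metadata only: the arithmetic is identical.

## Analysis datasets

`create_bysg` emits one row per identified gain: the pregain session,
the six around-gain scores, the raw magnitude x_N − x_{N+1}, the total
treatment change (start − end for gains, end − start for losses, so
that change in the analysed direction is positive), the gain's
proportion of that change (missing, with a warning, when total change
is zero or in the wrong direction), the 50%-loss reversal threshold
(midpoint of x_N and x_{N+1}) and whether any observed score from
session N+2 onward reaches it (inclusive; for losses, falls to or below
it). All gains of multi-gain subjects are kept — no suppression of
adjacent or overlapping flagged intervals — with the per-subject count
in `sg_freq_byperson`. `create_byperson` has one row per subject;
multi-gain subjects are represented by the gain chosen by the
`selector` (`first` by default, or `last` / `smallest` / `largest`,
ties broken by earlier session) and the selector is recorded in the
table's metadata, since the handling of multiple gains is an open
methodological issue. Gain ids are `"<subject>_sg<N>"`. The raw session
columns are carried on both tables so secondary-measure extraction and
plotting need no second join.

`extract_values` requires the secondary-measure column list to match
the primary list in length (same measurement occasions) and copies the
secondary scores at the absolute sessions N−2…N+3 of each row's gain;
out-of-range sessions and non-gainer rows yield missing values.

## Synthetic data generator

`GenerationSpec`/`generate` emulate the structure of a weekly
symptom-questionnaire trial: integer scores bounded to a 0–63 scale,
a per-subject baseline (normal, mean 30, SD 5 by default, with
deterministic overrides available), a gentle linear improvement of 0.5
points/session, and AR(1) session noise (SD 1, autocorrelation 0.3 by
default) so that the stability criterion is exercised non-trivially.
Planted gains superimpose an abrupt drop between two sessions; planted
rebounds add scores back later, producing reversals. Plants are
validated on the noise-free skeleton: construction guarantees that with
zero noise each planted interval satisfies all three criteria (at the
intended cutoff and percentage) and no other interval of that subject
does, so noise-free recovery is exact by design, and recovery degrades
as the noise SD approaches the cutoff. Random missingness spares the
six-session window around each plant (and the first two rebounded
sessions) so the planted structure stays observable; forced dropout per
subject is available for creating wholly untestable rows. Ground truth
is returned (and written by `sg simulate --truth`) as a sidecar table
so tests never re-derive it from generator internals.

The bundled demo (`default_demo`, fixed seed) is a 43-subject,
12-session dataset with a correlated secondary measure and a plant
layout chosen to give a realistic mix: 16 gainers, of whom 8 have two
gains and 1 has three (26 gains), three later full relapses, 4% random
missingness and two dropout subjects (one contributing no evaluable
interval at all). Planted drops are sized at least five points above
both the 7-point cutoff and 25% of the pregain score, several noise SDs
of margin, so the pipeline recovers exactly the planted set. **The demo
is entirely synthetic**: it reproduces the shape and headline counts of
a typical small trial dataset, not any real sample. What passing tests
on it show is that the criteria arithmetic, missing-data rules and
dataset reshaping are correct; they say nothing about how often real
trajectories — with therapist effects, floor effects, non-linear change
or informative dropout, none of which are simulated — produce gains.

## Numerical and interface choices

- Critical values come from the Student-t quantile (scipy) at
  1 − α/2 with df = n_pre + n_post − 2; df < 1 is a configuration error.
- A zero pooled SD is legal (plateau windows): criterion 3 then reduces
  to a strict comparison of the window means.
- Tri-state serialisation follows the flag-table convention:
  TRUE/FALSE/NA for per-criterion columns, 1/0/NA for combined flags;
  integer gain fields use pandas' nullable Int64 so non-gainers carry
  NA rather than a sentinel.
- File formats: CSV/TSV (canonical; comma, UTF-8, `NA` for missing),
  `.xlsx`, and Stata `.dta`. SPSS `.sav` is not supported; nullable
  integer columns are exported to Stata as floats.
- CLI exit codes: 0 success, 2 configuration error, 3 data error.
- All randomness flows through the explicit seed in `GenerationSpec`;
  identical specs yield byte-identical datasets.

## Problem sizes used in the checks

The bundled verification runs use the 43×12 demo for the end-to-end
pipeline counts, 10,000 random 2–3-point windows for the stability
criterion against its brute-force oracle, 100 random single-plant
layouts for noise-free recovery, and 500 random series for the
loss/gain mirror property — sizes at which every property is exercised
densely while the whole suite stays fast.

## Known limitations

Long-format input must be reshaped by the caller (`to_long` is provided
for the reverse direction). Overlapping gains are all reported; studies
wishing to suppress gains that reuse a prior gain's postgain sessions
must filter the bysg table themselves. The "stable reversal" refinement
(a reversal that is itself a sudden loss) is not operationalised.
Whether two overlapping evaluable intervals may both be flagged is not
settled in the literature; this package evaluates every interval
independently and flags both.
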