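# sgtools

Tools to identify and describe **sudden gains** (and sudden losses) in
longitudinal outcome data — large, stable improvements between two
consecutive measurements of a repeatedly administered outcome, such as
weekly depression scores during a course of psychotherapy. Sudden gains
are of interest to psychotherapy-process and clinical researchers
because experiencing one is associated with better treatment outcomes;
identifying them by hand is laborious and error-prone, and small
methodological choices (cutoffs, critical values, handling of missing
data and of multiple gains) are often reported inconsistently. This
package makes those choices explicit, automatic and reproducible.

## The three criteria

Let x₁, …, x_S be one subject's scores at sessions 1…S, and call the
session immediately before a candidate change *N* (the pregain session)
and the one after it *N+1* (the postgain session). The interval
N → N+1 is a **sudden gain** when:

1. **Absolute magnitude** — the drop is at least a cutoff in score
   units: xₙ − xₙ₊₁ ≥ c₁ (classically 7 points on the BDI; commonly
   derived from the Reliable Change Index, see below);
2. **Relative magnitude** — the drop is at least a fraction (default
   25%) of the pregain score: xₙ − xₙ₊₁ ≥ 0.25 · xₙ;
3. **Stability** — the change stands out from the surrounding
   session-to-session fluctuation:

   M_pre − M_post > t₍1−α/2; df₎ · √[ ((n_pre−1)·SD²_pre + (n_post−1)·SD²_post) / (n_pre + n_post − 2) ]

   where M/SD/n are the mean, sample SD and count of the up-to-three
   observed scores before (x_{N−2}, x_{N−1}, x_N) and after (x_{N+1},
   x_{N+2}, x_{N+3}) the interval, and df = n_pre + n_post − 2. With
   full windows the critical value at α = 0.05 is 2.776; with one point
   missing on a side it is 3.182, and with one missing on each side
   4.303.

An interval is only evaluable if the pregain and postgain points are
present and at least two of three points exist on each side (minimum
four of the six window points). Verdicts are tri-state: met, not met,
or indeterminate (NA) when missing data prevent the test. Sudden
*losses* use the same criteria with the direction of change inverted.

A gain is **reversed** if at any later session the score returns to or
beyond the midpoint of xₙ and xₙ₊₁ (i.e. 50% of the improvement is
lost): a 40 → 30 gain reverses at a score of 35 or more.

Criterion-1 cutoffs can be derived from reliability statistics via the
reliable-change chain S_E = SD·√(1−r), S_diff = √2·S_E, reliable change
= 1.96 · S_diff.

## Worked example

The package bundles a fully synthetic demo dataset shaped like a small
therapy trial: 43 subjects × 12 weekly sessions of a 0–63 depression
score (`bdi_s1…bdi_s12`) plus a correlated secondary rumination measure
(`rq_s1…rq_s12`), with known planted gains, relapses and missingness.

```python
import sgtools as sg

data = sg.default_demo()
config = sg.CriteriaConfig(crit1_cutoff=7)          # 25%, adjusted c3 by default

flags = sg.identify_sg(data, config, details=True)  # per-interval flag table
bysg = sg.create_bysg(data, config, "bdi_s1", "bdi_s12", measure_name="bdi")
byperson = sg.create_byperson(data, config, "bdi_s1", "bdi_s12", measure_name="bdi")
print(sg.describe_sg(bysg, byperson))
```

prints

```
subjects analysed:            43
subjects with a sudden gain: 16 (37.2%)
subjects with multiple gains: 9
total sudden gains:          26
mean gain magnitude:         14.77 (SD 3.01)
reversed gains:              3 (11.5%)
mean pregain session:         5.77
```

i.e. 16 of the 43 subjects experienced at least one gain, 9 of them
more than one (26 gains in total), the average gain was a 14.8-point
drop, and 3 gains later lost half or more of their improvement. The
flag table encodes each interval as 1/0/NA (with TRUE/FALSE/NA
per-criterion columns under `details=True`); `sg.extract_values` adds
the rumination scores from sessions N−2…N+3 around each gain, and
`sg.average_gain_profile` / `sg.trajectory_data` produce the plot-ready
aggregates behind `sgtools.plots.plot_sg` and `plot_sg_trajectories`.

The same pipeline is available from the shell:

```bash
sg cutoff --sd 10 --reliability 0.91
# standard error of measurement (S_E):  3.0000
# standard error of difference (S_diff): 4.2426
# reliable change (1.96 x S_diff):       8.3156
# recommended criterion-1 cutoff:        8.3156 (reliable_change convention)

sg simulate --out demo.csv --truth truth.csv
sg identify --input demo.csv --id id --vars bdi_s1:bdi_s12 \
    --crit1-cutoff 7 --details --output flags.csv
sg describe --input demo.csv --id id --vars bdi_s1:bdi_s12 \
    --crit1-cutoff 7 --tx-start bdi_s1 --tx-end bdi_s12 --measure-name bdi
```

Inputs and outputs are CSV/TSV, `.xlsx` or Stata `.dta`; missing cells
are read and written as `NA`.

## Limitations

The identification criteria are pattern detectors, not causal
statements: gains found this way are not necessarily attributable to
the intervention. No imputation is performed at the identification
stage (intervals that cannot be tested are reported as NA instead), and
"stable reversal" variants beyond the 50% rule are out of scope.
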