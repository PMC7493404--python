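# ctdnatrack

Tumor-informed longitudinal monitoring of circulating tumor DNA (ctDNA)
from targeted-panel variant-call tables: somatic/germline filtering, a
Monte Carlo ctDNA-presence test, total-ctDNA quantification, molecular
progression and lead-time calling, and progression-free-survival (PFS)
stratification by ctDNA status. Built for analysts working with serial
plasma (liquid biopsy) sequencing of cancer patients whose baseline tumor
tissue defines a personal tracking set of somatic mutations.

## The method

For each subject, high-confidence somatic variants from baseline tumor
tissue — calls in non-repetitive regions, not predicted germline, with
ExAC population frequency < 1% and AF > 5% (> 3% for hotspot whitelist
mutations) — form the tracking set of size *n*. For each plasma sample the
observed statistic is the mean allele frequency of the *n* tracked variants
(absent variants count as 0). The null distribution comes from the same
sample's background allele alterations (non-tracked positions with
alternate reads, mostly sequencing error): each of 10,000 Monte Carlo
iterations draws *n* distinct background alterations and records their mean
AF, giving the empirical p-value

    p = (1 + #{iteration means >= observed}) / (iterations + 1),

and the sample is ctDNA-positive iff p < 0.01. Germline variants are
removed beforehand by a logistic classifier over population-database and
allele-frequency features (no matched normal needed; hotspot variants are
never called germline). Total ctDNA is reported in mutated genome
equivalents, mGE = (sum of AFs) x input mass / 0.0033 ng. Molecular
progression is called after k = 2 consecutive strict AF increases from
baseline; lead time is the gap to the first radiographic progressive
disease (PD). PFS (diagnosis to first PD or death, censored at last
imaging) is compared between ctDNA-positive and -negative groups by
Kaplan-Meier, log-rank, and univariate Cox regression.

Because real cohorts of this kind are rarely shareable, the package ships a
first-class synthetic cohort generator with ground-truth labels (variant
origin, per-sample tumor fraction, true progression day, true hazard
ratio), so the entire pipeline is testable end to end. See
`docs/methods.md` for the model and its limits, `docs/formats.md` for file
formats.

## Worked example

The canonical single-subject trajectory — TP53 at 3.0% AF at diagnosis,
8.5% at day 47, 10.6% at day 68, with radiographic PD at day 159:

```python
from ctdnatrack.io import SampleRecord
from ctdnatrack.monitor import (SubjectTimeline, TimelineSample,
                                detect_molecular_progression, lead_time,
                                total_ctdna_level)

key = ("chr17", 7577120, "T", "G")
samples = [
    TimelineSample(record=SampleRecord("P1", f"P1-P{i:02d}", "plasma", day, 20.0),
                   af_by_variant={key: af})
    for i, (day, af) in enumerate([(0, 0.030), (47, 0.085), (68, 0.106)])
]
tl = SubjectTimeline(subject_id="P1", samples=samples, recist_events=[(159, "PD")])
mp = detect_molecular_progression(tl, k_increases=2)
print(f"molecular progression called: {mp.called} on day {mp.call_day}")
print(f"lead time vs radiographic PD: {lead_time(mp, tl)} days")
print(f"total ctDNA at day 68: {total_ctdna_level({key: 0.106}, 20.0):.1f} mGE")
```

prints

```
molecular progression called: True on day 68
lead time vs radiographic PD: 91 days
total ctDNA at day 68: 642.4 mGE
```

The two strict consecutive increases (3.0 -> 8.5 -> 10.6%) complete on day
68, 91 days before imaging shows progression; 10.6% AF in 20 ng of input
cfDNA corresponds to 642 mutated genome equivalents.

## Full pipeline

```sh
ctdnatrack run-all --out results --seed 3        # synthesizes a 71-subject cohort
ctdnatrack simulate --out cohort --seed 3        # or just the cohort bundle
```

`run-all` writes per-variant filter outcomes, tracking sets, per-sample
detection results, molecular-progression calls with lead times, ctDNA
levels, and a survival summary. On a default synthetic cohort the summary
looks like

```
stratification  n_positive  n_negative  median_pfs_positive  median_pfs_negative  logrank_p  cox_hr  cox_ci_low  cox_ci_high
first           53          18          107.0                162.0                0.082      1.80    0.92        3.54
last            22          49          78.0                 142.0                0.089      1.74    0.91        3.32
```

— ctDNA-positive subjects progress earlier (here the single-cohort HR
estimate is 1.8 against a generating hazard ratio of 2.3; across replicate
cohorts the 95% CI covers the true value at the nominal rate, which is what
the test suite asserts). A `manifest.json` records seeds and SHA-256
checksums; reruns with the same config are byte-identical.

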