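# dmcreport

Purposefully structured safety reports for Data Monitoring Committees
(DMCs), built from CDISC-ADaM-shaped subject-level trial tables.

A DMC reviewing an ongoing randomized trial has a few hours to answer a
few sharp questions: *is there an imbalance in any relevant safety
aspect? can it be explained by baseline differences? does it relate
across parameters or domains? and what changed since the last look?*
Conventional interim packages — hundreds of pages of frequency tables
and listings — make that needlessly hard. `dmcreport` produces the
displays and the report skeleton that support this workflow directly:
graphical baseline comparisons, an adverse-event overview dot plot and a
volcano display with exact per-term statistics, laboratory
distribution/abnormality/trajectory figures with per-subject limits of
normal, one-page patient profiles for subjects of special interest, and
a single continuously page-numbered document with a real table of
contents and a "what changed since the previous cut" summary.

A seeded synthetic-trial generator with injectable safety imbalances
makes the entire pipeline runnable, testable and exactly reproducible
offline.

## The statistics at the core

For each preferred term *t* and arm pair (*a*, *b*), with `n_a` dosed
subjects of which `x_a` report the event at least once during the
treatment-emergent window (first dose through last dose + 30 days):

* **subject-level incidence** `p̂_a = x_a / n_a`, and the
  **exposure-adjusted rate** `100 · x_a / T_a` per 100 person-years,
  where `T_a` is the arm's person-time from first to last dose day
  inclusive;
* **risk difference** `RD_t = 100·(p̂_a − p̂_b)` percentage points, or
  the **incidence rate ratio** `(x_a/T_a)/(x_b/T_b)` with a 0.5
  continuity correction applied only to zero counts;
* **two-sided Fisher exact p-value** on the 2×2 table
  `(x_a, n_a−x_a; x_b, n_b−x_b)`, computed by direct hypergeometric
  enumeration with the minimum-likelihood rule: conditional on both
  margins, `p = Σ P(table)` over all tables whose point probability does
  not exceed the observed one;
* **Benjamini–Hochberg adjustment** across all terms of one comparison:
  with order statistics `p(1) ≤ … ≤ p(m)`,
  `p̃(i) = min(1, min_{j≥i} m·p(j)/j)`.

These p-values are descriptive screening quantities for a volcano
display, not confirmatory tests. Laboratory values are flagged against
each measurement's own limits of normal (strictly: a value exactly at a
limit is normal), graded against configurable CTC-style thresholds
expressed as multiples of the subject's ULN/LLN, and summarized per
visit with linear-interpolation quartiles and Tukey whiskers at the last
data point within 1.5×IQR.

## Worked example

```python
from dmcreport import (generate_trial, volcano_stats,
                       xanomeline_like_fixture)

trial = generate_trial(xanomeline_like_fixture())
recs = volcano_stats(trial, "High Dose", "Placebo",
                     label_rule={"p_cutoff": 0.05})
for r in sorted(recs, key=lambda r: r.p_value)[:3]:
    print(f"{r.preferred_term:28s} RD {r.estimate:+6.1f} pp  "
          f"p={r.p_value:.4f}  FDR p={r.fdr_p:.4f}")
```

prints

```
Erythema                     RD  +13.1 pp  p=0.0011  FDR p=0.0113
Application site pruritus    RD  +14.4 pp  p=0.0025  FDR p=0.0124
Pruritus                     RD  +12.2 pp  p=0.0392  FDR p=0.1307
```

Erythema occurs in 13.1 more subjects per hundred on High Dose than on
Placebo; the exact test and the FDR-adjusted value both flag it well
below the 0.05 labeling cutoff, so it would carry a label in the volcano
figure. The `examples/` directory has one short script per capability
(synthetic data, AE statistics, laboratory review, patient profiles,
full report); each prints the numbers it computes and says what they
mean. The same operations are available from the shell:

```bash
dmcreport synth --seed 5 --out data/
dmcreport validate --subjects data/subjects.csv --arm "High Dose" --arm Placebo
dmcreport ae-stats --subjects data/subjects.csv --ae data/adverse_events.csv \
    --exposure data/exposure.csv --comparison "High Dose:Placebo" --label-p 0.05
dmcreport build --data data/ --out report/
```

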