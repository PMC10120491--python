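"""Adverse-event overview and volcano statistics for one arm comparison.

Incidence is subject-level (a subject counts once per term however many
episodes they report); the volcano pairs each term's risk difference in
percentage points with a two-sided Fisher exact p-value, plus the
Benjamini-Hochberg FDR adjustment across all terms of the comparison.
"""

from dmcreport import (ae_incidence, generate_trial, order_terms,
                       volcano_stats, xanomeline_like_fixture)

trial = generate_trial(xanomeline_like_fixture())

incidence = ae_incidence(trial)
order = order_terms(incidence, by_arm="High Dose")
print("terms ordered by High Dose incidence:")
for term in order[:5]:
    by_arm = {r.arm: r for r in incidence if r.preferred_term == term}
    cells = ", ".join(f"{arm}: {r.percent:.1f}% ({r.n_subjects_with_event}/"
                      f"{r.n_at_risk})" for arm, r in by_arm.items())
    print(f"  {term}: {cells}")

print()
print("volcano statistics, High Dose vs Placebo (labeled at p < 0.05):")
recs = volcano_stats(trial, "High Dose", "Placebo",
                     label_rule={"p_cutoff": 0.05})
for r in sorted(recs, key=lambda r: r.p_value):
    mark = " *" if r.labeled else ""
    print(f"  {r.preferred_term:28s} RD {r.estimate:+6.1f} pp  "
          f"p={r.p_value:.4f}  FDR p={r.fdr_p:.4f}{mark}")
# A positive risk difference means higher subject-level incidence on
# High Dose; starred terms would carry labels in the volcano figure.
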