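"""Laboratory review workflow: distributions over time, abnormal
prevalence, outlier-trajectory selection, and the shift display.

The creatine-kinase-like parameter carries subject-specific limits of
normal, so abnormality and grading are evaluated against each subject's
own range.
"""

from dmcreport import (abnormal_prevalence, default_grading_rules,
                       generate_trial, select_outlier_subjects, shift_pairs,
                       shift_table, visit_box_stats, xanomeline_like_fixture)

trial = generate_trial(xanomeline_like_fixture())

print("CK distribution by visit (High Dose):")
for b in visit_box_stats(trial, "CK"):
    if b.arm == "High Dose" and b.n:
        print(f"  visit {b.visit_index}: n={b.n:3d} median={b.median:6.1f} "
              f"IQR [{b.q1:6.1f}, {b.q3:6.1f}] outliers={len(b.outlier_values)}")

print()
print("abnormal CK prevalence (high side):")
prev = abnormal_prevalence(trial, "CK", side="high")
print(prev.to_string(index=False))

print()
sel = select_outlier_subjects(trial, "CK", multiplier=3.0,
                              grade_rule=default_grading_rules()["CK"],
                              min_grade=3)
print(f"subjects above 3x their own ULN (or CTC grade >= 3): {sorted(sel)}")
for sid, reasons in sorted(sel.items()):
    print(f"  {sid}: {reasons[0]}")

print()
pairs = shift_pairs(trial, "CHOL")
print(f"CHOL shift pairs (worst case post-baseline): {len(pairs)} subjects")
print(shift_table(pairs).to_string())
# The cross-tabulation is rebuilt from the same pairs that feed the shift
# scatter, so figure and table always agree.
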