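"""Select subjects of special interest and build a one-page profile.

Selection targets subjects with a serious adverse event, a grade >= 3
adverse event, or a grade >= 3 laboratory value; the profile gathers
demographics, history, medication, dosing, adverse events, the lab
parameters that went abnormal, and a key-event timeline.
"""

from dmcreport import (build_profile, default_grading_rules, generate_trial,
                       select_profile_subjects, xanomeline_like_fixture)
from dmcreport.report_builder import format_profile

trial = generate_trial(xanomeline_like_fixture())
rules = default_grading_rules()

selected = select_profile_subjects(trial, rules)
print(f"{len(selected)} subjects selected for detailed review")
first = next(iter(selected))
print(f"example reasons for {first}: {selected[first]}")
print()

profile = build_profile(trial, first, rules)
print(format_profile(profile))
# Every value shown traces back to the source tables; the timeline merges
# exposure, adverse-event and conmed intervals with flagged lab values.
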