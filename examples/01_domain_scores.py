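"""Score one person's typical week on the four well-being domains.

Builds the per-period inputs by hand and applies each threshold scorer,
printing the index each domain contributes to the composite.
"""

from wearwell import (
    ActivitySummary,
    Gender,
    PersonProfile,
    estimate_vo2max,
    score_physical_activity,
    score_sleep,
    score_vo2max,
    score_walking,
)

profile = PersonProfile("demo", age=34, gender=Gender.FEMALE)

steps_per_day = 9200
activity = ActivitySummary(weekly_moderate_min=110, weekly_vigorous_min=25)
sleep_hours = 6.4
hr_max, hr_rest = 186, 58

i_w = score_walking(steps_per_day)
i_p = score_physical_activity(activity)
i_s = score_sleep(profile.age, sleep_hours)
vo2 = estimate_vo2max(hr_max, hr_rest)
i_c = score_vo2max(vo2, profile)

print(f"walking:   {steps_per_day} steps/day            -> I_w = {i_w} (1-5)")
print(
    f"activity:  {activity.moderate_equivalent_min:.0f} moderate-equiv min/week "
    f"-> I_p = {i_p} (1-4)"
)
print(f"sleep:     {sleep_hours} h/night               -> I_s = {i_s} (1/1.75/2)")
print(f"fitness:   VO2max ~ {vo2:.1f} mL/(kg*min)    -> I_c = {i_c} (1-7)")
print()
print("Each index is a rule-based adherence level; higher is better.")
print("I_s = 1.75 marks a mildly risky sleep duration (short of the 7-9 h")
print("recommended band for adults but inside the 'may be appropriate' range).")
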