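"""Adjusted proportion-of-days-covered on a tiny hand-made fill history.

One person fills 34-day statin supplies, sometimes early, sometimes
late, and spends ten days in hospital.  We show how the engine defers
early refills, removes hospital days, truncates supply at the end of
follow-up, and measures both the summary PDC and 102-day interval PDCs.
"""
from pdcox import classify, interval_pdcs, person_schedule, summary_pdc

# fills on days 0, 20 (14 days early), 80, 200; hospital stay days 100-109;
# follow-up from day 0 to day 250
fills = [0, 20, 80, 200]
supplies = [34, 34, 34, 34]
timeline, schedule = person_schedule(
    "patient-1", first_statin_day=0, followup_end_day=250,
    dispense_days=fills, days_supplied=supplies,
    admit_days=[100], discharge_days=[109],
)

print(f"observation window: 250 days, {timeline.removed_days} hospital days removed "
      f"-> {schedule.W} adherence days")
for s, e in zip(schedule.starts, schedule.ends):
    print(f"  covered [{s:3d}, {e:3d})  ({e - s} days)")

overall = summary_pdc(schedule)
print(f"summary PDC: {overall.covered_days}/{overall.denominator_days} "
      f"= {overall.pdc:.3f} -> {classify(overall.pdc)}")
for iv in interval_pdcs(schedule):
    tag = "" if iv.complete else " (incomplete)"
    print(f"interval {iv.interval_index}: [{iv.start:3d},{iv.end:3d}) "
      f"PDC {iv.pdc:.3f} -> {classify(iv.pdc)}{tag}")

# The early refill on day 20 was deferred to day 34 (previous completion
# date), so the four fills chain into one long covered run; the summary
# hides the late-follow-up gap that the interval measures expose.
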