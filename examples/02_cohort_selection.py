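"""Generate a synthetic claims bundle and walk it through cohort selection.

The generator guarantees every person qualifies (index ACS admission,
first statin within 90 days, five years of prior coverage, 102-day
survival), so the exclusion flow is all zeros here; on real claims each
criterion would peel off its share, and the tally documents the flow.
"""
from pdcox import CohortCriteria, generate_bundle, scenario_preset, select_cohort

bundle, truth = generate_bundle(scenario_preset("null", n_persons=500, seed=42))
print(f"claims bundle: {len(bundle.dispensations)} dispensations, "
      f"{len(bundle.hospitalizations)} hospital episodes, {len(bundle.registry)} persons")

selection = select_cohort(bundle, CohortCriteria())
print("\nexclusion flow (applied in order):")
print(selection.tally.to_string(index=False))
print(f"\nretained {len(selection.cohort)} of {selection.n_universe} candidates")
print(selection.cohort[["person_id", "index_day", "first_statin_day",
                        "followup_end_day", "died", "age", "sex"]].head().to_string(index=False))

# Tightening the entry window from 90 to 14 days now excludes everyone
# who took longer to start therapy:
tight = select_cohort(bundle, CohortCriteria(statin_window=14))
n_excluded = tight.tally.set_index("criterion").loc["no_statin_within_window", "n_excluded"]
print(f"\nwith a 14-day statin window, {n_excluded} persons fail the fill-window criterion")
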