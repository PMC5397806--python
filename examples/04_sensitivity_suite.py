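"""The full sensitivity grid on a causal-scenario cohort.

Every parameterization of the adherence covariate — binary at 80%,
three-level (<=20 / 21-79 / >=80), continuous per unit of PDC, and the
first/last-interval classes entered as fixed covariates — fitted crude
and adjusted, for both measurement methods, in one tidy table.
"""
from pdcox import (
    adherence_table,
    generate_bundle,
    scenario_preset,
    select_cohort,
    sensitivity_suite,
)

bundle, _ = generate_bundle(scenario_preset("causal", n_persons=2000, seed=3))
selection = select_cohort(bundle)
adherence = adherence_table(selection.cohort, bundle.dispensations,
                            bundle.hospitalizations)

suite = sensitivity_suite(selection.cohort, adherence,
                          covariate_cols=("age_group", "sex", "revasc", "comorbidity"))
cols = ["variant", "adjustment", "term", "hr", "ci_lower", "ci_upper", "p"]
print(suite[cols].round(3).to_string(index=False))

# The generator's true effect is a 25% hazard reduction for optimal
# adherence in the previous interval, so the repeated_binary rows should
# sit near HR 0.75 while summary rows attenuate toward 1 — the summary
# measure averages over behaviour changes the repeated measure tracks.
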