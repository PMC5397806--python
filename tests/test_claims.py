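"""Claims IO and cohort-selection tests."""
import numpy as np
import pandas as pd
import pytest

from pdcox.claims import (
    ClaimsBundle,
    CohortCriteria,
    SchemaError,
    read_claims_bundle,
    select_cohort,
    write_claims_bundle,
)
from pdcox.simulate import generate_bundle, scenario_preset

from conftest import registry_row, tiny_bundle


class TestIO:
    def test_roundtrip_preserves_records(self, tmp_path):
        bundle, _ = generate_bundle(scenario_preset("null", n_persons=30, seed=3))
        write_claims_bundle(bundle, tmp_path)
        back = read_claims_bundle(tmp_path)
        for name in ("dispensations", "hospitalizations", "registry"):
            a, b = bundle.table(name), back.table(name)
            assert len(a) == len(b)
            pd.testing.assert_frame_equal(
                a.reset_index(drop=True).astype(str), b.reset_index(drop=True).astype(str))
        assert back.rejections.empty

    def test_row_invariants_rejected_with_row_numbers(self, tmp_path):
        pd.DataFrame({
            "person_id": ["a", "b", "c"],
            "dispense_day": [10, 20, 30],
            "days_supplied": [34, 0, 34],
            "drug_class": ["statin"] * 3,
        }).to_csv(tmp_path / "dispensations.csv", index=False)
        pd.DataFrame({
            "person_id": ["a"], "admit_day": [5], "discharge_day": [2], "primary_dx": ["MI"],
        }).to_csv(tmp_path / "hospitalizations.csv", index=False)
        pd.DataFrame([registry_row(p) for p in "abc"]).to_csv(tmp_path / "registry.csv", index=False)
        bundle = read_claims_bundle(tmp_path)
        reasons = dict(zip(bundle.rejections["table"] + ":" + bundle.rejections["row"].astype(str),
                           bundle.rejections["reason"]))
        assert reasons["dispensations:1"] == "days_supplied < 1"
        assert reasons["hospitalizations:0"] == "discharge before admission"
        assert len(bundle.dispensations) == 2
        assert bundle.hospitalizations.empty

    def test_iso_dates_parsed_against_epoch(self, tmp_path):
        pd.DataFrame({
            "person_id": ["a"], "dispense_day": ["1994-02-01"],
            "days_supplied": [34], "drug_class": ["statin"],
        }).to_csv(tmp_path / "dispensations.csv", index=False)
        pd.DataFrame(columns=["person_id", "admit_day", "discharge_day", "primary_dx"]).to_csv(
            tmp_path / "hospitalizations.csv", index=False)
        pd.DataFrame([registry_row("a")]).to_csv(tmp_path / "registry.csv", index=False)
        bundle = read_claims_bundle(tmp_path)
        assert bundle.dispensations.loc[0, "dispense_day"] == 31

    def test_iso_export_round_trips(self, tmp_path):
        bundle, _ = generate_bundle(scenario_preset("null", n_persons=15, seed=4))
        write_claims_bundle(bundle, tmp_path, iso_dates=True)
        back = read_claims_bundle(tmp_path)
        assert back.rejections.empty
        assert (back.dispensations["dispense_day"].to_numpy()
                == bundle.dispensations["dispense_day"].to_numpy()).all()
        first = (tmp_path / "registry.csv").read_text().splitlines()[1]
        assert "-" in first.split(",")[1]  # birth_day rendered as a calendar date

    def test_missing_column_is_schema_error(self, tmp_path):
        pd.DataFrame({"person_id": ["a"]}).to_csv(tmp_path / "dispensations.csv", index=False)
        pd.DataFrame(columns=["person_id", "admit_day", "discharge_day", "primary_dx"]).to_csv(
            tmp_path / "hospitalizations.csv", index=False)
        pd.DataFrame([registry_row("a")]).to_csv(tmp_path / "registry.csv", index=False)
        with pytest.raises(SchemaError):
            read_claims_bundle(tmp_path)

    def test_dispensation_outside_coverage_rejected(self, tmp_path):
        pd.DataFrame({
            "person_id": ["a", "a"], "dispense_day": [10, 6000],
            "days_supplied": [34, 34], "drug_class": ["statin", "statin"],
        }).to_csv(tmp_path / "dispensations.csv", index=False)
        pd.DataFrame(columns=["person_id", "admit_day", "discharge_day", "primary_dx"]).to_csv(
            tmp_path / "hospitalizations.csv", index=False)
        pd.DataFrame([registry_row("a", ce=5478)]).to_csv(tmp_path / "registry.csv", index=False)
        bundle = read_claims_bundle(tmp_path)
        assert len(bundle.dispensations) == 1
        assert "outside coverage" in bundle.rejections.iloc[0]["reason"]


def _one_violation_each():
    """Seven constructed persons: six each violating exactly one criterion."""
    hosp, disp, reg = [], [], []
    for pid in ["ok", "young", "cov", "revasc", "washout", "nofill", "die"]:
        dx = "REVASC_ONLY" if pid == "revasc" else "MI"
        hosp.append((pid, 2000, 2008, dx))
        birth = 2008 - 29 * 365 - 100 if pid == "young" else -40 * 365
        cs = 2000 - 1000 if pid == "cov" else -2000
        death = 2100 if pid == "die" else None
        reg.append(registry_row(pid, birth=birth, cs=cs, death=death))
        if pid != "nofill":
            disp.append((pid, 2010, 34, "statin"))
        if pid == "washout":
            disp.append((pid, 1900, 34, "statin"))
    return tiny_bundle(disp, hosp, reg)


class TestSelectCohort:
    def test_exclusion_cascade_one_per_criterion(self):
        sel = select_cohort(_one_violation_each())
        assert sel.n_universe == 7
        assert len(sel.cohort) == 1
        assert sel.cohort.iloc[0]["person_id"] == "ok"
        assert sel.tally["n_excluded"].tolist() == [1, 1, 1, 1, 1, 1]

    def test_tally_plus_retained_sums_to_universe(self):
        sel = select_cohort(_one_violation_each())
        assert sel.tally["n_excluded"].sum() + len(sel.cohort) == sel.n_universe

    @pytest.mark.parametrize("delay,retained", [(0, 1), (90, 1), (91, 0)])
    def test_statin_window_boundary_inclusive(self, delay, retained):
        b = tiny_bundle([("x", 2008 + delay, 34, "statin")],
                        [("x", 2000, 2008, "MI")],
                        [registry_row("x")])
        assert len(select_cohort(b).cohort) == retained

    def test_age_boundary_at_index(self):
        # 29 at index -> excluded under the age criterion
        b = tiny_bundle([("x", 2010, 34, "statin")], [("x", 2000, 2008, "MI")],
                        [registry_row("x", birth=2008 - 29 * 365)])
        sel = select_cohort(b)
        assert sel.cohort.empty
        assert sel.tally.set_index("criterion").loc["age_below_minimum", "n_excluded"] == 1

    def test_survival_boundary_102_days(self):
        # death exactly 102 days after the first fill is retained
        for offset, retained in [(102, 1), (101, 0)]:
            b = tiny_bundle([("x", 2010, 34, "statin")], [("x", 2000, 2008, "MI")],
                            [registry_row("x", death=2010 + offset)])
            assert len(select_cohort(b).cohort) == retained

    def test_earliest_eligible_discharge_is_index(self):
        b = tiny_bundle([("x", 2505, 34, "statin")],
                        [("x", 2500, 2504, "MI"), ("x", 3000, 3004, "UA")],
                        [registry_row("x")])
        sel = select_cohort(b)
        assert sel.cohort.iloc[0]["index_day"] == 2504

    def test_first_statin_day_within_window(self, causal_run):
        c = causal_run["selection"].cohort
        gap = c["first_statin_day"] - c["index_day"]
        assert ((gap >= 0) & (gap <= 90)).all()

    def test_selection_idempotent(self, causal_run):
        sel = causal_run["selection"]
        bundle = causal_run["bundle"]
        retained = set(sel.cohort["person_id"])
        sub = ClaimsBundle(
            bundle.dispensations[bundle.dispensations.person_id.isin(retained)],
            bundle.hospitalizations[bundle.hospitalizations.person_id.isin(retained)],
            bundle.registry[bundle.registry.person_id.isin(retained)],
        )
        again = select_cohort(sub)
        assert set(again.cohort["person_id"]) == retained
        merged = again.cohort.merge(sel.cohort, on="person_id", suffixes=("_a", "_b"))
        assert (merged["index_day_a"] == merged["index_day_b"]).all()
        assert (merged["followup_end_day_a"] == merged["followup_end_day_b"]).all()

    def test_empty_bundle_empty_cohort(self):
        sel = select_cohort(tiny_bundle([], [], [registry_row("z")]))
        assert sel.cohort.empty and sel.n_universe == 0
        assert (sel.tally["n_excluded"] == 0).all()
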