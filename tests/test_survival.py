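"""Survival-analysis module tests: dataset construction, Cox fits, KM,
concordance, diagnostics, sensitivity suite."""
import numpy as np
import pandas as pd
import pytest

from pdcox.survival import (
    ConstructionError,
    EstimationError,
    build_counting_process,
    build_fixed_dataset,
    check_ph,
    compute_vif,
    concordance_over_time,
    fit_cox,
    first_interval_pdc,
    kaplan_meier,
    last_complete_interval_pdc,
    null_log_likelihood,
    schoenfeld_residuals,
    sensitivity_suite,
)

ADH_COLS = ["person_id", "interval_index", "interval_start", "interval_end",
            "covered_days", "denominator_days", "pdc", "adherent", "complete"]


def one_person_adherence():
    # death at day 250 post fill; 34-day fills at days 0 and 102 only
    return pd.DataFrame([
        ("p", 0, 0, 250, 68, 250, 68 / 250, False, True),
        ("p", 1, 0, 102, 34, 102, 34 / 102, False, True),
        ("p", 2, 102, 204, 34, 102, 34 / 102, False, True),
        ("p", 3, 204, 250, 0, 46, 0.0, False, False),
    ], columns=ADH_COLS)


def one_person_cohort(died=True):
    return pd.DataFrame([dict(person_id="p", died=died,
                              first_statin_day=0, followup_end_day=250)])


class TestFixedDataset:
    def test_duration_from_origin_and_event(self):
        ds, dropped = build_fixed_dataset(one_person_cohort(), one_person_adherence(),
                                          form="continuous")
        assert dropped == 0
        assert ds.loc[0, "duration"] == 148.0
        assert bool(ds.loc[0, "event"])
        assert ds.loc[0, "pdc"] == pytest.approx(68 / 250)

    def test_zero_at_risk_person_dropped_and_counted(self):
        adh = pd.DataFrame([("q", 0, 0, 102, 50, 102, 50 / 102, False, True),
                            ("q", 1, 0, 102, 50, 102, 50 / 102, False, True)],
                           columns=ADH_COLS)
        cohort = pd.DataFrame([dict(person_id="q", died=False,
                                    first_statin_day=0, followup_end_day=102)])
        ds, dropped = build_fixed_dataset(cohort, adh)
        assert ds.empty and dropped == 1


class TestCountingProcess:
    def test_row_structure_concurrent(self):
        cp, _ = build_counting_process(one_person_cohort(), one_person_adherence(),
                                       form="continuous", timing="concurrent")
        assert cp["start"].tolist() == [0.0, 102.0]
        assert cp["stop"].tolist() == [102.0, 148.0]
        assert cp["pdc"].tolist() == pytest.approx([34 / 102, 0.0])
        assert cp["event"].tolist() == [False, True]

    def test_row_structure_lagged(self):
        cp, _ = build_counting_process(one_person_cohort(), one_person_adherence(),
                                       form="continuous", timing="lagged")
        # risk interval k carries interval k-1's PDC
        assert cp["pdc"].tolist() == pytest.approx([34 / 102, 34 / 102])

    def test_at_risk_time_conservation(self, causal_run):
        sel, adh = causal_run["selection"], causal_run["adherence"]
        fd, _ = build_fixed_dataset(sel.cohort, adh)
        cp, _ = build_counting_process(sel.cohort, adh)
        per_person = cp.groupby("person_id").apply(
            lambda g: (g["stop"] - g["start"]).sum(), include_groups=False)
        merged = fd.set_index("person_id")["duration"]
        assert np.allclose(per_person.reindex(merged.index), merged)
        # events conserved too
        assert cp["event"].sum() == fd["event"].sum()

    def test_gap_in_intervals_raises_naming_person(self):
        adh = one_person_adherence()
        adh.loc[adh["interval_index"] == 2, "interval_start"] = 110
        with pytest.raises(ConstructionError, match="p"):
            build_counting_process(one_person_cohort(), adh)

    def test_fully_covered_person_all_rows_optimal(self):
        adh = pd.DataFrame(
            [("r", 0, 0, 306, 306, 306, 1.0, True, True)]
            + [("r", k, 102 * (k - 1), 102 * k, 102, 102, 1.0, True, True)
               for k in (1, 2, 3)], columns=ADH_COLS)
        cohort = pd.DataFrame([dict(person_id="r", died=False,
                                    first_statin_day=0, followup_end_day=306)])
        cp, _ = build_counting_process(cohort, adh)
        assert (cp["adherent"] == 1.0).all()


class TestFitCox:
    def test_two_group_exponential_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(42)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.01 * np.exp(np.log(0.5) * x)))
        df = pd.DataFrame({"person_id": np.arange(n),
                           "duration": np.minimum(t, 300.0),
                           "event": t <= 300.0, "adherent": x})
        fit = fit_cox(df)
        r = fit.term("adherent")
        assert r["ci_lower"] < 0.5 < r["ci_upper"]
        assert fit.n_events == int(df["event"].sum())

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(1)
        covered = 0
        for _ in range(20):
            n = 400
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(100, n)
            df = pd.DataFrame({"person_id": np.arange(n), "duration": np.minimum(t, 150.0),
                               "event": t <= 150.0, "adherent": x})
            r = fit_cox(df).term("adherent")
            covered += r["ci_lower"] <= 1.0 <= r["ci_upper"]
        assert covered >= 16  # ~95% nominal over 20 draws

    def test_constant_covariate_not_estimable(self):
        df = pd.DataFrame({"person_id": [1, 2], "duration": [5.0, 7.0],
                           "event": [True, True], "adherent": [1.0, 1.0]})
        with pytest.raises(EstimationError):
            fit_cox(df)

    def test_no_events_not_estimable(self):
        df = pd.DataFrame({"person_id": [1, 2], "duration": [5.0, 7.0],
                           "event": [False, False], "adherent": [1.0, 0.0]})
        with pytest.raises(EstimationError):
            fit_cox(df)

    def test_null_partial_likelihood_identity(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(50, n)
        df = pd.DataFrame({"person_id": np.arange(n), "duration": np.minimum(t, 80.0),
                           "event": t <= 80.0, "adherent": x})
        fit = fit_cox(df)
        llr = fit.model.log_likelihood_ratio_test().test_statistic
        assert null_log_likelihood(df) == pytest.approx(fit.log_likelihood - llr / 2, rel=1e-9)

    def test_counting_and_fixed_agree_for_time_constant_covariates(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        t = np.minimum(rng.exponential(1 / (0.005 * np.exp(-0.4 * x))), 400.0)
        ev = t < 400.0
        fixed = pd.DataFrame({"person_id": np.arange(n), "duration": t,
                              "event": ev, "adherent": x})
        rows = []
        for i in range(n):
            k = 0
            while k * 102 < t[i]:
                stop = min((k + 1) * 102, t[i])
                rows.append((i, k * 102.0, stop, bool(ev[i] and stop == t[i]), x[i]))
                k += 1
        counting = pd.DataFrame(rows, columns=["person_id", "start", "stop", "event", "adherent"])
        ca, cb = fit_cox(fixed).term("adherent")["coef"], fit_cox(counting).term("adherent")["coef"]
        assert ca == pytest.approx(cb, abs=1e-6)


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        df = pd.DataFrame({"person_id": [1, 2, 3], "duration": [5.0, 10.0, 12.0],
                           "event": [True, True, False], "adherent": [1.0] * 3})
        km = kaplan_meier(df)
        s = km.set_index("time")["survival"]
        assert s.loc[5.0] == pytest.approx(2 / 3)
        assert s.loc[10.0] == pytest.approx(1 / 3)

    def test_no_events_flat_at_one(self):
        df = pd.DataFrame({"person_id": [1, 2], "duration": [5.0, 9.0],
                           "event": [False, False], "adherent": [1.0, 1.0]})
        km = kaplan_meier(df)
        assert (km["survival"] == 1.0).all()

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"person_id": np.arange(50),
                           "duration": rng.exponential(40, 50).round(1) + 1,
                           "event": rng.random(50) < 0.6,
                           "adherent": rng.integers(0, 2, 50).astype(float)})
        km1 = kaplan_meier(df)
        km2 = kaplan_meier(df.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(km1.reset_index(drop=True), km2.reset_index(drop=True))

    def test_curves_nonincreasing_from_one(self, causal_run):
        sel, adh = causal_run["selection"], causal_run["adherence"]
        cp, _ = build_counting_process(sel.cohort, adh)
        km = kaplan_meier(cp)
        for _, g in km.groupby("group"):
            s = g.sort_values("time")["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)


class TestConcordance:
    def test_hand_tabulated_two_by_two(self):
        rows = []
        for pid, (s_adh, i_adh) in enumerate(
                [(True, True), (False, False), (False, True), (False, True)]):
            rows.append((pid, 0, 0, 204, 0, 204, 0.9 if s_adh else 0.1, s_adh, True))
            rows.append((pid, 2, 102, 204, 0, 102, 0.9 if i_adh else 0.1, i_adh, True))
        conc = concordance_over_time(pd.DataFrame(rows, columns=ADH_COLS))
        r = conc.set_index("interval_index").loc[2]
        assert r["pct_match"] == pytest.approx(50.0)
        assert r["pct_summary_nonadh_interval_adh"] == pytest.approx(50.0)
        assert r["pct_summary_adh_interval_nonadh"] == pytest.approx(0.0)

    def test_percentages_partition(self, causal_run):
        conc = concordance_over_time(causal_run["adherence"])
        total = (conc["pct_match"] + conc["pct_summary_nonadh_interval_adh"]
                 + conc["pct_summary_adh_interval_nonadh"])
        assert np.allclose(total, 100.0)

    def test_constant_behaviour_fully_concordant(self):
        rows = []
        for pid in range(3):
            rows.append((pid, 0, 0, 204, 204, 204, 1.0, True, True))
            for k in (1, 2):
                rows.append((pid, k, 102 * (k - 1), 102 * k, 102, 102, 1.0, True, True))
        conc = concordance_over_time(pd.DataFrame(rows, columns=ADH_COLS))
        assert (conc["pct_match"] == 100.0).all()


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(17)
    n = 600
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.01 * np.exp(-0.3 * x)))
    df = pd.DataFrame({"person_id": np.arange(n), "duration": np.minimum(t, 250.0),
                       "event": t <= 250.0, "adherent": x})
    return fit_cox(df), df


class TestDiagnostics:
    def test_residual_count_equals_events(self, fitted):
        fit, df = fitted
        res = schoenfeld_residuals(fit, df)
        assert len(res) == fit.n_events

    def test_ph_not_rejected_under_proportional_hazards(self, fitted):
        fit, df = fitted
        diag = check_ph(fit, df)
        assert diag.test.loc["adherent", "p"] > 0.01
        assert diag.loglog is not None

    def test_diagnostics_need_two_events(self):
        df = pd.DataFrame({"person_id": [1, 2], "duration": [3.0, 9.0],
                           "event": [True, False], "adherent": [1.0, 0.0]})
        fit = fit_cox(pd.concat([df] * 3, ignore_index=True))
        fit.n_events = 1
        with pytest.raises(EstimationError):
            check_ph(fit, df)

    def test_reversing_effect_detected(self):
        # hazard ratio flips mid-study: slope test should reject
        rng = np.random.default_rng(23)
        n = 1500
        x = rng.integers(0, 2, n).astype(float)
        t1 = rng.exponential(1 / (0.02 * np.exp(-1.5 * x)))
        flip = t1 > 50
        t = np.where(flip, 50 + rng.exponential(1 / (0.02 * np.exp(1.5 * x))), t1)
        df = pd.DataFrame({"person_id": np.arange(n), "duration": np.minimum(t, 200.0),
                           "event": t <= 200.0, "adherent": x})
        diag = check_ph(fit_cox(df), df)
        assert diag.test.loc["adherent", "p"] < 0.01


class TestVIF:
    def test_orthogonal_covariates_unity(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]}, dtype=float)
        vif = compute_vif(X)
        assert np.allclose(vif["vif"], 1.0)
        assert not vif["flagged"].any()

    def test_near_duplicate_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        X = pd.DataFrame({"a": a, "b": rng.normal(size=200),
                          "c": a + rng.normal(scale=0.05, size=200)})
        vif = compute_vif(X)
        assert vif.set_index("covariate").loc["c", "vif"] > 10
        assert vif.set_index("covariate").loc["c", "flagged"]

    def test_exact_duplicate_infinite(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        vif = compute_vif(pd.DataFrame({"a": a, "b": rng.normal(size=50), "d": a}))
        by = vif.set_index("covariate")
        assert np.isinf(by.loc["d", "vif"]) and by.loc["d", "flagged"]


@pytest.fixture(scope="module")
def suite(causal_run):
    sel, adh = causal_run["selection"], causal_run["adherence"]
    return sensitivity_suite(sel.cohort, adh,
                             covariate_cols=("age_group", "sex", "revasc", "comorbidity"))


class TestSensitivitySuite:
    def test_one_row_per_variant_adjustment_term(self, suite):
        ok = suite[suite["error"].isna()]
        counts = ok.groupby(["variant", "adjustment"]).size()
        # binary/continuous variants yield 1 adherence term, three-level 2
        for (variant, _), n in counts.items():
            assert n == (2 if "three_level" in variant else 1)
        assert set(suite["adjustment"]) == {"crude", "adjusted"}
        assert len(set(suite["variant"])) == 8

    def test_errors_recorded_not_raised(self):
        # single person: adherence covariate cannot vary -> error rows
        suite = sensitivity_suite(one_person_cohort(), one_person_adherence())
        assert suite["error"].notna().any()

    def test_first_last_interval_sources(self, causal_run):
        adh = causal_run["adherence"]
        last = last_complete_interval_pdc(adh)
        first = first_interval_pdc(adh)
        one = adh[(adh["person_id"] == first.index[0]) & (adh["interval_index"] == 1)]
        assert first.iloc[0] == pytest.approx(one["pdc"].iloc[0])
        complete = adh[(adh["interval_index"] >= 1) & adh["complete"]]
        km = complete[complete["person_id"] == last.index[0]]["interval_index"].max()
        val = complete[(complete["person_id"] == last.index[0])
                       & (complete["interval_index"] == km)]["pdc"].iloc[0]
        assert last.iloc[0] == pytest.approx(val)
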