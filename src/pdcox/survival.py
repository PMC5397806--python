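"""Fixed and time-dependent survival analysis of adherence.

Two ways of entering the same PDC information into a Cox
proportional-hazards model of all-cause death:

* **method A** — one summary PDC per person, entered as a fixed
  (baseline) covariate;
* **method B** — interval PDCs entered as a time-dependent
  repeated-measure covariate in counting-process ``(start, stop]``
  rows, re-assessed every measurement interval.

Risk time starts one full measurement interval (default 102 days) after
the first statin fill, so the first interval is never at risk and early
deaths do not contaminate either measure.  All times are on the
compressed (hospital-free) clock used by the adherence engine, which
keeps the model's risk intervals aligned with the PDC measurement
windows.

Model fitting is delegated to lifelines (Efron ties); Kaplan-Meier
description, Schoenfeld-based proportional-hazards diagnostics,
variance-inflation screening, concordance between the two measures, and
the sensitivity suite (three-level, continuous, first/last-interval
variants) are provided on top.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .adherence import OPTIMAL_THRESHOLD, classify

logger = logging.getLogger(__name__)

DEFAULT_ORIGIN_OFFSET = 102


class EstimationError(RuntimeError):
    """Model cannot be estimated (degenerate design, no events, non-convergence)."""


class ConstructionError(ValueError):
    """Dataset construction failed (gaps/overlaps in a person's intervals)."""


# ---------------------------------------------------------------------------
# adherence covariate encodings
# ---------------------------------------------------------------------------

def adherence_covariate(pdc: pd.Series, form: str, threshold: float = OPTIMAL_THRESHOLD) -> pd.DataFrame:
    """Encode a PDC series as model columns.

    binary      -> ``adherent`` in {0,1} (1 iff pdc >= threshold)
    three_level -> dummies ``adh_middle``, ``adh_optimal`` (reference: low)
    continuous  -> ``pdc`` as-is (hazard ratio per 1-unit increase)
    """
    if form == "binary":
        return pd.DataFrame({"adherent": (pdc >= threshold).astype(float)})
    if form == "three_level":
        labels = pdc.map(lambda v: classify(v, "three_level"))
        return pd.DataFrame({
            "adh_middle": (labels == "middle").astype(float),
            "adh_optimal": (labels == "optimal").astype(float),
        })
    if form == "continuous":
        return pd.DataFrame({"pdc": pdc.astype(float)})
    raise ValueError(f"unknown adherence form {form!r}")


def encode_covariates(df: pd.DataFrame, covariate_cols: Sequence[str]) -> pd.DataFrame:
    """Numeric passthrough, categorical one-hot (first level dropped as reference)."""
    if not covariate_cols:
        return pd.DataFrame(index=df.index)
    sub = df[list(covariate_cols)]
    return pd.get_dummies(sub, drop_first=True, dtype=float)


def _summary_rows(adherence: pd.DataFrame) -> pd.DataFrame:
    s = adherence[adherence["interval_index"] == 0].set_index("person_id")
    return s


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def build_fixed_dataset(
    cohort: pd.DataFrame,
    adherence: pd.DataFrame,
    covariate_cols: Sequence[str] = (),
    form: str = "binary",
    threshold: float = OPTIMAL_THRESHOLD,
    origin_offset: int = DEFAULT_ORIGIN_OFFSET,
    pdc_override: pd.Series | None = None,
) -> tuple[pd.DataFrame, int]:
    """Method A rows: one ``(duration, event)`` record per person.

    ``duration`` runs from the analysis origin (``origin_offset`` days
    after the first fill, on the compressed clock) to follow-up end.
    Persons with zero at-risk time or missing adherence are dropped and
    counted in the returned drop count.  ``pdc_override`` substitutes
    another per-person PDC series (used by the first/last-interval
    sensitivity variants) for the summary PDC.
    """
    s = _summary_rows(adherence)
    df = cohort.set_index("person_id")
    pdc = pdc_override if pdc_override is not None else s["pdc"]
    out = pd.DataFrame({
        "duration": (s["denominator_days"] - origin_offset).astype(float),
        "event": df["died"].astype(bool),
        "_pdc": pdc,
    }, index=s.index)
    cov = encode_covariates(df, covariate_cols)
    out = out.join(cov, how="left")
    n0 = len(out)
    keep = (out["duration"] > 0) & out["_pdc"].notna()
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.info("fixed dataset: dropped %d person(s) with zero at-risk time or missing PDC", dropped)
    out = out[keep]
    adh = adherence_covariate(out["_pdc"], form, threshold)
    out = pd.concat([adh.set_index(out.index), out.drop(columns="_pdc")], axis=1)
    return out.reset_index().rename(columns={"index": "person_id"}), dropped


def build_counting_process(
    cohort: pd.DataFrame,
    adherence: pd.DataFrame,
    covariate_cols: Sequence[str] = (),
    form: str = "binary",
    threshold: float = OPTIMAL_THRESHOLD,
    timing: str = "lagged",
    origin_offset: int = DEFAULT_ORIGIN_OFFSET,
    interval_len: int = DEFAULT_ORIGIN_OFFSET,
) -> tuple[pd.DataFrame, int]:
    """Method B rows: one ``(start, stop]`` record per at-risk interval.

    Row *k* (k >= 2) covers ``(L(k-1), min(Lk, W)] - origin`` with the
    adherence covariate taken from interval *k-1* when
    ``timing="lagged"`` (default) or from interval *k* itself when
    ``timing="concurrent"``; the death indicator sits on the final row.
    A person's intervals must partition ``[0, W)`` — gaps or overlaps
    raise :class:`ConstructionError` naming the person.

    Lagged is the default because the covariate of each risk interval
    is then a fully observed, complete measurement interval.  Under
    concurrent timing the death interval's covariate is measured on a
    window truncated by the death itself, which makes the event-row
    covariate a near-uninformative short-window classification; that
    mode is retained for comparison.
    """
    if timing not in ("concurrent", "lagged"):
        raise ValueError(f"unknown timing {timing!r}")
    ivs = adherence[adherence["interval_index"] >= 1].sort_values(
        ["person_id", "interval_index"], kind="stable").reset_index(drop=True)
    if ivs.empty:
        return pd.DataFrame(columns=["person_id", "start", "stop", "event"]), 0
    pid = ivs["person_id"].to_numpy()
    same = np.concatenate([[False], pid[1:] == pid[:-1]])
    iv_start = ivs["interval_start"].to_numpy()
    iv_end = ivs["interval_end"].to_numpy()
    prev_end = np.concatenate([[0], iv_end[:-1]])
    bad = np.where((~same & (iv_start != 0)) | (same & (iv_start != prev_end)))[0]
    if len(bad):
        raise ConstructionError(
            f"person {pid[bad[0]]!r}: intervals do not partition follow-up")

    # lagged covariate = previous row's pdc within person (interval 1 lags to NaN)
    pdc = ivs["pdc"].to_numpy(dtype=float)
    if timing == "lagged":
        pdc = np.where(same, np.concatenate([[np.nan], pdc[:-1]]), np.nan)

    is_last = np.concatenate([~same[1:], [True]])
    W = np.zeros(len(ivs), dtype=np.int64)
    W[is_last] = iv_end[is_last]
    person_W = pd.Series(W[is_last], index=pid[is_last])
    dropped = int((person_W <= origin_offset).sum())

    keep = (iv_end > origin_offset) & (person_W.reindex(pid).to_numpy() > origin_offset)
    out = pd.DataFrame({
        "person_id": pid[keep],
        "start": (np.maximum(iv_start[keep], origin_offset) - origin_offset).astype(float),
        "stop": (iv_end[keep] - origin_offset).astype(float),
    })
    died = cohort.set_index("person_id")["died"].astype(bool)
    out["event"] = is_last[keep] & died.reindex(pid[keep]).fillna(False).to_numpy()
    adh = adherence_covariate(pd.Series(pdc[keep]), form, threshold)
    out = pd.concat([out[["person_id", "start", "stop"]], adh, out[["event"]]], axis=1)
    cov = encode_covariates(cohort.set_index("person_id"), covariate_cols)
    if len(cov.columns):
        out = out.join(cov, on="person_id")
    return out, dropped


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Fitted hazard ratios with confidence intervals and bookkeeping.

    ``summary`` is indexed by model term with columns coef, se, hr,
    ci_lower, ci_upper, p.  ``model`` retains the fitted lifelines
    object for diagnostics.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"
    layout: str = "fixed"
    model: object = None
    training: pd.DataFrame | None = field(default=None, repr=False)

    def term(self, name: str) -> pd.Series:
        return self.summary.loc[name]

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]


def _is_counting(df: pd.DataFrame) -> bool:
    return "start" in df.columns and "stop" in df.columns


def fit_cox(df: pd.DataFrame, robust: bool = False) -> CoxResult:
    """Maximize the Cox partial likelihood (Efron ties) on either layout.

    The layout is inferred from the columns: ``(duration, event)``
    fixed rows fit a :class:`~lifelines.CoxPHFitter`;
    ``(start, stop, event)`` counting-process rows are fitted as
    left-truncated segments via ``entry_col`` (the Andersen-Gill
    partial likelihood — identical estimates and information-based
    standard errors), or with a
    :class:`~lifelines.CoxTimeVaryingFitter` clustered by person when
    ``robust=True``.  Every column other than the bookkeeping ones is a
    covariate.  A covariate that does not vary, or a dataset without
    events, is non-estimable.
    """
    counting = _is_counting(df)
    reserved = {"person_id", "event", "start", "stop", "duration"}
    covars = [c for c in df.columns if c not in reserved]
    if not covars:
        raise EstimationError("no covariates to fit")
    if df["event"].sum() < 1:
        raise EstimationError("no events in dataset")
    for c in covars:
        if df[c].nunique(dropna=True) < 2:
            raise EstimationError(f"covariate {c!r} does not vary; model not estimable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if counting and robust:
                training = df[["person_id", "start", "stop", "event"] + covars]
                fitter = CoxTimeVaryingFitter()
                fitter.fit(training, id_col="person_id", start_col="start", stop_col="stop",
                           event_col="event", robust=True)
            elif counting:
                training = df[["start", "stop", "event"] + covars]
                fitter = CoxPHFitter()
                fitter.fit(training, entry_col="start", duration_col="stop", event_col="event")
            else:
                training = df[["duration", "event"] + covars]
                fitter = CoxPHFitter()
                fitter.fit(training, duration_col="duration", event_col="event", robust=robust)
        except Exception as exc:  # lifelines raises ConvergenceError/ValueError
            raise EstimationError(f"Cox fit failed: {exc}") from exc
    s = fitter.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_lower": s["exp(coef) lower 95%"],
        "ci_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    n = df["person_id"].nunique() if "person_id" in df.columns else len(df)
    return CoxResult(
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        n=int(n),
        n_events=int(df["event"].sum()),
        layout="counting" if counting else "fixed",
        model=fitter,
        training=training,
    )


def null_log_likelihood(df: pd.DataFrame) -> float:
    """Cox partial log-likelihood with every coefficient forced to zero.

    With all relative hazards equal to one, the Efron tie correction at
    an event time with *d* deaths contributes ``-sum_{l<d} log(n_at_risk
    - l)``.  Computed directly from the risk sets, independent of any
    fitted model.
    """
    if _is_counting(df):
        start, stop = df["start"].to_numpy(), df["stop"].to_numpy()
    else:
        stop = df["duration"].to_numpy()
        start = np.zeros_like(stop)
    event = df["event"].to_numpy(dtype=bool)
    ll = 0.0
    for t, d in zip(*np.unique(stop[event], return_counts=True)):
        n_risk = int(np.sum((start < t) & (stop >= t)))
        ll -= sum(np.log(n_risk - l) for l in range(d))
    return ll


# ---------------------------------------------------------------------------
# Kaplan-Meier description
# ---------------------------------------------------------------------------

def kaplan_meier(df: pd.DataFrame, group_col: str = "adherent") -> pd.DataFrame:
    """Per-group product-limit survival curves as a tidy step-function table.

    Fixed rows give the classical grouped Kaplan-Meier.  Counting-process
    rows give the extended (Simon-Makuch-style) estimator: each row
    contributes its person-time to the group matching its current
    covariate value, entering the risk set at ``start`` (left
    truncation) and leaving at ``stop``.  Columns: group, time,
    survival, n_at_risk.  Curves start at 1 and are nonincreasing.
    """
    if df.empty:
        raise EstimationError("no rows for Kaplan-Meier")
    counting = _is_counting(df)
    out = []
    for grp, g in df.groupby(group_col):
        if g.empty:
            logger.warning("Kaplan-Meier: empty group %r omitted", grp)
            continue
        kmf = KaplanMeierFitter()
        if counting:
            kmf.fit(g["stop"], event_observed=g["event"], entry=g["start"])
        else:
            kmf.fit(g["duration"], event_observed=g["event"])
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        out.append(pd.DataFrame({
            "group": grp, "time": sf.index.to_numpy(dtype=float),
            "survival": sf.to_numpy(), "n_at_risk": at_risk.to_numpy(dtype=float),
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# concordance between the two measures
# ---------------------------------------------------------------------------

def concordance_over_time(adherence: pd.DataFrame, threshold: float = OPTIMAL_THRESHOLD) -> pd.DataFrame:
    """Cross-tabulate the summary class against each interval's class.

    For every interval index *k*, among persons whose *k*-th interval is
    complete (spans the full length), report the percentage whose binary
    summary class matches the interval class, and the two discordant
    percentages.  The three percentages sum to 100 per interval.
    """
    s = _summary_rows(adherence)
    summary_adh = (s["pdc"] >= threshold)
    ivs = adherence[(adherence["interval_index"] >= 1) & adherence["complete"]].copy()
    ivs["interval_adh"] = ivs["pdc"] >= threshold
    ivs["summary_adh"] = ivs["person_id"].map(summary_adh)
    rows = []
    for k, g in ivs.groupby("interval_index"):
        n = len(g)
        if n == 0:
            continue
        match = (g["interval_adh"] == g["summary_adh"]).mean() * 100
        s_non_i_adh = ((~g["summary_adh"]) & g["interval_adh"]).mean() * 100
        s_adh_i_non = (g["summary_adh"] & ~g["interval_adh"]).mean() * 100
        rows.append((int(k), n, match, s_non_i_adh, s_adh_i_non))
    return pd.DataFrame(rows, columns=[
        "interval_index", "n", "pct_match",
        "pct_summary_nonadh_interval_adh", "pct_summary_adh_interval_nonadh",
    ])


def last_complete_interval_pdc(adherence: pd.DataFrame) -> pd.Series:
    """Per-person PDC of the last complete measurement interval."""
    ivs = adherence[(adherence["interval_index"] >= 1) & adherence["complete"]]
    idx = ivs.groupby("person_id")["interval_index"].idxmax()
    return ivs.loc[idx].set_index("person_id")["pdc"]


def first_interval_pdc(adherence: pd.DataFrame) -> pd.Series:
    """Per-person PDC of the first measurement interval."""
    ivs = adherence[adherence["interval_index"] == 1]
    return ivs.set_index("person_id")["pdc"]


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PHDiagnostics:
    """Proportional-hazards diagnostics for a fitted model.

    ``test``: per-covariate slope test of Schoenfeld residuals against
    event time (statistic, p).  ``residuals``: one row per event with
    the residual series per covariate.  ``loglog``: log(-log S(t)) curve
    data per group of the adherence covariate, for visual assessment.
    """

    test: pd.DataFrame
    residuals: pd.DataFrame
    loglog: pd.DataFrame | None = None


def schoenfeld_residuals(result: CoxResult, df: pd.DataFrame) -> pd.DataFrame:
    """Schoenfeld residuals at each event time, for either layout.

    The residual for the subject failing at time *t* is its covariate
    vector minus the hazard-weighted mean covariate over the risk set at
    *t*, with weights exp(x'beta) from the fitted model.  Row index:
    event time (ties keep separate rows).
    """
    covars = list(result.summary.index)
    beta = result.summary["coef"].to_numpy()
    X = df[covars].to_numpy(dtype=float)
    if _is_counting(df):
        start, stop = df["start"].to_numpy(), df["stop"].to_numpy()
    else:
        stop = df["duration"].to_numpy()
        start = np.zeros_like(stop)
    event = df["event"].to_numpy(dtype=bool)
    w = np.exp(X @ beta)
    rows, times = [], []
    for i in np.flatnonzero(event):
        t = stop[i]
        at_risk = (start < t) & (stop >= t)
        wr = w[at_risk]
        xbar = (wr[:, None] * X[at_risk]).sum(axis=0) / wr.sum()
        rows.append(X[i] - xbar)
        times.append(t)
    out = pd.DataFrame(rows, columns=covars)
    out.index = pd.Index(times, name="event_time")
    return out.sort_index()


def check_ph(result: CoxResult, df: pd.DataFrame) -> PHDiagnostics:
    """Schoenfeld-based proportional-hazards check plus log(-log) curve data.

    For fixed-layout fits the slope test is lifelines'
    ``proportional_hazard_test`` on observed event time; for
    counting-process fits an ordinary least-squares slope test of the
    residual series against event time is used.  The log(-log S) curves
    are emitted as data for visual assessment, not auto-judged.
    """
    if result.n_events < 2:
        raise EstimationError("proportional-hazards diagnostics need >= 2 events")
    res = schoenfeld_residuals(result, df)
    if result.layout == "fixed":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = proportional_hazard_test(result.model, result.training, time_transform="rank")
        test = pd.DataFrame({
            "statistic": ph.summary["test_statistic"],
            "p": ph.summary["p"],
        })
        test.index = [ix[0] if isinstance(ix, tuple) else ix for ix in test.index]
    else:
        rows = {}
        t = res.index.to_numpy(dtype=float)
        for c in res.columns:
            slope = stats.linregress(t, res[c].to_numpy())
            rows[c] = (slope.slope / slope.stderr if slope.stderr > 0 else 0.0, slope.pvalue)
        test = pd.DataFrame(rows, index=["statistic", "p"]).T
    loglog = None
    grp_col = next((c for c in ("adherent", "adh_optimal", "pdc") if c in df.columns), None)
    if grp_col is not None and df[grp_col].nunique() <= 5:
        km = kaplan_meier(df, group_col=grp_col)
        km = km[(km["survival"] > 0) & (km["survival"] < 1)].copy()
        km["log_neg_log_s"] = np.log(-np.log(km["survival"]))
        loglog = km[["group", "time", "log_neg_log_s"]]
    return PHDiagnostics(test=test, residuals=res, loglog=loglog)


def compute_vif(covariates: pd.DataFrame, flag_above: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor per covariate: VIF_j = 1 / (1 - R²_j).

    R²_j comes from regressing covariate *j* on all the others (with an
    intercept).  Perfect collinearity reports an infinite VIF.  Columns:
    covariate, vif, flagged.
    """
    X = covariates.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    out = []
    ones = np.ones((len(X), 1))
    for j, col in enumerate(X.columns):
        y = X[col].to_numpy()
        others = np.hstack([ones, X.drop(columns=col).to_numpy()])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"covariate {col!r} is constant")
        r2 = 1 - ss_res / ss_tot
        vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        out.append((col, vif, vif > flag_above))
    return pd.DataFrame(out, columns=["covariate", "vif", "flagged"])


# ---------------------------------------------------------------------------
# sensitivity suite
# ---------------------------------------------------------------------------

SUITE_VARIANTS = (
    ("summary_binary", "A", "binary"),
    ("repeated_binary", "B", "binary"),
    ("summary_three_level", "A", "three_level"),
    ("repeated_three_level", "B", "three_level"),
    ("summary_continuous", "A", "continuous"),
    ("repeated_continuous", "B", "continuous"),
    ("last_interval_fixed", "A", "binary"),
    ("first_interval_fixed", "A", "binary"),
)


def sensitivity_suite(
    cohort: pd.DataFrame,
    adherence: pd.DataFrame,
    covariate_cols: Sequence[str] = (),
    threshold: float = OPTIMAL_THRESHOLD,
    timing: str = "lagged",
    origin_offset: int = DEFAULT_ORIGIN_OFFSET,
    interval_len: int = DEFAULT_ORIGIN_OFFSET,
) -> pd.DataFrame:
    """Run the full grid of adherence parameterizations, crude and adjusted.

    Variants: binary/three-level/continuous adherence for both methods,
    plus the last-complete-interval and first-interval classes entered
    as fixed covariates.  Per-variant estimation errors are recorded in
    the output rather than aborting the suite.  Tidy columns: variant,
    method, adjustment, term, coef, hr, ci_lower, ci_upper, p, n,
    events, error.
    """
    rows = []
    for variant, method, form in SUITE_VARIANTS:
        try:
            if variant == "last_interval_fixed":
                ds, _ = build_fixed_dataset(cohort, adherence, covariate_cols, "binary",
                                            threshold, origin_offset,
                                            pdc_override=last_complete_interval_pdc(adherence))
                crude_ds, _ = build_fixed_dataset(cohort, adherence, (), "binary", threshold,
                                                  origin_offset,
                                                  pdc_override=last_complete_interval_pdc(adherence))
            elif variant == "first_interval_fixed":
                ds, _ = build_fixed_dataset(cohort, adherence, covariate_cols, "binary",
                                            threshold, origin_offset,
                                            pdc_override=first_interval_pdc(adherence))
                crude_ds, _ = build_fixed_dataset(cohort, adherence, (), "binary", threshold,
                                                  origin_offset,
                                                  pdc_override=first_interval_pdc(adherence))
            elif method == "A":
                ds, _ = build_fixed_dataset(cohort, adherence, covariate_cols, form, threshold, origin_offset)
                crude_ds, _ = build_fixed_dataset(cohort, adherence, (), form, threshold, origin_offset)
            else:
                ds, _ = build_counting_process(cohort, adherence, covariate_cols, form,
                                               threshold, timing, origin_offset, interval_len)
                crude_ds, _ = build_counting_process(cohort, adherence, (), form,
                                                     threshold, timing, origin_offset, interval_len)
        except Exception as exc:
            for adj in ("crude", "adjusted"):
                rows.append(dict(variant=variant, method=method, adjustment=adj, term=None,
                                 error=str(exc)))
            continue
        for adj, data in (("crude", crude_ds), ("adjusted", ds)):
            try:
                fit = fit_cox(data)
                adh_terms = [t for t in fit.summary.index
                             if t in ("adherent", "adh_middle", "adh_optimal", "pdc")]
                for t in adh_terms:
                    r = fit.term(t)
                    rows.append(dict(variant=variant, method=method, adjustment=adj, term=t,
                                     coef=r["coef"], hr=r["hr"], ci_lower=r["ci_lower"],
                                     ci_upper=r["ci_upper"], p=r["p"],
                                     n=fit.n, events=fit.n_events, error=None))
            except Exception as exc:
                rows.append(dict(variant=variant, method=method, adjustment=adj, term=None,
                                 error=str(exc)))
    return pd.DataFrame(rows)
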