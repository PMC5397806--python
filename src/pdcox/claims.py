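"""Administrative-claims tables, delimited-file IO, and cohort selection.

Three tables describe a pharmacy-claims world, all keyed by
``person_id`` and carrying dates as integer days since a configurable
epoch (default 1994-01-01):

* **dispensations** — one row per pharmacy fill (day, days supplied,
  drug class, optional product/dose columns);
* **hospitalizations** — one row per episode (admit day, discharge day,
  primary diagnosis code);
* **registry** — one row per person (birth day, sex, coverage period,
  optional death day, plus any extra columns which are carried through
  as baseline covariates).

Cohort selection implements a new-user design anchored on an acute
coronary syndrome (ACS) hospitalization: the index date is the earliest
eligible ACS discharge, entry requires a first statin fill within a
window of the index, a statin-free washout before it, five years of
prior coverage, a minimum age, and survival with coverage for at least
one full measurement interval after the first fill.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EPOCH = "1994-01-01"

REQUIRED_COLUMNS = {
    "dispensations": ["person_id", "dispense_day", "days_supplied", "drug_class"],
    "hospitalizations": ["person_id", "admit_day", "discharge_day", "primary_dx"],
    "registry": ["person_id", "birth_day", "sex", "coverage_start_day", "coverage_end_day", "death_day"],
}
DATE_COLUMNS = {
    "dispensations": ["dispense_day"],
    "hospitalizations": ["admit_day", "discharge_day"],
    "registry": ["birth_day", "coverage_start_day", "coverage_end_day", "death_day"],
}
TABLE_NAMES = tuple(REQUIRED_COLUMNS)


class SchemaError(ValueError):
    """A required column is missing or a table cannot be interpreted."""


@dataclass
class ClaimsBundle:
    """The three claims tables plus a log of rejected rows.

    ``rejections`` has columns (table, row, reason); rejected rows are
    dropped from the typed tables but fully accounted for.
    """

    dispensations: pd.DataFrame
    hospitalizations: pd.DataFrame
    registry: pd.DataFrame
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"])
    )

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _days_from_any(series: pd.Series, epoch: pd.Timestamp) -> pd.Series:
    """Coerce a column of integer days or ISO-8601 dates to nullable Int64 days."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype("Int64")
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    out = (parsed - epoch).dt.days.astype("Int64")
    # blank cells are legitimately missing (e.g. death_day); flag only non-blank failures
    bad = parsed.isna() & series.notna() & (series.astype(str).str.strip() != "")
    out[bad] = pd.NA
    out.attrs["unparseable"] = series.index[bad].tolist()
    return out


def _validate_table(name: str, df: pd.DataFrame, epoch: pd.Timestamp,
                    column_map: Mapping[str, str] | None) -> tuple[pd.DataFrame, list[tuple]]:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns and c != "death_day"]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")
    if name == "registry" and "death_day" not in df.columns:
        df = df.assign(death_day=pd.NA)
    rejections: list[tuple] = []
    df = df.copy()
    for col in DATE_COLUMNS[name]:
        coerced = _days_from_any(df[col], epoch)
        for row in coerced.attrs.get("unparseable", []):
            rejections.append((name, int(row), f"unparseable date in {col}"))
        df[col] = coerced

    def _reject(mask: pd.Series, reason: str) -> None:
        for row in df.index[mask.fillna(False)]:
            rejections.append((name, int(row), reason))

    bad = pd.Series(False, index=df.index)
    if name == "dispensations":
        m = df["days_supplied"].isna() | (pd.to_numeric(df["days_supplied"], errors="coerce") < 1)
        _reject(m, "days_supplied < 1")
        bad |= m | df["dispense_day"].isna()
    elif name == "hospitalizations":
        m = df["discharge_day"] < df["admit_day"]
        _reject(m, "discharge before admission")
        bad |= m.fillna(True) | df["admit_day"].isna() | df["discharge_day"].isna()
    else:
        m = df["coverage_end_day"] < df["coverage_start_day"]
        _reject(m, "coverage ends before it starts")
        m2 = df["death_day"].notna() & (df["death_day"] > df["coverage_end_day"])
        _reject(m2, "death after coverage end")
        bad |= m.fillna(True) | m2 | df["coverage_start_day"].isna()
    # rows listed as unparseable are already in `rejections`; ensure dropped
    bad |= pd.Series(
        df.index.isin([r for t, r, _ in rejections if t == name]), index=df.index
    )
    return df[~bad].reset_index(drop=True), rejections


def read_claims_bundle(
    paths: Mapping[str, str | Path] | str | Path,
    sep: str = ",",
    epoch: str = DEFAULT_EPOCH,
    column_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> ClaimsBundle:
    """Read the three delimited files into a typed, validated bundle.

    Parameters
    ----------
    paths
        Either a directory containing ``dispensations.csv``,
        ``hospitalizations.csv`` and ``registry.csv``, or a mapping from
        table name to file path.
    sep, epoch
        Field delimiter and the calendar date mapped to day 0.
    column_maps
        Optional per-table mapping of canonical field name to source
        column name for files with foreign headers.

    Rows violating a per-row invariant (non-positive supply, discharge
    before admission, unparseable dates, inverted coverage) are dropped
    and reported in ``bundle.rejections`` with their 0-based row number.
    Dispensations outside the dispensing person's registry coverage
    period are likewise rejected.
    """
    if not isinstance(paths, Mapping):
        root = Path(paths)
        paths = {name: root / f"{name}.csv" for name in TABLE_NAMES}
    epoch_ts = pd.Timestamp(epoch)
    tables: dict[str, pd.DataFrame] = {}
    rejections: list[tuple] = []
    for name in TABLE_NAMES:
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"{name} file not found: {path}")
        raw = pd.read_csv(path, sep=sep)
        cm = (column_maps or {}).get(name)
        tables[name], rej = _validate_table(name, raw, epoch_ts, cm)
        rejections.extend(rej)

    bundle = ClaimsBundle(
        tables["dispensations"], tables["hospitalizations"], tables["registry"],
        pd.DataFrame(rejections, columns=["table", "row", "reason"]),
    )
    return _reject_uncovered_dispensations(bundle)


def _reject_uncovered_dispensations(bundle: ClaimsBundle) -> ClaimsBundle:
    reg = bundle.registry.set_index("person_id")
    disp = bundle.dispensations
    start = disp["person_id"].map(reg["coverage_start_day"])
    end = disp["person_id"].map(reg["coverage_end_day"])
    bad = start.notna() & ((disp["dispense_day"] < start) | (disp["dispense_day"] > end))
    if bad.any():
        extra = pd.DataFrame(
            {"table": "dispensations", "row": disp.index[bad],
             "reason": "dispense_day outside coverage period"}
        )
        bundle = replace(
            bundle,
            dispensations=disp[~bad].reset_index(drop=True),
            rejections=pd.concat([bundle.rejections, extra], ignore_index=True),
        )
    return bundle


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path, sep: str = ",",
                        iso_dates: bool = False, epoch: str = DEFAULT_EPOCH) -> dict[str, Path]:
    """Write the bundle back to three delimited files.

    By default day columns stay integer days; with ``iso_dates=True``
    they are rendered as ISO-8601 calendar dates anchored at ``epoch``
    (day 0), which :func:`read_claims_bundle` parses back losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    epoch_ts = pd.Timestamp(epoch)
    out = {}
    for name in TABLE_NAMES:
        df = bundle.table(name)
        if iso_dates:
            df = df.copy()
            for col in DATE_COLUMNS[name]:
                days = pd.to_numeric(df[col], errors="coerce")
                df[col] = (epoch_ts + pd.to_timedelta(days, unit="D")).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        df.to_csv(path, sep=sep, index=False)
        out[name] = path
    return out


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCriteria:
    """Thresholds and code sets for new-user cohort entry.

    Defaults: age >= 30 at index, first statin fill within 90 days of
    the index discharge, 1825 days (5 years) of continuous coverage
    before index, no statin in the 365 days before the index admission,
    and >= 102 days of survival-with-coverage after the first fill.
    Diagnosis code sets are symbolic and configurable (real ICD lists
    plug in here).
    """

    min_age: int = 30
    statin_window: int = 90
    prior_coverage: int = 1825
    min_survival: int = 102
    statin_washout: int = 365
    statin_codes: frozenset = frozenset({"statin"})
    acs_codes: frozenset = frozenset({"MI", "UA"})
    revasc_codes: frozenset = frozenset({"REVASC_ONLY"})
    study_start_day: int = 0
    study_end_day: int = 5478


#: fixed order in which exclusion criteria are applied (affects the tally
#: attribution only, never final membership)
CRITERIA_ORDER = (
    "age_below_minimum",
    "insufficient_prior_coverage",
    "revascularization_without_acs",
    "statin_in_washout",
    "no_statin_within_window",
    "insufficient_survival",
)


@dataclass
class CohortSelection:
    """Selected cohort plus the exclusion flow.

    ``cohort`` has one row per member: person_id, index_day,
    index_admit_day, first_statin_day, followup_end_day, died, age,
    age_group, sex, and any extra registry columns (baseline
    covariates).  ``tally`` reports, per criterion in application order,
    how many persons were removed; its counts plus the retained count
    sum to ``n_universe`` (everyone with a qualifying hospitalization in
    the study window).
    """

    cohort: pd.DataFrame
    tally: pd.DataFrame
    n_universe: int


AGE_BINS = [-np.inf, 54, 65, 73, np.inf]
AGE_LABELS = ["<55", "55-65", "66-73", ">=74"]


def select_cohort(bundle: ClaimsBundle, criteria: CohortCriteria = CohortCriteria()) -> CohortSelection:
    """Apply the inclusion/exclusion cascade and return members + flow tally.

    The universe is every person with at least one hospitalization whose
    primary diagnosis is in the ACS or revascularization code sets and
    whose discharge falls in the study window.  The index is the
    earliest ACS discharge (persons with only revascularization episodes
    are given a provisional index so that age/coverage exclusions are
    attributable, then fall at the ACS criterion).  Criteria are applied
    in ``CRITERIA_ORDER``; each person is counted against the first
    criterion it fails.
    """
    crit = criteria
    hosp = bundle.hospitalizations
    qualifying = hosp[
        hosp["primary_dx"].isin(crit.acs_codes | crit.revasc_codes)
        & (hosp["discharge_day"] >= crit.study_start_day)
        & (hosp["discharge_day"] <= crit.study_end_day)
    ]
    if qualifying.empty:
        empty = pd.DataFrame(columns=["person_id", "index_day", "index_admit_day",
                                      "first_statin_day", "followup_end_day", "died",
                                      "age", "age_group", "sex"])
        tally = pd.DataFrame({"criterion": CRITERIA_ORDER, "n_excluded": 0})
        return CohortSelection(empty, tally, 0)

    is_acs = qualifying["primary_dx"].isin(crit.acs_codes)
    acs_first = (
        qualifying[is_acs].sort_values(["discharge_day", "admit_day"])
        .groupby("person_id").first()
    )
    any_first = (
        qualifying.sort_values(["discharge_day", "admit_day"])
        .groupby("person_id").first()
    )
    persons = any_first.index
    index_day = acs_first["discharge_day"].reindex(persons).fillna(any_first["discharge_day"]).astype(np.int64)
    index_admit = acs_first["admit_day"].reindex(persons).fillna(any_first["admit_day"]).astype(np.int64)
    has_acs = persons.isin(acs_first.index)

    reg = bundle.registry.set_index("person_id").reindex(persons)
    statins = bundle.dispensations[bundle.dispensations["drug_class"].isin(crit.statin_codes)]

    df = pd.DataFrame({
        "person_id": persons,
        "index_day": index_day.to_numpy(),
        "index_admit_day": index_admit.to_numpy(),
        "has_acs": has_acs,
    }).set_index("person_id")
    df["age"] = ((df["index_day"] - reg["birth_day"].astype("float")) // 365).astype("Int64")
    df["coverage_start_day"] = reg["coverage_start_day"]
    df["coverage_end_day"] = reg["coverage_end_day"]
    df["death_day"] = pd.to_numeric(reg["death_day"], errors="coerce").astype("Int64")

    # first statin on/after index and any statin in the washout before admission
    stat = statins.merge(df[["index_day", "index_admit_day"]], on="person_id", how="inner")
    post = stat[stat["dispense_day"] >= stat["index_day"]]
    first_fill = post.groupby("person_id")["dispense_day"].min()
    in_washout = stat[
        (stat["dispense_day"] < stat["index_admit_day"])
        & (stat["dispense_day"] >= stat["index_admit_day"] - crit.statin_washout)
    ]["person_id"].unique()
    df["first_statin_day"] = first_fill.reindex(df.index).astype("Int64")
    df["washout_violation"] = df.index.isin(in_washout)

    followup_end = pd.concat(
        [df["death_day"], df["coverage_end_day"],
         pd.Series(crit.study_end_day, index=df.index)], axis=1
    ).min(axis=1)
    df["followup_end_day"] = followup_end.astype("Int64")

    fails = {
        "age_below_minimum": df["age"].isna() | (df["age"] < crit.min_age),
        "insufficient_prior_coverage": df["coverage_start_day"].isna()
            | (df["index_day"] - df["coverage_start_day"] < crit.prior_coverage),
        "revascularization_without_acs": ~df["has_acs"],
        "statin_in_washout": df["washout_violation"],
        "no_statin_within_window": df["first_statin_day"].isna()
            | (df["first_statin_day"] - df["index_day"] > crit.statin_window),
        "insufficient_survival": df["followup_end_day"] - df["first_statin_day"] < crit.min_survival,
    }
    remaining = pd.Series(True, index=df.index)
    counts = {}
    for name in CRITERIA_ORDER:
        f = fails[name].fillna(True) & remaining
        counts[name] = int(f.sum())
        remaining &= ~f

    members = df[remaining].reset_index()
    members["died"] = members["death_day"].notna() & (members["death_day"] <= members["followup_end_day"])
    members["age_group"] = pd.cut(members["age"].astype(float), AGE_BINS, labels=AGE_LABELS)
    members["sex"] = reg["sex"].reindex(members["person_id"]).to_numpy()
    extra = [c for c in bundle.registry.columns
             if c not in REQUIRED_COLUMNS["registry"]]
    for c in extra:
        members[c] = bundle.registry.set_index("person_id")[c].reindex(members["person_id"]).to_numpy()
    keep = ["person_id", "index_day", "index_admit_day", "first_statin_day",
            "followup_end_day", "died", "age", "age_group", "sex"] + extra
    members = members[keep].astype({"first_statin_day": np.int64, "followup_end_day": np.int64})

    tally = pd.DataFrame({"criterion": CRITERIA_ORDER,
                          "n_excluded": [counts[c] for c in CRITERIA_ORDER]})
    logger.info("cohort selection: universe %d, retained %d", len(persons), len(members))
    return CohortSelection(members, tally, int(len(persons)))
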