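"""Adjusted proportion-of-days-covered (PDC) engine.

Measures medication adherence from pharmacy refill records with three
adjustments that prevent overestimation:

* each dispensation is assigned a *completion date*; a refill obtained
  before the previous supply is exhausted is deferred until the previous
  completion date, so overlapping supplies never double-count days;
* supply extending beyond the end of follow-up is truncated;
* hospitalized days are removed from the calculation (inpatient
  medication does not come from the outpatient dispensation record).

Hospital-day removal is implemented by *compressing* the timeline: all
hospitalized days are deleted and the remaining "adherence days" are
renumbered 0..W-1.  Supply chaining, interval windows and denominators
all live on this compressed clock, which removes hospital days from the
denominator and pauses supply consumption during a stay in one stroke.
The alternative reading — supply keeps running during hospitalization,
hospital days are only dropped from the numerator/denominator — is
available as ``hospital_mode="denominator_only"``.

Two measurement methods share one kernel:

* **summary PDC** (method A): covered days over the whole follow-up
  window divided by its length;
* **interval PDC** (method B): the window is partitioned into fixed
  intervals (default 102 days = three 34-day fills) and PDC is measured
  in each; carryover of unused supply between intervals is automatic
  because the completion-date chain is built once over the whole window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: binary optimal-adherence threshold (PDC >= 80% is "optimal")
OPTIMAL_THRESHOLD = 0.80
#: three-level cut points: low <= 20%, optimal >= 80%, middle otherwise
LOW_THRESHOLD = 0.20
#: default measurement-interval length in days (three 34-day fills)
DEFAULT_INTERVAL_LEN = 102


class AdherenceError(ValueError):
    """Raised for invalid windows or inconsistent adherence inputs."""


# ---------------------------------------------------------------------------
# timeline compression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompressedTimeline:
    """Monotone map between observed calendar days and adherence days.

    The observation span ``[span_start, span_end)`` (observed days) is
    mapped onto ``[0, W)`` (adherence days) by deleting every
    hospitalized day.  Observed days falling inside a hospital stay map
    to the same adherence day as the first post-discharge day, so a
    dispensation recorded during a stay starts contributing supply on
    discharge.

    Attributes
    ----------
    person_id : hashable
    span_start, span_end : int
        Observed-day bounds of the observation window (half-open).
    hosp_starts, hosp_ends : np.ndarray
        Merged, disjoint, sorted hospital intervals (half-open, observed
        days), already clipped to the span.
    """

    person_id: object
    span_start: int
    span_end: int
    hosp_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    hosp_ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if self.span_end < self.span_start:
            raise AdherenceError(
                f"span_end {self.span_end} precedes span_start {self.span_start}"
            )

    @property
    def removed_days(self) -> int:
        return int(np.sum(self.hosp_ends - self.hosp_starts))

    @property
    def W(self) -> int:
        """Number of adherence days (window length on the compressed clock)."""
        return self.span_end - self.span_start - self.removed_days

    @property
    def undefined(self) -> bool:
        """True when hospitalization swallows the whole window (W == 0, PDC missing)."""
        return self.W == 0 and self.span_end > self.span_start

    def _removed_before(self, days: np.ndarray) -> np.ndarray:
        # hospital days strictly before each observed day
        full = np.searchsorted(self.hosp_ends, days, side="right")
        removed = np.zeros(len(days), dtype=np.int64)
        if len(self.hosp_starts):
            cum = np.concatenate([[0], np.cumsum(self.hosp_ends - self.hosp_starts)])
            removed = cum[full]
            # partially passed interval
            inside = (full < len(self.hosp_starts)) & (days > self.hosp_starts[np.minimum(full, len(self.hosp_starts) - 1)])
            idx = np.minimum(full, len(self.hosp_starts) - 1)
            removed = removed + np.where(inside, days - self.hosp_starts[idx], 0)
        return removed

    def to_adherence(self, observed_days) -> np.ndarray:
        """Map observed days to adherence days (in-hospital days map forward)."""
        days = np.atleast_1d(np.asarray(observed_days, dtype=np.int64))
        return days - self.span_start - self._removed_before(days)

    def to_observed(self, adherence_days) -> np.ndarray:
        """Inverse map; defined for adherence days in [0, W]."""
        a = np.atleast_1d(np.asarray(adherence_days, dtype=np.int64))
        if np.any((a < 0) | (a > self.W)):
            raise AdherenceError("adherence day outside [0, W]")
        # adherence day of each hospital-interval start
        starts_a = self.hosp_starts - self.span_start
        if len(starts_a):
            cum = np.concatenate([[0], np.cumsum(self.hosp_ends - self.hosp_starts)])
            starts_a = starts_a - cum[:-1]
        k = np.searchsorted(starts_a, a, side="right") if len(starts_a) else np.zeros(len(a), dtype=np.int64)
        shift = np.zeros(len(a), dtype=np.int64)
        if len(self.hosp_starts):
            cum = np.concatenate([[0], np.cumsum(self.hosp_ends - self.hosp_starts)])
            shift = cum[k]
        return a + self.span_start + shift


def merge_intervals(starts: Sequence[int], ends: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping half-open intervals into a disjoint sorted set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def compress_timeline(
    person_id,
    span_start: int,
    span_end: int,
    admit_days: Sequence[int] = (),
    discharge_days: Sequence[int] = (),
) -> CompressedTimeline:
    """Build the hospital-free timeline for one person's observation window.

    A stay admitted on day ``a`` and discharged on day ``d`` occupies the
    inclusive day range ``a..d`` (a same-day admission/discharge counts
    as one hospitalized day).  Episodes may overlap each other and the
    window edges; only their intersection with the window is removed.
    """
    admits = np.asarray(admit_days, dtype=np.int64)
    disch = np.asarray(discharge_days, dtype=np.int64)
    if len(admits) != len(disch):
        raise AdherenceError("admit/discharge arrays differ in length")
    if np.any(disch < admits):
        raise AdherenceError("discharge precedes admission")
    s, e = merge_intervals(np.clip(admits, span_start, span_end), np.clip(disch + 1, span_start, span_end))
    tl = CompressedTimeline(person_id, int(span_start), int(span_end), s, e)
    if tl.undefined:
        logger.warning("person %s: hospitalization covers entire window; adherence undefined", person_id)
    return tl


# ---------------------------------------------------------------------------
# coverage schedule (completion-date chain)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageSchedule:
    """Disjoint, sorted covered day-intervals on the compressed clock.

    ``starts``/``ends`` are half-open intervals contained in ``[0, W)``;
    contiguous intervals are merged on construction.
    """

    person_id: object
    starts: np.ndarray
    ends: np.ndarray
    W: int

    def __post_init__(self) -> None:
        if len(self.starts) and (np.any(self.starts[1:] < self.ends[:-1]) or np.any(self.ends > self.W) or np.any(self.starts < 0)):
            raise AdherenceError("coverage intervals overlap or escape [0, W)")

    @property
    def total_covered(self) -> int:
        return int(np.sum(self.ends - self.starts))


def build_coverage_schedule(
    dispense_days: Sequence[int],
    days_supplied: Sequence[int],
    W: int,
    person_id=None,
) -> CoverageSchedule:
    """Chain dispensations into covered intervals with early-refill deferral.

    Supply from fill *i* starts at ``max(dispense_day_i, end_{i-1})``
    where ``end_i = start_i + days_supplied_i`` and ``end_0 = 0`` — the
    half-open form of "not applied until the previous completion date
    plus one day".  The chain is uncapped (stockpiled supply can be
    pushed arbitrarily far forward) but the covered set is truncated at
    ``W``: excess supply beyond the last follow-up day is discarded.
    Fills dispensed on or after day ``W`` contribute nothing.
    """
    days = np.asarray(dispense_days, dtype=np.int64)
    supply = np.asarray(days_supplied, dtype=np.int64)
    if np.any(supply < 1):
        raise AdherenceError("days_supplied must be >= 1")
    order = np.argsort(days, kind="stable")
    days, supply = days[order], supply[order]

    starts: list[int] = []
    ends: list[int] = []
    end_prev = 0
    for d, s in zip(days, supply):
        if d >= W:
            logger.debug("person %s: fill on day %d at/after window end %d ignored", person_id, d, W)
            continue
        start = max(int(d), end_prev)
        end_prev = start + int(s)
        lo, hi = start, min(end_prev, W)
        if lo >= hi:
            continue
        if starts and lo <= ends[-1]:
            ends[-1] = max(ends[-1], hi)
        else:
            starts.append(lo)
            ends.append(hi)
    return CoverageSchedule(
        person_id,
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        int(W),
    )


def covered_before(schedule: CoverageSchedule, points) -> np.ndarray:
    """Covered days in ``[0, x)`` for each x in ``points`` (vectorized)."""
    x = np.atleast_1d(np.asarray(points, dtype=np.int64))
    lens = schedule.ends - schedule.starts
    cum = np.concatenate([[0], np.cumsum(lens)])
    j = np.searchsorted(schedule.starts, x, side="right")
    out = cum[j].copy()
    has_prev = j > 0
    if has_prev.any():
        jp = np.maximum(j - 1, 0)
        overshoot = np.clip(schedule.ends[jp] - x, 0, lens[jp])
        out[has_prev] -= overshoot[has_prev]
    return out


def covered_days(schedule: CoverageSchedule, a: int, b: int) -> int:
    """Exact count of covered days in the half-open window ``[a, b)``."""
    if not (0 <= a < b <= schedule.W):
        raise AdherenceError(f"window [{a}, {b}) invalid for W={schedule.W}")
    lo = np.clip(schedule.starts, a, b)
    hi = np.clip(schedule.ends, a, b)
    return int(np.sum(hi - lo))


# ---------------------------------------------------------------------------
# PDC values, intervals, classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PDCValue:
    """A proportion of days covered with its numerator and denominator."""

    covered_days: int
    denominator_days: int

    def __post_init__(self) -> None:
        if self.denominator_days < 1:
            raise AdherenceError("PDC denominator must be >= 1 (W=0 is a missing state)")
        if not 0 <= self.covered_days <= self.denominator_days:
            raise AdherenceError("covered days outside [0, denominator]")

    @property
    def pdc(self) -> float:
        return self.covered_days / self.denominator_days


@dataclass(frozen=True)
class IntervalPDC:
    """Adherence over one fixed measurement interval (method B unit).

    ``interval_index`` is 1-based; the window is
    ``[L*(k-1), min(L*k, W))`` on the compressed clock.  ``complete`` is
    true iff the interval spans the full configured length; at most the
    last interval can be incomplete.
    """

    interval_index: int
    start: int
    end: int
    value: PDCValue
    complete: bool

    @property
    def pdc(self) -> float:
        return self.value.pdc

    def adherent(self, threshold: float = OPTIMAL_THRESHOLD) -> bool:
        return self.value.pdc >= threshold


def summary_pdc(schedule: CoverageSchedule) -> PDCValue | None:
    """Method A: one summary PDC over the whole window; None when W == 0."""
    if schedule.W == 0:
        return None
    return PDCValue(covered_days(schedule, 0, schedule.W), schedule.W)


def interval_pdcs(
    schedule: CoverageSchedule,
    interval_len: int = DEFAULT_INTERVAL_LEN,
) -> list[IntervalPDC]:
    """Method B: PDC in consecutive fixed-length intervals partitioning [0, W).

    Carryover of unused supply from one interval to the next needs no
    extra step: the completion-date chain was built over the whole
    window, so stockpiled supply simply extends into later intervals.
    The final interval keeps its true (shorter) length as denominator
    and is flagged ``complete=False``.
    """
    if interval_len < 1:
        raise AdherenceError("interval_len must be >= 1")
    out: list[IntervalPDC] = []
    k = 1
    while (k - 1) * interval_len < schedule.W:
        a = (k - 1) * interval_len
        b = min(k * interval_len, schedule.W)
        out.append(
            IntervalPDC(
                interval_index=k,
                start=a,
                end=b,
                value=PDCValue(covered_days(schedule, a, b), b - a),
                complete=(b - a) == interval_len,
            )
        )
        k += 1
    return out


def classify(pdc: float | None, scheme: str = "binary") -> str | None:
    """Classify a PDC: binary {optimal, suboptimal} or three_level {low, middle, optimal}.

    The optimal cut is inclusive (PDC >= 0.80); the three-level low cut
    is PDC <= 0.20.  A missing PDC (None or NaN) classifies as None.
    """
    if pdc is None or (isinstance(pdc, float) and np.isnan(pdc)):
        return None
    if not 0 <= pdc <= 1:
        raise AdherenceError(f"PDC {pdc} outside [0, 1]")
    if scheme == "binary":
        return "optimal" if pdc >= OPTIMAL_THRESHOLD else "suboptimal"
    if scheme == "three_level":
        if pdc >= OPTIMAL_THRESHOLD:
            return "optimal"
        if pdc <= LOW_THRESHOLD:
            return "low"
        return "middle"
    raise AdherenceError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# per-person and cohort-level drivers
# ---------------------------------------------------------------------------

def person_schedule(
    person_id,
    first_statin_day: int,
    followup_end_day: int,
    dispense_days: Sequence[int],
    days_supplied: Sequence[int],
    admit_days: Sequence[int] = (),
    discharge_days: Sequence[int] = (),
    hospital_mode: str = "compress",
) -> tuple[CompressedTimeline, CoverageSchedule]:
    """Observation window + hospital adjustment + completion chain for one person.

    ``hospital_mode="compress"`` (default) runs the supply chain on the
    compressed clock: consumption pauses during a stay.
    ``"denominator_only"`` runs the chain on the observed clock (supply
    keeps burning in hospital) and only then projects the covered set
    onto the compressed clock, so hospital days still leave the
    denominator but stockpiles do not survive a stay.
    """
    tl = compress_timeline(person_id, first_statin_day, followup_end_day, admit_days, discharge_days)
    days = np.asarray(dispense_days, dtype=np.int64)
    supply = np.asarray(days_supplied, dtype=np.int64)
    in_window = (days >= first_statin_day) & (days < followup_end_day)
    days, supply = days[in_window], supply[in_window]
    if tl.W == 0:
        return tl, CoverageSchedule(person_id, np.empty(0, np.int64), np.empty(0, np.int64), 0)
    if hospital_mode == "compress":
        sched = build_coverage_schedule(tl.to_adherence(days), supply, tl.W, person_id)
    elif hospital_mode == "denominator_only":
        raw = build_coverage_schedule(days - first_statin_day, supply,
                                      followup_end_day - first_statin_day, person_id)
        # project each covered interval onto the compressed clock: the image of
        # a half-open observed interval minus hospital days is contiguous
        s_obs = raw.starts + first_statin_day
        e_obs = raw.ends + first_statin_day
        a_s = tl.to_adherence(s_obs)
        a_e = tl.to_adherence(e_obs)
        sched = CoverageSchedule(person_id, *merge_intervals(a_s, a_e), tl.W)
    else:
        raise AdherenceError(f"unknown hospital_mode {hospital_mode!r}")
    return tl, sched


def adherence_table(
    cohort: pd.DataFrame,
    dispensations: pd.DataFrame,
    hospitalizations: pd.DataFrame | None = None,
    statin_codes: Iterable[str] = ("statin",),
    interval_len: int = DEFAULT_INTERVAL_LEN,
    threshold: float = OPTIMAL_THRESHOLD,
    hospital_mode: str = "compress",
) -> pd.DataFrame:
    """Tidy per-person adherence export for a whole cohort.

    One row per measurement interval plus a summary row flagged
    ``interval_index = 0``.  Columns: person_id, interval_index,
    interval_start, interval_end, covered_days, denominator_days, pdc,
    adherent, complete.  Persons with W == 0 contribute a single row
    with NaN pdc (missing adherence).
    """
    statin_codes = set(statin_codes)
    disp = dispensations[dispensations["drug_class"].isin(statin_codes)]

    def _slices(df: pd.DataFrame, cols: list[str]) -> dict:
        df = df.sort_values("person_id", kind="stable")
        pids = df["person_id"].to_numpy()
        arrays = [df[c].to_numpy(dtype=np.int64) for c in cols]
        uniq, idx = np.unique(pids, return_index=True)
        stops = np.append(idx[1:], len(pids))
        return {p: tuple(a[i:j] for a in arrays) for p, i, j in zip(uniq, idx, stops)}

    disp_by_person = _slices(disp, ["dispense_day", "days_supplied"])
    hosp_by_person: dict = {}
    if hospitalizations is not None and len(hospitalizations):
        hosp_by_person = _slices(hospitalizations, ["admit_day", "discharge_day"])

    empty = (np.empty(0, np.int64),) * 2
    rows = []
    for rec in cohort.itertuples(index=False):
        pid = rec.person_id
        d_days, d_supply = disp_by_person.get(pid, empty)
        h_admit, h_disch = hosp_by_person.get(pid, empty)
        _, sched = person_schedule(
            pid,
            int(rec.first_statin_day),
            int(rec.followup_end_day),
            d_days, d_supply, h_admit, h_disch,
            hospital_mode=hospital_mode,
        )
        if sched.W == 0:
            rows.append((pid, 0, 0, 0, 0, 0, np.nan, False, False))
            continue
        W = sched.W
        bounds = np.arange(0, W + interval_len, interval_len, dtype=np.int64)
        bounds[-1] = min(bounds[-1], W)
        if bounds[-1] == bounds[-2]:
            bounds = bounds[:-1]
        cov = np.diff(covered_before(sched, bounds))
        total = int(cov.sum())
        rows.append((pid, 0, 0, W, total, W, total / W, total / W >= threshold, True))
        for k in range(len(cov)):
            a, b = int(bounds[k]), int(bounds[k + 1])
            n = b - a
            rows.append((pid, k + 1, a, b, int(cov[k]), n, cov[k] / n,
                         cov[k] / n >= threshold, n == interval_len))
    return pd.DataFrame(
        rows,
        columns=["person_id", "interval_index", "interval_start", "interval_end",
                 "covered_days", "denominator_days", "pdc", "adherent", "complete"],
    )
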