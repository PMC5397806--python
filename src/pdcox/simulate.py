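"""Synthetic administrative-claims generator.

Emits the registry / hospitalization / dispensation bundle read by
:mod:`pdcox.claims`, built so that every generated person enters the
cohort by construction: an index ACS hospitalization, a first statin
fill within the entry window, five-plus years of prior coverage, and
survival past the first measurement interval.  A hidden truth table
(latent health, true interval adherence, true hazard) accompanies the
bundle for testing.

The behavioural core is a refill renewal process on a latent-health
scale.  Each person carries an interval-resolution latent health state
``H`` (a Gaussian random walk); after each fill's supply is exhausted
the delay until the next fill is geometric with per-day refill
probability ``p = sigmoid(alpha_i + gamma*H + trend*calendar_years)``.
Death follows a piecewise-constant hazard per interval,

    lambda_k = baseline_hazard * exp(beta * A_{k-1} + theta * H_k),

where ``A_{k-1}`` indicates optimal adherence in the *previous*
measurement interval.  Risk starts one full interval after the first
fill, so interval 1 exists purely to supply the first covariate value
and every risk interval's adherence driver is fully observed.  (A
hazard driven by the *current* interval's adherence is not identifiable
from claims: death truncates the very window that defines the
covariate, so the concurrent covariate of the death interval can never
be measured in full.)  Four scenario presets wire these dials:

* ``null`` — adherence and health affect nothing (beta = gamma = 0);
* ``causal`` — optimal adherence in the current interval lowers the
  hazard by 25% (beta = log 0.75);
* ``survival_bias`` — adherence has no effect (beta = 0) but death is
  preceded by a deterministic decline in latent health over the
  measurement interval(s) before the death interval, which drags refill
  behaviour down (gamma > 0): recent non-adherence becomes a marker of
  imminent death rather than a cause;
* ``improving_trend`` — a calendar-time improvement in refill
  propensity layered on the null scenario.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .claims import ClaimsBundle

SCENARIOS = ("null", "causal", "survival_bias", "improving_trend")


@dataclass(frozen=True)
class SimulationConfig:
    """All generator dials with their study-condition defaults.

    Times are integer days; day 0 is the configurable epoch.  The
    defaults emulate a provincial claims cohort: ~10 years of accrual,
    34-day fills measured in 102-day intervals, a death rate near 3% per
    person-year, mean age ~65, two thirds male.
    """

    n_persons: int = 9000
    seed: int = 0
    scenario: str = "null"
    #: events per person-day among the unexposed (≈3%/year)
    baseline_hazard: float = 8e-5
    #: log hazard ratio of current-interval optimal adherence (beta)
    causal_log_hr: float = 0.0
    #: log hazard slope of latent health (theta); negative values are protective
    health_log_hr: float = 0.0
    #: effect of latent health on the refill-propensity logit (gamma)
    adherence_slope: float = 0.0
    #: calendar improvement of the refill-propensity logit, per year
    trend_slope: float = 0.0
    #: deterministic drop in H over the complete measurement interval(s)
    #: immediately preceding the death interval
    pre_death_decline: bool = False
    decline_per_interval: float = 2.0
    decline_intervals: int = 1
    #: latent health scale: baseline spread and random-walk innovation SD
    frailty_sd: float = 1.0
    health_walk_sd: float = 0.25
    health_drift: float = 0.0
    #: refill propensity logit: population mean and between-person SD
    fill_logit_mean: float = -2.0
    fill_logit_sd: float = 2.0
    fill_quantity: int = 34
    interval_len: int = 102
    #: study window (accrual + follow-up); admin censoring at its end
    study_length_days: int = 5475
    #: geometric parameter for the index-discharge -> first-fill delay
    first_fill_delay_p: float = 0.12
    statin_products: tuple = ("atorvastatin", "simvastatin", "rosuvastatin")
    #: mid-follow-up hospital episodes (exercise timeline compression)
    hosp_rate_per_year: float = 0.15
    hosp_min_len: int = 3
    hosp_max_len: int = 14
    #: demographics
    age_mean: float = 64.8
    age_sd: float = 12.3
    age_min: int = 30
    age_max: int = 100
    male_frac: float = 0.692
    revasc_frac: float = 0.585
    comorbid_frac: float = 0.367

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")
        if self.n_persons < 0 or self.baseline_hazard <= 0:
            raise ValueError("n_persons must be >= 0 and rates positive")
        if self.pre_death_decline and (self.causal_log_hr != 0 or self.health_log_hr != 0):
            raise ValueError(
                "pre_death_decline schedules death independently of adherence/health; "
                "it requires causal_log_hr = health_log_hr = 0"
            )


def scenario_preset(name: str, n_persons: int = 9000, seed: int = 0, **overrides) -> SimulationConfig:
    """Named scenario with its defining dials set; other fields overridable."""
    base = dict(n_persons=n_persons, seed=seed, scenario=name)
    if name == "null":
        pass
    elif name == "causal":
        base["causal_log_hr"] = math.log(0.75)
    elif name == "survival_bias":
        base.update(adherence_slope=0.25, pre_death_decline=True)
    elif name == "improving_trend":
        base.update(trend_slope=0.12, fill_logit_mean=-2.9)
    else:
        raise ValueError(f"unknown scenario {name!r}; valid: {SCENARIOS}")
    base.update(overrides)
    return SimulationConfig(**base)


def expected_long_run_pdc(p: float, fill_quantity: int) -> float:
    """Renewal-reward expectation of PDC at constant refill probability *p*.

    Each cycle covers ``fill_quantity`` days then waits a geometric gap
    with mean ``(1-p)/p`` days, so the long-run covered fraction is
    ``q / (q + (1-p)/p)``.
    """
    return fill_quantity / (fill_quantity + (1 - p) / p)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_refill_process(
    horizon: int,
    propensity_logits: np.ndarray,
    interval_len: int,
    fill_quantity: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill days on the person clock (day 0 = guaranteed first fill).

    ``propensity_logits[k-1]`` is the refill logit in force during
    interval *k*; the gap after each supply exhaustion is geometric with
    the per-day probability of the interval in which the supply ran out.
    """
    fills = [0]
    supply_end = fill_quantity
    n_int = len(propensity_logits)
    while True:
        k = min(supply_end // interval_len, n_int - 1)
        p = _sigmoid(float(propensity_logits[k]))
        if p <= 0:
            break
        gap = int(rng.geometric(p)) - 1
        nxt = supply_end + gap
        if nxt >= horizon:
            break
        fills.append(nxt)
        supply_end = nxt + fill_quantity
    return np.asarray(fills, dtype=np.int64)


def _interval_covered(fills: np.ndarray, q: int, bounds: np.ndarray) -> np.ndarray:
    """Covered days per interval for non-overlapping supply runs [f, f+q)."""
    ends = fills + q
    out = np.empty(len(bounds) - 1, dtype=np.int64)
    for j in range(len(bounds) - 1):
        a, b = bounds[j], bounds[j + 1]
        out[j] = int(np.sum(np.clip(np.minimum(ends, b) - np.maximum(fills, a), 0, None)))
    return out


def simulate_survival(
    adherent: np.ndarray,
    health: np.ndarray,
    interval_bounds: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Interval-wise inversion sampling of the death time.

    Hazard is piecewise constant, ``lambda_k = lambda0 *
    exp(beta*A_{k-1} + theta*H_k)`` with the adherence driver lagged one
    interval, active from the second interval onward (the analysis
    origin).  Returns ``(followup_end_on_person_clock, died)`` with
    administrative censoring at the horizon.
    """
    lam0 = config.baseline_hazard
    horizon = float(interval_bounds[-1])
    for k in range(2, len(interval_bounds)):
        a, b = float(interval_bounds[k - 1]), float(interval_bounds[k])
        lam = lam0 * math.exp(
            config.causal_log_hr * float(adherent[k - 2])
            + config.health_log_hr * float(health[k - 1])
        )
        e = rng.exponential()
        if e < lam * (b - a):
            return a + e / lam, True
    return horizon, False


def _simulate_person(i: int, cfg: SimulationConfig):
    rng = np.random.default_rng([cfg.seed, i])
    L, q = cfg.interval_len, cfg.fill_quantity

    entry = int(rng.uniform(0, cfg.study_length_days - 400))
    stay = 1 + min(int(rng.poisson(7)), 29)
    index_day = entry + stay
    age = int(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), cfg.age_min, cfg.age_max))
    birth_day = index_day - age * 365 - int(rng.integers(0, 365))
    male = rng.random() < cfg.male_frac
    revasc = rng.random() < cfg.revasc_frac
    comorbid = rng.random() < cfg.comorbid_frac
    delay = min(int(rng.geometric(cfg.first_fill_delay_p)) - 1, 90)
    first_statin = index_day + delay
    coverage_start = index_day - 1825 - int(rng.integers(0, 1000))

    # Hospital stays pause outpatient dispensing and consumption, so the
    # behavioural process lives on the hospital-free "person clock"; the
    # stays are inserted into the calendar afterwards when claims are
    # emitted.  Timeline compression in the analysis inverts exactly
    # this insertion.
    horizon_cal = cfg.study_length_days - first_statin
    n_hosp = rng.poisson(cfg.hosp_rate_per_year * horizon_cal / 365.0)
    hosp_lens = rng.integers(cfg.hosp_min_len, cfg.hosp_max_len + 1, size=n_hosp)
    if horizon_cal - int(hosp_lens.sum()) < 200:
        n_hosp, hosp_lens = 0, hosp_lens[:0]
    horizon = horizon_cal - int(hosp_lens.sum())  # person-clock admin censor
    hosp_pos = np.sort(rng.integers(1, horizon - 1, size=n_hosp))
    n_int = max(1, math.ceil(horizon / L))
    bounds = np.minimum(np.arange(n_int + 1, dtype=np.int64) * L, horizon)

    # latent health path, interval resolution
    steps = cfg.health_drift + cfg.health_walk_sd * rng.standard_normal(n_int)
    H = cfg.frailty_sd * rng.normal() + np.cumsum(steps)

    death_t, died = math.inf, False
    if cfg.pre_death_decline:
        # death independent of adherence/health; health declines before it
        e = rng.exponential()
        t = L + e / cfg.baseline_hazard
        if t < horizon:
            death_t, died = t, True
            # sustained step down in latent health over the measurement
            # intervals preceding the death interval
            k_star = int(death_t // L)  # 0-based index of death interval
            lo = max(0, k_star - cfg.decline_intervals)
            H[lo:k_star] -= cfg.decline_per_interval

    alpha_i = cfg.fill_logit_mean + cfg.fill_logit_sd * rng.normal()
    cal_years = (entry + np.arange(n_int) * L) / 365.0
    logits = alpha_i + cfg.adherence_slope * H + cfg.trend_slope * cal_years
    fills = simulate_refill_process(horizon, logits, L, q, rng)
    covered = _interval_covered(fills, q, bounds)
    lens = np.diff(bounds)
    adherent = covered / np.maximum(lens, 1) >= 0.8

    if not cfg.pre_death_decline:
        death_t, died = simulate_survival(adherent, H, bounds, cfg, rng)

    end_t = min(death_t, float(horizon))
    end_int = int(math.ceil(end_t))
    fills = fills[fills < end_t]

    # insert hospital stays into the calendar: person-day t maps to
    # first_statin + t + (length of stays inserted at positions <= t)
    keep = hosp_pos < end_int
    pos, lens = hosp_pos[keep], hosp_lens[keep]
    cum = np.concatenate([[0], np.cumsum(lens)])

    def to_cal(t: int) -> int:
        return first_statin + t + int(cum[np.searchsorted(pos, t, side="right")])

    fill_days_cal = [to_cal(int(f)) for f in fills]
    hosp = []
    for j in range(len(pos)):
        admit = first_statin + int(pos[j]) + int(cum[j])
        hosp.append((admit, admit + int(lens[j]) - 1))
    death_day = to_cal(end_int) if died else None
    followup_end = to_cal(end_int) if died else first_statin + horizon_cal

    hazards = np.full(n_int, np.nan)
    for k in range(1, n_int):
        hazards[k] = cfg.baseline_hazard * math.exp(
            cfg.causal_log_hr * float(adherent[k - 1]) + cfg.health_log_hr * float(H[k])
        )
    last_iv = min(n_int, int(end_t // L) + 1) if end_t < horizon else n_int
    truth = dict(H=H[:last_iv], adherent=adherent[:last_iv], hazard=hazards[:last_iv])

    return dict(
        entry=entry, index_admit=entry, index_discharge=index_day, birth_day=birth_day,
        male=male, revasc=revasc, comorbid=comorbid, first_statin=first_statin,
        coverage_start=coverage_start, death_day=death_day, died=died,
        followup_end=followup_end, fill_days=fill_days_cal, hosp=hosp, truth=truth,
    )


def generate_bundle(config: SimulationConfig) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate the three-table claims bundle plus the hidden truth table.

    Fully reproducible from ``(config.seed, person index)``; every
    person satisfies the default cohort criteria by construction.  The
    truth table has one row per person-interval up to death/censoring:
    person_id, interval_index (1-based), H, adherent_true, hazard.
    """
    cfg = config
    disp_rows, hosp_rows, reg_rows, truth_rows = [], [], [], []
    study_end = cfg.study_length_days
    for i in range(cfg.n_persons):
        pid = f"P{i:06d}"
        s = _simulate_person(i, cfg)
        rng_prod = np.random.default_rng([cfg.seed, i, 7])
        prods = rng_prod.choice(len(cfg.statin_products), size=len(s["fill_days"]))
        for f, pr in zip(s["fill_days"], prods):
            disp_rows.append((pid, int(f), cfg.fill_quantity,
                              "statin", cfg.statin_products[pr]))
        hosp_rows.append((pid, s["index_admit"], s["index_discharge"], "MI"))
        for a, d in s["hosp"]:
            hosp_rows.append((pid, int(a), int(d), "OTHER"))
        reg_rows.append((pid, s["birth_day"], "M" if s["male"] else "F",
                         s["coverage_start"], study_end,
                         s["death_day"] if s["died"] else pd.NA,
                         int(s["revasc"]), int(s["comorbid"])))
        t = s["truth"]
        for k in range(len(t["H"])):
            truth_rows.append((pid, k + 1, t["H"][k], bool(t["adherent"][k]), t["hazard"][k]))

    bundle = ClaimsBundle(
        dispensations=pd.DataFrame(
            disp_rows, columns=["person_id", "dispense_day", "days_supplied", "drug_class", "product"]),
        hospitalizations=pd.DataFrame(
            hosp_rows, columns=["person_id", "admit_day", "discharge_day", "primary_dx"]),
        registry=pd.DataFrame(
            reg_rows, columns=["person_id", "birth_day", "sex", "coverage_start_day",
                               "coverage_end_day", "death_day", "revasc", "comorbidity"]),
    )
    truth = pd.DataFrame(truth_rows,
                         columns=["person_id", "interval_index", "H", "adherent_true", "hazard"])
    return bundle, truth
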