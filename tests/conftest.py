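import numpy as np
import pandas as pd
import pytest

from pdcox.adherence import adherence_table
from pdcox.claims import ClaimsBundle, select_cohort
from pdcox.simulate import generate_bundle, scenario_preset


def registry_row(pid, birth=-40 * 365, cs=-2000, ce=5478, death=None, sex="M", **extra):
    row = dict(person_id=pid, birth_day=birth, sex=sex, coverage_start_day=cs,
               coverage_end_day=ce, death_day=death)
    row.update(extra)
    return row


def tiny_bundle(disp_rows, hosp_rows, reg_rows) -> ClaimsBundle:
    return ClaimsBundle(
        dispensations=pd.DataFrame(
            disp_rows, columns=["person_id", "dispense_day", "days_supplied", "drug_class"]),
        hospitalizations=pd.DataFrame(
            hosp_rows, columns=["person_id", "admit_day", "discharge_day", "primary_dx"]),
        registry=pd.DataFrame(reg_rows),
    )


@pytest.fixture(scope="session")
def causal_run():
    """One small causal-scenario dataset shared across tests (seed-fixed)."""
    cfg = scenario_preset("causal", n_persons=400, seed=7)
    bundle, truth = generate_bundle(cfg)
    sel = select_cohort(bundle)
    adh = adherence_table(sel.cohort, bundle.dispensations, bundle.hospitalizations)
    return dict(config=cfg, bundle=bundle, truth=truth, selection=sel, adherence=adh)


# ---------------------------------------------------------------------------
# independent day-by-day oracle for the coverage engine
# ---------------------------------------------------------------------------

def day_by_day_coverage(fills, span, hospital_days=frozenset()):
    """Literal supply-stack simulation of the adjusted-PDC rules.

    Walks observed days 0..span-1 keeping a stock counter: each fill adds
    its supply to the stock on its day; every non-hospital day with
    positive stock is a covered adherence day and consumes one unit;
    hospital days consume nothing and are not adherence days.  Returns
    the boolean coverage vector on the compressed (adherence-day) clock.
    This reproduces completion-date chaining with early-refill deferral
    and end-of-window truncation by construction, through an entirely
    different mechanism than interval arithmetic.
    """
    add = {}
    for day, supply in fills:
        add[day] = add.get(day, 0) + supply
    stock = 0
    covered = []
    for day in range(span):
        stock += add.get(day, 0)
        if day in hospital_days:
            continue
        if stock > 0:
            covered.append(True)
            stock -= 1
        else:
            covered.append(False)
    return np.asarray(covered, dtype=bool)


def random_history(rng, max_span=2000):
    """A random fill/hospitalization history for oracle comparison."""
    span = int(rng.integers(50, max_span))
    n_fills = int(rng.integers(0, 25))
    fills = [(int(rng.integers(0, span)), int(rng.integers(1, 120)))
             for _ in range(n_fills)]
    hospital = set()
    for _ in range(int(rng.integers(0, 4))):
        start = int(rng.integers(0, span))
        hospital.update(range(start, min(span, start + int(rng.integers(1, 30)))))
    return span, fills, hospital
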