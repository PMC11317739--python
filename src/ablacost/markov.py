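"""Lifetime annual-cycle Markov cohort model.

States: free of AF symptoms (AF-), symptomatic AF (AF+), incident
ischemic stroke (IS), chronic post-stroke (Post-IS) and Dead.  AF- can
revert to AF+ (no further ablation once symptoms recur), either AF state
can suffer a stroke, and everyone faces age- and sex-blended background
mortality from a life table.  Stroke carries 28-day and first-year case
fatality; survivors move to Post-IS, which has its own annual mortality
floored at the background rate.  Repeat strokes are not modelled.

Within a cycle, background death is resolved first; stroke and
recurrence then compete additively among survivors, which keeps every
transition row exactly stochastic whenever their probabilities sum to at
most one (validated).

Costs accrue per person-year of state occupancy (AF-, AF+, Post-IS) and
per incident stroke event (fatal/non-fatal split at 28 days), discounted
on the model-year clock continued from the decision tree: a cost in
model year y carries the factor (1 + r)^-(y - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams, ParameterError
from .tree import TreeOutcome

__all__ = [
    "STATES",
    "LifeTable",
    "MarkovTrace",
    "blended_mortality",
    "transition_row",
    "run_markov",
    "COST_BUCKETS",
]

STATES = ("af_neg", "af_pos", "is", "post_is", "dead")
_IDX = {s: i for i, s in enumerate(STATES)}
COST_BUCKETS = ("af_neg", "af_pos", "is_fatal", "is_nonfatal", "post_is")

DEFAULT_HORIZON_AGE = 110.0


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age and sex."""

    age: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=int)
        qm = np.asarray(self.qx_male, dtype=float)
        qf = np.asarray(self.qx_female, dtype=float)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "qx_male", qm)
        object.__setattr__(self, "qx_female", qf)
        if not (len(age) == len(qm) == len(qf)) or len(age) == 0:
            raise ParameterError("life table columns must be equal-length and non-empty")
        if not np.array_equal(age, np.arange(age[0], age[0] + len(age))):
            raise ParameterError("life table ages must be consecutive integers")
        for name, q in (("qx_male", qm), ("qx_female", qf)):
            if np.any((q < 0) | (q > 1)):
                raise ParameterError(f"{name} values must lie in [0, 1]")
            if q[-1] != 1.0:
                raise ParameterError(f"{name} must close with qx = 1 at the final age")
            above60 = q[age >= 60]
            if np.any(np.diff(above60) < -1e-12):
                raise ParameterError(f"{name} must be non-decreasing above age 60")

    @property
    def max_age(self) -> int:
        return int(self.age[-1])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "qx_male", "qx_female"} - set(df.columns)
        if missing:
            raise ParameterError(f"life table CSV missing columns: {sorted(missing)}")
        return cls(
            age=df["age"].to_numpy(),
            qx_male=df["qx_male"].to_numpy(),
            qx_female=df["qx_female"].to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.age, "qx_male": self.qx_male, "qx_female": self.qx_female}
        )


def blended_mortality(age: float, male_fraction: float, lt: LifeTable) -> float:
    """Sex-blended annual death probability at a (possibly fractional) age.

    Non-integer ages use the floor-age row; ages beyond the table are
    absorbing (probability 1).
    """
    row_age = int(np.floor(age))
    if row_age > lt.max_age:
        return 1.0
    if row_age < lt.age[0]:
        raise ParameterError(f"age {age} below the life table range")
    i = row_age - int(lt.age[0])
    return float(
        male_fraction * lt.qx_male[i] + (1.0 - male_fraction) * lt.qx_female[i]
    )


def transition_row(
    state: str,
    years_since_entry: int,
    age: float,
    p: ModelParams,
    lt: LifeTable,
) -> np.ndarray:
    """One-cycle transition probabilities out of a state.

    ``years_since_entry`` is 1-based: recurrence from AF- runs at the
    early-phase annual rate in Markov years 1-2 and the late rate after.
    """
    if state not in STATES:
        raise ParameterError(f"unknown state {state}")
    row = np.zeros(len(STATES))
    q = blended_mortality(age, p.male_fraction, lt)
    if state == "af_neg":
        p_rec = p.p_recur_markov_y12 if years_since_entry <= 2 else p.p_recur_markov_later
        if p_rec + p.p_is_markov > 1.0:
            raise ParameterError(
                f"recurrence + stroke probabilities exceed 1 in Markov year {years_since_entry}"
            )
        surv = 1.0 - q
        row[_IDX["dead"]] = q
        row[_IDX["is"]] = surv * p.p_is_markov
        row[_IDX["af_pos"]] = surv * p_rec
        row[_IDX["af_neg"]] = surv * (1.0 - p.p_is_markov - p_rec)
    elif state == "af_pos":
        surv = 1.0 - q
        row[_IDX["dead"]] = q
        row[_IDX["is"]] = surv * p.p_is_markov
        row[_IDX["af_pos"]] = surv * (1.0 - p.p_is_markov)
    elif state == "is":
        # 28-day fatality plus first-year mortality among 28-day survivors.
        p_die = p.p_is_death_28d + (1.0 - p.p_is_death_28d) * p.p_is_death_1y_survivors
        row[_IDX["dead"]] = p_die
        row[_IDX["post_is"]] = 1.0 - p_die
    elif state == "post_is":
        # Never safer than the general population at high ages.
        p_die = max(p.p_death_post_is, q)
        row[_IDX["dead"]] = p_die
        row[_IDX["post_is"]] = 1.0 - p_die
    else:  # dead
        row[_IDX["dead"]] = 1.0
    return row


@dataclass(frozen=True)
class MarkovTrace:
    """Cohort trace with per-cycle discounted costs by bucket."""

    frame: pd.DataFrame  # year, age, state fractions, per-cycle bucket costs
    totals: dict[str, float]  # cumulative discounted cost per bucket

    def __post_init__(self) -> None:
        for b in COST_BUCKETS:
            col = float(self.frame[f"cost_{b}"].sum())
            if abs(col - self.totals[b]) > 1e-6:
                raise ValueError(f"bucket {b} total does not match per-cycle entries")


def _transition_matrix(
    years_since_entry: int, age: float, p: ModelParams, lt: LifeTable
) -> np.ndarray:
    return np.array(
        [transition_row(s, years_since_entry, age, p, lt) for s in STATES]
    )


def run_markov(
    entry: TreeOutcome,
    p: ModelParams,
    lt: LifeTable,
    horizon_age: float = DEFAULT_HORIZON_AGE,
) -> MarkovTrace:
    """Run the cohort to the horizon age and accumulate discounted costs.

    The tree hands over two sub-cohorts with identical state mix: most
    enter in model year 2, patients who received a third ablation enter
    in year 3 (their recurrence clock starts a year later).  Stroke-state
    entrants from the tree pass through the IS row but accrue no event
    costs here — their acute costs were charged in the tree; only strokes
    incident within the Markov model are charged the fatal/non-fatal
    event costs.
    """
    entry_years = sorted(entry.entry_year)
    if any(f < 0 for f in entry.entry_year.values()):
        raise ParameterError("entry-year fractions must be non-negative")
    first_entry = min(entry_years)
    if horizon_age <= p.start_age + first_entry - 1:
        raise ParameterError(
            f"horizon age {horizon_age} does not reach the Markov entry year"
        )

    dist = np.array([entry.entry_distribution.get(s, 0.0) for s in STATES])
    last_year = int(np.ceil(horizon_age - p.start_age)) + 1

    years = list(range(first_entry, last_year + 1))
    occ_by_year = {y: np.zeros(len(STATES)) for y in years}
    cost_by_year = {y: dict.fromkeys(COST_BUCKETS, 0.0) for y in years}

    for entry_year in entry_years:
        frac = entry.entry_year[entry_year]
        if frac == 0.0:
            continue
        occ = frac * dist
        for year in years:
            if year < entry_year:
                # Still in the decision tree; shown for conservation, no
                # Markov costs or transitions yet.
                occ_by_year[year] += occ
                continue
            age = p.start_age + (year - 1)
            occ_by_year[year] += occ
            if age >= horizon_age:
                continue
            disc = (1.0 + p.discount_rate) ** (-(year - 1))
            costs = cost_by_year[year]
            costs["af_neg"] += occ[_IDX["af_neg"]] * p.cost_state_af_neg * disc
            costs["af_pos"] += occ[_IDX["af_pos"]] * p.cost_state_af_pos * disc
            costs["post_is"] += occ[_IDX["post_is"]] * p.cost_state_post_is * disc
            years_since_entry = year - entry_year + 1
            t = _transition_matrix(years_since_entry, age, p, lt)
            inflow_is = (
                occ[_IDX["af_neg"]] * t[_IDX["af_neg"], _IDX["is"]]
                + occ[_IDX["af_pos"]] * t[_IDX["af_pos"], _IDX["is"]]
            )
            costs["is_fatal"] += (
                inflow_is * p.p_is_death_28d * p.cost_is_fatal * disc
            )
            costs["is_nonfatal"] += (
                inflow_is * (1.0 - p.p_is_death_28d) * p.cost_is_nonfatal * disc
            )
            occ = occ @ t

    records = []
    for year in years:
        age = p.start_age + (year - 1)
        rec = {"year": year, "age": age}
        rec.update({s: occ_by_year[year][i] for i, s in enumerate(STATES)})
        rec.update({f"cost_{b}": cost_by_year[year][b] for b in COST_BUCKETS})
        records.append(rec)
    frame = pd.DataFrame(records)
    totals = {b: float(frame[f"cost_{b}"].sum()) for b in COST_BUCKETS}
    return MarkovTrace(frame=frame, totals=totals)
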