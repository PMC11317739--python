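"""Synthetic stand-ins for inputs the evidence base does not publish.

Two generators:

* study sets for the meta-analysis with a known true risk ratio and
  between-study variance, used for parameter-recovery and coverage
  checks (the real per-study event counts exist only as figures);
* parametric Gompertz-Makeham life tables, used for background
  mortality because no specific national table is named.  The default
  fixture gives a mixed-sex cohort entering in its mid-sixties a
  remaining life expectancy in the high teens — realistic enough for a
  lifetime cost model, but a fixture, not a demographic claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import LifeTable
from .meta import StudyRecord

__all__ = [
    "MetaSimSpec",
    "LifeTableSpec",
    "simulate_meta_dataset",
    "make_life_table",
    "default_life_table",
]


@dataclass(frozen=True)
class MetaSimSpec:
    """Generative settings for a synthetic study set.

    Per study: a baseline (RFA-arm) recurrence risk and per-arm sizes
    drawn uniformly from their ranges, a study-level log risk ratio
    drawn Normal(true_log_rr, tau2), and binomial event counts per arm.
    Defaults emulate the published evidence base: 18 studies (about
    two-thirds randomized), arm sizes from tens to a few hundred,
    recurrence risks of 20-45% at roughly one year.
    """

    k: int = 18
    true_log_rr: float = math.log(0.93)
    tau2: float = 0.01
    baseline_risk: tuple[float, float] = (0.20, 0.45)
    n_per_arm: tuple[int, int] = (25, 380)
    cf_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        lo, hi = self.baseline_risk
        if not 0 < lo <= hi < 1:
            raise ValueError("baseline_risk range must be ordered within (0, 1)")
        nlo, nhi = self.n_per_arm
        if not 0 < nlo <= nhi:
            raise ValueError("n_per_arm range must be ordered and positive")
        if not 0 <= self.cf_fraction <= 1:
            raise ValueError("cf_fraction must be a probability")


def simulate_meta_dataset(spec: MetaSimSpec) -> list[StudyRecord]:
    """Draw a reproducible study set with known truth."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.k):
        p_rfa = rng.uniform(*spec.baseline_risk)
        n_rfa = int(rng.integers(spec.n_per_arm[0], spec.n_per_arm[1] + 1))
        n_cba = int(rng.integers(spec.n_per_arm[0], spec.n_per_arm[1] + 1))
        theta = rng.normal(spec.true_log_rr, math.sqrt(spec.tau2))
        p_cba = min(1.0, p_rfa * math.exp(theta))
        events_rfa = int(rng.binomial(n_rfa, p_rfa))
        events_cba = int(rng.binomial(n_cba, p_cba))
        rfa_type = "CF" if rng.random() < spec.cf_fraction else "non-CF"
        design = "RCT" if rng.random() < 2.0 / 3.0 else "PSM"
        records.append(
            StudyRecord(
                study_id=f"synthetic_{i + 1:02d}",
                design=design,
                n_cba=n_cba,
                n_rfa=n_rfa,
                events_cba=events_cba,
                events_rfa=events_rfa,
                rfa_type=rfa_type,
                followup_months=12.0,
            )
        )
    return records


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz-Makeham hazard: qx(age) = min(1, a + b * exp(c * age)).

    The male column is the same curve scaled by ``male_excess`` (capped
    at 1); the final row is forced to 1 so the table closes.
    """

    makeham_a: float = 0.0005
    gompertz_b: float = 0.00003
    gompertz_c: float = 0.095
    male_excess: float = 1.6
    max_age: int = 110

    def __post_init__(self) -> None:
        if self.makeham_a < 0 or self.gompertz_b < 0:
            raise ValueError("hazard parameters must be non-negative")
        if self.male_excess <= 0:
            raise ValueError("male_excess must be positive")
        if self.max_age < 1:
            raise ValueError("max_age must be at least 1")


def make_life_table(spec: LifeTableSpec) -> LifeTable:
    """Generate the parametric life table."""
    ages = np.arange(0, spec.max_age + 1)
    base = spec.makeham_a + spec.gompertz_b * np.exp(spec.gompertz_c * ages)
    qx_female = np.minimum(1.0, base)
    qx_male = np.minimum(1.0, spec.male_excess * base)
    qx_female[-1] = 1.0
    qx_male[-1] = 1.0
    return LifeTable(age=ages, qx_male=qx_male, qx_female=qx_female)


def default_life_table() -> LifeTable:
    """The bundled background-mortality fixture."""
    return make_life_table(LifeTableSpec())
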