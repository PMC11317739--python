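"""Pairwise meta-analysis of AF recurrence after catheter ablation.

Per-study effects are risk ratios (from 2x2 arm counts) or hazard ratios
(back-calculated from a reported 95% CI), pooled on the log scale by
inverse-variance weighting.  Both the fixed-effect model and the
DerSimonian-Laird random-effects model are provided, with Cochran's Q,
its chi-square p-value, and the inconsistency index I^2 = max(0, (Q -
df)/Q) quantifying between-study heterogeneity.  A subgroup split pools
contact-force and non-contact-force radiofrequency comparators
separately; studies whose comparator type cannot be determined are kept
in the overall pool but excluded from the split.

Convention: the treatment arm is cryoballoon ablation (CBA), the control
arm radiofrequency ablation (RFA); a ratio below 1 favours CBA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z95",
    "MetaError",
    "StudyRecord",
    "EffectEstimate",
    "PooledResult",
    "rr_effect",
    "hr_effect",
    "effects_from_studies",
    "pool_fixed",
    "pool_random_dl",
    "heterogeneity",
    "subgroup_pool",
    "studies_from_csv",
    "studies_to_csv",
    "forest_table",
]

#: Two-sided 95% standard-normal quantile.
Z95 = 1.959964

MIN_FOLLOWUP_MONTHS = 6.0


class MetaError(ValueError):
    """Invalid study data or an undefined pooled quantity."""


@dataclass(frozen=True)
class StudyRecord:
    """One trial or matched cohort comparing CBA against RFA.

    Either per-arm recurrence counts or a hazard-ratio triple (or both)
    must be present.
    """

    study_id: str
    design: str  # "RCT" or "PSM"
    n_cba: int
    n_rfa: int
    events_cba: int | None = None
    events_rfa: int | None = None
    hr: float | None = None
    hr_lcl: float | None = None
    hr_ucl: float | None = None
    rfa_type: str = "unknown"  # "CF", "non-CF" or "unknown"
    followup_months: float = 12.0

    def __post_init__(self) -> None:
        if self.design not in ("RCT", "PSM"):
            raise MetaError(f"{self.study_id}: design must be RCT or PSM, got {self.design}")
        if self.rfa_type not in ("CF", "non-CF", "unknown"):
            raise MetaError(f"{self.study_id}: invalid rfa_type {self.rfa_type}")
        if self.n_cba <= 0 or self.n_rfa <= 0:
            raise MetaError(f"{self.study_id}: arm sizes must be positive")
        has_counts = self.events_cba is not None and self.events_rfa is not None
        has_hr = self.hr is not None and self.hr_lcl is not None and self.hr_ucl is not None
        if not has_counts and not has_hr:
            raise MetaError(
                f"{self.study_id}: needs either event counts or an HR with CI"
            )
        if has_counts:
            if not 0 <= self.events_cba <= self.n_cba:  # type: ignore[operator]
                raise MetaError(f"{self.study_id}: events_cba exceeds n_cba")
            if not 0 <= self.events_rfa <= self.n_rfa:  # type: ignore[operator]
                raise MetaError(f"{self.study_id}: events_rfa exceeds n_rfa")
        if has_hr:
            if self.hr_lcl <= 0:  # type: ignore[operator]
                raise MetaError(f"{self.study_id}: HR confidence limits must be positive")
            if not self.hr_lcl <= self.hr <= self.hr_ucl:  # type: ignore[operator]
                raise MetaError(f"{self.study_id}: HR must lie within its CI")

    @property
    def has_counts(self) -> bool:
        return self.events_cba is not None and self.events_rfa is not None

    @property
    def has_hr(self) -> bool:
        return self.hr is not None


@dataclass(frozen=True)
class EffectEstimate:
    """A study's log-scale effect with its standard error."""

    study_id: str
    measure: str  # "RR" or "HR"
    log_effect: float
    se: float
    subgroup: str = "unknown"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_effect):
            raise MetaError(f"{self.study_id}: log effect is not finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise MetaError(f"{self.study_id}: standard error must be positive and finite")

    @property
    def ratio(self) -> float:
        return math.exp(self.log_effect)


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect with heterogeneity statistics."""

    measure: str
    method: str  # "fixed" or "random_DL"
    log_pooled: float
    se_pooled: float
    ci95: tuple[float, float]  # on the ratio scale
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float
    k: int

    @property
    def ratio(self) -> float:
        return math.exp(self.log_pooled)


def rr_effect(
    events_t: int,
    n_t: int,
    events_c: int,
    n_c: int,
    cc: float = 0.5,
    study_id: str = "",
    subgroup: str = "unknown",
) -> EffectEstimate:
    """Log risk ratio (treatment = CBA over control = RFA) with its SE.

    The continuity correction ``cc`` is added to all four cells only when
    any cell of the 2x2 table is zero.  With both arms event-free and
    ``cc = 0`` the effect is undefined and an error is raised.
    """
    if n_t <= 0 or n_c <= 0:
        raise MetaError("arm sizes must be positive")
    if not 0 <= events_t <= n_t or not 0 <= events_c <= n_c:
        raise MetaError("event counts must lie between 0 and the arm size")
    a, c = float(events_t), float(events_c)
    nt, nc = float(n_t), float(n_c)
    has_zero_cell = a == 0 or c == 0 or a == nt or c == nc
    if has_zero_cell and cc > 0:
        a, c, nt, nc = a + cc, c + cc, nt + cc, nc + cc
    if a == 0 and c == 0:
        raise MetaError("risk ratio undefined: no events in either arm and cc = 0")
    if a == 0 or c == 0 or a == nt or c == nc:
        raise MetaError("risk ratio undefined for a zero cell without continuity correction")
    log_effect = math.log((a / nt) / (c / nc))
    se = math.sqrt(1.0 / a - 1.0 / nt + 1.0 / c - 1.0 / nc)
    return EffectEstimate(study_id, "RR", log_effect, se, subgroup)


def hr_effect(
    hr: float,
    lcl: float,
    ucl: float,
    study_id: str = "",
    subgroup: str = "unknown",
) -> EffectEstimate:
    """Log hazard ratio with SE back-calculated from a 95% CI."""
    if lcl <= 0 or hr <= 0 or ucl <= 0:
        raise MetaError("hazard ratio and confidence limits must be positive")
    if not lcl <= hr <= ucl:
        raise MetaError("hazard ratio must lie within its confidence interval")
    if ucl == lcl:
        raise MetaError("zero-width confidence interval: standard error undefined")
    se = (math.log(ucl) - math.log(lcl)) / (2.0 * Z95)
    return EffectEstimate(study_id, "HR", math.log(hr), se, subgroup)


def effects_from_studies(
    studies: Iterable[StudyRecord], measure: str = "RR", cc: float = 0.5
) -> list[EffectEstimate]:
    """Per-study effects for one measure.

    RR uses studies reporting arm counts; HR uses only studies reporting
    an HR with CI (no imputation across measures).  Studies followed for
    less than six months are excluded.
    """
    measure = measure.upper()
    if measure not in ("RR", "HR"):
        raise MetaError(f"measure must be RR or HR, got {measure}")
    out: list[EffectEstimate] = []
    for s in studies:
        if s.followup_months < MIN_FOLLOWUP_MONTHS:
            continue
        if measure == "RR" and s.has_counts:
            out.append(
                rr_effect(
                    s.events_cba, s.n_cba, s.events_rfa, s.n_rfa,  # type: ignore[arg-type]
                    cc=cc, study_id=s.study_id, subgroup=s.rfa_type,
                )
            )
        elif measure == "HR" and s.has_hr:
            out.append(
                hr_effect(
                    s.hr, s.hr_lcl, s.hr_ucl,  # type: ignore[arg-type]
                    study_id=s.study_id, subgroup=s.rfa_type,
                )
            )
    return out


def _check_estimates(estimates: Sequence[EffectEstimate]) -> str:
    if len(estimates) == 0:
        raise MetaError("cannot pool an empty list of estimates")
    measures = {e.measure for e in estimates}
    if len(measures) > 1:
        raise MetaError(f"cannot pool mixed measures: {sorted(measures)}")
    return estimates[0].measure


def _het_stats(y: np.ndarray, w: np.ndarray) -> tuple[float, int, float, float]:
    """Cochran's Q, df, chi-square p and I^2 from fixed-effect weights."""
    k = len(y)
    df = k - 1
    if k < 2:
        return 0.0, 0, 1.0, 0.0
    y_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fixed) ** 2))
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, p_q, i2


def heterogeneity(
    estimates: Sequence[EffectEstimate],
) -> tuple[float, int, float, float]:
    """(Q, df, p, I^2) for a set of at least two study effects."""
    _check_estimates(estimates)
    if len(estimates) < 2:
        raise MetaError("heterogeneity requires at least two studies")
    y = np.array([e.log_effect for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    return _het_stats(y, w)


def pool_fixed(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling."""
    measure = _check_estimates(estimates)
    y = np.array([e.log_effect for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    log_pooled = float(np.sum(w * y) / np.sum(w))
    se_pooled = float(math.sqrt(1.0 / np.sum(w)))
    q, df, p_q, i2 = _het_stats(y, w)
    ci = (
        math.exp(log_pooled - Z95 * se_pooled),
        math.exp(log_pooled + Z95 * se_pooled),
    )
    return PooledResult(
        measure=measure, method="fixed", log_pooled=log_pooled, se_pooled=se_pooled,
        ci95=ci, q=q, df=df, p_q=p_q, i2=i2, tau2=0.0, k=len(estimates),
    )


def pool_random_dl(estimates: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 is the moment estimator max(0, (Q - df)/(S1 - S2/S1)) computed
    from fixed-effect weights; pooled statistics use the inflated weights
    1/(se^2 + tau^2).
    """
    measure = _check_estimates(estimates)
    if len(estimates) < 2:
        raise MetaError(
            "random-effects pooling requires at least two studies; use pool_fixed"
        )
    y = np.array([e.log_effect for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    w = 1.0 / v
    q, df, p_q, i2 = _het_stats(y, w)
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    tau2 = max(0.0, (q - df) / (s1 - s2 / s1))
    w_star = 1.0 / (v + tau2)
    log_pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se_pooled = float(math.sqrt(1.0 / np.sum(w_star)))
    ci = (
        math.exp(log_pooled - Z95 * se_pooled),
        math.exp(log_pooled + Z95 * se_pooled),
    )
    return PooledResult(
        measure=measure, method="random_DL", log_pooled=log_pooled,
        se_pooled=se_pooled, ci95=ci, q=q, df=df, p_q=p_q, i2=i2, tau2=tau2,
        k=len(estimates),
    )


def subgroup_pool(
    estimates: Sequence[EffectEstimate],
) -> dict[str, dict[str, PooledResult | None] | None]:
    """Pool the CF-RFA and non-CF-RFA comparator subgroups independently.

    Estimates with an unknown comparator type are excluded from both
    subgroups.  An empty subgroup is reported as ``None``; a singleton
    subgroup carries a fixed-effect result only.
    """
    out: dict[str, dict[str, PooledResult | None] | None] = {}
    for label in ("CF", "non-CF"):
        members = [e for e in estimates if e.subgroup == label]
        if not members:
            out[label] = None
            continue
        fixed = pool_fixed(members)
        random = pool_random_dl(members) if len(members) >= 2 else None
        out[label] = {"fixed": fixed, "random": random}
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "study_id", "design", "n_cba", "events_cba", "n_rfa", "events_rfa",
    "hr", "hr_lcl", "hr_ucl", "rfa_type", "followup_months",
]


def studies_from_csv(path: str | Path) -> list[StudyRecord]:
    """Read study records; empty cells mark absent measures."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise MetaError(f"study CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key: str, cast=float):
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else cast(v)

        records.append(
            StudyRecord(
                study_id=str(d["study_id"]),
                design=str(d["design"]),
                n_cba=int(d["n_cba"]),
                n_rfa=int(d["n_rfa"]),
                events_cba=opt("events_cba", int),
                events_rfa=opt("events_rfa", int),
                hr=opt("hr"),
                hr_lcl=opt("hr_lcl"),
                hr_ucl=opt("hr_ucl"),
                rfa_type=str(d["rfa_type"]),
                followup_months=float(d["followup_months"]),
            )
        )
    return records


def studies_to_csv(studies: Iterable[StudyRecord], path: str | Path) -> None:
    rows = [
        {col: getattr(s, col) for col in _CSV_COLUMNS}
        for s in studies
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def forest_table(
    estimates: Sequence[EffectEstimate], pooled: PooledResult
) -> pd.DataFrame:
    """Forest-plot-ready table: per-study ratios, CIs and weight shares.

    Weights are those of the pooled model supplied (fixed weights, or
    DL-inflated weights for a random-effects result).
    """
    tau2 = pooled.tau2
    w = np.array([1.0 / (e.se**2 + tau2) for e in estimates])
    weight_pct = 100.0 * w / w.sum()
    rows = [
        {
            "study": e.study_id,
            "ratio": e.ratio,
            "ci_low": math.exp(e.log_effect - Z95 * e.se),
            "ci_high": math.exp(e.log_effect + Z95 * e.se),
            "weight_pct": float(pct),
            "subgroup": e.subgroup,
        }
        for e, pct in zip(estimates, weight_pct)
    ]
    rows.append(
        {
            "study": f"pooled ({pooled.method})",
            "ratio": pooled.ratio,
            "ci_low": pooled.ci95[0],
            "ci_high": pooled.ci95[1],
            "weight_pct": 100.0,
            "subgroup": "",
        }
    )
    return pd.DataFrame(rows)
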