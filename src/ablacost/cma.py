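"""Cost-minimization report: per-strategy totals and component rows.

Runs the decision tree and the Markov model for both index-procedure
strategies under shared parameters and assembles the published report
shape: a total per strategy, seven component rows (intervention,
serious adverse events, AF-state and stroke buckets) and the difference
column (RFA minus CBA, so the negative entries read as savings for RFA).
Because every transition probability is shared between strategies, the
Markov rows cancel exactly and the total difference reduces to the
intervention plus complication-cost differences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .markov import DEFAULT_HORIZON_AGE, LifeTable, MarkovTrace, run_markov
from .params import ModelParams
from .tree import CBA, RFA, TreeOutcome, run_tree, strategy_from_params

__all__ = [
    "CostBreakdown",
    "CmaReport",
    "run_cma",
    "to_usd",
    "round_yen",
]

COMPONENT_ROWS = (
    "intervention",
    "sae",
    "af_neg",
    "af_pos",
    "is_fatal",
    "is_nonfatal",
    "post_is",
)

ROW_LABELS = {
    "total": "Total",
    "intervention": "Intervention costs",
    "sae": "Serious adverse event costs",
    "af_neg": "AF symptom (-)",
    "af_pos": "AF symptom (+)",
    "is_fatal": "Fatal IS",
    "is_nonfatal": "Non-fatal IS",
    "post_is": "Post IS",
}


def round_yen(x: float) -> int:
    """Round to the nearest yen, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def to_usd(jpy: float, rate: float) -> int:
    """Convert JPY to USD at a fixed rate, rounded to the nearest dollar."""
    if rate <= 0:
        raise ValueError(f"JPY/USD rate must be positive, got {rate}")
    return round_yen(jpy / rate)


@dataclass(frozen=True)
class CostBreakdown:
    """One strategy's lifetime discounted costs by component (JPY)."""

    strategy: str
    total: float
    intervention: float
    sae: float
    af_neg: float
    af_pos: float
    is_fatal: float
    is_nonfatal: float
    post_is: float

    def component(self, row: str) -> float:
        return getattr(self, row)

    def __post_init__(self) -> None:
        parts = sum(getattr(self, r) for r in COMPONENT_ROWS)
        if abs(parts - self.total) > 1.0:
            raise ValueError("total does not equal the sum of its components")


@dataclass(frozen=True)
class CmaReport:
    """Both strategies' breakdowns with the RFA - CBA difference column."""

    breakdown_rfa: CostBreakdown
    breakdown_cba: CostBreakdown
    difference: dict[str, float]  # row -> RFA - CBA
    usd_rate: float
    tree_rfa: TreeOutcome
    tree_cba: TreeOutcome
    markov_rfa: MarkovTrace
    markov_cba: MarkovTrace

    def report_frame(self) -> pd.DataFrame:
        """Published-report-shaped table, rounded to integer yen."""
        rows = []
        for key in ("total",) + COMPONENT_ROWS:
            rows.append(
                {
                    "row": ROW_LABELS[key],
                    "rfa_jpy": round_yen(self.breakdown_rfa.component(key))
                    if key != "total"
                    else round_yen(self.breakdown_rfa.total),
                    "cba_jpy": round_yen(self.breakdown_cba.component(key))
                    if key != "total"
                    else round_yen(self.breakdown_cba.total),
                    "difference_jpy": round_yen(self.difference[key]),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "usd_rate": self.usd_rate,
            "rows": self.report_frame().to_dict(orient="records"),
            "difference_total_usd": to_usd(self.difference["total"], self.usd_rate),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _breakdown(
    strategy_name: str, tree: TreeOutcome, trace: MarkovTrace
) -> CostBreakdown:
    intervention = tree.cost_intervention
    sae = tree.cost_sae
    af_neg = trace.totals["af_neg"]
    af_pos = trace.totals["af_pos"]
    is_fatal = tree.cost_is_fatal + trace.totals["is_fatal"]
    is_nonfatal = tree.cost_is_nonfatal + trace.totals["is_nonfatal"]
    post_is = trace.totals["post_is"]
    total = intervention + sae + af_neg + af_pos + is_fatal + is_nonfatal + post_is
    return CostBreakdown(
        strategy=strategy_name,
        total=total,
        intervention=intervention,
        sae=sae,
        af_neg=af_neg,
        af_pos=af_pos,
        is_fatal=is_fatal,
        is_nonfatal=is_nonfatal,
        post_is=post_is,
    )


def run_cma(
    p: ModelParams,
    lt: LifeTable,
    horizon_age: float = DEFAULT_HORIZON_AGE,
) -> CmaReport:
    """Run tree + Markov for both strategies and assemble the report."""
    tree_rfa = run_tree(strategy_from_params(p, RFA), p)
    tree_cba = run_tree(strategy_from_params(p, CBA), p)
    markov_rfa = run_markov(tree_rfa, p, lt, horizon_age)
    markov_cba = run_markov(tree_cba, p, lt, horizon_age)
    b_rfa = _breakdown("RFA_first", tree_rfa, markov_rfa)
    b_cba = _breakdown("CBA_first", tree_cba, markov_cba)
    difference = {"total": b_rfa.total - b_cba.total}
    for row in COMPONENT_ROWS:
        difference[row] = b_rfa.component(row) - b_cba.component(row)
    return CmaReport(
        breakdown_rfa=b_rfa,
        breakdown_cba=b_cba,
        difference=difference,
        usd_rate=p.jpy_per_usd,
        tree_rfa=tree_rfa,
        tree_cba=tree_cba,
        markov_rfa=markov_rfa,
        markov_cba=markov_cba,
    )
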