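"""One-way deterministic sensitivity analysis (tornado).

Each parameter with a published range is set to its low and high bound
in turn, everything else held at base, and the cost-minimization model
is re-run; the recorded endpoint is the total RFA - CBA difference.
Entries are ranked by span (|difference at high - difference at low|),
ties broken alphabetically — the shape of a tornado diagram.  Parameters
that only enter the Markov model have exactly zero span, because the
Markov rows cancel between strategies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cma import run_cma
from .markov import DEFAULT_HORIZON_AGE, LifeTable
from .params import ModelParams, apply_dsa_value

__all__ = ["TornadoEntry", "one_way_dsa", "tornado_frame"]


@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's low/high endpoints for the tornado diagram."""

    parameter: str
    low_value: float
    high_value: float
    diff_at_low: float  # total RFA - CBA at the low bound (JPY)
    diff_at_high: float

    @property
    def span(self) -> float:
        return abs(self.diff_at_high - self.diff_at_low)


def one_way_dsa(
    p: ModelParams,
    lt: LifeTable,
    horizon_age: float = DEFAULT_HORIZON_AGE,
) -> list[TornadoEntry]:
    """Vary every parameter in ``p.dsa_ranges`` one at a time."""
    entries = []
    for key in sorted(p.dsa_ranges):
        low, high = p.dsa_ranges[key]
        diff_low = run_cma(apply_dsa_value(p, key, low), lt, horizon_age).difference[
            "total"
        ]
        diff_high = run_cma(apply_dsa_value(p, key, high), lt, horizon_age).difference[
            "total"
        ]
        entries.append(
            TornadoEntry(
                parameter=key,
                low_value=low,
                high_value=high,
                diff_at_low=diff_low,
                diff_at_high=diff_high,
            )
        )
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low_value,
                "high": e.high_value,
                "diff_low": e.diff_at_low,
                "diff_high": e.diff_at_high,
                "span": e.span,
            }
            for e in entries
        ]
    )
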