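"""Model inputs for the ablation cost-minimization model.

Houses every base-case parameter of the decision-tree + Markov model —
cohort settings, per-procedure and per-year transition probabilities,
unit costs in JPY, the annual discount rate — together with the one-way
sensitivity (DSA) bounds for each of them.  A bundled default
configuration carries the published base case; :func:`load_params`
validates any user-supplied configuration against the same invariants
(probabilities in [0, 1], non-negative costs, DSA bounds bracketing the
base value).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ModelParams",
    "ParameterError",
    "load_params",
    "loads_params",
    "default_params",
    "dump_params",
    "effective_recurrence_after_reablation",
    "params_table",
    "DSA_PARAMETERS",
    "dsa_base_value",
    "apply_dsa_value",
]

logger = logging.getLogger("ablacost")

#: Complications modelled per procedure.  Phrenic nerve palsy occurs after
#: cryoballoon procedures only.
COMPLICATIONS_RFA = (
    "esophageal_injury",
    "cardiac_tamponade",
    "pv_stenosis",
    "vascular",
    "groin",
)
COMPLICATIONS_CBA = (
    "esophageal_injury",
    "cardiac_tamponade",
    "pv_stenosis",
    "phrenic_nerve_palsy",
    "vascular",
    "groin",
)
ALL_COMPLICATIONS = COMPLICATIONS_CBA


class ParameterError(ValueError):
    """A model input is missing, unknown, or violates its invariant."""


_PROBABILITY_FIELDS = (
    "male_fraction",
    "p_recur_first",
    "p_reablate_2nd",
    "p_reablate_3rd",
    "mix_2nd_rfa_after_rfa",
    "mix_2nd_rfa_after_cba",
    "mix_3rd_rfa_after_rfa",
    "mix_3rd_rfa_after_cba",
    "p_is_tree",
    "p_death_tree",
    "p_recur_markov_y12",
    "p_recur_markov_later",
    "p_is_markov",
    "p_is_death_28d",
    "p_is_death_1y_survivors",
    "p_death_post_is",
)

_COST_FIELDS = (
    "cost_proc_rfa",
    "cost_proc_cba",
    "cost_is_nonfatal",
    "cost_is_fatal",
    "cost_state_af_pos",
    "cost_state_af_neg",
    "cost_state_post_is",
)


@dataclass(frozen=True)
class ModelParams:
    """Complete, validated input set for the cost-minimization model.

    Probabilities under the decision tree are per procedure (or per tree
    period for recurrence); Markov probabilities are annual.  Costs are
    JPY per event or per state-year.
    """

    start_age: float
    male_fraction: float
    p_recur_first: float
    rr_recur_reablation: float
    p_reablate_2nd: float
    p_reablate_3rd: float
    mix_2nd_rfa_after_rfa: float
    mix_2nd_rfa_after_cba: float
    mix_3rd_rfa_after_rfa: float
    mix_3rd_rfa_after_cba: float
    sae_probs_rfa: dict[str, float]
    sae_probs_cba: dict[str, float]
    p_is_tree: float
    p_death_tree: float
    p_recur_markov_y12: float
    p_recur_markov_later: float
    p_is_markov: float
    p_is_death_28d: float
    p_is_death_1y_survivors: float
    p_death_post_is: float
    cost_proc_rfa: float
    cost_proc_cba: float
    sae_costs: dict[str, float]
    cost_is_nonfatal: float
    cost_is_fatal: float
    cost_state_af_pos: float
    cost_state_af_neg: float
    cost_state_post_is: float
    discount_rate: float
    jpy_per_usd: float
    dsa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a probability in [0, 1], got {v}")
        for name in _COST_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be a non-negative cost, got {v}")
        if self.start_age <= 0:
            raise ParameterError(f"start_age must be positive, got {self.start_age}")
        if self.rr_recur_reablation < 0:
            raise ParameterError(
                f"rr_recur_reablation must be non-negative, got {self.rr_recur_reablation}"
            )
        if not 0.0 <= self.discount_rate < 1.0:
            raise ParameterError(
                f"discount_rate must lie in [0, 1), got {self.discount_rate}"
            )
        if self.jpy_per_usd <= 0:
            raise ParameterError(f"jpy_per_usd must be positive, got {self.jpy_per_usd}")
        for arm, probs in (
            ("sae_probs_rfa", self.sae_probs_rfa),
            ("sae_probs_cba", self.sae_probs_cba),
        ):
            unknown = set(probs) - set(ALL_COMPLICATIONS)
            if unknown:
                raise ParameterError(f"{arm} has unknown complications: {sorted(unknown)}")
            for comp, v in probs.items():
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(
                        f"{arm}[{comp}] must be a probability in [0, 1], got {v}"
                    )
        needed = set(self.sae_probs_rfa) | set(self.sae_probs_cba)
        missing = needed - set(self.sae_costs)
        if missing:
            raise ParameterError(f"sae_costs missing complications: {sorted(missing)}")
        for comp, v in self.sae_costs.items():
            if comp not in ALL_COMPLICATIONS:
                raise ParameterError(f"sae_costs has unknown complication: {comp}")
            if v < 0:
                raise ParameterError(f"sae_costs[{comp}] must be non-negative, got {v}")
        for key, bounds in self.dsa_ranges.items():
            if key not in DSA_PARAMETERS:
                raise ParameterError(f"dsa_ranges has unknown parameter: {key}")
            low, high = bounds
            base = DSA_PARAMETERS[key].get(self)
            if not low <= base <= high:
                raise ParameterError(
                    f"dsa_ranges[{key}] = ({low}, {high}) does not bracket base value {base}"
                )


def effective_recurrence_after_reablation(p: ModelParams) -> float:
    """Recurrence probability after a repeat ablation.

    The repeat-procedure recurrence risk is the first-ablation risk scaled
    by the re-ablation relative risk, capped at 1 so sensitivity-analysis
    extremes cannot produce an invalid probability.
    """
    return min(1.0, p.p_recur_first * p.rr_recur_reablation)


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

_MAP_FIELDS = ("sae_probs_rfa", "sae_probs_cba", "sae_costs")


def _params_from_dict(raw: Mapping[str, object]) -> ModelParams:
    field_names = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(raw) - field_names
    if unknown:
        raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
    missing = field_names - set(raw) - {"dsa_ranges"}
    if missing:
        raise ParameterError(f"missing configuration keys: {sorted(missing)}")
    kwargs: dict[str, object] = {}
    for name in field_names:
        if name not in raw:
            continue
        value = raw[name]
        if name in _MAP_FIELDS:
            if not isinstance(value, Mapping):
                raise ParameterError(f"{name} must be a mapping")
            kwargs[name] = {str(k): float(v) for k, v in value.items()}
        elif name == "dsa_ranges":
            if not isinstance(value, Mapping):
                raise ParameterError("dsa_ranges must be a mapping")
            ranges: dict[str, tuple[float, float]] = {}
            for k, bounds in value.items():
                if not isinstance(bounds, (list, tuple)) or len(bounds) != 2:
                    raise ParameterError(f"dsa_ranges[{k}] must be a [low, high] pair")
                ranges[str(k)] = (float(bounds[0]), float(bounds[1]))
            kwargs[name] = ranges
        else:
            kwargs[name] = value
    return ModelParams(**kwargs)  # type: ignore[arg-type]


def loads_params(text: str) -> ModelParams:
    """Parse and validate a YAML configuration given as text."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterError("configuration must be a key: value mapping")
    return _params_from_dict(raw)


def load_params(path: str | Path) -> ModelParams:
    """Load and validate a YAML configuration file."""
    return loads_params(Path(path).read_text())


def default_params() -> ModelParams:
    """The bundled base-case configuration."""
    text = resources.files("ablacost.data").joinpath("default_params.yaml").read_text()
    return loads_params(text)


def dump_params(p: ModelParams) -> str:
    """Serialize parameters to YAML text; round-trips through load."""
    d = dataclasses.asdict(p)
    d["dsa_ranges"] = {k: [v[0], v[1]] for k, v in p.dsa_ranges.items()}
    return yaml.safe_dump(d, sort_keys=False)


# ---------------------------------------------------------------------------
# DSA parameter registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsaParameter:
    """Getter/setter pair mapping a DSA range key onto model fields.

    Shared rows (e.g. complication probabilities applying to both
    procedures) set every affected field together, mirroring how the
    published table prints them as a single row.
    """

    get: Callable[[ModelParams], float]
    set: Callable[[ModelParams, float], ModelParams]
    is_probability: bool = False


def _scalar(name: str, is_probability: bool = False) -> DsaParameter:
    return DsaParameter(
        get=lambda p: getattr(p, name),
        set=lambda p, v: replace(p, **{name: v}),
        is_probability=is_probability,
    )


def _sae_prob(comp: str, arms: tuple[str, ...]) -> DsaParameter:
    def get(p: ModelParams) -> float:
        return getattr(p, arms[0])[comp]

    def set_(p: ModelParams, v: float) -> ModelParams:
        updates = {}
        for arm in arms:
            m = dict(getattr(p, arm))
            m[comp] = v
            updates[arm] = m
        return replace(p, **updates)

    return DsaParameter(get=get, set=set_, is_probability=True)


def _sae_cost(comp: str) -> DsaParameter:
    def get(p: ModelParams) -> float:
        return p.sae_costs[comp]

    def set_(p: ModelParams, v: float) -> ModelParams:
        m = dict(p.sae_costs)
        m[comp] = v
        return replace(p, sae_costs=m)

    return DsaParameter(get=get, set=set_)


_BOTH = ("sae_probs_rfa", "sae_probs_cba")

DSA_PARAMETERS: dict[str, DsaParameter] = {
    "start_age": _scalar("start_age"),
    "male_fraction": _scalar("male_fraction", True),
    "p_recur_first": _scalar("p_recur_first", True),
    "rr_recur_reablation": _scalar("rr_recur_reablation"),
    "p_reablate_2nd": _scalar("p_reablate_2nd", True),
    "p_reablate_3rd": _scalar("p_reablate_3rd", True),
    "mix_2nd_rfa_after_rfa": _scalar("mix_2nd_rfa_after_rfa", True),
    "mix_2nd_rfa_after_cba": _scalar("mix_2nd_rfa_after_cba", True),
    "mix_3rd_rfa_after_rfa": _scalar("mix_3rd_rfa_after_rfa", True),
    "mix_3rd_rfa_after_cba": _scalar("mix_3rd_rfa_after_cba", True),
    "sae_prob_esophageal_injury": _sae_prob("esophageal_injury", _BOTH),
    "sae_prob_cardiac_tamponade_rfa": _sae_prob("cardiac_tamponade", ("sae_probs_rfa",)),
    "sae_prob_cardiac_tamponade_cba": _sae_prob("cardiac_tamponade", ("sae_probs_cba",)),
    "sae_prob_pv_stenosis": _sae_prob("pv_stenosis", _BOTH),
    "sae_prob_phrenic_nerve_palsy_cba": _sae_prob(
        "phrenic_nerve_palsy", ("sae_probs_cba",)
    ),
    "sae_prob_vascular": _sae_prob("vascular", _BOTH),
    "sae_prob_groin": _sae_prob("groin", _BOTH),
    "p_is_tree": _scalar("p_is_tree", True),
    "p_death_tree": _scalar("p_death_tree", True),
    "p_recur_markov_y12": _scalar("p_recur_markov_y12", True),
    "p_recur_markov_later": _scalar("p_recur_markov_later", True),
    "p_is_markov": _scalar("p_is_markov", True),
    "p_is_death_28d": _scalar("p_is_death_28d", True),
    "p_is_death_1y_survivors": _scalar("p_is_death_1y_survivors", True),
    "p_death_post_is": _scalar("p_death_post_is", True),
    "cost_proc_rfa": _scalar("cost_proc_rfa"),
    "cost_proc_cba": _scalar("cost_proc_cba"),
    "sae_cost_esophageal_injury": _sae_cost("esophageal_injury"),
    "sae_cost_cardiac_tamponade": _sae_cost("cardiac_tamponade"),
    "sae_cost_pv_stenosis": _sae_cost("pv_stenosis"),
    "sae_cost_phrenic_nerve_palsy": _sae_cost("phrenic_nerve_palsy"),
    "sae_cost_vascular": _sae_cost("vascular"),
    "sae_cost_groin": _sae_cost("groin"),
    "cost_is_nonfatal": _scalar("cost_is_nonfatal"),
    "cost_is_fatal": _scalar("cost_is_fatal"),
    "cost_state_af_pos": _scalar("cost_state_af_pos"),
    "cost_state_af_neg": _scalar("cost_state_af_neg"),
    "cost_state_post_is": _scalar("cost_state_post_is"),
    "discount_rate": _scalar("discount_rate"),
}


def dsa_base_value(p: ModelParams, key: str) -> float:
    """Base-case value of the parameter behind a DSA range key."""
    try:
        return DSA_PARAMETERS[key].get(p)
    except KeyError:
        raise ParameterError(f"unknown DSA parameter: {key}") from None


def apply_dsa_value(p: ModelParams, key: str, value: float) -> ModelParams:
    """Return a copy of the parameters with one DSA parameter set.

    Probability-typed parameters are clipped into [0, 1] with a warning,
    so printed sensitivity bounds can never produce an invalid cohort.
    """
    try:
        handle = DSA_PARAMETERS[key]
    except KeyError:
        raise ParameterError(f"unknown DSA parameter: {key}") from None
    if handle.is_probability and not 0.0 <= value <= 1.0:
        clipped = min(1.0, max(0.0, value))
        logger.warning("DSA value %s for %s clipped to %s", value, key, clipped)
        value = clipped
    if key in p.dsa_ranges:
        low, high = p.dsa_ranges[key]
        if not low <= value <= high:
            # Deliberate override outside the printed range: the range no
            # longer brackets the new base value, so drop it.
            ranges = {k: v for k, v in p.dsa_ranges.items() if k != key}
            p = replace(p, dsa_ranges=ranges)
    return handle.set(p, value)


def params_table(p: ModelParams) -> pd.DataFrame:
    """Flat parameter table (one row per input) including DSA bounds."""
    rows = []
    for key, handle in DSA_PARAMETERS.items():
        low, high = p.dsa_ranges.get(key, (float("nan"), float("nan")))
        rows.append(
            {"parameter": key, "value": handle.get(p), "dsa_low": low, "dsa_high": high}
        )
    # Inputs not varied in the DSA
    rows.append(
        {
            "parameter": "jpy_per_usd",
            "value": p.jpy_per_usd,
            "dsa_low": float("nan"),
            "dsa_high": float("nan"),
        }
    )
    return pd.DataFrame(rows)
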