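"""Two-year decision-tree model of up to three ablation procedures.

Patients enter with a first ablation (RFA or CBA by strategy).  Those
with recurrent AF may receive a second ablation at 6 months and, after a
further recurrence, a third at 18 months; repeat procedures are a
technology mix observed in claims data (overwhelmingly RFA regardless of
the index procedure).  Each procedure carries serious-adverse-event,
ischemic-stroke and death risks.  The tree emits discounted intervention
and complication costs, tree-phase stroke costs, and the cohort
distribution handed to the lifetime Markov model.

Discounting convention: the procedures at 0 and 6 months fall in the
first model year and are undiscounted; the 18-month procedure is
discounted by one year.  Expected repeat-procedure counts use the branch
probabilities alone (no mortality attrition between stages), matching
the accounting of the published model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParams, effective_recurrence_after_reablation

__all__ = [
    "RFA",
    "CBA",
    "Strategy",
    "TreeOutcome",
    "strategy_from_params",
    "procedure_cost_mix",
    "per_procedure_sae_cost",
    "stage_probabilities",
    "run_tree",
]

RFA = "RFA"
CBA = "CBA"


@dataclass(frozen=True)
class Strategy:
    """An index-procedure arm and its repeat-procedure technology mix.

    ``mix2_rfa`` is the probability that a second ablation is RFA given
    this arm's index procedure; the third-procedure mix is conditioned on
    the second procedure's type and shared between arms.
    """

    name: str  # "RFA_first" or "CBA_first"
    first_proc: str
    mix2_rfa: float
    mix3_rfa_after_rfa: float
    mix3_rfa_after_cba: float

    def __post_init__(self) -> None:
        for v in (self.mix2_rfa, self.mix3_rfa_after_rfa, self.mix3_rfa_after_cba):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: mix proportions must lie in [0, 1]")

    def stage_rfa_share(self, stage: int) -> float:
        """Probability the stage's procedure is RFA."""
        if stage == 1:
            return 1.0 if self.first_proc == RFA else 0.0
        if stage == 2:
            return self.mix2_rfa
        if stage == 3:
            # Two-step mix: second-procedure type propagated through the
            # third-procedure proportions.
            return (
                self.mix2_rfa * self.mix3_rfa_after_rfa
                + (1.0 - self.mix2_rfa) * self.mix3_rfa_after_cba
            )
        raise ValueError(f"invalid stage {stage}")


def strategy_from_params(p: ModelParams, first_proc: str) -> Strategy:
    if first_proc not in (RFA, CBA):
        raise ValueError(f"first_proc must be {RFA} or {CBA}, got {first_proc}")
    mix2 = p.mix_2nd_rfa_after_rfa if first_proc == RFA else p.mix_2nd_rfa_after_cba
    return Strategy(
        name=f"{first_proc}_first",
        first_proc=first_proc,
        mix2_rfa=mix2,
        mix3_rfa_after_rfa=p.mix_3rd_rfa_after_rfa,
        mix3_rfa_after_cba=p.mix_3rd_rfa_after_cba,
    )


@dataclass(frozen=True)
class TreeOutcome:
    """Discounted tree-phase costs and the Markov entry state."""

    strategy: str
    cost_intervention: float
    cost_sae: float
    cost_is_fatal: float
    cost_is_nonfatal: float
    entry_distribution: dict[str, float]  # af_neg, af_pos, is, dead
    entry_year: dict[int, float]  # model year -> cohort fraction
    procedures_expected: dict[int, float]  # stage -> expected procedures

    def __post_init__(self) -> None:
        total = sum(self.entry_distribution.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"entry distribution sums to {total}, not 1")
        if min(self.entry_distribution.values()) < -1e-15:
            raise ValueError("entry distribution has a negative fraction")
        for v in (
            self.cost_intervention,
            self.cost_sae,
            self.cost_is_fatal,
            self.cost_is_nonfatal,
        ):
            if v < 0:
                raise ValueError("tree costs must be non-negative")


def procedure_cost_mix(stage: int, strategy: Strategy, p: ModelParams) -> float:
    """Expected unit cost of the stage's procedure under the claims mix."""
    share_rfa = strategy.stage_rfa_share(stage)
    return share_rfa * p.cost_proc_rfa + (1.0 - share_rfa) * p.cost_proc_cba


def per_procedure_sae_cost(proc: str, p: ModelParams) -> float:
    """Expected complication cost of one procedure.

    Sum over the six complication types of probability x unit cost.
    Stroke and procedural death are accounted in their own buckets, not
    here.
    """
    if proc == RFA:
        probs = p.sae_probs_rfa
    elif proc == CBA:
        probs = p.sae_probs_cba
    else:
        raise ValueError(f"unknown procedure {proc}")
    return sum(prob * p.sae_costs[comp] for comp, prob in probs.items())


def _stage_sae_cost(stage: int, strategy: Strategy, p: ModelParams) -> float:
    share_rfa = strategy.stage_rfa_share(stage)
    return share_rfa * per_procedure_sae_cost(RFA, p) + (
        1.0 - share_rfa
    ) * per_procedure_sae_cost(CBA, p)


def stage_probabilities(p: ModelParams) -> tuple[float, float]:
    """Probability of reaching the second and third procedure.

    Second: recurrence after the index ablation and acceptance of a
    repeat.  Third: a further (RR-scaled) recurrence after the second
    ablation and acceptance of the final repeat.
    """
    p_recur2 = effective_recurrence_after_reablation(p)
    p_stage2 = p.p_recur_first * p.p_reablate_2nd
    p_stage3 = p_stage2 * p_recur2 * p.p_reablate_3rd
    return p_stage2, p_stage3


def run_tree(strategy: Strategy, p: ModelParams) -> TreeOutcome:
    """Evaluate the decision tree for one strategy.

    Returns discounted expected intervention and complication costs, the
    tree-phase fatal/non-fatal stroke costs, and the cohort distribution
    over health states at Markov entry (stroke survivors enter the IS
    state regardless of AF symptoms; patients reaching a third ablation
    enter the Markov model a year later than the rest).
    """
    p_stage2, p_stage3 = stage_probabilities(p)
    p_stages = (1.0, p_stage2, p_stage3)
    disc = (1.0, 1.0, 1.0 / (1.0 + p.discount_rate))

    cost_intervention = 0.0
    cost_sae = 0.0
    is_events_disc = 0.0  # discounted expected stroke events
    for stage, (prob, d) in enumerate(zip(p_stages, disc), start=1):
        cost_intervention += prob * procedure_cost_mix(stage, strategy, p) * d
        cost_sae += prob * _stage_sae_cost(stage, strategy, p) * d
        is_events_disc += prob * p.p_is_tree * d

    cost_is_fatal = is_events_disc * p.p_is_death_28d * p.cost_is_fatal
    cost_is_nonfatal = is_events_disc * (1.0 - p.p_is_death_28d) * p.cost_is_nonfatal

    procs_expected = sum(p_stages)
    p_is_event = p.p_is_tree * procs_expected
    p_dead = p.p_death_tree * procs_expected + p_is_event * p.p_is_death_28d
    p_is_state = p_is_event * (1.0 - p.p_is_death_28d)

    # Unresolved recurrence at the end of the tree: declined repeats plus
    # recurrence after the final permitted ablation.
    p_recur2 = effective_recurrence_after_reablation(p)
    af_pos_raw = (
        p.p_recur_first * (1.0 - p.p_reablate_2nd)
        + p_stage2 * p_recur2 * (1.0 - p.p_reablate_3rd)
        + p_stage3 * p_recur2
    )
    survivors_non_is = 1.0 - p_dead - p_is_state
    af_pos = af_pos_raw * survivors_non_is
    af_neg = survivors_non_is - af_pos

    return TreeOutcome(
        strategy=strategy.name,
        cost_intervention=cost_intervention,
        cost_sae=cost_sae,
        cost_is_fatal=cost_is_fatal,
        cost_is_nonfatal=cost_is_nonfatal,
        entry_distribution={
            "af_neg": af_neg,
            "af_pos": af_pos,
            "is": p_is_state,
            "dead": p_dead,
        },
        entry_year={2: 1.0 - p_stage3, 3: p_stage3},
        procedures_expected={1: 1.0, 2: p_stage2, 3: p_stage3},
    )
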