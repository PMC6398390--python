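"""Cost accounting for single-stage vs. two-stage screening policies.

A two-stage triage design runs every subject through a cheap first-stage
assay (e.g. a plasma protein panel); subjects on which the first-stage
classifier abstains are referred to an expensive second-stage assay
(e.g. CSF biomarkers).  Costs are abstract units per screening performed:
a two-stage policy costs n*c1 + n_referred*c2, against n*c2 for running
the expensive assay on everyone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CostPolicy", "StageOutcome", "PolicyResult", "evaluate_policy", "compare_policies"]


class IncompletePolicyError(ValueError):
    """A referred sample has no stage-2 decision."""


@dataclass
class CostPolicy:
    """Two-stage screening cost structure with reject->refer rule."""

    stage_names: tuple[str, str] = ("plasma", "CSF")
    unit_costs: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        if len(self.stage_names) != 2 or len(self.unit_costs) != 2:
            raise ValueError("exactly two stages are supported")
        if any(c < 0 for c in self.unit_costs):
            raise ValueError("unit costs must be nonnegative")


@dataclass
class StageOutcome:
    """Per-sample screening record: which stages ran, final decision, cost."""

    stage1_decision: int
    stage2_decision: int | None  # None when not screened at stage 2
    final_decision: int
    cost: float


@dataclass
class PolicyResult:
    name: str
    total_cost: float
    n_correct: int
    n_screened_per_stage: tuple[int, int]
    n_stage2_rejects: int
    outcomes: list[StageOutcome] = field(repr=False, default_factory=list)


def evaluate_policy(
    stage1_decisions,
    stage2_decisions,
    y,
    policy: CostPolicy,
    name: str = "two-stage",
) -> PolicyResult:
    """Evaluate a referral policy: stage-1 rejects are screened at stage 2.

    ``stage2_decisions`` must be defined (non-None) at least for stage-1
    rejects; pass None for a pure single-stage policy with no referral
    (any stage-1 reject then counts as not correct).  Stage-2 rejects, if
    the second model also abstains, count as not correct and are tallied
    separately.
    """
    s1 = np.asarray(stage1_decisions, dtype=int)
    yy = np.asarray(y, dtype=int)
    if s1.shape != yy.shape:
        raise ValueError("stage1_decisions and y must have equal length")
    c1, c2 = policy.unit_costs
    outcomes: list[StageOutcome] = []
    n_correct = 0
    n_stage2 = 0
    n_stage2_rejects = 0
    for i in range(s1.size):
        d1 = int(s1[i])
        if d1 != 0:
            final, d2, cost = d1, None, c1
        else:
            if stage2_decisions is None:
                final, d2, cost = 0, None, c1
            else:
                d2 = stage2_decisions[i]
                if d2 is None:
                    raise IncompletePolicyError(
                        f"sample {i} referred to stage 2 but has no stage-2 decision"
                    )
                d2 = int(d2)
                final, cost = d2, c1 + c2
                n_stage2 += 1
                if d2 == 0:
                    n_stage2_rejects += 1
        if final == int(yy[i]):
            n_correct += 1
        outcomes.append(StageOutcome(d1, d2, final, cost))
    total_cost = float(sum(o.cost for o in outcomes))
    return PolicyResult(
        name=name,
        total_cost=total_cost,
        n_correct=n_correct,
        n_screened_per_stage=(int(s1.size), n_stage2),
        n_stage2_rejects=n_stage2_rejects,
        outcomes=outcomes,
    )


def compare_policies(results: list[PolicyResult]) -> pd.DataFrame:
    """Rank policies by descending correct count, then ascending total cost.

    Ties keep input order (stable sort).
    """
    df = pd.DataFrame(
        {
            "policy": [r.name for r in results],
            "n_correct": [r.n_correct for r in results],
            "total_cost": [r.total_cost for r in results],
            "n_stage1": [r.n_screened_per_stage[0] for r in results],
            "n_stage2": [r.n_screened_per_stage[1] for r in results],
            "n_stage2_rejects": [r.n_stage2_rejects for r in results],
        }
    )
    return df.sort_values(
        ["n_correct", "total_cost"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
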