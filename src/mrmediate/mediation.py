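"""Two-step mediation on Mendelian-randomization estimates.

Given the total exposure→outcome effect β0, the exposure→mediator effect β1
and the mediator→outcome effect β2 (each from its own two-sample MR), the
mediated effect is the product β3 = β1·β2 and the mediated proportion β3/β0.
Delta-method uncertainty for both is provided as optional output; values
with inconsistent signs or proportions above one are flagged, never
truncated, since they signal model inconsistency worth surfacing.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import MRResult

__all__ = ["MediationResult", "mediate", "mediation_screen"]

_Z95 = stats.norm.ppf(0.975)


@dataclasses.dataclass(frozen=True)
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    beta0: float            # total exposure→outcome effect
    beta1: float            # exposure→mediator
    beta2: float            # mediator→outcome
    beta3: float            # mediated effect β1·β2
    proportion: float       # β3/β0
    se_beta3: float
    prop_se: float
    prop_ci: tuple[float, float]
    flags: tuple[str, ...]

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proportion_pct"] = self.proportion_pct
        return d


def mediate(
    beta0: MRResult,
    beta1: MRResult,
    beta2: MRResult,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Product-method mediation from three MR results.

    ``se_beta3 = sqrt(β1²·se2² + β2²·se1²)`` and the proportion CI use the
    first-order delta method (covariances between the three estimates are
    taken as zero — they come from non-overlapping instrument sets).
    Raises if the total effect is zero, where the proportion is undefined.
    """
    b0, b1, b2 = beta0.beta, beta1.beta, beta2.beta
    if b0 == 0.0:
        raise ValueError("mediation undefined: total effect beta0 = 0")
    b3 = b1 * b2
    prop = b3 / b0
    se3 = math.sqrt(b1**2 * beta2.se**2 + b2**2 * beta1.se**2)
    # delta method on (b1*b2)/b0
    var_prop = (se3**2 / b0**2) + (b3**2 / b0**4) * beta0.se**2
    prop_se = math.sqrt(var_prop)
    ci = (prop - _Z95 * prop_se, prop + _Z95 * prop_se)
    flags: list[str] = []
    if b3 != 0.0 and np.sign(b3) != np.sign(b0):
        flags.append("inconsistent_sign")
    if abs(prop) > 1.0:
        flags.append("proportion_gt_1")
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        beta0=b0, beta1=b1, beta2=b2, beta3=b3, proportion=prop,
        se_beta3=se3, prop_se=prop_se, prop_ci=ci, flags=tuple(flags),
    )


def mediation_screen(
    total: MRResult,
    candidates: Sequence[tuple[str, MRResult, MRResult]],
    leg_alpha: float = 0.05,
    exposure: str = "exposure",
    outcome: str = "outcome",
) -> list[MediationResult]:
    """Screen candidate mediators of an established exposure→outcome effect.

    ``candidates`` are ``(mediator_name, exposure→mediator result,
    mediator→outcome result)`` triples; only mediators where both legs reach
    ``leg_alpha`` survive. The caller is responsible for having established
    the exposure→outcome effect and ruled out reverse causation (see
    :func:`mrmediate.workflow.bidirectional_report`). Results are sorted by
    absolute mediated proportion, largest first.
    """
    survivors = []
    for name, leg1, leg2 in candidates:
        if leg1.pval < leg_alpha and leg2.pval < leg_alpha:
            survivors.append(mediate(total, leg1, leg2,
                                     exposure=exposure, mediator=name, outcome=outcome))
    return sorted(survivors, key=lambda m: abs(m.proportion), reverse=True)
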