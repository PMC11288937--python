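"""Two-step mediation decomposition with delta-method confidence intervals.

With Z the total log-odds effect of the exposure on the outcome, X the
exposure→mediator effect and Y the mediator→outcome effect (each from its
own two-sample MR on a non-overlapping GWAS sample), the indirect effect
is XY, the direct effect Z' = Z − XY, and the proportion mediated XY/Z.

The three estimates are treated as independent (non-overlapping samples),
so the first-order (delta-method) variances carry no covariance terms:

    var(XY)   = Y²·var(X) + X²·var(Y)
    var(XY/Z) = (Y/Z)²·var(X) + (X/Z)²·var(Y) + (XY/Z²)²·var(Z)

95% intervals are estimate ± 1.959964·SE on the same scale (no logit
transform for the proportion, which may legitimately fall outside [0,1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import UndefinedProportionError
from .estimators import MRResult, Z95


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of a total effect into direct and mediated components."""

    total_Z: float
    se_total: float
    beta_X: float
    se_X: float
    beta_Y: float
    se_Y: float
    indirect_XY: float
    direct_Zprime: float
    proportion: float
    se_indirect: float
    ci_indirect: tuple[float, float]
    se_proportion: float
    ci_proportion: tuple[float, float]
    label: str | None = None

    @property
    def indirect_or(self) -> float:
        """Indirect effect on the odds-ratio scale, exp(XY)."""
        return math.exp(self.indirect_XY)

    def to_row(self) -> dict:
        return {
            "result_type": "mediation", "label": self.label or "",
            "total_Z": self.total_Z, "se_total": self.se_total,
            "beta_X": self.beta_X, "se_X": self.se_X,
            "beta_Y": self.beta_Y, "se_Y": self.se_Y,
            "indirect_XY": self.indirect_XY, "se_indirect": self.se_indirect,
            "indirect_ci_low": self.ci_indirect[0], "indirect_ci_high": self.ci_indirect[1],
            "indirect_or": self.indirect_or, "direct_Zprime": self.direct_Zprime,
            "proportion": self.proportion, "se_proportion": self.se_proportion,
            "proportion_ci_low": self.ci_proportion[0],
            "proportion_ci_high": self.ci_proportion[1],
        }


def decompose(total: MRResult, step1: MRResult, step2: MRResult,
              label: str | None = None) -> MediationResult:
    """Decompose the total effect Z into indirect (X·Y) and direct (Z − X·Y) parts.

    ``total``, ``step1`` and ``step2`` are log-scale MR estimates of,
    respectively, exposure→outcome (Z), exposure→mediator (X) and
    mediator→outcome (Y).  Raises when Z = 0 (proportion undefined).
    """
    z, sz = total.beta, total.se
    x, sx = step1.beta, step1.se
    y, sy = step2.beta, step2.se
    if z == 0:
        raise UndefinedProportionError("total effect is zero; proportion undefined")
    indirect = x * y
    direct = z - indirect
    prop = indirect / z
    var_ind = y * y * sx * sx + x * x * sy * sy
    se_ind = math.sqrt(var_ind)
    var_prop = ((y / z) ** 2 * sx * sx + (x / z) ** 2 * sy * sy
                + (indirect / z**2) ** 2 * sz * sz)
    se_prop = math.sqrt(var_prop)
    return MediationResult(
        total_Z=z, se_total=sz, beta_X=x, se_X=sx, beta_Y=y, se_Y=sy,
        indirect_XY=indirect, direct_Zprime=direct, proportion=prop,
        se_indirect=se_ind,
        ci_indirect=(indirect - Z95 * se_ind, indirect + Z95 * se_ind),
        se_proportion=se_prop,
        ci_proportion=(prop - Z95 * se_prop, prop + Z95 * se_prop),
        label=label,
    )


def direction_compatible(step1: MRResult, step2: MRResult, total: MRResult) -> bool:
    """True when the indirect path pushes the same way as the total effect.

    The rule sign(X·Y) = sign(Z) reproduces the conventional exclusion of
    mediators whose two-step product opposes the total effect (e.g. a
    protective exposure→mediator arm under a risk-increasing total effect).
    """
    return (step1.beta * step2.beta) * total.beta > 0


class MediationModel:
    """Mediation model over three independent MR fits.

    Parameters are log-scale :class:`~mrmediate.estimators.MRResult`
    objects for the total (Z), exposure→mediator (X) and mediator→outcome
    (Y) effects; :meth:`fit` returns :class:`MediationResults`.
    """

    def __init__(self, total: MRResult, step1: MRResult, step2: MRResult,
                 label: str | None = None):
        self.total = total
        self.step1 = step1
        self.step2 = step2
        self.label = label

    @classmethod
    def from_odds_ratios(cls, total_or: tuple[float, float, float],
                         step1_or: tuple[float, float, float],
                         step2_or: tuple[float, float, float],
                         label: str | None = None) -> "MediationModel":
        """Build from printed (OR, ci_low, ci_high) triples."""
        return cls(MRResult.from_odds_ratio(*total_or),
                   MRResult.from_odds_ratio(*step1_or),
                   MRResult.from_odds_ratio(*step2_or), label=label)

    def fit(self) -> "MediationResults":
        return MediationResults(self, decompose(self.total, self.step1, self.step2,
                                                label=self.label))

    def direction_compatible(self) -> bool:
        return direction_compatible(self.step1, self.step2, self.total)


class MediationResults:
    """Fitted mediation decomposition with a text summary."""

    def __init__(self, model: MediationModel, result: MediationResult):
        self.model = model
        self.result = result
        r = result
        self.proportion = r.proportion
        self.indirect_XY = r.indirect_XY
        self.direct_Zprime = r.direct_Zprime
        self.se_indirect = r.se_indirect
        self.ci_indirect = r.ci_indirect
        self.se_proportion = r.se_proportion
        self.ci_proportion = r.ci_proportion
        self.indirect_or = r.indirect_or

    def summary(self) -> str:
        r = self.result
        lo_i, hi_i = r.ci_indirect
        lo_p, hi_p = r.ci_proportion
        lines = [
            "Two-step MR mediation analysis" + (f" — {r.label}" if r.label else ""),
            "",
            f"Total effect        Z  = {r.total_Z:.4f} (se {r.se_total:.4f}, "
            f"OR {math.exp(r.total_Z):.3f})",
            f"Exposure->mediator  X  = {r.beta_X:.4f} (se {r.se_X:.4f})",
            f"Mediator->outcome   Y  = {r.beta_Y:.4f} (se {r.se_Y:.4f})",
            f"Indirect effect     XY = {r.indirect_XY:.4f} "
            f"[{lo_i:.4f}, {hi_i:.4f}], OR {r.indirect_or:.3f}",
            f"Direct effect       Z' = {r.direct_Zprime:.4f}",
            f"Proportion mediated    = {100 * r.proportion:.3f}% "
            f"[{100 * lo_p:.3f}%, {100 * hi_p:.3f}%]",
        ]
        return "\n".join(lines)
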