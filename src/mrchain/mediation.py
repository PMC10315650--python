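"""Two-step mediation decomposition of an MR effect.

For a causal chain exposure X -> mediator Y -> outcome Z, the indirect
effect of X on Z through Y is the product of the two step estimates,
beta_XY·beta_YZ, and the total effect is beta_XZ + beta_XY·beta_YZ where
beta_XZ is the direct X->Z estimate. Because the three legs come from three
non-overlapping GWAS cohorts, the step estimates are treated as independent
and the indirect effect's standard error follows from the first-order
(Sobel) delta method:

    se² = beta_XY²·se_YZ² + beta_YZ²·se_XY²

with an optional second-order term se_XY²·se_YZ². All betas are log odds
ratios; the indirect effect is also reported as an OR with a 95% CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .estimators import MrResult, Z95

log = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Direct / indirect / total decomposition with a delta-method CI."""

    beta_xz: float
    beta_xy: float
    se_xy: float
    beta_yz: float
    se_yz: float
    indirect: float
    se_indirect: float
    total: float
    or_indirect: float
    ci_low: float
    ci_high: float
    pvalue: float
    proportion_mediated: float | None

    def to_dict(self) -> dict:
        return {
            "beta_xz": self.beta_xz,
            "beta_xy": self.beta_xy,
            "se_xy": self.se_xy,
            "beta_yz": self.beta_yz,
            "se_yz": self.se_yz,
            "indirect": self.indirect,
            "se_indirect": self.se_indirect,
            "total": self.total,
            "or_indirect": self.or_indirect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "proportion_mediated": self.proportion_mediated,
        }


def two_step_mediation(
    step1: MrResult,
    step2: MrResult,
    direct: MrResult,
    second_order: bool = False,
) -> MediationResult:
    """Combine the three MR legs into a mediation decomposition.

    Parameters
    ----------
    step1
        Exposure -> mediator estimate (beta_XY).
    step2
        Mediator -> outcome estimate (beta_YZ).
    direct
        Exposure -> outcome estimate (beta_XZ).
    second_order
        Include the se_XY²·se_YZ² product term in the delta-method variance
        (off by default; the first-order Sobel form is standard).

    The proportion mediated (indirect/total) is reported only when the
    indirect and total effects share a sign; otherwise it is suppressed with
    a warning, since a ratio of opposing effects is not interpretable.
    """
    for name, res in (("step1", step1), ("step2", step2), ("direct", direct)):
        if res is None:
            raise ValidationError(f"two_step_mediation: missing {name} estimate")
    bxy, sxy = step1.beta, step1.se
    byz, syz = step2.beta, step2.se
    bxz = direct.beta
    indirect = bxy * byz
    var = bxy**2 * syz**2 + byz**2 * sxy**2
    if second_order:
        var += sxy**2 * syz**2
    se = math.sqrt(var)
    total = bxz + indirect
    ci_low = math.exp(indirect - Z95 * se)
    ci_high = math.exp(indirect + Z95 * se)
    pvalue = float(2.0 * stats.norm.sf(abs(indirect) / se)) if se > 0 else float("nan")
    if total != 0.0 and indirect * total > 0:
        proportion = indirect / total
    else:
        proportion = None
        if indirect != 0.0:
            log.warning(
                "proportion mediated suppressed: indirect (%.4g) and total (%.4g) "
                "effects have opposite signs",
                indirect,
                total,
            )
    return MediationResult(
        beta_xz=bxz,
        beta_xy=bxy,
        se_xy=sxy,
        beta_yz=byz,
        se_yz=syz,
        indirect=indirect,
        se_indirect=se,
        total=total,
        or_indirect=math.exp(indirect),
        ci_low=ci_low,
        ci_high=ci_high,
        pvalue=pvalue,
        proportion_mediated=proportion,
    )
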