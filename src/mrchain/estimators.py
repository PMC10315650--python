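"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized per-variant summary statistics. The
building block is the per-variant Wald ratio beta_out/beta_exp with
first-order delta SE se_out/|beta_exp|. The estimators differ in how they
pool ratios and in which instrument-validity violations they tolerate:

* IVW (inverse-variance weighted): the efficient pooled estimate when all
  instruments are valid; the multiplicative random-effects variant inflates
  the SE by sqrt(max(1, Q/(J-1))) to absorb heterogeneity and is the primary
  mode here.
* MR-Egger: weighted regression with a free intercept; the intercept
  estimates the average directional pleiotropy and the slope remains
  consistent under the InSIDE assumption.
* Weighted median: consistent when at least half of the total weight comes
  from valid instruments.
* Maximum likelihood: joint normal model over per-variant true exposure
  effects and a single causal slope.

Results are reported as log-odds betas and as odds ratios with 95% CIs,
the convention for binary-trait GWAS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError, InsufficientInstrumentsError
from .harmonize import HarmonizedTable

log = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))

METHODS = ("ivw_fixed", "ivw_mre", "egger", "weighted_median", "max_likelihood")


@dataclass
class MrResult:
    """One estimator's causal estimate.

    ``beta`` is on the log-odds (or linear) scale of the outcome GWAS;
    ``or_value`` and the CI are its exponential.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
        }
        d.update(self.extras)
        return d


def wald_ratios(h: HarmonizedTable | pd.DataFrame) -> pd.DataFrame:
    """Per-variant Wald ratios with first-order SEs and IVW weights.

    Variants with ``beta_exp == 0`` (undefined ratio) are excluded with a
    warning.
    """
    t = h.table if isinstance(h, HarmonizedTable) else h
    nonzero = t["beta_exp"] != 0.0
    if (~nonzero).any():
        log.warning(
            "wald_ratios: excluding %d variant(s) with zero exposure beta",
            int((~nonzero).sum()),
        )
    t = t[nonzero]
    ratio = t["beta_out"] / t["beta_exp"]
    ratio_se = t["se_out"] / t["beta_exp"].abs()
    return pd.DataFrame(
        {
            "variant_id": t["variant_id"].to_numpy(),
            "ratio": ratio.to_numpy(),
            "ratio_se": ratio_se.to_numpy(),
            "weight": 1.0 / ratio_se.to_numpy() ** 2,
        }
    )


def _check_min(n: int, minimum: int, method: str) -> None:
    if n < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {minimum} instruments, got {n}"
        )


def ivw(
    r: pd.DataFrame,
    mode: str = "multiplicative_random_effects",
    dist: str = "normal",
) -> MrResult:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    ``mode='fixed'`` uses SE = sqrt(1/sum w); the default multiplicative
    random-effects mode scales it by sqrt(max(1, Q/(J-1))), never deflating
    below the fixed-effect SE. ``dist`` selects the normal (default) or
    t(J-1) reference for the p-value.
    """
    if mode not in ("fixed", "multiplicative_random_effects"):
        raise ValueError(f"unknown ivw mode {mode!r}")
    j = len(r)
    _check_min(j, 2, "ivw")
    w = r["weight"].to_numpy()
    ratio = r["ratio"].to_numpy()
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (ratio - beta) ** 2))
    df = j - 1
    q_p = float(stats.chi2.sf(q, df))
    if mode == "fixed":
        se = se_fixed
    else:
        se = se_fixed * math.sqrt(max(1.0, q / df))
    z = abs(beta) / se
    if dist == "t":
        pvalue = float(2.0 * stats.t.sf(z, df))
    else:
        pvalue = float(2.0 * stats.norm.sf(z))
    method = "ivw_fixed" if mode == "fixed" else "ivw_mre"
    return MrResult(
        method=method,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n_snps=j,
        extras={"q": q, "q_df": df, "q_pvalue": q_p, "se_fixed": se_fixed},
    )


def egger(h: HarmonizedTable | pd.DataFrame) -> MrResult:
    """MR-Egger regression: beta_out on beta_exp with a free intercept,
    weights 1/se_out².

    Exposure effects are orientation-fixed so every beta_exp >= 0 (flipping
    the outcome beta together), which makes the intercept interpretable as
    the average directional pleiotropic effect. The residual variance is
    floored at 1 (multiplicative random effects); p-values use a t(J-2)
    reference, standard for this estimator.
    """
    t = h.table if isinstance(h, HarmonizedTable) else h
    j = len(t)
    _check_min(j, 3, "egger")
    sign = np.where(t["beta_exp"].to_numpy() < 0, -1.0, 1.0)
    bx = t["beta_exp"].to_numpy() * sign
    by = t["beta_out"].to_numpy() * sign
    sy = t["se_out"].to_numpy()
    w = 1.0 / sy**2

    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:  # collinear design
        raise EstimationError(f"egger design matrix is singular: {exc}") from exc
    coef = cov_unscaled @ (xtw @ by)
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2)) if j > 2 else 0.0
    # Floor the dispersion at 1 so the SE never undercuts the weighting model.
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov_unscaled) * scale)
    df = j - 2
    slope, slope_se = float(coef[1]), float(ses[1])
    intercept, intercept_se = float(coef[0]), float(ses[0])
    pvalue = float(2.0 * stats.t.sf(abs(slope) / slope_se, df)) if slope_se > 0 else float("nan")
    intercept_p = (
        float(2.0 * stats.t.sf(abs(intercept) / intercept_se, df))
        if intercept_se > 0
        else float("nan")
    )
    return MrResult(
        method="egger",
        beta=slope,
        se=slope_se,
        pvalue=pvalue,
        n_snps=j,
        extras={
            "intercept": intercept,
            "intercept_se": intercept_se,
            "intercept_pvalue": intercept_p,
            "residual_dispersion": sigma2,
        },
    )


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    w = weight[order]
    cw = np.cumsum(w)
    s = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(0.5, s, r))


def weighted_median(
    r: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MrResult:
    """Weighted-median estimator of the causal effect.

    The estimate is the inverse-variance-weighted median of the Wald ratios
    (linear interpolation of the weighted empirical CDF at probability 0.5);
    it is consistent when valid instruments carry at least half the total
    weight. The SE comes from a parametric bootstrap resampling each ratio
    from Normal(ratio_j, ratio_se_j²).
    """
    j = len(r)
    _check_min(j, 3, "weighted_median")
    ratio = r["ratio"].to_numpy()
    ratio_se = r["ratio_se"].to_numpy()
    weight = r["weight"].to_numpy()
    beta = _weighted_median(ratio, weight)
    rng = np.random.default_rng(seed)
    sims = ratio + ratio_se * rng.standard_normal((n_boot, j))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = _weighted_median(sims[i], weight)
    se = float(np.std(boot, ddof=1))
    pvalue = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return MrResult(
        method="weighted_median",
        beta=beta,
        se=se,
        pvalue=pvalue,
        n_snps=j,
        extras={"n_boot": n_boot, "seed": seed},
    )


def max_likelihood(h: HarmonizedTable | pd.DataFrame) -> MrResult:
    """Maximum-likelihood estimator under the joint normal measurement model.

    Observed effects are modelled as beta_exp_j ~ N(gamma_j, se_exp_j²) and
    beta_out_j ~ N(beta·gamma_j, se_out_j²) with a single causal slope beta.
    The per-variant nuisance effects gamma_j are profiled out analytically,
    leaving a one-dimensional optimization; the SE comes from the observed
    information with the gamma block eliminated by Schur complement.
    """
    t = h.table if isinstance(h, HarmonizedTable) else h
    j = len(t)
    _check_min(j, 1, "max_likelihood")
    bx = t["beta_exp"].to_numpy()
    by = t["beta_out"].to_numpy()
    sx = t["se_exp"].to_numpy()
    sy = t["se_out"].to_numpy()

    def neg_profile(b: float) -> float:
        return 0.5 * float(np.sum((by - b * bx) ** 2 / (sy**2 + b**2 * sx**2)))

    w0 = bx**2 / sy**2
    b0 = float(np.sum(w0 * (by / bx)) / np.sum(w0)) if np.all(bx != 0) else 0.0
    try:
        res = optimize.minimize_scalar(
            neg_profile, bracket=(b0 - 1.0, b0, b0 + 1.0), method="brent",
            options={"xtol": 1e-12},
        )
    except Exception:
        res = optimize.minimize_scalar(neg_profile, method="golden")
    if not np.isfinite(res.x):
        raise EstimationError(
            f"max_likelihood failed to converge (fun={res.fun!r}, x={res.x!r})"
        )
    beta = float(res.x)
    gamma = (bx / sx**2 + beta * by / sy**2) / (1.0 / sx**2 + beta**2 / sy**2)
    i_bb = float(np.sum(gamma**2 / sy**2))
    i_bg = (2.0 * beta * gamma - by) / sy**2
    i_gg = 1.0 / sx**2 + beta**2 / sy**2
    info = i_bb - float(np.sum(i_bg**2 / i_gg))
    if info <= 0:
        raise EstimationError(f"max_likelihood: non-positive observed information {info}")
    se = float(1.0 / math.sqrt(info))
    pvalue = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MrResult(
        method="max_likelihood",
        beta=beta,
        se=se,
        pvalue=pvalue,
        n_snps=j,
        extras={"neg_loglik": float(res.fun)},
    )


def all_estimators(
    h: HarmonizedTable | pd.DataFrame,
    ivw_mode: str = "multiplicative_random_effects",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MrResult]:
    """Run the full estimator battery; returns a dict keyed by method name
    (both IVW modes, Egger, weighted median, maximum likelihood)."""
    r = wald_ratios(h)
    out = {
        "ivw_fixed": ivw(r, mode="fixed"),
        "ivw_mre": ivw(r, mode="multiplicative_random_effects"),
        "weighted_median": weighted_median(r, n_boot=n_boot, seed=seed),
        "egger": egger(h),
        "max_likelihood": max_likelihood(h),
    }
    assert out["ivw_mre"].method == "ivw_mre"
    return out
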