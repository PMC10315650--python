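"""Sensitivity analyses for two-sample MR estimates.

Battery: Cochran's Q heterogeneity test across Wald ratios; MR-PRESSO
(global residual test, per-variant outlier test, distortion test, and the
corrected IVW estimate after outlier removal); leave-one-out re-estimation;
the Steiger directionality test; and plot-ready scatter/forest/funnel tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError, ValidationError
from .estimators import MrResult, Z95, ivw, wald_ratios
from .harmonize import HarmonizedTable
from .instruments import variance_explained

log = logging.getLogger(__name__)


def cochran_q(r: pd.DataFrame, beta_ivw: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic of the Wald ratios around the IVW
    estimate; chi-square with J-1 df under homogeneity."""
    j = len(r)
    if j < 2:
        raise InsufficientInstrumentsError("cochran_q needs at least 2 instruments")
    w = r["weight"].to_numpy()
    ratio = r["ratio"].to_numpy()
    q = float(np.sum(w * (ratio - beta_ivw) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class PressoResult:
    """MR-PRESSO output: global test, per-variant outlier flags, distortion
    test and the outlier-corrected IVW estimate (absent when nothing was
    flagged)."""

    global_rss: float
    global_p: float
    per_snp_p: pd.Series
    outlier_ids: list[str]
    distortion_p: float | None
    corrected: MrResult | None
    n_sim: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "global_rss": self.global_rss,
            "global_p": self.global_p,
            "outlier_ids": list(self.outlier_ids),
            "distortion_p": self.distortion_p,
            "corrected": self.corrected.to_dict() if self.corrected else None,
            "n_sim": self.n_sim,
        }


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out slopes of the no-intercept WLS fit of by on bx
    (equivalently leave-one-out fixed-effect IVW), vectorized."""
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx**2) - w * bx**2
    return num / den


def presso(
    h: HarmonizedTable | pd.DataFrame,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    ivw_mode: str = "multiplicative_random_effects",
) -> PressoResult:
    """MR-PRESSO outlier detection.

    The observed statistic is the weighted residual sum of squares of each
    variant's outcome effect against its leave-one-out IVW prediction,
    RSS = sum_j w_j (beta_out_j - beta_loo(-j)·beta_exp_j)² with
    w_j = 1/se_out_j². Its null distribution is built from ``n_sim``
    parametric replicates drawing beta_exp*_j ~ N(beta_exp_j, se_exp_j²) and
    beta_out*_j ~ N(beta_loo(-j)·beta_exp_j, se_out_j²), re-deriving the
    leave-one-out slopes within every replicate (so the simulated residuals
    carry the same exposure-noise component beta²·se_exp² as the observed
    ones). The per-variant outlier test
    compares each observed squared residual with its own simulated null and
    flags variants at the Bonferroni-adjusted level ``alpha/J``. When
    outliers are flagged, the corrected estimate is IVW on the retained set,
    and the distortion test compares the resulting shift in the estimate
    with a null of 1000 random same-size removals.
    """
    t = h.table if isinstance(h, HarmonizedTable) else h
    j = len(t)
    if j < 4:
        raise InsufficientInstrumentsError(f"presso needs at least 4 instruments, got {j}")
    bx = t["beta_exp"].to_numpy()
    by = t["beta_out"].to_numpy()
    sx = t["se_exp"].to_numpy()
    sy = t["se_out"].to_numpy()
    w = 1.0 / sy**2
    ids = t["variant_id"].to_numpy()

    slopes = _loo_slopes(bx, by, w)
    resid = by - slopes * bx
    rss_obs = float(np.sum(w * resid**2))
    resid2_obs = resid**2

    rng = np.random.default_rng(seed)
    bx_sim = bx + sx * rng.standard_normal((n_sim, j))
    by_sim = slopes * bx + sy * rng.standard_normal((n_sim, j))
    wxy = w * bx_sim * by_sim
    wxx = w * bx_sim**2
    num_sim = wxy.sum(axis=1, keepdims=True) - wxy
    den_sim = wxx.sum(axis=1, keepdims=True) - wxx
    slopes_sim = num_sim / den_sim
    resid_sim = by_sim - slopes_sim * bx_sim
    rss_sim = resid_sim**2 @ w
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    exceed = np.sum(resid_sim**2 >= resid2_obs, axis=0)
    per_p = (1 + exceed) / (1 + n_sim)
    per_snp_p = pd.Series(per_p, index=ids, name="presso_outlier_p")
    flagged = per_p < alpha / j
    outlier_ids = sorted(ids[flagged])

    corrected = None
    distortion_p = None
    if outlier_ids:
        keep = ~np.isin(ids, outlier_ids)
        if keep.sum() >= 2:
            kept_tab = t[keep]
            corrected = ivw(wald_ratios(kept_tab), mode=ivw_mode)
            full = ivw(wald_ratios(t), mode=ivw_mode)
            d_obs = abs(corrected.beta - full.beta)
            n_rand = 1000
            n_out = int(len(outlier_ids))
            d_null = np.empty(n_rand)
            sw_xy = np.sum(w * bx * by)
            sw_xx = np.sum(w * bx**2)
            beta_full_fe = sw_xy / sw_xx
            for b in range(n_rand):
                drop = rng.choice(j, size=n_out, replace=False)
                m = np.ones(j, dtype=bool)
                m[drop] = False
                d_null[b] = abs(
                    np.sum(w[m] * bx[m] * by[m]) / np.sum(w[m] * bx[m] ** 2)
                    - beta_full_fe
                )
            distortion_p = float((1 + np.sum(d_null >= d_obs)) / (1 + n_rand))
        else:
            log.warning("presso flagged all but <2 instruments; no corrected estimate")
    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        per_snp_p=per_snp_p,
        outlier_ids=outlier_ids,
        distortion_p=distortion_p,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(
    h: HarmonizedTable | pd.DataFrame,
    ivw_mode: str = "multiplicative_random_effects",
    alpha: float = 0.008,
) -> pd.DataFrame:
    """Re-estimate IVW omitting each variant in turn.

    Returns one row per omitted variant with the J-1-variant estimate, OR,
    CI and p-value, a ``significant`` flag at ``alpha`` and a
    ``flips_significance`` flag marking omissions that change the call
    relative to the full-set estimate.
    """
    t = h.table if isinstance(h, HarmonizedTable) else h
    j = len(t)
    if j < 3:
        raise InsufficientInstrumentsError("leave_one_out needs at least 3 instruments")
    full = ivw(wald_ratios(t), mode=ivw_mode)
    full_sig = full.pvalue < alpha
    rows = []
    for i in range(j):
        sub = t.drop(t.index[i])
        res = ivw(wald_ratios(sub), mode=ivw_mode)
        rows.append(
            {
                "variant_id": t.iloc[i]["variant_id"],
                "beta": res.beta,
                "se": res.se,
                "or": res.or_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pvalue": res.pvalue,
                "n_snps": res.n_snps,
                "significant": res.pvalue < alpha,
                "flips_significance": (res.pvalue < alpha) != full_sig,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SteigerResult:
    """Directionality check: variance explained by the instruments in the
    exposure versus in the outcome."""

    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    pvalue: float

    def to_dict(self) -> dict:
        return {
            "r2_exposure": self.r2_exposure,
            "r2_outcome": self.r2_outcome,
            "direction_ok": self.direction_ok,
            "pvalue": self.pvalue,
        }


def steiger(
    h: HarmonizedTable | pd.DataFrame, n_exp: float, n_out: float
) -> SteigerResult:
    """Steiger directionality test.

    Sums the per-variant variance explained 2·EAF·(1−EAF)·beta² over the
    instrument set for each trait; the causal direction exposure->outcome is
    supported when the instruments explain more variance in the exposure.
    The p-value compares the implied correlations sqrt(R²) by Fisher
    z-transformation at the two sample sizes (two-sided). An exact tie is
    resolved to ``direction_ok=False``.
    """
    t = h.table if isinstance(h, HarmonizedTable) else h
    if t[["eaf_exp", "eaf_out"]].isna().any().any():
        raise ValidationError("steiger requires EAF for every variant in both traits")
    r2_exp = float(np.sum(variance_explained(t["eaf_exp"], t["beta_exp"])))
    r2_out = float(np.sum(variance_explained(t["eaf_out"], t["beta_out"])))
    r_exp = min(math.sqrt(max(r2_exp, 0.0)), 1.0 - 1e-12)
    r_out = min(math.sqrt(max(r2_out, 0.0)), 1.0 - 1e-12)
    z_diff = math.atanh(r_exp) - math.atanh(r_out)
    se = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    pvalue = float(2.0 * stats.norm.sf(abs(z_diff) / se))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction_ok=r2_exp > r2_out,
        pvalue=pvalue,
    )


def diagnostic_tables(
    h: HarmonizedTable | pd.DataFrame,
    r: pd.DataFrame,
    results: dict[str, MrResult],
) -> dict[str, pd.DataFrame]:
    """Plot-ready diagnostic tables.

    Returns ``scatter`` (per-variant effects with SEs), ``scatter_lines``
    (one fitted line per estimator; slope equals the estimator's beta,
    intercept is the Egger intercept or zero), ``forest`` (per-variant Wald
    ratios with 95% CIs plus one pooled row per estimator) and ``funnel``
    (ratio vs precision with the IVW reference).
    """
    t = h.table if isinstance(h, HarmonizedTable) else h
    scatter = t[["variant_id", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()
    lines = pd.DataFrame(
        {
            "method": list(results),
            "slope": [res.beta for res in results.values()],
            "intercept": [res.extras.get("intercept", 0.0) for res in results.values()],
        }
    )
    forest_snps = pd.DataFrame(
        {
            "label": r["variant_id"],
            "beta": r["ratio"],
            "ci_low": r["ratio"] - Z95 * r["ratio_se"],
            "ci_high": r["ratio"] + Z95 * r["ratio_se"],
            "kind": "snp",
        }
    )
    forest_pooled = pd.DataFrame(
        {
            "label": [f"All - {m}" for m in results],
            "beta": [res.beta for res in results.values()],
            "ci_low": [res.beta - Z95 * res.se for res in results.values()],
            "ci_high": [res.beta + Z95 * res.se for res in results.values()],
            "kind": "pooled",
        }
    )
    forest = pd.concat([forest_snps, forest_pooled], ignore_index=True)
    ivw_key = next((k for k in ("ivw_mre", "ivw_fixed") if k in results), None)
    funnel = pd.DataFrame(
        {
            "variant_id": r["variant_id"],
            "ratio": r["ratio"],
            "precision": 1.0 / r["ratio_se"],
        }
    )
    funnel.attrs["ivw_reference"] = results[ivw_key].beta if ivw_key else None
    return {
        "scatter": scatter,
        "scatter_lines": lines,
        "forest": forest,
        "funnel": funnel,
    }
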