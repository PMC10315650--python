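"""LD score regression: SNP heritability and cross-trait genetic correlation.

Under a polygenic model, the expected association chi-square of variant j
grows with its LD score l_j (the sum of r² with all tagged variants):

    E[chi²_j] = N·h²·l_j/M + intercept,

where N is the GWAS sample size, M the number of SNPs backing the LD
scores and the intercept absorbs confounding (1 under the null). For two
traits the product of z-scores regresses on LD scores the same way,

    E[z1_j·z2_j] = sqrt(N1·N2)·rho_g·l_j/M + intercept,

with slope the genetic covariance rho_g; the genetic correlation is
rg = rho_g / sqrt(h²_1·h²_2). Uncertainty comes from a delete-a-block
jackknife over contiguous SNP blocks. Intercepts are always free, which
keeps the estimates valid under (modest) sample overlap between cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ValidationError

log = logging.getLogger(__name__)

#: Bonferroni threshold for three pairwise genetic-correlation tests.
ALPHA_LDSC = 0.017


@dataclass
class LdscPanel:
    """Per-SNP LD scores and z-scores for two traits.

    ``data`` columns: ``variant_id, ldscore, z1, z2``. ``n1``/``n2`` are the
    two GWAS sample sizes, ``m`` the total number of SNPs backing the LD
    scores (m >= number of rows).
    """

    data: pd.DataFrame
    n1: float
    n2: float
    m: int

    def __post_init__(self):
        required = {"variant_id", "ldscore", "z1", "z2"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"LdscPanel data needs columns {sorted(required)}")
        if not (self.data["ldscore"] > 0).all():
            raise ValidationError("all LD scores must be positive")
        if self.m < len(self.data):
            raise ValidationError("m must be at least the number of panel SNPs")

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out["n1"] = self.n1
        out["n2"] = self.n2
        out[["variant_id", "ldscore", "z1", "n1", "z2", "n2"]].to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read(cls, path: str | Path, m: int) -> "LdscPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            data=df[["variant_id", "ldscore", "z1", "z2"]].copy(),
            n1=float(df["n1"].iloc[0]),
            n2=float(df["n2"].iloc[0]),
            m=m,
        )


@dataclass
class LdscResult:
    """Heritabilities, intercepts and the genetic correlation with jackknife
    SEs; ``rg`` is None when either heritability estimate is non-positive."""

    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    intercept_1: float
    intercept_2: float
    gcov: float
    gcov_intercept: float
    rg: float | None
    rg_se: float | None
    pvalue: float | None
    significant_after_bonferroni: bool

    def to_dict(self) -> dict:
        return {
            "h2_1": self.h2_1,
            "h2_1_se": self.h2_1_se,
            "h2_2": self.h2_2,
            "h2_2_se": self.h2_2_se,
            "intercept_1": self.intercept_1,
            "intercept_2": self.intercept_2,
            "gcov": self.gcov,
            "gcov_intercept": self.gcov_intercept,
            "rg": self.rg,
            "rg_se": self.rg_se,
            "pvalue": self.pvalue,
            "significant_after_bonferroni": self.significant_after_bonferroni,
        }


def _effective_blocks(n_snps: int, n_blocks: int) -> int:
    # Standard practice is ~200 blocks; small panels fall back to at most
    # half the SNP count so every block keeps >= 2 SNPs.
    if n_snps < 2 * n_blocks:
        n_blocks = max(2, n_snps // 2)
    return n_blocks


def _block_bounds(n_snps: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, n_snps, n_blocks + 1).astype(int)


def _wls_sums(x: np.ndarray, y: np.ndarray, w: np.ndarray, bounds: np.ndarray):
    """Per-block sufficient statistics for a weighted straight-line fit."""
    comps = np.column_stack([w, w * x, w * x * x, w * y, w * x * y])
    starts = bounds[:-1]
    block = np.add.reduceat(comps, starts, axis=0)
    total = comps.sum(axis=0)
    return total, block


def _solve_line(s: np.ndarray) -> tuple[float, float]:
    sw, swx, swxx, swy, swxy = s
    den = swxx * sw - swx**2
    if den <= 0:
        raise EstimationError("degenerate regression design (constant LD scores?)")
    slope = (swxy * sw - swx * swy) / den
    intercept = (swy - slope * swx) / sw
    return float(slope), float(intercept)


def _jackknife_line(x, y, w, n_blocks):
    """Weighted line fit plus delete-a-block jackknife estimates.

    Returns (slope, intercept, slope_blocks, intercept_blocks) where the
    block arrays hold the delete-one-block estimates.
    """
    n = len(x)
    if np.ptp(x) == 0:
        raise EstimationError("degenerate regression design: constant predictor")
    bounds = _block_bounds(n, n_blocks)
    total, block = _wls_sums(np.asarray(x, float), np.asarray(y, float), np.asarray(w, float), bounds)
    slope, intercept = _solve_line(total)
    slopes = np.empty(n_blocks)
    intercepts = np.empty(n_blocks)
    for b in range(n_blocks):
        s = total - block[b]
        slopes[b], intercepts[b] = _solve_line(s)
    return slope, intercept, slopes, intercepts


def _jackknife_se(block_estimates: np.ndarray) -> float:
    b = len(block_estimates)
    mean = block_estimates.mean()
    return float(np.sqrt((b - 1) / b * np.sum((block_estimates - mean) ** 2)))


def _h2_fit(panel: LdscPanel, trait: int, n_blocks: int):
    z = panel.data["z1" if trait == 1 else "z2"].to_numpy(dtype=float)
    n = panel.n1 if trait == 1 else panel.n2
    ell = panel.data["ldscore"].to_numpy(dtype=float)
    x = n * ell / panel.m
    y = z**2
    # Unweighted first pass sets the heteroskedasticity weights.
    slope0, _ = _solve_line(_wls_sums(x, y, np.ones_like(x), np.array([0, len(x)]))[0])
    h0 = min(max(slope0, 0.0), 1.0)
    w = 1.0 / (1.0 + n * h0 * ell / panel.m) ** 2
    return _jackknife_line(x, y, w, n_blocks)


def estimate_h2(panel: LdscPanel, trait: int = 1, n_blocks: int = 200) -> dict:
    """SNP heritability of one trait by LD score regression.

    Returns a dict with ``h2``, ``h2_se``, ``intercept``, ``intercept_se``.
    """
    if trait not in (1, 2):
        raise ValidationError("trait must be 1 or 2")
    n_blocks = _effective_blocks(len(panel.data), n_blocks)
    slope, intercept, slopes_b, intercepts_b = _h2_fit(panel, trait, n_blocks)
    return {
        "h2": slope,
        "h2_se": _jackknife_se(slopes_b),
        "intercept": intercept,
        "intercept_se": _jackknife_se(intercepts_b),
        "n_blocks": n_blocks,
    }


def estimate_rg(
    panel: LdscPanel, n_blocks: int = 200, alpha: float = ALPHA_LDSC
) -> LdscResult:
    """Cross-trait LD score regression.

    Fits both single-trait heritability regressions and the z-score-product
    regression, and propagates all three through the same delete-a-block
    jackknife to obtain the SE of rg = rho_g/sqrt(h²_1·h²_2). When either
    full-panel heritability is non-positive, rg is undefined and reported as
    None with a warning.
    """
    n_blocks = _effective_blocks(len(panel.data), n_blocks)
    h1, i1, h1_b, i1_b = _h2_fit(panel, 1, n_blocks)
    h2, i2, h2_b, _ = _h2_fit(panel, 2, n_blocks)

    ell = panel.data["ldscore"].to_numpy(dtype=float)
    x = np.sqrt(panel.n1 * panel.n2) * ell / panel.m
    y = (panel.data["z1"] * panel.data["z2"]).to_numpy(dtype=float)
    w = 1.0 / (
        (1.0 + panel.n1 * max(h1, 0.0) * ell / panel.m)
        * (1.0 + panel.n2 * max(h2, 0.0) * ell / panel.m)
    )
    gcov, gint, gcov_b, _ = _jackknife_line(x, y, w, n_blocks)

    if h1 <= 0 or h2 <= 0:
        log.warning(
            "rg undefined: non-positive heritability estimate (h2_1=%.4g, h2_2=%.4g)",
            h1,
            h2,
        )
        rg = rg_se = pvalue = None
        significant = False
    else:
        rg = float(gcov / np.sqrt(h1 * h2))
        floor = 1e-12
        rg_blocks = gcov_b / np.sqrt(
            np.clip(h1_b, floor, None) * np.clip(h2_b, floor, None)
        )
        rg_se = _jackknife_se(rg_blocks)
        pvalue = float(2.0 * stats.norm.sf(abs(rg) / rg_se)) if rg_se > 0 else float("nan")
        significant = bool(pvalue < alpha)
    return LdscResult(
        h2_1=h1,
        h2_1_se=_jackknife_se(h1_b),
        h2_2=h2,
        h2_2_se=_jackknife_se(h2_b),
        intercept_1=i1,
        intercept_2=i2,
        gcov=gcov,
        gcov_intercept=gint,
        rg=rg,
        rg_se=rg_se,
        pvalue=pvalue,
        significant_after_bonferroni=significant,
    )
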