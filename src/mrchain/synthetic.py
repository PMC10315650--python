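"""Synthetic GWAS summary statistics for a three-trait causal chain.

Generates the summary-level data that a two-sample MR mediation study
consumes: per-variant association statistics for an exposure X, a mediator Y
and an outcome Z linked by the chain X -> Y -> Z (plus an optional direct
X -> Z path), together with the ground truth needed for parameter-recovery
tests. Effects are simulated directly at the summary level — two-sample MR
never sees individual genotypes — with independent sampling noise in the
three (non-overlapping) cohorts:

* variant j carries a true effect gamma_j on X, drawn from a truncated
  normal so that every instrument is detectable at the default sample size;
* its expected marginal effect on Y is beta_XY·gamma_j, and on Z is
  (beta_XZ + beta_XY·beta_YZ)·gamma_j, plus a direct (pleiotropic) effect
  alpha_j on Z for a configurable fraction of variants;
* the observed beta is the expectation plus Gaussian noise with
  SE = 1/sqrt(2·EAF·(1−EAF)·N), the standard-error profile of a regression
  coefficient on a standardized trait, and p = 2·Phi(−|beta/se|).

The default causal effects reproduce the chain structure of a
reflux-depression-COPD style study (step ORs ~1.31 and ~1.004, no direct
path); sample sizes default to the scale of the contributing consortia.
LD is emulated as equicorrelated blocks exposed through an explicit r²
matrix, sufficient to exercise clumping. A companion generator produces LD
score regression panels under the standard polygenic expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .instruments import LdMatrix
from .ldsc import LdscPanel

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated causal chain.

    Defaults encode the study conditions this harness emulates: three large
    non-overlapping case-control GWAS (sample sizes at the scale of the
    reflux, depression and COPD consortia), ~50 independent instruments with
    per-variant effects gamma_j ~ Normal(0.05, 0.02) truncated at
    |gamma| > 0.01 (detectable at these N), step effects
    beta_XY = ln 1.309 and beta_YZ = ln 1.004, no direct X->Z path, no
    pleiotropy and no outliers unless requested.
    """

    n_snps: int = 50
    n_x: int = 385_276
    n_y: int = 807_553
    n_z: int = 257_811
    beta_xy: float = math.log(1.309)
    beta_yz: float = math.log(1.004)
    beta_xz: float = 0.0
    gamma_mean: float = 0.05
    gamma_sd: float = 0.02
    gamma_min_abs: float = 0.01
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    n_outliers: int = 0
    outlier_multiplier: float = 10.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    palindrome_frac: float = 0.1
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ConfigError("n_snps must be at least 1")
        for name in ("n_x", "n_y", "n_z"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be at least 2")
        for name in ("pleiotropy_frac", "palindrome_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("eaf_range must satisfy 0 < low < high < 1")
        if not (0.0 <= self.ld_within_r2 <= 1.0):
            raise ConfigError("ld_within_r2 must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be at least 1")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            raise ConfigError("n_outliers must be in [0, n_snps]")
        if self.gamma_sd < 0:
            raise ConfigError("gamma_sd must be non-negative")


@dataclass
class TruthManifest:
    """Ground truth of one simulated chain, for parameter-recovery tests.

    ``per_snp_gamma`` holds the true SNP->X effects of the exposure's own
    instruments; ``x/y/z_instrument_ids`` identify which simulated variants
    are the dedicated instruments of each trait.
    """

    beta_xy: float
    beta_yz: float
    beta_xz: float
    per_snp_gamma: np.ndarray
    pleiotropic_ids: set[str] = field(default_factory=set)
    outlier_ids: set[str] = field(default_factory=set)
    x_instrument_ids: tuple[str, ...] = ()
    y_instrument_ids: tuple[str, ...] = ()
    z_instrument_ids: tuple[str, ...] = ()

    def write(self, path: str | Path) -> None:
        lines = [
            f"beta_xy={float(self.beta_xy)!r}",
            f"beta_yz={float(self.beta_yz)!r}",
            f"beta_xz={float(self.beta_xz)!r}",
            "per_snp_gamma=" + ",".join(repr(float(g)) for g in self.per_snp_gamma),
            "pleiotropic_ids=" + ",".join(sorted(self.pleiotropic_ids)),
            "outlier_ids=" + ",".join(sorted(self.outlier_ids)),
            "x_instrument_ids=" + ",".join(self.x_instrument_ids),
            "y_instrument_ids=" + ",".join(self.y_instrument_ids),
            "z_instrument_ids=" + ",".join(self.z_instrument_ids),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                key, _, value = line.partition("=")
                kv[key] = value
        return cls(
            beta_xy=float(kv["beta_xy"]),
            beta_yz=float(kv["beta_yz"]),
            beta_xz=float(kv["beta_xz"]),
            per_snp_gamma=np.array(
                [float(v) for v in kv["per_snp_gamma"].split(",") if v]
            ),
            pleiotropic_ids=set(v for v in kv["pleiotropic_ids"].split(",") if v),
            outlier_ids=set(v for v in kv["outlier_ids"].split(",") if v),
            x_instrument_ids=tuple(v for v in kv.get("x_instrument_ids", "").split(",") if v),
            y_instrument_ids=tuple(v for v in kv.get("y_instrument_ids", "").split(",") if v),
            z_instrument_ids=tuple(v for v in kv.get("z_instrument_ids", "").split(",") if v),
        )


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def _observe(true_beta, eaf, n, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    beta = true_beta + se * rng.standard_normal(len(se))
    return beta, se, _pvalues(beta, se)


def _truncated_gamma(rng, mean, sd, min_abs, size) -> np.ndarray:
    gamma = rng.normal(mean, sd, size)
    if sd > 0:
        for _ in range(1000):
            weak = np.abs(gamma) <= min_abs
            if not weak.any():
                break
            gamma[weak] = rng.normal(mean, sd, int(weak.sum()))
    return gamma


def simulate_chain_gwas(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Simulate GWAS summary tables for X, Y and Z plus the ground truth.

    Each trait carries its own block of ``n_snps`` dedicated instruments
    (3·n_snps variants in total), as in a bidirectional MR design where
    every trait has genome-wide-significant hits of its own. Effects
    propagate only downstream through the causal chain: X's instruments
    influence Y via beta_XY and Z via beta_XZ + beta_XY·beta_YZ (plus any
    pleiotropic direct effect), Y's instruments influence Z via beta_YZ,
    and Z's instruments influence Z alone. Pleiotropy and injected outliers
    apply to the X-instrument block's effects on Z.

    The three tables share variant ids, positions, alleles and allele
    frequencies (one ancestry) but have independent sampling noise scaled to
    their own sample sizes. Identical configs (including the seed) give
    byte-identical outputs.
    """
    k = config.n_snps
    j = 3 * k
    rng = np.random.default_rng(config.seed)
    ids = np.array([f"rs{100000 + i}" for i in range(j)])
    chrom = np.repeat("1", j)
    pos = 1 + 10_000 * np.arange(j, dtype=np.int64)

    eaf = rng.uniform(config.eaf_range[0], config.eaf_range[1], j)

    gamma_x = _truncated_gamma(rng, config.gamma_mean, config.gamma_sd,
                               config.gamma_min_abs, k)
    gamma_y = _truncated_gamma(rng, config.gamma_mean, config.gamma_sd,
                               config.gamma_min_abs, k)
    gamma_z = _truncated_gamma(rng, config.gamma_mean, config.gamma_sd,
                               config.gamma_min_abs, k)

    n_pal = int(round(config.palindrome_frac * j))
    pal_idx = rng.choice(j, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    pair_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), j)
    ea = np.array([_NONPALINDROMIC_PAIRS[c][0] for c in pair_choice])
    oa = np.array([_NONPALINDROMIC_PAIRS[c][1] for c in pair_choice])
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), j)
    for i in pal_idx:
        ea[i], oa[i] = _PALINDROMIC_PAIRS[pal_choice[i]]

    # Pleiotropy: direct X-instrument -> Z effects bypassing the chain.
    n_pleio = int(round(config.pleiotropy_frac * k))
    pleio_idx = (
        rng.choice(k, size=n_pleio, replace=False) if n_pleio else np.array([], dtype=int)
    )
    alpha = np.zeros(k)
    if n_pleio:
        alpha[pleio_idx] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n_pleio)

    zeros = np.zeros(k)
    true_x = np.concatenate([gamma_x, zeros, zeros])
    true_y = np.concatenate([config.beta_xy * gamma_x, gamma_y, zeros])
    true_z = np.concatenate(
        [
            (config.beta_xz + config.beta_xy * config.beta_yz) * gamma_x + alpha,
            config.beta_yz * gamma_y,
            gamma_z,
        ]
    )

    bx, sx, px = _observe(true_x, eaf, config.n_x, rng)
    by, sy, py = _observe(true_y, eaf, config.n_y, rng)
    bz, sz, pz = _observe(true_z, eaf, config.n_z, rng)

    def _table(beta, se, p, n):
        return pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pvalue": p,
                "n": float(n),
            }
        )

    gx = _table(bx, sx, px, config.n_x)
    gy = _table(by, sy, py, config.n_y)
    gz = _table(bz, sz, pz, config.n_z)

    outlier_ids: set[str] = set()
    if config.n_outliers:
        out_idx = rng.choice(k, size=config.n_outliers, replace=False)
        outlier_ids = set(ids[out_idx])
        gz = inject_outliers(gz, outlier_ids, config.outlier_multiplier)

    truth = TruthManifest(
        beta_xy=config.beta_xy,
        beta_yz=config.beta_yz,
        beta_xz=config.beta_xz,
        per_snp_gamma=gamma_x,
        pleiotropic_ids=set(ids[pleio_idx]),
        outlier_ids=outlier_ids,
        x_instrument_ids=tuple(ids[:k]),
        y_instrument_ids=tuple(ids[k : 2 * k]),
        z_instrument_ids=tuple(ids[2 * k :]),
    )
    return gx, gy, gz, truth


def inject_outliers(
    table: pd.DataFrame, ids, multiplier: float
) -> pd.DataFrame:
    """Return a copy of ``table`` with the listed variants' betas multiplied
    by ``multiplier`` (their p-values re-derived so every record stays
    internally consistent). The input table is not modified.

    Raises ``LookupError`` for ids absent from the table.
    """
    ids = set(ids)
    known = set(table["variant_id"])
    unknown = ids - known
    if unknown:
        raise LookupError(f"unknown variant id(s): {sorted(unknown)}")
    out = table.copy()
    mask = out["variant_id"].isin(ids)
    out.loc[mask, "beta"] = out.loc[mask, "beta"] * multiplier
    out.loc[mask, "pvalue"] = _pvalues(
        out.loc[mask, "beta"].to_numpy(), out.loc[mask, "se"].to_numpy()
    )
    return out


def block_ld_matrix(
    variant_ids, block_size: int, within_r2: float
) -> LdMatrix:
    """Equicorrelated-block LD: consecutive runs of ``block_size`` variants
    share r² = ``within_r2``; variants in different blocks are independent."""
    ld = LdMatrix()
    ids = list(variant_ids)
    if block_size < 2 or within_r2 <= 0.0:
        return ld
    for start in range(0, len(ids), block_size):
        block = ids[start : start + block_size]
        for i in range(len(block)):
            for k in range(i + 1, len(block)):
                ld.set(block[i], block[k], within_r2)
    return ld


def simulate_ldsc_panel(
    n_snps: int = 20_000,
    h2_1: float = 0.3,
    h2_2: float = 0.3,
    rg: float = 0.5,
    n1: int = 50_000,
    n2: int = 50_000,
    m: int | None = None,
    seed: int = 0,
) -> LdscPanel:
    """Simulate an LD score regression panel for two traits.

    Per-SNP LD scores are drawn as 1 + Gamma(2, 20) (a right-skewed spread
    resembling real LD score distributions) and the z-score pair at SNP j is
    bivariate normal, mean zero, with

        Var(z_t) = 1 + N_t·h²_t·l_j/m,
        Cov(z1, z2) = sqrt(N1·N2)·rg·sqrt(h²_1·h²_2)·l_j/m,

    i.e. the standard LDSC expectations with unit null intercepts.
    """
    for name, v in (("h2_1", h2_1), ("h2_2", h2_2)):
        if not (0.0 <= v <= 1.0):
            raise ConfigError(f"{name} must be in [0, 1]")
    if not (-1.0 <= rg <= 1.0):
        raise ConfigError("rg must be in [-1, 1]")
    if n_snps < 1:
        raise ConfigError("n_snps must be at least 1")
    for name, v in (("n1", n1), ("n2", n2)):
        if v < 2:
            raise ConfigError(f"{name} must be at least 2")
    m = int(m) if m is not None else n_snps
    if m < n_snps:
        raise ConfigError("m must be at least n_snps")

    rng = np.random.default_rng(seed)
    ell = 1.0 + rng.gamma(2.0, 20.0, n_snps)
    v1 = 1.0 + n1 * h2_1 * ell / m
    v2 = 1.0 + n2 * h2_2 * ell / m
    cov = math.sqrt(n1 * n2) * rg * math.sqrt(h2_1 * h2_2) * ell / m
    a = rng.standard_normal(n_snps)
    b = rng.standard_normal(n_snps)
    z1 = np.sqrt(v1) * a
    resid_var = np.maximum(v2 - cov**2 / v1, 0.0)
    z2 = (cov / np.sqrt(v1)) * a + np.sqrt(resid_var) * b
    data = pd.DataFrame(
        {
            "variant_id": [f"rs{200000 + i}" for i in range(n_snps)],
            "ldscore": ell,
            "z1": z1,
            "z2": z2,
        }
    )
    return LdscPanel(data=data, n1=float(n1), n2=float(n2), m=m)
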