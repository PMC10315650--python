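"""Instrument selection for two-sample Mendelian randomization.

A valid genetic instrument must be (i) robustly associated with the exposure,
(ii) independent of other instruments, (iii) not associated with confounders
of the exposure-outcome relation, and (iv) not directly associated with the
outcome. This module implements that pipeline: genome-wide significance
filtering (default p < 5e-8), greedy LD clumping (default r² < 0.001 within a
10,000 kb window), a confounder screen based on delta-method Wald ratios
pooled by DerSimonian-Laird random-effects meta-analysis, an
outcome-association exclusion (default p < 5e-5), and the per-variant
instrument-strength diagnostics R² = 2·EAF·(1−EAF)·beta² and
F = R²·(N−2)/(1−R²), with F > 10 the conventional strength rule of thumb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .harmonize import DROP_OUTCOME_ASSOCIATED, HarmonizedTable, harmonize

log = logging.getLogger(__name__)

DROP_NOT_SIGNIFICANT = "not_significant"
DROP_CLUMPED = "clumped"
DROP_CONFOUNDER = "confounder_associated"

WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class ClumpConfig:
    """LD clumping parameters; defaults follow common MR practice."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self):
        if not self.p_threshold > 0:
            raise ConfigError("p_threshold must be positive")
        if not (0 < self.r2_threshold <= 1):
            raise ConfigError("r2_threshold must be in (0, 1]")
        if not self.window_kb > 0:
            raise ConfigError("window_kb must be positive")


class LdMatrix:
    """Sparse symmetric pairwise-r² lookup keyed by variant id.

    Pairs absent from the matrix are treated as independent (r² = 0), so an
    empty matrix means all variants are mutually independent. The diagonal is
    implicitly 1.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2 must be in [0,1], got {r2} for ({a},{b})")
        if a == b and r2 != 1.0:
            raise ValidationError(f"diagonal entry for {a} must be 1")
        if a != b:
            self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_pairs_frame(cls, df: pd.DataFrame) -> "LdMatrix":
        """Build from a long-format frame with columns
        ``variant_id_a, variant_id_b, r2``; duplicated unordered pairs with
        conflicting values are rejected as asymmetric input."""
        required = {"variant_id_a", "variant_id_b", "r2"}
        if not required.issubset(df.columns):
            raise ValidationError(f"LD pairs frame needs columns {sorted(required)}")
        ld = cls()
        seen: dict[frozenset, float] = {}
        for a, b, r2 in df[["variant_id_a", "variant_id_b", "r2"]].itertuples(index=False):
            key = frozenset((str(a), str(b)))
            r2 = float(r2)
            if key in seen and abs(seen[key] - r2) > 1e-12:
                raise ValidationError(
                    f"asymmetric LD input for pair ({a},{b}): {seen[key]} vs {r2}"
                )
            seen[key] = r2
            ld.set(str(a), str(b), r2)
        return ld

    @classmethod
    def read(cls, path) -> "LdMatrix":
        return cls.from_pairs_frame(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        rows = []
        for key, r2 in sorted(self._r2.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(key)
            rows.append((a, b, r2))
        pd.DataFrame(rows, columns=["variant_id_a", "variant_id_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


def filter_significance(table: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Retain records with ``pvalue < p_threshold`` (strict inequality)."""
    kept = table[table["pvalue"] < p_threshold].reset_index(drop=True)
    if kept.empty:
        log.warning("significance filter at %g left no variants", p_threshold)
    return kept


def clump(
    table: pd.DataFrame,
    ld: LdMatrix | None = None,
    config: ClumpConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy LD clumping.

    Repeatedly takes the remaining variant with the smallest p-value as the
    index variant and drops all remaining variants on the same chromosome
    within ``window_kb`` whose r² with the index is >= ``r2_threshold``.
    Ties on p-value are broken by larger ``|beta|``, then by lexicographic
    ``variant_id``, making the result invariant to input row order.

    Returns ``(kept, dropped)`` where ``dropped`` is a ledger frame with
    columns ``variant_id, reason, index_variant``.
    """
    config = config or ClumpConfig()
    ld = ld or LdMatrix()
    if table.empty:
        return table.copy(), pd.DataFrame(columns=["variant_id", "reason", "index_variant"])

    order = table.assign(_abs_beta=-table["beta"].abs()).sort_values(
        ["pvalue", "_abs_beta", "variant_id"], kind="mergesort"
    )
    window_bp = config.window_kb * 1000.0
    alive = order[["variant_id", "chrom", "pos"]].to_numpy(dtype=object)
    kept_ids: list[str] = []
    dropped: list[tuple[str, str, str]] = []
    remaining = list(range(len(alive)))
    removed = np.zeros(len(alive), dtype=bool)
    for i in remaining:
        if removed[i]:
            continue
        vid, chrom, pos = alive[i]
        kept_ids.append(vid)
        for j in range(i + 1, len(alive)):
            if removed[j]:
                continue
            vj, cj, pj = alive[j]
            if cj == chrom and abs(float(pj) - float(pos)) <= window_bp:
                if ld.r2(vid, vj) >= config.r2_threshold:
                    removed[j] = True
                    dropped.append((vj, DROP_CLUMPED, vid))
    kept = table[table["variant_id"].isin(kept_ids)].reset_index(drop=True)
    ledger = pd.DataFrame(dropped, columns=["variant_id", "reason", "index_variant"])
    return kept, ledger


def variance_explained(eaf, beta):
    """Per-variant variance in the trait explained by the variant:
    R² = 2·EAF·(1−EAF)·beta². Accepts scalars or arrays."""
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValidationError("eaf must be strictly inside (0, 1)")
    beta = np.asarray(beta, dtype=float)
    out = 2.0 * eaf * (1.0 - eaf) * beta**2
    return float(out) if out.ndim == 0 else out


def f_statistic(r_squared, n):
    """Instrument-strength F statistic: F = R²·(N−2)/(1−R²)."""
    r_squared = np.asarray(r_squared, dtype=float)
    if np.any((r_squared < 0) | (r_squared >= 1)):
        raise ValidationError("r_squared must be in [0, 1)")
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValidationError("n must exceed 2")
    out = r_squared * (n - 2.0) / (1.0 - r_squared)
    return float(out) if out.ndim == 0 else out


def annotate_strength(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``r_squared``, ``f_stat`` and a ``weak`` flag
    (F <= 10). Weak instruments are flagged, not dropped: F is a reported
    diagnostic."""
    out = table.copy()
    out["r_squared"] = variance_explained(out["eaf"], out["beta"])
    out["f_stat"] = f_statistic(out["r_squared"], out["n"])
    out["weak"] = out["f_stat"] <= WEAK_INSTRUMENT_F
    n_weak = int(out["weak"].sum())
    if n_weak:
        log.warning("%d instrument(s) have F <= %g", n_weak, WEAK_INSTRUMENT_F)
    return out


def dersimonian_laird(effects, ses) -> dict:
    """DerSimonian-Laird random-effects meta-analysis of independent effects.

    Returns the pooled estimate, its SE, a two-sided normal p-value, the
    between-study variance tau² and Cochran's Q of the fixed-effect fit.
    """
    y = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValidationError("meta-analysis needs at least one effect")
    w = 1.0 / s**2
    mu_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    df = y.size - 1
    tau2 = 0.0
    if df > 0:
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    mu = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    p = float(2.0 * stats.norm.sf(abs(mu) / se))
    return {"beta": mu, "se": se, "pvalue": p, "tau2": tau2, "q": q, "df": df, "n": int(y.size)}


def confounder_screen(
    instruments: pd.DataFrame,
    confounder: pd.DataFrame,
    p_drop: float = 5e-8,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Screen instruments against a confounder GWAS.

    The candidate instruments are harmonized against the confounder table;
    for each shared variant the exposure->confounder Wald ratio
    ``beta_conf / beta_exp`` with first-order delta-method SE
    ``se_conf / |beta_exp|`` is pooled by DerSimonian-Laird random-effects
    meta-analysis (the overall exposure-confounder association). Instruments
    whose confounder association has ``p < p_drop`` are removed.

    Returns ``(screened, dropped_ledger, pooled_effect)``. Variants with zero
    exposure beta are excluded from the meta-analysis with a log message.
    """
    h = harmonize(instruments, confounder, drop_palindromes=False)
    t = h.table
    pooled: dict = {"beta": 0.0, "se": float("nan"), "pvalue": float("nan"), "tau2": 0.0, "n": 0}
    if not t.empty:
        nonzero = t["beta_exp"] != 0.0
        if (~nonzero).any():
            log.warning(
                "confounder screen: %d variant(s) with zero exposure beta excluded "
                "from the meta-analysis",
                int((~nonzero).sum()),
            )
        tt = t[nonzero]
        if len(tt):
            ratios = tt["beta_out"] / tt["beta_exp"]
            ratio_se = tt["se_out"] / tt["beta_exp"].abs()
            pooled = dersimonian_laird(ratios.to_numpy(), ratio_se.to_numpy())
    assoc = t[t["p_out"] < p_drop]["variant_id"]
    drop_ids = set(assoc)
    dropped = pd.DataFrame(
        {"variant_id": sorted(drop_ids), "reason": DROP_CONFOUNDER}
    )
    screened = instruments[~instruments["variant_id"].isin(drop_ids)].reset_index(drop=True)
    return screened, dropped, pooled


def outcome_association_filter(
    h: HarmonizedTable, p_out_threshold: float = 5e-5
) -> HarmonizedTable:
    """Drop harmonized variants whose outcome p-value is below the threshold
    (possible direct outcome association violating the exclusion assumption)."""
    mask = h.table["p_out"] < p_out_threshold
    new_drops = pd.DataFrame(
        {
            "variant_id": h.table.loc[mask, "variant_id"].to_numpy(),
            "reason": DROP_OUTCOME_ASSOCIATED,
        }
    )
    drops = pd.concat([h.drops, new_drops], ignore_index=True) if len(new_drops) else h.drops
    return HarmonizedTable(table=h.table[~mask].reset_index(drop=True), drops=drops)
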