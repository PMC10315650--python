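"""End-to-end orchestration of the bidirectional two-step MR study.

A full study over three traits X (exposure), Y (mediator), Z (outcome)
comprises six MR legs (X->Z, X->Y, Y->Z and their reverses), a mediation
decomposition in each direction, and pairwise LD score regression. Each leg
runs the complete instrument-selection pipeline (significance filter, LD
clumping, optional confounder screen, harmonization, outcome-association
filter), the five-estimator battery and the sensitivity analyses, and emits
an auditable report with drop counts at every stage.

Effects with p below the Bonferroni threshold 0.008 (0.05/6 legs) are
labelled significant; those in [0.008, 0.05) are labelled suggestive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import estimators, instruments, sensitivity
from .errors import InsufficientInstrumentsError, MrChainError
from .estimators import MrResult
from .harmonize import harmonize
from .instruments import ClumpConfig, LdMatrix
from .ldsc import LdscPanel, estimate_rg
from .mediation import two_step_mediation

log = logging.getLogger(__name__)

#: Frozen analysis thresholds; config defaults must match these exactly.
DEFAULT_THRESHOLDS = {
    "p_instrument": 5e-8,
    "r2_clump": 0.001,
    "window_kb": 10_000.0,
    "p_outcome": 5e-5,
    "p_confounder": 5e-8,
    "alpha_mr": 0.008,
    "alpha_ldsc": 0.017,
}


@dataclass
class RunConfig:
    """All thresholds and estimator settings for a study run."""

    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    window_kb: float = 10_000.0
    p_outcome: float = 5e-5
    p_confounder: float = 5e-8
    alpha_mr: float = 0.008
    alpha_ldsc: float = 0.017
    ivw_mode: str = "multiplicative_random_effects"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    drop_palindromes: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MrChainError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _classify(pvalue: float, alpha_strict: float) -> str:
    if pvalue < alpha_strict:
        return "significant"
    if pvalue < 0.05:
        return "suggestive"
    return "not_significant"


def run_leg(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    config: RunConfig | None = None,
    ld: LdMatrix | None = None,
    confounders: dict[str, pd.DataFrame] | None = None,
    eqtl_ids: set[str] | None = None,
) -> dict:
    """Run one exposure->outcome MR leg end to end.

    Returns a JSON-serializable report with per-stage variant counts, the
    drop ledger, all five estimator results and the sensitivity battery.
    A stage failure (e.g. too few instruments) marks the leg failed with the
    stage name instead of raising.
    """
    config = config or RunConfig()
    report: dict = {"counts": {}, "drops": [], "status": "ok"}
    counts = report["counts"]
    stage = "significance_filter"
    try:
        counts["input"] = len(exposure)
        sig = instruments.filter_significance(exposure, config.p_instrument)
        counts["significant"] = len(sig)

        stage = "clump"
        clumped, clump_drops = instruments.clump(
            sig,
            ld,
            ClumpConfig(
                p_threshold=config.p_instrument,
                r2_threshold=config.r2_clump,
                window_kb=config.window_kb,
            ),
        )
        counts["after_clump"] = len(clumped)
        report["drops"] += clump_drops[["variant_id", "reason"]].to_dict("records")

        stage = "confounder_screen"
        screened = clumped
        report["confounders"] = {}
        for name, ctab in (confounders or {}).items():
            screened, cdrops, pooled = instruments.confounder_screen(
                screened, ctab, p_drop=config.p_confounder
            )
            report["confounders"][name] = pooled
            report["drops"] += cdrops.to_dict("records")
        counts["after_confounder_screen"] = len(screened)

        stage = "eqtl_subset"
        if eqtl_ids is not None:
            screened = screened[screened["variant_id"].isin(set(eqtl_ids))].reset_index(
                drop=True
            )
        counts["after_eqtl_subset"] = len(screened)

        stage = "strength"
        screened = instruments.annotate_strength(screened)
        if len(screened):
            report["f_stat"] = {
                "mean": float(screened["f_stat"].mean()),
                "min": float(screened["f_stat"].min()),
                "max": float(screened["f_stat"].max()),
                "n_weak": int(screened["weak"].sum()),
            }

        stage = "harmonize"
        h = harmonize(screened, outcome, drop_palindromes=config.drop_palindromes)
        counts["after_harmonize"] = h.n_snps

        stage = "outcome_filter"
        h = instruments.outcome_association_filter(h, config.p_outcome)
        counts["after_outcome_filter"] = h.n_snps
        report["drops"] += h.drops.to_dict("records")

        stage = "estimators"
        results = estimators.all_estimators(
            h, ivw_mode=config.ivw_mode, n_boot=config.n_boot, seed=config.seed
        )
        report["mr"] = {name: res.to_dict() for name, res in results.items()}
        primary_key = "ivw_fixed" if config.ivw_mode == "fixed" else "ivw_mre"
        primary = results[primary_key]
        report["primary_method"] = primary_key
        report["classification"] = _classify(primary.pvalue, config.alpha_mr)

        stage = "sensitivity"
        r = estimators.wald_ratios(h)
        q, q_df, q_p = sensitivity.cochran_q(r, primary.beta)
        sens: dict = {"cochran_q": {"q": q, "df": q_df, "pvalue": q_p}}
        try:
            pres = sensitivity.presso(
                h,
                n_sim=config.presso_n_sim,
                seed=config.seed,
                alpha=config.presso_alpha,
                ivw_mode=config.ivw_mode,
            )
            sens["presso"] = pres.to_dict()
        except InsufficientInstrumentsError as exc:
            sens["presso"] = {"skipped": str(exc)}
        try:
            loo = sensitivity.leave_one_out(h, ivw_mode=config.ivw_mode, alpha=config.alpha_mr)
            sens["leave_one_out"] = {
                "n_rows": len(loo),
                "any_flips_significance": bool(loo["flips_significance"].any()),
                "rows": loo.to_dict("records"),
            }
        except InsufficientInstrumentsError as exc:
            sens["leave_one_out"] = {"skipped": str(exc)}
        n_exp = float(h.table["n_exp"].median())
        n_out = float(h.table["n_out"].median())
        sens["steiger"] = sensitivity.steiger(h, n_exp, n_out).to_dict()
        report["sensitivity"] = sens
        report["diagnostics"] = {
            name: tab.to_dict("records")
            for name, tab in sensitivity.diagnostic_tables(h, r, results).items()
        }
        return report
    except MrChainError as exc:
        log.error("leg failed at stage %s: %s", stage, exc)
        report["status"] = "failed"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        return report


_LEGS = (
    ("x_on_z", "x", "z"),
    ("x_on_y", "x", "y"),
    ("y_on_z", "y", "z"),
    ("z_on_x", "z", "x"),
    ("z_on_y", "z", "y"),
    ("y_on_x", "y", "x"),
)


def _mr_from_report(leg_report: dict, method: str | None = None) -> MrResult | None:
    if leg_report.get("status") != "ok":
        return None
    method = method or leg_report["primary_method"]
    d = leg_report["mr"][method]
    return MrResult(
        method=d["method"],
        beta=d["beta"],
        se=d["se"],
        pvalue=d["pvalue"],
        n_snps=d["n_snps"],
    )


def run_full(
    tables: dict[str, pd.DataFrame],
    config: RunConfig | None = None,
    ld: LdMatrix | None = None,
    confounders: dict[str, dict[str, pd.DataFrame]] | None = None,
    eqtl_ids: set[str] | None = None,
    ldsc_panels: dict[str, LdscPanel] | None = None,
) -> dict:
    """Run the full bidirectional two-step study.

    Parameters
    ----------
    tables
        ``{"x": exposure, "y": mediator, "z": outcome}`` GWAS tables.
    confounders
        Optional per-trait confounder GWAS tables,
        e.g. ``{"x": {"smoking": df, ...}}``; applied when that trait is the
        exposure of a leg.
    eqtl_ids
        Optional externally supplied eQTL variant-id list; each leg is
        re-run restricted to these instruments, mirroring an eQTL-MR
        validation pass.
    ldsc_panels
        Optional panels keyed ``"x_y"``, ``"x_z"``, ``"y_z"`` for the three
        pairwise genetic-correlation analyses.

    The report contains the six legs, forward (X->Y->Z) and reverse
    (Z->Y->X) mediation blocks and, when panels are given, three LDSC
    results. Deterministic given config and seed.
    """
    config = config or RunConfig()
    for key in ("x", "y", "z"):
        if key not in tables:
            raise MrChainError(f"tables must contain {key!r}")
    report: dict = {"config": config.to_dict(), "legs": {}}
    for name, exp_key, out_key in _LEGS:
        report["legs"][name] = run_leg(
            tables[exp_key],
            tables[out_key],
            config=config,
            ld=ld,
            confounders=(confounders or {}).get(exp_key),
        )
    if eqtl_ids is not None:
        report["eqtl_legs"] = {}
        for name, exp_key, out_key in _LEGS:
            report["eqtl_legs"][name] = run_leg(
                tables[exp_key],
                tables[out_key],
                config=config,
                ld=ld,
                confounders=(confounders or {}).get(exp_key),
                eqtl_ids=eqtl_ids,
            )

    report["mediation"] = {}
    forward = _mediate_from_legs(
        report["legs"], step1="x_on_y", step2="y_on_z", direct="x_on_z"
    )
    reverse = _mediate_from_legs(
        report["legs"], step1="z_on_y", step2="y_on_x", direct="z_on_x"
    )
    report["mediation"]["forward"] = forward
    report["mediation"]["reverse"] = reverse

    report["ldsc"] = {}
    for pair, panel in (ldsc_panels or {}).items():
        report["ldsc"][pair] = estimate_rg(panel, alpha=config.alpha_ldsc).to_dict()
    return report


def _mediate_from_legs(legs: dict, step1: str, step2: str, direct: str) -> dict:
    s1 = _mr_from_report(legs[step1])
    s2 = _mr_from_report(legs[step2])
    d = _mr_from_report(legs[direct])
    if s1 is None or s2 is None or d is None:
        failed = [n for n, r in ((step1, s1), (step2, s2), (direct, d)) if r is None]
        return {"status": "failed", "missing_legs": failed}
    med = two_step_mediation(s1, s2, d)
    out = med.to_dict()
    out["status"] = "ok"
    out["legs"] = {"step1": step1, "step2": step2, "direct": direct}
    return out


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report as canonical JSON (sorted keys, fixed layout), so
    identical runs produce byte-identical files."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
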