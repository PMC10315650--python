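"""GWAS summary-statistic I/O and effect-allele harmonization.

Two-sample Mendelian randomization combines per-variant effect estimates from
an exposure GWAS and an outcome GWAS. Before any causal estimate can be
formed, the two tables must refer to the same effect allele at every shared
variant: when the outcome study reports the opposite allele, its beta is
negated and its effect-allele frequency complemented. Allele pairs that match
in neither orientation are incompatible (likely strand or multi-allelic
artefacts) and are removed, as are palindromic (A/T or C/G) variants whose
strand cannot be resolved from the alleles alone.

A GWAS table is an ordinary :class:`pandas.DataFrame` with the columns in
:data:`GWAS_COLUMNS`; :func:`read_gwas` validates files into that layout and
:func:`harmonize` produces a :class:`HarmonizedTable` carrying both the
aligned effects and a complete ledger of dropped variants with reasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: Canonical column order for a GWAS summary-statistic table.
GWAS_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

_NUMERIC_COLUMNS = ("pos", "eaf", "beta", "se", "pvalue", "n")

VALID_ALLELES = frozenset("ACGT")
_PALINDROME_PAIRS = ({"A", "T"}, {"C", "G"})

# Drop-ledger reason codes shared across the pipeline.
DROP_NOT_IN_OUTCOME = "not_in_outcome"
DROP_INCOMPATIBLE = "incompatible_alleles"
DROP_PALINDROMIC = "palindromic"
DROP_OUTCOME_ASSOCIATED = "outcome_associated"


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}.

    Such variants are ambiguous under strand flips and are removed during
    harmonization by default.
    """
    ea = str(effect_allele).upper()
    oa = str(other_allele).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise ValidationError(
            f"alleles must be single bases in A/C/G/T, got {effect_allele!r}/{other_allele!r}"
        )
    return {ea, oa} in _PALINDROME_PAIRS


def validate_gwas(
    df: pd.DataFrame, name: str = "table"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a GWAS table, returning ``(clean, rejected)``.

    Rows violating record-level invariants (non-ACGT or identical alleles,
    EAF outside (0,1), non-positive SE, p-value outside (0,1], n < 2,
    missing values) are returned in ``rejected`` with their original row
    number and a reason, and logged. Indels and multi-allelic records fail
    the single-base allele check and are rejected the same way.

    Raises
    ------
    FormatError
        If a required column is missing or a numeric column contains
        unparsable entries (the offending rows are listed).
    ValidationError
        If ``variant_id`` is duplicated among otherwise-valid rows.
    """
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing required column(s) {missing}")

    out = df.loc[:, list(GWAS_COLUMNS)].copy()
    out["variant_id"] = out["variant_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            rows = list(np.flatnonzero(bad.to_numpy()))
            raise FormatError(
                f"{name}: unparsable numeric values in column {col!r} at rows {rows}"
            )
        out[col] = coerced.astype(float)

    ea = out["effect_allele"].astype(str).str.upper()
    oa = out["other_allele"].astype(str).str.upper()
    out["effect_allele"] = ea
    out["other_allele"] = oa

    checks = [
        ("invalid_allele", ~(ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES))),
        ("identical_alleles", ea == oa),
        ("eaf_out_of_range", ~((out["eaf"] > 0.0) & (out["eaf"] < 1.0))),
        ("nonpositive_se", ~(out["se"] > 0.0)),
        ("pvalue_out_of_range", ~((out["pvalue"] > 0.0) & (out["pvalue"] <= 1.0))),
        ("sample_size_below_2", ~(out["n"] >= 2)),
    ]
    numeric_na = out[list(_NUMERIC_COLUMNS)].isna().any(axis=1)
    reason = pd.Series("", index=out.index, dtype=object)
    bad_any = numeric_na.copy()
    reason[numeric_na] = "missing_value"
    for label, mask in checks:
        mask = mask.fillna(True) & ~bad_any
        reason[mask] = label
        bad_any |= mask

    rejected = pd.DataFrame(
        {
            "row": np.flatnonzero(bad_any.to_numpy()),
            "variant_id": out.loc[bad_any, "variant_id"].to_numpy(),
            "reason": reason[bad_any].to_numpy(),
        }
    )
    if len(rejected):
        log.warning(
            "%s: rejected %d row(s) violating record invariants: %s",
            name,
            len(rejected),
            rejected.to_dict("records"),
        )
    clean = out.loc[~bad_any].reset_index(drop=True)
    dup = clean["variant_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{name}: duplicated variant_id(s): {sorted(clean.loc[dup, 'variant_id'].unique())}"
        )
    return clean, rejected


def read_gwas(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-statistic file into the canonical layout.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from canonical name (e.g. ``"variant_id"``) to the
        column name used in the file (e.g. ``"SNP"``), for dialects such as
        IEU-style headers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)
    clean, _ = validate_gwas(raw, name=str(path))
    return clean


def write_gwas(df: pd.DataFrame, path: str | Path) -> None:
    """Write a GWAS table as TSV in the canonical column order."""
    df.loc[:, list(GWAS_COLUMNS)].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedTable:
    """Exposure and outcome effects aligned to the exposure's effect allele.

    ``table`` has one row per retained variant with ``*_exp`` / ``*_out``
    statistics; ``drops`` is the ledger mapping each excluded variant to a
    reason code. Retained and dropped sets partition the exposure variants
    considered for the merge.
    """

    table: pd.DataFrame
    drops: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def write(self, prefix: str | Path) -> None:
        """Write the aligned table to ``<prefix>.tsv`` and the drop ledger to
        ``<prefix>.drops.tsv``."""
        prefix = Path(prefix)
        self.table.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        self.drops.to_csv(
            prefix.with_name(prefix.name + ".drops.tsv"), sep="\t", index=False
        )


_HARMONIZED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf_exp",
    "beta_exp",
    "se_exp",
    "p_exp",
    "n_exp",
    "eaf_out",
    "beta_out",
    "se_out",
    "p_out",
    "n_out",
]


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    drop_palindromes: bool = True,
    infer_palindromes: bool = False,
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedTable:
    """Align outcome effects to the exposure's effect allele.

    Matching is by ``variant_id``. For each shared variant:

    * identical allele pair -> kept as-is;
    * swapped pair (outcome effect allele equals exposure other allele and
      vice versa) -> outcome beta negated, outcome EAF complemented;
    * any other pair -> dropped as ``incompatible_alleles``;
    * palindromic pair -> dropped as ``palindromic`` when
      ``drop_palindromes`` (the default), since strand cannot be resolved.

    With ``drop_palindromes=False`` and ``infer_palindromes=True``,
    palindromic variants are kept when both studies' EAF fall outside
    ``eaf_window`` and the frequencies identify the strand; ambiguous ones
    (EAF inside the window) are still dropped.

    An empty intersection is not an error: an empty table is returned and a
    warning logged.
    """
    exp = exposure
    out = outcome
    in_outcome = exp["variant_id"].isin(set(out["variant_id"]))
    drops: list[pd.DataFrame] = []
    if (~in_outcome).any():
        drops.append(
            pd.DataFrame(
                {
                    "variant_id": exp.loc[~in_outcome, "variant_id"].to_numpy(),
                    "reason": DROP_NOT_IN_OUTCOME,
                }
            )
        )
    m = exp.merge(out, on="variant_id", suffixes=("_exp", "_out"))
    if m.empty:
        log.warning("harmonize: no shared variants between exposure and outcome")
        return HarmonizedTable(
            table=pd.DataFrame(columns=_HARMONIZED_COLUMNS),
            drops=_concat_drops(drops),
        )

    ea_e = m["effect_allele_exp"]
    oa_e = m["other_allele_exp"]
    ea_o = m["effect_allele_out"]
    oa_o = m["other_allele_out"]

    same = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    pair = ea_e + oa_e
    palindromic = pair.isin(["AT", "TA", "CG", "GC"])
    incompatible = ~(same | swapped)

    beta_out = m["beta_out"].to_numpy(copy=True)
    eaf_out = m["eaf_out"].to_numpy(copy=True)
    flip = swapped.to_numpy()
    beta_out[flip] = -beta_out[flip]
    eaf_out[flip] = 1.0 - eaf_out[flip]

    drop_mask = incompatible.copy()
    if (~incompatible & palindromic).any():
        pal_live = ~incompatible & palindromic
        if drop_palindromes:
            drop_mask |= pal_live
            pal_reason = pal_live
        elif infer_palindromes:
            lo, hi = eaf_window
            ambiguous = (
                ((m["eaf_exp"] >= lo) & (m["eaf_exp"] <= hi))
                | ((eaf_out >= lo) & (eaf_out <= hi))
            ) & pal_live
            drop_mask |= ambiguous
            pal_reason = ambiguous
            # Strand resolved by frequency: discordant minor-allele side means
            # the outcome is on the opposite strand -> flip sign and frequency.
            discord = (
                pal_live
                & ~ambiguous
                & ((m["eaf_exp"] - 0.5) * (eaf_out - 0.5) < 0)
            ).to_numpy()
            beta_out[discord] = -beta_out[discord]
            eaf_out[discord] = 1.0 - eaf_out[discord]
            pal_reason = pal_reason
        else:
            pal_reason = pd.Series(False, index=m.index)
    else:
        pal_reason = pd.Series(False, index=m.index)

    if incompatible.any():
        drops.append(
            pd.DataFrame(
                {
                    "variant_id": m.loc[incompatible, "variant_id"].to_numpy(),
                    "reason": DROP_INCOMPATIBLE,
                }
            )
        )
    if pal_reason.any():
        drops.append(
            pd.DataFrame(
                {
                    "variant_id": m.loc[pal_reason, "variant_id"].to_numpy(),
                    "reason": DROP_PALINDROMIC,
                }
            )
        )

    keep = ~drop_mask
    table = pd.DataFrame(
        {
            "variant_id": m.loc[keep, "variant_id"].to_numpy(),
            "chrom": m.loc[keep, "chrom_exp"].to_numpy(),
            "pos": m.loc[keep, "pos_exp"].to_numpy(),
            "effect_allele": ea_e[keep].to_numpy(),
            "other_allele": oa_e[keep].to_numpy(),
            "eaf_exp": m.loc[keep, "eaf_exp"].to_numpy(),
            "beta_exp": m.loc[keep, "beta_exp"].to_numpy(),
            "se_exp": m.loc[keep, "se_exp"].to_numpy(),
            "p_exp": m.loc[keep, "pvalue_exp"].to_numpy(),
            "n_exp": m.loc[keep, "n_exp"].to_numpy(),
            "eaf_out": eaf_out[keep.to_numpy()],
            "beta_out": beta_out[keep.to_numpy()],
            "se_out": m.loc[keep, "se_out"].to_numpy(),
            "p_out": m.loc[keep, "pvalue_out"].to_numpy(),
            "n_out": m.loc[keep, "n_out"].to_numpy(),
        }
    )
    return HarmonizedTable(table=table, drops=_concat_drops(drops))


def _concat_drops(frames: list[pd.DataFrame]) -> pd.DataFrame:
    if not frames:
        return pd.DataFrame(columns=["variant_id", "reason"])
    return pd.concat(frames, ignore_index=True)
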