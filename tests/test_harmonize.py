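"""I/O validation and effect-allele harmonization rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrchain import (
    FormatError,
    ValidationError,
    harmonize,
    is_palindromic,
    read_gwas,
    validate_gwas,
    write_gwas,
)
from tests.conftest import make_gwas


@pytest.mark.parametrize(
    "ea,oa,expected",
    [
        ("A", "T", True),
        ("T", "A", True),
        ("C", "G", True),
        ("G", "C", True),
        ("A", "G", False),
        ("A", "C", False),
        ("T", "C", False),
        ("a", "t", True),  # case-insensitive
    ],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_is_palindromic_rejects_non_acgt():
    with pytest.raises(ValidationError):
        is_palindromic("A", "N")
    with pytest.raises(ValidationError):
        is_palindromic("AT", "G")


class TestReadWrite:
    def test_roundtrip(self, tmp_path):
        df = make_gwas(["rs1", "rs2", "rs3"], [0.1, -0.2, 0.05], [0.01, 0.02, 0.01])
        path = tmp_path / "gwas.tsv"
        write_gwas(df, path)
        back = read_gwas(path)
        np.testing.assert_allclose(back["beta"], df["beta"])
        np.testing.assert_allclose(back["se"], df["se"])
        assert list(back["variant_id"]) == list(df["variant_id"])

    def test_missing_se_column_names_it(self, tmp_path):
        df = make_gwas(["rs1"], [0.1], [0.01]).drop(columns=["se"])
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="se"):
            read_gwas(path)

    def test_column_map_dialect(self, tmp_path):
        df = make_gwas(["rs1"], [0.1], [0.01]).rename(
            columns={"variant_id": "SNP", "pvalue": "P"}
        )
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_gwas(path, column_map={"variant_id": "SNP", "pvalue": "P"})
        assert back["variant_id"].iloc[0] == "rs1"

    def test_unparsable_numeric_lists_rows(self, tmp_path):
        df = make_gwas(["rs1", "rs2"], [0.1, 0.2], [0.01, 0.01]).astype({"beta": object})
        df.loc[1, "beta"] = "oops"
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="beta"):
            read_gwas(path)


class TestValidate:
    def test_eaf_out_of_range_rejected_with_reason(self):
        df = make_gwas(["rs1", "rs2"], [0.1, 0.2], [0.01, 0.01], eaf=[0.3, 1.2])
        clean, rejected = validate_gwas(df)
        assert list(clean["variant_id"]) == ["rs1"]
        assert rejected.iloc[0]["variant_id"] == "rs2"
        assert rejected.iloc[0]["reason"] == "eaf_out_of_range"

    def test_indel_rejected(self):
        df = make_gwas(["rs1"], [0.1], [0.01], effect_allele=["AT"], other_allele=["A"])
        clean, rejected = validate_gwas(df)
        assert clean.empty
        assert rejected.iloc[0]["reason"] == "invalid_allele"

    def test_identical_alleles_rejected(self):
        df = make_gwas(["rs1"], [0.1], [0.01], effect_allele=["A"], other_allele=["A"])
        _, rejected = validate_gwas(df)
        assert rejected.iloc[0]["reason"] == "identical_alleles"

    def test_duplicate_variant_id_raises(self):
        df = make_gwas(["rs1", "rs1"], [0.1, 0.2], [0.01, 0.01])
        with pytest.raises(ValidationError, match="rs1"):
            validate_gwas(df)

    def test_nonpositive_se_rejected(self):
        df = make_gwas(["rs1"], [0.1], [0.01])
        df.loc[0, "se"] = 0.0
        _, rejected = validate_gwas(df)
        assert rejected.iloc[0]["reason"] == "nonpositive_se"


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_gwas(["rs1"], [0.10], [0.01], effect_allele=["A"], other_allele=["G"])
        out = make_gwas(
            ["rs1"], [-0.05], [0.02], eaf=[0.7], effect_allele=["G"], other_allele=["A"]
        )
        h = harmonize(exp, out)
        assert h.n_snps == 1
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.05)
        assert h.table["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_incompatible_alleles_dropped(self):
        exp = make_gwas(["rs1"], [0.1], [0.01], effect_allele=["A"], other_allele=["G"])
        out = make_gwas(["rs1"], [0.1], [0.01], effect_allele=["C"], other_allele=["T"])
        h = harmonize(exp, out)
        assert h.n_snps == 0
        assert h.drops.iloc[0]["reason"] == "incompatible_alleles"

    def test_palindromic_dropped_when_requested(self):
        exp = make_gwas(["rs1"], [0.1], [0.01], effect_allele=["A"], other_allele=["T"])
        out = make_gwas(["rs1"], [0.1], [0.01], effect_allele=["A"], other_allele=["T"])
        h = harmonize(exp, out, drop_palindromes=True)
        assert h.n_snps == 0
        assert h.drops.iloc[0]["reason"] == "palindromic"
        kept = harmonize(exp, out, drop_palindromes=False)
        assert kept.n_snps == 1

    def test_not_in_outcome_ledgered(self):
        exp = make_gwas(["rs1", "rs2"], [0.1, 0.2], [0.01, 0.01])
        out = make_gwas(["rs1"], [0.1], [0.01])
        h = harmonize(exp, out)
        assert h.n_snps == 1
        assert set(h.drops["variant_id"]) == {"rs2"}
        assert (h.drops["reason"] == "not_in_outcome").all()

    def test_empty_intersection_returns_empty_not_error(self):
        exp = make_gwas(["rs1"], [0.1], [0.01])
        out = make_gwas(["rs9"], [0.1], [0.01])
        h = harmonize(exp, out)
        assert h.n_snps == 0
        assert set(h.drops["reason"]) == {"not_in_outcome"}

    def test_idempotent_on_aligned_pair(self, chain):
        _, gx, gy, _, _ = chain
        h1 = harmonize(gx, gy)
        # Rebuild outcome restricted to the kept variants: alleles already aligned.
        kept = gy[gy["variant_id"].isin(h1.table["variant_id"])].reset_index(drop=True)
        h2 = harmonize(gx[gx["variant_id"].isin(kept["variant_id"])].reset_index(drop=True), kept)
        np.testing.assert_allclose(h1.table["beta_out"], h2.table["beta_out"])
        np.testing.assert_allclose(h1.table["eaf_out"], h2.table["eaf_out"])

    def test_sign_coherence_under_outcome_allele_flip(self, chain):
        """Flipping every outcome record's alleles, beta and EAF before
        harmonization yields an identical harmonized table."""
        _, gx, gy, _, _ = chain
        flipped = gy.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            gy["other_allele"],
            gy["effect_allele"],
        )
        flipped["beta"] = -gy["beta"]
        flipped["eaf"] = 1 - gy["eaf"]
        h_ref = harmonize(gx, gy)
        h_flip = harmonize(gx, flipped)
        assert list(h_ref.table["variant_id"]) == list(h_flip.table["variant_id"])
        np.testing.assert_allclose(h_ref.table["beta_out"], h_flip.table["beta_out"], atol=1e-15)
        np.testing.assert_allclose(h_ref.table["eaf_out"], h_flip.table["eaf_out"], atol=1e-15)

    def test_retained_and_dropped_partition_inputs(self, chain):
        _, gx, gy, _, _ = chain
        h = harmonize(gx, gy)
        retained = set(h.table["variant_id"])
        dropped = set(h.drops["variant_id"])
        assert retained | dropped == set(gx["variant_id"])
        assert retained & dropped == set()

    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
        swap=st.booleans(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_harmonized_outcome_effect_matches_orientation(self, beta, eaf, swap):
        exp = make_gwas(["rs1"], [0.1], [0.01], effect_allele=["A"], other_allele=["G"])
        if swap:
            out = make_gwas(
                ["rs1"], [beta], [0.01], eaf=[eaf],
                effect_allele=["G"], other_allele=["A"],
            )
            expected_beta, expected_eaf = -beta, 1 - eaf
        else:
            out = make_gwas(
                ["rs1"], [beta], [0.01], eaf=[eaf],
                effect_allele=["A"], other_allele=["G"],
            )
            expected_beta, expected_eaf = beta, eaf
        h = harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(expected_beta, abs=1e-12)
        assert h.table["eaf_out"].iloc[0] == pytest.approx(expected_eaf, abs=1e-12)


def test_palindrome_inference_mode():
    """With inference on, unambiguous palindromes are strand-resolved by
    frequency and ambiguous ones (EAF near 0.5) are dropped."""
    exp = make_gwas(
        ["rs1", "rs2"], [0.1, 0.1], [0.01, 0.01], eaf=[0.1, 0.5],
        effect_allele=["A", "C"], other_allele=["T", "G"],
    )
    out = make_gwas(
        ["rs1", "rs2"], [0.2, 0.2], [0.01, 0.01], eaf=[0.9, 0.5],
        effect_allele=["A", "C"], other_allele=["T", "G"],
    )
    h = harmonize(exp, out, drop_palindromes=False, infer_palindromes=True)
    # rs1: exposure minor side differs from outcome -> opposite strand, flipped.
    assert h.n_snps == 1
    assert h.table["beta_out"].iloc[0] == pytest.approx(-0.2)
    assert h.table["eaf_out"].iloc[0] == pytest.approx(0.1)
    assert set(h.drops["variant_id"]) == {"rs2"}
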