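"""Reading, validation and allele harmonization of summary statistics."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomr.sumstats import (
    AnalysisError,
    ConfigurationError,
    InputError,
    SummaryStatTable,
    harmonize,
    is_palindromic,
    read_sumstats,
    write_sumstats,
)

TSV = "SNP\tCHR\tBP\tA1\tA2\tEAF\tBETA\tSE\tP\tN\n"


def _tsv(rows):
    return io.StringIO(TSV + "\n".join("\t".join(map(str, r)) for r in rows))


def table_from(rows, name="trait"):
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pvalue", "n"],
    )
    df.index = pd.Index(df["variant_id"])
    df.index.name = None
    return SummaryStatTable(name, df)


class TestReadSumstats:
    def test_well_formed_table_ingested_identically(self):
        t = read_sumstats(_tsv([
            ("rs1", 1, 100, "A", "G", 0.2, 0.10, 0.02, 1e-9, 1000),
            ("rs2", 1, 200, "C", "T", 0.3, -0.05, 0.01, 1e-8, 1000),
            ("rs3", 2, 300, "G", "T", 0.4, 0.02, 0.02, 0.3, 1000),
        ]))
        assert len(t) == 3 and t.n_dropped == 0
        assert t.records.loc["rs2", "beta"] == -0.05

    def test_nonpositive_se_row_dropped_and_counted(self):
        t = read_sumstats(_tsv([
            ("rs1", 1, 100, "A", "G", 0.2, 0.10, 0.02, 1e-9, 1000),
            ("rs2", 1, 200, "C", "T", 0.3, -0.05, 0.0, 1e-8, 1000),
        ]))
        assert len(t) == 1 and t.n_dropped == 1
        assert t.drop_log == [("rs2", "nonpositive_se")]

    def test_lowercase_alleles_uppercased(self):
        t = read_sumstats(_tsv([("rs1", 1, 100, "a", "g", 0.2, 0.1, 0.02, 1e-9, 1000)]))
        rec = t.records.loc["rs1"]
        assert (rec["effect_allele"], rec["other_allele"]) == ("A", "G")

    def test_missing_mandatory_column_names_it(self):
        bad = io.StringIO("SNP\tA1\tA2\tBETA\nrs1\tA\tG\t0.1\n")
        with pytest.raises(ConfigurationError, match="SE"):
            read_sumstats(bad)

    def test_empty_file_is_input_error(self):
        with pytest.raises(InputError):
            read_sumstats(io.StringIO(""))

    def test_comma_delimiter_autodetected(self):
        t = read_sumstats(io.StringIO(
            "SNP,CHR,BP,A1,A2,EAF,BETA,SE,P,N\nrs1,1,100,A,G,0.2,0.1,0.02,1e-9,1000\n"
        ))
        assert len(t) == 1

    def test_roundtrip_through_writer(self, tmp_path):
        t = read_sumstats(_tsv([("rs1", 1, 100, "A", "G", 0.2, 0.1, 0.02, 1e-9, 1000)]))
        out = tmp_path / "sumstats.tsv"
        write_sumstats(t, out)
        t2 = read_sumstats(out)
        pd.testing.assert_frame_equal(t.records, t2.records, check_dtype=False)


class TestPalindromic:
    @pytest.mark.parametrize(
        "ea,oa,expected",
        [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
         ("A", "G", False), ("C", "T", False), ("a", "t", True)],
    )
    def test_definition(self, ea, oa, expected):
        assert is_palindromic(ea, oa) is expected

    def test_invalid_symbol_rejected(self):
        with pytest.raises(InputError):
            is_palindromic("A", "N")


def _pair(beta_out=-0.05, ea_out="G", oa_out="A", p_out=0.5):
    exp = table_from([("rs1", "1", 100, "A", "G", 0.2, 0.10, 0.02, 1e-9, 1000)])
    out = table_from([("rs1", "1", 100, ea_out, oa_out, 0.8, beta_out, 0.02, p_out, 1000)],
                     name="out")
    return exp, out


class TestHarmonize:
    def test_swapped_alleles_force_sign_flip(self):
        exp, out = _pair()
        h = harmonize(exp, out, ["rs1"])
        assert h.beta_out[0] == pytest.approx(0.05)
        assert h.beta_exp[0, 0] == pytest.approx(0.10)

    def test_strand_complement_match(self):
        # outcome reported on the other strand: A/G vs T/C
        exp, _ = _pair()
        out = table_from([("rs1", "1", 100, "T", "C", 0.2, 0.07, 0.02, 0.5, 1000)], "out")
        h = harmonize(exp, out, ["rs1"])
        assert h.beta_out[0] == pytest.approx(0.07)

    def test_palindromic_dropped(self):
        exp = table_from([("rs2", "1", 100, "A", "T", 0.2, 0.10, 0.02, 1e-9, 1000)])
        out = table_from([("rs2", "1", 100, "A", "T", 0.2, 0.05, 0.02, 0.5, 1000)], "out")
        with pytest.raises(AnalysisError):
            harmonize(exp, out, ["rs2"])  # all dropped -> error listing reasons
        exp2, out2 = _pair()
        exp2.records = pd.concat([exp2.records, exp.records])
        out2.records = pd.concat([out2.records, out.records])
        h = harmonize(exp2, out2, ["rs1", "rs2"])
        assert ("rs2", "palindromic") in h.dropped and h.variant_ids == ["rs1"]

    def test_direct_effect_on_outcome_dropped(self):
        exp, out = _pair()
        exp3 = table_from([("rs3", "1", 300, "A", "G", 0.2, 0.10, 0.02, 1e-9, 1000)])
        out3 = table_from([("rs3", "1", 300, "A", "G", 0.2, 0.12, 0.02, 1e-9, 1000)], "out")
        exp.records = pd.concat([exp.records, exp3.records])
        out.records = pd.concat([out.records, out3.records])
        h = harmonize(exp, out, ["rs1", "rs3"])
        assert ("rs3", "direct_effect") in h.dropped

    def test_irreconcilable_alleles_dropped(self):
        exp, _ = _pair()
        out = table_from([("rs1", "1", 100, "A", "C", 0.2, 0.05, 0.02, 0.5, 1000)], "out")
        with pytest.raises(AnalysisError, match="allele_mismatch"):
            harmonize(exp, out, ["rs1"])

    def test_missing_in_outcome_dropped_with_reason(self):
        exp, out = _pair()
        exp2 = table_from([("rs9", "1", 900, "A", "G", 0.2, 0.1, 0.02, 1e-9, 1000)])
        exp.records = pd.concat([exp.records, exp2.records])
        h = harmonize(exp, out, ["rs1", "rs9"])
        assert ("rs9", "missing_in_outcome") in h.dropped

    def test_drop_accounting(self):
        exp, out = _pair()
        h = harmonize(exp, out, ["rs1"])
        assert len(h.variant_ids) + len(h.dropped) == 1

    def test_idempotent_on_aligned_input(self):
        exp, out = _pair(beta_out=0.05, ea_out="A", oa_out="G")
        h1 = harmonize(exp, out, ["rs1"])
        h2 = harmonize(exp, out, ["rs1"])
        np.testing.assert_array_equal(h1.beta_out, h2.beta_out)
        assert h1.variant_ids == h2.variant_ids

    def test_sign_symmetry_of_input_representation(self):
        # flipping effect/other alleles AND beta sign leaves the result unchanged
        exp, out = _pair()
        h1 = harmonize(exp, out, ["rs1"])
        flipped = out.records.copy()
        flipped.loc["rs1", ["effect_allele", "other_allele"]] = ["A", "G"]
        flipped.loc["rs1", "beta"] = 0.05
        h2 = harmonize(exp, SummaryStatTable("out", flipped), ["rs1"])
        np.testing.assert_allclose(h1.beta_out, h2.beta_out)
        np.testing.assert_allclose(h1.beta_exp, h2.beta_exp)


@settings(max_examples=30, deadline=None)
@given(
    beta=st.floats(-1, 1, allow_nan=False),
    swap=st.booleans(),
)
def test_harmonized_outcome_beta_invariant_under_reporting_convention(beta, swap):
    """The harmonized outcome effect is a function of the variant, not of
    which allele the outcome GWAS happened to report as the effect allele."""
    exp = table_from([("rs1", "1", 100, "A", "G", 0.2, 0.10, 0.02, 1e-9, 1000)])
    if swap:
        out = table_from([("rs1", "1", 100, "G", "A", 0.8, -beta, 0.02, 0.5, 1000)], "o")
    else:
        out = table_from([("rs1", "1", 100, "A", "G", 0.2, beta, 0.02, 0.5, 1000)], "o")
    h = harmonize(exp, out, ["rs1"], direct_effect_p=0.0)
    assert h.beta_out[0] == pytest.approx(beta, abs=1e-12)
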