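import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbayess.sumstats import (MHC_DEFAULT, SummaryDataError, SummaryDataset,
                              compute_scaling, match_to_reference, qc_filter,
                              read_ma)


def make_ds(**cols):
    base = dict(SNP=["s1"], A1=["A"], A2=["G"], freq=[0.3], b=[0.1],
                se=[0.02], p=[0.5], N=[1000.0])
    base.update(cols)
    return SummaryDataset(df=pd.DataFrame(base))


class TestReadMa:
    def test_reads_rows_in_file_order(self, small_ma):
        ds = read_ma(small_ma)
        assert len(ds) == 3
        assert list(ds.df["SNP"]) == ["rs1", "rs2", "rs3"]
        assert list(ds.df["freq"]) == [0.5, 0.1, 0.3]

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "no_n.ma"
        path.write_text("SNP A1 A2 freq b se p\nrs1 A G 0.5 0.1 0.02 0.5\n")
        with pytest.raises(SummaryDataError, match="N"):
            read_ma(path)

    def test_nonpositive_se_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad_se.ma"
        path.write_text("SNP A1 A2 freq b se p N\n"
                        "rs1 A G 0.5 0.1 0.02 0.5 1000\n"
                        "rs2 A G 0.5 0.1 0.0 0.5 1000\n")
        with pytest.raises(SummaryDataError, match="standard error.*row 2"):
            read_ma(path)

    def test_non_numeric_field_reports_row(self, tmp_path):
        path = tmp_path / "bad_num.ma"
        path.write_text("SNP A1 A2 freq b se p N\n"
                        "rs1 A G xx 0.1 0.02 0.5 1000\n")
        with pytest.raises(SummaryDataError, match="freq.*row 1"):
            read_ma(path)

    def test_round_trip(self, small_ma, tmp_path):
        ds = read_ma(small_ma)
        out = tmp_path / "rt.ma"
        ds.write_ma(out)
        ds2 = read_ma(out)
        pd.testing.assert_frame_equal(ds.df, ds2.df)


class TestQcFilter:
    def test_low_maf_removed(self):
        ds = make_ds(SNP=["a", "b"], A1=["A", "A"], A2=["G", "G"],
                     freq=[0.005, 0.3], b=[0.1, 0.1], se=[0.02, 0.02],
                     p=[0.5, 0.5], N=[1000.0, 1000.0])
        out = qc_filter(ds, maf_min=0.01)
        assert list(out.df["SNP"]) == ["b"]
        assert out.qc.removed["MAF below threshold"] == 1

    @pytest.mark.parametrize("a1,a2,kept", [
        ("A", "T", False), ("C", "G", False), ("G", "C", False),
        ("A", "G", True), ("C", "T", True)])
    def test_strand_ambiguous_pairs(self, a1, a2, kept):
        ds = make_ds(SNP=["x", "keep"], A1=[a1, "A"], A2=[a2, "C"],
                     freq=[0.3, 0.3], b=[0.1, 0.1], se=[0.02, 0.02],
                     p=[0.5, 0.5], N=[1000.0, 1000.0])
        out = qc_filter(ds, drop_ambiguous=True)
        assert ("x" in set(out.df["SNP"])) == kept

    def test_mhc_interval_removed(self):
        ds = make_ds(SNP=["in_mhc", "out"], A1=["A", "A"], A2=["G", "G"],
                     freq=[0.3, 0.3], b=[0.1, 0.1], se=[0.02, 0.02],
                     p=[0.5, 0.5], N=[1000.0, 1000.0])
        ds.df["chrom"] = ["6", "6"]
        ds.df["pos"] = [30_000_000, 50_000_000]
        out = qc_filter(ds, mhc=MHC_DEFAULT)
        assert list(out.df["SNP"]) == ["out"]

    def test_all_removed_raises(self):
        ds = make_ds(freq=[0.001])
        with pytest.raises(SummaryDataError, match="every SNP"):
            qc_filter(ds, maf_min=0.01)


class TestMatchToReference:
    def test_swapped_alleles_flip_effect_and_freq(self, ref_map):
        # GWAS orientation (A, G) at rs1 vs reference (A, G): same; craft a
        # swapped record at rs2 where reference is (T, C)
        ds = make_ds(SNP=["rs2"], A1=["C"], A2=["T"], freq=[0.12], b=[0.07])
        out = match_to_reference(ds, ref_map)
        assert out.df.loc[0, "b"] == pytest.approx(-0.07)
        assert out.df.loc[0, "freq"] == pytest.approx(0.88)

    def test_flip_is_involution(self, ref_map):
        ds = make_ds(SNP=["rs2"], A1=["C"], A2=["T"], freq=[0.12], b=[0.07])
        once = match_to_reference(ds, ref_map)
        flipped_map = ref_map.copy()
        flipped_map.loc[flipped_map["SNP"] == "rs2", ["A1", "A2"]] = ["C", "T"]
        flipped_map.loc[flipped_map["SNP"] == "rs2", "freq"] = 0.12
        twice = match_to_reference(once, flipped_map)
        assert twice.df.loc[0, "b"] == pytest.approx(0.07)
        assert twice.df.loc[0, "freq"] == pytest.approx(0.12)

    def test_absent_snp_dropped_and_counted(self, ref_map):
        ds = make_ds(SNP=["rs1", "nope"], A1=["A", "A"], A2=["G", "G"],
                     freq=[0.5, 0.3], b=[0.1, 0.1], se=[0.02, 0.02],
                     p=[0.5, 0.5], N=[1000.0, 1000.0])
        out = match_to_reference(ds, ref_map)
        assert list(out.df["SNP"]) == ["rs1"]
        assert out.qc.removed["absent from reference"] == 1

    def test_frequency_discordance_dropped(self, ref_map):
        ds = make_ds(SNP=["rs4"], A1=["C"], A2=["A"], freq=[0.45])
        with pytest.raises(SummaryDataError):
            match_to_reference(ds, ref_map, freq_diff_max=0.2)

    def test_zero_overlap_raises(self, ref_map):
        ds = make_ds(SNP=["zzz"])
        with pytest.raises(SummaryDataError, match="overlap"):
            match_to_reference(ds, ref_map)

    def test_output_follows_reference_order(self, ref_map):
        ds = make_ds(SNP=["rs3", "rs1"], A1=["G", "A"], A2=["A", "G"],
                     freq=[0.31, 0.5], b=[0.1, 0.1], se=[0.02, 0.02],
                     p=[0.5, 0.5], N=[1000.0, 1000.0])
        out = match_to_reference(ds, ref_map)
        assert list(out.df["SNP"]) == ["rs1", "rs3"]


class TestComputeScaling:
    def test_d_jj_arithmetic(self):
        ds = make_ds(freq=[0.5], N=[100.0])
        assert ds.d[0] == pytest.approx(50.0)

    def test_single_snp_yty_by_hand(self):
        # D = 50; n se^2 + b^2 = 100 * 0.02 + 0 = 2; yty = 100
        ds = make_ds(freq=[0.5], N=[100.0], b=[0.0], se=[np.sqrt(1 / 50)])
        out = compute_scaling(ds)
        assert out.yty == pytest.approx(100.0)

    def test_yty_permutation_invariant(self, rng):
        m = 20
        df = pd.DataFrame({
            "SNP": [f"s{i}" for i in range(m)], "A1": "A", "A2": "G",
            "freq": rng.uniform(0.05, 0.5, m), "b": rng.normal(0, 0.05, m),
            "se": rng.uniform(0.01, 0.05, m), "p": rng.uniform(0.001, 1, m),
            "N": 1000.0,
        })
        ds = compute_scaling(SummaryDataset(df=df))
        perm = df.sample(frac=1, random_state=1).reset_index(drop=True)
        ds2 = compute_scaling(SummaryDataset(df=perm))
        assert ds.yty == pytest.approx(ds2.yty)

    @settings(max_examples=25, deadline=None)
    @given(freq=st.floats(0.01, 0.99), n=st.integers(10, 100_000))
    def test_d_positive_for_valid_records(self, freq, n):
        ds = make_ds(freq=[freq], N=[float(n)])
        assert ds.d[0] > 0

    def test_simulated_standardized_phenotype_has_unit_variance(self, recovery_data):
        ds, _ = recovery_data
        n = ds.df["N"].median()
        assert ds.yty / n == pytest.approx(1.0, abs=0.05)
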