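"""Summary-statistic parsing, QC, alignment and sufficient-statistic
reconstruction."""

import numpy as np
import pandas as pd
import pytest

import sbayesr as sb
from sbayesr.sumstats import read_regions

from conftest import make_sumstats


def _write_ma(tmp_path, rows, header="SNP A1 A2 freq b se p N"):
    path = tmp_path / "test.ma"
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadMa:
    def test_well_formed_two_rows(self, tmp_path):
        path = _write_ma(tmp_path, [
            "rs1 a g 0.3 0.1 0.05 0.04 1000",
            "rs2 C T 0.5 -0.05 0.04 0.2 1200",
        ])
        ds = sb.read_ma(path)
        assert len(ds) == 2
        assert list(ds.A1) == ["A", "C"]  # upper-cased
        assert ds.b[1] == pytest.approx(-0.05)
        assert ds.n[0] == 1000

    def test_missing_se_column_is_format_error(self, tmp_path):
        path = _write_ma(tmp_path, ["rs1 A G 0.3 0.1 0.04 1000"],
                         header="SNP A1 A2 freq b p N")
        with pytest.raises(sb.FormatError, match="se"):
            sb.read_ma(path)

    def test_zero_se_row_rejected_with_warning(self, tmp_path, caplog):
        path = _write_ma(tmp_path, [
            "rs1 A G 0.3 0.1 0.0 0.04 1000",
            "rs2 C T 0.5 -0.05 0.04 0.2 1200",
        ])
        with caplog.at_level("WARNING"):
            ds = sb.read_ma(path)
        assert len(ds) == 1
        assert ds.snp_id[0] == "rs2"
        assert "rejected 1" in caplog.text

    def test_non_numeric_rows_rejected(self, tmp_path):
        path = _write_ma(tmp_path, [
            "rs1 A G 0.3 xx 0.05 0.04 1000",
            "rs2 C T 0.5 -0.05 0.04 0.2 1200",
        ])
        assert len(sb.read_ma(path)) == 1

    def test_duplicate_snp_id_raises(self, tmp_path):
        path = _write_ma(tmp_path, [
            "rs1 A G 0.3 0.1 0.05 0.04 1000",
            "rs1 C T 0.5 -0.05 0.04 0.2 1200",
        ])
        with pytest.raises(sb.DuplicateSNPError, match="rs1"):
            sb.read_ma(path)


class TestQCFilter:
    def test_strand_ambiguous_removed(self, toy_sumstats):
        cfg = sb.QCConfig(maf_min=0.0, drop_ambiguous=True)
        out, counts = sb.qc_filter(toy_sumstats, cfg)
        # rs3 (C/T) kept, rs4 (A/T) ambiguous removed
        assert "rs4" not in out.snp_id
        assert counts["ambiguous"] == 1

    def test_maf_threshold(self, toy_sumstats):
        cfg = sb.QCConfig(maf_min=0.2, drop_ambiguous=False)
        out, counts = sb.qc_filter(toy_sumstats, cfg)
        assert set(out.snp_id) == {"rs1", "rs2", "rs4"}
        assert counts["maf"] == 1

    def test_sample_size_percentile_window(self):
        rng = np.random.default_rng(1)
        ds = make_sumstats(100, rng)
        ds.df["n"] = np.arange(1, 101, dtype=float)
        ds.df["freq"] = 0.3
        cfg = sb.QCConfig(maf_min=0.0, drop_ambiguous=False,
                          n_lower_pct=5, n_upper_pct=95)
        out, counts = sb.qc_filter(ds, cfg)
        kept_n = sorted(out.n)
        assert len(out) == 90
        assert kept_n[0] == 6 and kept_n[-1] == 95
        assert counts["sample_size"] == 10

    def test_region_exclusion_half_open(self):
        rng = np.random.default_rng(2)
        ds = make_sumstats(10, rng)
        ds.df["chrom"] = "1"
        ds.df["bp"] = np.arange(100, 1100, 100)
        cfg = sb.QCConfig(maf_min=0.0, drop_ambiguous=False,
                          exclude_regions=[("1", 300, 500)])
        out, counts = sb.qc_filter(ds, cfg)
        assert counts["region"] == 2  # bp 300 and 400; 500 survives (half-open)
        assert 500 in out.bp

    def test_no_filters_is_identity(self, toy_sumstats):
        cfg = sb.QCConfig(maf_min=0.0, drop_ambiguous=False)
        out, _ = sb.qc_filter(toy_sumstats, cfg)
        pd.testing.assert_frame_equal(out.df, toy_sumstats.df)

    def test_idempotent(self):
        # the sample-size band is defined relative to the current n
        # distribution, so idempotence holds for the threshold rules
        rng = np.random.default_rng(3)
        ds = make_sumstats(200, rng)
        ds.df["chrom"] = "1"
        ds.df["bp"] = np.arange(200) * 1000 + 1
        cfg = sb.QCConfig(maf_min=0.05, drop_ambiguous=True,
                          exclude_regions=[("1", 1, 20000)])
        once, _ = sb.qc_filter(ds, cfg)
        twice, _ = sb.qc_filter(once, cfg)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_all_removed_raises(self, toy_sumstats):
        cfg = sb.QCConfig(maf_min=0.5, drop_ambiguous=True)
        with pytest.raises(sb.EmptyResultError):
            sb.qc_filter(toy_sumstats, cfg)


class TestAlignToReference:
    def _ref(self, **kw):
        base = {
            "snp_id": ["rs1", "rs2"],
            "A1": ["A", "G"],
            "A2": ["G", "A"],
            "freq": [0.3, 0.5],
        }
        base.update(kw)
        return pd.DataFrame(base)

    def test_matching_orientation_unchanged(self, toy_sumstats):
        out, counts = sb.align_to_reference(toy_sumstats, self._ref())
        rs1 = out.df.set_index("snp_id").loc["rs1"]
        assert rs1["b"] == pytest.approx(0.1)
        assert counts["matched"] == 2

    def test_swapped_alleles_flip_effect_and_freq(self, toy_sumstats):
        ref = self._ref(A1=["G", "A"], A2=["A", "G"], freq=[0.7, 0.5])
        out, counts = sb.align_to_reference(toy_sumstats, ref)
        rs1 = out.df.set_index("snp_id").loc["rs1"]
        assert rs1["b"] == pytest.approx(-0.1)
        assert rs1["freq"] == pytest.approx(0.7)
        assert counts["flipped"] == 2

    def test_allele_mismatch_dropped(self, toy_sumstats):
        ref = pd.DataFrame({"snp_id": ["rs1", "rs2"], "A1": ["C", "G"],
                            "A2": ["T", "A"], "freq": [0.3, 0.5]})
        out, counts = sb.align_to_reference(toy_sumstats, ref)
        assert counts["allele_mismatch"] == 1
        assert list(out.snp_id) == ["rs2"]

    def test_flip_is_involution(self, toy_sumstats):
        ref = self._ref()
        swapped = ref.assign(A1=ref["A2"], A2=ref["A1"], freq=1 - ref["freq"])
        once, _ = sb.align_to_reference(toy_sumstats, swapped)
        back, _ = sb.align_to_reference(once, ref)
        orig = toy_sumstats.df.set_index("snp_id").loc[back.snp_id]
        np.testing.assert_allclose(back.b, orig["b"].to_numpy())
        np.testing.assert_allclose(back.freq, orig["freq"].to_numpy())

    def test_zero_overlap_raises(self, toy_sumstats):
        ref = self._ref(snp_id=["rsX", "rsY"])
        with pytest.raises(sb.EmptyResultError):
            sb.align_to_reference(toy_sumstats, ref)

    def test_freq_mismatch_warns_and_optionally_drops(self, toy_sumstats, caplog):
        ref = self._ref(freq=[0.9, 0.5])
        with caplog.at_level("WARNING"):
            out, counts = sb.align_to_reference(toy_sumstats, ref)
        assert counts["freq_mismatch"] == 1
        assert len(out) == 2  # warn only by default
        out2, _ = sb.align_to_reference(toy_sumstats, ref, drop_freq_mismatch=True)
        assert len(out2) == 1


class TestReconstruction:
    def test_D_centred_formula(self, toy_sumstats):
        D = sb.reconstruct_D(toy_sumstats, scaled=False)
        # b=0.1, se=0.05, n=1000 -> 1/(0.0025 + 1e-5)
        assert D[0] == pytest.approx(1.0 / 0.00251, rel=1e-12)
        assert D[0] == pytest.approx(398.406, abs=5e-4)
        # b=0 -> 1/se^2 = 400
        assert D[2] == pytest.approx(400.0)

    def test_D_scaled_is_n(self, toy_sumstats):
        np.testing.assert_allclose(sb.reconstruct_D(toy_sumstats, scaled=True),
                                   toy_sumstats.n)

    def test_sufficient_stats_fields(self, toy_sumstats):
        stats = sb.reconstruct_sufficient(toy_sumstats, scaled=False)
        D = sb.reconstruct_D(toy_sumstats, scaled=False)
        np.testing.assert_allclose(stats.Xty, D * toy_sumstats.b)
        assert stats.Xty[0] == pytest.approx(39.84, abs=0.01)
        assert stats.yty == stats.n_bar == 1000.0

    def test_median_n(self):
        rng = np.random.default_rng(4)
        ds = make_sumstats(3, rng)
        ds.df["n"] = [100.0, 100.0, 200.0]
        assert sb.reconstruct_sufficient(ds).n_bar == 100.0

    def test_zero_effects_give_zero_Xty(self, toy_sumstats):
        toy_sumstats.df["b"] = 0.0
        stats = sb.reconstruct_sufficient(toy_sumstats)
        np.testing.assert_array_equal(stats.Xty, np.zeros(4))

    def test_reconstructed_D_matches_true_XtX_diagonal(self, small_panel, small_trait):
        """On summaries produced by this package's own GWAS, the se-based
        D reconstruction recovers diag(X'X) of centred genotypes to 1%."""
        y = small_trait["y"]
        y = (y - y.mean()) / y.std()
        ds = sb.run_gwas(small_panel, y)
        D = sb.reconstruct_D(ds, scaled=False)
        X = small_panel.standardized(scale=False)
        true_diag = (X**2).sum(axis=0)
        np.testing.assert_allclose(D, true_diag, rtol=0.01)


def test_read_regions(tmp_path):
    path = tmp_path / "regions.txt"
    path.write_text("# MHC-like exclusion\n6 25000000 35000000\n1 100 200\n")
    assert read_regions(path) == [("6", 25000000, 35000000), ("1", 100, 200)]
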