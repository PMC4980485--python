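"""Variant table IO, the somatic LLR filter, CN masking and the LOD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import llr_oracle
from clonaldrift import vario
from clonaldrift.simdata import write_fixture


class TestVariantTableIO:
    def test_tsv_round_trip_is_byte_identical(self, stable_case, tmp_path):
        truth, reads = stable_case
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        vario.write_variant_table(reads, p1)
        df = vario.read_variant_table(p1)
        vario.write_variant_table(df, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_negative_counts_rejected_with_line_number(self, tmp_path):
        df = pd.DataFrame(
            [["C", "B1", "baseline", "1", 100, "A", "T", 10, -3, 20, 0, -1, -1, "", "", 1]],
            columns=vario.VARIANT_COLUMNS,
        )
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(vario.VariantTableError, match="line.*2"):
            vario.read_variant_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("case\tsample\nC\tB1\n")
        with pytest.raises(vario.VariantTableError, match="missing mandatory"):
            vario.read_variant_table(path)

    def test_vcf_matches_equivalent_tsv(self, tmp_path):
        import pysam

        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
        header.contigs.add("1", length=1_000_000)
        for s in ("NORMAL", "B1", "S1"):
            header.add_sample(s)
        path = tmp_path / "case.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            rec = vf.new_record(contig="1", start=99, stop=100, alleles=("A", "T"))
            rec.samples["NORMAL"]["AD"] = (50, 0)
            rec.samples["B1"]["AD"] = (60, 40)
            rec.samples["S1"]["AD"] = (80, 20)
            vf.write(rec)
        df = vario.read_vcf(path, "CASE1", timepoints={"B1": "baseline", "S1": "surgical"})
        assert len(df) == 2
        b1 = df.loc[df["sample"] == "B1"].iloc[0]
        assert (b1.pos, b1.ref, b1.alt) == (100, "A", "T")
        assert (b1.dna_ref_reads, b1.dna_var_reads) == (60, 40)
        assert (b1.normal_ref_reads, b1.normal_var_reads) == (50, 0)

    def test_fixture_round_trips_through_readers(self, monoclonal_case, tmp_path):
        truth, reads = monoclonal_case
        paths = write_fixture(reads, truth, tmp_path)
        back = vario.read_variant_table(paths["variants"])
        pd.testing.assert_frame_equal(back, reads.reset_index(drop=True), check_dtype=False)
        seg = vario.read_segments(paths["segments"])
        assert set(seg["sample"]) == set(truth.samples)
        assert (seg["copy_number"] == 2.0).all()


class TestSomaticLLRFilter:
    @pytest.mark.parametrize(
        "tumour, normal, retained, llr_sign",
        [
            ((70, 30), (100, 0), True, 1),    # clean somatic call
            ((50, 50), (50, 50), False, -1),  # germline heterozygous
            ((5, 4), (100, 0), False, 1),     # tumour depth 9 < 10
            ((100, 0), (100, 0), False, 0),   # wild type: degenerate, llr 0
        ],
    )
    def test_decisions(self, tumour, normal, retained, llr_sign):
        llr, kept = vario.llr_somatic_filter(tumour, normal)
        assert kept is retained
        assert np.sign(llr) == llr_sign

    def test_strong_somatic_llr_far_exceeds_cutoff(self):
        llr, _ = vario.llr_somatic_filter((70, 30), (100, 0))
        assert llr > 30

    @pytest.mark.parametrize("bad", [0.0, 0.5, -0.1, 0.7])
    def test_error_rate_domain(self, bad):
        with pytest.raises(ValueError):
            vario.llr_somatic_filter((10, 5), (10, 0), error_rate=bad)

    def test_grid_matches_direct_likelihood_evaluation(self):
        # exhaustive cross-check on a small grid; the full depth<=30 grid
        # runs in the acceptance suite
        for t_depth in range(10, 14):
            for t_var in range(t_depth + 1):
                for n_depth in (10, 12):
                    for n_var in (0, 1, n_depth // 2):
                        llr, kept = vario.llr_somatic_filter(
                            (t_depth - t_var, t_var), (n_depth - n_var, n_var)
                        )
                        expected = llr_oracle(t_depth - t_var, t_var, n_depth - n_var, n_var)
                        assert llr == pytest.approx(expected, abs=1e-9)
                        assert kept == (expected > 3.0)

    @given(
        depth=st.integers(20, 200),
        var_lo=st.integers(1, 50),
        extra=st.integers(1, 50),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotone_in_variant_reads_while_wild_type_dominates(
        self, depth, var_lo, extra
    ):
        """More variant reads never weaken the call against wild type.

        Monotonicity holds while the wild-type model is the best germline
        explanation; once the heterozygous branch takes over, the LLR must
        fall again as the tumour VAF approaches 0.5.
        """

        def branch_and_llr(var):
            e = 0.001
            t_mle = max(var / depth, e)
            ll_het = (
                var * np.log(0.5) + (depth - var) * np.log(0.5) + 50 * np.log(0.5)
            )
            ll_wt = (
                var * np.log(e)
                + (depth - var) * np.log(1 - e)
                + 50 * np.log(1 - e)
            )
            llr, _ = vario.llr_somatic_filter((depth - var, var), (50, 0))
            return ll_wt >= ll_het, llr

        var_lo = min(var_lo, depth - 1)
        var_hi = min(var_lo + extra, depth)
        if var_lo / depth <= 0.001:  # MLE must exceed the error rate
            return
        wt_lo, llr_lo = branch_and_llr(var_lo)
        wt_hi, llr_hi = branch_and_llr(var_hi)
        if wt_lo and wt_hi:
            assert llr_hi >= llr_lo - 1e-9


def _one_row(sample, timepoint, pos=100):
    return ["C", sample, timepoint, "1", pos, "A", "T", 60, 40, 50, 0, -1, -1, "", "", 1]


def _segments(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "copy_number"])


class TestCNNeutralMask:
    @pytest.mark.parametrize(
        "cn_b, cn_s, kept",
        [
            (2.0, 2.0, True),
            (2.25, 2.0, True),   # closed boundary
            (2.26, 2.0, False),
            (1.75, 2.25, True),
            (2.3, 3.1, False),
        ],
    )
    def test_margin_rule_over_all_samples(self, cn_b, cn_s, kept):
        df = pd.DataFrame([_one_row("B1", "baseline"), _one_row("S1", "surgical")],
                          columns=vario.VARIANT_COLUMNS)
        seg = _segments([["1", 0, 1000, "B1", cn_b], ["1", 0, 1000, "S1", cn_s]])
        out = vario.cn_neutral_mask(df, seg, 0.25)
        assert (len(out) == 2) is kept

    def test_uncovered_locus_defaults_to_diploid(self):
        df = pd.DataFrame([_one_row("B1", "baseline")], columns=vario.VARIANT_COLUMNS)
        seg = _segments([["2", 0, 1000, "B1", 5.0]])  # other chromosome
        assert len(vario.cn_neutral_mask(df, seg, 0.25)) == 1

    def test_infinite_margin_is_identity(self, stable_case):
        _, reads = stable_case
        seg = _segments([["1", 0, 10**9, s, 7.0] for s in reads["sample"].unique()])
        out = vario.cn_neutral_mask(reads, seg, np.inf)
        assert len(out) == len(reads)

    def test_contradictory_overlap_rejected(self):
        df = pd.DataFrame([_one_row("B1", "baseline")], columns=vario.VARIANT_COLUMNS)
        seg = _segments([["1", 0, 1000, "B1", 2.0], ["1", 500, 1500, "B1", 4.0]])
        with pytest.raises(vario.VariantTableError, match="contradictory"):
            vario.cn_neutral_mask(df, seg, 0.25)


@pytest.mark.parametrize(
    "value, present",
    [(0.009, False), (0.01, True), (0.0, False), (0.5, True), (1.0, True)],
)
def test_detection_limit_boundary(value, present):
    assert vario.apply_detection_limit(value) is present


def test_detection_limit_domain():
    with pytest.raises(ValueError):
        vario.apply_detection_limit(1.2)
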