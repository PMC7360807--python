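import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triadshift import (
    bh_adjust,
    call_expressed,
    call_qualitative,
    generate_dataset,
    proportion_test,
    tally_by_chromosome,
    test_differential as run_differential,
)
from triadshift.errors import DesignMismatchError, ValueOutOfRangeError

from _oracles import bh_step_up_brute, binom_two_sided_exact


class TestCallExpressed:
    def test_condition_specific_flags(self, toy_matrix):
        flags = call_expressed(toy_matrix, threshold=0.5)
        # g2: hexaploid mean 0, nonaploid mean 6 -> expressed in one condition only
        assert not flags.loc["g2", "hexaploid"]
        assert flags.loc["g2", "nonaploid"]
        assert flags.loc["g2", "overall"]
        # g5: means 0.1 and 0.1, both below threshold
        assert not flags.loc["g5", "overall"]

    def test_zero_threshold_any_positive_expressed(self, toy_matrix):
        flags = call_expressed(toy_matrix, threshold=0.0)
        assert flags["overall"].all()

    def test_all_zero_gene_not_expressed(self, toy_matrix):
        m = toy_matrix
        m.values.loc["g5"] = 0.0
        flags = call_expressed(m, threshold=0.5)
        assert not flags.loc["g5"].any()


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_hand_computed_step_up(self, raw, expected):
        assert np.allclose(bh_adjust(raw), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueOutOfRangeError):
            bh_adjust([0.5, 1.5])

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            p = rng.random(n)
            assert np.allclose(bh_adjust(p), bh_step_up_brute(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=50)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()


class TestWelchDifferential:
    def test_identical_replicates_not_deg(self, toy_matrix):
        deg = run_differential(toy_matrix, "hexaploid", "nonaploid")
        assert deg.loc["g3", "log2fc"] == 0.0
        assert deg.loc["g3", "status"] == "unchanged"

    def test_fourfold_constant_gene_log_ratio(self, toy_matrix):
        # reference (10,10,10), test (40,40,40), pseudocount 1 -> log2(41/11)
        deg = run_differential(toy_matrix, "hexaploid", "nonaploid", pseudocount=1.0)
        assert deg.loc["g1", "log2fc"] == pytest.approx(np.log2(41 / 11), abs=1e-12)
        assert np.log2(41 / 11) == pytest.approx(1.898, abs=1e-3)
        # zero variance in both conditions with unequal means: p = 0 by convention
        assert deg.loc["g1", "pvalue"] == 0.0
        assert deg.loc["g1", "status"] == "up"

    def test_status_is_a_partition(self, small_config):
        matrix, *_ = generate_dataset(small_config(seed=5))
        deg = run_differential(matrix, "hexaploid", "nonaploid")
        counts = deg["status"].value_counts()
        assert counts.sum() == len(matrix.gene_ids)
        assert set(counts.index) <= {
            "up", "down", "activated", "silenced", "unchanged", "not_expressed"
        }

    def test_adjusted_never_below_raw(self, small_config):
        matrix, *_ = generate_dataset(small_config(seed=6))
        deg = run_differential(matrix, "hexaploid", "nonaploid")
        ok = deg["padj"].notna()
        assert (deg.loc[ok, "padj"] >= deg.loc[ok, "pvalue"] - 1e-15).all()
        assert deg.loc[~ok, "status"].eq("not_expressed").all()

    def test_up_down_imply_fold_gate(self, small_config):
        matrix, *_ = generate_dataset(small_config(seed=7))
        deg = run_differential(matrix, "hexaploid", "nonaploid", fold=2.0)
        assert (deg.loc[deg["status"] == "up", "log2fc"] > 1).all()
        assert (deg.loc[deg["status"] == "down", "log2fc"] < -1).all()

    def test_absent_condition_rejected(self, toy_matrix):
        with pytest.raises(DesignMismatchError):
            run_differential(toy_matrix, "hexaploid", "dodecaploid")


class TestCallQualitative:
    def test_activation_and_silencing_rules(self, toy_matrix):
        qual = call_qualitative(toy_matrix, "hexaploid", "nonaploid", threshold=0.5)
        assert qual["g2"] == "activated"  # (0,0,0) -> (5,6,7)
        assert qual["g1"] == "none"  # both conditions well above threshold
        assert qual["g5"] == "none"  # below threshold on both sides

    def test_silenced_is_mirror_image(self, toy_matrix):
        qual = call_qualitative(toy_matrix, "nonaploid", "hexaploid", threshold=0.5)
        assert qual["g2"] == "silenced"

    def test_injected_counts_recovered_exactly(self, small_config):
        cfg = small_config(n_activated=17, n_silenced=9, seed=8)
        matrix, _, _, truth = generate_dataset(cfg)
        qual = call_qualitative(matrix, "hexaploid", "nonaploid", threshold=0.5)
        assert (qual == "activated").sum() == 17
        assert (qual == "silenced").sum() == 9
        assert set(qual.index[qual == "activated"]) == set(
            truth.genes_with(qualitative="activated")
        )
        assert set(qual.index[qual == "silenced"]) == set(
            truth.genes_with(qualitative="silenced")
        )


class TestProportionTest:
    def test_perfectly_balanced_counts(self):
        res = proportion_test(6227, 6227)
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_nine_against_one_exact_binomial(self):
        res = proportion_test(9, 1)
        assert res.method == "exact_binomial"
        assert res.pvalue == pytest.approx(22 / 1024, abs=1e-12)

    def test_exact_branch_matches_enumeration_to_n20(self):
        for n in range(1, 21):
            for k in range(n + 1):
                got = proportion_test(k, n - k).pvalue
                want = binom_two_sided_exact(k, n)
                assert got == pytest.approx(want, abs=1e-12), (k, n)

    @given(st.integers(0, 5000), st.integers(0, 5000))
    @settings(derandomize=True, max_examples=60)
    def test_symmetric_in_up_and_down(self, a, b):
        if a + b == 0:
            return
        assert proportion_test(a, b).pvalue == pytest.approx(
            proportion_test(b, a).pvalue, rel=1e-12
        )

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueOutOfRangeError):
            proportion_test(0, 0)


class TestChromosomeTally:
    def _deg_frame(self, statuses):
        return pd.DataFrame(
            {"status": statuses},
            index=pd.Index([f"g{i}" for i in range(len(statuses))], name="gene_id"),
        )

    def test_single_chromosome_single_row(self):
        degs = self._deg_frame(["up", "down", "up", "unchanged"])
        tab = tally_by_chromosome(degs, {f"g{i}": "1A" for i in range(4)})
        assert len(tab) == 1
        assert tab.loc[0, ["up", "down", "total"]].tolist() == [2, 1, 3]

    def test_counts_partition_regulated_set_with_unplaced(self):
        statuses = ["up"] * 5 + ["down"] * 3 + ["activated", "silenced", "unchanged"]
        degs = self._deg_frame(statuses)
        mapping = {f"g{i}": "2B" for i in range(4)}  # rest unplaced
        tab = tally_by_chromosome(degs, mapping).set_index("chromosome")
        assert tab["total"].sum() == 10  # all regulated genes, once each
        assert "unplaced" in tab.index

    def test_uniform_assignment_is_chi_square_uniform(self):
        rng = np.random.default_rng(123)
        n = 2100
        degs = self._deg_frame(["up"] * n)
        chroms = [f"{i}{s}" for i in range(1, 8) for s in "ABD"]
        mapping = {f"g{i}": chroms[rng.integers(21)] for i in range(n)}
        tab = tally_by_chromosome(degs, mapping)
        from scipy.stats import chisquare

        p = chisquare(tab["total"].to_numpy()).pvalue
        assert p > 0.01
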