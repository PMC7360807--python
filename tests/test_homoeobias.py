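import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triadshift import (
    CATEGORIES,
    PROFILES,
    classify_triad,
    classify_triads,
    cluster_subgenome_profiles,
    generate_dataset,
    normalize_triads,
    summarize_categories,
    trace_shifts,
)
from triadshift.homoeobias import classify_profiles
from triadshift.errors import (
    EmptyIntersectionError,
    MissingGeneError,
    NotOnSimplexError,
)

from _oracles import nearest_profile_brute


def _cls_frame(triad_ids, categories, expressed=None):
    n = len(triad_ids)
    return pd.DataFrame(
        {
            "triad_id": triad_ids,
            "category": categories,
            "expressed": [True] * n if expressed is None else expressed,
        }
    )


class TestClassify:
    def test_profiles_classify_as_themselves(self):
        for name, prof in zip(CATEGORIES, PROFILES):
            assert classify_triad(prof) == name

    def test_suppressed_point_beats_balanced(self):
        rel = (0.10, 0.45, 0.45)
        assert classify_triad(rel) == "A_suppressed"
        idx, d = classify_profiles(np.array([rel]))
        assert d[0] == pytest.approx(np.sqrt(0.015), abs=1e-12)  # 0.1225
        d_bal = np.linalg.norm(np.array(rel) - PROFILES[0])
        assert d_bal == pytest.approx(0.2858, abs=1e-3)

    def test_tie_breaks_by_fixed_order(self):
        # exactly representable midpoints, equidistant between two profiles:
        # the earlier category in the fixed order wins
        mid_ds = (PROFILES[3] + PROFILES[4]) / 2  # D-dominant vs A-suppressed
        assert classify_triad(mid_ds) == "D_dominant"
        mid_bd = (PROFILES[2] + PROFILES[6]) / 2  # B-dominant vs D-suppressed
        assert classify_triad(mid_bd) == "B_dominant"

    def test_off_simplex_rejected(self):
        with pytest.raises(NotOnSimplexError):
            classify_triad((0.5, 0.5, 0.5))
        with pytest.raises(NotOnSimplexError):
            classify_triad((-0.1, 0.6, 0.5))

    def test_matches_exhaustive_oracle_on_random_simplex_points(self):
        rng = np.random.default_rng(7)
        pts = rng.dirichlet([1.0, 1.0, 1.0], size=2000)
        idx, _ = classify_profiles(pts)
        got = [CATEGORIES[i] for i in idx]
        want = [nearest_profile_brute(tuple(p)) for p in pts]
        assert got == want

    @given(
        st.tuples(
            st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 1.0)
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_arbitrary_positive_triples_match_oracle(self, raw):
        rel = np.asarray(raw) / np.sum(raw)
        assert classify_triad(rel) == nearest_profile_brute(tuple(rel))


class TestNormalize:
    def test_equal_means_give_thirds(self, toy_matrix, toy_triads):
        # g3 has means 12 in both conditions; craft a triad of three copies
        norm = normalize_triads(toy_matrix, toy_triads, "hexaploid")
        row = norm.set_index("triad_id").loc["tr1"]
        # means: g1=10, g2=0, g3=12 -> (10/22, 0, 12/22)
        assert row["a"] == pytest.approx(10 / 22)
        assert row["b"] == pytest.approx(0.0)
        assert row["d"] == pytest.approx(12 / 22)
        assert row["expressed"]

    def test_exact_arithmetic_30_10_0(self):
        values = pd.DataFrame(
            {"s1": [30.0, 10.0, 0.0], "s2": [30.0, 10.0, 0.0]},
            index=pd.Index(["a", "b", "d"], name="gene_id"),
        )
        design = pd.DataFrame(
            {"condition": ["c", "c"], "replicate": [1, 2]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
        from triadshift import ExpressionMatrix, TriadMap

        em = ExpressionMatrix(values, design)
        tm = TriadMap(
            pd.DataFrame(
                {"triad_id": ["t"], "gene_A": ["a"], "gene_B": ["b"], "gene_D": ["d"]}
            )
        )
        row = normalize_triads(em, tm, "c").iloc[0]
        assert (row["a"], row["b"], row["d"]) == (0.75, 0.25, 0.0)

    def test_all_zero_triad_excluded(self, toy_matrix, toy_triads):
        toy_matrix.values.loc[["g4", "g5", "g6"]] = 0.0
        cls = classify_triads(toy_matrix, toy_triads, "hexaploid")
        row = cls.set_index("triad_id").loc["tr2"]
        assert not row["expressed"]
        assert pd.isna(row["category"])

    def test_missing_member_rejected(self, toy_matrix, toy_triads):
        toy_matrix.values.drop(index="g6", inplace=True)
        with pytest.raises(MissingGeneError):
            normalize_triads(toy_matrix, toy_triads, "hexaploid")


class TestSummaries:
    def test_all_balanced_proportions(self):
        cls = _cls_frame([f"t{i}" for i in range(5)], ["balanced"] * 5)
        summ = summarize_categories(cls).set_index("category")
        assert summ.loc["balanced", "proportion"] == 1.0
        assert summ["count"].sum() == 5
        assert summ["proportion"].sum() == pytest.approx(1.0)

    def test_counts_invariant_to_global_rescaling(self, small_config):
        matrix, triads, _, _ = generate_dataset(small_config(seed=9))
        before = classify_triads(matrix, triads, "hexaploid")
        matrix.values *= 37.5
        after = classify_triads(matrix, triads, "hexaploid", threshold=0.5 * 37.5)
        assert before["category"].tolist() == after["category"].tolist()


class TestTraceShifts:
    def test_identical_classifications_fully_conserved(self):
        cats = ["balanced", "A_dominant", "D_suppressed"]
        a = _cls_frame(["t1", "t2", "t3"], cats)
        sh = trace_shifts(a, a.copy())
        assert sh.conserved_fraction == 1.0
        off = sh.counts.to_numpy() - np.diag(np.diag(sh.counts.to_numpy()))
        assert (off == 0).all()

    def test_five_triad_hand_example(self):
        ref = _cls_frame(
            ["t1", "t2", "t3", "t4", "t5"],
            ["balanced", "A_dominant", "A_suppressed", "balanced", "D_dominant"],
        )
        tst = _cls_frame(
            ["t1", "t2", "t3", "t4", "t5"],
            ["balanced", "A_suppressed", "balanced", "B_dominant", "D_dominant"],
        )
        sh = trace_shifts(ref, tst)
        assert sh.total == 5
        assert sh.conserved == 2  # t1, t5
        assert sh.shifted == 3
        assert sh.n_direct_opposite == 1  # t2: A_dominant -> A_suppressed
        assert sh.counts.loc["balanced", "B_dominant"] == 1
        assert sh.counts.loc["A_suppressed", "balanced"] == 1

    def test_margins_match_per_condition_counts_on_shared_set(self):
        ref = _cls_frame(
            ["t1", "t2", "t3"], ["balanced", "balanced", "A_dominant"],
            expressed=[True, True, True],
        )
        tst = _cls_frame(
            ["t2", "t3", "t4"], ["balanced", "balanced", "A_dominant"],
            expressed=[True, True, True],
        )
        sh = trace_shifts(ref, tst)  # shared: t2, t3
        assert sh.total == 2
        assert sh.reference_margin()["balanced"] == 1
        assert sh.reference_margin()["A_dominant"] == 1
        assert sh.test_margin()["balanced"] == 2

    def test_no_shared_triads_rejected(self):
        a = _cls_frame(["t1"], ["balanced"])
        b = _cls_frame(["t2"], ["balanced"])
        with pytest.raises(EmptyIntersectionError):
            trace_shifts(a, b)

    def test_non_expressed_triads_drop_out(self):
        a = _cls_frame(["t1", "t2"], ["balanced", "balanced"], [True, False])
        b = _cls_frame(["t1", "t2"], ["balanced", "balanced"], [True, True])
        assert trace_shifts(a, b).total == 1


class TestSubgenomeClustering:
    def test_identical_conditions_pair_at_height_zero(self, small_config):
        matrix, triads, _, _ = generate_dataset(small_config(seed=10))
        # make the second condition an exact copy of the first
        ref_cols = matrix.samples_for("hexaploid")
        tst_cols = matrix.samples_for("nonaploid")
        matrix.values[tst_cols] = matrix.values[ref_cols].to_numpy()
        res = cluster_subgenome_profiles(matrix, triads)
        corr = res["correlations"]
        for sub in "ABD":
            assert corr.loc[f"hexaploid_{sub}", f"nonaploid_{sub}"] == pytest.approx(1.0)
        # the three first merges are the three zero-height counterpart pairs
        assert np.allclose(res["linkage"][:3, 2], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_subgenome_vectors_are_mutual_nearest_neighbors(self, small_config, seed):
        cfg = small_config(seed=seed, shift_fraction=0.05, n_triads=300)
        matrix, triads, _, _ = generate_dataset(cfg)
        corr = cluster_subgenome_profiles(matrix, triads)["correlations"]
        for sub in "ABD":
            a, b = f"hexaploid_{sub}", f"nonaploid_{sub}"
            others_a = corr.loc[a].drop([a, b])
            others_b = corr.loc[b].drop([a, b])
            assert corr.loc[a, b] > others_a.max()
            assert corr.loc[a, b] > others_b.max()

    def test_single_condition_gives_three_by_three(self, small_config):
        matrix, triads, _, _ = generate_dataset(small_config(seed=11))
        res = cluster_subgenome_profiles(matrix, triads, conditions=["hexaploid"])
        assert res["correlations"].shape == (3, 3)
        assert all(lbl.startswith("hexaploid") for lbl in res["leaf_order"])
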