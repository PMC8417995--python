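import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncscape import annotate as ann
from lncscape.types import ExpressionMatrix, GenomeAnnotation, TranscriptModel


class TestTau:
    def test_closed_forms(self):
        assert ann.compute_tau([0, 0, 10]) == 1.0
        assert ann.compute_tau([5, 5, 5]) == 0.0
        assert ann.compute_tau([2, 4, 8]) == pytest.approx(0.625)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            ann.compute_tau([0.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        profile=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=12),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, profile, c):
        x = np.asarray(profile)
        if x.max() <= 0:
            return
        assert ann.compute_tau(c * x) == pytest.approx(ann.compute_tau(x), rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=10))
    def test_zero_iff_constant_one_iff_single_nonzero(self, profile):
        x = np.asarray(profile)
        tau = ann.compute_tau(x)
        if np.allclose(x, x[0], rtol=1e-12):
            assert tau == pytest.approx(0.0, abs=1e-9)
        else:
            assert tau > 0
        one_hot = np.zeros_like(x)
        one_hot[0] = 1.0
        assert ann.compute_tau(one_hot) == 1.0


class TestTsi:
    def test_arithmetic(self):
        s = ann.compute_tsi([2, 4, 8], ["a", "b", "c"])
        assert s.top_tsi == pytest.approx(8 / 14)
        assert s.top_sample == "c" and not s.tie

    def test_tie_goes_to_lexicographic_smallest(self):
        s = ann.compute_tsi([1, 1], ["b", "a"])
        assert s.top_sample == "a" and s.tie

    def test_one_hot_gives_tsi_one(self):
        assert ann.compute_tsi([0, 5, 0], ["a", "b", "c"]).top_tsi == 1.0


class TestTissueCalling:
    def _expr(self, rows, meta):
        return ExpressionMatrix(
            pd.DataFrame(rows["values"], index=rows["ids"], columns=list(meta)),
            meta,
        )

    def test_strict_boundary_at_tau(self):
        # 20 samples, expressed in exactly one -> tau = 1; flat -> 0;
        # constructed profile with tau exactly 0.95 must NOT be called
        n = 21
        profile = np.ones(n)
        profile[0] = 20.0  # tau = sum(1 - x/20)/20 = (20 * 0.95)/20 = 0.95
        meta = {f"s{i:02d}": f"tissue{i}" for i in range(n)}
        expr = self._expr({"values": [profile], "ids": ["l1"]}, meta)
        calls = ann.call_tissue_specific(expr)
        assert calls.empty
        profile2 = profile.copy()
        profile2[0] = 1000.0
        expr2 = self._expr({"values": [profile2], "ids": ["l1"]}, meta)
        calls2 = ann.call_tissue_specific(expr2)
        assert list(calls2["tissue_annotation"]) == ["tissue0"]

    def test_undescribed_samples_excluded(self):
        meta = {"s1": "shoot", "s2": "", "s3": "root"}
        expr = self._expr({"values": [[1.0, 500.0, 1.0]], "ids": ["l1"]}, meta)
        calls = ann.call_tissue_specific(expr)
        # the huge undescribed sample is ignored: profile (1, 1) -> tau 0
        assert calls.empty

    def test_fewer_than_two_described_warns_and_returns_empty(self):
        meta = {"s1": "shoot", "s2": ""}
        expr = self._expr({"values": [[1.0, 2.0]], "ids": ["l1"]}, meta)
        with pytest.warns(UserWarning):
            assert ann.call_tissue_specific(expr).empty


class TestAdjacentGenes:
    def _ref(self):
        return GenomeAnnotation(
            [
                TranscriptModel("a.1", "near", "chr1", "+", ((50_000, 60_000),)),
                TranscriptModel("b.1", "far", "chr1", "-", ((260_000, 270_000),)),
                TranscriptModel("c.1", "inside", "chr1", "+", ((100_500, 100_900),)),
            ]
        )

    def test_window_and_distances(self):
        lnc = TranscriptModel("l", "l", "chr1", "+", ((100_000, 101_000),))
        hits = ann.annotate_adjacent_genes(lnc, self._ref())
        assert [g for g, _ in hits] == ["inside", "near"]
        assert dict(hits)["inside"] == 0
        assert dict(hits)["near"] == 40_000
        assert "far" not in dict(hits)  # gap 159,000 > 100 kb

    def test_strict_window_boundary(self):
        ref = GenomeAnnotation(
            [TranscriptModel("g.1", "g", "chr1", "+", ((200_000, 201_000),))]
        )
        at = TranscriptModel("l", "l", "chr1", "+", ((99_000, 100_000),))
        assert ann.annotate_adjacent_genes(at, ref) == []  # gap exactly 100,000
        near = TranscriptModel("l", "l", "chr1", "+", ((99_001, 100_001),))
        assert ann.annotate_adjacent_genes(near, ref) == [("g", 99_999)]


class TestTom:
    def test_hand_worked_three_node_network(self):
        # engineer pairwise |cor| = 0.5^(1/6) so adjacency = 0.5 exactly
        net = ann.TomNetwork(
            node_ids=["a", "b", "c"], beta=6.0,
            adjacency=np.full((3, 3), 0.5) - np.diag([0.5] * 3),
            tom=np.zeros((3, 3)),
        )
        A = net.adjacency
        k = A.sum(axis=1)
        L = A @ A
        tom = (L + A) / (np.minimum.outer(k, k) + 1 - A)
        assert tom[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))
        assert tom[0, 1] == pytest.approx(0.5)

    def test_identical_profiles_give_tom_one(self):
        base = np.linspace(1, 10, 8)
        df = pd.DataFrame([base, base * 2, base * 0.5], index=list("abc"))
        net = ann.build_tom(df)
        off = net.tom[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(10, 25)))
        net = ann.build_tom(df, beta=6)
        A, n = net.adjacency, 10
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                L = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                ki = sum(A[i, u] for u in range(n) if u != i)
                kj = sum(A[j, u] for u in range(n) if u != j)
                expect = (L + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
                assert net.tom[i, j] == pytest.approx(expect, abs=1e-10)

    def test_requires_four_samples_and_drops_constant_rows(self):
        df = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            ann.build_tom(df)
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        df.loc["a"] = 7.0
        net = ann.build_tom(df)
        assert net.dropped == ["a"] and "a" not in net.node_ids


class TestPartners:
    def _net(self):
        tom = np.array([[1.0, 0.1, 0.4], [0.1, 1.0, 0.2], [0.4, 0.2, 1.0]])
        return ann.TomNetwork(list("abc"), 6.0, np.zeros((3, 3)), tom)

    def test_strict_threshold(self):
        partners = ann.coexpression_partners(self._net(), "a")
        assert partners == [("c", 0.4)]  # 0.1 exactly is excluded

    def test_unknown_id_errors(self):
        with pytest.raises(KeyError):
            ann.coexpression_partners(self._net(), "zzz")

    def test_module_members_fully_connected(self, simulation, annotation):
        for members in simulation.truth.planted_modules:
            lnc = members[0]
            partners = {g for g, _ in
                        ann.coexpression_partners(annotation.tom, lnc)}
            assert set(members[1:]) <= partners


class TestGsea:
    def test_extreme_enrichment(self):
        rng = np.random.default_rng(0)
        metric = pd.Series(
            np.sort(np.abs(rng.normal(size=100)))[::-1],
            index=[f"g{i}" for i in range(100)],
        )
        top = set(metric.index[:10])
        (res,) = ann.gsea_annotate(metric, {"top": top}, n_perm=1000, seed=1)
        assert res.es > 0.9 and res.p <= 0.01

    def test_deterministic_p_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        metric = pd.Series(rng.random(60), index=[f"g{i}" for i in range(60)])
        sets = {f"t{k}": set(rng.choice(metric.index, 8, replace=False))
                for k in range(4)}
        r1 = ann.gsea_annotate(metric, sets, n_perm=300, seed=11)
        r2 = ann.gsea_annotate(metric, sets, n_perm=300, seed=11)
        assert [x.p for x in r1] == [x.p for x in r2]

    def test_bh_adjustment_monotone_and_at_least_p(self):
        rng = np.random.default_rng(3)
        metric = pd.Series(rng.random(80), index=[f"g{i}" for i in range(80)])
        sets = {f"t{k}": set(rng.choice(metric.index, 10, replace=False))
                for k in range(12)}
        res = ann.gsea_annotate(metric, sets, n_perm=200, seed=5)
        assert all(r.padj >= r.p for r in res)
        by_p = sorted(res, key=lambda r: r.p)
        ranked_padj = [min(x.padj for x in by_p[i:]) for i in range(len(by_p))]
        assert ranked_padj == sorted(ranked_padj)

    def test_size_filters_and_empty_universe(self):
        metric = pd.Series([1.0, 0.5], index=["a", "b"])
        assert ann.gsea_annotate(metric, {"tiny": {"a"}}, n_perm=10, seed=0) == []
        with pytest.raises(ValueError):
            ann.gsea_annotate(pd.Series(dtype=float), {"t": {"a"}})


class TestCombineAnnotations:
    def test_printed_overall_percentage(self):
        universe = [f"l{i}" for i in range(37_009)]
        tissue = {f"l{i}": "shoot" for i in range(14_132)}
        # overlap structure irrelevant to the union percentage
        adjacent = {f"l{i}": [("g", 0)] for i in range(10_000, 26_000)}
        coexpr = {f"l{i}": ["GO:1"] for i in range(26_000, 28_227)}
        records, summary = ann.combine_annotations(
            universe, tissue, adjacent, coexpr
        )
        assert summary["annotated"] == 28_227
        assert summary["percent_annotated"] == 76.27

    def test_empty_channels(self):
        _, summary = ann.combine_annotations(["a", "b"])
        assert summary["percent_annotated"] == 0.0
        assert all(v == 0 for v in summary["venn"].values())

    def test_triple_overlap_counted_once_in_union(self):
        _, summary = ann.combine_annotations(
            ["a"], {"a": "shoot"}, {"a": [("g", 0)]}, {"a": ["GO:1"]}
        )
        assert summary["annotated"] == 1
        assert summary["venn"]["all_three"] == 1
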