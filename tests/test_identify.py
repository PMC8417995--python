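import numpy as np
import pandas as pd
import pytest

from lncscape import identify as idf
from lncscape.types import ExpressionMatrix, GenomeAnnotation, TranscriptModel


def _t(tid, exons, strand="+", chrom="chr1", sample=""):
    return TranscriptModel(tid, tid, chrom, strand, tuple(exons), sample)


@pytest.fixture
def reference():
    # three-exon gene on '+': exons 100-200, 300-400, 500-600
    return GenomeAnnotation(
        [_t("ref1", [(100, 200), (300, 400), (500, 600)])],
        {"chr1": 10_000},
    )


class TestClassCode:
    def test_identical_chain_is_equal(self, reference):
        q = _t("q", [(100, 200), (300, 400), (500, 600)])
        assert idf.assign_class_code(q, reference) == "="

    def test_boundary_extension_keeps_equal(self, reference):
        q = _t("q", [(90, 200), (300, 400), (500, 650)])
        assert idf.assign_class_code(q, reference) == "="

    def test_shared_junction_partial_chain_is_j(self, reference):
        q = _t("q", [(150, 200), (300, 450)])  # shares junction (200, 300)
        assert idf.assign_class_code(q, reference) == "j"

    def test_mono_exonic_inside_intron_same_strand_is_i(self, reference):
        q = _t("q", [(220, 280)])
        assert idf.assign_class_code(q, reference) == "i"

    def test_inside_intron_opposite_strand_is_u(self, reference):
        q = _t("q", [(220, 280)], strand="-")
        assert idf.assign_class_code(q, reference) == "u"

    def test_antisense_exonic_overlap_is_x(self, reference):
        q = _t("q", [(150, 250)], strand="-")
        assert idf.assign_class_code(q, reference) == "x"

    def test_same_strand_overlap_without_junction_is_o(self, reference):
        q = _t("q", [(150, 250)])
        assert idf.assign_class_code(q, reference) == "o"

    def test_intergenic_is_u(self, reference):
        q = _t("q", [(2000, 2300)])
        assert idf.assign_class_code(q, reference) == "u"

    def test_unknown_contig_errors(self, reference):
        with pytest.raises(ValueError, match="contig"):
            idf.assign_class_code(_t("q", [(0, 10)], chrom="chrZ"), reference)

    def test_mono_exonic_equal_needs_reciprocal_095(self):
        ref = GenomeAnnotation([_t("r", [(0, 1000)])], {"chr1": 10_000})
        near = _t("q", [(0, 960)])      # reciprocal 0.96
        far = _t("q2", [(0, 700)])      # reciprocal 0.70
        assert idf.assign_class_code(near, ref) == "="
        assert idf.assign_class_code(far, ref) == "o"


class TestOverlapRatio:
    def test_partial(self):
        q = _t("q", [(0, 1000)])
        assert idf.overlap_ratio(q, {"chr1": [(200, 1000)]}) == pytest.approx(0.8)

    def test_disjoint_and_full(self):
        q = _t("q", [(0, 1000)])
        assert idf.overlap_ratio(q, {"chr1": [(5000, 6000)]}) == 0.0
        assert idf.overlap_ratio(q, {"chr1": [(0, 1000)]}) == 1.0

    def test_strict_boundaries_of_interval_filters(self):
        ts = [_t(f"t{r}", [(0, 100)]) for r in range(3)]
        organelle = {"chr1": [(0, 74)]}, {"chr1": [(0, 75)]}, {"chr1": [(0, 76)]}
        thr = idf.FilterThresholds()
        for t, org, removed in zip(ts, organelle, (False, False, True)):
            kept, log = idf.organelle_and_ncrna_filter([t], org, {}, thr)
            assert (len(kept) == 0) == removed
        # ncRNA boundary: 0.30 kept, 0.31 removed
        kept, log = idf.organelle_and_ncrna_filter(
            [_t("a", [(0, 100)]), _t("b", [(0, 100)])],
            {},
            {"chr1": [(0, 30)]},
            thr,
        )
        assert len(kept) == 2
        kept, log = idf.organelle_and_ncrna_filter(
            [_t("a", [(0, 100)])], {}, {"chr1": [(0, 31)]}, thr
        )
        assert kept == [] and log.iloc[0]["filter"] == "ncrna"

    def test_empty_bed_is_identity(self):
        ts = [_t("a", [(0, 100)])]
        kept, log = idf.organelle_and_ncrna_filter(ts, {}, {})
        assert kept == ts and log.empty


class TestMerge:
    def test_same_transcript_three_samples(self):
        ts = [_t(f"t|{s}", [(0, 100), (200, 300)], sample=s) for s in "abc"]
        m = idf.merge_transcripts(ts)
        assert len(m.representatives) == 1
        assert list(m.recurrence.values()) == [3]

    def test_strand_opposite_overlap_gives_two_loci(self):
        ts = [_t("a", [(0, 100)]), _t("b", [(50, 150)], strand="-")]
        m = idf.merge_transcripts(ts)
        assert len(m.loci) == 2

    def test_disjoint_transcripts_each_get_locus(self):
        ts = [_t(f"t{i}", [(i * 1000, i * 1000 + 100)]) for i in range(5)]
        assert len(idf.merge_transcripts(ts).loci) == 5

    def test_mono_exonic_merge_at_reciprocal_095(self):
        a = _t("a|s1", [(0, 1000)], sample="s1")
        b = _t("b|s2", [(0, 960)], sample="s2")   # reciprocal 0.96 -> merge
        c = _t("c|s3", [(0, 700)], sample="s3")   # reciprocal 0.70 -> separate
        m = idf.merge_transcripts([a, b, c])
        assert len(m.representatives) == 2


class TestFeatures:
    def test_arithmetic(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[0.0, 0.0, 6.0]], index=["t"], columns=["a", "b", "c"])
        )
        t = _t("t", [(0, 100), (200, 350)])
        vec = idf.extract_features(t, 1, expr)
        assert vec == pytest.approx([1 / 3, 6.0, 2.0, 250, 2])

    def test_missing_row_errors(self):
        expr = ExpressionMatrix(pd.DataFrame([[1.0]], index=["x"], columns=["a"]))
        with pytest.raises(KeyError, match="t"):
            idf.extract_features(_t("t", [(0, 100)]), 1, expr)


def _separable_features(rng, n=60):
    eq = np.column_stack([
        rng.uniform(0.6, 1.0, n), rng.uniform(20, 60, n),
        rng.uniform(8, 30, n), rng.uniform(500, 2000, n),
        rng.integers(2, 6, n),
    ])
    intron = np.column_stack([
        rng.uniform(0.0, 0.15, n), rng.uniform(0.1, 1.5, n),
        rng.uniform(0.05, 0.6, n), rng.uniform(150, 600, n),
        np.ones(n),
    ])
    return eq, intron


class TestContaminationFilter:
    def test_separable_classes_reach_high_holdout_accuracy(self):
        for seed in range(5):
            eq, intron = _separable_features(np.random.default_rng(seed))
            model = idf.train_contamination_filter(eq, intron, seed=seed)
            assert model.training_summary["holdout_accuracy_forest"] >= 0.95
            assert model.training_summary["holdout_accuracy_margin"] >= 0.95

    def test_label_permutation_gives_chance_accuracy(self):
        rng = np.random.default_rng(0)
        pool = rng.uniform(0, 1, size=(200, 5))
        model = idf.train_contamination_filter(pool[:100], pool[100:], seed=0)
        assert 0.35 <= model.training_summary["holdout_accuracy_forest"] <= 0.65

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        eq, intron = _separable_features(rng)
        probe = np.random.default_rng(9).uniform(0, 1, size=(10, 5)) * [1, 60, 30, 2000, 5]
        preds = [
            idf.train_contamination_filter(eq, intron, seed=7).predict_intronic(probe)
            for _ in range(2)
        ]
        assert (preds[0] == preds[1]).all()

    def test_combination_rules(self):
        class Stub:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.array([self.label] * len(X))

        model = idf.ContaminationModel("both_agree")
        model.fitted = True
        model.forest = Stub(idf.LABEL_INTRONIC)
        model.margin = Stub(idf.LABEL_EQUAL)
        kept, removed = idf.apply_contamination_filter(model, {"c": np.zeros(5)})
        assert kept == ["c"] and removed == []
        model.combination_rule = "either"
        kept, removed = idf.apply_contamination_filter(model, {"c": np.zeros(5)})
        assert kept == [] and removed == ["c"]

    def test_unfitted_model_refuses(self):
        model = idf.ContaminationModel()
        with pytest.raises(RuntimeError):
            model.predict_intronic(np.zeros((1, 5)))

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            idf.train_contamination_filter([], np.zeros((30, 5)))


class TestCodingPotential:
    def test_no_atg_means_no_orf(self):
        ev = idf.score_coding_potential("CCGCTGCCG" * 30)
        assert ev.longest_orf_aa == 0 and ev.verdict == "noncoding"

    def test_planted_120_codon_orf_is_coding(self):
        rng = np.random.default_rng(1)
        import itertools

        sense = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
                 if c not in ("TAA", "TAG", "TGA")]
        body = "".join(rng.choice(sense, 120))
        seq = "CC" + "ATG" + body + "TAA"
        seq = seq + "A" * (400 - len(seq))
        ev = idf.score_coding_potential(seq)
        assert ev.longest_orf_aa == 120 and ev.verdict == "coding"

    def test_random_sequences_rarely_called_coding(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        rate = np.mean([
            idf.score_coding_potential("".join(bases[rng.integers(0, 4, 300)])).verdict
            == "coding"
            for _ in range(1000)
        ])
        assert rate <= 0.10

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            idf.score_coding_potential("ACGTX")


class TestCodingCascade:
    def _run(self, transcripts, sim_rows=(), dom_rows=()):
        from lncscape.types import HIT_COLUMNS

        seqs = {t.transcript_id: "CCGCTG" * max(1, t.exonic_length // 6)
                for t in transcripts}
        sim_hits = pd.DataFrame(list(sim_rows), columns=HIT_COLUMNS)
        dom_hits = pd.DataFrame(list(dom_rows), columns=HIT_COLUMNS)
        return idf.coding_ability_cascade(transcripts, seqs, sim_hits, dom_hits)

    def _hit(self, tid, e, alen, pid):
        return [tid, "s", pid, alen, 0, 0, 1, 100, 1, 100, e, 50.0]

    def test_similarity_requires_all_three_thresholds(self):
        ts = [_t("a", [(0, 300)]), _t("b", [(0, 300)])]
        kept, log = self._run(
            ts,
            sim_rows=[self._hit("a", 1e-5, 45, 40.0),   # all pass -> removed
                      self._hit("b", 1e-5, 39, 90.0)],  # alen fails -> kept
        )
        assert {t.transcript_id for t in kept} == {"b"}
        assert log.iloc[0]["stage"] == "similarity"

    def test_length_boundary_strict(self):
        ts = [_t("short", [(0, 149)]), _t("edge", [(0, 150)])]
        kept, _ = self._run(ts)
        assert {t.transcript_id for t in kept} == {"edge"}

    def test_domain_hit_removes(self):
        ts = [_t("a", [(0, 300)])]
        kept, log = self._run(ts, dom_rows=[self._hit("a", 1e-5, 60, 40.0)])
        assert kept == [] and log.iloc[0]["stage"] == "domain"

    def test_cascade_is_contraction_with_unique_stages(self):
        ts = [_t(f"t{i}", [(0, 140 + 20 * i)]) for i in range(6)]
        kept, log = self._run(ts)
        kept_ids = {t.transcript_id for t in kept}
        assert kept_ids <= {t.transcript_id for t in ts}
        assert not log["transcript_id"].duplicated().any()
        assert kept_ids.isdisjoint(set(log["transcript_id"]))

    def test_missing_sequence_errors(self):
        t = _t("a", [(0, 300)])
        with pytest.raises(KeyError):
            idf.coding_ability_cascade([t], {}, pd.DataFrame(), pd.DataFrame())
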