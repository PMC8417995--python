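import numpy as np
import pytest

from lncscape import simulate as sim
from lncscape.annotate import compute_tau
from lncscape.identify import assign_class_code, overlap_ratio
from lncscape.types import TranscriptModel


class TestMakeGenome:
    def test_deterministic_for_fixed_seed(self):
        g1, a1 = sim.make_genome(seed=1)
        g2, a2 = sim.make_genome(seed=1)
        assert g1 == g2
        assert [(t.transcript_id, t.exons) for t in a1.transcripts] == [
            (t.transcript_id, t.exons) for t in a2.transcripts
        ]

    def test_gene_count_and_disjoint_spans(self):
        params = sim.GenomeParams(n_genes=10)
        _, ann = sim.make_genome(params, seed=2)
        spans = ann.gene_spans()
        assert len(spans) == 10
        by_chrom = {}
        for g, (c, s, e) in spans.items():
            by_chrom.setdefault(c, []).append((s, e))
        for ivs in by_chrom.values():
            for i, (s1, e1) in enumerate(ivs):
                for s2, e2 in ivs[i + 1:]:
                    assert min(e1, e2) <= max(s1, s2)  # no overlap

    def test_infeasible_density_errors(self):
        with pytest.raises(ValueError, match="density"):
            sim.make_genome(sim.GenomeParams(contig_len=10_000, n_genes=60), seed=0)


class TestMakeAssembly:
    def test_planted_codes_match_assignment(self, simulation):
        # closure: the generator's codes agree with the classifier on all
        # planted bases (including contaminants)
        truth = simulation.truth
        seen = {}
        for t in simulation.assembly.transcripts:
            base = t.transcript_id.split("|")[0]
            seen.setdefault(
                base, TranscriptModel(base, base, t.chrom, t.strand, t.exons)
            )
        for base, model in seen.items():
            assert assign_class_code(model, simulation.reference) == \
                truth.true_class_code[base]

    def test_pure_equal_rates(self):
        genome, ref = sim.make_genome(sim.GenomeParams(n_genes=20), seed=3)
        params = sim.AssemblyParams(
            n_transcripts=50, rates=(("=", 1.0),),
            organelle_ratios=(), ncrna_ratios=(),
            n_coding_orf=0, n_coding_sim=0, n_coding_domain=0, n_short=0,
        )
        res = sim.make_assembly(ref, genome, params, n_samples=4, seed=3)
        bases = {}
        for t in res.transcripts:
            bases.setdefault(t.transcript_id.split("|")[0], t)
        for base, t in bases.items():
            q = TranscriptModel(base, base, t.chrom, t.strand, t.exons)
            assert assign_class_code(q, ref) == "="

    def test_organelle_ratios_straddle_threshold(self, simulation):
        truth = simulation.truth
        bed = simulation.assembly.organelle_bed
        geoms = {}
        for t in simulation.assembly.transcripts:
            base = t.transcript_id.split("|")[0]
            geoms.setdefault(
                base, TranscriptModel(base, base, t.chrom, t.strand, t.exons)
            )
        organelle_bases = [b for b, t in geoms.items() if t.chrom in ("chrC", "chrM")]
        assert organelle_bases
        for b in organelle_bases:
            ratio = overlap_ratio(geoms[b], bed)
            if truth.contaminated_ids.get(b) == "organelle":
                assert ratio > 0.75
            else:
                assert ratio <= 0.75

    def test_deterministic(self):
        genome, ref = sim.make_genome(seed=4)
        r1 = sim.make_assembly(ref, dict(genome), n_samples=6, seed=9)
        r2 = sim.make_assembly(ref, dict(genome), n_samples=6, seed=9)
        assert [(t.transcript_id, t.exons) for t in r1.transcripts] == [
            (t.transcript_id, t.exons) for t in r2.transcripts
        ]
        assert r1.genome == r2.genome


class TestMakeExpression:
    def test_planted_specific_has_extreme_tau(self):
        ids = [f"l{i}" for i in range(30)]
        tissues = tuple(f"tissue{i}" for i in range(8))
        params = sim.ExpressionParams(n_specific=5, n_modules=0, module_size=2,
                                      n_negative_pairs=0, n_undescribed=0)
        expr, truth = sim.make_expression(ids, [], tissues, params, seed=0)
        for rid in truth.planted_specific:
            assert compute_tau(expr.profile(rid)) > 0.95

    def test_negative_pairs_anticorrelate(self):
        ids = [f"l{i}" for i in range(10)]
        genes = [f"g{i}" for i in range(10)]
        params = sim.ExpressionParams(n_specific=0, n_modules=0, module_size=2,
                                      n_negative_pairs=5)
        hits = 0
        trials = 50
        for seed in range(trials):
            expr, truth = sim.make_expression(ids, genes, params=params, seed=seed)
            for lnc, gene in truth.planted_negative_pairs:
                r = np.corrcoef(expr.profile(lnc), expr.profile(gene))[0, 1]
                hits += r <= -0.8
        assert hits / (trials * 5) >= 0.95

    def test_module_members_correlate(self):
        ids = [f"l{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(20)]
        params = sim.ExpressionParams(n_specific=0, n_modules=2, module_size=5,
                                      n_negative_pairs=0)
        expr, truth = sim.make_expression(ids, genes, params=params, seed=3)
        for members in truth.planted_modules:
            profiles = np.array([expr.profile(m) for m in members])
            r = np.corrcoef(profiles)
            assert r[np.triu_indices(len(members), 1)].min() >= 0.8

    def test_null_pairs_rarely_exceed_08(self):
        ids = [f"l{i}" for i in range(40)]
        params = sim.ExpressionParams(n_specific=0, n_modules=0, module_size=2,
                                      n_negative_pairs=0, n_undescribed=34)
        # 16 described + 34 undescribed = 50 samples
        expr, _ = sim.make_expression(ids, [], params=params, seed=5)
        r = np.corrcoef(expr.values.to_numpy())
        off = np.abs(r[np.triu_indices(40, 1)])
        assert (off > 0.8).mean() <= 0.01

    def test_structure_exceeding_ids_errors(self):
        with pytest.raises(ValueError, match="planted structure"):
            sim.make_expression(["a"], [], params=sim.ExpressionParams(), seed=0)


class TestPromotersAndOrthologs:
    def test_zero_hit_rate_low_false_positive_rate(self):
        from lncscape.regscan import scan_pwm

        params = sim.PromoterParams(n_promoters=40, hit_rate=0.0)
        promoters, (pwm,), truth = sim.make_promoters_and_motifs(params, seed=0)
        assert truth.planted_motif_hits == {}
        with_hits = sum(
            bool(scan_pwm(seq, pwm, 1e-6)) for seq in promoters.values()
        )
        assert with_hits / len(promoters) <= 0.01

    def test_planted_consensus_recovered_at_offset(self):
        from lncscape.regscan import scan_pwm

        params = sim.PromoterParams(n_promoters=10, hit_rate=1.0)
        promoters, (pwm,), truth = sim.make_promoters_and_motifs(params, seed=1)
        for pid, [(off, strand)] in truth.planted_motif_hits.items():
            hits = scan_pwm(promoters[pid], pwm, 1e-6, promoter_id=pid)
            assert any(h.offset == off and h.strand == strand for h in hits)

    def test_promoter_determinism(self):
        p1, _, _ = sim.make_promoters_and_motifs(seed=7)
        p2, _, _ = sim.make_promoters_and_motifs(seed=7)
        assert p1 == p2

    def test_zero_orthologs_zero_primary(self):
        from lncscape.regscan import rbh_orthologs

        ab, ba, truth = sim.make_ortholog_scores(
            sim.OrthologParams(n_orthologs=0), seed=0
        )
        assert truth.planted_orthologs == []
        assert all(p.tier != "primary" for p in rbh_orthologs(ab, ba))

    def test_planted_orthologs_are_mutual_best(self):
        from lncscape.regscan import rbh_orthologs

        ab, ba, truth = sim.make_ortholog_scores(
            sim.OrthologParams(n_orthologs=5), seed=2
        )
        primary = {(p.id_a, p.id_b) for p in rbh_orthologs(ab, ba)
                   if p.tier == "primary"}
        assert primary == set(truth.planted_orthologs)


def test_written_outputs_round_trip(tmp_path, simulation):
    from lncscape import io as fio

    sim.write_outputs(simulation, tmp_path)
    back = fio.read_annotation(tmp_path / "assembly.gtf")
    assert len(back.transcripts) == len(simulation.assembly.transcripts)
    expr = fio.read_expression(tmp_path / "expr.tsv", tmp_path / "meta.tsv")
    assert expr.values.shape == simulation.expression.values.shape
    assert set(expr.undescribed_samples) == set(
        simulation.expression.undescribed_samples
    )
    truth = sim.SyntheticTruth.from_json(tmp_path / "truth.json")
    assert truth.true_class_code == simulation.truth.true_class_code
    assert set(truth.planted_negative_pairs) == set(
        simulation.truth.planted_negative_pairs
    )
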