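"""End-to-end orchestration of identification and annotation.

Thin wiring over the stage modules: the same call paths back the CLI, the
closure tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotate as ann
from . import identify as idf
from .types import ExpressionMatrix, GenomeAnnotation, TranscriptModel


@dataclass
class IdentificationResult:
    lncrnas: list                       # final TranscriptModel set
    class_codes: dict                   # candidate id -> class code
    merge: idf.MergeResult
    model: idf.ContaminationModel | None
    removal_logs: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    @property
    def lncrna_ids(self) -> set[str]:
        return {t.transcript_id for t in self.lncrnas}


def run_identification(
    assembly_transcripts,
    reference: GenomeAnnotation,
    genome: dict[str, str],
    expr: ExpressionMatrix,
    organelle_bed: dict,
    ncrna_bed: dict,
    sim_hits: pd.DataFrame,
    domain_hits: pd.DataFrame,
    thresholds: idf.FilterThresholds = idf.FilterThresholds(),
    combination_rule: str = "both_agree",
    seed: int = 0,
    canonical_id=None,
    skip_merge_and_ml: bool = False,
) -> IdentificationResult:
    """Run the identification cascade on assembled transcripts.

    Order mirrors the study: organelle/ncRNA overlap filters on the
    per-sample assemblies, cross-sample merge, class-code assignment, the
    two-classifier contamination filter (trained on "=" vs "i"
    candidates, applied to retained-code candidates), retention of codes
    {j, u, x, o}, then the coding-ability cascade. ``canonical_id`` maps
    a merged representative's id to a stable name (identity by default).
    ``skip_merge_and_ml`` routes full-length inputs (cDNA / Iso-Seq)
    directly into the coding cascade.
    """
    canonical_id = canonical_id or (lambda tid: tid)
    stage_counts = {"input": len(list(assembly_transcripts))}
    kept, interval_log = idf.organelle_and_ncrna_filter(
        assembly_transcripts, organelle_bed, ncrna_bed, thresholds
    )
    stage_counts["interval_filters"] = len(kept)

    if skip_merge_and_ml:
        candidates = [
            TranscriptModel(canonical_id(t.transcript_id), t.gene_id, t.chrom,
                            t.strand, t.exons, t.source_sample)
            for t in kept
        ]
        codes = {t.transcript_id: idf.assign_class_code(t, reference) for t in candidates}
        retained = [t for t in candidates if codes[t.transcript_id] in thresholds.retained_codes]
        model = None
        ml_removed: list[str] = []
        merged_result = idf.MergeResult([], {}, {})
    else:
        merged = idf.merge_transcripts(kept)
        reps = [
            TranscriptModel(canonical_id(t.transcript_id), t.gene_id, t.chrom,
                            t.strand, t.exons, t.source_sample)
            for t in merged.representatives
        ]
        recurrence = {
            canonical_id(tid): r for tid, r in merged.recurrence.items()
        }
        stage_counts["merged"] = len(reps)
        codes = {t.transcript_id: idf.assign_class_code(t, reference) for t in reps}

        feats = {
            t.transcript_id: idf.extract_features(t, recurrence[t.transcript_id], expr)
            for t in reps
            if t.transcript_id in expr.values.index
        }
        eq_feats = [feats[tid] for tid, c in codes.items() if c == "=" and tid in feats]
        in_feats = [feats[tid] for tid, c in codes.items() if c == "i" and tid in feats]
        candidates = {
            t.transcript_id: feats[t.transcript_id]
            for t in reps
            if codes[t.transcript_id] in thresholds.retained_codes
            and t.transcript_id in feats
        }
        if len(eq_feats) >= 20 and len(in_feats) >= 20:
            model = idf.train_contamination_filter(
                eq_feats, in_feats, combination_rule, seed
            )
            kept_ids, ml_removed = idf.apply_contamination_filter(model, candidates)
        else:
            model = None
            kept_ids, ml_removed = sorted(candidates), []
        retained = [t for t in reps if t.transcript_id in set(kept_ids)]
        merged_result = merged
    stage_counts["retained_codes"] = len(retained)

    sequences = {
        t.transcript_id: idf.transcript_sequence(t, genome) for t in retained
    }
    lncrnas, cascade_log = idf.coding_ability_cascade(
        retained, sequences, sim_hits, domain_hits, thresholds
    )
    stage_counts["lncrnas"] = len(lncrnas)
    return IdentificationResult(
        lncrnas=lncrnas,
        class_codes=codes,
        merge=merged_result,
        model=model,
        removal_logs={
            "intervals": interval_log,
            "ml_removed": ml_removed,
            "cascade": cascade_log,
        },
        stage_counts=stage_counts,
    )


@dataclass
class AnnotationResultSet:
    records: list
    summary: dict
    specificity: pd.DataFrame
    tom: ann.TomNetwork
    enrichment: dict


def run_annotation(
    lncrnas,
    reference: GenomeAnnotation,
    expr: ExpressionMatrix,
    go_annotation: dict[str, set] | None = None,
    tau_threshold: float = 0.95,
    tom_beta: float = 6.0,
    tom_threshold: float = 0.1,
    adjacency_window: int = 100_000,
    gsea_n_perm: int = 3000,
    gsea_min_partners: int = 5,
    padj_threshold: float = 0.005,
    seed: int = 0,
) -> AnnotationResultSet:
    """Annotate lncRNAs through the three evidence channels and combine."""
    lncrnas = list(lncrnas)
    lnc_ids = [t.transcript_id for t in lncrnas]
    gene_ids = sorted({t.gene_id for t in reference.transcripts})

    # channel 1: tissue specificity over described samples
    present = [i for i in lnc_ids if i in expr.values.index]
    specificity = ann.call_tissue_specific(expr.subset_rows(present), tau_threshold)
    tissue = dict(zip(specificity["lncrna_id"], specificity["tissue_annotation"]))

    # channel 2: adjacent coding genes
    adjacent = {
        t.transcript_id: ann.annotate_adjacent_genes(t, reference, adjacency_window)
        for t in lncrnas
    }
    adjacent = {k: v for k, v in adjacent.items() if v}

    # channel 3: co-expression (TOM) + GSEA over each lncRNA's partners
    node_ids = [i for i in present + gene_ids if i in expr.values.index]
    tom = ann.build_tom(expr.values.loc[node_ids], beta=tom_beta)
    coding = set(gene_ids)
    enrichment: dict[str, list] = {}
    if go_annotation:
        gene_sets: dict[str, set] = {}
        for g, ts in go_annotation.items():
            for term in ts:
                gene_sets.setdefault(term, set()).add(g)
        for lnc in present:
            if lnc not in tom.node_ids:
                continue
            partners = [
                (g, w) for g, w in ann.coexpression_partners(tom, lnc, tom_threshold)
                if g in coding
            ]
            if len(partners) < gsea_min_partners:
                continue
            i = tom.index(lnc)
            ranked = {
                g: float(tom.tom[i, tom.index(g)])
                for g in coding if g in tom.node_ids and g != lnc
            }
            results = ann.gsea_annotate(
                ranked, gene_sets, n_perm=gsea_n_perm, seed=seed,
                padj_threshold=padj_threshold,
            )
            # positively enriched terms only: depletion is not an annotation
            sig = [r for r in results if r.padj < padj_threshold and r.es > 0]
            if sig:
                enrichment[lnc] = sig

    records, summary = ann.combine_annotations(
        lnc_ids, tissue=tissue, adjacent=adjacent, coexpression=enrichment
    )
    return AnnotationResultSet(
        records=records,
        summary=summary,
        specificity=specificity,
        tom=tom,
        enrichment=enrichment,
    )
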