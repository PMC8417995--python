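"""Functional annotation of lncRNAs through three evidence channels.

1. tissue specificity — the Tau index over per-sample expression, with the
   top-TSI sample's free-text description as the annotation;
2. adjacent coding genes — reference genes within 100 kb;
3. co-expression — topological-overlap (TOM) partners plus a running-sum
   gene-set enrichment (GSEA) over each lncRNA's ranked partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GenomeAnnotation, TranscriptModel

# ---------------------------------------------------------------------------
# tissue specificity


def compute_tau(profile) -> float:
    """Tau tissue-specificity index: sum(1 - x_i/max(x)) / (N - 1).

    0 for a uniform profile, 1 when a single condition carries all
    expression; scale-invariant. Undefined (ValueError) for all-zero
    profiles — callers exclude those rows.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector of length >= 2")
    if (x < 0).any():
        raise ValueError("negative expression in profile")
    m = x.max()
    if m <= 0:
        raise ValueError("all-zero profile: Tau undefined")
    xhat = x / m
    return float((1.0 - xhat).sum() / (x.size - 1))


@dataclass(frozen=True)
class SpecificityScores:
    tau: float
    tsi: tuple[float, ...]
    top_sample: str
    top_tsi: float
    tie: bool = False


def compute_tsi(profile, sample_ids) -> SpecificityScores:
    """Per-sample TSI fractions x_i / sum(x); the argmax sample names the
    candidate specific sample (ties: lexicographically smallest id)."""
    x = np.asarray(profile, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("zero total expression: TSI undefined")
    tsi = x / total
    top = tsi.max()
    winners = [s for s, v in zip(sample_ids, tsi) if v == top]
    return SpecificityScores(
        tau=compute_tau(x),
        tsi=tuple(float(v) for v in tsi),
        top_sample=min(winners),
        top_tsi=float(top),
        tie=len(winners) > 1,
    )


def call_tissue_specific(
    expr: ExpressionMatrix, tau_threshold: float = 0.95
) -> pd.DataFrame:
    """Call tissue-specific lncRNAs at Tau strictly above the threshold.

    Samples without a tissue description are excluded first; the
    annotation is the description of the top-TSI sample. Returns a
    DataFrame (lncrna_id, tau, top_sample, top_tsi, tissue_annotation)
    restricted to called rows.
    """
    described = expr.described_samples
    if len(described) < 2:
        import warnings

        warnings.warn("fewer than 2 described samples: no tissue-specific calls",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["lncrna_id", "tau", "top_sample", "top_tsi", "tissue_annotation"]
        )
    sub = expr.values[described]
    rows = []
    for rid, profile in zip(sub.index, sub.to_numpy(dtype=float)):
        if profile.max() <= 0:
            continue
        scores = compute_tsi(profile, described)
        if scores.tau > tau_threshold:
            rows.append(
                {
                    "lncrna_id": rid,
                    "tau": scores.tau,
                    "top_sample": scores.top_sample,
                    "top_tsi": scores.top_tsi,
                    "tissue_annotation": expr.sample_meta[scores.top_sample],
                }
            )
    return pd.DataFrame(
        rows, columns=["lncrna_id", "tau", "top_sample", "top_tsi", "tissue_annotation"]
    )


# ---------------------------------------------------------------------------
# adjacent coding genes


def annotate_adjacent_genes(
    lncrna: TranscriptModel, annotation: GenomeAnnotation, window: int = 100_000
) -> list[tuple[str, int]]:
    """Reference genes within ``window`` bp of the lncRNA span.

    Distance is the gap between span ends (0 when spans overlap),
    strand-agnostic; result sorted by distance then gene id, so the
    nearest gene(s) come first. Strictly-less-than-window semantics.
    """
    ls, le = lncrna.span
    out = []
    for gene_id, (chrom, gs, ge) in annotation.gene_spans().items():
        if chrom != lncrna.chrom:
            continue
        if ge <= ls:
            d = ls - ge
        elif le <= gs:
            d = gs - le
        else:
            d = 0
        if d < window:
            out.append((gene_id, d))
    out.sort(key=lambda x: (x[1], x[0]))
    return out


# ---------------------------------------------------------------------------
# topological overlap


@dataclass
class TomNetwork:
    """Soft-threshold adjacency and topological-overlap weights.

    adjacency a_ij = |cor(x_i, x_j)|^beta (unsigned);
    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj and k_i = sum_u a_iu (diagonal excluded).
    """

    node_ids: list[str]
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"node {node_id} not in TOM network") from None

    def weight(self, a: str, b: str) -> float:
        return float(self.tom[self.index(a), self.index(b)])


def build_tom(expr_values: pd.DataFrame, beta: float = 6.0) -> TomNetwork:
    """Unsigned WGCNA-style TOM from a features x samples matrix.

    Rows with zero variance are excluded (recorded in ``dropped``);
    requires at least 4 samples.
    """
    if expr_values.shape[1] < 4:
        raise ValueError("TOM requires >= 4 samples")
    arr = expr_values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    dropped = [rid for rid, k in zip(expr_values.index, keep) if not k]
    arr = arr[keep]
    ids = [rid for rid, k in zip(expr_values.index, keep) if k]
    if len(ids) < 2:
        raise ValueError("fewer than 2 non-constant rows")
    corr = np.corrcoef(arr)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    L = adj @ adj  # diagonal of adj is zero, so u != i, j automatically
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (L + adj) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TomNetwork(node_ids=ids, beta=beta, adjacency=adj, tom=tom, dropped=dropped)


def coexpression_partners(
    tom: TomNetwork, lncrna_id: str, threshold: float = 0.1
) -> list[tuple[str, float]]:
    """Partners with TOM weight strictly above ``threshold``, sorted by
    weight descending (ties: node id)."""
    i = tom.index(lncrna_id)
    out = [
        (nid, float(w))
        for nid, w in zip(tom.node_ids, tom.tom[i])
        if nid != lncrna_id and w > threshold
    ]
    out.sort(key=lambda x: (-x[1], x[0]))
    return out


# ---------------------------------------------------------------------------
# GSEA


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    es: float
    nes: float
    p: float
    padj: float


def _enrichment_score(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum ES (weight exponent 1).

    ``metric`` must be sorted descending; ``in_set`` is a boolean mask on
    the same order.
    """
    w = np.abs(metric)
    hit_w = np.where(in_set, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = (~in_set).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0
    step = hit_w / total_hit - (~in_set) / n_miss
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def gsea_annotate(
    ranked: pd.Series | dict,
    gene_sets: dict[str, set],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    padj_threshold: float = 0.005,
) -> list[EnrichmentResult]:
    """GSEA over genes ranked by their co-expression weight with a lncRNA.

    ``ranked`` maps gene -> ranking metric (e.g. TOM weight). Significance
    is by gene-label permutation (one-sided in the sign of the observed
    ES, +1 smoothed); BH adjustment across the tested terms. Returns all
    tested terms sorted by adjusted then raw p; callers filter at
    ``padj < padj_threshold``.
    """
    if isinstance(ranked, dict):
        ranked = pd.Series(ranked)
    if ranked.empty:
        raise ValueError("empty ranked universe")
    order = np.lexsort((np.array(ranked.index), -ranked.to_numpy(dtype=float)))
    genes = np.array(ranked.index)[order]
    metric = ranked.to_numpy(dtype=float)[order]
    universe = set(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    tested = {}
    for term, members in gene_sets.items():
        inside = members & universe
        if min_size <= len(inside) <= max_size:
            tested[term] = inside
    if not tested:
        return []

    rng = np.random.default_rng(seed)
    n = len(genes)
    results = []
    for term in sorted(tested):
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in tested[term]]] = True
        es = _enrichment_score(metric, mask)
        m = int(mask.sum())
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=m, replace=False)] = True
            null[b] = _enrichment_score(metric, perm_mask)
        # significance against same-sign permutations (GSEA convention:
        # positive and negative enrichment are judged on their own tails)
        if es >= 0:
            same = null[null >= 0]
            p = (1 + int((same >= es).sum())) / (1 + same.size)
        else:
            same = null[null < 0]
            p = (1 + int((same <= es).sum())) / (1 + same.size)
        nes = es / np.abs(same).mean() if same.size else 0.0
        results.append((term, es, float(nes), p))

    raw_p = [r[3] for r in results]
    padj = multipletests(raw_p, method="fdr_bh")[1]
    out = [
        EnrichmentResult(term_id=t, es=e, nes=nes, p=p, padj=float(q))
        for (t, e, nes, p), q in zip(results, padj)
    ]
    out.sort(key=lambda r: (r.padj, r.p, r.term_id))
    return out


# ---------------------------------------------------------------------------
# channel combination


@dataclass
class AnnotationRecord:
    lncrna_id: str
    tissue_annotation: str = ""
    adjacent_genes: list = field(default_factory=list)
    enriched_terms: list = field(default_factory=list)

    @property
    def channels_used(self) -> set[str]:
        used = set()
        if self.tissue_annotation:
            used.add("tissue")
        if self.adjacent_genes:
            used.add("adjacent")
        if self.enriched_terms:
            used.add("coexpression")
        return used


def combine_annotations(
    universe,
    tissue: dict[str, str] | None = None,
    adjacent: dict[str, list] | None = None,
    coexpression: dict[str, list] | None = None,
):
    """Union-combine the three channels over a shared lncRNA universe.

    Returns ``(records, summary)``. The summary holds per-channel counts,
    the seven Venn cells, and the overall annotated percentage
    (100 * annotated / total, rounded to 2 decimals).
    """
    universe = list(universe)
    tissue = tissue or {}
    adjacent = adjacent or {}
    coexpression = coexpression or {}
    records = []
    t_set, a_set, c_set = set(), set(), set()
    for lid in universe:
        rec = AnnotationRecord(
            lncrna_id=lid,
            tissue_annotation=tissue.get(lid, ""),
            adjacent_genes=list(adjacent.get(lid, [])),
            enriched_terms=list(coexpression.get(lid, [])),
        )
        records.append(rec)
        if rec.tissue_annotation:
            t_set.add(lid)
        if rec.adjacent_genes:
            a_set.add(lid)
        if rec.enriched_terms:
            c_set.add(lid)
    annotated = t_set | a_set | c_set
    total = len(universe)
    summary = {
        "total": total,
        "annotated": len(annotated),
        "percent_annotated": round(100.0 * len(annotated) / total, 2) if total else 0.0,
        "per_channel": {
            "tissue": len(t_set),
            "adjacent": len(a_set),
            "coexpression": len(c_set),
        },
        "percent_per_channel": {
            "tissue": round(100.0 * len(t_set) / total, 2) if total else 0.0,
            "adjacent": round(100.0 * len(a_set) / total, 2) if total else 0.0,
            "coexpression": round(100.0 * len(c_set) / total, 2) if total else 0.0,
        },
        "venn": {
            "tissue_only": len(t_set - a_set - c_set),
            "adjacent_only": len(a_set - t_set - c_set),
            "coexpression_only": len(c_set - t_set - a_set),
            "tissue_adjacent": len((t_set & a_set) - c_set),
            "tissue_coexpression": len((t_set & c_set) - a_set),
            "adjacent_coexpression": len((a_set & c_set) - t_set),
            "all_three": len(t_set & a_set & c_set),
        },
    }
    return records, summary
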