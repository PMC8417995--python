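"""Mining the annotated lncRNA set for a pathway of interest.

Keyword selection over annotation channels, the lncRNA-gene bipartite
co-expression network, z-scored expression-pattern clustering, a
negative-correlation scan for candidate repressive lncRNA-gene pairs, and
empirical-Bayes moderated-t differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotationRecord, TomNetwork

CHANNELS = ("tissue", "adjacent", "coexpression")


@dataclass(frozen=True)
class KeywordQuery:
    """Free-text terms and/or GO ids searched across annotation channels.

    Text terms match case-insensitively as substrings; GO ids match
    exactly.
    """

    terms: tuple[str, ...]
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        if not self.terms:
            raise ValueError("query needs at least one term")
        bad = set(self.channels) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")


def _term_matches(term: str, text: str) -> bool:
    if term.upper().startswith("GO:"):
        return term.upper() == text.upper()
    return term.lower() in text.lower()


def select_related(
    annotations: list[AnnotationRecord],
    query: KeywordQuery,
    go_annotation: dict[str, set[str]] | None = None,
    term_names: dict[str, str] | None = None,
) -> set[str]:
    """lncRNAs whose searched channels contain any query term.

    - tissue channel: the tissue description text;
    - adjacent channel: adjacent gene ids, their GO ids (via
      ``go_annotation``), and GO term names (via ``term_names``);
    - coexpression channel: enriched GO term ids and names.
    """
    go_annotation = go_annotation or {}
    term_names = term_names or {}
    selected = set()
    for rec in annotations:
        texts: list[str] = []
        if "tissue" in query.channels and rec.tissue_annotation:
            texts.append(rec.tissue_annotation)
        if "adjacent" in query.channels:
            for entry in rec.adjacent_genes:
                gene_id = entry[0] if isinstance(entry, (tuple, list)) else entry
                texts.append(str(gene_id))
                for go_id in go_annotation.get(gene_id, ()):
                    texts.append(go_id)
                    if go_id in term_names:
                        texts.append(term_names[go_id])
        if "coexpression" in query.channels:
            for er in rec.enriched_terms:
                term_id = getattr(er, "term_id", er)
                texts.append(str(term_id))
                if term_id in term_names:
                    texts.append(term_names[term_id])
        if any(_term_matches(t, txt) for t in query.terms for txt in texts):
            selected.add(rec.lncrna_id)
    return selected


def build_bipartite_network(
    selected: set[str], tom: TomNetwork, coding_genes: set[str], threshold: float = 0.1
) -> pd.DataFrame:
    """All (lncRNA, coding gene) pairs with TOM weight strictly > threshold.

    Returns an edge DataFrame (lncrna_id, gene_id, weight) whose
    ``attrs`` carry the unique gene and pair counts.
    """
    idx = {nid: i for i, nid in enumerate(tom.node_ids)}
    missing = sorted(set(selected) - set(idx))
    if missing:
        raise KeyError(f"selected ids absent from TOM: {missing}")
    gene_ids = [g for g in tom.node_ids if g in coding_genes]
    rows = []
    for lnc in sorted(selected):
        weights = tom.tom[idx[lnc]]
        for g in gene_ids:
            if g == lnc:
                continue
            w = float(weights[idx[g]])
            if w > threshold:
                rows.append({"lncrna_id": lnc, "gene_id": g, "weight": w})
    edges = pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "weight"])
    edges.attrs["n_pairs"] = len(edges)
    edges.attrs["n_genes"] = edges["gene_id"].nunique() if len(edges) else 0
    return edges


# ---------------------------------------------------------------------------
# expression patterns


def scale_profile(values) -> np.ndarray:
    """z-score over ordered conditions (sample sd, n-1 denominator),
    matching R's scale(). Constant input is undefined."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 conditions to scale")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant profile cannot be scaled")
    return (x - x.mean()) / sd


def scale_matrix(df: pd.DataFrame):
    """Row-wise scaling; constant rows are excluded and returned."""
    rows, kept, dropped = [], [], []
    for rid, row in zip(df.index, df.to_numpy(dtype=float)):
        if row.std(ddof=1) == 0:
            dropped.append(rid)
        else:
            rows.append(scale_profile(row))
            kept.append(rid)
    return pd.DataFrame(rows, index=kept, columns=df.columns), dropped


def cluster_patterns(scaled: pd.DataFrame, k: int = 12, seed: int = 0):
    """K-means over scaled profiles, 10 restarts, clusters renumbered by
    descending size (1-based). Returns (labels Series, cluster-mean
    DataFrame)."""
    n = len(scaled)
    if n < k:
        raise ValueError(f"{n} profiles < k={k}; choose a smaller k")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(scaled.to_numpy(dtype=float))
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=scaled.index, name="cluster")
    means = pd.DataFrame(
        {c: scaled.loc[labels[labels == c].index].mean(axis=0) for c in sorted(relabel.values())}
    ).T
    means.index.name = "cluster"
    return labels, means


def negative_pair_scan(
    lnc_scaled: pd.DataFrame, gene_scaled: pd.DataFrame, r_threshold: float = -0.8
) -> pd.DataFrame:
    """Pearson correlation between every lncRNA and gene profile on the
    same ordered conditions; pairs at r <= r_threshold, sorted ascending
    by r."""
    if list(lnc_scaled.columns) != list(gene_scaled.columns):
        raise ValueError("lncRNA and gene profiles must share ordered conditions")
    A = lnc_scaled.to_numpy(dtype=float)
    B = gene_scaled.to_numpy(dtype=float)
    n = A.shape[1]
    Az = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    Bz = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    R = Az @ Bz.T / n
    rows = []
    for i, lid in enumerate(lnc_scaled.index):
        for j, gid in enumerate(gene_scaled.index):
            r = float(R[i, j])
            if r <= r_threshold:
                rows.append({"lncrna_id": lid, "gene_id": gid, "r": r})
    out = pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "r"])
    return out.sort_values(["r", "lncrna_id", "gene_id"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# differential expression (moderated t)


@dataclass(frozen=True)
class DifferentialResult:
    lncrna_id: str
    logfc: float
    t_mod: float
    p: float
    adj_p: float
    called: bool


def _fit_f_dist(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to observed variances on
    the log scale: var(log s^2) = trigamma(d/2) + trigamma(d0/2)."""
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e_z = z.mean()
    var_z = z.var(ddof=1) if s2.size > 1 else 0.0
    target = var_z - float(special.polygamma(1, df_resid / 2))
    if target <= 1e-8:
        return np.inf, float(np.exp(e_z - special.digamma(df_resid / 2) + np.log(df_resid / 2)))
    # invert trigamma by Newton iteration (limma-style)
    y = 0.5 + 1.0 / target
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / target) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    d0 = 2.0 * y
    log_s0 = (
        e_z
        - float(special.digamma(df_resid / 2)) + np.log(df_resid / 2)
        + float(special.digamma(d0 / 2)) - np.log(d0 / 2)
    )
    return d0, float(np.exp(log_s0))


def de_lncrna(
    expr_values: pd.DataFrame,
    groups,
    logfc_min: float = 2.0,
    alpha: float = 0.001,
) -> list[DifferentialResult]:
    """Two-group moderated-t differential expression on log2(TPM + 1).

    ``groups`` assigns each sample (column) a label; exactly two labels,
    each with >= 2 samples. logFC is the mean difference (second label in
    order of first appearance minus the first). The per-row variance is
    shrunk toward a moment-matched scaled-F prior and tested on
    d0 + d_residual degrees of freedom; BH across rows; a row is called
    when |logFC| > logfc_min and adj_p < alpha (both strict).
    """
    groups = list(groups)
    if len(groups) != expr_values.shape[1]:
        raise ValueError("one group label per sample required")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1 = [i for i, g in enumerate(groups) if g == labels[0]]
    g2 = [i for i, g in enumerate(groups) if g == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")
    logx = np.log2(expr_values.to_numpy(dtype=float) + 1.0)
    x1, x2 = logx[:, g1], logx[:, g2]
    n1, n2 = len(g1), len(g2)
    logfc = x2.mean(axis=1) - x1.mean(axis=1)
    df_resid = n1 + n2 - 2
    pooled = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    d0, s0_2 = _fit_f_dist(pooled, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(pooled, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * pooled) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = logfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    adj = multipletests(p, method="fdr_bh")[1]
    return [
        DifferentialResult(
            lncrna_id=rid,
            logfc=float(fc),
            t_mod=float(t),
            p=float(pv),
            adj_p=float(q),
            called=bool(abs(fc) > logfc_min and q < alpha),
        )
        for rid, fc, t, pv, q in zip(expr_values.index, logfc, t_mod, p, adj)
    ]
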