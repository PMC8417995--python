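"""Promoter motif scanning and reciprocal-best-hit orthology.

PWM hits are scored as log-odds (bits) against a background model; exact
p-values come from a dynamic-programming convolution of the per-column
score distributions on a discretized (1e-3 bit) grid — no simulation.
Orthologs are inferred from two outfmt-6 hit tables in two tiers: mutual
best hits (primary) and top-three forward hits below the peak of the
best-hit e-value distribution (secondary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import TranscriptModel

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SCORE_BIN_BITS = 1e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix: width x 4 base probabilities (A, C, G, T).

    ``pseudocount`` is added per cell before normalization so log-odds
    stay finite even for degenerate columns.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if (self.matrix < 0).any():
            raise ValueError("negative probabilities in PWM")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def probabilities(self) -> np.ndarray:
        """Per-column probabilities after pseudocount normalization
        (each row sums to 1)."""
        m = self.matrix + self.pseudocount
        return m / m.sum(axis=1, keepdims=True)

    def log_odds_bits(self) -> np.ndarray:
        """width x 4 log2(p / background) scoring matrix."""
        return np.log2(self.probabilities() / self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    motif_id: str
    offset: int
    strand: str
    score: float
    p_value: float


def _score_grid(pwm: PWM) -> np.ndarray:
    """Integer (binned) log-odds scores, width x 4."""
    return np.rint(pwm.log_odds_bits() / SCORE_BIN_BITS).astype(np.int64)


def _null_survival(pwm: PWM):
    """Exact null score distribution by DP over the background model.

    Returns ``(offset, sf)`` where ``sf[k - offset] = P(score_bin >= k)``
    for binned total scores ``k``.
    """
    grid = _score_grid(pwm)
    bg = pwm.background
    # convolve column by column; each column contributes one of 4 shifts
    cur = np.ones(1)
    cur_lo = 0
    for col in range(pwm.width):
        shifts = grid[col]
        new_lo = cur_lo + int(shifts.min())
        new_hi = cur_lo + len(cur) - 1 + int(shifts.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            s = int(shifts[b])
            start = cur_lo + s - new_lo
            new[start:start + len(cur)] += bg[b] * cur
        cur, cur_lo = new, new_lo
    sf = np.cumsum(cur[::-1])[::-1]
    return cur_lo, sf


def _scan_one_strand(seq: str, grid: np.ndarray, null_lo: int, sf: np.ndarray):
    """Binned window scores and p-values along one strand."""
    w = grid.shape[0]
    n = len(seq)
    if n < w:
        return np.empty(0, dtype=np.int64), np.empty(0)
    codes = np.full(n, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    n_win = n - w + 1
    scores = np.zeros(n_win, dtype=np.int64)
    n_count = np.zeros(n_win, dtype=np.int64)
    for col in range(w):
        c = codes[col:col + n_win]
        col_scores = np.where(c >= 0, grid[col][np.clip(c, 0, 3)], 0)
        scores += col_scores
        n_count += (c < 0).astype(np.int64)
    idx = np.clip(scores - null_lo, 0, len(sf) - 1)
    p = sf[idx].copy()
    p[scores - null_lo < 0] = 1.0
    p[scores - null_lo >= len(sf)] = sf[-1]
    # windows dominated by N carry no motif information
    p[n_count * 2 > w] = 1.0
    return scores, p


def scan_pwm(
    promoter: str,
    pwm: PWM,
    threshold: float = 1e-6,
    promoter_id: str = "promoter",
) -> list[MotifHit]:
    """Scan both strands of a promoter for PWM hits with exact p < threshold.

    Scores are log-odds in bits; ``N`` positions contribute 0. The
    p-value of a window is the exact probability, under the background
    model, of a random width-w word scoring at least as high (computed on
    the discretized score grid). Hits are sorted by p ascending, ties by
    offset then strand.
    """
    seq = promoter.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("promoter sequence must be over ACGTN")
    if len(seq) < pwm.width:
        return []
    grid = _score_grid(pwm)
    null_lo, sf = _null_survival(pwm)
    hits = []
    fwd_scores, fwd_p = _scan_one_strand(seq, grid, null_lo, sf)
    for off, (s, p) in enumerate(zip(fwd_scores, fwd_p)):
        if p < threshold:
            hits.append(MotifHit(promoter_id, pwm.motif_id, off, "+",
                                 float(s * SCORE_BIN_BITS), float(p)))
    rc = reverse_complement(seq)
    rev_scores, rev_p = _scan_one_strand(rc, grid, null_lo, sf)
    L, w = len(seq), pwm.width
    for i, (s, p) in enumerate(zip(rev_scores, rev_p)):
        if p < threshold:
            hits.append(MotifHit(promoter_id, pwm.motif_id, L - i - w, "-",
                                 float(s * SCORE_BIN_BITS), float(p)))
    hits.sort(key=lambda h: (h.p_value, h.offset, h.strand))
    return hits


def score_pvalue(pwm: PWM, score_bits: float) -> float:
    """Exact P(null score >= score_bits) on the discretized grid."""
    null_lo, sf = _null_survival(pwm)
    k = int(np.rint(score_bits / SCORE_BIN_BITS)) - null_lo
    if k < 0:
        return 1.0
    if k >= len(sf):
        return 0.0
    return float(sf[k])


# ---------------------------------------------------------------------------
# promoters


def extract_promoter(
    lncrna: TranscriptModel, genome: dict[str, str], length: int = 3000
) -> tuple[str, int]:
    """The ``length``-bp region upstream of the transcript's 5' end.

    Plus strand: genomic [TSS - length, TSS); minus strand:
    [TSS, TSS + length) reverse-complemented. Truncated at contig
    boundaries; returns ``(sequence, actual_length)``.
    """
    if lncrna.chrom not in genome:
        raise KeyError(f"contig {lncrna.chrom} absent from genome")
    contig = genome[lncrna.chrom]
    tss = lncrna.tss
    if lncrna.strand == "+":
        start = max(0, tss - length)
        seq = contig[start:tss]
    else:
        end = min(len(contig), tss + length)
        seq = reverse_complement(contig[tss:end])
    return seq, len(seq)


# ---------------------------------------------------------------------------
# reciprocal best hits


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    e_forward: float
    e_reverse: float
    tier: str
    rank_forward: int


def _ranked_hits(table: pd.DataFrame) -> pd.DataFrame:
    """Hits sorted per query by (e-value asc, bit score desc, subject id)."""
    return table.sort_values(
        ["query_id", "e_value", "bit_score", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )


def _best_hits(table: pd.DataFrame) -> dict[str, tuple[str, float]]:
    best = {}
    for row in _ranked_hits(table).itertuples(index=False):
        if row.query_id not in best:
            best[row.query_id] = (row.subject_id, float(row.e_value))
    return best


def evalue_peak(best_evalues) -> float:
    """Mode of the best-hit e-value distribution, located on the log10
    scale with Freedman-Diaconis bins (e = 0 mapped to 1e-200). Returns
    the e-value at the modal bin center."""
    e = np.asarray(list(best_evalues), dtype=float)
    if e.size == 0:
        return 0.0
    loge = np.log10(np.maximum(e, 1e-200))
    if np.allclose(loge, loge[0]):
        return float(10 ** loge[0])
    q75, q25 = np.percentile(loge, [75, 25])
    if q75 - q25 <= 0:
        # degenerate spread: the mode is the most common exact value
        vals, counts = np.unique(np.round(loge, 6), return_counts=True)
        return float(10 ** vals[np.argmax(counts)])
    edges = np.histogram_bin_edges(loge, bins="fd")
    if len(edges) < 3:
        return float(10 ** np.median(loge))
    counts, edges = np.histogram(loge, bins=edges)
    mode_bin = int(np.argmax(counts))
    center = (edges[mode_bin] + edges[mode_bin + 1]) / 2
    return float(10 ** center)


def rbh_orthologs(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, secondary_rule: bool = True
) -> list[OrthologPair]:
    """Two-tier ortholog inference from reciprocal hit tables.

    Primary tier: mutual best hits (best = lowest e-value, ties by higher
    bit score then lexicographic subject id). Secondary tier: non-primary
    pairs among each query's top-three forward hits whose e-value is
    strictly below the peak of the pooled best-hit e-value distribution
    (see :func:`evalue_peak`). Sorted by tier then forward e-value.
    """
    if hits_ab.empty or hits_ba.empty:
        return []
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    rev_e = {(q, s): e for q, (s, e) in best_ba.items()}

    pairs: list[OrthologPair] = []
    primary = set()
    for a, (b, e_fwd) in best_ab.items():
        if best_ba.get(b, (None,))[0] == a:
            primary.add((a, b))
            pairs.append(OrthologPair(a, b, e_fwd, rev_e.get((b, a), np.nan),
                                      "primary", 1))
    if secondary_rule:
        pooled = [e for _, e in best_ab.values()] + [e for _, e in best_ba.values()]
        peak = evalue_peak(pooled)
        ranked = _ranked_hits(hits_ab)
        ranked = ranked.assign(rank=ranked.groupby("query_id").cumcount() + 1)
        top3 = ranked[ranked["rank"] <= 3]
        for row in top3.itertuples(index=False):
            pair = (row.query_id, row.subject_id)
            if pair in primary:
                continue
            if float(row.e_value) < peak:
                rev = best_ba.get(row.subject_id)
                pairs.append(
                    OrthologPair(
                        row.query_id, row.subject_id, float(row.e_value),
                        float(rev[1]) if rev and rev[0] == row.query_id else np.nan,
                        "secondary", int(row.rank),
                    )
                )
    tier_order = {"primary": 0, "secondary": 1}
    pairs.sort(key=lambda p: (tier_order[p.tier], p.e_forward, p.id_a, p.id_b))
    return pairs
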