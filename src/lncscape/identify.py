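"""Transcript-to-lncRNA identification.

Assembled transcripts are compared against the reference annotation
(cuffcompare-style class codes), screened against organelle and known-ncRNA
intervals, merged across samples, passed through a two-classifier
contamination filter trained on "="-vs-"i" transcripts, and finally through
a coding-ability cascade (similarity, length, coding potential, protein
domains). Every step is a contraction with a removal log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import ExpressionMatrix, GenomeAnnotation, TranscriptModel

CLASS_CODES = ("=", "j", "i", "x", "o", "u")
#: precedence when several codes could describe the same comparison
CODE_PRECEDENCE = ("=", "j", "i", "x", "o", "u")

FEATURE_NAMES = ("recurrence_ratio", "max_tpm", "mean_tpm", "length", "exon_count")


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the identification cascade (all boundaries as printed:
    overlaps are strict ``>``, similarity is a conjunction, length is
    strict ``<`` for removal)."""

    organelle_overlap: float = 0.75
    ncrna_overlap: float = 0.3
    sim_evalue: float = 1e-4
    sim_alen: int = 40
    sim_pid: float = 35.0
    min_length: int = 150
    domain_evalue: float = 1e-4
    retained_codes: tuple[str, ...] = ("j", "u", "x", "o")

    def __post_init__(self):
        if not (0 < self.organelle_overlap <= 1 and 0 < self.ncrna_overlap <= 1):
            raise ValueError("overlap thresholds must lie in (0, 1]")
        for v in (self.sim_evalue, self.sim_alen, self.sim_pid,
                  self.min_length, self.domain_evalue):
            if v <= 0:
                raise ValueError("thresholds must be strictly positive")


# ---------------------------------------------------------------------------
# interval helpers


def _merge_intervals(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersection_bp(a, b):
    """Total bp shared by two sorted non-overlapping interval lists."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    if a.chrom != b.chrom:
        return 0
    return _intersection_bp(list(a.exons), list(b.exons))


# ---------------------------------------------------------------------------
# class-code assignment


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel) -> float:
    ov = exonic_overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.exonic_length, ov / b.exonic_length)


def _is_equal(query: TranscriptModel, ref: TranscriptModel) -> bool:
    if query.strand != ref.strand or query.chrom != ref.chrom:
        return False
    if query.exon_count > 1 or ref.exon_count > 1:
        return query.exon_count > 1 and ref.exon_count > 1 and query.introns == ref.introns
    return _reciprocal_overlap(query, ref) >= 0.95


def _within_single_intron(query: TranscriptModel, ref: TranscriptModel) -> bool:
    if query.strand != ref.strand or query.chrom != ref.chrom:
        return False
    qs, qe = query.span
    return any(s <= qs and qe <= e for s, e in ref.introns)


def assign_class_code(query: TranscriptModel, reference: GenomeAnnotation) -> str:
    """Assign the cuffcompare-style class code of ``query`` vs. a reference.

    Codes, in precedence order ``= > j > i > x > o > u``:

    - ``=``  identical intron chain with a same-strand reference transcript
      (mono-exonic pairs: reciprocal exonic overlap >= 0.95);
    - ``j``  shares >= 1 splice junction with a same-strand reference
      transcript, but is not ``=``;
    - ``i``  all exons inside a single intron of a same-strand reference
      transcript;
    - ``x``  exonic overlap with a reference transcript on the opposite
      strand;
    - ``o``  same-strand exonic overlap without a shared junction;
    - ``u``  none of the above (intergenic).
    """
    if reference.contig_lengths and query.chrom not in reference.chroms:
        raise ValueError(f"contig {query.chrom} absent from reference")
    refs = reference.transcripts_on(query.chrom)
    q_junc = set(query.introns)
    saw_j = saw_i = saw_x = saw_o = False
    for ref in refs:
        if _is_equal(query, ref):
            return "="
        same = ref.strand == query.strand
        if same and q_junc and q_junc & set(ref.introns):
            saw_j = True
            continue
        ov = exonic_overlap_bp(query, ref)
        if same and _within_single_intron(query, ref):
            saw_i = True
        elif ov > 0:
            if same:
                saw_o = True
            else:
                saw_x = True
    for code, flag in (("j", saw_j), ("i", saw_i), ("x", saw_x), ("o", saw_o)):
        if flag:
            return code
    return "u"


# ---------------------------------------------------------------------------
# organelle / ncRNA interval filters


def overlap_ratio(query: TranscriptModel, intervals: dict[str, list[tuple[int, int]]]) -> float:
    """Fraction of the query's exonic bp covered by ``intervals``
    (strand-agnostic; 0.0 when nothing overlaps)."""
    ivs = _merge_intervals(intervals.get(query.chrom, []))
    if not ivs:
        return 0.0
    return _intersection_bp(list(query.exons), ivs) / query.exonic_length


def organelle_and_ncrna_filter(
    transcripts,
    organelle: dict[str, list[tuple[int, int]]],
    ncrna: dict[str, list[tuple[int, int]]],
    thresholds: FilterThresholds = FilterThresholds(),
):
    """Drop transcripts overlapping organelle intervals > 0.75 of their
    exonic length, or known ncRNAs > 0.3 (both strictly greater-than).

    Returns ``(kept, removal_log)`` where the log is a DataFrame with
    columns (transcript_id, filter, ratio).
    """
    kept, log = [], []
    for t in transcripts:
        r_org = overlap_ratio(t, organelle)
        if r_org > thresholds.organelle_overlap:
            log.append({"transcript_id": t.transcript_id, "filter": "organelle", "ratio": r_org})
            continue
        r_nc = overlap_ratio(t, ncrna)
        if r_nc > thresholds.ncrna_overlap:
            log.append({"transcript_id": t.transcript_id, "filter": "ncrna", "ratio": r_nc})
            continue
        kept.append(t)
    return kept, pd.DataFrame(log, columns=["transcript_id", "filter", "ratio"])


# ---------------------------------------------------------------------------
# cross-sample merge


@dataclass
class MergeResult:
    """Outcome of the cross-sample merge.

    ``representatives`` carry the shared geometry (one transcript per
    distinct structure); ``recurrence`` counts the distinct contributing
    samples; ``loci`` are connected components of same-strand exonic
    overlap among representatives.
    """

    representatives: list[TranscriptModel]
    recurrence: dict[str, int]
    members: dict[str, list[str]]
    loci: dict[str, list[str]] = field(default_factory=dict)

    @property
    def shared_locus_fraction(self) -> float:
        """Fraction of representatives sharing their locus with another."""
        n = len(self.representatives)
        if n == 0:
            return 0.0
        shared = sum(len(tids) for tids in self.loci.values() if len(tids) >= 2)
        return shared / n


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def merge_transcripts(transcripts) -> MergeResult:
    """Collapse structurally identical transcripts across samples.

    Multi-exon transcripts merge on identical (chrom, strand, intron
    chain); mono-exonic ones merge transitively on same-strand reciprocal
    exonic overlap >= 0.95. The representative of a group is its longest
    member (ties: lexicographically smallest id).
    """
    transcripts = list(transcripts)
    n = len(transcripts)
    uf = _UnionFind(n)
    multi: dict[tuple, int] = {}
    mono_by_key: dict[tuple, list[int]] = {}
    for idx, t in enumerate(transcripts):
        if t.exon_count > 1:
            key = (t.chrom, t.strand, t.introns)
            if key in multi:
                uf.union(idx, multi[key])
            else:
                multi[key] = idx
        else:
            mono_by_key.setdefault((t.chrom, t.strand), []).append(idx)
    for idxs in mono_by_key.values():
        idxs.sort(key=lambda i: transcripts[i].start)
        for a_pos, i in enumerate(idxs):
            ti = transcripts[i]
            for j in idxs[a_pos + 1:]:
                tj = transcripts[j]
                if tj.start >= ti.end:
                    break
                if _reciprocal_overlap(ti, tj) >= 0.95:
                    uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for idx in range(n):
        groups.setdefault(uf.find(idx), []).append(idx)

    reps: list[TranscriptModel] = []
    recurrence: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for idxs in groups.values():
        ts = [transcripts[i] for i in idxs]
        rep = max(ts, key=lambda t: (t.exonic_length, t.transcript_id))
        samples = {t.source_sample for t in ts if t.source_sample}
        reps.append(rep)
        recurrence[rep.transcript_id] = max(len(samples), 1)
        members[rep.transcript_id] = sorted(t.transcript_id for t in ts)
    reps.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))

    # loci: connected components of same-strand exonic overlap
    uf2 = _UnionFind(len(reps))
    by_key: dict[tuple, list[int]] = {}
    for idx, t in enumerate(reps):
        by_key.setdefault((t.chrom, t.strand), []).append(idx)
    for idxs in by_key.values():
        idxs.sort(key=lambda i: reps[i].start)
        active: list[int] = []
        for i in idxs:
            active = [j for j in active if reps[j].end > reps[i].start]
            for j in active:
                if exonic_overlap_bp(reps[i], reps[j]) > 0:
                    uf2.union(i, j)
            active.append(i)
    comp: dict[int, list[str]] = {}
    for idx, t in enumerate(reps):
        comp.setdefault(uf2.find(idx), []).append(t.transcript_id)
    loci = {f"LOC{k:06d}": sorted(tids) for k, tids in enumerate(comp.values())}
    return MergeResult(reps, recurrence, members, loci)


# ---------------------------------------------------------------------------
# contamination filter (two classifiers over five features)


def extract_features(
    transcript: TranscriptModel, recurrence: int, expr: ExpressionMatrix
) -> np.ndarray:
    """Five-feature vector: (recurrence ratio, max TPM, mean TPM, exonic
    length, exon count)."""
    if transcript.transcript_id not in expr.values.index:
        raise KeyError(f"transcript {transcript.transcript_id} missing from expression matrix")
    row = expr.profile(transcript.transcript_id)
    n_samples = len(expr.sample_ids)
    vec = np.array(
        [recurrence / n_samples, row.max(), row.mean(),
         transcript.exonic_length, transcript.exon_count],
        dtype=float,
    )
    if not np.isfinite(vec).all():
        raise ValueError(f"non-finite feature for {transcript.transcript_id}")
    if not 0 <= vec[0] <= 1:
        raise ValueError("recurrence ratio outside [0, 1]")
    return vec


LABEL_EQUAL = "equal_like"
LABEL_INTRONIC = "intronic_like"
COMBINATION_RULES = ("both_agree", "either", "forest_only", "margin_only")


class ContaminationModel:
    """Forest-style + margin-style classifier pair over the five features.

    Mirrors the random-forest / SVM pairing used to separate reference
    matches ("=") from intronic artifacts ("i"); the combination rule
    decides how the two votes merge when filtering candidates.
    """

    def __init__(self, combination_rule: str = "both_agree", seed: int = 0):
        if combination_rule not in COMBINATION_RULES:
            raise ValueError(f"unknown combination rule {combination_rule!r}")
        self.combination_rule = combination_rule
        self.seed = seed
        self.forest = RandomForestClassifier(random_state=seed)
        self.margin = make_pipeline(StandardScaler(), SVC(random_state=seed))
        self.fitted = False
        self.training_summary: dict = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ContaminationModel":
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("both classes required to train the contamination filter")
        if counts.min() < 20:
            raise ValueError("need >= 20 examples per class")
        if counts.max() / counts.min() > 50:
            import warnings

            warnings.warn("class imbalance exceeds 50:1", stacklevel=2)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=0.2, stratify=y, random_state=self.seed
        )
        self.forest.fit(X_tr, y_tr)
        self.margin.fit(X_tr, y_tr)
        self.training_summary = {
            "class_counts": {str(c): int(n) for c, n in zip(classes, counts)},
            "holdout_accuracy_forest": float((self.forest.predict(X_te) == y_te).mean()),
            "holdout_accuracy_margin": float((self.margin.predict(X_te) == y_te).mean()),
        }
        self.fitted = True
        return self

    def predict_intronic(self, X: np.ndarray) -> np.ndarray:
        """Boolean mask: True where the combined rule says intronic_like."""
        if not self.fitted:
            raise RuntimeError("contamination model is not fitted")
        X = np.asarray(X, dtype=float)
        f = self.forest.predict(X) == LABEL_INTRONIC
        m = self.margin.predict(X) == LABEL_INTRONIC
        if self.combination_rule == "both_agree":
            return f & m
        if self.combination_rule == "either":
            return f | m
        if self.combination_rule == "forest_only":
            return f
        return m


def train_contamination_filter(
    eq_features, intron_features, combination_rule: str = "both_agree", seed: int = 0
) -> ContaminationModel:
    """Fit the two classifiers on "="-labelled vs. "i"-labelled features."""
    eq = np.asarray(list(eq_features), dtype=float)
    intron = np.asarray(list(intron_features), dtype=float)
    if eq.size == 0 or intron.size == 0:
        raise ValueError("one training class is empty")
    X = np.vstack([eq, intron])
    y = np.array([LABEL_EQUAL] * len(eq) + [LABEL_INTRONIC] * len(intron))
    return ContaminationModel(combination_rule, seed).fit(X, y)


def apply_contamination_filter(model: ContaminationModel, candidates: dict[str, np.ndarray]):
    """Partition candidate ids into (kept, removed) by the fitted model."""
    ids = sorted(candidates)
    if not ids:
        return [], []
    X = np.vstack([candidates[i] for i in ids])
    intronic = model.predict_intronic(X)
    kept = [i for i, bad in zip(ids, intronic) if not bad]
    removed = [i for i, bad in zip(ids, intronic) if bad]
    return kept, removed


# ---------------------------------------------------------------------------
# coding-ability cascade

# Fickett TESTCODE lookup tables (position bias and base composition),
# as published for the original algorithm and reused by CPAT.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CodingEvidence:
    longest_orf_aa: int
    orf_coverage: float
    fickett_score: float
    verdict: str


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic from codon-position bias and base
    composition (higher = more coding-like; classic coding cutoff 0.95)."""
    seq = sequence.upper()
    total = len(seq)
    score = 0.0
    for base in "ACGT":
        pos_counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                pos_counts[i % 3] += 1
        pos_value = max(pos_counts) / (min(pos_counts) + 1)
        content = sum(pos_counts) / total if total else 0.0
        for para, prob in zip(_POSITION_PARA, _POSITION_PROB[base]):
            if pos_value >= para:
                score += prob * _POSITION_WEIGHT[base]
                break
        for para, prob in zip(_CONTENT_PARA, _CONTENT_PROB[base]):
            if content >= para:
                score += prob * _CONTENT_WEIGHT[base]
                break
    return score


def _longest_orf(seq: str) -> tuple[int, int]:
    """Longest forward-frame ORF: returns (aa between ATG and stop/end,
    nt length of the ORF including ATG and any stop)."""
    best_aa, best_nt = 0, 0
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i:i + 3] == "ATG":
                j = i + 3
                stopped = False
                while j + 3 <= n:
                    if seq[j:j + 3] in _STOPS:
                        stopped = True
                        break
                    j += 3
                aa = (j - i - 3) // 3
                nt = j - i + (3 if stopped else 0)
                if aa > best_aa or (aa == best_aa and nt > best_nt):
                    best_aa, best_nt = aa, nt
                i = j + 3 if stopped else n
            else:
                i += 3
    return best_aa, best_nt


def score_coding_potential(sequence: str) -> CodingEvidence:
    """ORF + Fickett coding-potential call.

    ``longest_orf_aa`` counts the sense codons strictly between the ATG and
    the stop (or sequence end). Verdict is "coding" iff the ORF reaches
    100 aa, or the Fickett score reaches 0.95 with an ORF of at least
    50 aa.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    aa, nt = _longest_orf(seq)
    fick = fickett_score(seq)
    coding = aa >= 100 or (fick >= 0.95 and aa >= 50)
    return CodingEvidence(
        longest_orf_aa=aa,
        orf_coverage=nt / len(seq),
        fickett_score=fick,
        verdict="coding" if coding else "noncoding",
    )


def coding_ability_cascade(
    transcripts,
    sequences: dict[str, str],
    sim_hits: pd.DataFrame,
    domain_hits: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
    external_verdicts: dict[str, str] | None = None,
):
    """Remove coding transcripts in four ordered stages.

    1. similarity: any protein hit with e-value < 1e-4 AND alignment
       length >= 40 aa AND identity >= 35% (all three jointly);
    2. length: exonic length < 150 bp;
    3. coding potential: verdict "coding" from
       :func:`score_coding_potential` (or an external verdict table);
    4. domain: any domain hit with e-value < 1e-4.

    Returns ``(kept, log)``; the log records each removed id once with its
    stage, plus per-stage survivor counts in ``log.attrs['survivors']``.
    """
    transcripts = list(transcripts)
    for t in transcripts:
        if t.transcript_id not in sequences:
            raise KeyError(f"transcript {t.transcript_id} missing from FASTA")

    sim_bad: set[str] = set()
    if sim_hits is not None and not sim_hits.empty:
        mask = (
            (sim_hits["e_value"] < thresholds.sim_evalue)
            & (sim_hits["alignment_length"] >= thresholds.sim_alen)
            & (sim_hits["percent_identity"] >= thresholds.sim_pid)
        )
        sim_bad = set(sim_hits.loc[mask, "query_id"])
    dom_bad: set[str] = set()
    if domain_hits is not None and not domain_hits.empty:
        dom_bad = set(
            domain_hits.loc[domain_hits["e_value"] < thresholds.domain_evalue, "query_id"]
        )

    log_rows = []
    survivors = {}
    current = transcripts

    def _stage(name, keep_pred):
        nonlocal current
        kept = []
        for t in current:
            if keep_pred(t):
                kept.append(t)
            else:
                log_rows.append({"transcript_id": t.transcript_id, "stage": name})
        current = kept
        survivors[name] = len(kept)

    _stage("similarity", lambda t: t.transcript_id not in sim_bad)
    _stage("length", lambda t: t.exonic_length >= thresholds.min_length)
    if external_verdicts is not None:
        _stage("coding_potential",
               lambda t: external_verdicts.get(t.transcript_id, "noncoding") != "coding")
    else:
        _stage("coding_potential",
               lambda t: score_coding_potential(sequences[t.transcript_id]).verdict != "coding")
    _stage("domain", lambda t: t.transcript_id not in dom_bad)

    log = pd.DataFrame(log_rows, columns=["transcript_id", "stage"])
    log.attrs["survivors"] = survivors
    return current, log


def transcript_sequence(transcript: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence (reverse-complemented on '-')."""
    from Bio.Seq import Seq

    seq = "".join(genome[transcript.chrom][s:e] for s, e in transcript.exons)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
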