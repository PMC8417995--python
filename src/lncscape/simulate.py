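"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study conditions end to end: a random genome
with an annotated gene complement, multi-sample transcript assemblies whose
class codes are known by construction (including organelle / known-ncRNA /
coding contaminants straddling the filter thresholds), an expression matrix
with planted tissue-specific, co-expressed and anti-correlated members,
promoters with embedded motif instances, and reciprocal alignment tables
with planted orthologs. Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .types import HIT_COLUMNS, ExpressionMatrix, GenomeAnnotation, TranscriptModel

_BASES = np.array(list("ACGT"))

DEFAULT_TISSUES = (
    "shoot", "root", "leaf", "rhizome", "culm", "sheath", "bud", "flower",
    "seed", "seedling", "internode", "node", "panicle", "stem apex",
    "young shoot", "lateral branch",
)

RETAINED_CODES = ("j", "u", "x", "o")


@dataclass
class SyntheticTruth:
    """Planted ground truth, recoverable by the corresponding stages."""

    true_class_code: dict = field(default_factory=dict)        # base id -> code
    contaminated_ids: dict = field(default_factory=dict)       # base id -> kind
    planted_specific: dict = field(default_factory=dict)       # lnc id -> tissue
    planted_modules: list = field(default_factory=list)        # [[ids], ...]
    planted_negative_pairs: list = field(default_factory=list) # [(lnc, gene)]
    planted_motif_hits: dict = field(default_factory=dict)     # prom -> [(off, strand)]
    planted_orthologs: list = field(default_factory=list)      # [(idA, idB)]

    def expected_lncrnas(self) -> set[str]:
        """Base ids a correct identification run should retain: planted
        retained-code transcripts that are not contaminants."""
        return {
            tid for tid, code in self.true_class_code.items()
            if code in RETAINED_CODES and tid not in self.contaminated_ids
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_negative_pairs"] = [tuple(p) for p in d["planted_negative_pairs"]]
        d["planted_orthologs"] = [tuple(p) for p in d["planted_orthologs"]]
        d["planted_motif_hits"] = {
            k: [tuple(h) for h in v] for k, v in d["planted_motif_hits"].items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeParams:
    n_contigs: int = 2
    contig_len: int = 300_000
    n_genes: int = 60
    organelle_len: int = 30_000
    min_exons: int = 1
    max_exons: int = 8


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_genome(params: GenomeParams = GenomeParams(), seed: int = 0):
    """Random genome plus a non-overlapping gene annotation.

    Main contigs carry the genes; two dedicated organelle contigs
    (``chrC``, ``chrM``) carry none. Gene structures have 1-8 exons on
    either strand. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    contigs = [f"chr{i + 1}" for i in range(params.n_contigs)]
    genome = {c: _random_seq(rng, params.contig_len) for c in contigs}
    genome["chrC"] = _random_seq(rng, params.organelle_len)
    genome["chrM"] = _random_seq(rng, params.organelle_len)
    contig_lengths = {c: len(s) for c, s in genome.items()}

    transcripts = []
    per_contig = [params.n_genes // params.n_contigs] * params.n_contigs
    for i in range(params.n_genes % params.n_contigs):
        per_contig[i] += 1
    gene_no = 0
    for contig, n_here in zip(contigs, per_contig):
        cursor = int(rng.integers(2000, 5000))
        for _ in range(n_here):
            n_exons = int(rng.integers(params.min_exons, params.max_exons + 1))
            exons = []
            pos = cursor
            for k in range(n_exons):
                elen = int(rng.integers(120, 401))
                exons.append((pos, pos + elen))
                pos += elen
                if k < n_exons - 1:
                    pos += int(rng.integers(150, 801))
            gap = int(rng.integers(2500, 5000))
            if pos + gap > params.contig_len:
                raise ValueError(
                    "gene density infeasible: increase contig_len or reduce n_genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"GENE{gene_no:04d}"
            transcripts.append(
                TranscriptModel(f"{gid}.1", gid, contig, strand, tuple(exons))
            )
            gene_no += 1
            cursor = pos + gap
    return genome, GenomeAnnotation(transcripts, contig_lengths)


# ---------------------------------------------------------------------------
# assembly with planted class codes and contaminants


@dataclass(frozen=True)
class AssemblyParams:
    n_transcripts: int = 240
    rates: tuple = (("=", 0.25), ("j", 0.15), ("i", 0.15),
                    ("u", 0.25), ("x", 0.10), ("o", 0.10))
    organelle_ratios: tuple = (0.5, 0.74, 0.76, 0.9, 1.0, 0.5, 0.74, 0.76, 0.9, 1.0)
    ncrna_ratios: tuple = (0.2, 0.29, 0.31, 0.6, 0.9, 1.0, 0.29, 0.31)
    n_coding_orf: int = 6
    n_coding_sim: int = 4
    n_coding_domain: int = 2
    n_short: int = 3
    max_geometry_tries: int = 50


@dataclass
class AssemblyResult:
    transcripts: list            # per-sample TranscriptModel, id "base|sample"
    truth: SyntheticTruth
    genome: dict                 # genome with planted ORFs written in
    organelle_bed: dict
    ncrna_bed: dict
    sim_hits: pd.DataFrame       # keyed by base id
    domain_hits: pd.DataFrame
    recurrence_plan: dict        # base id -> sample list
    base_levels: dict            # base id -> expression baseline (TPM scale)


class _FreeSpace:
    """Intergenic free intervals per contig, consumed as placements
    are made so planted transcripts never coincide."""

    def __init__(self, annotation: GenomeAnnotation, margin: int = 300):
        self.free: dict[str, list[tuple[int, int]]] = {}
        spans = sorted(
            (chrom, s - margin, e + margin)
            for _, (chrom, s, e) in annotation.gene_spans().items()
        )
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in spans:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, length in annotation.contig_lengths.items():
            if chrom in ("chrC", "chrM"):
                continue
            occupied = by_chrom.get(chrom, [])
            gaps, prev = [], 100
            for s, e in occupied:
                if s - prev >= 600:
                    gaps.append((prev, s))
                prev = max(prev, e)
            if length - 100 - prev >= 600:
                gaps.append((prev, length - 100))
            self.free[chrom] = gaps

    def take(self, rng, size: int) -> tuple[str, int]:
        candidates = [
            (chrom, i) for chrom, gaps in self.free.items()
            for i, (s, e) in enumerate(gaps) if e - s >= size + 100
        ]
        if not candidates:
            raise ValueError("no intergenic space left for planted transcripts")
        chrom, i = candidates[int(rng.integers(0, len(candidates)))]
        s, e = self.free[chrom][i]
        start = int(rng.integers(s, e - size - 50))
        # split the gap
        rest = []
        if start - s >= 600:
            rest.append((s, start))
        if e - (start + size + 50) >= 600:
            rest.append((start + size + 50, e))
        self.free[chrom] = self.free[chrom][:i] + rest + self.free[chrom][i + 1:]
        return chrom, start


def _plant_code(code, ref: TranscriptModel, rng, space: _FreeSpace):
    """Exon geometry realizing ``code`` against reference ``ref`` (or the
    intergenic space for 'u'); returns (chrom, strand, exons) or None if
    this reference cannot host the code."""
    if code == "=":
        return ref.chrom, ref.strand, ref.exons
    if code == "j":
        if ref.exon_count < 3:
            return None
        m = int(rng.integers(2, min(ref.exon_count, 5)))  # partial chain of 2-4 exons
        if rng.random() < 0.5:  # keep the first m exons, read into the next intron
            exons = list(ref.exons[:m])
            intron_len = ref.exons[m][0] - ref.exons[m - 1][1]
            ext = int(rng.integers(20, max(21, intron_len - 20)))
            s, e = exons[-1]
            exons[-1] = (s, e + ext)
        else:  # keep the last m exons, read back into the preceding intron
            exons = list(ref.exons[-m:])
            intron_len = ref.exons[-m][0] - ref.exons[-m - 1][1]
            ext = int(rng.integers(20, max(21, intron_len - 20)))
            s, e = exons[0]
            exons[0] = (s - ext, e)
        return ref.chrom, ref.strand, tuple(exons)
    if code == "i":
        introns = [iv for iv in ref.introns if iv[1] - iv[0] >= 300]
        if not introns:
            return None
        s, e = introns[int(rng.integers(0, len(introns)))]
        length = int(rng.integers(180, min(500, e - s - 60)))
        start = int(rng.integers(s + 20, e - length - 20))
        return ref.chrom, ref.strand, ((start, start + length),)
    if code in ("x", "o"):
        exon = ref.exons[int(rng.integers(0, ref.exon_count))]
        es, ee = exon
        mid = int(rng.integers(es + (ee - es) // 3, ee - 30))
        ext = int(rng.integers(150, 400))
        strand = ("+" if ref.strand == "-" else "-") if code == "x" else ref.strand
        return ref.chrom, strand, ((mid, ee + ext),)
    if code == "u":
        length = int(rng.integers(250, 501))
        chrom, start = space.take(rng, length)
        return chrom, "+" if rng.random() < 0.5 else "-", ((start, start + length),)
    raise ValueError(f"unknown code {code}")


_STOPS = ("TAA", "TAG", "TGA")
_RC = str.maketrans("ACGTN", "TGCAN")


def _spliced_forward(genome: dict, t: TranscriptModel) -> str:
    return "".join(genome[t.chrom][s:e] for s, e in t.exons)


def _find_longest_orf(seq: str) -> tuple[int, int]:
    """(aa, start) of the longest ATG-initiated forward-frame ORF; open
    ORFs run to the sequence end."""
    best_aa, best_start = 0, -1
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i:i + 3] == "ATG":
                j = i + 3
                while j + 3 <= n and seq[j:j + 3] not in _STOPS:
                    j += 3
                aa = (j - i - 3) // 3
                if aa > best_aa:
                    best_aa, best_start = aa, i
                i = j + 3
            else:
                i += 3
    return best_aa, best_start


def _disrupt_orfs(genome: dict, t: TranscriptModel, rng, max_aa: int = 85) -> bool:
    """Edit the genome under a planted noncoding transcript until its
    spliced sequence carries no ORF of ``max_aa`` aa or more (a planted
    lncRNA must genuinely lack coding capacity). Returns True if edited."""
    edited = False
    offsets = []
    pos = 0
    for s, e in t.exons:
        offsets.append((pos, pos + (e - s), s))
        pos += e - s
    total = pos

    def _full_to_genomic(a: int):
        for lo, hi, gs in offsets:
            if lo <= a and a + 3 <= hi:
                return gs + (a - lo)
        return None

    for _ in range(40):
        full = _spliced_forward(genome, t)
        seq = full.translate(_RC)[::-1] if t.strand == "-" else full
        aa, start = _find_longest_orf(seq)
        if aa < max_aa:
            return edited
        # place a stop mid-ORF, at a codon fully inside one exon
        codon_order = list(rng.permutation(np.arange(aa // 4, aa - aa // 4)))
        for c in codon_order:
            p = start + 3 * (1 + int(c))
            a = p if t.strand == "+" else total - 3 - p
            g = _full_to_genomic(a)
            if g is None:
                continue
            payload = "TAA" if t.strand == "+" else "TTA"
            contig = genome[t.chrom]
            genome[t.chrom] = contig[:g] + payload + contig[g + 3:]
            edited = True
            break
        else:
            break
    return edited


def _write_orf(genome: dict, chrom: str, start: int, n_codons: int, rng) -> None:
    """Overwrite genome sequence with ATG + n_codons sense codons + TAA."""
    import itertools

    sense = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
             if c not in ("TAA", "TAG", "TGA")]
    body = "".join(sense[int(i)] for i in rng.integers(0, len(sense), size=n_codons))
    orf = "ATG" + body + "TAA"
    s = genome[chrom]
    genome[chrom] = s[:start] + orf + s[start + len(orf):]


def make_assembly(
    annotation: GenomeAnnotation,
    genome: dict,
    params: AssemblyParams = AssemblyParams(),
    n_samples: int = 24,
    seed: int = 0,
    sample_names: list[str] | None = None,
) -> AssemblyResult:
    """Plant transcripts with known class codes plus contaminants.

    Each planted base transcript is replicated into a random subset of
    samples (its recurrence). Organelle and ncRNA contaminants are placed
    at controlled overlap ratios straddling the 0.75 / 0.3 filter
    thresholds; coding contaminants carry a real >= 100 aa ORF or rows in
    the similarity / domain hit tables; under-length transcripts exercise
    the 150 bp filter.
    """
    rng = np.random.default_rng(seed)
    rates = dict(params.rates)
    if abs(sum(rates.values()) - 1.0) > 1e-9:
        raise ValueError("class-code rates must sum to 1")
    genome = dict(genome)
    truth = SyntheticTruth()
    space = _FreeSpace(annotation)
    refs = [t for t in annotation.transcripts]
    samples = list(sample_names) if sample_names else [f"S{i + 1:02d}" for i in range(n_samples)]
    n_samples = len(samples)

    bases: list[TranscriptModel] = []
    counts = {c: int(round(rates[c] * params.n_transcripts)) for c in rates}
    base_no = 0

    def _add_base(chrom, strand, exons, code, kind=None, level=None):
        nonlocal base_no
        tid = f"T{base_no:05d}"
        base_no += 1
        bases.append(TranscriptModel(tid, tid, chrom, strand, tuple(exons)))
        truth.true_class_code[tid] = code
        if kind:
            truth.contaminated_ids[tid] = kind
        if level is not None:
            levels[tid] = level
        return tid

    levels: dict[str, float] = {}
    used_multi: set = set()
    used_mono: dict[tuple, list] = {}

    def _collides(chrom, strand, exons) -> bool:
        """Would this geometry merge with an already planted transcript?"""
        if len(exons) > 1:
            chain = tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))
            return (chrom, strand, chain) in used_multi
        s, e = exons[0]
        for ps, pe in used_mono.get((chrom, strand), []):
            ov = min(e, pe) - max(s, ps)
            if ov > 0 and min(ov / (e - s), ov / (pe - ps)) >= 0.9:
                return True
        return False

    def _record_geometry(chrom, strand, exons) -> None:
        if len(exons) > 1:
            chain = tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))
            used_multi.add((chrom, strand, chain))
        else:
            used_mono.setdefault((chrom, strand), []).append(exons[0])

    for code, n_code in counts.items():
        made = 0
        tries = 0
        while made < n_code:
            ref = refs[int(rng.integers(0, len(refs)))]
            geom = _plant_code(code, ref, rng, space)
            tries += 1
            if tries > params.max_geometry_tries * max(n_code, 1):
                raise ValueError(f"cannot realize class code {code!r}")
            if geom is None:
                continue
            if code != "=" and _collides(*geom):
                continue
            if code != "=":
                _record_geometry(*geom)
            level = 0.4 if code == "i" else float(2 ** rng.uniform(2, 6))
            _add_base(*geom, code,
                      kind="intronic_artifact" if code == "i" else None,
                      level=level)
            made += 1

    # organelle contaminants: chrC/chrM, overlap with BED straddles 0.75
    organelle_bed: dict[str, list[tuple[int, int]]] = {"chrC": [], "chrM": []}
    for i, ratio in enumerate(params.organelle_ratios):
        chrom = "chrC" if i % 2 == 0 else "chrM"
        slot = (i // 2) * 2500
        bed_iv = (slot, slot + 2000)
        organelle_bed[chrom].append(bed_iv)
        start = int(bed_iv[1] - round(ratio * 1000))
        _add_base(chrom, "+", ((start, start + 1000),), "u",
                  kind="organelle" if ratio > 0.75 else None,
                  level=float(2 ** rng.uniform(2, 6)))

    # known-ncRNA contaminants on main contigs, straddling 0.3
    ncrna_bed: dict[str, list[tuple[int, int]]] = {}
    for ratio in params.ncrna_ratios:
        chrom, start = space.take(rng, 2100)
        bed_iv = (start, start + 1000)
        ncrna_bed.setdefault(chrom, []).append(bed_iv)
        t_start = int(bed_iv[1] - round(ratio * 1000))
        _add_base(chrom, "+", ((t_start, t_start + 1000),), "u",
                  kind="ncrna" if ratio > 0.3 else None,
                  level=float(2 ** rng.uniform(2, 6)))

    # coding contaminants
    sim_rows, dom_rows = [], []
    for _ in range(params.n_coding_orf):
        length = 600
        chrom, start = space.take(rng, length)
        tid = _add_base(chrom, "+", ((start, start + length),), "u",
                        kind="coding", level=float(2 ** rng.uniform(2, 6)))
        _write_orf(genome, chrom, start + 30, n_codons=int(rng.integers(120, 170)), rng=rng)
    for _ in range(params.n_coding_sim):
        length = int(rng.integers(300, 600))
        chrom, start = space.take(rng, length)
        tid = _add_base(chrom, "+", ((start, start + length),), "u",
                        kind="coding", level=float(2 ** rng.uniform(2, 6)))
        sim_rows.append(
            dict(zip(HIT_COLUMNS,
                     [tid, f"sp|Q{int(rng.integers(10000, 99999))}", 62.0, 80, 10, 1,
                      1, 240, 1, 80, 1e-30, 180.0])))
    for _ in range(params.n_coding_domain):
        length = int(rng.integers(300, 600))
        chrom, start = space.take(rng, length)
        tid = _add_base(chrom, "+", ((start, start + length),), "u",
                        kind="coding", level=float(2 ** rng.uniform(2, 6)))
        dom_rows.append(
            dict(zip(HIT_COLUMNS,
                     [tid, f"PF{int(rng.integers(10000, 99999))}", 40.0, 60, 10, 1,
                      1, 180, 1, 60, 1e-10, 90.0])))
    # harmless decoy hits that must NOT trigger removal
    decoys = [tid for tid, c in truth.true_class_code.items()
              if c in RETAINED_CODES and tid not in truth.contaminated_ids]
    for tid in decoys[: max(3, len(decoys) // 20)]:
        sim_rows.append(
            dict(zip(HIT_COLUMNS,
                     [tid, "sp|DECOY", 30.0, 35, 20, 2, 1, 100, 1, 35, 1e-3, 40.0])))

    # under-length transcripts (length filter)
    for _ in range(params.n_short):
        length = int(rng.integers(100, 150))
        chrom, start = space.take(rng, length)
        _add_base(chrom, "+", ((start, start + length),), "u",
                  kind="short", level=float(2 ** rng.uniform(2, 6)))

    # planted lncRNAs must genuinely lack coding capacity: disrupt chance
    # ORFs under every retained-code non-contaminant (edits can touch
    # overlapping transcripts, so iterate to a fixed point)
    noncoding_targets = [
        t for t in bases
        if truth.true_class_code[t.transcript_id] in RETAINED_CODES
        and t.transcript_id not in truth.contaminated_ids
    ]
    for _ in range(6):
        edited = [_disrupt_orfs(genome, t, rng) for t in noncoding_targets]
        if not any(edited):
            break

    # replicate into samples: intronic artifacts are rare, the rest recur
    transcripts: list[TranscriptModel] = []
    recurrence_plan: dict[str, list[str]] = {}
    for t in bases:
        code = truth.true_class_code[t.transcript_id]
        if code == "i":
            k = int(rng.integers(1, 3))
        else:
            k = int(rng.integers(max(2, n_samples // 3), n_samples + 1))
        chosen = sorted(rng.choice(samples, size=k, replace=False))
        recurrence_plan[t.transcript_id] = list(chosen)
        for s in chosen:
            transcripts.append(
                TranscriptModel(f"{t.transcript_id}|{s}", t.gene_id, t.chrom,
                                t.strand, t.exons, source_sample=s)
            )

    sim_hits = pd.DataFrame(sim_rows, columns=HIT_COLUMNS)
    domain_hits = pd.DataFrame(dom_rows, columns=HIT_COLUMNS)
    return AssemblyResult(
        transcripts=transcripts,
        truth=truth,
        genome=genome,
        organelle_bed=organelle_bed,
        ncrna_bed=ncrna_bed,
        sim_hits=sim_hits,
        domain_hits=domain_hits,
        recurrence_plan=recurrence_plan,
        base_levels=levels,
    )


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionParams:
    n_specific: int = 20
    n_modules: int = 5
    module_size: int = 6        # 1 lncRNA + (module_size - 1) genes
    n_negative_pairs: int = 8
    noise_sd: float = 0.1       # sd of multiplicative log-normal noise
    fold: float = 100.0         # tissue-specific over-expression factor
    n_undescribed: int = 8      # samples lacking a tissue description


def make_expression(
    lnc_ids,
    gene_ids,
    tissues=DEFAULT_TISSUES,
    params: ExpressionParams = ExpressionParams(),
    seed: int = 0,
    base_levels: dict[str, float] | None = None,
):
    """Expression matrix with planted structure and its truth record.

    One described sample per tissue plus ``n_undescribed`` unlabeled
    samples. Planted structure (all id sets disjoint):

    - tissue-specific lncRNAs: ``fold``-times higher in one tissue's sample;
    - modules: one lncRNA plus genes sharing a bounded uniform latent
      profile (pairwise correlation ~0.95 at the default noise);
    - negative pairs: lncRNA tracks the latent, the gene its mirror image,
      so scaled profiles anti-correlate below -0.8;
    - everything else: independent log-normal noise about its baseline.
    """
    rng = np.random.default_rng(seed)
    lnc_ids, gene_ids = list(lnc_ids), list(gene_ids)
    base_levels = dict(base_levels or {})
    need_lnc = params.n_specific + params.n_modules + params.n_negative_pairs
    need_gene = params.n_modules * (params.module_size - 1) + params.n_negative_pairs
    if need_lnc > len(lnc_ids) or need_gene > len(gene_ids):
        raise ValueError("planted structure exceeds available ids")

    described = [f"S{i + 1:02d}" for i in range(len(tissues))]
    undescribed = [f"U{i + 1:02d}" for i in range(params.n_undescribed)]
    samples = described + undescribed
    meta = {s: t for s, t in zip(described, tissues)}
    meta.update({s: "" for s in undescribed})
    n = len(samples)

    lnc_pool = list(rng.permutation(lnc_ids))
    gene_pool = list(rng.permutation(gene_ids))
    specific = [lnc_pool.pop() for _ in range(params.n_specific)]
    module_lncs = [lnc_pool.pop() for _ in range(params.n_modules)]
    pair_lncs = [lnc_pool.pop() for _ in range(params.n_negative_pairs)]
    module_genes = [
        [gene_pool.pop() for _ in range(params.module_size - 1)]
        for _ in range(params.n_modules)
    ]
    pair_genes = [gene_pool.pop() for _ in range(params.n_negative_pairs)]

    truth = SyntheticTruth()
    all_ids = list(dict.fromkeys(lnc_ids + gene_ids))
    values = pd.DataFrame(0.0, index=all_ids, columns=samples)

    def _noise():
        return np.exp(rng.normal(0.0, params.noise_sd, size=n))

    def _base(rid):
        if rid not in base_levels:
            base_levels[rid] = float(2 ** rng.uniform(2, 6))
        return base_levels[rid]

    structured = set()
    for rid, tissue_idx in zip(specific, rng.integers(0, len(tissues),
                                                      size=len(specific))):
        mu = np.full(n, _base(rid))
        mu[int(tissue_idx)] *= params.fold
        values.loc[rid] = mu * _noise()
        truth.planted_specific[rid] = tissues[int(tissue_idx)]
        structured.add(rid)

    for lnc, genes in zip(module_lncs, module_genes):
        latent = rng.uniform(0.0, 1.0, size=n)
        members = [lnc] + genes
        truth.planted_modules.append(members)
        for rid in members:
            values.loc[rid] = _base(rid) * (0.1 + latent) * _noise()
            structured.add(rid)

    for lnc, gene in zip(pair_lncs, pair_genes):
        latent = rng.uniform(0.0, 1.0, size=n)
        values.loc[lnc] = _base(lnc) * (0.1 + latent) * _noise()
        values.loc[gene] = _base(gene) * (1.1 - latent) * _noise()
        truth.planted_negative_pairs.append((lnc, gene))
        structured.update((lnc, gene))

    for rid in all_ids:
        if rid not in structured:
            values.loc[rid] = _base(rid) * _noise()

    return ExpressionMatrix(values, meta), truth


# ---------------------------------------------------------------------------
# promoters and motifs


@dataclass(frozen=True)
class PromoterParams:
    n_promoters: int = 60
    promoter_len: int = 3000
    pwm_width: int = 12
    hit_rate: float = 0.5
    consensus_prob: float = 0.91


def make_promoters_and_motifs(
    params: PromoterParams = PromoterParams(), seed: int = 0
):
    """Random promoters with consensus motif words embedded at recorded
    offsets/strands; background uniform. Returns
    ``(promoters, [PWM], truth)``."""
    from .regscan import PWM, reverse_complement

    rng = np.random.default_rng(seed)
    w = params.pwm_width
    if w > params.promoter_len:
        raise ValueError("pwm_width exceeds promoter length")
    expected_hits = params.hit_rate * params.n_promoters
    if expected_hits > params.n_promoters * (params.promoter_len // w):
        raise ValueError("hit_rate exceeds feasible density")
    consensus_idx = rng.integers(0, 4, size=w)
    consensus = "".join(_BASES[consensus_idx])
    off_p = (1.0 - params.consensus_prob) / 3.0
    matrix = np.full((w, 4), off_p)
    matrix[np.arange(w), consensus_idx] = params.consensus_prob
    pwm = PWM(motif_id="MOTIF1", matrix=matrix)

    truth = SyntheticTruth()
    promoters = {}
    for i in range(params.n_promoters):
        pid = f"PROM{i:04d}"
        seq = list(_random_seq(rng, params.promoter_len))
        if rng.random() < params.hit_rate:
            off = int(rng.integers(0, params.promoter_len - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            word = consensus if strand == "+" else reverse_complement(consensus)
            seq[off:off + w] = list(word)
            truth.planted_motif_hits[pid] = [(off, strand)]
        promoters[pid] = "".join(seq)
    return promoters, [pwm], truth


# ---------------------------------------------------------------------------
# ortholog score tables


@dataclass(frozen=True)
class OrthologParams:
    n_a: int = 40
    n_b: int = 40
    n_orthologs: int = 10


def make_ortholog_scores(params: OrthologParams = OrthologParams(), seed: int = 0):
    """Reciprocal hit tables with planted mutual-best orthologs.

    Planted pairs get e-values in 1e-120..1e-60 in both directions; decoy
    hits (1e-40..1e-5) point only at planted subjects, so no spurious
    mutual best pair can arise. Returns ``(hits_ab, hits_ba, truth)``.
    """
    if params.n_orthologs > min(params.n_a, params.n_b):
        raise ValueError("n_orthologs exceeds min(n_a, n_b)")
    rng = np.random.default_rng(seed)
    ids_a = [f"bambooA{i:03d}" for i in range(params.n_a)]
    ids_b = [f"riceB{i:03d}" for i in range(params.n_b)]
    truth = SyntheticTruth()
    rows_ab, rows_ba = [], []

    def _row(q, s, e):
        bits = max(30.0, -10.0 * np.log10(max(e, 1e-200)) + float(rng.uniform(0, 20)))
        return dict(zip(HIT_COLUMNS,
                        [q, s, float(rng.uniform(40, 95)), int(rng.integers(60, 400)),
                         5, 1, 1, 300, 1, 300, e, round(bits, 1)]))

    for i in range(params.n_orthologs):
        a, b = ids_a[i], ids_b[i]
        truth.planted_orthologs.append((a, b))
        rows_ab.append(_row(a, b, float(10 ** rng.uniform(-120, -60))))
        rows_ba.append(_row(b, a, float(10 ** rng.uniform(-120, -60))))
        # weaker extra hits exercise top-3 ranking
        for _ in range(int(rng.integers(1, 3))):
            j = int(rng.integers(0, params.n_orthologs))
            if ids_b[j] != b:
                rows_ab.append(_row(a, ids_b[j], float(10 ** rng.uniform(-40, -5))))
    # decoy hits from unplanted queries target planted subjects (whose
    # reciprocal best is their planted partner), or, with no planted
    # pairs, follow an offset scheme that precludes mutual bests
    for i, a in enumerate(ids_a[params.n_orthologs:]):
        for _ in range(int(rng.integers(1, 4))):
            if params.n_orthologs:
                j = int(rng.integers(0, params.n_orthologs))
            else:
                j = (i + 1) % params.n_b
            rows_ab.append(_row(a, ids_b[j], float(10 ** rng.uniform(-40, -5))))
    for i, b in enumerate(ids_b[params.n_orthologs:]):
        for _ in range(int(rng.integers(1, 4))):
            if params.n_orthologs:
                j = int(rng.integers(0, params.n_orthologs))
            else:
                j = (i + 2) % params.n_a
            rows_ba.append(_row(b, ids_a[j], float(10 ** rng.uniform(-40, -5))))
    hits_ab = pd.DataFrame(rows_ab, columns=HIT_COLUMNS)
    hits_ba = pd.DataFrame(rows_ba, columns=HIT_COLUMNS)
    return hits_ab, hits_ba, truth


# ---------------------------------------------------------------------------
# GO annotation for the co-expression / pathway closures


def make_go_annotation(truth: SyntheticTruth, gene_ids, seed: int = 0,
                       n_decoy_terms: int = 5, decoy_size: int = 8):
    """GO table over coding genes: each planted module's genes share one
    term; decoy terms are random gene draws. Returns
    ``(gene -> GO ids, term names)``."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    go: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    module_names = [
        "plant-type secondary cell wall biogenesis",
        "photosynthesis, light reaction",
        "response to heat",
        "mitotic cell cycle",
        "xylan biosynthetic process",
        "cellulose biosynthetic process",
        "phenylpropanoid metabolic process",
    ]
    for k, members in enumerate(truth.planted_modules):
        term = f"GO:90000{k:02d}"
        names[term] = module_names[k % len(module_names)]
        for rid in members:
            if rid in gene_ids:
                go.setdefault(rid, set()).add(term)
    for d in range(n_decoy_terms):
        term = f"GO:91000{d:02d}"
        names[term] = f"synthetic background process {d}"
        for rid in rng.choice(gene_ids, size=min(decoy_size, len(gene_ids)),
                              replace=False):
            go.setdefault(str(rid), set()).add(term)
    return go, names


# ---------------------------------------------------------------------------
# one-call simulation used by the CLI and downstream closures


@dataclass(frozen=True)
class SimulationConfig:
    genome: GenomeParams = GenomeParams()
    assembly: AssemblyParams = AssemblyParams()
    expression: ExpressionParams = ExpressionParams()
    promoters: PromoterParams = PromoterParams()
    orthologs: OrthologParams = OrthologParams()
    tissues: tuple = DEFAULT_TISSUES


@dataclass
class SimulationResult:
    genome: dict
    reference: GenomeAnnotation
    assembly: AssemblyResult
    expression: ExpressionMatrix
    truth: SyntheticTruth
    promoters: dict
    motifs: list
    hits_ab: pd.DataFrame
    hits_ba: pd.DataFrame
    go_annotation: dict
    go_names: dict


def _merge_truth(*truths: SyntheticTruth) -> SyntheticTruth:
    out = SyntheticTruth()
    for t in truths:
        out.true_class_code.update(t.true_class_code)
        out.contaminated_ids.update(t.contaminated_ids)
        out.planted_specific.update(t.planted_specific)
        out.planted_modules.extend(t.planted_modules)
        out.planted_negative_pairs.extend(t.planted_negative_pairs)
        out.planted_motif_hits.update(t.planted_motif_hits)
        out.planted_orthologs.extend(t.planted_orthologs)
    return out


def simulate(config: SimulationConfig = SimulationConfig(), seed: int = 0) -> SimulationResult:
    """Generate every pipeline input from one seed."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    genome, reference = make_genome(config.genome, int(seeds[0]))
    described = [f"S{i + 1:02d}" for i in range(len(config.tissues))]
    undescribed = [f"U{i + 1:02d}" for i in range(config.expression.n_undescribed)]
    assembly = make_assembly(reference, genome, config.assembly,
                             seed=int(seeds[1]),
                             sample_names=described + undescribed)
    lnc_candidates = sorted(assembly.truth.true_class_code)
    gene_ids = sorted({t.gene_id for t in reference.transcripts})
    expr, expr_truth = make_expression(
        # planted expression structure lives on true lncRNAs only
        sorted(assembly.truth.expected_lncrnas()),
        gene_ids,
        tissues=config.tissues,
        params=config.expression,
        seed=int(seeds[2]),
        base_levels=assembly.base_levels,
    )
    # candidates without planted structure still need expression rows
    missing = [t for t in lnc_candidates if t not in expr.values.index]
    if missing:
        extra, _ = make_expression(
            missing, [], tissues=config.tissues,
            params=ExpressionParams(n_specific=0, n_modules=0, module_size=2,
                                    n_negative_pairs=0,
                                    noise_sd=config.expression.noise_sd,
                                    n_undescribed=config.expression.n_undescribed),
            seed=int(seeds[2]) + 1,
            base_levels=assembly.base_levels,
        )
        expr = ExpressionMatrix(
            pd.concat([expr.values, extra.values]), expr.sample_meta
        )
    promoters, motifs, prom_truth = make_promoters_and_motifs(
        config.promoters, int(seeds[3])
    )
    hits_ab, hits_ba, orth_truth = make_ortholog_scores(
        config.orthologs, int(seeds[4])
    )
    truth = _merge_truth(assembly.truth, expr_truth, prom_truth, orth_truth)
    go, names = make_go_annotation(truth, gene_ids, seed=int(seeds[4]))
    return SimulationResult(
        genome=assembly.genome,
        reference=reference,
        assembly=assembly,
        expression=expr,
        truth=truth,
        promoters=promoters,
        motifs=motifs,
        hits_ab=hits_ab,
        hits_ba=hits_ba,
        go_annotation=go,
        go_names=names,
    )


def write_outputs(result: SimulationResult, outdir) -> None:
    """Write the simulation as the plain-text files the CLI stages read."""
    from pathlib import Path

    from . import io as fio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_fasta(result.genome, out / "genome.fa")
    fio.write_annotation(result.reference, out / "reference.gtf")
    fio.write_annotation(
        GenomeAnnotation(result.assembly.transcripts,
                         result.reference.contig_lengths),
        out / "assembly.gtf",
    )
    fio.write_expression(result.expression, out / "expr.tsv", out / "meta.tsv")
    fio.write_bed(result.assembly.organelle_bed, out / "organelle.bed", "organelle")
    fio.write_bed(result.assembly.ncrna_bed, out / "ncrna.bed", "ncrna")
    fio.write_meme_motifs(result.motifs, out / "motifs.txt")
    fio.write_fasta(result.promoters, out / "promoters.fa")
    fio.write_hit_table(result.hits_ab, out / "hitsAB.tsv")
    fio.write_hit_table(result.hits_ba, out / "hitsBA.tsv")
    fio.write_hit_table(result.assembly.sim_hits, out / "simhits.tsv")
    fio.write_hit_table(result.assembly.domain_hits, out / "domainhits.tsv")
    fio.write_go_annotation(result.go_annotation, out / "go.tsv")
    result.truth.to_json(out / "truth.json")
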