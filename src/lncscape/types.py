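"""Core domain containers shared across the pipeline.

Coordinates are 0-based half-open genomic intervals throughout; GTF/GFF
conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, multi-exon transcript anchored on a genomic contig.

    Parameters
    ----------
    transcript_id, gene_id : str
        Identifiers; ``gene_id`` groups isoforms into loci.
    chrom : str
        Contig name.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Sorted, non-overlapping ``[start, end)`` intervals in genomic bp.
    source_sample : str
        Sample of origin for assembled transcripts; empty for reference
        models.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source_sample: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: zero exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start >= end:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals, i.e. the splice-junction chain."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def tss(self) -> int:
        """Genomic coordinate of the 5' end (transcription start site)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeAnnotation:
    """A set of reference transcripts with gene spans and contig lengths."""

    transcripts: list[TranscriptModel]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, length in self.contig_lengths.items():
            for t in self._by_chrom.get(chrom, []):
                if t.end > length:
                    raise ValueError(
                        f"transcript {t.transcript_id} extends past contig "
                        f"{chrom} length {length}"
                    )

    def transcripts_on(self, chrom: str) -> list[TranscriptModel]:
        return self._by_chrom.get(chrom, [])

    @property
    def chroms(self) -> set[str]:
        return set(self.contig_lengths) | set(self._by_chrom)

    def gene_spans(self) -> dict[str, tuple[str, int, int]]:
        """gene_id -> (chrom, start, end) hull over the gene's transcripts."""
        spans: dict[str, tuple[str, int, int]] = {}
        for t in self.transcripts:
            if t.gene_id in spans:
                chrom, s, e = spans[t.gene_id]
                if chrom != t.chrom:
                    raise ValueError(f"gene {t.gene_id} spans multiple contigs")
                spans[t.gene_id] = (chrom, min(s, t.start), max(e, t.end))
            else:
                spans[t.gene_id] = (t.chrom, t.start, t.end)
        return spans


class ExpressionMatrix:
    """Transcript/gene x sample TPM table with per-sample tissue metadata.

    ``values`` is a pandas DataFrame (rows: feature ids, columns: sample
    ids). ``sample_meta`` maps sample_id -> tissue description; an empty
    description flags the sample as unusable for tissue-specific calling.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: dict[str, str] | None = None):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("NA values not allowed in expression matrix")
        if (arr < 0).any():
            raise ValueError("negative expression values")
        self.values = values.astype(float)
        self.sample_meta = dict(sample_meta or {})
        for s in self.values.columns:
            self.sample_meta.setdefault(s, "")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def undescribed_samples(self) -> list[str]:
        return [s for s in self.sample_ids if not self.sample_meta.get(s, "")]

    @property
    def described_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.sample_meta.get(s, "")]

    def profile(self, row_id: str) -> np.ndarray:
        return self.values.loc[row_id].to_numpy(dtype=float)

    def subset_rows(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.sample_meta)


def validate_hit_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check outfmt-6-style hit table invariants and coerce dtypes."""
    missing = [c for c in ("query_id", "subject_id", "percent_identity",
                           "alignment_length", "e_value", "bit_score")
               if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    df = df.copy()
    for col in ("percent_identity", "e_value", "bit_score"):
        df[col] = df[col].astype(float)
    df["alignment_length"] = df["alignment_length"].astype(int)
    if (df["e_value"] < 0).any():
        raise ValueError("negative e-values in hit table")
    if (df["alignment_length"] < 1).any():
        raise ValueError("alignment_length < 1 in hit table")
    return df
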