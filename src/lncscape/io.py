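"""Readers and writers for the formats the pipeline touches.

GTF/GFF3 annotation goes through :mod:`gffutils`; FASTA through Biopython;
tabular formats (expression TSV, BED6, outfmt-6 hit tables, result tables)
through pandas. Internal coordinates are 0-based half-open; the 1-based
inclusive GTF convention is converted here and nowhere else.
"""

from __future__ import annotations

import os
from pathlib import Path
import warnings

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import HIT_COLUMNS, ExpressionMatrix, GenomeAnnotation, TranscriptModel, validate_hit_table


def _prevalidate_gtf(path: str) -> None:
    """Cheap structural scan so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: malformed record at line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed coordinates at line {lineno}"
                ) from exc
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}: invalid interval {start}-{end} at line {lineno}"
                )


def read_annotation(path: str | os.PathLike, contig_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read a GTF or GFF3 file into a :class:`GenomeAnnotation`.

    Exon records are grouped by transcript; 1-based inclusive coordinates
    become 0-based half-open. Strand ``"."`` is treated as ``"+"`` with a
    warning. Transcripts without exon records are rejected.
    """
    path = str(path)
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    declared: set[str] = set()
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype in ("transcript", "mrna"):
            tid = _attr(feat, "transcript_id") or feat.id
            declared.add(tid)
            continue
        if ftype != "exon":
            continue
        tid = _attr(feat, "transcript_id")
        if tid is None:
            parents = feat.attributes.get("Parent", [])
            tid = parents[0] if parents else None
        if tid is None:
            raise ValueError(f"{path}: exon without transcript_id/Parent: {feat}")
        gid = _attr(feat, "gene_id") or tid
        strand = feat.strand
        if strand == ".":
            warnings.warn(
                f"transcript {tid}: strand '.' treated as '+'", stacklevel=2
            )
            strand = "+"
        rec = exons.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": strand, "ivs": [],
                  "sample": _attr(feat, "source_sample") or ""}
        )
        rec["ivs"].append((feat.start - 1, feat.end))
    empties = sorted(declared - set(exons))
    if empties:
        raise ValueError(f"{path}: transcripts with zero exons: {empties}")
    transcripts = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["ivs"])),
            source_sample=rec["sample"],
        )
        for tid, rec in exons.items()
    ]
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return GenomeAnnotation(transcripts, contig_lengths=dict(contig_lengths or {}))


def _attr(feat, key: str):
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def write_annotation(annotation: GenomeAnnotation, path: str | os.PathLike, source: str = "lncscape") -> None:
    """Write transcripts as Ensembl-style GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(
            annotation.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)
        ):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.source_sample:
                attrs += f' source_sample "{t.source_sample}";'
            fh.write(
                "\t".join(
                    [t.chrom, source, "transcript", str(t.start + 1), str(t.end),
                     ".", t.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(s + 1), str(e), ".",
                         t.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_expression(path: str | os.PathLike, meta_path: str | os.PathLike | None = None) -> ExpressionMatrix:
    """Read an expression TSV (first column ids, header sample ids).

    ``meta_path`` is a two-column TSV ``sample_id<TAB>tissue_description``;
    samples missing from it, or with an empty description, are flagged as
    undescribed and later excluded from tissue-specific calling.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids: {dups}")
    meta: dict[str, str] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
        sample_col, tissue_col = mdf.columns[0], mdf.columns[1]
        meta = dict(zip(mdf[sample_col], mdf[tissue_col]))
    return ExpressionMatrix(df, meta)


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike, meta_path: str | os.PathLike | None = None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="id")
    if meta_path is not None:
        pd.DataFrame(
            {"sample_id": expr.sample_ids,
             "tissue_description": [expr.sample_meta.get(s, "") for s in expr.sample_ids]}
        ).to_csv(meta_path, sep="\t", index=False)


def write_table(records, path: str | os.PathLike, columns: list[str] | None = None) -> None:
    """Write tabular results as TSV with a deterministic order.

    Rows sort by the first column, ties broken by subsequent columns in
    order, so the output is stable regardless of input order.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records), columns=columns)
    if columns is not None:
        df = df[columns]
    if len(df.columns) and len(df):
        df = df.sort_values(by=list(df.columns), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """Read BED intervals (already 0-based half-open) grouped by contig."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end <= start:
                raise ValueError(f"{path}: invalid BED interval at line {lineno}")
            intervals.setdefault(chrom, []).append((start, end))
    for ivs in intervals.values():
        ivs.sort()
    return intervals


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str | os.PathLike, name_prefix: str = "region") -> None:
    with open(path, "w") as fh:
        i = 0
        for chrom in sorted(intervals):
            for start, end in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{name_prefix}{i}\t0\t+\n")
                i += 1


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_hit_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 12-column outfmt-6 style hit table (no header required)."""
    with open(path) as fh:
        first = fh.readline()
    has_header = first.split("\t")[0].strip() == "query_id"
    df = pd.read_csv(
        path, sep="\t",
        header=0 if has_header else None,
        names=None if has_header else HIT_COLUMNS,
    )
    return validate_hit_table(df)


def write_hit_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_hit_table(df)[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_go_annotation(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a gene -> GO id mapping from a two-column TSV.

    The second column may hold one GO id or a comma-separated list.
    """
    out: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_col, go_col = df.columns[0], df.columns[1]
    for gene, gos in zip(df[gene_col], df[go_col]):
        out.setdefault(gene, set()).update(g.strip() for g in gos.split(",") if g.strip())
    return out


def write_go_annotation(go: dict[str, set[str]], path: str | os.PathLike) -> None:
    rows = [{"gene_id": g, "go_ids": ",".join(sorted(ts))} for g, ts in sorted(go.items())]
    pd.DataFrame(rows, columns=["gene_id", "go_ids"]).to_csv(path, sep="\t", index=False)


def read_meme_motifs(path: str | os.PathLike):
    """Read PWMs from minimal MEME text format."""
    from .regscan import PWM

    motifs = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability"):
                j += 1
            header = lines[j].strip()
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(j + 1, j + 1 + width):
                rows.append([float(x) for x in lines[k].split()])
            motifs.append(PWM(motif_id=motif_id, matrix=np.array(rows), background=background))
            i = j + 1 + width
            continue
        i += 1
    return motifs


def write_meme_motifs(motifs, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
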