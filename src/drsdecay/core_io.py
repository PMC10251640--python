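"""Annotation, alignment and sample-sheet I/O for transcriptome-space DRS data.

All internal coordinates are 0-based half-open intervals on the transcript
sense strand.  GTF input (1-based, closed) is converted at parse time.
Alignments on the reverse strand of a transcript reference are dropped on
read: direct RNA sequencing reads the strand of origin, so antisense
transcriptome hits are alignment artifacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "SampleInfo",
    "ReadAlignment",
    "GTFParseError",
    "ALN_COLUMNS",
    "SAMPLE_SHEET_COLUMNS",
    "read_annotation",
    "write_annotation",
    "filter_single_isoform",
    "build_genes",
    "read_alignments",
    "read_alignment_table",
    "write_alignment_table",
    "alignments_to_table",
    "table_to_alignments",
    "read_sample_sheet",
    "write_sample_sheet",
    "sample_sheet_to_info",
]

#: Column order of the tabular alignment format.
ALN_COLUMNS = [
    "read_id",
    "transcript_id",
    "score",
    "target_start",
    "target_end",
    "is_primary",
    "read_length",
    "pass",
]

#: Required sample sheet columns (extra columns are preserved).
SAMPLE_SHEET_COLUMNS = ["sample_id", "time_h", "rin", "batch", "spike_mix"]


class GTFParseError(ValueError):
    """Raised for a structurally malformed GTF line (reports line number)."""


@dataclass
class TranscriptModel:
    """One annotated isoform.

    Lengths are in nucleotides on the mature transcript.  For protein-coding
    transcripts with a complete annotation ``utr5_len + cds_len + utr3_len ==
    length``; for transcripts without CDS/UTR records the three are 0.
    ``gc_frac`` is the G+C fraction of the transcript sequence, present only
    when a FASTA was supplied (or the transcript was simulated).
    """

    transcript_id: str
    gene_id: str
    length: int
    utr5_len: int = 0
    cds_len: int = 0
    utr3_len: int = 0
    gc_frac: float | None = None
    is_spikein: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.transcript_id}: length must be > 0")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.transcript_id}: {name} must be >= 0")
        if self.gc_frac is not None and not (0.0 <= self.gc_frac <= 1.0):
            raise ValueError(f"{self.transcript_id}: gc_frac outside [0, 1]")


@dataclass
class GeneModel:
    """A gene and its annotated isoforms.

    ``length`` is the length of the longest annotated isoform (the common
    convention when stratifying 'gene length').
    """

    gene_id: str
    transcript_ids: tuple[str, ...]
    length: int

    @property
    def n_isoforms(self) -> int:
        return len(self.transcript_ids)

    def __post_init__(self) -> None:
        if len(self.transcript_ids) < 1:
            raise ValueError(f"{self.gene_id}: gene without transcripts")


@dataclass
class SampleInfo:
    """Per-sample covariates: time post-treatment, RIN, batch and spike mix."""

    sample_id: str
    time_h: float
    rin: float
    batch: str
    spike_mix: str = "none"

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise ValueError(f"{self.sample_id}: time_h must be finite and >= 0")
        if not (0.0 <= self.rin <= 10.0):
            raise ValueError(f"{self.sample_id}: rin outside [0, 10]")
        if self.spike_mix not in ("A", "B", "none"):
            raise ValueError(f"{self.sample_id}: spike_mix must be A, B or none")


@dataclass
class ReadAlignment:
    """One alignment of one read to one transcript reference.

    ``target_start``/``target_end`` form a 0-based half-open interval on the
    transcript.  ``pass_qc`` mirrors the basecaller pass/fail flag (mean read
    quality >= 7); when the source format carries no per-read quality every
    read is a pass.
    """

    read_id: str
    transcript_id: str
    score: float
    target_start: int
    target_end: int
    is_primary: bool
    read_length: int
    pass_qc: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(
                f"{self.read_id}: invalid target interval "
                f"[{self.target_start}, {self.target_end})"
            )

    @property
    def span(self) -> int:
        return self.target_end - self.target_start


# ---------------------------------------------------------------------------
# GTF / FASTA
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )


def _feat_len(feat) -> int:
    return feat.end - feat.start + 1


def read_annotation(
    gtf_path: str | Path,
    fasta_path: str | Path | None = None,
    spike_prefix: str = "spike",
) -> tuple[list[TranscriptModel], list[GeneModel]]:
    """Parse a GENCODE-dialect GTF (and optional transcript FASTA).

    Transcript length is the sum of exon lengths; CDS length the sum of CDS
    records; UTR lengths come from ``five_prime_utr``/``three_prime_utr``
    records, or from generic ``UTR`` records classified by position relative
    to the CDS on the annotated strand.  ``gc_frac`` is computed from the
    FASTA when given; transcripts missing from the FASTA get a warning and
    no gc_frac.  Genes/transcripts whose id starts with ``spike_prefix`` are
    marked as spike-ins.
    """
    import gffutils

    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    fasta = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path))

    transcripts: list[TranscriptModel] = []
    for tx in db.features_of_type("transcript"):
        tid = tx.attributes["transcript_id"][0]
        gid = tx.attributes["gene_id"][0]
        exons = list(db.children(tx, featuretype="exon"))
        length = sum(_feat_len(e) for e in exons) if exons else _feat_len(tx)
        cds = list(db.children(tx, featuretype="CDS"))
        cds_len = sum(_feat_len(c) for c in cds)
        utr5 = sum(
            _feat_len(u) for u in db.children(tx, featuretype="five_prime_utr")
        )
        utr3 = sum(
            _feat_len(u) for u in db.children(tx, featuretype="three_prime_utr")
        )
        generic_utrs = list(db.children(tx, featuretype="UTR"))
        if generic_utrs and cds:
            cds_start = min(c.start for c in cds)
            cds_end = max(c.end for c in cds)
            for u in generic_utrs:
                upstream = u.end <= cds_start
                five_prime = upstream if tx.strand != "-" else not upstream
                if five_prime:
                    utr5 += _feat_len(u)
                else:
                    utr3 += _feat_len(u)

        gc: float | None = None
        if fasta is not None:
            if tid in fasta:
                seq = str(fasta[tid]).upper()
                if seq:
                    gc = (seq.count("G") + seq.count("C")) / len(seq)
            else:
                warnings.warn(
                    f"transcript {tid} absent from FASTA; gc_frac unavailable",
                    stacklevel=2,
                )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                length=length,
                utr5_len=utr5,
                cds_len=cds_len,
                utr3_len=utr3,
                gc_frac=gc,
                is_spikein=gid.startswith(spike_prefix),
            )
        )
    genes = build_genes(transcripts)
    return transcripts, genes


def build_genes(transcripts: Sequence[TranscriptModel]) -> list[GeneModel]:
    """Group transcripts into GeneModels (gene length = longest isoform)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [
        GeneModel(
            gene_id=gid,
            transcript_ids=tuple(t.transcript_id for t in txs),
            length=max(t.length for t in txs),
        )
        for gid, txs in by_gene.items()
    ]


def write_annotation(
    transcripts: Sequence[TranscriptModel], path: str | Path
) -> None:
    """Write a transcript set as a GENCODE-dialect GTF.

    Each gene gets its own contig (named after the gene) with transcripts on
    the forward strand; UTR/CDS partitions are emitted when annotated, so
    ``read_annotation(write_annotation(x))`` preserves ids, lengths, gene
    membership and feature architecture.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        for gid, txs in by_gene.items():
            span = max(t.length for t in txs)
            attrs = f'gene_id "{gid}";'
            fh.write(
                f"{gid}\tdrsdecay\tgene\t1\t{span}\t.\t+\t.\t{attrs}\n"
            )
            for t in txs:
                attrs = f'gene_id "{gid}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{gid}\tdrsdecay\ttranscript\t1\t{t.length}\t.\t+\t.\t{attrs}\n"
                )
                fh.write(
                    f"{gid}\tdrsdecay\texon\t1\t{t.length}\t.\t+\t.\t{attrs}\n"
                )
                if t.cds_len > 0:
                    if t.utr5_len > 0:
                        fh.write(
                            f"{gid}\tdrsdecay\tfive_prime_utr\t1\t{t.utr5_len}"
                            f"\t.\t+\t.\t{attrs}\n"
                        )
                    fh.write(
                        f"{gid}\tdrsdecay\tCDS\t{t.utr5_len + 1}"
                        f"\t{t.utr5_len + t.cds_len}\t.\t+\t.\t{attrs}\n"
                    )
                    if t.utr3_len > 0:
                        fh.write(
                            f"{gid}\tdrsdecay\tthree_prime_utr"
                            f"\t{t.utr5_len + t.cds_len + 1}\t{t.length}"
                            f"\t.\t+\t.\t{attrs}\n"
                        )


def filter_single_isoform(
    genes: Sequence[GeneModel], transcripts: Sequence[TranscriptModel]
) -> tuple[list[GeneModel], list[TranscriptModel]]:
    """Retain exactly the genes with one annotated isoform (idempotent)."""
    keep_genes = [g for g in genes if g.n_isoforms == 1]
    keep_ids = {g.gene_id for g in keep_genes}
    keep_tx = [t for t in transcripts if t.gene_id in keep_ids]
    return keep_genes, keep_tx


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> Iterator[ReadAlignment]:
    """Stream alignments from SAM/BAM (transcriptome-space) or the tabular
    alignment format.

    Unmapped and reverse-strand records are dropped.  SAM records must carry
    an ``AS`` score tag; its absence is an error naming the record.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        yield from _read_sam(path)
    else:
        df = read_alignment_table(path)
        yield from table_to_alignments(df)


def _read_sam(path: Path) -> Iterator[ReadAlignment]:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_reverse:
                continue
            try:
                score = rec.get_tag("AS")
            except KeyError as exc:
                raise ValueError(
                    f"alignment record {rec.query_name} -> "
                    f"{rec.reference_name} has no AS score tag"
                ) from exc
            read_len = rec.infer_read_length() or rec.query_length or rec.query_alignment_length
            yield ReadAlignment(
                read_id=rec.query_name,
                transcript_id=rec.reference_name,
                score=float(score),
                target_start=rec.reference_start,
                target_end=rec.reference_end,
                is_primary=not (rec.is_secondary or rec.is_supplementary),
                read_length=int(read_len),
                pass_qc=True,
            )


def _coerce_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin(("true", "1", "t", "yes"))


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    """Read the tabular alignment format (TSV with ALN_COLUMNS header)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: alignment table missing columns {missing}")
    for col in ("is_primary", "pass"):
        df[col] = _coerce_bool(df[col])
    for col in ("target_start", "target_end", "read_length"):
        df[col] = df[col].astype(np.int64)
    df["score"] = df["score"].astype(float)
    bad = df["target_start"] >= df["target_end"]
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} records with empty/inverted intervals"
        )
    return df[ALN_COLUMNS + [c for c in df.columns if c not in ALN_COLUMNS]]


def write_alignment_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def alignments_to_table(alns: Iterable[ReadAlignment]) -> pd.DataFrame:
    rows = [
        (
            a.read_id,
            a.transcript_id,
            a.score,
            a.target_start,
            a.target_end,
            a.is_primary,
            a.read_length,
            a.pass_qc,
        )
        for a in alns
    ]
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


def table_to_alignments(df: pd.DataFrame) -> Iterator[ReadAlignment]:
    # itertuples mangles the 'pass' column name (a Python keyword), so
    # iterate plain tuples in the canonical column order
    for row in df[ALN_COLUMNS].itertuples(index=False, name=None):
        rid, tid, score, start, end, prim, rlen, pq = row
        yield ReadAlignment(
            read_id=str(rid),
            transcript_id=str(tid),
            score=float(score),
            target_start=int(start),
            target_end=int(end),
            is_primary=bool(prim),
            read_length=int(rlen),
            pass_qc=bool(pq),
        )


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet TSV; unknown columns are preserved."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    df["time_h"] = df["time_h"].astype(float)
    df["rin"] = df["rin"].astype(float)
    if not np.isfinite(df["time_h"]).all():
        raise ValueError(f"{path}: non-finite time_h")
    if ((df["rin"] < 0) | (df["rin"] > 10)).any():
        raise ValueError(f"{path}: rin outside [0, 10]")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return df


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.sample_id, s.time_h, s.rin, s.batch, s.spike_mix)
            for s in samples
        ],
        columns=SAMPLE_SHEET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def sample_sheet_to_info(df: pd.DataFrame) -> list[SampleInfo]:
    return [
        SampleInfo(
            sample_id=str(r.sample_id),
            time_h=float(r.time_h),
            rin=float(r.rin),
            batch=str(r.batch),
            spike_mix=str(r.spike_mix),
        )
        for r in df.itertuples(index=False)
    ]
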