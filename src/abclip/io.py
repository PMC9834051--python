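"""Readers and writers for the on-disk formats the package exchanges.

FASTA/FASTQ go through Biopython; SAM/BAM through pysam; tabular formats
(BED6+, TSV, bedGraph) through pandas.  The GTF reader/writer is a compact
pair restricted to the exon/CDS feature lines this package itself emits.
"""
from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    PEAK_COLUMNS, READ_COLUMNS, TRUTH_SITE_COLUMNS, TranscriptModel,
    CassetteEvent, CASSETTE_REGIONS,
)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write ``(read_id, sequence, quality)`` triplets; '.gz' suffix gzips."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), qual


# ---------------------------------------------------------------------------
# Aligned reads as BED6+ (name=read_id; extra columns umi, rbp, molecule_id)

def write_reads_bed(reads: pd.DataFrame, path) -> None:
    out = reads[["chrom", "start", "end", "read_id"]].copy()
    out["score"] = 0
    out["strand"] = reads["strand"].values
    out["umi"] = reads["umi"].values
    out["rbp"] = reads["rbp"].values
    out["molecule_id"] = reads["molecule_id"].values
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "read_id", "score", "strand", "umi",
            "rbp", "molecule_id"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df["truncation"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    return df[READ_COLUMNS]


def reads_from_sam(path, umi_tag: str = "RX", rbp_tag: str = "RG") -> pd.DataFrame:
    """Adapter mapping a SAM/BAM file to an aligned-read table.

    UMI and RBP labels are read from per-read tags (defaults: RX/RG);
    unmapped and secondary/supplementary records are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            start, end = aln.reference_start, aln.reference_end
            umi = aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else ""
            rbp = aln.get_tag(rbp_tag) if aln.has_tag(rbp_tag) else "."
            trunc = start if strand == "+" else end - 1
            rows.append((aln.query_name, rbp, umi, aln.reference_name,
                         start, end, strand, trunc, -1))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


# ---------------------------------------------------------------------------
# Peaks (BED6 + optional sidecar columns)

def write_peaks_bed(peaks: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    out = peaks[["chrom", "start", "end", "peak_id", "score", "strand"]].copy()
    for c in ("rbp", *(extra_cols or [])):
        if c in peaks.columns:
            out[c] = peaks[c].values
    out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["chrom", "start", "end", "peak_id", "score", "strand", "rbp"]
    df.columns = names[: df.shape[1]] + [f"extra_{i}" for i in range(df.shape[1] - len(names))] if df.shape[1] > len(names) else names[: df.shape[1]]
    if "rbp" not in df.columns:
        df["rbp"] = "."
    return df[PEAK_COLUMNS]


# ---------------------------------------------------------------------------
# Transcript models: GTF (exon/CDS features) and BED12

def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    with _open_text(path, "wt") as fh:
        for m in models:
            attrs = (f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                     f'gene_class "{m.gene_class}";')
            for s, e in m.exons:
                fh.write(f"{m.chrom}\tabclip\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.cds:
                fh.write(f"{m.chrom}\tabclip\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")


def _gtf_attr(attrs: str, key: str) -> str:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return ""


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon/CDS GTF lines back into transcript models."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feat, start, end, _, strand, _, attrs = f[:9]
            if feat not in ("exon", "CDS"):
                continue
            tid = _gtf_attr(attrs, "transcript_id")
            meta[tid] = (_gtf_attr(attrs, "gene_id"), chrom, strand,
                         _gtf_attr(attrs, "gene_class") or "protein_coding")
            iv = (int(start) - 1, int(end))
            (exons if feat == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, exon_list in exons.items():
        gid, chrom, strand, gclass = meta[tid]
        models.append(TranscriptModel(gid, tid, chrom, strand, exon_list,
                                      cds.get(tid, []), gclass))
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def write_bed12(models: Iterable[TranscriptModel], path) -> None:
    with _open_text(path, "wt") as fh:
        for m in models:
            if m.cds:
                thick_s, thick_e = m.cds[0][0], m.cds[-1][1]
            else:
                thick_s = thick_e = m.start
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.start) for s, e in m.exons) + ","
            fh.write("\t".join(map(str, [
                m.chrom, m.start, m.end, m.transcript_id, 0, m.strand,
                thick_s, thick_e, 0, len(m.exons), sizes, starts,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Truth sites, barcode table, cassette events, bedGraph

def write_truth_sites(sites_frame: pd.DataFrame, path) -> None:
    sites_frame[TRUTH_SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_barcode_table(path) -> dict[str, str]:
    """TSV of ``barcode<TAB>rbp_label`` rows (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "rbp"])
    return dict(zip(df["barcode"].str.upper(), df["rbp"]))


def write_barcode_table(table: dict[str, str], path) -> None:
    pd.DataFrame(table.items(), columns=["barcode", "rbp"]).to_csv(
        path, sep="\t", header=False, index=False)


def write_events_tsv(events: Iterable[CassetteEvent], path) -> None:
    rows = []
    for ev in events:
        row = {"event_id": ev.event_id, "chrom": ev.chrom, "strand": ev.strand,
               "event_class": ev.event_class}
        for label in CASSETTE_REGIONS:
            s, e = ev.region(label)
            row[f"{label}_start"], row[f"{label}_end"] = s, e
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[CassetteEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, r in df.iterrows():
        regions = {lab: (int(r[f"{lab}_start"]), int(r[f"{lab}_end"]))
                   for lab in CASSETTE_REGIONS}
        events.append(CassetteEvent(r["event_id"], r["chrom"], r["strand"],
                                    event_class=r["event_class"], **regions))
    return events


def read_bedgraph(path) -> dict[str, pd.DataFrame]:
    """Per-chromosome interval score tables (chrom -> start/end/score frame)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="t",
                     names=["chrom", "start", "end", "score"])
    df = df[pd.to_numeric(df["start"], errors="coerce").notna()]
    df = df.astype({"start": int, "end": int, "score": float})
    return {chrom: g.sort_values("start").reset_index(drop=True)
            for chrom, g in df.groupby("chrom")}


def write_bedgraph(track: dict[str, pd.DataFrame], path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in sorted(track):
            for _, r in track[chrom].iterrows():
                fh.write(f"{chrom}\t{int(r.start)}\t{int(r.end)}\t{r.score:g}\n")
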