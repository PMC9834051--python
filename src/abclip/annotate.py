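"""Transcriptomic feature annotation of peaks, motif scanning with
conservation filtering, and size/GC-matched background sampling.

Feature definitions: splice-site windows span +/-100 bp across each
annotated junction (100 bp exonic + 100 bp intronic); proximal intron is
intronic sequence within 500 bp of either splice site (outside the splice
window); distal intron is the remainder.  Within one transcript the
derived features tile exons plus introns without overlap.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coords import merge_intervals
from .model import TranscriptModel, peaks_to_frame, reads_to_frame
from .simulate import reverse_complement

#: Highest-priority first.  The field convention at stake: a peak touching
#: a splice-site window is a splice-site peak no matter what else it spans.
DEFAULT_PRIORITY = [
    "3ss", "5ss", "3utr", "5utr", "cds",
    "proximal_intron", "distal_intron", "noncoding_exon", "intergenic",
]

FEATURE_COLUMNS = ["chrom", "start", "end", "label", "strand",
                   "gene_id", "transcript_id"]


def derive_features(model: TranscriptModel, proximal: int = 500,
                    splice_window: int = 100) -> pd.DataFrame:
    """Labeled feature intervals for one transcript.

    Splice windows are painted on top of exonic/intronic base features so
    the result is a partition of the transcript span.
    """
    span = model.span
    # paint order: low to high precedence
    label_codes = {"5utr": 1, "cds": 2, "3utr": 3, "noncoding_exon": 4,
                   "distal_intron": 5, "proximal_intron": 6, "5ss": 7, "3ss": 8}
    arr = np.zeros(span, dtype=np.int8)
    off = model.start

    def paint(ivs, label):
        for s, e in ivs:
            s, e = max(s, model.start), min(e, model.end)
            if s < e:
                arr[s - off:e - off] = label_codes[label]

    if model.is_coding:
        paint(model.utr5, "5utr")
        paint(model.cds, "cds")
        paint(model.utr3, "3utr")
    else:
        paint(model.exons, "noncoding_exon")
    introns = model.introns
    paint(introns, "distal_intron")
    paint([(s, min(s + proximal, e)) for s, e in introns], "proximal_intron")
    paint([(max(s, e - proximal), e) for s, e in introns], "proximal_intron")
    # splice windows across each junction; donor (5'SS) is the exon->intron
    # boundary in transcript orientation
    for s, e in introns:
        donor_at_start = model.strand == "+"
        paint([(s - splice_window, s + splice_window)],
              "5ss" if donor_at_start else "3ss")
        paint([(e - splice_window, e + splice_window)],
              "3ss" if donor_at_start else "5ss")

    rows = []
    code_labels = {v: k for k, v in label_codes.items()}
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [span]])
    for s, e in zip(starts, ends):
        code = arr[s]
        if code:
            rows.append((model.chrom, int(s + off), int(e + off),
                         code_labels[code], model.strand,
                         model.gene_id, model.transcript_id))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def derive_all_features(models, proximal: int = 500,
                        splice_window: int = 100) -> pd.DataFrame:
    frames = [derive_features(m, proximal, splice_window) for m in models]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FEATURE_COLUMNS)


class _FeatureIndex:
    def __init__(self, features: pd.DataFrame) -> None:
        self.groups = {key: grp[["start", "end", "label", "gene_id"]].to_numpy()
                       for key, grp in features.groupby(["chrom", "strand"], sort=False)}

    def hits(self, chrom, strand, start, end):
        grp = self.groups.get((chrom, strand))
        if grp is None:
            return []
        s, e = grp[:, 0].astype(int), grp[:, 1].astype(int)
        mask = (s < end) & (e > start)
        return grp[mask]


def assign_region(peak, features: pd.DataFrame,
                  priority: list[str] | None = None) -> str:
    """Highest-priority feature label overlapping the peak (>= 1 bp, same
    strand); ``intergenic`` when nothing overlaps."""
    labels = assign_regions(peaks_to_frame([peak] if not isinstance(peak, pd.DataFrame) else peak),
                            features, priority)["label"]
    return labels.iloc[0]


def assign_regions(peaks, features: pd.DataFrame,
                   priority: list[str] | None = None) -> pd.DataFrame:
    """Vectorised region assignment; returns peak table + label + gene_id."""
    priority = priority or DEFAULT_PRIORITY
    known = set(features["label"]) | {"intergenic"}
    unknown = known - set(priority)
    if unknown:
        raise ValueError(f"priority list missing labels: {sorted(unknown)}")
    rank = {lab: i for i, lab in enumerate(priority)}
    peaks = peaks_to_frame(peaks)
    index = _FeatureIndex(features)
    labels, genes = [], []
    for p in peaks.itertuples():
        hits = index.hits(p.chrom, p.strand, p.start, p.end)
        if len(hits) == 0:
            labels.append("intergenic")
            genes.append("")
            continue
        best = min(hits, key=lambda h: rank[h[2]])
        labels.append(best[2])
        genes.append(best[3])
    out = peaks.copy()
    out["label"] = labels
    out["gene_id"] = genes
    return out


# ---------------------------------------------------------------------------
# Motif scanning and conservation

def _scan(seq: str, motif: str):
    pos, out = seq.find(motif), []
    while pos != -1:
        out.append(pos)
        pos = seq.find(motif, pos + 1)  # overlapping occurrences
    return out


def scan_motif(genome: dict[str, str], motif: str,
               models: list[TranscriptModel] | None = None) -> pd.DataFrame:
    """Exact occurrences of an RNA/DNA motif.

    With transcript models, only the sense strand of each transcript span
    is scanned; without, both genomic strands.  The motif may be given in
    the RNA alphabet (U == T).
    """
    motif = motif.upper().replace("U", "T")
    if not set(motif) <= set("ACGT"):
        raise ValueError("motif must be over A/C/G/U/T")
    rows = []
    if models is not None:
        seen = set()
        for m in models:
            seq = genome[m.chrom][m.start:m.end]
            target = motif if m.strand == "+" else reverse_complement(motif)
            for off in _scan(seq, target):
                key = (m.chrom, m.start + off, m.strand)
                if key not in seen:
                    seen.add(key)
                    rows.append((m.chrom, m.start + off, m.start + off + len(motif),
                                 m.strand, motif))
    else:
        for chrom, seq in genome.items():
            for off in _scan(seq, motif):
                rows.append((chrom, off, off + len(motif), "+", motif))
            for off in _scan(seq, reverse_complement(motif)):
                rows.append((chrom, off, off + len(motif), "-", motif))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "motif"])
    return out.sort_values(["chrom", "start", "strand"], kind="mergesort").reset_index(drop=True)


class ConservationTrack:
    """Per-base conservation scores (phyloP-like) from a bedGraph table.

    Bases without a value score ``missing`` (0 by default, conservative).
    """

    def __init__(self, track: dict[str, pd.DataFrame], missing: float = 0.0) -> None:
        self.missing = missing
        self._chrom = {}
        for chrom, df in track.items():
            self._chrom[chrom] = (df["start"].to_numpy(), df["end"].to_numpy(),
                                  df["score"].to_numpy(float))

    def mean(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self._chrom:
            return self.missing
        starts, ends, scores = self._chrom[chrom]
        pos = np.arange(start, end)
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        inside = (idx >= 0) & (pos < ends[idx_c])
        vals = np.where(inside, scores[idx_c], self.missing)
        return float(vals.mean())


DEFAULT_CONSERVED_CLASSES = frozenset(
    {"proximal_intron", "distal_intron", "5utr", "3utr"})


def conserved_sites(sites: pd.DataFrame, track: ConservationTrack,
                    features: pd.DataFrame, threshold: float = 3.0,
                    allowed_classes=DEFAULT_CONSERVED_CLASSES) -> pd.DataFrame:
    """Motif sites with mean per-base conservation strictly above the
    threshold that fall in an allowed feature class (intronic/UTR)."""
    if sites.empty:
        return sites.assign(mean_conservation=pd.Series(dtype=float), label=pd.Series(dtype=object))
    scored = sites.copy()
    scored["mean_conservation"] = [track.mean(r.chrom, r.start, r.end)
                                   for r in sites.itertuples()]
    sites_as_peaks = scored.rename(columns={"motif": "peak_id"})
    labels = assign_regions(sites_as_peaks, features)["label"]
    scored["label"] = labels.values
    keep = (scored["mean_conservation"] > threshold) & scored["label"].isin(allowed_classes)
    return scored[keep].reset_index(drop=True)


def read_motif_fraction(reads, sites: pd.DataFrame) -> float:
    """Fraction of usable reads overlapping >= 1 site (same strand)."""
    df = reads_to_frame(reads)
    if df.empty:
        raise ValueError("no usable reads")
    if sites.empty:
        return 0.0
    merged = {}
    for key, grp in sites.groupby(["chrom", "strand"], sort=False):
        ivs = merge_intervals(list(zip(grp["start"], grp["end"])))
        merged[key] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
    n_hit = 0
    for key, grp in df.groupby(["chrom", "strand"], sort=False):
        if key not in merged:
            continue
        s_arr, e_arr = merged[key]
        rs, re = grp["start"].to_numpy(), grp["end"].to_numpy()
        hit = (np.searchsorted(s_arr, re, "left")
               > np.searchsorted(e_arr, rs, "right"))
        n_hit += int(hit.sum())
    return n_hit / len(df)


# ---------------------------------------------------------------------------
# Size- and GC-matched background sampling

def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / max(1, len(seq))


def sample_matched_background(foreground: pd.DataFrame, features: pd.DataFrame,
                              genome: dict[str, str], gc_tolerance: float = 0.05,
                              seed: int = 0, max_tries: int = 200) -> pd.DataFrame:
    """One background region per foreground region: same length, same
    feature class, GC within ``gc_tolerance``, not overlapping any
    foreground region.  Deterministic per seed; after ``max_tries``
    rejections the GC tolerance is doubled with a warning.
    """
    rng = np.random.default_rng(seed)
    fg = foreground.copy()
    if "label" not in fg.columns:
        fg = assign_regions(fg, features)
    fg_by_chrom = {c: grp[["start", "end"]].to_numpy()
                   for c, grp in fg.groupby("chrom")}
    feat_groups = {lab: grp.reset_index(drop=True)
                   for lab, grp in features.groupby("label")}
    rows = []
    for r in fg.itertuples():
        length = r.end - r.start
        pool = feat_groups.get(r.label)
        if pool is None:
            raise ValueError(f"no candidate features of class {r.label!r}")
        pool = pool[(pool["end"] - pool["start"]) >= length]
        if pool.empty:
            raise ValueError(f"candidate space exhausted for class {r.label!r}")
        fg_gc = _gc(genome[r.chrom][r.start:r.end])
        tol, found = gc_tolerance, None
        for attempt in range(3 * max_tries):
            if attempt and attempt % max_tries == 0:
                tol *= 2
                warnings.warn(f"relaxing GC tolerance to {tol:.3f} for {r.peak_id}")
            cand = pool.iloc[int(rng.integers(len(pool)))]
            start = int(rng.integers(cand.start, cand.end - length + 1))
            end = start + length
            occ = fg_by_chrom.get(cand.chrom)
            if occ is not None and ((occ[:, 0] < end) & (occ[:, 1] > start)).any():
                continue
            if abs(_gc(genome[cand.chrom][start:end]) - fg_gc) <= tol:
                found = (cand.chrom, start, end, r.peak_id, 0, cand.strand, r.label)
                break
        if found is None:
            raise RuntimeError(f"could not sample a matched background for {r.peak_id}")
        rows.append(found)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id",
                                       "score", "strand", "label"])
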