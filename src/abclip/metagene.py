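"""Metagene profiles: relative information content (RIC) of crosslink
truncations, and peak-density metagenes on spliced-mRNA and splice-site
coordinate systems.

RIC compares the IP truncation distribution p with a background
distribution q position-by-position: ``RIC_i = p_i * log2(p_i / q_i)``
with an additive pseudocount before normalisation.  Summed over positions
this is the Kullback-Leibler divergence KL(p||q), so identical profiles
give identically zero RIC.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .coords import TranscriptCoords
from .model import MetageneProfile, TranscriptModel, peaks_to_frame, reads_to_frame


def truncation_profile(reads, model: TranscriptModel, mode: str = "mrna") -> np.ndarray:
    """Per-position truncation counts along one transcript.

    Reads must match the transcript's strand; truncations falling in
    introns are dropped in ``mrna`` mode and kept in ``premrna`` mode.
    """
    coords = TranscriptCoords(model, mode=mode)
    df = reads_to_frame(reads)
    df = df[(df["chrom"] == model.chrom) & (df["strand"] == model.strand)]
    profile = np.zeros(coords.length, dtype=np.int64)
    if len(df):
        tpos = coords.to_transcript(df["truncation"].to_numpy())
        tpos = tpos[tpos >= 0]
        np.add.at(profile, tpos, 1)
    return profile


def ric(profile_ip, profile_bg, alpha: float = 1.0) -> np.ndarray:
    """Per-position relative information content in bits."""
    t = np.asarray(profile_ip, dtype=float)
    b = np.asarray(profile_bg, dtype=float)
    if t.shape != b.shape or t.size == 0:
        raise ValueError("profiles must be equal-length and non-empty")
    p = (t + alpha) / (t + alpha).sum()
    q = (b + alpha) / (b + alpha).sum()
    return p * np.log2(p / q)


def mean_ric(profiles) -> tuple[np.ndarray, np.ndarray | None]:
    """Position-wise mean and standard error over a gene set.

    Profiles must share a common coordinate (equal length).  With a single
    gene the SE is undefined and returned as ``None``.
    """
    arrs = [np.asarray(p, dtype=float) for p in profiles]
    if not arrs:
        raise ValueError("no profiles")
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("profiles must be scaled/padded to a common length")
    stack = np.vstack(arrs)
    mean = stack.mean(axis=0)
    if len(arrs) < 2:
        return mean, None
    se = stack.std(axis=0, ddof=1) / np.sqrt(len(arrs))
    return mean, se


# ---------------------------------------------------------------------------
# Peak-density metagenes

def _select_models(models, coding_only=True) -> list[TranscriptModel]:
    """Longest coding isoform per gene."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        if coding_only and not m.is_coding:
            continue
        cur = best.get(m.gene_id)
        if cur is None or m.spliced_length > cur.spliced_length:
            best[m.gene_id] = m
    return list(best.values())


def peak_density_metagene(peaks, models, n_bins: tuple[int, int, int] = (50, 100, 150),
                          ) -> MetageneProfile:
    """Merged protein-coding mRNA metagene of peak density.

    The spliced transcript is split into 5'UTR/CDS/3'UTR segments, each
    rescaled to a fixed number of meta-bins.  Every peak contributes unit
    mass spread uniformly over the meta-bins it covers; the final vector
    is normalised to total density 1.
    """
    n5, nc, n3 = n_bins
    total_bins = n5 + nc + n3
    values = np.zeros(total_bins)
    peaks = peaks_to_frame(peaks)
    chosen = _select_models(models)
    n_mapped = 0
    for m in chosen:
        coords = TranscriptCoords(m)
        # spliced-coordinate boundaries of the three regions (5'->3')
        u5 = sum(e - s for s, e in m.utr5)
        cds = sum(e - s for s, e in m.cds)
        u3 = coords.length - u5 - cds
        sub = peaks[(peaks["chrom"] == m.chrom) & (peaks["strand"] == m.strand)
                    & (peaks["start"] < m.end) & (peaks["end"] > m.start)]
        for p in sub.itertuples():
            gpos = np.arange(p.start, p.end)
            tpos = coords.to_transcript(gpos)
            tpos = tpos[tpos >= 0]
            if tpos.size == 0:
                continue
            bins = np.empty(tpos.size, dtype=np.int64)
            in5 = tpos < u5
            incds = (tpos >= u5) & (tpos < u5 + cds)
            in3 = tpos >= u5 + cds
            if u5:
                bins[in5] = np.minimum((tpos[in5] * n5) // u5, n5 - 1)
            if cds:
                bins[incds] = n5 + np.minimum(((tpos[incds] - u5) * nc) // cds, nc - 1)
            if u3:
                bins[in3] = n5 + nc + np.minimum(((tpos[in3] - u5 - cds) * n3) // u3, n3 - 1)
            covered = np.unique(bins[(in5 & (u5 > 0)) | (incds & (cds > 0)) | (in3 & (u3 > 0))])
            if covered.size:
                values[covered] += 1.0 / covered.size
                n_mapped += 1
    if values.sum() == 0:
        raise ValueError("no peak maps onto the selected transcripts")
    values /= values.sum()
    labels = ([f"5utr_{i}" for i in range(n5)] + [f"cds_{i}" for i in range(nc)]
              + [f"3utr_{i}" for i in range(n3)])
    return MetageneProfile("mrna_bins", labels, values, n_units=n_mapped)


def splice_site_metagene(peaks, models, window: int = 300, site: str = "5ss",
                         ) -> MetageneProfile:
    """Peak density around annotated splice sites at 1-bp resolution.

    Offsets run 5'->3' along the transcript: negative offsets are upstream
    of the junction.  For ``site='5ss'`` (donor) negative offsets are
    exonic; for ``site='3ss'`` (acceptor) they are intronic.  Each peak
    contributes unit mass uniformly over its covered offsets at each
    junction whose window it touches; the profile is normalised to 1.
    """
    if site not in ("5ss", "3ss"):
        raise ValueError(f"unknown splice-site type {site!r}")
    offsets = np.arange(-window, window + 1)
    values = np.zeros(offsets.size)
    peaks = peaks_to_frame(peaks)
    n_mapped = 0
    for m in models:
        for (istart, iend) in m.introns:
            if m.strand == "+":
                junction = istart if site == "5ss" else iend
                sign = 1
            else:
                junction = iend - 1 if site == "5ss" else istart - 1
                sign = -1
            sub = peaks[(peaks["chrom"] == m.chrom) & (peaks["strand"] == m.strand)
                        & (peaks["start"] <= junction + window)
                        & (peaks["end"] > junction - window)]
            for p in sub.itertuples():
                gpos = np.arange(max(p.start, junction - window),
                                 min(p.end, junction + window + 1))
                off = sign * (gpos - junction)
                idx = off + window
                idx = idx[(idx >= 0) & (idx < values.size)]
                if idx.size:
                    values[idx] += 1.0 / idx.size
                    n_mapped += 1
    if values.sum() == 0:
        raise ValueError("no peak maps into any splice-site window")
    values /= values.sum()
    return MetageneProfile("splice_window", offsets.tolist(), values, n_units=n_mapped)
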