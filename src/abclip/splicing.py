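"""Splicing maps: positional enrichment of significant peaks around
differentially spliced cassette exons versus sampled background events.

An event "overlaps" a region when at least one significant peak has >= 50%
of its length inside that region (same strand).  Per region and event
class, a 2x2 table of overlapping vs non-overlapping events (changed vs
background) yields an odds ratio

    OR = (a / b) / (c / d)

(a,b = changed events with/without a peak; c,d = background events), with
a Haldane +0.5 correction when any cell is zero, and a p-value from the
same Yates chi-squared / Fisher fallback rule used for peak enrichment.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .coords import intersect_length
from .enrich import CHI2_P_FLOOR, FISHER_P_FLOOR, _needs_fisher
from .model import CASSETTE_REGIONS, CassetteEvent, peaks_to_frame

RESULT_COLUMNS = ["region", "event_class", "n_overlap", "n_nonoverlap",
                  "n_overlap_bg", "n_nonoverlap_bg", "odds_ratio",
                  "p_value", "test_used", "corrected", "significance"]


def overlap50(peak, region: tuple[int, int]) -> bool:
    """True iff at least 50% of the peak's length lies inside the region."""
    start, end = (peak.start, peak.end) if hasattr(peak, "start") else peak
    inter = intersect_length((start, end), region)
    return inter * 2 >= (end - start)


def sample_background_events(pool: list[CassetteEvent], n: int = 1500,
                             seed: int = 0) -> list[CassetteEvent]:
    """Uniform sample of unchanged events, relabeled as background.

    Sampling is without replacement; if the pool is smaller than ``n`` the
    sample is drawn with replacement and a warning is issued.
    """
    if not pool:
        raise ValueError("empty background-event pool")
    rng = np.random.default_rng(seed)
    replace = len(pool) < n
    if replace:
        warnings.warn(f"pool of {len(pool)} events < n={n}; sampling with replacement")
    idx = rng.choice(len(pool), size=n, replace=replace)
    out = []
    for i in idx:
        ev = pool[int(i)]
        out.append(CassetteEvent(ev.event_id, ev.chrom, ev.strand,
                                 ev.upstream_exon, ev.upstream_intron,
                                 ev.cassette_exon, ev.downstream_intron,
                                 ev.downstream_exon, "background"))
    return out


def significance_tier(p: float) -> str:
    """Categorical significance annotation: * p<0.05, ** p<0.001, *** p<1e-4."""
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """(a/b)/(c/d); Haldane +0.5 on all cells when any is zero (flagged)."""
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a / b) / (c / d), corrected


def _table_pvalue(table: np.ndarray) -> tuple[float, str]:
    if _needs_fisher(table):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return max(float(p), FISHER_P_FLOOR), "fisher"
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return max(float(p), CHI2_P_FLOOR), "chi2_yates"


def _event_overlaps(event: CassetteEvent, region: str, peaks: pd.DataFrame) -> bool:
    iv = event.region(region)
    sub = peaks[(peaks["chrom"] == event.chrom) & (peaks["strand"] == event.strand)
                & (peaks["start"] < iv[1] + 10_000) & (peaks["end"] > iv[0] - 10_000)]
    return any(overlap50(p, iv) for p in sub.itertuples())


def region_enrichment(changed: list[CassetteEvent], background: list[CassetteEvent],
                      peaks) -> pd.DataFrame:
    """Per (region x changed-class) enrichment of peak binding.

    ``peaks`` must already be filtered to significant peaks (p < 0.001,
    fold > 8).  Event classes without members are skipped with a warning.
    """
    peaks = peaks_to_frame(peaks)
    classes = sorted({ev.event_class for ev in changed})
    if not classes:
        warnings.warn("no changed events; nothing to test")
    bg_flags = {region: np.array([_event_overlaps(ev, region, peaks) for ev in background])
                for region in CASSETTE_REGIONS}
    rows = []
    for cls in classes:
        members = [ev for ev in changed if ev.event_class == cls]
        for region in CASSETTE_REGIONS:
            flags = np.array([_event_overlaps(ev, region, peaks) for ev in members])
            a, b = int(flags.sum()), int((~flags).sum())
            c = int(bg_flags[region].sum())
            d = len(background) - c
            oratio, corrected = odds_ratio_2x2(a, b, c, d)
            p, test = _table_pvalue(np.array([[a, b], [c, d]], dtype=np.int64))
            rows.append((region, cls, a, b, c, d, oratio, p, test, corrected,
                         significance_tier(p)))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# Synthetic cassette events (simulator plumbing for the splicing map)

def make_cassette_events(n_changed: int = 40, n_background_pool: int = 1500,
                         chrom: str = "chr1", seed: int = 0,
                         exon_len: int = 150, intron_len: int = 1500,
                         spacing: int = 10_000) -> tuple[list[CassetteEvent], list[CassetteEvent]]:
    """Fabricate non-overlapping cassette-exon events along one contig.

    Returns ``(changed, unchanged_pool)``; changed events alternate
    between the included/excluded-on-knockdown classes.
    """
    rng = np.random.default_rng(seed)
    events = []
    pos = 1000
    total = n_changed + n_background_pool
    for i in range(total):
        strand = "+" if rng.random() < 0.5 else "-"
        e1 = (pos, pos + exon_len)
        i1 = (e1[1], e1[1] + intron_len)
        ce = (i1[1], i1[1] + exon_len)
        i2 = (ce[1], ce[1] + intron_len)
        e2 = (i2[1], i2[1] + exon_len)
        if i < n_changed:
            cls = "excluded_on_KD" if i % 2 == 0 else "included_on_KD"
        else:
            cls = "unchanged"
        if strand == "+":
            regions = dict(upstream_exon=e1, upstream_intron=i1, cassette_exon=ce,
                           downstream_intron=i2, downstream_exon=e2)
        else:
            regions = dict(upstream_exon=e2, upstream_intron=i2, cassette_exon=ce,
                           downstream_intron=i1, downstream_exon=e1)
        events.append(CassetteEvent(f"ev{i}", chrom, strand, event_class=cls, **regions))
        pos = e2[1] + spacing
    return events[:n_changed], events[n_changed:]
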