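"""Peak-level enrichment against complement-control, size-matched-input or
RNA-seq backgrounds.

For a candidate peak the 2x2 contingency table is

    [[k_ip,  N_ip - k_ip ],
     [k_bg,  N_bg - k_bg ]]

with k the reads overlapping the peak and N the whole-library usable read
counts.  The p-value comes from Yates' continuity-corrected chi-squared
test, falling back to a two-sided Fisher's exact test whenever any
observed or expected cell is below five; reported p-values are floored at
1e-88 (chi-squared) and 2.2e-16 (Fisher).  The complement control (CC)
background for one RBP pools the reads of all other RBPs in the multiplex.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coords import merge_intervals
from .model import PEAK_COLUMNS, peaks_to_frame, reads_to_frame

CHI2_P_FLOOR = 1e-88
FISHER_P_FLOOR = 2.2e-16

RESULT_COLUMNS = ["peak_id", "chrom", "start", "end", "strand", "rbp",
                  "k_ip", "n_ip", "k_bg", "n_bg", "fold", "p_value",
                  "test_used", "bg_kind", "fold_floored"]


class ReadIndex:
    """Sorted per-(chrom, strand) interval arrays for O(log n) overlap counts."""

    def __init__(self, reads) -> None:
        df = reads_to_frame(reads)
        self.total = len(df)
        self._starts: dict[tuple[str, str], np.ndarray] = {}
        self._ends: dict[tuple[str, str], np.ndarray] = {}
        for key, grp in df.groupby(["chrom", "strand"], sort=False):
            self._starts[key] = np.sort(grp["start"].to_numpy())
            self._ends[key] = np.sort(grp["end"].to_numpy())

    def count(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Reads overlapping [start, end) by >= 1 bp on the given strand."""
        key = (chrom, strand)
        if key not in self._starts:
            return 0
        n_started = np.searchsorted(self._starts[key], end, side="left")
        n_ended = np.searchsorted(self._ends[key], start, side="right")
        return int(n_started - n_ended)

    def count_many(self, peaks: pd.DataFrame) -> np.ndarray:
        return np.array([self.count(c, s, a, b) for c, s, a, b in
                         zip(peaks["chrom"], peaks["strand"],
                             peaks["start"], peaks["end"])])


def count_reads_in_peak(reads, peak_chrom, peak_start=None, peak_end=None,
                        peak_strand=None) -> int:
    """Reads overlapping one peak (>= 1 bp, same strand).

    Accepts either ``(reads, Peak)`` or explicit coordinates.
    """
    if peak_start is None:  # a Peak-like object
        p = peak_chrom
        peak_chrom, peak_start, peak_end, peak_strand = p.chrom, p.start, p.end, p.strand
    return ReadIndex(reads).count(peak_chrom, peak_strand, peak_start, peak_end)


def cluster_candidate_peaks(reads, min_reads: int = 3, merge_gap: int = 0,
                            anchor: str = "interval") -> pd.DataFrame:
    """Naive candidate-peak generator from deduplicated reads.

    ``anchor='interval'`` merges full read intervals separated by at most
    ``merge_gap`` bp (strand-specific) and keeps clusters holding at least
    ``min_reads`` reads.  ``anchor='truncation'`` clusters the 1-bp
    crosslink truncation positions instead, which isolates binding sites
    at depths where fragment intervals tile the transcriptome.
    """
    if anchor not in ("interval", "truncation"):
        raise ValueError(f"unknown anchor {anchor!r}")
    df = reads_to_frame(reads)
    rows = []
    for (rbp, chrom, strand), grp in df.groupby(["rbp", "chrom", "strand"], sort=False):
        if anchor == "interval":
            ivs = list(zip(grp["start"], grp["end"]))
        else:
            ivs = [(t, t + 1) for t in grp["truncation"]]
        clusters = merge_intervals(ivs, gap=merge_gap)
        starts = np.sort(np.array([s for s, _ in ivs]))
        for cs, ce in clusters:
            n = int(np.searchsorted(starts, ce, "left") - np.searchsorted(starts, cs, "left"))
            if n >= min_reads:
                rows.append((chrom, cs, ce, n, strand, rbp))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "strand", "rbp"])
    out = out.sort_values(["chrom", "start", "strand"], kind="mergesort").reset_index(drop=True)
    out["peak_id"] = [f"{r.rbp}_peak_{i}" for i, r in enumerate(out.itertuples())]
    return out[PEAK_COLUMNS]


def complement_control(counts: dict[str, int], totals: dict[str, int],
                       focal: str) -> tuple[int, int]:
    """Pooled complement-control background for the focal RBP.

    Returns ``(k_bg, N_bg)``: the summed in-region counts and library
    totals of every other RBP in the multiplex.
    """
    if focal not in counts or focal not in totals:
        raise KeyError(f"focal RBP {focal!r} not in the multiplex")
    if len(totals) < 2:
        raise ValueError("complement control undefined for a singleton multiplex")
    k_bg = sum(v for r, v in counts.items() if r != focal)
    n_bg = sum(v for r, v in totals.items() if r != focal)
    return k_bg, n_bg


@dataclass(frozen=True)
class TestResult:
    fold: float
    p_value: float
    test_used: str
    fold_floored: bool


def _needs_fisher(table: np.ndarray, rule: str = "any_cell") -> bool:
    """Low-count rule: route to Fisher when an observed or expected cell
    is below five (``rule='first_column'`` checks only the in-region
    counts and their expectations)."""
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if rule == "any_cell":
        return bool((table < 5).any() or (expected < 5).any())
    if rule == "first_column":
        return bool((table[:, 0] < 5).any() or (expected[:, 0] < 5).any())
    raise ValueError(f"unknown low-count rule {rule!r}")


def enrichment_test(k_ip: int, n_ip: int, k_bg: int, n_bg: int,
                    rule: str = "any_cell") -> TestResult:
    """Fold enrichment and p-value for one peak's 2x2 table.

    Fold change is ``(k_ip/N_ip) / (max(k_bg, 1)/N_bg)``; the background
    count is floored at one for the ratio only (flagged) so that fold
    stays finite when the background is empty.
    """
    if not (1 <= k_ip <= n_ip):
        raise ValueError("need 1 <= k_ip <= N_ip")
    if not (0 <= k_bg <= n_bg):
        raise ValueError("need 0 <= k_bg <= N_bg")
    if n_ip == 0 or n_bg == 0:
        raise ValueError("zero-margin table")
    fold_floored = k_bg == 0
    fold = (k_ip / n_ip) / (max(k_bg, 1) / n_bg)
    table = np.array([[k_ip, n_ip - k_ip], [k_bg, n_bg - k_bg]], dtype=np.int64)
    if _needs_fisher(table, rule):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return TestResult(fold, max(float(p), FISHER_P_FLOOR), "fisher", fold_floored)
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return TestResult(fold, max(float(p), CHI2_P_FLOOR), "chi2_yates", fold_floored)


def enrich_all(peaks, multiplex: dict[str, pd.DataFrame], bg_kind: str = "cc",
               background=None, rule: str = "any_cell") -> pd.DataFrame:
    """Enrichment of every peak against the chosen background.

    ``multiplex`` maps RBP label -> deduplicated read table; each peak's
    IP library is its own RBP's reads.  For ``bg_kind='cc'`` the
    background is the pooled complement of the multiplex; for
    ``'smi'``/``'rnaseq'`` a single background read set is required.
    N values are whole-library usable counts.  Results are sorted by
    (p ascending, fold descending, peak_id ascending).
    """
    peaks = peaks_to_frame(peaks)
    indexes = {r: ReadIndex(df) for r, df in multiplex.items()}
    totals = {r: ix.total for r, ix in indexes.items()}
    if bg_kind == "cc":
        if len(multiplex) < 2:
            raise ValueError("complement control needs >= 2 RBPs")
        bg_index = None
    else:
        if background is None:
            raise ValueError(f"background read set required for bg_kind={bg_kind!r}")
        bg_index = ReadIndex(background)
    rows = []
    for p in peaks.itertuples():
        if p.rbp not in indexes:
            raise KeyError(f"peak {p.peak_id}: RBP {p.rbp!r} not in the multiplex")
        counts = {r: ix.count(p.chrom, p.strand, p.start, p.end)
                  for r, ix in indexes.items()}
        k_ip, n_ip = counts[p.rbp], totals[p.rbp]
        if bg_kind == "cc":
            k_bg, n_bg = complement_control(counts, totals, p.rbp)
        else:
            k_bg = bg_index.count(p.chrom, p.strand, p.start, p.end)
            n_bg = bg_index.total
        if k_ip == 0:
            continue  # nothing to test; the peak caller should prevent this
        res = enrichment_test(k_ip, n_ip, k_bg, n_bg, rule=rule)
        rows.append((p.peak_id, p.chrom, p.start, p.end, p.strand, p.rbp,
                     k_ip, n_ip, k_bg, n_bg, res.fold, res.p_value,
                     res.test_used, bg_kind, res.fold_floored))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return out.sort_values(["p_value", "fold", "peak_id"],
                           ascending=[True, False, True],
                           kind="mergesort").reset_index(drop=True)


def filter_enriched(results: pd.DataFrame, p_max: float = 1e-3,
                    fold_min: float = 8.0) -> pd.DataFrame:
    """Significant peaks: p < p_max AND fold > fold_min (both strict)."""
    keep = (results["p_value"] < p_max) & (results["fold"] > fold_min)
    return results[keep].reset_index(drop=True)


def repeat_filter(peaks, mask: pd.DataFrame | None = None,
                  blacklist_chroms: tuple[str, ...] = ()) -> pd.DataFrame:
    """Reverse intersection with a repeat mask / abundant-RNA blacklist.

    Removes peaks overlapping any mask interval by >= 1 bp (strand-blind)
    and peaks on blacklisted contigs (e.g. chrM).
    """
    peaks = peaks_to_frame(peaks)
    keep = ~peaks["chrom"].isin(blacklist_chroms)
    if mask is not None and len(mask):
        m_starts = {c: np.sort(g["start"].to_numpy()) for c, g in mask.groupby("chrom")}
        m_ends = {c: np.sort(g["end"].to_numpy()) for c, g in mask.groupby("chrom")}
        hits = []
        for p in peaks.itertuples():
            if p.chrom not in m_starts:
                hits.append(False)
                continue
            n = (np.searchsorted(m_starts[p.chrom], p.end, "left")
                 - np.searchsorted(m_ends[p.chrom], p.start, "right"))
            hits.append(n > 0)
        keep &= ~np.array(hits)
    return peaks[keep].reset_index(drop=True)
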