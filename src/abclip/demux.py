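"""Parsing multiplexed ABC reads: UMI extraction, barcode demultiplexing,
reverse complementation and UMI-based deduplication into usable reads.

A "usable" read is one that maps uniquely to the genome and survives PCR
duplicate removal; deduplication keys on the strand-aware crosslink
truncation coordinate because in truncation-based CLIP that position, not
the fragment end, identifies the original molecule.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .model import READ_COLUMNS, reads_to_frame
from .simulate import hamming, reverse_complement  # re-exported primitives

__all__ = [
    "BarcodeConfig", "ReadTooShortError", "extract_umi", "assign_barcode",
    "reverse_complement", "demux_fastq", "deduplicate", "usable_read_count",
]


class ReadTooShortError(ValueError):
    """Read shorter than the UMI + barcode prefix."""


@dataclass
class BarcodeConfig:
    """Inline barcode table and read layout.

    ``table`` maps barcode sequence -> RBP label.  ``layout`` gives the
    order of UMI and barcode at the read 5' end.
    """

    table: dict[str, str]
    umi_length: int = 10
    layout: str = "umi_first"  # umi_first | barcode_first
    max_mismatch: int = 0
    barcode_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.table:
            raise ValueError("empty barcode table")
        lengths = {len(b) for b in self.table}
        if len(lengths) != 1:
            raise ValueError("all barcodes must have the same length")
        self.barcode_length = lengths.pop()
        if len(set(self.table)) != len(self.table):
            raise ValueError("duplicate barcodes")
        if self.max_mismatch < 0 or self.umi_length < 0:
            raise ValueError("negative length/mismatch")
        if self.layout not in ("umi_first", "barcode_first"):
            raise ValueError(f"unknown layout {self.layout!r}")


def extract_umi(seq: str, config: BarcodeConfig) -> tuple[str, str]:
    """Split the UMI off the read per the configured layout.

    Returns ``(umi, remainder)`` with the remainder preserved verbatim
    (the barcode, if any, stays at the remainder's 5' end).
    """
    min_len = config.umi_length + config.barcode_length
    if len(seq) <= min_len:
        raise ReadTooShortError(f"read of {len(seq)} nt, need > {min_len}")
    u, b = config.umi_length, config.barcode_length
    if config.layout == "umi_first":
        return seq[:u], seq[u:]
    return seq[b:b + u], seq[:b] + seq[b + u:]


def assign_barcode(remainder: str, config: BarcodeConfig) -> str | None:
    """Assign the read to an RBP by its leading barcode; ``None`` if
    unassigned (no barcode within ``max_mismatch``, or an ambiguous tie)."""
    obs = remainder[: config.barcode_length]
    if config.max_mismatch == 0:
        return config.table.get(obs)
    best, best_d, tie = None, config.max_mismatch + 1, False
    for bc, rbp in config.table.items():
        d = hamming(obs, bc)
        if d < best_d:
            best, best_d, tie = rbp, d, False
        elif d == best_d:
            tie = True
    return None if (tie or best_d > config.max_mismatch) else best


def demux_fastq(records, config: BarcodeConfig,
                ) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Demultiplex sequenced records into per-RBP processed reads.

    Each assigned read has its UMI and barcode stripped and the insert
    reverse-complemented into alignment (sense) orientation; qualities are
    reversed to match.  Returns ``(per_rbp_records, report)`` where the
    report counts assigned / unassigned / discarded reads and the per-read
    UMI travels in the record id as ``<read_id> UMI:<umi>``.
    """
    out: dict[str, list[tuple[str, str, str]]] = {r: [] for r in config.table.values()}
    n_unassigned = n_discarded = 0
    n_assigned: Counter[str] = Counter()
    for rid, seq, qual in records:
        try:
            umi, remainder = extract_umi(seq.upper(), config)
        except ReadTooShortError:
            n_discarded += 1
            continue
        rbp = assign_barcode(remainder, config)
        if rbp is None:
            n_unassigned += 1
            continue
        insert = remainder[config.barcode_length:]
        tail_qual = qual[-len(insert):] if insert else ""
        out[rbp].append((f"{rid} UMI:{umi}", reverse_complement(insert),
                         tail_qual[::-1]))
        n_assigned[rbp] += 1
    report = pd.DataFrame(
        [(rbp, n_assigned.get(rbp, 0)) for rbp in out] +
        [("__unassigned__", n_unassigned), ("__discarded__", n_discarded)],
        columns=["rbp", "n_reads"])
    return out, report


# ---------------------------------------------------------------------------
# Deduplication

def _directional_components(counts: Counter) -> list[list[str]]:
    """Connected components under the directional adjacency rule:
    merge v into u when Hamming(u, v) == 1 and count(u) >= 2*count(v) - 1."""
    umis = sorted(counts)
    parent = {u: u for u in umis}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, u in enumerate(umis):
        for v in umis[i + 1:]:
            if hamming(u, v) != 1:
                continue
            cu, cv = counts[u], counts[v]
            if cu >= 2 * cv - 1 or cv >= 2 * cu - 1:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[rv] = ru
    comps: dict[str, list[str]] = {}
    for u in umis:
        comps.setdefault(find(u), []).append(u)
    return list(comps.values())


def deduplicate(reads, method: str = "directional", key: str = "truncation") -> pd.DataFrame:
    """Collapse PCR duplicates; one representative read per molecule.

    ``key`` selects the positional part of the grouping: the strand-aware
    truncation coordinate (default) or the full ``(start, end)`` interval.
    ``exact`` keeps one read per distinct UMI within a position group;
    ``directional`` additionally merges UMIs one substitution apart when
    the count ratio supports a PCR/sequencing-error origin.  The
    representative is the lexicographically smallest read_id.
    """
    if method not in ("exact", "directional"):
        raise ValueError(f"unknown dedup method {method!r}")
    if key not in ("truncation", "interval"):
        raise ValueError(f"unknown dedup key {key!r}")
    df = reads_to_frame(reads)
    if df.empty:
        return df
    pos_cols = ["rbp", "chrom", "strand"] + (
        ["truncation"] if key == "truncation" else ["start", "end"])

    df = df.sort_values("read_id", kind="mergesort")
    if method == "exact":
        return (df.drop_duplicates(pos_cols + ["umi"], keep="first")
                  .sort_values("read_id", kind="mergesort").reset_index(drop=True)[READ_COLUMNS])

    # exact collapse first; directional merging only matters where a
    # position group still holds >1 distinct UMI
    counts = df.groupby(pos_cols + ["umi"], sort=False)["read_id"].count()
    rep = df.drop_duplicates(pos_cols + ["umi"], keep="first")
    group_sizes = rep.groupby(pos_cols, sort=False)["umi"].transform("size")
    simple = rep[group_sizes == 1]
    multi = rep[group_sizes > 1]
    kept = [simple]
    for gkey, grp in multi.groupby(pos_cols, sort=False):
        c = Counter({u: int(counts[gkey + (u,)]) for u in grp["umi"]})
        keep_rows = []
        by_umi = {u: rid for u, rid in zip(grp["umi"], grp["read_id"])}
        for comp in _directional_components(c):
            keep_rows.append(min(by_umi[u] for u in comp))
        keep_rows = set(keep_rows)
        kept.append(grp[grp["read_id"].isin(keep_rows)])
    out = pd.concat(kept, ignore_index=True)
    return out.sort_values("read_id", kind="mergesort").reset_index(drop=True)[READ_COLUMNS]


def usable_read_count(reads, method: str = "directional") -> int:
    """Number of usable reads: uniquely-mapping reads after deduplication."""
    return len(deduplicate(reads, method=method))
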