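"""Dataset-level comparisons: peak-set overlap coefficients, gene-target
ranking curves, background-removal concordance and library-complexity
saturation curves.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .demux import deduplicate
from .model import peaks_to_frame, reads_to_frame


def _any_overlap_flags(query: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Per-query flag: overlaps >= 1 peak of ``other`` by >= 1 bp, same strand."""
    idx = {}
    for key, grp in other.groupby(["chrom", "strand"], sort=False):
        idx[key] = (np.sort(grp["start"].to_numpy()), np.sort(grp["end"].to_numpy()))
    flags = np.zeros(len(query), dtype=bool)
    for i, p in enumerate(query.itertuples()):
        arrs = idx.get((p.chrom, p.strand))
        if arrs is None:
            continue
        s_arr, e_arr = arrs
        flags[i] = (np.searchsorted(s_arr, p.end, "left")
                    > np.searchsorted(e_arr, p.start, "right"))
    return flags


def overlap_coefficient(peaks_a, peaks_b) -> float:
    """Overlapping peaks divided by the size of the smaller peak set.

    The smaller set's peaks are the ones counted; on a size tie the first
    argument is taken as the smaller set.
    """
    a, b = peaks_to_frame(peaks_a), peaks_to_frame(peaks_b)
    if a.empty or b.empty:
        raise ValueError("overlap coefficient undefined for an empty peak set")
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    return float(_any_overlap_flags(small, large).mean())


def rank_targets(results: pd.DataFrame, peak_to_gene: dict[str, str],
                 target_genes, top_n: int = 100) -> pd.DataFrame:
    """Cumulative target-gene counts over the p-value-ranked gene list.

    Peaks are ranked by (p ascending, fold descending), duplicate gene
    names dropped keeping the best rank, genes in ``target_genes`` labeled
    1 else 0, and the label sum accumulated over ranks ``1..top_n`` (the
    curve is shorter when fewer unique genes exist).
    """
    targets = set(target_genes)
    ranked = results.sort_values(["p_value", "fold", "peak_id"],
                                 ascending=[True, False, True], kind="mergesort")
    genes, seen = [], set()
    for pid in ranked["peak_id"]:
        gene = peak_to_gene.get(pid, "")
        if gene and gene not in seen:
            seen.add(gene)
            genes.append(gene)
        if len(genes) == top_n:
            break
    labels = [1 if g in targets else 0 for g in genes]
    return pd.DataFrame({
        "rank": np.arange(1, len(genes) + 1),
        "gene": genes,
        "is_target": labels,
        "cumulative": np.cumsum(labels),
    })


def background_removal_overlap(prioritized, discarded) -> float:
    """Fraction of prioritized peaks overlapping (>= 1 bp, same strand)
    any discarded reference peak; lower means less experimental background
    retained.  Compare across backgrounds at matched peak counts.
    """
    pri = peaks_to_frame(prioritized)
    if pri.empty:
        raise ValueError("empty prioritized peak set")
    dis = peaks_to_frame(discarded)
    if dis.empty:
        return 0.0
    return float(_any_overlap_flags(pri, dis).mean())


def complexity_curve(reads, depths, n_seeds: int = 3, method: str = "directional",
                     seed: int = 0) -> pd.DataFrame:
    """UMI saturation: unique molecules recovered at subsampled depths.

    For each depth, reads are sampled without replacement and
    deduplicated; the unique-molecule count is averaged over ``n_seeds``
    subsampling repetitions.
    """
    df = reads_to_frame(reads)
    depths = sorted(int(d) for d in depths)
    if depths and depths[-1] > len(df):
        raise ValueError(f"depth {depths[-1]} exceeds library size {len(df)}")
    rows = []
    for depth in depths:
        vals = []
        for j in range(n_seeds):
            rng = np.random.default_rng([seed, depth, j])
            sub = df.iloc[rng.choice(len(df), size=depth, replace=False)]
            vals.append(len(deduplicate(sub, method=method)))
        rows.append((depth, float(np.mean(vals))))
    return pd.DataFrame(rows, columns=["depth", "unique_molecules"]).assign(n_seeds=n_seeds)
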