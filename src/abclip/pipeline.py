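"""End-to-end convenience pipeline over the library modules:

simulate -> (FASTQ -> demultiplex) -> deduplicate -> candidate peaks ->
complement-control enrichment -> significance filter -> truth recovery.

Alignment is out of scope: simulated reads carry their true genomic
coordinates, and when the FASTQ route is exercised the demultiplexer's
RBP/UMI assignments are joined back onto those coordinates by read id,
standing in for a uniquely-mapping aligner.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demux as dx
from . import enrich as en
from . import simulate as sim
from .model import READ_COLUMNS, TranscriptModel, TruthSite, sites_to_frame


@dataclass
class PipelineResult:
    config: sim.SimConfig
    genome: dict[str, str]
    models: list[TranscriptModel]
    sites: list[TruthSite]
    truth: pd.DataFrame
    usable: dict[str, pd.DataFrame]
    peaks: pd.DataFrame
    results: dict[str, pd.DataFrame] = field(default_factory=dict)
    enriched: dict[str, pd.DataFrame] = field(default_factory=dict)
    demux_report: pd.DataFrame | None = None


def demuxed_alignments(records, truth: pd.DataFrame,
                       bc_config: dx.BarcodeConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Demultiplex FASTQ records and join assignments onto truth coordinates.

    Returns ``(aligned_reads, demux_report)``; the RBP label and UMI of
    each aligned read come from the demultiplexer, the coordinates from
    the simulator's truth table (the stand-in for unique alignment).
    """
    per_rbp, report = dx.demux_fastq(records, bc_config)
    coords = truth.set_index("read_id")[["chrom", "start", "end", "strand",
                                         "truncation", "molecule_id"]]
    frames = []
    for rbp, recs in per_rbp.items():
        if not recs:
            continue
        rids = [rid.split(" ", 1)[0] for rid, _, _ in recs]
        umis = [rid.split("UMI:", 1)[1] for rid, _, _ in recs]
        sub = coords.loc[rids].reset_index()
        sub["rbp"] = rbp
        sub["umi"] = umis
        frames.append(sub[READ_COLUMNS])
    reads = (pd.concat(frames, ignore_index=True)
             if frames else pd.DataFrame(columns=READ_COLUMNS))
    return reads, report


def run_pipeline(config: sim.SimConfig, *, via_fastq: bool = False,
                 backgrounds: tuple[str, ...] = ("cc",),
                 rnaseq_reads: int | None = None,
                 min_reads: int = 10, merge_gap: int = 15,
                 dedup_method: str = "directional",
                 max_mismatch: int = 0) -> PipelineResult:
    """Run the full computational pipeline on one simulated experiment."""
    genome, models = sim.make_genome(config)
    sites = sim.plant_sites(models, config)
    truth = sim.generate_reads(models, sites, config)

    report = None
    if via_fastq:
        records = sim.reads_to_fastq_records(genome, truth, config)
        bc = dx.BarcodeConfig(config.barcode_table(), umi_length=config.umi_length,
                              layout=config.layout, max_mismatch=max_mismatch)
        aligned, report = demuxed_alignments(records, truth, bc)
    else:
        aligned = truth

    usable = {rbp: dx.deduplicate(grp, method=dedup_method)
              for rbp, grp in aligned.groupby("rbp", sort=False)}
    peaks = pd.concat(
        [en.cluster_candidate_peaks(df, min_reads=min_reads, merge_gap=merge_gap,
                                    anchor="truncation") for df in usable.values()],
        ignore_index=True)

    result = PipelineResult(config, genome, models, sites, truth, usable, peaks,
                            demux_report=report)
    for bg in backgrounds:
        if bg == "cc":
            res = en.enrich_all(peaks, usable, bg_kind="cc")
        elif bg == "rnaseq":
            n = rnaseq_reads or config.reads_per_rbp
            bg_reads = sim.generate_expression_background(models, config, n)
            res = en.enrich_all(peaks, usable, bg_kind="rnaseq", background=bg_reads)
        else:
            raise ValueError(f"unknown background {bg!r}")
        result.results[bg] = res
        result.enriched[bg] = en.filter_enriched(res)
    return result


def site_recovery(sites: list[TruthSite], enriched: pd.DataFrame) -> dict[str, float]:
    """Fraction of truth sites recovered by the enriched-peak set.

    A site counts as recovered when an enriched peak of the same RBP and
    strand overlaps it by >= 1 bp.  Shared sites are scored per (RBP,
    interval) listing.
    """
    frame = sites_to_frame(sites)
    flags = []
    for s in frame.itertuples():
        sub = enriched[(enriched["rbp"] == s.rbp) & (enriched["chrom"] == s.chrom)
                       & (enriched["strand"] == s.strand)
                       & (enriched["start"] < s.end) & (enriched["end"] > s.start)]
        flags.append(len(sub) > 0)
    frame = frame.assign(recovered=flags)
    out = {}
    for kind, grp in frame.groupby("kind"):
        out[kind] = float(np.mean(grp["recovered"]))
    return out
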