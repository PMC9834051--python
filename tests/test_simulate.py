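import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from abclip.simulate import (
    SimConfig, SimSizingError, SitePlacementError, default_barcodes,
    generate_expression_background, generate_multiplex, generate_reads,
    hamming, make_genome, plant_sites, reads_to_fastq_records,
    transcript_expression,
)


# ---------------------------------------------------------------------------
# primitives

def test_reverse_complement_examples():
    from abclip.simulate import reverse_complement
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AACGTN") == "NACGTT"


@given(st.text(alphabet="ACGTN", max_size=64))
def test_reverse_complement_involution(s):
    from abclip.simulate import reverse_complement
    assert reverse_complement(reverse_complement(s)) == s


def test_hamming():
    assert hamming("ACGT", "ACGA") == 1
    with pytest.raises(ValueError):
        hamming("AC", "ACG")


def test_default_barcodes_pairwise_distance():
    bcs = default_barcodes(8, length=6, min_dist=3)
    assert len(set(bcs)) == 8
    assert all(hamming(a, b) >= 3 for i, a in enumerate(bcs) for b in bcs[i + 1:])
    assert bcs == default_barcodes(8, length=6, min_dist=3)  # deterministic


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(site_enrichment=0.5)
    with pytest.raises(ValueError):
        SimConfig(error_rate=-0.1)
    with pytest.raises(ValueError):
        SimConfig(n_rbps=2, barcodes=("AAAAAA", "AAAAAT"))  # distance < 2
    cfg = SimConfig(n_rbps=2, efficiency=(3.0, 1.0))
    assert cfg.rbp_names == ("RBP1", "RBP2")


# ---------------------------------------------------------------------------
# genome

def test_make_genome_deterministic(small_config):
    g1, m1 = make_genome(small_config)
    g2, m2 = make_genome(small_config)
    assert g1 == g2
    assert [(m.transcript_id, m.exons, m.cds) for m in m1] == \
           [(m.transcript_id, m.exons, m.cds) for m in m2]


def test_make_genome_empty_annotation():
    cfg = SimConfig(chrom_lengths=(5_000,), n_transcripts=0)
    genome, models = make_genome(cfg)
    assert models == []
    assert set(genome["chr1"]) <= set("ACGT") and len(genome["chr1"]) == 5_000


def test_make_genome_bounds_and_structure():
    cfg = SimConfig(chrom_lengths=(100_000,) * 3, n_transcripts=9, seed=3)
    genome, models = make_genome(cfg)
    assert len(models) == 9
    for m in models:
        for s, e in m.exons:
            assert 0 <= s < e <= 100_000
        # CDS contained in exons
        exonic = {p for s, e in m.exons for p in range(s, e)}
        assert all(set(range(s, e)) <= exonic for s, e in m.cds)
    # transcripts on one chromosome do not overlap
    for chrom in genome:
        spans = sorted((m.start, m.end) for m in models if m.chrom == chrom)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


def test_make_genome_histone_like_genes():
    cfg = SimConfig(chrom_lengths=(150_000,), n_transcripts=10,
                    histone_fraction=0.2, seed=5)
    _, models = make_genome(cfg)
    hist = [m for m in models if m.gene_class == "histone_like"]
    assert len(hist) == 2
    assert all(len(m.exons) == 1 and m.span == cfg.histone_length for m in hist)


def test_make_genome_sizing_error():
    with pytest.raises(SimSizingError):
        make_genome(SimConfig(chrom_lengths=(2_000,), n_transcripts=5))


# ---------------------------------------------------------------------------
# sites

def test_plant_sites_counts_and_determinism():
    cfg = SimConfig(chrom_lengths=(150_000, 150_000), n_transcripts=20,
                    n_rbps=2, sites_per_rbp=5, n_shared_sites=2, seed=11)
    _, models = make_genome(cfg)
    sites = plant_sites(models, cfg)
    specific = [s for s in sites if s.kind == "specific"]
    shared = [s for s in sites if s.kind == "shared"]
    assert len(specific) == 10          # 2 RBPs x 5 sites
    assert len(shared) == 4             # 2 shared intervals listed once per RBP
    assert len({(s.chrom, s.start, s.end) for s in shared}) == 2
    assert sites == plant_sites(models, cfg)


def test_plant_sites_min_gap(small_world, small_config):
    _, _, sites, _ = small_world
    ivs = sorted({(s.chrom, s.start, s.end) for s in sites})
    for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
        if c1 == c2:
            assert s2 - e1 >= small_config.site_min_gap


def test_plant_sites_3utr_feature_class():
    cfg = SimConfig(chrom_lengths=(150_000, 150_000), n_transcripts=20,
                    site_feature_class="3utr", site_length=80, seed=2)
    _, models = make_genome(cfg)
    sites = plant_sites(models, cfg)
    by_tx = {m.transcript_id: m for m in models}
    for s in sites:
        utr3 = by_tx[s.transcript_id].utr3
        assert any(us <= s.start and s.end <= ue for us, ue in utr3)


def test_plant_sites_placement_error():
    cfg = SimConfig(chrom_lengths=(150_000,), n_transcripts=10,
                    site_feature_class="3utr", site_length=400, seed=2)
    _, models = make_genome(cfg)
    with pytest.raises(SitePlacementError):
        plant_sites(models, cfg)  # 3'UTRs are at most 300 bp


# ---------------------------------------------------------------------------
# reads

def test_generate_reads_deterministic_and_conserved(small_world, small_config):
    _, models, sites, truth = small_world
    again = generate_reads(models, sites, small_config)
    assert truth.equals(again)
    assert len(truth) == small_config.reads_per_rbp * small_config.n_rbps
    assert truth["read_id"].is_unique


def test_fastq_matches_truth_one_to_one(small_world, small_config):
    genome, models, sites, truth = small_world
    records, truth2 = generate_multiplex(genome, models, sites, small_config)
    assert truth2.equals(truth)
    assert [r[0] for r in records] == truth["read_id"].tolist()


def test_reads_within_transcripts(small_world):
    _, models, _, truth = small_world
    spans = pd.DataFrame([(m.chrom, m.strand, m.start, m.end) for m in models],
                         columns=["chrom", "strand", "lo", "hi"])
    for r in truth.sample(500, random_state=0).itertuples():
        hit = spans[(spans.chrom == r.chrom) & (spans.strand == r.strand)
                    & (spans.lo <= r.truncation) & (r.truncation < spans.hi)]
        assert len(hit) == 1
        assert r.start <= r.truncation < r.end


def test_truncation_definition(small_world):
    _, _, _, truth = small_world
    plus = truth[truth.strand == "+"]
    minus = truth[truth.strand == "-"]
    assert (plus["truncation"] == plus["start"]).all()
    assert (minus["truncation"] == minus["end"] - 1).all()


def test_no_duplication_means_one_read_per_molecule(small_config):
    cfg = SimConfig(**{**small_config.__dict__, "pcr_duplication": 0.0,
                       "barcodes": (), "efficiency": (), "rbp_names": ()})
    genome, models = make_genome(cfg)
    sites = plant_sites(models, cfg)
    truth = generate_reads(models, sites, cfg)
    assert truth["molecule_id"].is_unique
    assert len(truth) == cfg.reads_per_rbp * cfg.n_rbps


def test_efficiency_split_binomial():
    cfg = SimConfig(chrom_lengths=(150_000, 150_000), n_transcripts=20,
                    n_rbps=2, efficiency=(3.0, 1.0), reads_per_rbp=20_000,
                    sites_per_rbp=2, n_shared_sites=0, seed=13)
    _, models = make_genome(cfg)
    truth = generate_reads(models, plant_sites(models, cfg), cfg)
    n = len(truth)
    share = (truth["rbp"] == "RBP1").mean()
    sigma = math.sqrt(0.75 * 0.25 / n)
    assert abs(share - 0.75) <= 3 * sigma


def test_site_rate_ratio_matches_lambda(small_world, small_config):
    """In-site vs flanking per-bp molecule rate ~ lambda (3-sigma, log scale)."""
    _, models, sites, truth = small_world
    lam = small_config.site_enrichment
    by_tx = {m.transcript_id: m for m in models}
    mols = truth.drop_duplicates("molecule_id")
    k_in = k_fl = 0
    l_in = l_fl = 0
    for s in sites:
        if s.kind != "specific":
            continue
        m = by_tx[s.transcript_id]
        sub = mols[(mols.rbp == s.rbp) & (mols.chrom == s.chrom)]
        t = sub["truncation"]
        k_in += int(((t >= s.start) & (t < s.end)).sum())
        l_in += s.end - s.start
        # flanks of equal total length inside the same transcript span
        half = (s.end - s.start) // 2
        lo, hi = max(m.start, s.start - half), min(m.end, s.end + half)
        k_fl += int((((t >= lo) & (t < s.start)) | ((t >= s.end) & (t < hi))).sum())
        l_fl += (s.start - lo) + (hi - s.end)
    ratio = (k_in / l_in) / (k_fl / l_fl)
    sigma_log = math.sqrt(1 / k_in + 1 / k_fl)
    assert abs(math.log(ratio / lam)) <= 3 * sigma_log


def test_fastq_record_layout(small_world, small_config):
    from abclip.simulate import reverse_complement
    genome, _, _, truth = small_world
    records = reads_to_fastq_records(genome, truth.head(50), small_config)
    bc_of = {rbp: bc for bc, rbp in small_config.barcode_table().items()}
    for (rid, seq, qual), row in zip(records, truth.head(50).itertuples()):
        assert rid == row.read_id and len(seq) == len(qual)
        frag = genome[row.chrom][row.start:row.end]
        sense = frag if row.strand == "+" else reverse_complement(frag)
        assert seq == row.umi + bc_of[row.rbp] + reverse_complement(sense)


def test_fastq_barcode_first_layout(small_world, small_config):
    genome, _, _, truth = small_world
    cfg = SimConfig(**{**small_config.__dict__, "layout": "barcode_first",
                       "barcodes": (), "efficiency": (), "rbp_names": ()})
    rec = reads_to_fastq_records(genome, truth.head(1), cfg)[0]
    row = truth.iloc[0]
    bc_of = {rbp: bc for bc, rbp in cfg.barcode_table().items()}
    assert rec[1].startswith(bc_of[row.rbp] + row.umi)


def test_error_rate_perturbs_reads(small_world, small_config):
    genome, _, _, truth = small_world
    cfg = SimConfig(**{**small_config.__dict__, "error_rate": 0.01,
                       "barcodes": (), "efficiency": (), "rbp_names": ()})
    clean = reads_to_fastq_records(genome, truth.head(2000), small_config)
    noisy = reads_to_fastq_records(genome, truth.head(2000), cfg)
    n_bases = sum(len(s) for _, s, _ in clean)
    n_diff = sum(sum(a != b for a, b in zip(s1, s2))
                 for (_, s1, _), (_, s2, _) in zip(clean, noisy))
    rate = n_diff / n_bases
    sigma = math.sqrt(0.01 * 0.99 / n_bases)
    assert abs(rate - 0.01) <= 4 * sigma


def test_expression_background_expression_proportional(small_world, small_config):
    _, models, _, _ = small_world
    bg = generate_expression_background(models, small_config, 30_000)
    assert bg["molecule_id"].is_unique and len(bg) == 30_000
    assert bg.equals(generate_expression_background(models, small_config, 30_000))
    expr = transcript_expression(models, small_config)
    w = np.array([m.span for m in models]) * expr
    # per-transcript truncation share tracks span x expression (loose 5-sigma)
    spans = [(m.chrom, m.strand, m.start, m.end) for m in models]
    for i in np.argsort(w)[-3:]:
        c, st_, lo, hi = spans[i]
        n = int(((bg.chrom == c) & (bg.strand == st_)
                 & (bg.truncation >= lo) & (bg.truncation < hi)).sum())
        exp = 30_000 * w[i] / w.sum()
        assert abs(n - exp) <= 5 * math.sqrt(exp)
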