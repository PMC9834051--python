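import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from abclip.enrich import (
    CHI2_P_FLOOR, FISHER_P_FLOOR, ReadIndex, _needs_fisher,
    cluster_candidate_peaks, complement_control, count_reads_in_peak,
    enrich_all, enrichment_test, filter_enriched, repeat_filter,
)
from abclip.model import AlignedRead, Peak, peaks_to_frame, reads_to_frame

from oracles import fisher_two_sided, needs_fisher_bruteforce, yates_chi2_p


def _read(rid, start, end, strand="+", rbp="A", chrom="chr1"):
    return AlignedRead(rid, rbp, "AAAA", chrom, start, end, strand)


# ---------------------------------------------------------------------------
# read counting and candidate peaks

def test_count_reads_in_peak_examples():
    peak = Peak("chr1", 40, 100, "+")
    assert count_reads_in_peak([_read("r", 10, 50)], peak) == 1      # 10 bp overlap
    assert count_reads_in_peak([_read("r", 10, 40)], peak) == 0      # half-open
    assert count_reads_in_peak([_read("r", 10, 50, "-")], peak) == 0  # strand


@given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60),
                          st.sampled_from("+-")), max_size=30),
       st.integers(0, 300), st.integers(1, 80), st.sampled_from("+-"))
def test_read_index_matches_bruteforce(raw, ps, plen, pstrand):
    reads = [_read(f"r{i}", s, s + l, strand) for i, (s, l, strand) in enumerate(raw)]
    pe = ps + plen
    want = sum(1 for r in reads
               if r.strand == pstrand and r.start < pe and r.end > ps)
    assert ReadIndex(reads).count("chr1", pstrand, ps, pe) == want


def test_cluster_candidate_peaks_examples():
    reads = [_read("r1", 10, 50), _read("r2", 30, 70), _read("r3", 40, 90)]
    peaks = cluster_candidate_peaks(reads, min_reads=3)
    assert len(peaks) == 1
    assert (peaks.loc[0, "start"], peaks.loc[0, "end"]) == (10, 90)

    far = [_read("r1", 10, 50), _read("r2", 100, 140)]
    assert len(cluster_candidate_peaks(far, min_reads=1, merge_gap=10)) == 2

    four = [_read(f"r{i}", 10, 50) for i in range(4)]
    assert len(cluster_candidate_peaks(four, min_reads=5)) == 0


def test_cluster_truncation_anchor():
    # fragments overlap heavily but truncations form two separated clusters
    reads = ([_read(f"a{i}", 100, 400) for i in range(3)]
             + [_read(f"b{i}", 300, 600) for i in range(3)])
    interval = cluster_candidate_peaks(reads, min_reads=3, anchor="interval")
    trunc = cluster_candidate_peaks(reads, min_reads=3, anchor="truncation",
                                    merge_gap=15)
    assert len(interval) == 1
    assert len(trunc) == 2
    with pytest.raises(ValueError):
        cluster_candidate_peaks(reads, anchor="midpoint")


# ---------------------------------------------------------------------------
# complement control

def test_complement_control_examples():
    counts = {"A": 10, "B": 2, "C": 3}
    totals = {"A": 1000, "B": 1000, "C": 2000}
    assert complement_control(counts, totals, "A") == (5, 3000)
    assert complement_control({"A": 1, "B": 7}, {"A": 10, "B": 20}, "A") == (7, 20)
    with pytest.raises(KeyError):
        complement_control(counts, totals, "Z")
    with pytest.raises(ValueError):
        complement_control({"A": 1}, {"A": 10}, "A")


def test_cc_additivity_invariant(small_world):
    """Sum over RBPs of (k_focal + k_bg) = n_rbps x pooled count per region."""
    _, _, sites, truth = small_world
    indexes = {rbp: ReadIndex(grp) for rbp, grp in truth.groupby("rbp")}
    totals = {r: ix.total for r, ix in indexes.items()}
    regions = [(s.chrom, s.strand, s.start, s.end) for s in sites[:5]]
    for chrom, strand, start, end in regions:
        counts = {r: ix.count(chrom, strand, start, end) for r, ix in indexes.items()}
        pooled = sum(counts.values())
        acc = sum(counts[r] + complement_control(counts, totals, r)[0]
                  for r in counts)
        assert acc == len(counts) * pooled


# ---------------------------------------------------------------------------
# the 2x2 test

def test_enrichment_test_identical_proportions():
    res = enrichment_test(10, 100, 10, 100)
    assert res.fold == 1.0
    assert res.p_value == 1.0
    assert res.test_used == "chi2_yates"
    assert not res.fold_floored


def test_enrichment_test_chi2_against_oracle():
    res = enrichment_test(40, 1000, 5, 1000)
    assert res.fold == 8.0
    assert res.test_used == "chi2_yates"
    want = yates_chi2_p(40, 960, 5, 995)
    assert res.p_value == pytest.approx(want, rel=1e-6)


def test_enrichment_test_degenerate_fisher():
    res = enrichment_test(1, 1, 0, 1)
    assert res.test_used == "fisher"
    assert res.p_value == 1.0
    assert res.fold_floored  # k_bg = 0


def test_enrichment_test_zero_background_large_library():
    # k_bg = 0 forces the low-count rule to Fisher; p hits the Fisher floor
    res = enrichment_test(50_000, 10**6, 0, 10**6)
    assert res.test_used == "fisher"
    assert res.p_value == FISHER_P_FLOOR
    assert res.fold == pytest.approx(50_000.0, rel=1e-12) and res.fold_floored


def test_enrichment_test_chi2_floor_exact():
    # all observed and expected cells >= 5 -> chi-squared path; p underflows
    res = enrichment_test(500_000, 10**6, 5, 10**6)
    assert res.test_used == "chi2_yates"
    assert res.p_value == CHI2_P_FLOOR


def test_enrichment_test_errors():
    with pytest.raises(ValueError):
        enrichment_test(0, 100, 5, 100)
    with pytest.raises(ValueError):
        enrichment_test(5, 100, 5, 0)
    with pytest.raises(ValueError):
        enrichment_test(5, 100, 200, 100)


def test_first_column_rule():
    # cells (6, 994, 6, 94): observed fine; expected d-cell < 5? No --
    # build a table where only a second-column cell is small:
    # k_ip=96, n_ip=100, k_bg=90, n_bg=100 -> observed b=4 < 5
    table = np.array([[96, 4], [90, 10]])
    assert _needs_fisher(table, rule="any_cell")
    assert not _needs_fisher(table, rule="first_column")
    with pytest.raises(ValueError):
        _needs_fisher(table, rule="bogus")


def test_switching_rule_matches_bruteforce_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(400):
        a = int(rng.integers(1, 51))
        b, c, d = (int(x) for x in rng.integers(0, 51, 3))
        if c + d == 0:
            continue
        table = np.array([[a, b], [c, d]])
        assert _needs_fisher(table) == needs_fisher_bruteforce(a, b, c, d)
        res = enrichment_test(a, a + b, c, c + d)
        assert res.test_used == ("fisher" if needs_fisher_bruteforce(a, b, c, d)
                                 else "chi2_yates")


def test_fisher_and_yates_match_oracles_spot_checks():
    for (a, b, c, d) in [(3, 40, 1, 44), (2, 0, 1, 7), (49, 2, 3, 50),
                         (1, 50, 50, 1), (12, 13, 14, 15)]:
        res = enrichment_test(a, a + b, c, c + d)
        if res.test_used == "fisher":
            assert res.p_value == pytest.approx(
                max(fisher_two_sided(a, b, c, d), FISHER_P_FLOOR), abs=1e-9)
        else:
            assert res.p_value == pytest.approx(yates_chi2_p(a, b, c, d), rel=1e-6)


def test_monotonicity_within_regime():
    # chi-squared regime: all cells stay >= 5
    ps = [enrichment_test(k, 10_000, 50, 10_000).p_value for k in range(500, 521)]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
    # Fisher regime: expected first-column cells stay < 5
    ps = [enrichment_test(k, 10_000, 1, 10_000).p_value for k in range(2, 8)]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# enrich_all / filter / repeat mask

@pytest.fixture(scope="module")
def small_enrichment(small_world):
    _, _, sites, truth = small_world
    usable = {rbp: grp.reset_index(drop=True) for rbp, grp in truth.groupby("rbp")}
    peaks = pd.concat(
        [cluster_candidate_peaks(df, min_reads=10, merge_gap=15, anchor="truncation")
         for df in usable.values()], ignore_index=True)
    results = enrich_all(peaks, usable, bg_kind="cc")
    return sites, usable, peaks, results


def test_enrich_all_cc_kbg_is_sum_of_others(small_enrichment):
    sites, usable, peaks, results = small_enrichment
    indexes = {r: ReadIndex(df) for r, df in usable.items()}
    for row in results.head(20).itertuples():
        k_others = sum(ix.count(row.chrom, row.strand, row.start, row.end)
                       for r, ix in indexes.items() if r != row.rbp)
        assert row.k_bg == k_others
        assert row.n_bg == sum(len(df) for r, df in usable.items() if r != row.rbp)


def test_enrich_all_sorted_and_planted_sites_on_top(small_enrichment):
    sites, _, _, results = small_enrichment
    order = list(zip(results["p_value"], -results["fold"]))
    assert order == sorted(order)
    spec = [s for s in sites if s.kind == "specific"]

    def hits_site(row):
        return any(s.rbp == row.rbp and s.chrom == row.chrom
                   and s.strand == row.strand
                   and row.start < s.end and row.end > s.start for s in spec)

    top = results.head(len(spec))
    assert sum(hits_site(r) for r in top.itertuples()) >= len(spec) - 1


def test_enrich_all_identical_ip_and_background(small_world):
    _, _, _, truth = small_world
    one = truth[truth["rbp"] == "RBP1"].reset_index(drop=True)
    peaks = cluster_candidate_peaks(one, min_reads=10, merge_gap=15,
                                    anchor="truncation")
    res = enrich_all(peaks, {"RBP1": one}, bg_kind="smi", background=one)
    assert (res["fold"] <= 8).all()
    assert res["bg_kind"].eq("smi").all()


def test_enrich_all_requires_background_or_multiplex(small_world):
    _, _, _, truth = small_world
    one = truth[truth["rbp"] == "RBP1"].reset_index(drop=True)
    peaks = cluster_candidate_peaks(one, min_reads=10, anchor="truncation",
                                    merge_gap=15)
    with pytest.raises(ValueError):
        enrich_all(peaks, {"RBP1": one}, bg_kind="cc")
    with pytest.raises(ValueError):
        enrich_all(peaks, {"RBP1": one}, bg_kind="rnaseq")


def test_filter_enriched_boundaries():
    res = pd.DataFrame({
        "peak_id": ["a", "b", "c"],
        "fold": [8.0, 8.01, 9.0],
        "p_value": [1e-6, 1e-3, 1e-4],
    })
    kept = filter_enriched(res)
    assert kept["peak_id"].tolist() == ["c"]  # both thresholds strict


def test_repeat_filter():
    peaks = peaks_to_frame([Peak("chr1", 100, 200, "+", peak_id="in"),
                            Peak("chr1", 299, 400, "-", peak_id="edge"),
                            Peak("chr1", 500, 600, "+", peak_id="out"),
                            Peak("chrM", 0, 50, "+", peak_id="mito")])
    mask = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [120, 250],
                         "end": [180, 300]})
    kept = repeat_filter(peaks, mask=mask, blacklist_chroms=("chrM",))
    assert kept["peak_id"].tolist() == ["out"]
    ident = repeat_filter(peaks, mask=pd.DataFrame(columns=["chrom", "start", "end"]))
    assert ident["peak_id"].tolist() == ["in", "edge", "out", "mito"]
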