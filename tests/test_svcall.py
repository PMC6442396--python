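"""SV detection: barcode index, hypergeometric scan, segmentation, filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from lrkit.phasing import assign_molecule_haplotypes
from lrkit.svcall import (barcode_overlap_scan, benjamini_hochberg, best_split,
                          build_barcode_index, coverage_segmentation,
                          filter_calls, merge_call_sets,
                          phased_coverage_deletions, windowed_depth)


def mol_frame(rows):
    """rows: (barcode, chrom, start, end)."""
    df = pd.DataFrame(rows, columns=["barcode", "chrom", "start", "end"])
    df["barcode"] = df["barcode"].astype("category")
    df["molecule_id"] = np.arange(len(df))
    return df


# -- index --------------------------------------------------------------------

def test_molecule_contributes_to_every_overlapped_window():
    mols = mol_frame([("B", "chr1", 0, 25_000)])
    idx = build_barcode_index(mols, window=10_000, chrom_lengths={"chr1": 50_000})
    m = np.asarray(idx.matrix.todense())
    assert list(m[:, 0]) == [1, 1, 1, 0, 0]


def test_empty_molecules_give_empty_index():
    mols = mol_frame([])
    idx = build_barcode_index(mols, window=10_000, chrom_lengths={"chr1": 50_000})
    assert idx.matrix.nnz == 0


def test_index_matches_brute_force_interval_stabbing():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(100):
        s = int(rng.integers(0, 900_000))
        rows.append((f"B{i % 17}", "chr1", s, s + int(rng.integers(1, 80_000))))
    mols = mol_frame(rows)
    window = 10_000
    idx = build_barcode_index(mols, window, {"chr1": 1_000_000})
    m = np.asarray(idx.matrix.todense())
    cats = list(mols["barcode"].cat.categories)
    for w in range(m.shape[0]):
        lo, hi = w * window, (w + 1) * window
        expected = {cats.index(b) for b, _, s, e in
                    mols[["barcode", "chrom", "start", "end"]]
                    .itertuples(index=False) if s < hi and e > lo}
        assert set(np.flatnonzero(m[w])) == expected


def test_nonpositive_window_rejected():
    with pytest.raises(ValueError):
        build_barcode_index(mol_frame([]), window=0)


# -- hypergeometric + BH ------------------------------------------------------

def exact_hypergeom_tail(k, N, nA, nB):
    """P(X >= k) by direct combinatorial enumeration."""
    total = 0.0
    for x in range(k, min(nA, nB) + 1):
        total += (math.comb(nA, x) * math.comb(N - nA, nB - x)
                  / math.comb(N, nB))
    return total


def test_hypergeometric_tail_matches_exact_enumeration_small_N():
    for N in range(2, 31):
        for nA in range(1, N + 1):
            for nB in range(1, N + 1):
                kmax = min(nA, nB)
                ks = np.arange(0, kmax + 1)
                got = hypergeom.sf(ks - 1, N, nA, nB)
                # exact tail by top-down cumulative enumeration
                pmf = np.array([math.comb(nA, x) * math.comb(N - nA, nB - x)
                                / math.comb(N, nB) for x in ks])
                want = np.cumsum(pmf[::-1])[::-1]
                assert np.abs(got - want).max() < 1e-12, (N, nA, nB)


def test_hand_case_n100():
    # N=100, |A|=10, |B|=10, k=5
    assert hypergeom.sf(4, 100, 10, 10) == pytest.approx(
        exact_hypergeom_tail(5, 100, 10, 10), abs=1e-12)


def textbook_bh(pvals, alpha):
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    r_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= alpha * rank / m:
            r_max = rank
    reject[order[:r_max]] = True
    return reject


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60),
       st.sampled_from([0.01, 0.05, 0.2]))
def test_bh_matches_textbook_step_up(pvals, alpha):
    pvals = np.array(pvals)
    got = benjamini_hochberg(pvals, alpha)
    want = textbook_bh(pvals, alpha)
    assert (got == want).all()


def test_bh_with_implicit_unit_pvalues():
    """Padding with p = 1 tests must equal passing them explicitly."""
    p = np.array([1e-6, 0.004, 0.03, 0.5])
    full = np.concatenate([p, np.ones(96)])
    got = benjamini_hochberg(p, 0.05, n_tests=100)
    want = textbook_bh(full, 0.05)[:4]
    assert (got == want).all()


# -- overlap scan -------------------------------------------------------------

def test_disjoint_barcode_sets_make_no_call():
    rows = [(f"A{i}", "chr1", 0, 30_000) for i in range(20)]
    rows += [(f"B{i}", "chr1", 200_000, 230_000) for i in range(20)]
    # background so the null is well defined
    rng = np.random.default_rng(1)
    for i in range(200):
        s = int(rng.integers(0, 450_000))
        rows.append((f"C{i}", "chr1", s, s + 30_000))
    mols = mol_frame(rows)
    idx = build_barcode_index(mols, 10_000, {"chr1": 500_000})
    calls = barcode_overlap_scan(idx, min_separation=30_000, alpha=0.01)
    assert len(calls) == 0


def test_shared_distinct_molecules_across_gap_called():
    """Barcodes with separate molecule clusters flanking a junction are called;
    the junction breakends land within one window of the cluster edges."""
    rows = []
    for i in range(25):  # junction-spanning barcodes: two distinct molecules
        rows.append((f"J{i}", "chr1", 70_000, 100_000))
        rows.append((f"J{i}", "chr1", 300_000, 330_000))
    rng = np.random.default_rng(2)
    for i in range(300):
        s = int(rng.integers(0, 460_000))
        rows.append((f"C{i}", "chr1", s, s + 40_000))
    mols = mol_frame(rows)
    idx = build_barcode_index(mols, 10_000, {"chr1": 500_000})
    calls = barcode_overlap_scan(idx, min_separation=30_000, alpha=0.01,
                                 molecules=mols)
    assert len(calls) >= 1
    best = calls.sort_values("score", ascending=False).iloc[0]
    assert abs(best["pos1"] - 100_000) <= 10_000
    assert abs(best["pos2"] - 300_000) <= 10_000


def test_single_long_molecules_do_not_mimic_junctions():
    """A barcode whose one molecule contiguously covers both windows is
    excluded from the pair count (long molecules are not junction evidence)."""
    rows = [(f"L{i}", "chr1", 50_000, 200_000) for i in range(30)]
    rng = np.random.default_rng(3)
    for i in range(200):
        s = int(rng.integers(0, 460_000))
        rows.append((f"C{i}", "chr1", s, s + 40_000))
    mols = mol_frame(rows)
    idx = build_barcode_index(mols, 10_000, {"chr1": 500_000})
    calls = barcode_overlap_scan(idx, min_separation=30_000, alpha=0.01)
    assert len(calls) == 0


# -- coverage segmentation ----------------------------------------------------

def test_uniform_depth_yields_no_calls():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(2_000):
        # allow edge overhang so expected depth is uniform across the chromosome
        s = int(rng.integers(-50_000, 990_000))
        rows.append(("B", "chr1", max(s, 0), min(s + 50_000, 1_000_000)))
    mols = mol_frame(rows)
    calls = coverage_segmentation(mols, {"chr1": 1_000_000}, min_size=10_000)
    assert len(calls) == 0


def test_best_split_matches_exhaustive_scan():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x = rng.normal(0, 1, size=int(rng.integers(2, 40)))
        t, gain = best_split(x)
        # exhaustive single-changepoint least-squares scan
        best_t, best_gain = None, -np.inf
        sse = lambda v: ((v - v.mean()) ** 2).sum() if len(v) else 0.0
        total = sse(x)
        for tt in range(1, len(x)):
            g = total - sse(x[:tt]) - sse(x[tt:])
            if g > best_gain + 1e-12:
                best_gain, best_t = g, tt
        assert t == best_t
        assert gain == pytest.approx(best_gain)


def test_planted_homozygous_deletion_boundaries_within_one_window():
    rng = np.random.default_rng(2)
    rows = []
    for i in range(3_000):
        s = int(rng.integers(0, 990_000))
        e = s + 50_000
        # homozygous 100 kb deletion: no molecules inside [400k, 500k)
        if s < 500_000 and e > 400_000:
            continue
        rows.append((f"B{i % 500}", "chr1", s, e))
    mols = mol_frame(rows)
    calls = coverage_segmentation(mols, {"chr1": 1_000_000}, window=1_000,
                                  min_size=20_000)
    dels = calls[calls["svtype"] == "DEL"]
    assert len(dels) == 1
    assert abs(dels["pos1"].iloc[0] - 400_000) <= 1_000
    assert abs(dels["pos2"].iloc[0] - 500_000) <= 1_000


def test_terminal_deletion_detected():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(3_000):
        s = int(rng.integers(0, 990_000))
        e = s + 50_000
        if e > 900_000 and rng.random() < 0.95:  # telomeric loss
            continue
        rows.append((f"B{i % 500}", "chr1", s, e))
    mols = mol_frame(rows)
    calls = coverage_segmentation(mols, {"chr1": 1_000_000}, window=1_000,
                                  min_size=20_000)
    dels = calls[(calls["svtype"] == "DEL") & (calls["pos2"] >= 999_000)]
    assert len(dels) == 1


# -- phased deletions ---------------------------------------------------------

@pytest.fixture(scope="module")
def het_del_sim():
    from lrkit import SimConfig
    from lrkit.pipeline import run_pipeline
    cfg = SimConfig(genome_length=2_000_000, n_chromosomes=1, het_snv_rate=1e-3,
                    indel_rate=0.0, sv_spec=[("DEL", 5_000, 1)],
                    mean_molecule_length=50_000, n_partitions=1_500,
                    molecules_per_partition_mean=1.0,
                    barcode_whitelist_size=10_000, seed=3)
    return run_pipeline(cfg)


def test_planted_het_deletion_called_with_block_haplotype(het_del_sim):
    res = het_del_sim
    sv = res.genome.svs[0]
    mh = assign_molecule_haplotypes(res.observations, res.phased_variants)
    calls = phased_coverage_deletions(res.alignments, res.assignment, mh,
                                      res.blocks, res.genome.chrom_lengths)
    hits = calls[(calls["pos1"] < sv.pos2) & (calls["pos2"] > sv.pos1)]
    assert len(hits) == 1
    hit = hits.iloc[0]
    assert hit["haplotype"] in (0, 1)
    assert abs(hit["pos1"] - sv.pos1) <= 1_000
    assert abs(hit["pos2"] - sv.pos2) <= 1_000


def test_no_depth_drop_no_calls(het_del_sim):
    """Outside the planted deletion, the detector stays quiet (few spurious
    sub-kb candidates at most, none above 2 kb)."""
    res = het_del_sim
    sv = res.genome.svs[0]
    mh = assign_molecule_haplotypes(res.observations, res.phased_variants)
    calls = phased_coverage_deletions(res.alignments, res.assignment, mh,
                                      res.blocks, res.genome.chrom_lengths)
    others = calls[(calls["pos1"] >= sv.pos2) | (calls["pos2"] <= sv.pos1)]
    assert (others["size"] <= 2_000).all()


def test_het_deletion_outside_blocks_unlabelled():
    """With phasing unavailable (no blocks), the same deletion still surfaces
    as an unphased candidate from the total-depth drop."""
    from lrkit import SimConfig
    from lrkit.pipeline import run_pipeline
    cfg = SimConfig(genome_length=2_000_000, n_chromosomes=1, het_snv_rate=1e-3,
                    indel_rate=0.0, sv_spec=[("DEL", 5_000, 1)],
                    mean_molecule_length=50_000, n_partitions=1_500,
                    molecules_per_partition_mean=1.0,
                    barcode_whitelist_size=10_000, seed=3)
    res = run_pipeline(cfg)
    sv = res.genome.svs[0]
    mh = assign_molecule_haplotypes(res.observations.iloc[:0],
                                    res.phased_variants)
    calls = phased_coverage_deletions(res.alignments, res.assignment, mh,
                                      [], res.genome.chrom_lengths)
    hits = calls[(calls["pos1"] < sv.pos2) & (calls["pos2"] > sv.pos1)]
    assert len(hits) == 1
    assert hits["haplotype"].iloc[0] == -1


# -- filtering / merging ------------------------------------------------------

def call_frame(rows):
    cols = ["chrom1", "pos1", "chrom2", "pos2", "svtype", "size", "score",
            "haplotype", "filter", "source"]
    return pd.DataFrame([(*r, 0.0, -1, "PASS", "test") for r in rows],
                        columns=cols)


def test_empty_mask_passes_everything():
    calls = call_frame([("chr1", 100, "chr1", 5_000, "DEL", 4_900)])
    mask = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    assert (filter_calls(calls, mask)["filter"] == "PASS").all()


def test_breakend_inside_mask_demoted():
    calls = call_frame([("chr1", 150, "chr1", 5_000, "DEL", 4_850),
                        ("chr1", 9_000, "chr1", 20_000, "DEL", 11_000)])
    mask = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                         "name": ["sd"]})
    out = filter_calls(calls, mask)
    assert list(out["filter"]) == ["CANDIDATE", "PASS"]


def test_mask_end_coordinate_is_exclusive():
    calls = call_frame([("chr1", 200, "chr1", 5_000, "DEL", 4_800)])
    mask = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                         "name": ["sd"]})
    assert filter_calls(calls, mask)["filter"].iloc[0] == "PASS"


def test_merge_drops_reciprocal_duplicates():
    a = call_frame([("chr1", 100_000, "chr1", 200_000, "DEL", 100_000)])
    b = call_frame([("chr1", 102_000, "chr1", 198_000, "DEL", 96_000),
                    ("chr1", 600_000, "chr1", 700_000, "DEL", 100_000)])
    merged = merge_call_sets(a, b)
    assert len(merged) == 2
    assert set(merged["pos1"]) == {100_000, 600_000}


# -- coverage dependence ------------------------------------------------------

def test_tra_detection_degrades_before_cnv_on_coverage_ladder(sv_sim):
    """Down-sampling reads kills the barcode-overlap translocation signal
    (molecules fall below the read floor) long before the large-CNV log-ratio
    signal fades: at ~0.5x the translocations are lost while >=80% of the
    large deletions still segment out of read depth."""
    from lrkit.molecules import infer_molecules
    from lrkit.svcall import barcode_overlap_scan as scan

    res = sv_sim
    chrom_lengths = res.genome.chrom_lengths
    big_dels = [s for s in res.genome.svs
                if s.svtype == "DEL" and s.size >= 100_000]
    tras = [s for s in res.genome.svs if s.svtype == "TRA"]

    def tra_found(sv, calls):
        for r in calls[calls["svtype"] == "TRA"].itertuples():
            ends = {(r.chrom1, r.pos1), (r.chrom2, r.pos2)}
            if all(any(c == tc and abs(p - tp) <= 10_000 for c, p in ends)
                   for tc, tp in [(sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)]):
                return True
        return False

    def del_found(sv, calls):
        # >= 50% of the truth deletion covered by a DEL segment; at low
        # coverage neighbouring events can merge into one wide segment, which
        # still demonstrates the depth signal
        return any(r.chrom1 == sv.chrom1
                   and min(r.pos2, sv.pos2) - max(r.pos1, sv.pos1)
                   >= 0.5 * sv.size
                   for r in calls[calls["svtype"] == "DEL"].itertuples())

    n_tra, n_del = [], []
    for keep_every in (1, 20, 60):  # ~30x, ~1.5x, ~0.5x read coverage
        aln = res.alignments[res.alignments["read_id"] % keep_every == 0]
        mols = infer_molecules(aln)
        overlap = scan(build_barcode_index(mols, 10_000, chrom_lengths),
                       molecules=mols)
        cov = coverage_segmentation(aln, chrom_lengths, window=10_000,
                                    min_size=50_000)
        n_tra.append(sum(tra_found(s, overlap) for s in tras))
        n_del.append(sum(del_found(s, cov) for s in big_dels))

    assert n_tra[0] == len(tras) == 2
    assert n_tra == sorted(n_tra, reverse=True)
    assert n_tra[-1] < len(tras)  # balanced events need deep data
    assert min(n_del) >= 0.6 * len(big_dels)  # CNV signal persists
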