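"""Phasing: genotyper, observations, link evidence, block assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lrkit.phasing import (DEFAULT_LINK_WEIGHT, build_links, call_het_variants,
                           extract_observations, phase, phased_vcf_frame)


def make_aln(rows):
    """rows: (barcode, chrom, start, seq[, mapq]); end = start + len(seq)."""
    recs = []
    for r in rows:
        bc, ch, start, seq = r[:4]
        mapq = r[4] if len(r) > 4 else 60
        recs.append((bc, ch, start, start + len(seq), seq, mapq))
    df = pd.DataFrame(recs, columns=["barcode", "chrom", "start", "end",
                                     "seq", "mapq"])
    df["barcode"] = df["barcode"].astype("category")
    df["chrom"] = df["chrom"].astype("category")
    df["read_id"] = np.arange(len(df))
    return df


def variants_frame(rows):
    """rows: (chrom, pos, ref, alt)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


# -- genotyper ----------------------------------------------------------------

def test_balanced_pileup_called_het():
    ref = {"chr1": b"A" * 100}
    rows = [("B", "chr1", 50, b"A") for _ in range(15)]
    rows += [("B", "chr1", 50, b"G") for _ in range(15)]
    out = call_het_variants(make_aln(rows), ref)
    assert len(out) == 1
    row = out.iloc[0]
    assert (row["pos"], row["ref"], row["alt"]) == (50, "A", "G")
    assert row["n_ref"] == row["n_alt"] == 15


def test_lone_error_not_called_het():
    ref = {"chr1": b"A" * 100}
    rows = [("B", "chr1", 50, b"A") for _ in range(30)]
    rows += [("B", "chr1", 50, b"G")]
    assert len(call_het_variants(make_aln(rows), ref)) == 0


def test_depth_floor_respected():
    ref = {"chr1": b"A" * 100}
    rows = [("B", "chr1", 50, b"A"), ("B", "chr1", 50, b"A"),
            ("B", "chr1", 50, b"G"), ("B", "chr1", 50, b"G")]
    assert len(call_het_variants(make_aln(rows), ref, min_depth=8)) == 0
    assert len(call_het_variants(make_aln(rows), ref, min_depth=4)) == 1


def test_genotyper_recall_precision_on_simulation(recovery_sim):
    truth = set(zip(recovery_sim.genome.het_snvs()["chrom"],
                    recovery_sim.genome.het_snvs()["pos"]))
    called = set(zip(recovery_sim.het_variants["chrom"],
                     recovery_sim.het_variants["pos"]))
    recall = len(truth & called) / len(truth)
    precision = len(truth & called) / len(called)
    assert recall >= 0.98
    assert precision >= 0.99


# -- observations -------------------------------------------------------------

def test_read_without_het_site_yields_no_observation():
    variants = variants_frame([("chr1", 500, "A", "G")])
    aln = make_aln([("B", "chr1", 10, b"ACGT" * 10)])
    assert len(extract_observations(aln, variants)) == 0


def test_read_over_two_sites_yields_two_matching_observations():
    # read carries alt T at pos 12 and ref A at pos 18 (offset 8 of ACGT*5)
    variants = variants_frame([("chr1", 12, "G", "T"), ("chr1", 18, "A", "C")])
    seq = bytearray(b"ACGTACGTACGTACGTACGT")
    seq[2] = ord("T")  # pos 12 = start 10 + offset 2
    aln = make_aln([("B", "chr1", 10, bytes(seq))])
    obs = extract_observations(aln, variants)
    assert len(obs) == 2
    assert list(obs["allele"]) == [1, 0]


def test_third_allele_bases_dropped():
    variants = variants_frame([("chr1", 10, "A", "G")])
    aln = make_aln([("B", "chr1", 10, b"C")])  # neither ref nor alt
    assert len(extract_observations(aln, variants)) == 0


def test_observation_error_rate_matches_substitution_model(recovery_sim):
    """A substitution flips an observation ref<->alt only when it hits the
    exact partner base, i.e. in 1/3 of errors; the observed allele-flip rate
    must sit within 3 sigma of base_error_rate / 3."""
    res = recovery_sim
    truth = res.genome.het_snvs().set_index(["chrom", "pos"])["haplotype"]
    var_key = [(c, p) for c, p in zip(res.het_variants["chrom"],
                                      res.het_variants["pos"])]
    obs = res.observations
    vi = obs["var_idx"].to_numpy()
    hap_alt = np.array([truth.get(var_key[i], -1) for i in vi])
    read_hap = res.alignments["haplotype"].to_numpy()[obs["row"].to_numpy()]
    known = hap_alt >= 0
    expected_allele = (read_hap[known] == hap_alt[known]).astype(np.int8)
    flips = int((obs["allele"].to_numpy()[known] != expected_allele).sum())
    total = int(known.sum())
    rate = res.config.base_error_rate / 3
    sd = np.sqrt(total * rate * (1 - rate))
    assert abs(flips - rate * total) < 3 * sd


# -- links --------------------------------------------------------------------

def obs_frame(rows):
    """rows: (molecule_id, var_idx, allele)."""
    return pd.DataFrame(rows, columns=["molecule_id", "var_idx", "allele"]
                        ).assign(barcode=0)[["var_idx", "allele", "barcode",
                                             "molecule_id"]]


def test_single_cis_molecule_counts_once():
    links = build_links(obs_frame([(0, 3, 1), (0, 7, 1)]))
    assert len(links) == 1
    row = links.iloc[0]
    assert (row["i"], row["j"], row["n_cis"], row["n_trans"]) == (3, 7, 1, 0)
    assert row["log_odds"] == pytest.approx(DEFAULT_LINK_WEIGHT)


def test_balanced_cis_trans_cancels():
    links = build_links(obs_frame([(0, 1, 1), (0, 2, 1),
                                   (1, 1, 1), (1, 2, 0)]))
    row = links.iloc[0]
    assert row["n_cis"] == 1 and row["n_trans"] == 1
    assert row["log_odds"] == 0.0


def test_links_match_hand_tally_on_toy():
    """4 variants, 6 molecules, hand-tallied adjacent-pair counts."""
    rows = [
        (0, 0, 1), (0, 1, 1), (0, 2, 1),           # cis 0-1, cis 1-2
        (1, 1, 0), (1, 2, 0),                       # cis 1-2
        (2, 2, 1), (2, 3, 0),                       # trans 2-3
        (3, 0, 1), (3, 2, 1),                       # cis 0-2 (skips 1)
        (4, 1, 1), (4, 3, 1),                       # cis 1-3
        (5, 0, 0), (5, 1, 1), (5, 3, 1),            # trans 0-1, cis 1-3
    ]
    links = build_links(obs_frame(rows))
    got = {(r.i, r.j): (r.n_cis, r.n_trans) for r in links.itertuples()}
    assert got == {(0, 1): (1, 1), (1, 2): (2, 0), (2, 3): (0, 1),
                   (0, 2): (1, 0), (1, 3): (2, 0)}


def test_conflicting_duplicate_reads_dropped():
    # one molecule reads the same site twice with different alleles
    links = build_links(obs_frame([(0, 1, 1), (0, 1, 0), (0, 2, 1)]))
    assert len(links) == 0


# -- phase --------------------------------------------------------------------

def toy_variants(n, chrom="chr1", spacing=1_000):
    return pd.DataFrame({"chrom": chrom, "pos": np.arange(n) * spacing,
                         "ref": "A", "alt": "G"})


def test_two_variants_single_cis_molecule_one_block():
    variants = toy_variants(2)
    links = build_links(obs_frame([(0, 0, 1), (0, 1, 1),
                                   (1, 0, 0), (1, 1, 0)]))
    phased, blocks = phase(variants, links, min_block_logodds=1.0)
    multi = [b for b in blocks if b.n_variants == 2]
    assert len(multi) == 1
    assert list(phased["orientation"]) == [0, 0]  # same orientation (cis)


def test_no_spanning_molecule_breaks_block():
    variants = toy_variants(4)
    rows = [(0, 0, 1), (0, 1, 1), (1, 0, 1), (1, 1, 1),
            (2, 2, 1), (2, 3, 1), (3, 2, 0), (3, 3, 0)]  # no 1-2 link
    phased, blocks = phase(variants, build_links(obs_frame(rows)))
    sets = phased["phase_set"].to_numpy()
    assert sets[0] == sets[1] and sets[2] == sets[3]
    assert sets[1] != sets[2]


def test_weak_link_below_threshold_breaks_block():
    variants = toy_variants(2)
    links = build_links(obs_frame([(0, 0, 1), (0, 1, 1)]))  # one molecule
    # default threshold requires two concordant molecules
    phased, blocks = phase(variants, links)
    assert (phased["phase_set"] == -1).all()
    phased2, _ = phase(variants, links, min_block_logodds=1.0)
    assert (phased2["phase_set"] >= 0).all()


def brute_force_best_orientation(n, links):
    """Exhaustive max-concordance orientation over all 2^n assignments."""
    Li = links["i"].to_numpy()
    Lj = links["j"].to_numpy()
    n_cis = links["n_cis"].to_numpy()
    n_trans = links["n_trans"].to_numpy()
    best_score, best = -1, None
    for bits in itertools.product((0, 1), repeat=n):
        o = np.array(bits)
        score = int(np.where(o[Li] == o[Lj], n_cis, n_trans).sum())
        if score > best_score:
            best_score, best = score, o
    return best_score, best


def test_phase_matches_exhaustive_search_on_16_variants():
    """Greedy union-find + windowed refinement reaches the global
    max-concordance orientation found by exhaustive 2^16 search."""
    rng = np.random.default_rng(42)
    n = 16
    truth = rng.integers(0, 2, n)
    rows = []
    mol = 0
    for _ in range(60):  # 60 molecules observing random windows, 4% flips
        start = int(rng.integers(0, n - 1))
        span = int(rng.integers(2, 5))
        hap = int(rng.integers(0, 2))
        for v in range(start, min(start + span, n)):
            allele = truth[v] if hap == 1 else 1 - truth[v]
            if rng.random() < 0.04:
                allele = 1 - allele
            rows.append((mol, v, int(allele)))
        mol += 1
    links = build_links(obs_frame(rows))
    variants = toy_variants(n)
    phased, _ = phase(variants, links, min_block_logodds=1.0)
    got = phased["orientation"].to_numpy()
    assert (got >= 0).all(), "all 16 variants should be phased"
    best_score, best = brute_force_best_orientation(n, links)
    Li, Lj = links["i"].to_numpy(), links["j"].to_numpy()
    score = int(np.where(got[Li] == got[Lj], links["n_cis"].to_numpy(),
                         links["n_trans"].to_numpy()).sum())
    assert score == best_score


def test_refinement_repairs_isolated_flip():
    """A variant whose direct links are individually below threshold but whose
    context is unambiguous gets corrected by the window sweep."""
    n = 8
    rows = []
    mol = 0
    for v in range(n - 1):  # strong cis chain
        for _ in range(4):
            rows.append((mol, v, 1))
            rows.append((mol, v + 1, 1))
            mol += 1
    # adversarial molecule pair flipping variant 4
    rows += [(mol, 3, 1), (mol, 4, 0)]
    links = build_links(obs_frame(rows))
    phased, _ = phase(toy_variants(n), links, min_block_logodds=1.0)
    o = phased["orientation"].to_numpy()
    assert len(set(o)) == 1  # all same orientation, flip repaired


def test_global_flip_leaves_concordance_unchanged():
    rng = np.random.default_rng(1)
    rows = [(m, v, int(rng.integers(0, 2)))
            for m in range(10) for v in sorted(rng.choice(6, 3, replace=False))]
    links = build_links(obs_frame(rows))
    Li, Lj = links["i"].to_numpy(), links["j"].to_numpy()
    n_cis, n_trans = links["n_cis"].to_numpy(), links["n_trans"].to_numpy()
    o = rng.integers(0, 2, 6)
    s1 = np.where(o[Li] == o[Lj], n_cis, n_trans).sum()
    s2 = np.where((1 - o)[Li] == (1 - o)[Lj], n_cis, n_trans).sum()
    assert s1 == s2


def test_phased_vcf_frame_conventions():
    variants = toy_variants(3)
    variants["orientation"] = [0, 1, -1]
    variants["phase_set"] = [0, 0, -1]
    frame = phased_vcf_frame(variants)
    assert list(frame["gt"]) == ["1|0", "0|1", "0/1"]
    assert frame["ps"].iloc[0] == 1  # 1-based phase set anchor
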