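"""Structural variant detection from Linked-Read barcode and coverage signals.

Two complementary detectors for large events:

* **Barcode overlap** — molecules spanning a rearrangement junction scatter
  their reads across the two joined loci, so the flanking windows share far
  more barcodes than chance.  Sharing is tested per distant window pair with a
  hypergeometric null on barcode presence/absence, corrected for multiple
  testing by Benjamini-Hochberg.  Detects deletions, duplications, inversions
  and translocations, but not terminal events.
* **Coverage segmentation** — recursive binary segmentation of windowed
  molecule (or read) depth on a log2 scale; segments deviating from the genome
  median call CNVs, including terminal ones.

A third, haplotype-resolved detector finds intermediate-size heterozygous
deletions as a depth drop on a single haplotype inside phase blocks (reads are
routed to haplotypes via barcode -> molecule -> phase-block vote).

Calls overlapping a segmental-duplication mask are demoted from PASS to
CANDIDATE.  Insertions are not called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from scipy.stats import hypergeom

DEFAULT_OVERLAP_WINDOW = 10_000
DEFAULT_COVERAGE_WINDOW = 1_000
DEFAULT_MIN_SEPARATION = 30_000
DEFAULT_ALPHA = 0.01

CALL_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "svtype", "size", "score",
                "haplotype", "filter", "source"]


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS)


@dataclass
class WindowBarcodeIndex:
    """Per-window barcode presence, tiled half-open across each chromosome."""

    window: int
    chroms: list[str]
    chrom_lengths: dict[str, int]
    n_windows: dict[str, int]
    offsets: dict[str, int]  # global index of each chromosome's first window
    matrix: sp.csr_matrix  # (total windows x barcodes), boolean presence
    #: distinct-molecule coverage count per same-chromosome window pair is
    #: derived from molecule window ranges stored here
    molecule_ranges: pd.DataFrame  # chrom, w0, w1, barcode (unique)
    n_total_barcodes: int

    def window_of(self, chrom: str, pos: int) -> int:
        return self.offsets[chrom] + pos // self.window


def build_barcode_index(molecules: pd.DataFrame, window: int = DEFAULT_OVERLAP_WINDOW,
                        chrom_lengths: dict[str, int] | None = None
                        ) -> WindowBarcodeIndex:
    """Index which barcodes have molecules overlapping each genomic window."""
    if window <= 0:
        raise ValueError("window must be positive")
    if chrom_lengths is None:
        chrom_lengths = {str(c): int(g["end"].max())
                         for c, g in molecules.groupby("chrom", observed=True)}
    chroms = list(chrom_lengths)
    n_windows = {c: max(1, -(-chrom_lengths[c] // window)) for c in chroms}
    offsets, off = {}, 0
    for c in chroms:
        offsets[c] = off
        off += n_windows[c]

    bc = molecules["barcode"].cat.codes.to_numpy().astype(np.int64)
    n_bc_cats = len(molecules["barcode"].cat.categories)
    chrom_arr = molecules["chrom"].astype(str).to_numpy()
    w0 = molecules["start"].to_numpy() // window
    w1 = np.maximum(molecules["end"].to_numpy() - 1, molecules["start"].to_numpy()) // window
    goff = np.array([offsets[c] for c in chrom_arr], dtype=np.int64)
    nwin = np.array([n_windows[c] for c in chrom_arr], dtype=np.int64)
    w1 = np.minimum(w1, nwin - 1)

    if len(molecules):
        span = (w1 - w0 + 1).astype(np.int64)
        rows = np.repeat(goff + w0, span)
        rows += (np.arange(span.sum(), dtype=np.int64)
                 - np.repeat(np.concatenate([[0], np.cumsum(span)[:-1]]), span))
        cols = np.repeat(bc, span)
        pairs = np.unique(np.stack([rows, cols], axis=1), axis=0)
        mat = sp.csr_matrix(
            (np.ones(len(pairs), dtype=np.int64), (pairs[:, 0], pairs[:, 1])),
            shape=(off, n_bc_cats))
    else:
        mat = sp.csr_matrix((off, n_bc_cats), dtype=np.int64)
    ranges = pd.DataFrame({"chrom": chrom_arr, "w0": w0, "w1": w1, "barcode": bc}
                          ).drop_duplicates()
    return WindowBarcodeIndex(window, chroms, chrom_lengths, n_windows, offsets,
                              mat, ranges, int(len(np.unique(bc))))


def benjamini_hochberg(pvalues: np.ndarray, alpha: float,
                       n_tests: int | None = None) -> np.ndarray:
    """Step-up BH procedure; returns a boolean rejection mask.

    ``n_tests`` allows the total test count to exceed ``len(pvalues)`` when
    the omitted tests all have p = 1 (untestable zero-overlap pairs).
    """
    p = np.asarray(pvalues, dtype=np.float64)
    m = len(p) if n_tests is None else int(n_tests)
    if m < len(p):
        raise ValueError("n_tests smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, len(p) + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(len(p), dtype=bool)
    if len(passed):
        reject[order[:passed[-1] + 1]] = True
    return reject


def _distinct_pair_counts(index: WindowBarcodeIndex, chrom: str) -> np.ndarray:
    """For every same-chromosome window pair (a, b): the number of barcodes
    counted in both windows *through a single contiguous molecule* covering the
    pair.  Subtracted from raw sharing so that long molecules do not mimic
    junctions at moderate separations."""
    nw = index.n_windows[chrom]
    r = index.molecule_ranges
    r = r[r["chrom"] == chrom]
    H = np.zeros((nw, nw), dtype=np.int64)
    np.add.at(H, (r["w0"].to_numpy(), r["w1"].to_numpy()), 1)
    # cover(a, b) = sum_{w0 <= a, w1 >= b} H[w0, w1]
    c1 = np.cumsum(H, axis=0)                     # over w0 <= a
    c2 = np.cumsum(c1[:, ::-1], axis=1)[:, ::-1]  # over w1 >= b
    return c2


def barcode_overlap_scan(index: WindowBarcodeIndex,
                         min_separation: int = DEFAULT_MIN_SEPARATION,
                         alpha: float = DEFAULT_ALPHA,
                         molecules: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scan distant window pairs for excess barcode sharing.

    For each pair of windows separated by more than ``min_separation`` on one
    chromosome (or on different chromosomes), the shared barcode count k is
    tested against a hypergeometric null P(X >= k | N, |bc(A)|, |bc(B)|);
    sharing attributable to a single molecule contiguously covering both
    windows is excluded from k first.  BH-significant pairs are clustered with
    their diagonal neighbours into one call per junction.  Event type is
    assigned from the molecule depth between same-chromosome breakends
    (depressed -> DEL, elevated -> DUP, unchanged -> INV); cross-chromosome
    junctions are translocations.
    """
    M = index.matrix
    K = np.asarray((M @ M.T).todense())
    n_per = np.asarray(M.sum(axis=1)).ravel()
    N = index.n_total_barcodes
    w = index.window

    pair_rows = []  # (global_a, global_b, k)
    n_tested = 0
    for ci, c1 in enumerate(index.chroms):
        o1, n1 = index.offsets[c1], index.n_windows[c1]
        # same-chromosome distant pairs
        sep_windows = min_separation // w + 1
        cover = _distinct_pair_counts(index, c1)
        a_idx, b_idx = np.triu_indices(n1, k=sep_windows)
        # separation between window intervals: b*w - (a*w + w) > min_separation
        sep_ok = (b_idx - a_idx - 1) * w > min_separation
        a_idx, b_idx = a_idx[sep_ok], b_idx[sep_ok]
        n_tested += len(a_idx)
        k = K[o1 + a_idx, o1 + b_idx] - cover[a_idx, b_idx]
        nz = k > 0
        for a, b, kk in zip(a_idx[nz], b_idx[nz], k[nz]):
            pair_rows.append((o1 + a, o1 + b, int(kk)))
        # cross-chromosome pairs
        for c2 in index.chroms[ci + 1:]:
            o2, n2 = index.offsets[c2], index.n_windows[c2]
            sub = K[o1:o1 + n1, o2:o2 + n2]
            n_tested += n1 * n2
            aa, bb = np.nonzero(sub)
            for a, b in zip(aa, bb):
                pair_rows.append((o1 + a, o2 + b, int(sub[a, b])))

    if not pair_rows:
        return _empty_calls()
    pairs = np.array(pair_rows, dtype=np.int64)
    k_arr = pairs[:, 2]
    nA = n_per[pairs[:, 0]]
    nB = n_per[pairs[:, 1]]
    pvals = hypergeom.sf(k_arr - 1, N, nA, nB)
    reject = benjamini_hochberg(pvals, alpha, n_tests=n_tested)
    sig = pairs[reject]
    sig_p = pvals[reject]
    if not len(sig):
        return _empty_calls()

    # cluster diagonally adjacent significant pairs into junction calls
    order = np.lexsort((sig[:, 1], sig[:, 0]))
    sig, sig_p = sig[order], sig_p[order]
    parent = list(range(len(sig)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    coords = {(int(a), int(b)): i for i, (a, b, _) in enumerate(sig)}
    for i, (a, b, _) in enumerate(sig):
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                jj = coords.get((int(a) + da, int(b) + db))
                if jj is not None:
                    ra, rb = find(i), find(jj)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)

    comp: dict[int, list[int]] = {}
    for i in range(len(sig)):
        comp.setdefault(find(i), []).append(i)

    glob_to_chrom = []
    for c in index.chroms:
        glob_to_chrom += [c] * index.n_windows[c]

    median_depth = None
    if molecules is not None and len(molecules):
        median_depth = _window_molecule_depth(molecules, index)

    rows = []
    for members in comp.values():
        best = max(members, key=lambda i: (sig[i, 2], -sig_p[i], -sig[i, 0]))
        ga, gb, k = sig[best]
        c1 = glob_to_chrom[ga]
        c2 = glob_to_chrom[gb]
        a_local = ga - index.offsets[c1]
        b_local = gb - index.offsets[c2]
        pos1 = int((a_local + 1) * w)  # junction just right of window a
        pos2 = int(b_local * w)        # junction just left of window b
        score = float(-np.log10(max(sig_p[best], 1e-300)))
        if c1 != c2:
            rows.append((c1, pos1, c2, pos2, "TRA", -1, score, -1, "PASS",
                         "barcode_overlap"))
            continue
        size = pos2 - pos1
        svtype = "INV"
        if median_depth is not None:
            depth, med = median_depth
            o1 = index.offsets[c1]
            between = depth[o1 + a_local + 1:o1 + b_local]
            ratio = float(np.mean(between)) / med if len(between) and med > 0 else 1.0
            if ratio < 0.75:
                svtype = "DEL"
            elif ratio > 1.25:
                svtype = "DUP"
        rows.append((c1, pos1, c2, pos2, svtype, size, score, -1, "PASS",
                     "barcode_overlap"))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom1", "pos1"]).reset_index(drop=True)


def _window_molecule_depth(molecules: pd.DataFrame, index: WindowBarcodeIndex
                           ) -> tuple[np.ndarray, float]:
    """Mean molecule depth per window (global window indexing) and its genome
    median."""
    w = index.window
    total = sum(index.n_windows.values())
    depth = np.zeros(total, dtype=np.float64)
    for chrom, grp in molecules.groupby("chrom", observed=True):
        chrom = str(chrom)
        if chrom not in index.offsets:
            continue
        L = index.n_windows[chrom] * w
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, np.clip(grp["start"].to_numpy(), 0, L), 1)
        np.add.at(diff, np.clip(grp["end"].to_numpy(), 0, L), -1)
        per_base = np.cumsum(diff[:-1])
        o = index.offsets[chrom]
        depth[o:o + index.n_windows[chrom]] = per_base.reshape(-1, w).mean(axis=1)
    return depth, float(np.median(depth))


# -- coverage segmentation ----------------------------------------------------

def windowed_depth(intervals: pd.DataFrame, chrom_lengths: dict[str, int],
                   window: int) -> dict[str, np.ndarray]:
    """Mean per-base depth of a set of intervals in tiling windows."""
    out = {}
    for chrom, L in chrom_lengths.items():
        nw = -(-L // window)
        diff = np.zeros(nw * window + 1, dtype=np.int64)
        grp = intervals[intervals["chrom"].astype(str) == chrom]
        if len(grp):
            np.add.at(diff, np.clip(grp["start"].to_numpy(), 0, nw * window), 1)
            np.add.at(diff, np.clip(grp["end"].to_numpy(), 0, nw * window), -1)
        per_base = np.cumsum(diff[:-1])
        out[chrom] = per_base.reshape(-1, window).mean(axis=1)
    return out


def best_split(x: np.ndarray) -> tuple[int, float]:
    """Least-squares single changepoint of a signal: the split index t
    (1 <= t < len(x)) minimizing SSE(x[:t]) + SSE(x[t:]), and the SSE gain
    over the unsplit segment.  Ties take the smallest t."""
    n = len(x)
    if n < 2:
        raise ValueError("need at least two points to split")
    c = np.cumsum(x)
    c2 = np.cumsum(x ** 2)
    t = np.arange(1, n)
    left_sse = c2[t - 1] - c[t - 1] ** 2 / t
    right_sum = c[-1] - c[t - 1]
    right_sse = (c2[-1] - c2[t - 1]) - right_sum ** 2 / (n - t)
    total_sse = c2[-1] - c[-1] ** 2 / n
    gains = total_sse - (left_sse + right_sse)
    best = int(np.argmax(gains))
    return int(t[best]), float(gains[best])


def _segment(x: np.ndarray, lo: int, hi: int, min_gain: float,
             out: list[tuple[int, int]]) -> None:
    if hi - lo < 2:
        out.append((lo, hi))
        return
    t, gain = best_split(x[lo:hi])
    if gain < min_gain:
        out.append((lo, hi))
        return
    t += lo
    _segment(x, lo, t, min_gain, out)
    _segment(x, t, hi, min_gain, out)


def _noise_variance(x: np.ndarray) -> float:
    """Robust per-window noise variance from successive differences (median
    absolute difference scaled for normality, halved because differencing
    doubles the variance); insensitive to step changes."""
    if len(x) < 3:
        return float(np.var(x))
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float((1.4826 * mad) ** 2 / 2.0)


def _merge_segments(x: np.ndarray, segs: list[tuple[int, int]],
                    margin: float) -> list[tuple[int, int]]:
    """Re-join adjacent segments whose means differ by less than ``margin``.

    Depth windows are autocorrelated when molecules span many windows, so the
    difference-based noise floor over-segments smooth signals; pruning by mean
    similarity restores the true changepoints."""
    segs = sorted(segs)
    merged = True
    while merged and len(segs) > 1:
        merged = False
        out = [segs[0]]
        for lo, hi in segs[1:]:
            plo, phi = out[-1]
            if abs(x[plo:phi].mean() - x[lo:hi].mean()) < margin:
                out[-1] = (plo, hi)
                merged = True
            else:
                out.append((lo, hi))
        segs = out
    return segs


def coverage_segmentation(intervals: pd.DataFrame,
                          chrom_lengths: dict[str, int],
                          window: int = DEFAULT_COVERAGE_WINDOW,
                          min_size: int = 10_000,
                          log2_threshold: float = 0.4,
                          gain_factor: float = 3.0,
                          merge_margin: float = 0.3) -> pd.DataFrame:
    """CNV calls from depth deviations.

    Windowed depth (from molecules, or reads at low coverage) is expressed as
    log2(depth / genome median) and recursively split at least-squares
    changepoints as long as the SSE gain of the best split exceeds
    ``gain_factor * sigma^2 * log n`` (sigma estimated from successive window
    differences, a BIC-style floor); adjacent segments whose means differ by
    less than ``merge_margin`` are then re-joined, pruning spurious splits of
    smooth autocorrelated molecule depth.  Segments of at least ``min_size``
    with |log2 ratio| >= ``log2_threshold`` are reported as DEL (negative) or
    DUP (positive); terminal segments are eligible, covering telomeric events
    invisible to the barcode-overlap scan.
    """
    depth = windowed_depth(intervals, chrom_lengths, window)
    all_windows = np.concatenate(list(depth.values()))
    med = np.median(all_windows)
    if med <= 0:
        raise ValueError("zero median depth; cannot normalize")
    rows = []
    for chrom, d in depth.items():
        x = np.log2(np.maximum(d, 1e-3) / med)
        min_gain = gain_factor * _noise_variance(x) * np.log(max(len(x), 2))
        segs: list[tuple[int, int]] = []
        _segment(x, 0, len(x), min_gain, segs)
        segs = _merge_segments(x, segs, merge_margin)
        for lo, hi in segs:
            mean = float(x[lo:hi].mean())
            size = (hi - lo) * window
            if abs(mean) >= log2_threshold and size >= min_size:
                svtype = "DEL" if mean < 0 else "DUP"
                rows.append((chrom, lo * window, chrom, min(hi * window, chrom_lengths[chrom]),
                             svtype, size, abs(mean), -1, "PASS", "coverage"))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom1", "pos1"]).reset_index(drop=True)


# -- haplotype-resolved deletions ---------------------------------------------

def phased_coverage_deletions(aln: pd.DataFrame,
                              molecule_assignment: np.ndarray,
                              molecule_haplotypes: pd.DataFrame,
                              blocks,
                              chrom_lengths: dict[str, int],
                              window: int = 500,
                              size_range: tuple[int, int] = (50, 30_000),
                              drop_frac: float = 0.2) -> pd.DataFrame:
    """Heterozygous deletions from single-haplotype depth drops.

    Inside phase blocks, reads are routed to block haplotypes via their
    molecule's phase vote; windows where one haplotype's depth falls below
    ``drop_frac`` of that haplotype's block-wide median while the other stays
    at least half of its own median become DEL calls labelled with the block
    haplotype.  Outside blocks, a total-depth drop to about half the genome
    median yields an unlabelled candidate.
    """
    hap_of_mol = dict(zip(molecule_haplotypes["molecule_id"],
                          molecule_haplotypes["haplotype"]))
    mol = molecule_assignment
    hap = np.array([hap_of_mol.get(int(m), -1) for m in mol], dtype=np.int64)
    chrom_arr = aln["chrom"].astype(str).to_numpy()
    start = aln["start"].to_numpy()
    end = aln["end"].to_numpy()

    depths: dict[str, np.ndarray] = {}
    for chrom, L in chrom_lengths.items():
        nw = -(-L // window)
        per_hap = np.zeros((3, nw), dtype=np.float64)  # hap0, hap1, unassigned
        sel = chrom_arr == chrom
        for h, row in ((0, 0), (1, 1), (-1, 2)):
            s2 = sel & (hap == h)
            if not s2.any():
                continue
            diff = np.zeros(nw * window + 1, dtype=np.int64)
            np.add.at(diff, np.clip(start[s2], 0, nw * window), 1)
            np.add.at(diff, np.clip(end[s2], 0, nw * window), -1)
            per_hap[row] = np.cumsum(diff[:-1]).reshape(-1, window).mean(axis=1)
        depths[chrom] = per_hap

    rows = []
    covered = {c: np.zeros(len(depths[c][0]), dtype=bool) for c in chrom_lengths}
    for blk in blocks:
        if blk.n_variants < 2 or blk.chrom not in depths:
            continue
        nw = len(depths[blk.chrom][0])
        w_lo, w_hi = blk.start // window, min(blk.end // window + 1, nw)
        if w_hi - w_lo < 3:
            continue
        covered[blk.chrom][w_lo:w_hi] = True
        d = depths[blk.chrom][:2, w_lo:w_hi]
        med = np.median(d, axis=1)
        if np.any(med <= 0):
            continue
        for h in (0, 1):
            o = 1 - h
            low = (d[h] < drop_frac * med[h]) & (d[o] >= 0.5 * med[o])
            for s, e in _runs(low):
                size = (e - s) * window
                if size_range[0] <= size <= size_range[1]:
                    p1 = (w_lo + s) * window
                    p2 = (w_lo + e) * window
                    score = 1.0 - float(d[h, s:e].mean()) / med[h]
                    rows.append((blk.chrom, p1, blk.chrom, p2, "DEL", size,
                                 score, h, "PASS", "phased_coverage"))
    # outside phase blocks: total-depth drop to ~0.5x
    totals = {c: depths[c].sum(axis=0) for c in depths}
    gmed = np.median(np.concatenate([t for t in totals.values()]))
    if gmed > 0:
        for chrom, t in totals.items():
            low = (t > 0.3 * gmed) & (t < 0.7 * gmed) & ~covered[chrom]
            if len(low) > 2:  # read-level coverage tapers at chromosome ends
                low[0] = low[-1] = False
            for s, e in _runs(low):
                size = (e - s) * window
                if size_range[0] <= size <= size_range[1]:
                    score = 1.0 - float(t[s:e].mean()) / gmed
                    rows.append((chrom, s * window, chrom, e * window, "DEL",
                                 size, score, -1, "PASS", "phased_coverage"))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom1", "pos1"]).reset_index(drop=True)


def _runs(mask: np.ndarray):
    """(start, end) index pairs of the True runs of a boolean mask."""
    if not len(mask):
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


# -- filtering and merging ----------------------------------------------------

def filter_calls(calls: pd.DataFrame, segdup_mask: pd.DataFrame) -> pd.DataFrame:
    """Demote calls with a breakend inside a segmental-duplication interval to
    CANDIDATE (mask intervals are half-open; a breakend at the end coordinate
    is outside)."""
    trees: dict[str, IntervalTree] = {}
    for row in segdup_mask.itertuples():
        trees.setdefault(str(row.chrom), IntervalTree()).addi(row.start, row.end)
    out = calls.copy()
    flt = []
    for row in out.itertuples():
        hit = (str(row.chrom1) in trees and trees[str(row.chrom1)][row.pos1]) or \
              (str(row.chrom2) in trees and trees[str(row.chrom2)][row.pos2])
        flt.append("CANDIDATE" if hit else "PASS")
    out["filter"] = flt
    return out


def merge_call_sets(primary: pd.DataFrame, secondary: pd.DataFrame,
                    reciprocal: float = 0.5) -> pd.DataFrame:
    """Union of two call streams, dropping secondary interval calls that
    duplicate a primary call of the same type at >= ``reciprocal`` reciprocal
    overlap."""
    keep = []
    for row in secondary.itertuples():
        if row.svtype == "TRA":
            keep.append(True)
            continue
        dup = False
        for p in primary.itertuples():
            if p.svtype != row.svtype or p.chrom1 != row.chrom1 or p.svtype == "TRA":
                continue
            ov = min(p.pos2, row.pos2) - max(p.pos1, row.pos1)
            if ov <= 0:
                continue
            if (ov / max(p.pos2 - p.pos1, 1) >= reciprocal
                    and ov / max(row.pos2 - row.pos1, 1) >= reciprocal):
                dup = True
                break
        keep.append(not dup)
    kept = secondary[np.array(keep, dtype=bool)] if len(secondary) else secondary
    frames = [f for f in (primary, kept) if len(f)]
    if not frames:
        return _empty_calls()
    merged = pd.concat(frames, ignore_index=True)
    return merged.sort_values(["chrom1", "pos1"]).reset_index(drop=True)
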