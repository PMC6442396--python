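"""Evaluation metrics: phasing accuracy, coverage metrics, N50, and the SV
benchmarking harness.

Phasing errors are decomposed per phased heterozygous variant into
*short switches* (a small isolated stretch of variants flipped relative to
truth, bracketed by two nearby switch points) and *long switches* (a single
switch point after which the flip persists).  All phasing metrics are invariant
to a global flip of any block, since block haplotype labels are arbitrary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ISOLATION_SPAN = 5  # max flipped variants between paired switch points


@dataclass
class SwitchReport:
    """Switch-error decomposition of called phasing against truth."""

    short_switch_rate: float
    long_switch_rate: float
    within_block_correct_rate: float
    gene_phasing_correct_rate: float
    n_phased: int
    n_short: int
    n_long: int


@dataclass
class EvalReport:
    """Container for the evaluation metrics of one simulated run."""

    phase_block_n50: float
    heterozygosity: float
    switch: SwitchReport | None = None
    gene_finishing: dict[str, float] = field(default_factory=dict)
    coverage_histogram: dict[int, int] = field(default_factory=dict)
    unique_gain: tuple[int, int, int] | None = None
    sv_precision: float | None = None
    sv_recall: float | None = None

    def to_dict(self) -> dict:
        d = {
            "phase_block_n50": self.phase_block_n50,
            "heterozygosity": self.heterozygosity,
            "gene_finishing": dict(sorted(self.gene_finishing.items())),
            "coverage_histogram": {int(k): int(v) for k, v in
                                   sorted(self.coverage_histogram.items())},
            "unique_gain": self.unique_gain,
            "sv_precision": self.sv_precision,
            "sv_recall": self.sv_recall,
        }
        if self.switch is not None:
            d["switch"] = vars(self.switch)
        return d


def n50(lengths) -> int:
    """Largest L such that elements of length >= L sum to at least half the
    total length."""
    arr = np.sort(np.asarray(lengths))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty set")
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, csum[-1] / 2.0)])


def phase_block_n50(blocks) -> int:
    """N50 of phase-block spans; single-variant blocks are excluded."""
    spans = [b.span for b in blocks if b.n_variants > 1]
    if not spans:
        return 0
    return n50(spans)


# -- switch errors ------------------------------------------------------------

def _classify_switch_points(points: list[int], isolation_span: int
                            ) -> tuple[int, int]:
    """Greedy left-to-right pairing of switch points.

    Two consecutive switch points enclosing at most ``isolation_span``
    variants form one short switch; an unpaired point is a long switch.
    ``points[k]`` is the index of the first variant after the k-th sign change.
    """
    n_short = n_long = 0
    k = 0
    while k < len(points):
        if k + 1 < len(points) and points[k + 1] - points[k] <= isolation_span:
            n_short += 1
            k += 2
        else:
            n_long += 1
            k += 1
    return n_short, n_long


def switch_errors(called: pd.DataFrame, truth: pd.DataFrame,
                  isolation_span: int = DEFAULT_ISOLATION_SPAN,
                  genes: pd.DataFrame | None = None,
                  on_mismatch: str = "error") -> SwitchReport:
    """Compare called phasing against truth.

    Parameters
    ----------
    called : DataFrame
        Phased het variants with columns chrom, pos, orientation, phase_set
        (orientation/phase_set == -1 for unphased variants, which are excluded
        from all denominators).
    truth : DataFrame
        Truth het variants with chrom, pos, orientation (fully phased).
    isolation_span : int
        Maximum number of enclosed variants for two switch points to count as
        one short switch.
    genes : DataFrame, optional
        BED-like gene intervals (chrom, start, end, name) for the gene-level
        phasing correctness rate.
    on_mismatch : str
        ``error`` (default): raise when the called variant set is not a subset
        of the truth positions; ``intersect``: silently restrict to common
        sites.
    """
    c = called[called["phase_set"] >= 0][["chrom", "pos", "orientation",
                                          "phase_set"]].copy()
    t = truth[["chrom", "pos", "orientation"]].rename(
        columns={"orientation": "truth_orientation"})
    merged = c.merge(t, on=["chrom", "pos"], how="left")
    missing = merged["truth_orientation"].isna()
    if missing.any():
        if on_mismatch == "error":
            bad = merged.loc[missing, ["chrom", "pos"]].head(20)
            raise ValueError(
                "called variants absent from truth set:\n" + bad.to_string())
        merged = merged[~missing]
    merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)

    n_phased = len(merged)
    n_short = n_long = 0
    block_correct = []
    for (_, _), grp in merged.groupby(["chrom", "phase_set"], sort=True):
        agree = (grp["orientation"].to_numpy()
                 == grp["truth_orientation"].to_numpy()).astype(np.int8)
        if len(agree) < 2:
            continue
        changes = np.flatnonzero(np.diff(agree) != 0) + 1
        s, l = _classify_switch_points(list(changes), isolation_span)
        n_short += s
        n_long += l
        frac = agree.mean()
        block_correct.append(max(frac, 1.0 - frac))

    gene_rates = []
    if genes is not None and len(genes):
        for g in genes.itertuples():
            sel = merged[(merged["chrom"] == g.chrom)
                         & (merged["pos"] >= g.start) & (merged["pos"] < g.end)]
            if len(sel) < 2:
                continue
            top_ps = sel["phase_set"].value_counts().index[0]
            sel = sel[sel["phase_set"] == top_ps]
            if len(sel) < 2:
                continue
            frac = (sel["orientation"] == sel["truth_orientation"]).mean()
            gene_rates.append(max(frac, 1.0 - frac))

    return SwitchReport(
        short_switch_rate=n_short / n_phased if n_phased else 0.0,
        long_switch_rate=n_long / n_phased if n_phased else 0.0,
        within_block_correct_rate=float(np.mean(block_correct)) if block_correct else 1.0,
        gene_phasing_correct_rate=float(np.mean(gene_rates)) if gene_rates else 1.0,
        n_phased=n_phased, n_short=n_short, n_long=n_long)


# -- coverage metrics ---------------------------------------------------------

def coverage_track(aln: pd.DataFrame, chrom_lengths: dict[str, int],
                   min_mapq: int = 30) -> dict[str, np.ndarray]:
    """Exact per-base read depth from MapQ-filtered alignments."""
    work = aln[aln["mapq"] >= min_mapq]
    chrom_arr = work["chrom"].astype(str).to_numpy()
    out = {}
    for chrom, L in chrom_lengths.items():
        diff = np.zeros(L + 1, dtype=np.int64)
        sel = chrom_arr == chrom
        if sel.any():
            np.add.at(diff, np.clip(work["start"].to_numpy()[sel], 0, L), 1)
            np.add.at(diff, np.clip(work["end"].to_numpy()[sel], 0, L), -1)
        out[chrom] = np.cumsum(diff[:-1])
    return out


def coverage_evenness(track: dict[str, np.ndarray]) -> dict[int, int]:
    """Histogram depth -> number of bases at that depth; counts sum to the
    genome length."""
    hist: dict[int, int] = {}
    for depth in track.values():
        counts = np.bincount(depth.astype(np.int64))
        for d, c in enumerate(counts):
            if c:
                hist[int(d)] = hist.get(int(d), 0) + int(c)
    return hist


def gene_finishing(track: dict[str, np.ndarray], exons: pd.DataFrame,
                   min_depth: int = 10) -> dict[str, float]:
    """Per-gene fraction of exonic bases covered at >= ``min_depth``.

    ``exons`` is BED-like with a gene name column; exons of one gene are
    aggregated.  Genes with zero exonic bases are skipped with a warning.
    """
    out: dict[str, float] = {}
    for gene, grp in exons.groupby("name", sort=True):
        total = covered = 0
        for row in grp.itertuples():
            if str(row.chrom) not in track:
                continue
            depth = track[str(row.chrom)][row.start:row.end]
            total += len(depth)
            covered += int((depth >= min_depth).sum())
        if total == 0:
            warnings.warn(f"gene {gene} has zero exonic bases; skipped")
            continue
        out[str(gene)] = covered / total
    return out


def unique_coverage_gain(track_a: dict[str, np.ndarray],
                         track_b: dict[str, np.ndarray],
                         min_depth: int = 5) -> tuple[int, int, int]:
    """Bases covered >= ``min_depth`` in exactly one of two tracks:
    (a-only, b-only, net = a_only - b_only)."""
    if set(track_a) != set(track_b):
        raise ValueError("tracks cover different chromosomes")
    a_only = b_only = 0
    for chrom in track_a:
        da, db = track_a[chrom], track_b[chrom]
        if len(da) != len(db):
            raise ValueError(f"track length mismatch on {chrom}")
        ma, mb = da >= min_depth, db >= min_depth
        a_only += int((ma & ~mb).sum())
        b_only += int((mb & ~ma).sum())
    return a_only, b_only, a_only - b_only


# -- SV benchmarking ----------------------------------------------------------

def _reciprocal_overlap(s1, e1, s2, e2) -> float:
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1), ov / (e2 - s2))


def merge_breakpoint_clusters(calls: pd.DataFrame, distance: int = 50
                              ) -> pd.DataFrame:
    """Transitive-closure merging of interval calls whose breakpoints are both
    within ``distance`` bp (SURVIVOR-style); merged calls take the member
    union interval and the best score."""
    iv = calls[calls["svtype"] != "TRA"].reset_index(drop=True)
    tra = calls[calls["svtype"] == "TRA"]
    if not len(iv):
        return calls.reset_index(drop=True)
    parent = list(range(len(iv)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(iv)):
        for j in range(i + 1, len(iv)):
            if iv.at[j, "pos1"] - iv.at[i, "pos1"] > distance:
                break
            if (iv.at[i, "chrom1"] == iv.at[j, "chrom1"]
                    and abs(iv.at[i, "pos1"] - iv.at[j, "pos1"]) <= distance
                    and abs(iv.at[i, "pos2"] - iv.at[j, "pos2"]) <= distance
                    and iv.at[i, "svtype"] == iv.at[j, "svtype"]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    rows = []
    for root in sorted({find(i) for i in range(len(iv))}):
        members = iv[[find(i) == root for i in range(len(iv))]]
        row = members.iloc[0].copy()
        row["pos1"] = int(members["pos1"].min())
        row["pos2"] = int(members["pos2"].max())
        row["size"] = row["pos2"] - row["pos1"]
        row["score"] = float(members["score"].max())
        rows.append(row)
    merged = pd.DataFrame(rows)
    out = pd.concat([merged, tra], ignore_index=True)
    return out.sort_values(["chrom1", "pos1"]).reset_index(drop=True)


def sv_compare(calls: pd.DataFrame, truth: pd.DataFrame, mode: str = "large",
               reciprocal: float = 0.5, merge_distance: int = 50,
               breakend_tol: int = 10_000
               ) -> tuple[float, float, list[tuple[int, int]]]:
    """Benchmark SV calls against a truth set.

    mode="large": interval calls match at >= ``reciprocal`` reciprocal overlap
    (one-to-one, greedy by decreasing overlap); translocations match when both
    breakends agree within ``breakend_tol`` on the same chromosome pair.
    mode="intermediate": calls are first merged by transitive closure of
    breakpoint distance <= ``merge_distance``; a merged call matches a truth
    event when both breakpoints agree within ``merge_distance``.

    Returns (precision, recall, matched (call_idx, truth_idx) pairs) with
    indices into the (merged) call and truth frames.
    """
    calls = calls.sort_values(["chrom1", "pos1"]).reset_index(drop=True)
    truth = truth.sort_values(["chrom1", "pos1"]).reset_index(drop=True)
    if mode == "intermediate":
        calls = merge_breakpoint_clusters(calls, merge_distance)

    candidates = []  # (sort key, call idx, truth idx)
    for ci, c in enumerate(calls.itertuples()):
        for ti, t in enumerate(truth.itertuples()):
            if (c.svtype == "TRA") != (t.svtype == "TRA"):
                continue
            if c.svtype == "TRA":
                ends_c = {(c.chrom1, c.pos1), (c.chrom2, c.pos2)}
                ok = all(any(ce[0] == te[0] and abs(ce[1] - te[1]) <= breakend_tol
                             for ce in ends_c)
                         for te in [(t.chrom1, t.pos1), (t.chrom2, t.pos2)])
                if ok:
                    candidates.append((1.0, ci, ti))
                continue
            if c.chrom1 != t.chrom1:
                continue
            if mode == "intermediate":
                if (abs(c.pos1 - t.pos1) <= merge_distance
                        and abs(c.pos2 - t.pos2) <= merge_distance):
                    candidates.append((1.0, ci, ti))
                continue
            ro = _reciprocal_overlap(c.pos1, c.pos2, t.pos1, t.pos2)
            if ro >= reciprocal:
                candidates.append((ro, ci, ti))

    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches.append((ci, ti))
    precision = len(matches) / len(calls) if len(calls) else 1.0
    recall = len(matches) / len(truth) if len(truth) else 1.0
    return precision, recall, matches


def heterozygosity(het_variants: pd.DataFrame | int,
                   reference: dict[str, bytes]) -> float:
    """Heterozygosity: called het sites divided by non-N reference bases."""
    n_het = het_variants if isinstance(het_variants, int) else len(het_variants)
    non_n = sum(len(seq) - seq.upper().count(b"N") for seq in reference.values())
    if non_n == 0:
        raise ValueError("reference has no non-N bases")
    return n_het / non_n
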