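"""Diploid phasing from molecule-level allele observations.

Heterozygous SNVs are called by a minimal pileup genotyper, each read
contributes allele observations at the het sites it overlaps, observations are
grouped by inferred molecule, and molecules spanning consecutive het sites
provide cis/trans link evidence.  Phase blocks are built by a greedy
parity-tracking union-find over links in order of decreasing evidence, followed
by a windowed exhaustive refinement sweep that repairs isolated orientation
flips ("short switches").  Links weaker than ``min_block_logodds`` never join
variants, so weak junctions become block boundaries.

Orientation convention: ``orientation[i]`` is the haplotype (0 or 1) carrying
the alternate allele of variant ``i``, defined up to a global flip per block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_EPSILON = 0.02  # assumed allele-observation error rate
#: per-observation link weight, log10((1 - eps) / eps)
DEFAULT_LINK_WEIGHT = math.log10((1 - DEFAULT_EPSILON) / DEFAULT_EPSILON)
#: two concordant molecules of evidence required to join a block
DEFAULT_MIN_BLOCK_LOGODDS = 2 * DEFAULT_LINK_WEIGHT
REFINE_WINDOW = 5

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class PhaseBlock:
    """A maximal run of het variants phased relative to each other."""

    phase_set: int  # position of the first member variant (0-based)
    chrom: str
    start: int
    end: int
    variant_indices: np.ndarray
    orientations: np.ndarray  # per member; haplotype carrying the alt allele

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)

    @property
    def span(self) -> int:
        return self.end - self.start


# -- het variant calling ------------------------------------------------------

def call_het_variants(aln: pd.DataFrame, reference: dict[str, bytes],
                      min_depth: int = 8, min_allele_frac: float = 0.15,
                      min_mapq: int = 30) -> pd.DataFrame:
    """Minimal diploid pileup SNV genotyper.

    A site is called heterozygous when both the reference allele and one
    alternate allele are each seen in at least ``min_allele_frac`` of reads at
    depth >= ``min_depth``.  The floor is set below the naive binomial scale
    because Linked-Read depth is molecule-clustered: reads arrive in bursts
    from few molecules per haplotype, so local haplotype imbalance is
    overdispersed relative to coin-flip sampling.  At 0.15 a false het needs
    several identical errors at one site (negligible at ~1e-3 error rates)
    while genuinely imbalanced het sites are retained.  Deterministic.
    """
    work = aln[aln["mapq"] >= min_mapq]
    chrom_cat = pd.Categorical(work["chrom"])
    rows = []
    for ci, chrom in enumerate(chrom_cat.categories):
        if chrom not in reference:
            continue
        L = len(reference[chrom])
        sel = np.flatnonzero(chrom_cat.codes == ci)
        counts = np.zeros(4 * L, dtype=np.int64)
        starts = work["start"].to_numpy()[sel]
        seqs = work["seq"].to_numpy()[sel]
        chunk = 200_000
        for lo in range(0, len(sel), chunk):
            hi = min(lo + chunk, len(sel))
            blob = b"".join(seqs[lo:hi])
            lens = np.array([len(s) for s in seqs[lo:hi]], dtype=np.int64)
            offs = np.arange(lens.sum(), dtype=np.int64)
            offs -= np.repeat(np.concatenate([[0], np.cumsum(lens)[:-1]]), lens)
            pos = np.repeat(starts[lo:hi], lens) + offs
            code = _CODE[np.frombuffer(blob, dtype=np.uint8)]
            ok = code < 4
            counts += np.bincount(pos[ok] * 4 + code[ok], minlength=4 * L)
        cmat = counts.reshape(L, 4)
        depth = cmat.sum(axis=1)
        refcode = _CODE[np.frombuffer(reference[chrom], dtype=np.uint8)]
        valid = (depth >= min_depth) & (refcode < 4)
        pos_idx = np.flatnonzero(valid)
        if not len(pos_idx):
            continue
        sub = cmat[pos_idx]
        rc = refcode[pos_idx]
        n_ref = sub[np.arange(len(pos_idx)), rc]
        alt_counts = sub.copy()
        alt_counts[np.arange(len(pos_idx)), rc] = -1
        ac = alt_counts.argmax(axis=1)
        n_alt = alt_counts[np.arange(len(pos_idx)), ac]
        d = depth[pos_idx]
        het = (n_ref >= min_allele_frac * d) & (n_alt >= min_allele_frac * d) & (n_alt > 0)
        for p, r, a, nr, na, dd in zip(pos_idx[het], rc[het], ac[het],
                                       n_ref[het], n_alt[het], d[het]):
            rows.append((chrom, int(p), "ACGT"[r], "ACGT"[a], int(nr), int(na),
                         int(dd)))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                      "n_ref", "n_alt", "depth"])
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


# -- allele observations ------------------------------------------------------

def extract_observations(aln: pd.DataFrame, variants: pd.DataFrame,
                         molecule_assignment: np.ndarray | None = None,
                         min_mapq: int = 30) -> pd.DataFrame:
    """One allele observation per (read, overlapped het site).

    Bases matching neither the ref nor the alt allele are dropped.  Returns a
    DataFrame with columns var_idx (index into ``variants``), allele (0/1),
    barcode (category code), molecule_id (-1 when no assignment given).
    """
    if molecule_assignment is None:
        molecule_assignment = np.full(len(aln), -1, dtype=np.int64)
    mask = (aln["mapq"] >= min_mapq).to_numpy()
    chrom_cat = pd.Categorical(aln["chrom"])
    out = []
    for ci, chrom in enumerate(chrom_cat.categories):
        vsub = variants[variants["chrom"] == chrom]
        if not len(vsub):
            continue
        vpos = vsub["pos"].to_numpy()
        vidx = vsub.index.to_numpy()
        vref = np.frombuffer("".join(vsub["ref"]).encode(), dtype=np.uint8)
        valt = np.frombuffer("".join(vsub["alt"]).encode(), dtype=np.uint8)
        sel = np.flatnonzero((chrom_cat.codes == ci) & mask)
        if not len(sel):
            continue
        starts = aln["start"].to_numpy()[sel]
        ends = aln["end"].to_numpy()[sel]
        lo = np.searchsorted(vpos, starts, side="left")
        hi = np.searchsorted(vpos, ends, side="left")
        cnt = hi - lo
        nz = cnt > 0
        sel, starts, lo, cnt = sel[nz], starts[nz], lo[nz], cnt[nz]
        if not len(cnt):
            continue
        rep = np.repeat(np.arange(len(sel)), cnt)
        local = np.arange(cnt.sum(), dtype=np.int64)
        local -= np.repeat(np.concatenate([[0], np.cumsum(cnt)[:-1]]), cnt)
        vi = lo[rep] + local
        offs = vpos[vi] - starts[rep]
        seqs = aln["seq"].to_numpy()[sel]
        bases = np.frombuffer(
            bytes(bytearray(seqs[r][o] for r, o in zip(rep, offs))),
            dtype=np.uint8)
        is_ref = bases == vref[vi]
        is_alt = bases == valt[vi]
        keep = is_ref | is_alt
        out.append(pd.DataFrame({
            "var_idx": vidx[vi[keep]],
            "allele": is_alt[keep].astype(np.int8),
            "barcode": aln["barcode"].cat.codes.to_numpy()[sel][rep[keep]],
            "molecule_id": molecule_assignment[sel][rep[keep]],
            "row": sel[rep[keep]],  # positional index of the source alignment
        }))
    if not out:
        return pd.DataFrame(columns=["var_idx", "allele", "barcode",
                                     "molecule_id", "row"])
    return pd.concat(out, ignore_index=True)


# -- link evidence ------------------------------------------------------------

def build_links(observations: pd.DataFrame,
                weight: float = DEFAULT_LINK_WEIGHT) -> pd.DataFrame:
    """Cis/trans link evidence between het sites co-observed on a molecule.

    For each molecule and each adjacent pair of het sites it observes, n_cis is
    incremented when the alleles are equal (alt with alt / ref with ref) and
    n_trans otherwise; log_odds = (n_cis - n_trans) * weight.  Observations not
    assigned to a molecule (molecule_id == -1) are ignored.
    """
    obs = observations[observations["molecule_id"] >= 0]
    if not len(obs):
        return pd.DataFrame(columns=["i", "j", "n_cis", "n_trans", "log_odds"])
    # collapse duplicate reads of one molecule at one site by consensus;
    # drop sites where a molecule's reads disagree evenly
    g = (obs.groupby(["molecule_id", "var_idx"], sort=True)["allele"]
         .mean().reset_index())
    g = g[g["allele"] != 0.5]
    g["allele"] = (g["allele"] > 0.5).astype(np.int8)
    mol = g["molecule_id"].to_numpy()
    var = g["var_idx"].to_numpy()
    allele = g["allele"].to_numpy()
    same = mol[1:] == mol[:-1]
    i = var[:-1][same]
    j = var[1:][same]
    cis = (allele[:-1][same] == allele[1:][same])
    links = (pd.DataFrame({"i": i, "j": j, "cis": cis})
             .groupby(["i", "j"], sort=True)["cis"]
             .agg(n_cis="sum", n_trans=lambda s: int((~s).sum()))
             .reset_index())
    links["n_cis"] = links["n_cis"].astype(np.int64)
    links["n_trans"] = links["n_trans"].astype(np.int64)
    links["log_odds"] = (links["n_cis"] - links["n_trans"]) * weight
    return links


# -- phasing ------------------------------------------------------------------

class _ParityUnionFind:
    """Union-find tracking orientation parity relative to the root."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.rank = np.zeros(n, dtype=np.int8)
        self.parity = np.zeros(n, dtype=np.int8)

    def find(self, x: int) -> tuple[int, int]:
        root, parity = x, 0
        while self.parent[root] != root:
            parity ^= self.parity[root]
            root = self.parent[root]
        # path compression
        cur, cp = x, parity
        while self.parent[cur] != root:
            nxt, np_ = self.parent[cur], self.parity[cur]
            self.parent[cur], self.parity[cur] = root, cp
            cur, cp = nxt, cp ^ np_
        return root, parity

    def union(self, a: int, b: int, rel: int) -> None:
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
            pa, pb = pb, pa
        self.parent[rb] = ra
        self.parity[rb] = pa ^ pb ^ rel
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def _concordance(orient: dict[int, int], links: pd.DataFrame) -> float:
    """Total molecule concordance of an orientation assignment: each link
    contributes n_cis when its endpoints share orientation, n_trans otherwise."""
    total = 0
    for i, j, n_cis, n_trans in links[["i", "j", "n_cis", "n_trans"]].itertuples(index=False):
        if i in orient and j in orient:
            total += n_cis if orient[i] == orient[j] else n_trans
    return total


def phase(variants: pd.DataFrame, links: pd.DataFrame,
          min_block_logodds: float = DEFAULT_MIN_BLOCK_LOGODDS,
          refine_window: int = REFINE_WINDOW,
          ) -> tuple[pd.DataFrame, list[PhaseBlock]]:
    """Assemble phase blocks from link evidence.

    Links are processed greedily in descending |log_odds| (ties broken by
    variant index); a link joins two groups with the relative orientation given
    by its sign.  Links with |log_odds| below ``min_block_logodds`` never join,
    creating block boundaries.  A sliding-window exhaustive refinement
    (``2^refine_window`` configurations per window) then repairs local flips.

    Returns the variant table with ``orientation`` and ``phase_set`` columns
    (``-1`` for unphased singletons) and the list of phase blocks in genome
    order.  Blocks are runs of *consecutive* variants sharing a component, so
    phase sets are contiguous in variant order.
    """
    n = len(variants)
    uf = _ParityUnionFind(n)
    strong = links[np.abs(links["log_odds"]) >= min_block_logodds]
    strong = strong[strong["log_odds"] != 0.0]
    si = strong["i"].to_numpy()
    sj = strong["j"].to_numpy()
    slo = strong["log_odds"].to_numpy()
    order = np.lexsort((sj, si, -np.abs(slo)))
    for k in order:
        uf.union(int(si[k]), int(sj[k]), 0 if slo[k] > 0 else 1)

    root = np.empty(n, dtype=np.int64)
    parity = np.empty(n, dtype=np.int8)
    for x in range(n):
        r, p = uf.find(x)
        root[x], parity[x] = r, p

    # component size; singletons stay unphased
    sizes = pd.Series(root).value_counts()
    orientation = np.full(n, -1, dtype=np.int64)
    phase_set = np.full(n, -1, dtype=np.int64)

    blocks: list[PhaseBlock] = []
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    idx_by_link: dict[int, list[int]] = {}
    for li, (i, j) in enumerate(zip(links["i"].to_numpy(), links["j"].to_numpy())):
        idx_by_link.setdefault(int(i), []).append(li)
        idx_by_link.setdefault(int(j), []).append(li)

    start = 0
    while start < n:
        end = start + 1
        while (end < n and chroms[end] == chroms[start]
               and root[end] == root[start]):
            end += 1
        members = np.arange(start, end)
        if len(members) > 1 and sizes[root[start]] > 1:
            orient = parity[members].astype(np.int64)
            orient = _refine_block(members, orient, links, idx_by_link,
                                   refine_window)
            orient ^= orient[0]  # normalize: first member is orientation 0
            ps = int(pos[start])
            orientation[members] = orient
            phase_set[members] = ps
            blocks.append(PhaseBlock(ps, str(chroms[start]), int(pos[start]),
                                     int(pos[end - 1]), members, orient))
        else:
            blocks.append(PhaseBlock(int(pos[start]), str(chroms[start]),
                                     int(pos[start]), int(pos[start]),
                                     members, np.full(len(members), -1)))
        start = end

    out = variants.copy()
    out["orientation"] = orientation
    out["phase_set"] = phase_set
    return out, blocks


def _refine_block(members: np.ndarray, orient: np.ndarray, links: pd.DataFrame,
                  idx_by_link: dict[int, list[int]], window: int) -> np.ndarray:
    """One left-to-right sweep of exhaustive window flips maximizing molecule
    concordance within the block."""
    if len(members) < 2 or not len(links):
        return orient
    member_set = {int(m): k for k, m in enumerate(members)}
    li_all = sorted({li for m in members for li in idx_by_link.get(int(m), [])})
    if not li_all:
        return orient
    lsub = links.iloc[li_all]
    keep = lsub["i"].isin(member_set) & lsub["j"].isin(member_set)
    lsub = lsub[keep]
    if not len(lsub):
        return orient
    Li = np.array([member_set[int(v)] for v in lsub["i"]])
    Lj = np.array([member_set[int(v)] for v in lsub["j"]])
    n_cis = lsub["n_cis"].to_numpy()
    n_trans = lsub["n_trans"].to_numpy()

    w = min(window, len(members))
    configs = np.array([[(c >> b) & 1 for b in range(w)] for c in range(2 ** w)],
                       dtype=np.int64)
    o = orient.copy()
    for s in range(0, len(members) - w + 1):
        in_i = (Li >= s) & (Li < s + w)
        in_j = (Lj >= s) & (Lj < s + w)
        touch = in_i | in_j
        if not touch.any():
            continue
        ti, tj = Li[touch], Lj[touch]
        # flip applied to each endpoint under every configuration
        fi = np.where(in_i[touch], configs[:, np.clip(ti - s, 0, w - 1)], 0)
        fj = np.where(in_j[touch], configs[:, np.clip(tj - s, 0, w - 1)], 0)
        same = (o[ti] ^ fi) == (o[tj] ^ fj)
        scores = np.where(same, n_cis[touch], n_trans[touch]).sum(axis=1)
        best = int(np.argmax(scores))  # argmax takes the lowest index on ties
        o[s:s + w] ^= configs[best]
    return o


def phased_vcf_frame(variants: pd.DataFrame) -> pd.DataFrame:
    """VCF frame for :func:`lrkit.io.write_vcf`: phased hets get ``GT`` with
    ``|`` and a ``PS`` phase set; unphased singletons keep ``0/1``."""
    phased = variants["phase_set"].to_numpy() >= 0
    orient = variants["orientation"].to_numpy()
    gt = np.where(phased, np.where(orient == 0, "1|0", "0|1"), "0/1")
    ps = np.where(phased, variants["phase_set"].to_numpy() + 1, pd.NA)
    return pd.DataFrame({"chrom": variants["chrom"], "pos": variants["pos"],
                         "ref": variants["ref"], "alt": variants["alt"],
                         "gt": gt, "ps": ps})


def assign_molecule_haplotypes(observations: pd.DataFrame,
                               phased_variants: pd.DataFrame) -> pd.DataFrame:
    """Vote each molecule onto a haplotype of its phase block.

    An observation of allele ``a`` at a phased variant with orientation ``o``
    implies the molecule lies on haplotype ``o`` when ``a == 1`` (it carries
    the alt) and ``1 - o`` otherwise.  The majority vote within the molecule's
    dominant phase set wins; ties are unassigned.
    """
    obs = observations[observations["molecule_id"] >= 0].copy()
    orient = phased_variants["orientation"].to_numpy()
    ps = phased_variants["phase_set"].to_numpy()
    vi = obs["var_idx"].to_numpy()
    phased = ps[vi] >= 0
    obs = obs[phased]
    vi = vi[phased]
    implied = np.where(obs["allele"].to_numpy() == 1, orient[vi], 1 - orient[vi])
    df = pd.DataFrame({"molecule_id": obs["molecule_id"].to_numpy(),
                       "phase_set": ps[vi], "hap": implied})
    rows = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        top_ps = grp["phase_set"].value_counts().index[0]
        votes = grp[grp["phase_set"] == top_ps]["hap"]
        mean = votes.mean()
        if mean == 0.5:
            continue
        rows.append((mol, int(top_ps), int(mean > 0.5), len(votes)))
    return pd.DataFrame(rows, columns=["molecule_id", "phase_set", "haplotype",
                                       "n_votes"])
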