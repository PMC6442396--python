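"""Diploid genome construction with planted variants and full truth tracking.

A simulated sample is a random reference plus two haplotypes that differ from
it only at planted heterozygous variants: SNVs, short indels, and structural
variants (deletions, tandem duplications, inversions, balanced translocations).
Each haplotype chromosome carries a *block map* — a sorted list of segments
mapping haplotype coordinates back to reference coordinates (with orientation)
— so that reads simulated on a haplotype can be placed at their true reference
position without running an aligner, even across SV junctions and indels.

Coordinates are 0-based half-open everywhere; only the VCF writer is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# minimum spacing between planted small variants; avoids overlapping edits
_MIN_VARIANT_SPACING = 20
# exclusion margin around SV breakpoints for small variants and other SVs
_SV_MARGIN = 5_000


def revcomp(seq: bytes) -> bytes:
    """Reverse complement of an ASCII nucleotide sequence."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class TruthSV:
    """A planted structural variant (always heterozygous).

    ``pos1``/``pos2`` are the two breakends in reference coordinates.  For
    DEL/DUP/INV they delimit the affected interval on one chromosome; for a
    balanced translocation they are the exchange points on two chromosomes.
    """

    svtype: str  # DEL | DUP | INV | TRA
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    haplotype: int
    size: int | None  # None for TRA

    @property
    def interval(self) -> tuple[str, int, int]:
        if self.svtype == "TRA":
            raise ValueError("balanced translocations have no single interval")
        return self.chrom1, self.pos1, self.pos2


@dataclass
class BlockMap:
    """Sorted segment map from one haplotype chromosome to the reference.

    Segment ``i`` maps haplotype interval ``[hap_start[i], hap_start[i]+length[i])``
    to reference interval ``[ref_start[i], ref_start[i]+length[i])`` on
    chromosome index ``ref_chrom[i]`` (-1 for novel inserted sequence).  With
    ``strand[i] == -1`` the mapping is reverse-complemented: haplotype offset
    ``k`` within the segment corresponds to reference position
    ``ref_start + length - 1 - k``.
    """

    hap_start: np.ndarray
    length: np.ndarray
    ref_chrom: np.ndarray
    ref_start: np.ndarray
    strand: np.ndarray

    @property
    def hap_length(self) -> int:
        return int(self.hap_start[-1] + self.length[-1]) if len(self.hap_start) else 0

    def locate(self, pos: np.ndarray) -> np.ndarray:
        """Index of the segment containing each haplotype position."""
        return np.searchsorted(self.hap_start, pos, side="right") - 1


@dataclass
class DiploidGenome:
    """Reference, two haplotypes, and the truth variant/SV sets."""

    chrom_names: list[str]
    reference: dict[str, bytes]
    haplotypes: tuple[dict[str, bytes], dict[str, bytes]]
    block_maps: dict[tuple[int, str], BlockMap]
    variants: pd.DataFrame  # chrom,pos,kind,ref,alt,haplotype,edit_pos,del_len,ins_seq
    svs: list[TruthSV] = field(default_factory=list)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    def het_snvs(self) -> pd.DataFrame:
        """Truth heterozygous SNVs (chrom, pos, ref, alt, haplotype)."""
        v = self.variants
        return v[v["kind"] == "snv"].reset_index(drop=True)

    def hap_interval_to_ref(self, hap: int, chrom: str, start: int, end: int
                            ) -> tuple[str, int, int]:
        """Reference interval of the largest mapped segment overlapped by a
        haplotype interval (used to express truth molecules in reference
        coordinates; exact when the interval crosses no SV junction)."""
        bm = self.block_maps[(hap, chrom)]
        lo = int(bm.locate(np.array([start]))[0])
        hi = int(bm.locate(np.array([end - 1]))[0])
        best = None
        for i in range(lo, hi + 1):
            if bm.ref_chrom[i] < 0:
                continue
            s = max(start, bm.hap_start[i])
            e = min(end, bm.hap_start[i] + bm.length[i])
            if best is None or e - s > best[0]:
                best = (e - s, i, s, e)
        if best is None:  # entirely within novel sequence (pathological)
            return self.chrom_names[0], 0, 0
        _, i, s, e = best
        off = s - bm.hap_start[i]
        if bm.strand[i] > 0:
            rs = int(bm.ref_start[i] + off)
        else:
            rs = int(bm.ref_start[i] + bm.length[i] - off - (e - s))
        return self.chrom_names[bm.ref_chrom[i]], rs, rs + int(e - s)


def _random_reference(rng: np.random.Generator, cfg: SimConfig) -> dict[str, bytes]:
    ref = {}
    for i in range(cfg.n_chromosomes):
        idx = rng.integers(0, 4, size=cfg.genome_length)
        ref[f"chr{i + 1}"] = _BASES[idx].tobytes()
    return ref


def _place_svs(cfg: SimConfig, rng: np.random.Generator,
               chrom_names: list[str]) -> list[TruthSV]:
    """Place requested SVs uniformly, rejecting overlaps (with margin)."""
    L = cfg.genome_length
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def collides(chrom: str, s: int, e: int) -> bool:
        return any(s < be + _SV_MARGIN and bs - _SV_MARGIN < e
                   for bs, be in blocked[chrom])

    svs: list[TruthSV] = []
    n_tra = 0
    for svtype, size, count in cfg.sv_spec:
        for _ in range(count):
            if svtype == "TRA":
                if cfg.n_chromosomes < 2:
                    raise ValueError("balanced translocations need >= 2 chromosomes")
                for _attempt in range(1000):
                    c1, c2 = [chrom_names[j] for j in
                              rng.choice(cfg.n_chromosomes, size=2, replace=False)]
                    p1 = int(rng.integers(_SV_MARGIN, L - _SV_MARGIN))
                    p2 = int(rng.integers(_SV_MARGIN, L - _SV_MARGIN))
                    if not collides(c1, p1, p1 + 1) and not collides(c2, p2, p2 + 1):
                        break
                else:
                    raise ValueError("could not place TRA without overlapping another SV")
                blocked[c1].append((p1, p1 + 1))
                blocked[c2].append((p2, p2 + 1))
                # alternate haplotypes so each haplotype carries at most one
                # exchange per chromosome pair (keeps derivatives well formed)
                hap = n_tra % 2
                n_tra += 1
                svs.append(TruthSV("TRA", c1, p1, c2, p2, hap, None))
                continue
            if size >= L - 2 * _SV_MARGIN:
                raise ValueError(
                    f"SV of size {size} does not fit on a {L} bp chromosome")
            for _attempt in range(1000):
                chrom = chrom_names[int(rng.integers(0, cfg.n_chromosomes))]
                s = int(rng.integers(_SV_MARGIN, L - _SV_MARGIN - size))
                if not collides(chrom, s, s + size):
                    break
            else:
                raise ValueError(
                    f"could not place {svtype} of size {size} without overlap; "
                    "reduce count/size or enlarge the genome")
            blocked[chrom].append((s, s + size))
            hap = int(rng.integers(0, 2))
            svs.append(TruthSV(svtype, chrom, s, chrom, s + size, hap, size))
    return svs


def _sample_small_variants(cfg: SimConfig, rng: np.random.Generator,
                           reference: dict[str, bytes],
                           svs: list[TruthSV],
                           snv_positions: dict[str, np.ndarray] | None,
                           ) -> pd.DataFrame:
    """Sample het SNV and indel positions, thinned to avoid overlapping edits
    and kept clear of SV breakpoints."""
    rows = []
    for chrom, seq in reference.items():
        L = len(seq)
        if snv_positions is not None:
            snv_pos = np.asarray(snv_positions.get(chrom, np.empty(0, int)), dtype=np.int64)
        elif cfg.het_snv_rate > 0:
            snv_pos = np.flatnonzero(rng.random(L) < cfg.het_snv_rate)
        else:
            snv_pos = np.empty(0, dtype=np.int64)
        if cfg.indel_rate > 0:
            indel_pos = np.flatnonzero(rng.random(L) < cfg.indel_rate)
        else:
            indel_pos = np.empty(0, dtype=np.int64)
        pos = np.concatenate([snv_pos, indel_pos])
        kind = np.concatenate([np.zeros(len(snv_pos), int), np.ones(len(indel_pos), int)])
        order = np.argsort(pos, kind="stable")
        pos, kind = pos[order], kind[order]
        # enforce spacing and distance from chromosome ends
        ok = (pos >= 1) & (pos < L - 12)
        pos, kind = pos[ok], kind[ok]
        if len(pos):
            keep = np.ones(len(pos), bool)
            last = -_MIN_VARIANT_SPACING
            for i, p in enumerate(pos):
                if p - last < _MIN_VARIANT_SPACING:
                    keep[i] = False
                else:
                    last = p
            pos, kind = pos[keep], kind[keep]
        # exclude SV footprints (+ margin)
        exclusions = []
        for sv in svs:
            if sv.svtype == "TRA":
                exclusions.append((sv.chrom1, sv.pos1, sv.pos1 + 1))
                exclusions.append((sv.chrom2, sv.pos2, sv.pos2 + 1))
            else:
                exclusions.append((sv.chrom1, sv.pos1, sv.pos2))
        for c, s, e in exclusions:
            if c != chrom:
                continue
            mask = (pos < s - _SV_MARGIN) | (pos >= e + _SV_MARGIN)
            pos, kind = pos[mask], kind[mask]
        for p, k in zip(pos, kind):
            p = int(p)
            refb = seq[p:p + 1].decode()
            hap = int(rng.integers(0, 2))
            if k == 0:  # SNV
                alt = "ACGT".replace(refb, "")[int(rng.integers(0, 3))]
                rows.append((chrom, p, "snv", refb, alt, hap, p, 1, alt))
            else:
                dlen = int(rng.integers(1, 11))
                if rng.random() < 0.5:  # deletion of [p+1, p+1+dlen)
                    ref_allele = seq[p:p + 1 + dlen].decode()
                    rows.append((chrom, p, "del", ref_allele, refb, hap,
                                 p + 1, dlen, ""))
                else:  # insertion after p
                    ins = "".join("ACGT"[j] for j in rng.integers(0, 4, dlen))
                    rows.append((chrom, p, "ins", refb, refb + ins, hap,
                                 p + 1, 0, ins))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "kind", "ref", "alt", "haplotype",
                       "edit_pos", "del_len", "ins_seq"],
    )


# -- haplotype assembly -------------------------------------------------------

def _apply_svs_to_pieces(chrom_names: list[str], L: int,
                         svs: list[TruthSV], hap: int,
                         ) -> dict[str, list[tuple[str, int, int, int]]]:
    """Build per-chromosome piece lists (ref_chrom, start, end, strand) for one
    haplotype after applying its SVs."""
    pieces = {c: [(c, 0, L, 1)] for c in chrom_names}

    def split_at(chrom_key: str, ref_chrom: str, refpos: int) -> int:
        """Split the piece of ``chrom_key`` containing reference position
        ``refpos`` (on ``ref_chrom``, forward strand); return split index."""
        plist = pieces[chrom_key]
        for i, (c, s, e, st) in enumerate(plist):
            if c == ref_chrom and st == 1 and s < refpos < e:
                plist[i:i + 1] = [(c, s, refpos, 1), (c, refpos, e, 1)]
                return i + 1
            if c == ref_chrom and st == 1 and refpos == s:
                return i
        raise ValueError(f"breakpoint {ref_chrom}:{refpos} not inside a forward piece")

    def locate_and_split(ref_chrom: str, refpos: int) -> tuple[str, int]:
        """Find the derivative chromosome currently carrying reference locus
        (ref_chrom, refpos) — earlier exchanges may have moved it — and split
        its piece list there."""
        for key in chrom_names:
            for (c, s, e, st) in pieces[key]:
                if c == ref_chrom and st == 1 and s <= refpos < e:
                    return key, split_at(key, ref_chrom, refpos)
        raise ValueError(
            f"breakpoint {ref_chrom}:{refpos} not on any derivative chromosome")

    linear = [sv for sv in svs if sv.haplotype == hap and sv.svtype != "TRA"]
    for sv in sorted(linear, key=lambda s: (s.chrom1, -s.pos1)):
        c = sv.chrom1
        i1 = split_at(c, c, sv.pos1)
        i2 = split_at(c, c, sv.pos2)
        body = pieces[c][i1:i2]
        if sv.svtype == "DEL":
            pieces[c][i1:i2] = []
        elif sv.svtype == "DUP":
            pieces[c][i1:i2] = body + [p for p in body]
        elif sv.svtype == "INV":
            pieces[c][i1:i2] = [(pc, ps, pe, -st) for pc, ps, pe, st in reversed(body)]
    for sv in svs:
        if sv.haplotype != hap or sv.svtype != "TRA":
            continue
        k1, i1 = locate_and_split(sv.chrom1, sv.pos1)
        k2, i2 = locate_and_split(sv.chrom2, sv.pos2)
        if k1 == k2:
            raise ValueError(
                f"translocation breakpoints {sv.chrom1}:{sv.pos1} and "
                f"{sv.chrom2}:{sv.pos2} both lie on derivative {k1}; reduce "
                "the number of translocations per haplotype")
        tail1 = pieces[k1][i1:]
        tail2 = pieces[k2][i2:]
        pieces[k1][i1:] = tail2
        pieces[k2][i2:] = tail1
    return pieces


def _materialize(reference: dict[str, bytes], chrom_names: list[str],
                 pieces: list[tuple[str, int, int, int]],
                 small: pd.DataFrame) -> tuple[bytes, BlockMap]:
    """Concatenate reference pieces, applying small variants inside forward
    pieces, and record the haplotype->reference block map."""
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    parts: list[bytes] = []
    blocks: list[tuple[int, int, int, int]] = []  # (length, ref_chrom, ref_start, strand)

    for (c, s, e, strand) in pieces:
        seq = reference[c][s:e]
        if strand == -1:
            parts.append(revcomp(seq))
            blocks.append((e - s, chrom_index[c], s, -1))
            continue
        sub = small[(small["chrom"] == c) & (small["edit_pos"] >= s)
                    & (small["edit_pos"] + small["del_len"] <= e)]
        if not len(sub):
            parts.append(seq)
            blocks.append((e - s, chrom_index[c], s, 1))
            continue
        seg = bytearray(seq)
        indels = []
        for row in sub.itertuples():
            if row.kind == "snv":
                seg[row.edit_pos - s] = ord(row.ins_seq)
            else:
                indels.append((row.edit_pos, row.del_len, row.ins_seq.encode()))
        cur = s
        for epos, dlen, iseq in sorted(indels):
            if epos > cur:
                parts.append(bytes(seg[cur - s:epos - s]))
                blocks.append((epos - cur, chrom_index[c], cur, 1))
            if iseq:
                parts.append(iseq)
                blocks.append((len(iseq), -1, 0, 1))
            cur = epos + dlen
        if e > cur:
            parts.append(bytes(seg[cur - s:]))
            blocks.append((e - cur, chrom_index[c], cur, 1))

    lengths = np.array([b[0] for b in blocks], dtype=np.int64)
    hap_start = np.concatenate([[0], np.cumsum(lengths)[:-1]]) if len(blocks) else np.empty(0, np.int64)
    bm = BlockMap(
        hap_start=hap_start.astype(np.int64),
        length=lengths,
        ref_chrom=np.array([b[1] for b in blocks], dtype=np.int64),
        ref_start=np.array([b[2] for b in blocks], dtype=np.int64),
        strand=np.array([b[3] for b in blocks], dtype=np.int8),
    )
    return b"".join(parts), bm


def build_diploid_genome(config: SimConfig,
                         rng: np.random.Generator | None = None,
                         snv_positions: dict[str, np.ndarray] | None = None,
                         ) -> DiploidGenome:
    """Generate a random reference and two haplotypes with planted variants.

    Parameters
    ----------
    config : SimConfig
    rng : numpy Generator, optional
        Source of randomness; defaults to ``default_rng(config.seed)``.
    snv_positions : dict, optional
        Explicit het SNV positions per chromosome, overriding ``het_snv_rate``
        (used for controlled phasing experiments with designed variant spacing).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    reference = _random_reference(rng, config)
    svs = _place_svs(config, rng, chrom_names)
    variants = _sample_small_variants(config, rng, reference, svs, snv_positions)

    haplotypes: tuple[dict[str, bytes], dict[str, bytes]] = ({}, {})
    block_maps: dict[tuple[int, str], BlockMap] = {}
    for hap in (0, 1):
        small = variants[variants["haplotype"] == hap]
        pieces = _apply_svs_to_pieces(chrom_names, config.genome_length, svs, hap)
        for c in chrom_names:
            seq, bm = _materialize(reference, chrom_names, pieces[c], small)
            haplotypes[hap][c] = seq
            block_maps[(hap, c)] = bm
    return DiploidGenome(chrom_names, reference, haplotypes, block_maps,
                         variants, svs)
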