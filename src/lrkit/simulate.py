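"""Barcoded Linked-Read simulation on a diploid genome.

Molecules are distributed over barcoded partitions (Poisson loading), sampled
from a random haplotype, and sequenced shallowly by short read pairs.  Every
read is emitted twice: as a FASTQ record carrying its partition barcode in a
``BX:Z:`` comment tag, and as a row of a *truth alignment table* giving its
exact reference placement (derived from the haplotype block map), so that the
downstream modules can be exercised without an external aligner.

Truth alignment table columns (one row per mate)::

    read_id   int    pair identifier
    mate      int    1 or 2
    barcode   category
    molecule_id int  truth molecule of origin
    haplotype int    truth haplotype of origin
    chrom     str    reference chromosome
    start,end int    reference interval of the aligned portion (0-based, half-open)
    strand    int    +1/-1 on the reference
    mapq      int    mapping quality (60 for simulated truth placements)
    seq       bytes  reference-forward base sequence over [start, end)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SimConfig
from .genome import DiploidGenome, revcomp

logger = logging.getLogger(__name__)

ALN_COLUMNS = ["read_id", "mate", "barcode", "molecule_id", "haplotype",
               "chrom", "start", "end", "strand", "mapq", "seq"]

MOLECULE_COLUMNS = ["molecule_id", "barcode", "partition_id", "haplotype",
                    "chrom", "start", "end"]

_BARCODE_LEN = 16
_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_barcodes(indices: np.ndarray, whitelist_size: int) -> list[str]:
    """Map whitelist indices to 16-mer barcode strings (10x-style, with the
    ``-1`` GEM-group suffix).  The whitelist is the first ``whitelist_size``
    16-mers in lexicographic order, so membership is checkable by decoding."""
    indices = np.asarray(indices, dtype=np.int64)
    if np.any((indices < 0) | (indices >= whitelist_size)):
        raise ValueError("barcode index outside whitelist")
    digits = np.empty((len(indices), _BARCODE_LEN), dtype=np.int64)
    rem = indices.copy()
    for k in range(_BARCODE_LEN - 1, -1, -1):
        digits[:, k] = rem % 4
        rem //= 4
    chars = _BASE_CHARS[digits]
    return [row.tobytes().decode() + "-1" for row in chars]


def decode_barcode(barcode: str) -> int:
    """Whitelist index of a barcode string (inverse of :func:`encode_barcodes`)."""
    seq = barcode.split("-")[0]
    idx = 0
    for ch in seq:
        idx = idx * 4 + "ACGT".index(ch)
    return idx


def sample_molecules(genome: DiploidGenome, config: SimConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Sample truth molecules into barcoded partitions.

    Each partition receives ``Poisson(molecules_per_partition_mean)`` molecules.
    Molecule lengths follow the configured model (exponential or lognormal),
    truncated at chromosome bounds; haplotype and chromosome of origin are
    chosen uniformly / length-proportionally.

    Returns a DataFrame with :data:`MOLECULE_COLUMNS` (reference coordinates of
    the molecule's largest contiguous reference segment) plus haplotype-frame
    columns ``hap_chrom, hap_start, hap_end`` used internally by the read
    generator.
    """
    barcode_idx = rng.permutation(config.barcode_whitelist_size)[:config.n_partitions]
    barcodes = encode_barcodes(barcode_idx, config.barcode_whitelist_size)
    counts = rng.poisson(config.molecules_per_partition_mean, config.n_partitions)
    total = int(counts.sum())
    partition_id = np.repeat(np.arange(config.n_partitions), counts)

    hap = rng.integers(0, 2, size=total)
    # chromosome chosen proportionally to haplotype chromosome length
    chrom_idx = np.zeros(total, dtype=np.int64)
    for h in (0, 1):
        mask = hap == h
        lens = np.array([len(genome.haplotypes[h][c]) for c in genome.chrom_names],
                        dtype=np.float64)
        chrom_idx[mask] = rng.choice(len(lens), size=int(mask.sum()),
                                     p=lens / lens.sum())
    if config.molecule_length_model == "exponential":
        lengths = rng.exponential(config.mean_molecule_length, size=total)
    else:
        sigma = config.lognormal_sigma
        mu = np.log(config.mean_molecule_length) - sigma ** 2 / 2
        lengths = rng.lognormal(mu, sigma, size=total)
    lengths = np.maximum(lengths.astype(np.int64), 1)

    chrom_len = np.array(
        [[len(genome.haplotypes[h][c]) for c in genome.chrom_names] for h in (0, 1)],
        dtype=np.int64)
    clen = chrom_len[hap, chrom_idx]
    # molecules may overhang chromosome ends (sampled on an extended range and
    # truncated), keeping expected physical coverage uniform at the edges
    raw_start = (rng.random(total) * (clen + lengths - 1)).astype(np.int64) - (lengths - 1)
    start = np.maximum(raw_start, 0)
    end = np.minimum(raw_start + lengths, clen)

    hap_chrom = np.array(genome.chrom_names, dtype=object)[chrom_idx]
    ref = [genome.hap_interval_to_ref(int(h), str(c), int(s), int(e))
           for h, c, s, e in zip(hap, hap_chrom, start, end)]
    mols = pd.DataFrame({
        "molecule_id": np.arange(total, dtype=np.int64),
        "barcode": pd.Categorical.from_codes(
            partition_id, categories=pd.Index(barcodes)),
        "partition_id": partition_id,
        "haplotype": hap.astype(np.int8),
        "chrom": [r[0] for r in ref],
        "start": np.array([r[1] for r in ref], dtype=np.int64),
        "end": np.array([r[2] for r in ref], dtype=np.int64),
        "hap_chrom": hap_chrom,
        "hap_start": start,
        "hap_end": end,
    })
    return mols


def pairs_per_molecule(length: np.ndarray, config: SimConfig) -> np.ndarray:
    """Deterministic read-pair count: round(coverage * L / (2 * read_length)),
    zero for molecules too short to hold one insert."""
    n = np.rint(config.per_molecule_read_coverage * np.asarray(length)
                / (2.0 * config.read_length)).astype(np.int64)
    return np.where(np.asarray(length) < 2 * config.read_length, 0, n)


def generate_read_pairs(molecules: pd.DataFrame, genome: DiploidGenome,
                        config: SimConfig, rng: np.random.Generator
                        ) -> pd.DataFrame:
    """Generate barcoded read pairs and their truth alignments.

    Read pairs are placed uniformly along each molecule with a Normal insert
    model; substitution errors are applied at ``base_error_rate``.  Each mate is
    mapped back to reference coordinates through the haplotype block map; a mate
    crossing a block boundary (SV junction or indel) is truncated to the portion
    in its starting block, and a mate starting inside novel inserted sequence is
    dropped as unalignable.
    """
    mol_len = (molecules["hap_end"] - molecules["hap_start"]).to_numpy()
    n_pairs = pairs_per_molecule(mol_len, config)
    n_short = int(((mol_len < 2 * config.read_length)
                   & (config.per_molecule_read_coverage > 0)).sum())
    if n_short:
        logger.warning("%d molecules shorter than one insert produced no reads",
                       n_short)
    mi = np.repeat(np.arange(len(molecules)), n_pairs)
    total_pairs = len(mi)
    rl = config.read_length

    plen = mol_len[mi]
    insert = rng.normal(config.insert_mean, config.insert_sd, size=total_pairs)
    insert = np.clip(insert, 2 * rl, plen).astype(np.int64)
    pstart = (molecules["hap_start"].to_numpy()[mi]
              + (rng.random(total_pairs) * (plen - insert + 1)).astype(np.int64))

    # two mates per pair, haplotype-frame intervals
    m_start = np.empty(2 * total_pairs, dtype=np.int64)
    m_strand = np.empty(2 * total_pairs, dtype=np.int8)
    m_start[0::2] = pstart
    m_start[1::2] = pstart + insert - rl
    m_strand[0::2] = 1
    m_strand[1::2] = -1
    m_pair = np.repeat(np.arange(total_pairs, dtype=np.int64), 2)
    m_mate = np.tile(np.array([1, 2], dtype=np.int8), total_pairs)
    m_mol = np.repeat(mi, 2)
    hap = molecules["haplotype"].to_numpy()[m_mol]
    hap_chrom_cat = pd.Categorical(molecules["hap_chrom"])
    hap_chrom_codes = hap_chrom_cat.codes[m_mol]
    hap_chroms = list(hap_chrom_cat.categories)

    out = {k: [] for k in ALN_COLUMNS}
    err_total = 0
    for h in (0, 1):
        for ci, chrom in enumerate(hap_chroms):
            sel = np.flatnonzero((hap == h) & (hap_chrom_codes == ci))
            if not len(sel):
                continue
            bm = genome.block_maps[(h, chrom)]
            hseq = genome.haplotypes[h][chrom]
            pos = m_start[sel]
            bi = bm.locate(pos)
            off = pos - bm.hap_start[bi]
            alen = np.minimum(rl, bm.length[bi] - off)
            mapped = bm.ref_chrom[bi] >= 0
            sel, bi, off, alen, pos = (sel[mapped], bi[mapped], off[mapped],
                                       alen[mapped], pos[mapped])
            fwd = bm.strand[bi] > 0
            rstart = np.where(
                fwd,
                bm.ref_start[bi] + off,
                bm.ref_start[bi] + bm.length[bi] - off - alen)
            # substitution errors: per-mate error count, then per-base positions
            nerr = rng.binomial(alen, config.base_error_rate)
            err_total += int(nerr.sum())
            seqs = []
            for k in range(len(sel)):
                p, a = int(pos[k]), int(alen[k])
                s = hseq[p:p + a]
                ne = int(nerr[k])
                if ne:
                    s = bytearray(s)
                    # distinct error positions so errors never cancel out
                    for epos in rng.choice(a, size=min(ne, a), replace=False):
                        cur = s[epos]
                        choices = [b for b in b"ACGT" if b != cur]
                        s[epos] = choices[int(rng.integers(0, 3))]
                    s = bytes(s)
                if not fwd[k]:
                    s = revcomp(s)
                seqs.append(s)
            rc = bm.ref_chrom[bi]
            out["read_id"].append(m_pair[sel])
            out["mate"].append(m_mate[sel])
            out["barcode"].append(np.asarray(
                molecules["barcode"].cat.codes.to_numpy()[m_mol[sel]]))
            out["molecule_id"].append(
                molecules["molecule_id"].to_numpy()[m_mol[sel]])
            out["haplotype"].append(np.full(len(sel), h, dtype=np.int8))
            out["chrom"].append(rc)
            out["start"].append(rstart)
            out["end"].append(rstart + alen)
            out["strand"].append((m_strand[sel] * bm.strand[bi]).astype(np.int8))
            out["mapq"].append(np.full(len(sel), 60, dtype=np.int16))
            out["seq"].append(seqs)

    barcode_cats = molecules["barcode"].cat.categories
    aln = pd.DataFrame({
        "read_id": np.concatenate(out["read_id"]) if out["read_id"] else np.empty(0, np.int64),
        "mate": np.concatenate(out["mate"]) if out["mate"] else np.empty(0, np.int8),
        "barcode": pd.Categorical.from_codes(
            np.concatenate(out["barcode"]).astype(np.int64) if out["barcode"] else np.empty(0, np.int64),
            categories=barcode_cats),
        "molecule_id": np.concatenate(out["molecule_id"]) if out["molecule_id"] else np.empty(0, np.int64),
        "haplotype": np.concatenate(out["haplotype"]) if out["haplotype"] else np.empty(0, np.int8),
        "chrom": pd.Categorical.from_codes(
            np.concatenate(out["chrom"]).astype(np.int64) if out["chrom"] else np.empty(0, np.int64),
            categories=genome.chrom_names),
        "start": np.concatenate(out["start"]) if out["start"] else np.empty(0, np.int64),
        "end": np.concatenate(out["end"]) if out["end"] else np.empty(0, np.int64),
        "strand": np.concatenate(out["strand"]) if out["strand"] else np.empty(0, np.int8),
        "mapq": np.concatenate(out["mapq"]) if out["mapq"] else np.empty(0, np.int16),
        "seq": [s for chunk in out["seq"] for s in chunk],
    })
    aln = aln.sort_values(["read_id", "mate"], kind="stable").reset_index(drop=True)
    logger.info("simulated %d read pairs (%d substitution errors)",
                total_pairs, err_total)
    return aln
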