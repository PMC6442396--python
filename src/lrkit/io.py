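"""Readers and writers for the formats the toolkit exchanges.

Plain-text formats only: FASTA, FASTQ (barcode in a ``BX:Z:`` comment tag),
VCF 4.2 (phased genotypes with ``PS`` phase sets), BED, BEDPE, and TSV tables
for molecules and truth alignments.  Reading goes through pysam wherever pysam
has a parser (FASTA, FASTQ, VCF, SAM); writers emit plain text.
"""

from __future__ import annotations

import math
import os

import numpy as np
import pandas as pd
import pysam

from .config import SimConfig
from .genome import DiploidGenome, TruthSV, revcomp
from .simulate import ALN_COLUMNS, MOLECULE_COLUMNS

# -- FASTA --------------------------------------------------------------------

def write_fasta(sequences: dict[str, bytes], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            s = seq.decode()
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, bytes]:
    out = {}
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            out[entry.name] = entry.sequence.encode()
    return out


# -- FASTQ --------------------------------------------------------------------

def write_fastq(aln: pd.DataFrame, path: str, base_error_rate: float = 1e-3) -> None:
    """Interleaved FASTQ with the partition barcode as a ``BX:Z:`` comment tag.

    Sequences are emitted in sequencing orientation (reverse-strand placements
    are reverse-complemented back); the constant quality reflects the simulated
    substitution error rate.
    """
    q = min(40, round(-10 * math.log10(max(base_error_rate, 1e-8))))
    with open(path, "w") as fh:
        for row in aln.itertuples():
            seq = row.seq if row.strand > 0 else revcomp(row.seq)
            qual = chr(q + 33) * len(seq)
            fh.write(f"@sim:{row.read_id}/{row.mate} BX:Z:{row.barcode}\n"
                     f"{seq.decode()}\n+\n{qual}\n")


def read_fastq(path: str) -> pd.DataFrame:
    """Read a barcoded FASTQ into (read_id, mate, barcode, seq, qual)."""
    rows = []
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            name, _, mate = entry.name.partition("/")
            barcode = None
            for tag in (entry.comment or "").split():
                if tag.startswith("BX:Z:"):
                    barcode = tag[5:]
            rows.append((name, int(mate) if mate else 0, barcode,
                         entry.sequence.encode(), entry.quality))
    return pd.DataFrame(rows, columns=["read_id", "mate", "barcode", "seq", "qual"])


# -- VCF ----------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=lrkit
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(variants: pd.DataFrame, contig_lengths: dict[str, int], path: str,
              sample: str = "sim") -> None:
    """Write a diploid VCF.

    ``variants`` needs columns chrom, pos (0-based), ref, alt, gt (e.g. ``0|1``)
    and optionally ps (phase-set id, NA for unphased records).
    """
    contigs = "".join(f"##contig=<ID={c},length={l}>\n"
                      for c, l in contig_lengths.items())
    has_ps = "ps" in variants.columns
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for row in variants.itertuples():
            gt = row.gt
            ps = getattr(row, "ps", None) if has_ps else None
            if ps is not None and not pd.isna(ps) and "|" in gt:
                fmt, val = "GT:PS", f"{gt}:{int(ps)}"
            else:
                fmt, val = "GT", gt
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\t{fmt}\t{val}\n")


def read_vcf(path: str) -> pd.DataFrame:
    """Read the first sample of a VCF into a DataFrame with 0-based positions,
    allele pair, phased flag, and phase set."""
    rows = []
    with pysam.VariantFile(path) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            call = rec.samples[sample]
            alleles = call["GT"]
            if alleles is None or len(alleles) != 2 or None in alleles:
                continue
            ps = call.get("PS")
            rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0] if rec.alts else ".",
                         alleles[0], alleles[1], bool(call.phased),
                         ps if ps is not None else pd.NA))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "allele0", "allele1", "phased", "ps"])


def truth_variants_to_vcf_frame(genome: DiploidGenome) -> pd.DataFrame:
    """Truth small variants as a phased VCF frame (GT = hap0|hap1, one phase
    set per chromosome anchored at its first variant)."""
    v = genome.variants.sort_values(["chrom", "pos"]).reset_index(drop=True)
    gt = np.where(v["haplotype"].to_numpy() == 0, "1|0", "0|1")
    ps = v.groupby("chrom")["pos"].transform("min") + 1
    return pd.DataFrame({"chrom": v["chrom"], "pos": v["pos"], "ref": v["ref"],
                         "alt": v["alt"], "gt": gt, "ps": ps})


# -- BED / BEDPE --------------------------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=".")
    df.columns = ["chrom", "start", "end", "name"][:df.shape[1]]
    if df.shape[1] == 3:
        df["name"] = "."
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: malformed BED interval (end <= start)")
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "strand1", "strand2", "svtype", "size",
                 "haplotype", "filter"]


def write_bedpe(svs: pd.DataFrame, path: str) -> None:
    svs.to_csv(path, sep="\t", header=False, index=False,
               columns=[c for c in BEDPE_COLUMNS if c in svs.columns])


def read_bedpe(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BEDPE_COLUMNS[:df.shape[1]]
    return df


def truth_svs_to_bedpe(svs: list[TruthSV]) -> pd.DataFrame:
    rows = []
    for i, sv in enumerate(svs):
        rows.append((sv.chrom1, sv.pos1, sv.pos1 + 1, sv.chrom2, sv.pos2,
                     sv.pos2 + 1, f"truth_{i}", ".", ".", ".", sv.svtype,
                     sv.size if sv.size is not None else -1, sv.haplotype,
                     "PASS"))
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


# -- molecule & alignment tables ---------------------------------------------

def write_molecules_tsv(molecules: pd.DataFrame, path: str) -> None:
    molecules.to_csv(path, sep="\t", index=False, columns=MOLECULE_COLUMNS)


def read_molecules_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["barcode"] = df["barcode"].astype("category")
    return df


def write_alignments_tsv(aln: pd.DataFrame, path: str) -> None:
    out = aln.copy()
    out["seq"] = [s.decode() for s in out["seq"]]
    out.to_csv(path, sep="\t", index=False, columns=ALN_COLUMNS)


def read_alignments_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["seq"] = [s.encode() for s in df["seq"]]
    df["barcode"] = df["barcode"].astype("category")
    df["chrom"] = df["chrom"].astype("category")
    return df


def alignments_from_sam(path: str) -> pd.DataFrame:
    """Adapter for real barcoded alignments: build the alignment table from a
    SAM/BAM with ``BX:Z`` tags.  Truth columns (molecule, haplotype) are -1."""
    rows = []
    with pysam.AlignmentFile(path) as fh:
        for i, rec in enumerate(fh):
            if rec.is_unmapped or not rec.has_tag("BX"):
                continue
            seq = rec.query_alignment_sequence
            if seq is None:
                continue
            rows.append((i, 2 if rec.is_read2 else 1, rec.get_tag("BX"), -1, -1,
                         rec.reference_name, rec.reference_start,
                         rec.reference_end, -1 if rec.is_reverse else 1,
                         rec.mapping_quality, seq.encode()))
    df = pd.DataFrame(rows, columns=ALN_COLUMNS)
    df["barcode"] = df["barcode"].astype("category")
    df["chrom"] = df["chrom"].astype("category")
    return df


# -- bundle writer ------------------------------------------------------------

def write_outputs(genome: DiploidGenome, molecules: pd.DataFrame,
                  aln: pd.DataFrame, outdir: str,
                  config: SimConfig | None = None) -> dict[str, str]:
    """Write the full simulation bundle: reference FASTA, phased truth VCF,
    truth molecules TSV, truth SVs BEDPE, barcoded interleaved FASTQ, and the
    truth alignment TSV.  Returns the path of each artifact."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "ref.fasta"),
        "vcf": os.path.join(outdir, "truth.vcf"),
        "molecules": os.path.join(outdir, "molecules.tsv"),
        "bedpe": os.path.join(outdir, "truth_svs.bedpe"),
        "fastq": os.path.join(outdir, "reads.fastq"),
        "alignments": os.path.join(outdir, "alignments.tsv"),
    }
    write_fasta(genome.reference, paths["fasta"])
    write_vcf(truth_variants_to_vcf_frame(genome), genome.chrom_lengths,
              paths["vcf"])
    write_molecules_tsv(molecules, paths["molecules"])
    write_bedpe(truth_svs_to_bedpe(genome.svs), paths["bedpe"])
    err = config.base_error_rate if config is not None else 1e-3
    write_fastq(aln, paths["fastq"], base_error_rate=err)
    write_alignments_tsv(aln, paths["alignments"])
    return paths
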