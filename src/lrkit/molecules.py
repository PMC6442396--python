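"""Reconstruction of input DNA molecules from barcoded alignments.

Reads sharing a barcode cluster tightly along the genome around their molecule
of origin, while distinct molecules in the same partition land megabases apart.
Single-linkage clustering of same-barcode reads with a gap cutoff therefore
recovers the molecules: within a (barcode, chromosome) group, a gap larger than
``gap_threshold`` between consecutive reads splits clusters, and clusters with
fewer than ``min_reads`` reads are discarded as barcode noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_GAP_THRESHOLD = 50_000
DEFAULT_MIN_READS = 4
DEFAULT_MIN_MAPQ = 30

INFERRED_COLUMNS = ["molecule_id", "barcode", "chrom", "start", "end",
                    "n_read_pairs", "mean_mapq"]


@dataclass(frozen=True)
class MoleculeStats:
    """Summary statistics of an inferred molecule set."""

    length_weighted_mean_length: float
    unweighted_mean_length: float
    molecules_per_barcode: float
    n_molecules: int


def infer_molecules(aln: pd.DataFrame, gap_threshold: int = DEFAULT_GAP_THRESHOLD,
                    min_reads: int = DEFAULT_MIN_READS,
                    min_mapq: int = DEFAULT_MIN_MAPQ,
                    return_assignment: bool = False):
    """Cluster barcoded alignments into inferred molecules.

    Parameters
    ----------
    aln : DataFrame
        Alignment table (see :mod:`lrkit.simulate`), sorted by
        (barcode, chrom, start).  Unsorted input raises ``ValueError``.
    gap_threshold : int
        A start-to-previous-end gap above this splits same-barcode clusters.
    min_reads : int
        Clusters with fewer reads are dropped.
    min_mapq : int
        Reads below this mapping quality are excluded before clustering.
    return_assignment : bool
        Also return, for every row of ``aln``, the inferred molecule id it was
        assigned to (-1 for filtered reads); used to key downstream allele
        observations to molecules.

    Returns
    -------
    DataFrame with :data:`INFERRED_COLUMNS`; the molecule interval is
    ``[first read start, last read end)``.
    """
    work = aln[aln["mapq"] >= min_mapq]
    bc = work["barcode"].cat.codes.to_numpy()
    ch = pd.Categorical(work["chrom"]).codes
    start = work["start"].to_numpy()
    end = work["end"].to_numpy()

    key = (bc.astype(np.int64) << 20) | ch.astype(np.int64)
    if np.any(np.diff(key) < 0) or np.any((np.diff(key) == 0) & (np.diff(start) < 0)):
        raise ValueError("alignments must be sorted by (barcode, chrom, start); "
                         "use sort_alignments() first")

    if len(work) == 0:
        mols = pd.DataFrame(columns=INFERRED_COLUMNS)
        return (mols, np.full(len(aln), -1)) if return_assignment else mols

    # running maximum of read ends within each (barcode, chrom) group defines
    # the current cluster end for the gap test
    new_group = np.concatenate([[True], np.diff(key) != 0])
    grp = np.cumsum(new_group) - 1
    run_end = pd.Series(end).groupby(grp).cummax().to_numpy()

    gap_break = np.concatenate(
        [[False], (start[1:] - run_end[:-1]) > gap_threshold])
    boundary = new_group | gap_break
    cluster = np.cumsum(boundary) - 1

    cl = pd.DataFrame({
        "cluster": cluster,
        "bc": bc,
        "ch": ch,
        "start": start,
        "end": end,
        "mapq": work["mapq"].to_numpy(),
    })
    agg = cl.groupby("cluster", sort=True).agg(
        bc=("bc", "first"), ch=("ch", "first"), start=("start", "min"),
        end=("end", "max"), n=("start", "size"), mean_mapq=("mapq", "mean"))
    # count read *pairs*: distinct read_ids if available, else rows
    if "read_id" in work.columns:
        pairs = (pd.DataFrame({"cluster": cluster,
                               "read_id": work["read_id"].to_numpy()})
                 .groupby("cluster")["read_id"].nunique())
        agg["n_pairs"] = pairs
    else:
        agg["n_pairs"] = agg["n"]

    keep = agg[agg["n"] >= min_reads].reset_index()
    barcode_cats = work["barcode"].cat.categories
    chrom_cats = pd.Categorical(work["chrom"]).categories
    mols = pd.DataFrame({
        "molecule_id": np.arange(len(keep), dtype=np.int64),
        "barcode": pd.Categorical.from_codes(keep["bc"].to_numpy(),
                                             categories=barcode_cats),
        "chrom": pd.Categorical.from_codes(keep["ch"].to_numpy(),
                                           categories=chrom_cats),
        "start": keep["start"].to_numpy(),
        "end": keep["end"].to_numpy(),
        "n_read_pairs": keep["n_pairs"].to_numpy(),
        "mean_mapq": keep["mean_mapq"].to_numpy(),
    })
    if not return_assignment:
        return mols
    cluster_to_mol = np.full(int(cluster.max()) + 1 if len(cluster) else 0, -1,
                             dtype=np.int64)
    cluster_to_mol[keep["cluster"].to_numpy()] = mols["molecule_id"].to_numpy()
    assignment = np.full(len(aln), -1, dtype=np.int64)
    assignment[aln["mapq"].to_numpy() >= min_mapq] = cluster_to_mol[cluster]
    return mols, assignment


def sort_alignments(aln: pd.DataFrame) -> pd.DataFrame:
    """Sort an alignment table by (barcode, chrom, start) for molecule
    inference."""
    codes = aln["barcode"].cat.codes
    ch = pd.Categorical(aln["chrom"]).codes
    order = np.lexsort((aln["start"].to_numpy(), ch, codes.to_numpy()))
    return aln.iloc[order].reset_index(drop=True)


def length_weighted_mean(lengths) -> float:
    """Length-weighted mean, sum(L_i^2) / sum(L_i): the expected length of the
    molecule underlying a uniformly chosen base of input DNA."""
    arr = np.asarray(lengths, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("length_weighted_mean of an empty set")
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    return float((arr ** 2).sum() / arr.sum())


def molecule_stats(molecules: pd.DataFrame) -> MoleculeStats:
    """Aggregate statistics of inferred molecules."""
    if len(molecules) == 0:
        raise ValueError("no molecules to summarize")
    lengths = (molecules["end"] - molecules["start"]).to_numpy()
    per_bc = molecules.groupby(
        molecules["barcode"].cat.codes, observed=True).size()
    return MoleculeStats(
        length_weighted_mean_length=length_weighted_mean(lengths),
        unweighted_mean_length=float(lengths.mean()),
        molecules_per_barcode=float(per_bc.mean()),
        n_molecules=int(len(molecules)),
    )
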