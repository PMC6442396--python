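"""Barcode-aware alignment disambiguation ("read-cloud rescue").

A read with several equally good candidate placements is usually unplaceable
from its own sequence.  But its barcode identifies the molecules already
inferred from confidently mapped same-barcode reads; a candidate that falls
inside (or near) one of those molecules is far more likely to be the true
origin — provided the repeat copies are far enough apart that they rarely share
a barcode.  We model this as a two-component mixture: with probability
``prior_new_molecule`` the read comes from an unseen molecule (any candidate
equally likely a priori), otherwise it belongs to a known same-barcode
molecule and only supported candidates are plausible:

    posterior_j  ∝  exp(score_j) * [p_new + (1 - p_new) * supported_j]

where ``supported_j`` is 1 when candidate j lies within ``support_window`` bp
of a same-barcode molecule.  The winning candidate's mapping quality is
recomputed from its posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AlignmentCandidate:
    """One candidate placement of a multi-mapping read."""

    chrom: str
    pos: int
    strand: int = 1
    alignment_score: float = 0.0  # log scale, higher is better
    n_mismatches: int = 0


@dataclass(frozen=True)
class RescueParams:
    support_window: int = 50_000
    prior_new_molecule: float = 0.1
    mapq_cap: int = 60

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_new_molecule < 1.0:
            raise ValueError("prior_new_molecule must be in (0, 1)")
        if self.support_window <= 0:
            raise ValueError("support_window must be positive")


def _supported(cand: AlignmentCandidate, barcode_molecules: pd.DataFrame,
               window: int) -> bool:
    if barcode_molecules is None or len(barcode_molecules) == 0:
        return False
    sel = barcode_molecules["chrom"] == cand.chrom
    if not sel.any():
        return False
    start = barcode_molecules.loc[sel, "start"].to_numpy()
    end = barcode_molecules.loc[sel, "end"].to_numpy()
    return bool(np.any((cand.pos >= start - window) & (cand.pos < end + window)))


def rescue_read(candidates: list[AlignmentCandidate],
                barcode_molecules: pd.DataFrame,
                params: RescueParams = RescueParams()
                ) -> tuple[AlignmentCandidate, float]:
    """Choose among candidate placements using same-barcode molecule support.

    Returns the maximum-posterior candidate and its normalized posterior.
    Ties are broken deterministically toward the lower (chrom, pos).
    """
    if not candidates:
        raise ValueError("no alignment candidates")
    scores = np.array([c.alignment_score for c in candidates], dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("alignment scores must be finite")
    support = np.array(
        [_supported(c, barcode_molecules, params.support_window)
         for c in candidates], dtype=np.float64)
    p_new = params.prior_new_molecule
    logw = scores + np.log(p_new + (1.0 - p_new) * support)
    logw -= logw.max()
    w = np.exp(logw)
    post = w / w.sum()
    order = sorted(range(len(candidates)),
                   key=lambda j: (-post[j], candidates[j].chrom, candidates[j].pos))
    best = order[0]
    return candidates[best], float(post[best])


def recalibrate_mapq(posterior: float, mapq_cap: int = 60) -> int:
    """Mapping quality from a placement posterior:
    min(cap, round(-10 log10(1 - posterior))); a posterior of 1 maps to the cap."""
    if not 0.0 < posterior <= 1.0:
        raise ValueError(f"posterior must be in (0, 1], got {posterior}")
    if posterior == 1.0:
        return int(mapq_cap)
    return int(min(mapq_cap, round(-10.0 * math.log10(1.0 - posterior))))


def decisive_score_margin(params: RescueParams) -> float:
    """Score lead above which barcode support can never change the winner.

    If candidate a leads candidate b by more than ``log(1/p_new)`` in alignment
    score, then even an unsupported a beats a fully supported b:
    ``exp(s_a) * p_new > exp(s_b) * 1``  whenever  ``s_a - s_b > -log(p_new)``.
    """
    return -math.log(params.prior_new_molecule)


def rescue_alignments(candidates: pd.DataFrame, molecules: pd.DataFrame,
                      params: RescueParams = RescueParams()) -> pd.DataFrame:
    """Apply rescue to a table of candidate placements.

    ``candidates`` has one row per (read_id, candidate): columns read_id,
    barcode, chrom, pos, strand, alignment_score.  ``molecules`` are inferred
    molecules from confidently mapped reads (first pass, high MapQ only), so
    the reads being rescued do not support themselves.  Returns one row per
    read: the chosen placement with posterior, recalibrated MapQ, and a
    ``rescued`` audit flag (True when barcode support changed the ranking
    relative to alignment score alone).
    """
    mol_by_bc = {bc: grp for bc, grp in molecules.groupby("barcode", observed=True)}
    rows = []
    for read_id, grp in candidates.groupby("read_id", sort=True):
        cands = [AlignmentCandidate(r.chrom, int(r.pos), int(getattr(r, "strand", 1)),
                                    float(r.alignment_score),
                                    int(getattr(r, "n_mismatches", 0)))
                 for r in grp.itertuples()]
        bc = grp["barcode"].iloc[0]
        chosen, post = rescue_read(cands, mol_by_bc.get(bc), params)
        naive = min(range(len(cands)),
                    key=lambda j: (-cands[j].alignment_score, cands[j].chrom,
                                   cands[j].pos))
        rows.append((read_id, bc, chosen.chrom, chosen.pos, chosen.strand,
                     post, recalibrate_mapq(post, params.mapq_cap),
                     cands[naive] is not chosen))
    return pd.DataFrame(rows, columns=["read_id", "barcode", "chrom", "pos",
                                       "strand", "posterior", "mapq", "rescued"])
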