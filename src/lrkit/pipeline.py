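"""End-to-end Linked-Read analysis on simulated data.

Chains the library stages — simulate, infer molecules, call and phase het
variants, call SVs, evaluate — with the default parameters of each module.
Used by the examples, the CLI, and the evaluation scripts; every stage remains
individually accessible for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate, molecules as mol_mod, phasing, simulate, svcall
from .config import SimConfig
from .genome import DiploidGenome, build_diploid_genome


@dataclass
class PipelineResult:
    config: SimConfig
    genome: DiploidGenome
    molecules_truth: pd.DataFrame
    alignments: pd.DataFrame
    molecules: pd.DataFrame              # inferred
    assignment: np.ndarray               # per-alignment inferred molecule id
    het_variants: pd.DataFrame
    observations: pd.DataFrame
    links: pd.DataFrame
    phased_variants: pd.DataFrame
    blocks: list = field(default_factory=list)
    sv_calls: pd.DataFrame | None = None


def simulate_dataset(config: SimConfig,
                     snv_positions: dict[str, np.ndarray] | None = None
                     ) -> tuple[DiploidGenome, pd.DataFrame, pd.DataFrame]:
    """Genome + truth molecules + truth alignments for one configuration."""
    rng = np.random.default_rng(config.seed)
    genome = build_diploid_genome(config, rng, snv_positions=snv_positions)
    mols = simulate.sample_molecules(genome, config, rng)
    aln = simulate.generate_read_pairs(mols, genome, config, rng)
    return genome, mols, aln


def run_pipeline(config: SimConfig,
                 snv_positions: dict[str, np.ndarray] | None = None,
                 call_svs: bool = False,
                 gap_threshold: int = mol_mod.DEFAULT_GAP_THRESHOLD,
                 min_reads: int = mol_mod.DEFAULT_MIN_READS) -> PipelineResult:
    """Simulate one dataset and run molecule inference, het calling, and
    phasing (plus SV calling on request) with default parameters."""
    genome, mols_truth, aln = simulate_dataset(config, snv_positions)
    aln_sorted = mol_mod.sort_alignments(aln)
    inferred, assignment = mol_mod.infer_molecules(
        aln_sorted, gap_threshold=gap_threshold, min_reads=min_reads,
        return_assignment=True)
    hets = phasing.call_het_variants(aln_sorted, genome.reference)
    obs = phasing.extract_observations(aln_sorted, hets, assignment)
    links = phasing.build_links(obs)
    phased, blocks = phasing.phase(hets, links)

    result = PipelineResult(config, genome, mols_truth, aln_sorted, inferred,
                            assignment, hets, obs, links, phased, blocks)
    if call_svs:
        result.sv_calls = call_structural_variants(result)
    return result


def call_structural_variants(result: PipelineResult,
                             window: int = svcall.DEFAULT_OVERLAP_WINDOW,
                             min_separation: int = svcall.DEFAULT_MIN_SEPARATION,
                             alpha: float = svcall.DEFAULT_ALPHA) -> pd.DataFrame:
    """Union of the barcode-overlap and coverage-segmentation detectors,
    deduplicated at 50% reciprocal overlap."""
    chrom_lengths = result.genome.chrom_lengths
    index = svcall.build_barcode_index(result.molecules, window, chrom_lengths)
    overlap_calls = svcall.barcode_overlap_scan(
        index, min_separation=min_separation, alpha=alpha,
        molecules=result.molecules)
    cov_calls = svcall.coverage_segmentation(
        result.molecules, chrom_lengths, min_size=30_000)
    return svcall.merge_call_sets(overlap_calls, cov_calls)


def truth_phased_frame(genome: DiploidGenome) -> pd.DataFrame:
    """Truth het SNVs with their orientation (haplotype carrying the alt)."""
    snvs = genome.het_snvs()
    return pd.DataFrame({"chrom": snvs["chrom"], "pos": snvs["pos"],
                         "orientation": snvs["haplotype"]})
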