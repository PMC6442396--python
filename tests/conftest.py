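"""Shared fixtures: simulated datasets reused across test modules.

The two session-scoped simulations are the study conditions for the
parameter-recovery checks: a 10 Mb diploid genome at ~1 het/kb with 50 kb
molecules, ~30x coverage and 0.1% base error, once without SVs (molecule /
genotyping / phasing recovery) and once with 20 planted large deletions plus
two balanced translocations (SV recovery).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lrkit import SimConfig
from lrkit.pipeline import PipelineResult, run_pipeline


def crit_config(**overrides) -> SimConfig:
    """Desk-scale study conditions: 2 x 5 Mb diploid, 1e-3 het SNVs, 50 kb
    exponential molecules, one molecule per partition on average, 0.8x
    per-molecule read coverage (=> ~30x read depth), 0.1% base error."""
    fields = dict(
        genome_length=5_000_000, n_chromosomes=2, het_snv_rate=1e-3,
        indel_rate=0.0, mean_molecule_length=50_000, n_partitions=7_500,
        molecules_per_partition_mean=1.0, barcode_whitelist_size=100_000,
        per_molecule_read_coverage=0.8, base_error_rate=1e-3, seed=1)
    fields.update(overrides)
    return SimConfig(**fields)


@pytest.fixture(scope="session")
def recovery_sim() -> PipelineResult:
    """SNV-only 10 Mb simulation through molecule inference and phasing."""
    return run_pipeline(crit_config())


@pytest.fixture(scope="session")
def sv_sim() -> PipelineResult:
    """10 Mb simulation with 20 heterozygous 50-200 kb deletions and 2
    balanced translocations, through SV calling."""
    sv_spec = ([("DEL", int(s), 1)
                for s in np.linspace(50_000, 200_000, 20)] + [("TRA", 0, 2)])
    return run_pipeline(crit_config(sv_spec=sv_spec, seed=2), call_svs=True)


@pytest.fixture(scope="session")
def small_sim() -> PipelineResult:
    """Fast 2 x 1 Mb simulation for tests that only need a realistic dataset."""
    return run_pipeline(crit_config(genome_length=1_000_000, n_partitions=1_500,
                                    seed=3))


def truth_orientation_frame(genome) -> pd.DataFrame:
    """Truth het SNVs with orientation = haplotype carrying the alt allele."""
    snvs = genome.het_snvs()
    return pd.DataFrame({"chrom": snvs["chrom"], "pos": snvs["pos"],
                         "orientation": snvs["haplotype"].astype(np.int64)})


def adjacent_pair_concordance(phased: pd.DataFrame, genome) -> tuple[float, int]:
    """Fraction of consecutive phased het pairs whose relative orientation
    matches truth (invariant to per-block global flips)."""
    truth = truth_orientation_frame(genome)
    m = (phased[phased["phase_set"] >= 0]
         .merge(truth, on=["chrom", "pos"], suffixes=("", "_truth")))
    conc = tot = 0
    for _, grp in m.groupby(["chrom", "phase_set"], sort=True):
        if len(grp) < 2:
            continue
        o = grp["orientation"].to_numpy()
        t = grp["orientation_truth"].to_numpy()
        conc += int(((np.diff(o) == 0) == (np.diff(t) == 0)).sum())
        tot += len(grp) - 1
    return (conc / tot if tot else 1.0), tot
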