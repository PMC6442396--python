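"""Simulation configuration for Linked-Read data generation.

The simulator emulates a droplet-partitioned barcoded library: high molecular
weight DNA molecules (tens of kb) are distributed into partitions, each
partition receives a unique barcode, and every molecule is sequenced shallowly
by barcoded short read pairs.  Defaults describe the platform regime (millions
of whitelist barcodes, >1e6 partitions, few molecules per partition); desk-scale
experiments override ``n_partitions`` and ``genome_length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


_SV_TYPES = {"DEL", "DUP", "INV", "TRA"}
_LENGTH_MODELS = {"exponential", "lognormal"}


@dataclass
class SimConfig:
    """Parameters of a Linked-Read simulation.

    Parameters
    ----------
    genome_length : int
        Reference length per chromosome, bp.
    n_chromosomes : int
        Number of chromosomes (named ``chr1`` .. ``chrN``).
    het_snv_rate : float
        Heterozygous SNV rate per bp (human-like samples: ~1e-3, i.e. one het
        site per 1-2 kb).
    indel_rate : float
        Heterozygous short indel (1-10 bp) rate per bp.
    sv_spec : list of (type, size, count)
        Structural variants to plant, all heterozygous.  ``type`` is one of
        DEL, DUP (tandem), INV, TRA (balanced reciprocal translocation; size
        is ignored for TRA).
    mean_molecule_length : float
        Mean input molecule length, bp.  Fresh DNA extractions run 50-100 kb.
    molecule_length_model : str
        ``exponential`` (fragmentation physics default) or ``lognormal``.
    lognormal_sigma : float
        Shape of the lognormal model (ignored for exponential).
    molecules_per_partition_mean : float
        Poisson mean of molecules loaded per partition.
    n_partitions : int
        Number of occupied partitions; each receives one whitelist barcode.
    barcode_whitelist_size : int
        Size of the barcode whitelist the partition barcodes are drawn from.
    per_molecule_read_coverage : float
        Fold read coverage of each molecule by its own read pairs.  Linked-Read
        libraries sequence each molecule shallowly (well below 1x) and rely on
        many overlapping molecules for depth.
    read_length : int
        Length of each mate, bp.
    insert_mean, insert_sd : float
        Normal model of the sequenced fragment (insert) size, bp.
    base_error_rate : float
        Per-base substitution error rate.
    seed : int
        Seed for all randomness; a fixed seed gives byte-identical outputs.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    het_snv_rate: float = 1e-3
    indel_rate: float = 1e-4
    sv_spec: list[tuple[str, int, int]] = field(default_factory=list)
    mean_molecule_length: float = 75_000.0
    molecule_length_model: str = "exponential"
    lognormal_sigma: float = 0.5
    molecules_per_partition_mean: float = 3.0
    n_partitions: int = 1_200_000
    barcode_whitelist_size: int = 4_000_000
    per_molecule_read_coverage: float = 0.8
    read_length: int = 150
    insert_mean: float = 385.0
    insert_sd: float = 50.0
    base_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("het_snv_rate", "indel_rate", "base_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if self.mean_molecule_length <= 2 * self.insert_mean:
            raise ValueError(
                "mean_molecule_length must exceed 2 x insert_mean "
                f"({self.mean_molecule_length} <= {2 * self.insert_mean})"
            )
        if self.molecule_length_model not in _LENGTH_MODELS:
            raise ValueError(f"unknown molecule_length_model {self.molecule_length_model!r}")
        if self.n_partitions > self.barcode_whitelist_size:
            raise ValueError("n_partitions cannot exceed barcode_whitelist_size")
        if self.molecules_per_partition_mean < 0:
            raise ValueError("molecules_per_partition_mean must be >= 0")
        if self.per_molecule_read_coverage < 0:
            raise ValueError("per_molecule_read_coverage must be >= 0")
        if self.read_length <= 0 or self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 x read_length")
        for sv in self.sv_spec:
            svtype, size, count = sv
            if svtype not in _SV_TYPES:
                raise ValueError(f"unknown SV type {svtype!r}")
            if svtype != "TRA" and size <= 0:
                raise ValueError(f"SV size must be positive, got {size}")
            if count < 0:
                raise ValueError("SV count must be >= 0")
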