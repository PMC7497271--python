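"""Copy-number arithmetic from whole-genome read proportions.

The estimator follows the standard read-proportion scheme for tandem
repeat dosage: the genome proportion GP is the percentage of reads
mapping to the 18S reference; the genome space GS = genome size (Mb) x
GP / 100 is the megabases of genome occupied by the family; and the copy
number per 1C is GS divided by the size of one 18S unit (0.00181 Mb,
i.e. the 1.81-kb reference).  All arithmetic runs on unrounded
intermediates; rounding happens only at reporting (GP and GS to two
decimals, copies half-away-from-zero to the nearest integer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mapper import AlignerConfig, map_reads
from .synthetic import ReadSet

#: Megabases per picogram of DNA (Dolezel conversion: 1 pg = 978 Mb).
MB_PER_PG = 978.0

#: Size of the 18S reference unit in Mb (1.81 kb).
REFERENCE_UNIT_MB = 0.00181


@dataclass
class CopyNumberEstimate:
    mapped_reads: int
    total_reads: int
    genome_size_mb: float
    reference_unit_mb: float = REFERENCE_UNIT_MB

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.mapped_reads > self.total_reads or self.mapped_reads < 0:
            raise ValueError("mapped_reads must be in [0, total_reads]")

    @property
    def gp_percent(self) -> float:
        """Unrounded genome proportion, in percent."""
        return genome_proportion(self.mapped_reads, self.total_reads)

    @property
    def gs_mb(self) -> float:
        """Unrounded genome space, in Mb."""
        return genome_space(self.gp_percent, self.genome_size_mb)

    @property
    def copies_per_1c(self) -> int:
        return copy_number(self.gs_mb, self.reference_unit_mb)

    def report_row(self) -> dict:
        return {
            "mapped": self.mapped_reads,
            "total": self.total_reads,
            "gp_percent": round(self.gp_percent, 2),
            "gs_mb": round(self.gs_mb, 2),
            "copies_per_1c": self.copies_per_1c,
        }


def genome_proportion(mapped_reads: int, total_reads: int) -> float:
    """GP = 100 x mapped / total, full precision."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mapped_reads > total_reads:
        raise ValueError("mapped_reads exceeds total_reads")
    return 100.0 * mapped_reads / total_reads


def genome_space(gp_percent: float, genome_size_mb: float) -> float:
    """GS = genome size (Mb) x GP / 100, full precision."""
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    return genome_size_mb * gp_percent / 100.0


def copy_number(gs_mb: float, reference_unit_mb: float = REFERENCE_UNIT_MB) -> int:
    """Copies per 1C, rounded half away from zero on the unrounded GS."""
    if reference_unit_mb <= 0:
        raise ValueError("reference_unit_mb must be positive")
    value = gs_mb / reference_unit_mb
    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


def pg_to_mb(picograms: float) -> float:
    """Convert 1C DNA content from pg to Mb (1 pg = 978 Mb)."""
    if picograms < 0:
        raise ValueError("picograms must be non-negative")
    return picograms * MB_PER_PG


def estimate_copies(
    reads: ReadSet,
    reference_18s: str,
    genome_size_mb: float,
    aligner_config: AlignerConfig | None = None,
    reference_unit_mb: float | None = None,
) -> CopyNumberEstimate:
    """Full pipeline: map reads to the 18S reference, then the GP chain.

    ``reference_18s`` must be the 18S subregion sequence (not the whole
    unit); the default unit size constant corresponds to the 1.81-kb 18S
    reference, and ``reference_unit_mb`` should be overridden when a
    scaled-down reference is used.
    """
    if reference_unit_mb is None:
        reference_unit_mb = len(reference_18s) / 1e6
    mapping = map_reads(reads, reference_18s, aligner_config, circular=False)
    return CopyNumberEstimate(
        mapped_reads=mapping.mapped_read_count,
        total_reads=mapping.total_read_count,
        genome_size_mb=genome_size_mb,
        reference_unit_mb=reference_unit_mb,
    )
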