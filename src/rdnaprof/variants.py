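"""Per-position variant calling on tandem-repeat mappings.

Variants are called from the allele tallies of a :class:`MappingResult`
using three thresholds: minimum coverage at the position (default 300),
minimum reads supporting the allele (default 30) and minimum allele
frequency (0.10 for high-frequency calls, 0.01 for low-frequency calls).
Frequency is the supporting count divided by the coverage at the position,
computed per alternative allele.  Deletions count spanning reads as
coverage; insertions are left-anchored to the reference base on their
left.  Windowed summaries reproduce the per-100-bp SNP-density view used
for tandem rDNA arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapper import MappingResult

_BASE_ROWS = "ACGT"


@dataclass
class VariantConfig:
    min_coverage: int = 300
    min_count: int = 30
    min_frequency: float = 0.10

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_count < 0 or self.min_frequency < 0:
            raise ValueError("variant thresholds must be non-negative")


@dataclass
class VariantCall:
    position: int  # 1-based
    ref: str
    alt: str  # substitution base, '-' for deletion, or inserted sequence
    count: int
    coverage: int
    subregion: str | None = None
    type: str = "substitution"  # or "InDel"

    def __post_init__(self) -> None:
        if self.count > self.coverage:
            raise ValueError("supporting count exceeds coverage")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive for a call")

    @property
    def frequency(self) -> float:
        return self.count / self.coverage


def call_variants(
    mapping: MappingResult, config: VariantConfig | None = None
) -> list[VariantCall]:
    """Emit all calls passing the coverage/count/frequency thresholds.

    Multiple alternative alleles at a position yield one call each.
    Subregion annotation is attached when the mapping carries an annotated
    unit; calls outside any annotated interval get ``subregion=None``.
    """
    config = config or VariantConfig()
    calls: list[VariantCall] = []
    coverage = mapping.coverage
    tallies = mapping.tallies
    unit = mapping.unit
    for pos0 in range(mapping.unit_length):
        cov = int(coverage[pos0])
        if cov < config.min_coverage:
            continue
        position = pos0 + 1
        ref_base = mapping.reference[pos0] if mapping.reference else "N"
        subregion = unit.subregion_of(position) if unit is not None else None
        for b, base in enumerate(_BASE_ROWS):
            if base == ref_base:
                continue
            count = int(tallies[pos0, b])
            if count >= config.min_count and count / cov >= config.min_frequency:
                calls.append(VariantCall(position, ref_base, base, count, cov,
                                         subregion, "substitution"))
        del_count = int(tallies[pos0, 4])
        if del_count >= config.min_count and del_count / cov >= config.min_frequency:
            calls.append(VariantCall(position, ref_base, "-", del_count, cov,
                                     subregion, "InDel"))
    for anchor, alleles in sorted(mapping.insertions.items()):
        pos0 = anchor - 1
        cov = int(coverage[pos0])
        if cov < config.min_coverage:
            continue
        ref_base = mapping.reference[pos0] if mapping.reference else "N"
        subregion = unit.subregion_of(anchor) if unit is not None else None
        for inserted, count in sorted(alleles.items()):
            if count >= config.min_count and count / cov >= config.min_frequency:
                calls.append(VariantCall(anchor, ref_base, ref_base + inserted,
                                         count, cov, subregion, "InDel"))
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls


def window_counts(
    variants: list[VariantCall], unit_length: int, window_width: int = 100
) -> tuple[np.ndarray, int]:
    """Variant counts in non-overlapping windows [1-w], [w+1-2w], ...

    Returns the per-window counts (the last window may be short) and the
    maximum per-window count (the density-plot y-axis cap).  Counts sum to
    the number of variants.
    """
    if window_width < 1:
        raise ValueError("window_width must be >= 1")
    n_windows = (unit_length + window_width - 1) // window_width
    counts = np.zeros(n_windows, dtype=np.int64)
    for call in variants:
        counts[(call.position - 1) // window_width] += 1
    return counts, int(counts.max()) if n_windows else 0


def classify_variant_types(variants: list[VariantCall]) -> tuple[int, int]:
    """Exhaustive, exclusive partition into (substitutions, InDels)."""
    n_subst = sum(1 for v in variants if v.type == "substitution")
    return n_subst, len(variants) - n_subst


def write_vcf(variants: list[VariantCall], reference_name: str, path) -> None:
    """Minimal VCF v4.2 with DP/AD/AF info fields."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">\n')
        handle.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Allele depth">\n')
        handle.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if v.alt == "-":  # deletion in anchored VCF style
                ref_field, alt_field = v.ref + "N", v.ref
            else:
                ref_field, alt_field = v.ref, v.alt
            handle.write(
                f"{reference_name}\t{v.position}\t.\t{ref_field}\t{alt_field}\t.\t"
                f"PASS\tDP={v.coverage};AD={v.count};AF={v.frequency:.4f}\n"
            )


def write_variants_tsv(variants: list[VariantCall], path) -> None:
    with open(path, "w") as handle:
        handle.write("position\tsubregion\tref\talt\ttype\tcount\tcoverage\tfrequency\n")
        for v in variants:
            handle.write(
                f"{v.position}\t{v.subregion or 'NA'}\t{v.ref}\t{v.alt}\t{v.type}\t"
                f"{v.count}\t{v.coverage}\t{v.frequency:.4f}\n"
            )
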