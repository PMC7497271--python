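"""End-to-end orchestration: simulate -> trim -> map -> variants -> dosage
-> homoeologue ratio -> digest, with deterministic seed fan-out.

A single :class:`RunConfig` drives every stage.  The global seed is fanned
out into named per-stage substreams (hash of ``(seed, stage index)``), so
each stage is individually reproducible regardless of execution order,
and a full run under a fixed seed is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import digest as digest_mod
from . import dosage, homoeologue, read_prep, synthetic, variants
from .mapper import AlignerConfig, consensus_from_mapping, map_reads
from .read_prep import TrimConfig
from .variants import VariantConfig

logger = logging.getLogger("rdnaprof")

_STAGES = ("units", "array", "reads", "trim", "map", "variants",
           "dosage", "homoeologue", "digest")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2**31)."""
    index = _STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, index]).generate_state(1)[0]
               % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    #: when set, reads are loaded from this FASTQ instead of simulated
    #: (genome_size_mb must then be given for the dosage stage)
    input_fastq: str | None = None
    # simulation
    n_units: int = 20
    mutation_mode: str = "spacer_biased"
    mutation_rate: float = 0.002
    n_reads: int = 1200
    read_length: int = 100
    error_rate: float = 0.002
    background_genome_size: int = 120_000
    s_fraction: float = 0.26
    # analysis
    trim: TrimConfig = field(default_factory=TrimConfig)
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    variant_min_coverage: int = 10
    variant_min_count: int = 3
    window_width: int = 100
    fragment_sample_size: int = 222
    #: size of the ITS1-overlapping read pool used for homoeologue typing
    #: (emulates BLAST recruitment from the full archive, which extracts
    #: only reads homologous to the diagnostic region)
    fragment_pool_reads: int = 1200
    enzymes: tuple[str, ...] = ("BglII", "PstI", "XhoI", "MluI")
    genome_size_mb: float | None = None  # default: simulated genome size

    def validate(self) -> None:
        if self.n_units < 1 or self.n_reads < 1:
            raise ValueError("n_units and n_reads must be positive")
        if not 0.0 <= self.s_fraction <= 1.0:
            raise ValueError("s_fraction must be in [0, 1]")
        if self.input_fastq is not None and self.genome_size_mb is None:
            raise ValueError(
                "genome_size_mb is required when reads are loaded from a "
                "file (it cannot be derived from simulation parameters)"
            )
        synthetic.MutationModel(self.mutation_mode, self.mutation_rate)


def run_profile(config: RunConfig) -> dict:
    """Execute all stages in fixed order and return the summary dict.

    Any stage failure aborts with the stage name attached.  When
    ``config.outdir`` is set, per-stage artifacts (FASTA/FASTQ/TSV/VCF)
    and the JSON summary are written there.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "units"
    try:
        d_unit, s_unit = synthetic.make_default_units(
            seed=stage_seed(config.seed, "units")
        )
        summary["stages"]["units"] = {
            "d_length": d_unit.length, "s_length": s_unit.length,
        }

        stage = "array"
        model = synthetic.MutationModel(
            config.mutation_mode, config.mutation_rate,
            seed=stage_seed(config.seed, "array"),
        )
        d_variants = synthetic.mutate_units(d_unit, config.n_units, model)
        s_model = synthetic.MutationModel(
            config.mutation_mode, config.mutation_rate,
            seed=stage_seed(config.seed, "array") + 1,
        )
        s_variants = synthetic.mutate_units(s_unit, config.n_units, s_model)

        stage = "reads"
        if config.input_fastq is not None:
            reads = synthetic.ReadSet.read_fastq(config.input_fastq)
        else:
            n_d, n_s = len(d_variants), len(s_variants)
            # weights are copy numbers: scale so the array keeps its
            # physical size while the S share of rDNA bp is s_fraction
            array_bp = n_d * d_unit.length + n_s * s_unit.length
            weights = (
                [(1.0 - config.s_fraction) * array_bp / (n_d * d_unit.length)]
                * n_d
                + [config.s_fraction * array_bp / (n_s * s_unit.length)] * n_s
            )
            labels = ["D"] * n_d + ["S"] * n_s
            reads = synthetic.simulate_reads(
                d_variants + s_variants,
                weights,
                n_reads=config.n_reads,
                read_length=config.read_length,
                error_rate=config.error_rate,
                background_genome_size=config.background_genome_size,
                seed=stage_seed(config.seed, "reads"),
                labels=labels,
            )
        if outdir:
            reads.write_fastq(outdir / "reads.fastq")
            reads.write_truth(outdir / "truth_labels.tsv")

        stage = "trim"
        kept, trim_report = read_prep.filter_reads(reads, config.trim)
        summary["stages"]["trim"] = trim_report

        stage = "map"
        mapping = map_reads(kept, d_unit, config.aligner, circular=True)
        summary["stages"]["map"] = {
            "mapped": mapping.mapped_read_count,
            "total": mapping.total_read_count,
        }
        consensus = consensus_from_mapping(mapping)
        summary["stages"]["map"]["consensus_length"] = len(consensus)

        stage = "variants"
        high = variants.call_variants(mapping, VariantConfig(
            config.variant_min_coverage, config.variant_min_count, 0.10))
        low = variants.call_variants(mapping, VariantConfig(
            config.variant_min_coverage, config.variant_min_count, 0.01))
        win_high, max_high = variants.window_counts(
            high, d_unit.length, config.window_width)
        summary["stages"]["variants"] = {
            "n_high_frequency": len(high),
            "n_low_frequency": len(low),
            "max_per_window_high": max_high,
            "window_counts_high": [int(x) for x in win_high],
        }
        if outdir:
            variants.write_vcf(high, d_unit.name, outdir / "variants_high.vcf")
            variants.write_variants_tsv(high, outdir / "variants_high.tsv")

        stage = "dosage"
        genome_bp = config.background_genome_size + sum(
            len(v) for v in d_variants + s_variants
        )
        genome_size_mb = (
            config.genome_size_mb
            if config.genome_size_mb is not None
            else genome_bp / 1e6
        )
        estimate = dosage.estimate_copies(
            kept, d_unit.subregion_sequence("18S"), genome_size_mb,
            config.aligner,
        )
        summary["stages"]["dosage"] = estimate.report_row()

        stage = "homoeologue"
        d_its1, s_its1 = synthetic.aligned_its1_pair(d_unit, s_unit)
        window = homoeologue.select_diagnostic_window(d_its1, s_its1)
        # recruitment pool: reads overlapping the ITS1 region, mirroring
        # BLAST recruitment of window-homologous reads from the archive
        pool = _simulate_its1_pool(
            d_variants, s_variants, d_unit, s_unit, config,
            seed=stage_seed(config.seed, "homoeologue") + 1,
        )
        recruited = homoeologue.recruit_fragments(pool, window)
        n_sample = min(config.fragment_sample_size, len(recruited))
        sampled = homoeologue.sample_fragments(
            recruited, n_sample, seed=stage_seed(config.seed, "homoeologue"))
        sampled, ratio = homoeologue.classify_fragments(sampled, window)
        summary["stages"]["homoeologue"] = {
            "window_start": window.start,
            "window_divergence": window.divergence,
            "n_recruited": len(recruited),
            "n_sampled": n_sample,
            **{k: (round(v, 4) if isinstance(v, float) else v)
               for k, v in ratio.items()},
        }
        for family in ("D", "S"):
            seqs = [seq for fid, seq in sampled.fragments
                    if sampled.labels.get(fid) == family]
            if seqs:
                stat = homoeologue.haplotype_diversity(seqs)
                summary["stages"]["homoeologue"][f"diversity_{family}"] = round(
                    stat.diversity, 4)
        if outdir:
            homoeologue.write_fragments_fasta(sampled, outdir / "fragments.fasta")

        stage = "digest"
        digest_summary = {}
        for name in config.enzymes:
            enzyme = digest_mod.ENZYMES[name]
            per_unit = {}
            for unit in (d_unit, s_unit):
                sites = digest_mod.find_sites(unit, enzyme)
                pattern = digest_mod.digest_tandem(
                    unit.length, sites, config.n_units)
                per_unit[unit.genome_label] = {
                    "sites": sites,
                    "fragments": sorted(pattern.lengths()),
                }
            digest_summary[name] = per_unit
        amplicons = [
            (u.genome_label, _its1_amplicon(u)) for u in (d_unit, s_unit)
        ]
        digest_summary["MluI_CAPS"] = digest_mod.caps_predict(amplicons, "MluI")
        summary["stages"]["digest"] = digest_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir:
        (outdir / "summary.json").write_text(summary_json(summary))
    return summary


def _simulate_its1_pool(
    d_variants, s_variants, d_unit, s_unit, config: RunConfig, seed: int
) -> synthetic.ReadSet:
    """Reads drawn from the ITS1 regions of the array variants.

    The real workflow recruits window-homologous reads from the whole
    archive; simulating the ITS1-overlapping subset directly gives the
    same pool without generating the uninformative remainder of the
    genome.  Family shares follow the configured S fraction.
    """
    flank = config.read_length - 1

    def region(variant: str, unit: synthetic.RDNAUnit) -> str:
        start, end = unit.subregions["ITS1"]
        return variant[max(0, start - 1 - flank) : end + flank]

    regions = [region(v, d_unit) for v in d_variants] + [
        region(v, s_unit) for v in s_variants
    ]
    labels = ["D"] * len(d_variants) + ["S"] * len(s_variants)
    weights = [
        (1.0 - config.s_fraction) / (len(d_variants) * len(r))
        for r in regions[: len(d_variants)]
    ] + [
        config.s_fraction / (len(s_variants) * len(r))
        for r in regions[len(d_variants) :]
    ]
    return synthetic.simulate_reads(
        regions, weights,
        n_reads=config.fragment_pool_reads,
        read_length=config.read_length,
        error_rate=config.error_rate,
        seed=seed,
        labels=labels,
        id_prefix="its1",
    )


def _its1_amplicon(unit: synthetic.RDNAUnit, flank: int = 30) -> str:
    """PCR amplicon spanning the 18S 3' end, ITS1 and the 5.8S 5' end."""
    its1_start, its1_end = unit.subregions["ITS1"]
    return unit.sequence[its1_start - 1 - flank : its1_end + flank]


def summary_json(summary: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a run summary."""
    return json.dumps(summary, sort_keys=True, indent=1, default=float)


def table1_report(rows: list[tuple[str, int, int, float]]) -> pd.DataFrame:
    """Copy-number report from (label, mapped, total, genome Mb) rows.

    GP and GS are reported to two decimals and copies as an integer; all
    arithmetic runs on unrounded intermediates.
    """
    out = []
    for label, mapped, total, genome_mb in rows:
        estimate = dosage.CopyNumberEstimate(mapped, total, genome_mb)
        out.append({"genotype": label, **estimate.report_row()})
    columns = ["genotype", "mapped", "total", "gp_percent", "gs_mb",
               "copies_per_1c"]
    return pd.DataFrame(out, columns=columns)


def write_table1_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
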