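"""Synthetic 35S rDNA units, tandem-array heterogeneity and read simulation.

A 35S rDNA unit is modelled as the ordered concatenation of six subregions
(18S, ITS1, 5.8S, ITS2, 25S, IGS) with restriction-enzyme motifs planted at
planned positions.  Two unit families are supported, mirroring the two
homoeologous arrays of an allotetraploid: a D-like unit of 8084 bp and an
S-like unit of 9215 bp whose coding regions are strongly conserved while the
spacers (ITS1/ITS2/IGS) are diverged.

Intragenomic heterogeneity within an array is emulated by two mutation
regimes: ``spacer_biased`` (substitutions confined to the non-coding
subregions, the signature of concerted evolution) and ``uniform``
(position-independent substitutions across the whole unit, the signature of
pseudogenised copies).

Reads are drawn from a circular tandem-unit model (wrap-around substrings),
optionally diluted with unrelated background sequence so that the rDNA
genome proportion is controllable, and carry per-base error probabilities
and ground-truth source labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUBREGION_ORDER = ("18S", "ITS1", "5.8S", "ITS2", "25S", "IGS")

#: Recognition motifs of the enzymes used throughout the analysis.
ENZYME_MOTIFS = {
    "BglII": "AGATCT",
    "PstI": "CTGCAG",
    "XhoI": "CTCGAG",
    "MluI": "ACGCGT",
}

# Default geometry.  Unit totals (8084 / 9215 bp) and the 18S length
# (1.81 kb) are fixed by the reference consensus lengths; the remaining
# subregion lengths are free parameters chosen to be realistic for a grass.
D_UNIT_LENGTH = 8084
S_UNIT_LENGTH = 9215
D_SUBREGION_LENGTHS = {
    "18S": 1810, "ITS1": 220, "5.8S": 164, "ITS2": 230, "25S": 3376, "IGS": 2284,
}
S_SUBREGION_LENGTHS = {
    "18S": 1810, "ITS1": 225, "5.8S": 164, "ITS2": 235, "25S": 3376, "IGS": 3405,
}

# Planned restriction sites (1-based motif start positions).  Both unit
# families carry two BglII sites inside the 25S gene spaced 1335 bp apart,
# reproducing the 1.3 kb / ~6.7-7.9 kb tandem fragment pair; PstI sits in
# ITS2 (plus a second IGS site in the S family); XhoI has a single site in
# the 25S gene of both; MluI is diagnostic, present only in the D ITS1.
D_SITE_PLAN = [
    ("MluI", 1900),
    ("PstI", 2300),
    ("BglII", 3850),
    ("XhoI", 4000),
    ("BglII", 5185),
]
S_SITE_PLAN = [
    ("PstI", 2300),
    ("BglII", 3850),
    ("XhoI", 4000),
    ("BglII", 5185),
    ("PstI", 6200),
]

_BASES = np.array(list("ACGT"))
CODING_SUBREGIONS = ("18S", "5.8S", "25S")
SPACER_SUBREGIONS = ("ITS1", "ITS2", "IGS")


class PlacementError(ValueError):
    """Raised when a planned motif cannot be placed in a unit template."""


@dataclass
class RDNAUnit:
    """An annotated 35S rDNA unit sequence.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence over ``ACGT``.
    genome_label : str
        ``"D"`` or ``"S"``.
    subregions : dict
        Map subregion name -> (start, end), 1-based inclusive.  The six
        subregions must tile ``[1, len(sequence)]`` in canonical order.
    site_plan : list of (str, int)
        Planned restriction sites as (enzyme name, 1-based motif start).
    """

    sequence: str
    genome_label: str
    subregions: dict[str, tuple[int, int]]
    site_plan: list[tuple[str, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"{self.genome_label}_unit"
        if self.length <= 0:
            raise ValueError("unit length must be positive")
        expected_start = 1
        for sub in SUBREGION_ORDER:
            if sub not in self.subregions:
                raise ValueError(f"missing subregion {sub}")
            start, end = self.subregions[sub]
            if start != expected_start or end < start:
                raise ValueError(
                    f"subregions must tile the unit in order; {sub} starts at "
                    f"{start}, expected {expected_start}"
                )
            expected_start = end + 1
        if expected_start != self.length + 1:
            raise ValueError("subregions do not tile the full unit")
        for enzyme, start in self.site_plan:
            motif = ENZYME_MOTIFS[enzyme]
            found = self.sequence[start - 1 : start - 1 + len(motif)]
            if found != motif:
                raise ValueError(
                    f"planned {enzyme} motif absent at {start}: found {found!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subregion_sequence(self, name: str) -> str:
        start, end = self.subregions[name]
        return self.sequence[start - 1 : end]

    def subregion_of(self, position: int) -> str | None:
        """Subregion containing a 1-based position, or None if outside."""
        for name, (start, end) in self.subregions.items():
            if start <= position <= end:
                return name
        return None


@dataclass
class MutationModel:
    """Intragenomic substitution regime for a tandem array.

    ``spacer_biased`` confines substitutions to ITS1/ITS2/IGS; ``uniform``
    draws them position-independently over the whole unit.
    """

    mode: str = "spacer_biased"
    per_site_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("spacer_biased", "uniform"):
            raise ValueError(f"unknown mutation mode {self.mode!r}")
        if not 0.0 <= self.per_site_rate <= 1.0:
            raise ValueError("per_site_rate must be in [0, 1]")


@dataclass
class Read:
    id: str
    sequence: str
    perr: np.ndarray  # per-base error probability, in (0, 1)

    def __post_init__(self) -> None:
        self.perr = np.asarray(self.perr, dtype=float)
        if len(self.perr) != len(self.sequence):
            raise ValueError("per-base error vector length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """A collection of reads with optional ground-truth source labels."""

    reads: list[Read] = field(default_factory=list)
    truth_labels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def write_fastq(self, path) -> None:
        records = []
        for read in self.reads:
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = [
                _phred_from_perr(p) for p in read.perr
            ]
            records.append(rec)
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fastq")

    @classmethod
    def read_fastq(cls, path, truth_labels: dict[str, str] | None = None) -> "ReadSet":
        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            perr = np.array([10.0 ** (-q / 10.0) for q in quals])
            reads.append(Read(rec.id, str(rec.seq), perr))
        return cls(reads=reads, truth_labels=dict(truth_labels or {}))

    def write_truth(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("read_id\tlabel\n")
            for read_id, label in self.truth_labels.items():
                handle.write(f"{read_id}\t{label}\n")


def _phred_from_perr(perr: float) -> int:
    return int(min(60, max(0, round(-10.0 * math.log10(max(perr, 1e-6))))))


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _from_str(sequence: str) -> np.ndarray:
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([lookup[b] for b in sequence], dtype=np.int64)


def _plant_and_scrub(
    codes: np.ndarray,
    site_plan: list[tuple[str, int]],
    exclude_motifs: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Plant planned motifs, then remove spurious occurrences.

    Spurious occurrences of any planned or excluded motif are destroyed by
    substituting one base inside them (never touching a planted interval);
    the scan repeats until the sequence is clean.
    """
    length = len(codes)
    planted: list[tuple[int, int]] = []  # 0-based [start, end) intervals
    for enzyme, start in sorted(site_plan, key=lambda item: item[1]):
        motif = ENZYME_MOTIFS[enzyme]
        lo = start - 1
        hi = lo + len(motif)
        if lo < 0 or hi > length:
            raise PlacementError(f"{enzyme} site at {start} outside the unit")
        for plo, phi in planted:
            if lo < phi and plo < hi:
                raise PlacementError(
                    f"{enzyme} site at {start} overlaps another planned motif"
                )
        codes[lo:hi] = _from_str(motif)
        planted.append((lo, hi))

    protected = np.zeros(length, dtype=bool)
    for lo, hi in planted:
        protected[lo:hi] = True

    motifs = {ENZYME_MOTIFS[enz] for enz, _ in site_plan}
    motifs.update(exclude_motifs)
    planted_starts = {
        (ENZYME_MOTIFS[enz], start - 1) for enz, start in site_plan
    }
    for _ in range(200):  # convergence guard; each pass strictly removes hits
        dirty = False
        sequence = _to_str(codes)
        for motif in sorted(motifs):
            found = sequence.find(motif)
            while found != -1:
                if (motif, found) not in planted_starts:
                    free = [
                        pos
                        for pos in range(found, found + len(motif))
                        if not protected[pos]
                    ]
                    if not free:
                        raise PlacementError(
                            f"cannot scrub motif {motif} at {found + 1}: all "
                            "bases belong to planned sites"
                        )
                    pos = free[len(free) // 2]
                    choices = [b for b in range(4) if b != codes[pos]]
                    codes[pos] = choices[rng.integers(0, 3)]
                    dirty = True
                found = sequence.find(motif, found + 1)
        if not dirty:
            return codes
    raise PlacementError("motif scrubbing did not converge")


def _default_geometry(genome_label: str):
    if genome_label == "D":
        return D_UNIT_LENGTH, dict(D_SUBREGION_LENGTHS), list(D_SITE_PLAN)
    if genome_label == "S":
        return S_UNIT_LENGTH, dict(S_SUBREGION_LENGTHS), list(S_SITE_PLAN)
    raise ValueError(f"genome_label must be 'D' or 'S', got {genome_label!r}")


def subregions_from_lengths(lengths: dict[str, int]) -> dict[str, tuple[int, int]]:
    intervals = {}
    cursor = 1
    for sub in SUBREGION_ORDER:
        sub_len = lengths[sub]
        intervals[sub] = (cursor, cursor + sub_len - 1)
        cursor += sub_len
    return intervals


def build_unit_template(
    genome_label: str,
    total_length: int | None = None,
    subregion_lengths: dict[str, int] | None = None,
    site_plan: list[tuple[str, int]] | None = None,
    seed: int = 0,
    base_sequence: str | None = None,
    exclude_motifs: list[str] | None = None,
) -> RDNAUnit:
    """Build an annotated unit template with planted restriction motifs.

    With all defaults the D template is 8084 bp and the S template is
    9215 bp with BglII motifs starting at 3850 and 5185.  ``base_sequence``
    substitutes a caller-provided backbone for the random one (motifs are
    still planted and spurious occurrences scrubbed).
    """
    default_total, default_lengths, default_plan = _default_geometry(genome_label)
    if total_length is None:
        total_length = default_total
    if subregion_lengths is None:
        subregion_lengths = default_lengths
    if site_plan is None:
        site_plan = default_plan

    if sum(subregion_lengths[s] for s in SUBREGION_ORDER) != total_length:
        raise ValueError("subregion lengths do not sum to total_length")

    rng = np.random.default_rng(seed)
    if base_sequence is None:
        codes = _random_sequence(rng, total_length)
    else:
        if len(base_sequence) != total_length:
            raise ValueError("base_sequence length does not match total_length")
        codes = _from_str(base_sequence)

    codes = _plant_and_scrub(codes, site_plan, list(exclude_motifs or []), rng)
    return RDNAUnit(
        sequence=_to_str(codes),
        genome_label=genome_label,
        subregions=subregions_from_lengths(subregion_lengths),
        site_plan=sorted(site_plan, key=lambda item: item[1]),
    )


def _mutable_positions(unit: RDNAUnit, mode: str) -> np.ndarray:
    """0-based positions eligible for substitution under the regime."""
    if mode == "uniform":
        return np.arange(unit.length)
    positions = []
    for sub in SPACER_SUBREGIONS:
        start, end = unit.subregions[sub]
        positions.append(np.arange(start - 1, end))
    return np.concatenate(positions)


def mutate_units(
    template: RDNAUnit, n_units: int, model: MutationModel
) -> list[str]:
    """Derive ``n_units`` array-member sequences from a template.

    Each eligible position mutates independently with probability
    ``model.per_site_rate``; eligibility depends on the regime (spacers
    only, or the whole unit).  Substitutions are to a uniformly chosen
    different base.  Returns plain sequences (annotation stays with the
    template, since lengths are preserved).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(model.seed)
    eligible = _mutable_positions(template, model.mode)
    base_codes = _from_str(template.sequence)
    variants = []
    for _ in range(n_units):
        codes = base_codes.copy()
        hits = eligible[rng.random(len(eligible)) < model.per_site_rate]
        for pos in hits:
            choices = [b for b in range(4) if b != codes[pos]]
            codes[pos] = choices[rng.integers(0, 3)]
        variants.append(_to_str(codes))
    return variants


def simulate_reads(
    units: list[str] | list[RDNAUnit],
    unit_weights: list[float] | None,
    n_reads: int,
    read_length: int = 100,
    error_rate: float = 0.002,
    background_genome_size: int = 0,
    seed: int = 0,
    labels: list[str] | None = None,
    id_prefix: str = "read",
) -> ReadSet:
    """Simulate Illumina-like reads from a circular tandem-unit model.

    Each rDNA read is a wrap-around substring of one source unit (the unit
    is treated as one turn of the tandem circle, so reads may span the
    IGS/18S junction).  With ``background_genome_size`` > 0, reads are drawn
    from unrelated uniform-random sequence with probability
    ``background / (background + array bp)``, making the rDNA genome
    proportion controllable.  Substitution errors are applied at a constant
    per-base ``error_rate``; the recorded per-base error probabilities are
    the Phred-quantised equivalent so that FASTQ round-trips are exact.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    sequences = [u.sequence if isinstance(u, RDNAUnit) else u for u in units]
    if labels is None:
        labels = [
            u.genome_label if isinstance(u, RDNAUnit) else "rDNA" for u in units
        ]
    if unit_weights is None:
        unit_weights = [1.0] * len(sequences)
    weights = np.asarray(unit_weights, dtype=float)
    if len(weights) != len(sequences):
        raise ValueError("unit_weights length mismatch")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    lengths = np.array([len(s) for s in sequences])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest unit")

    array_bp = float((weights * lengths).sum())
    p_background = background_genome_size / (background_genome_size + array_bp)
    unit_probs = weights * lengths / array_bp

    rng = np.random.default_rng(seed)
    perr = 10.0 ** (-_phred_from_perr(max(error_rate, 1e-6)) / 10.0)
    perr_vec = np.full(read_length, perr)

    reads = []
    truth = {}
    for i in range(n_reads):
        read_id = f"{id_prefix}_{i}"
        if rng.random() < p_background:
            codes = _random_sequence(rng, read_length)
            truth[read_id] = "background"
        else:
            u = rng.choice(len(sequences), p=unit_probs)
            src = sequences[u]
            start = int(rng.integers(0, len(src)))
            doubled = src + src
            codes = _from_str(doubled[start : start + read_length])
            truth[read_id] = labels[u]
        if error_rate > 0:
            err = np.flatnonzero(rng.random(read_length) < error_rate)
            for pos in err:
                choices = [b for b in range(4) if b != codes[pos]]
                codes[pos] = choices[rng.integers(0, 3)]
        reads.append(Read(read_id, _to_str(codes), perr_vec.copy()))
    return ReadSet(reads=reads, truth_labels=truth)


def build_mixture(
    d_reads: ReadSet,
    s_reads: ReadSet,
    s_fraction: float | None = None,
    n_total: int | None = None,
    seed: int = 0,
    counts: tuple[int, int] | None = None,
) -> ReadSet:
    """Mix D- and S-derived reads at a target S fraction or explicit counts.

    In fraction mode the S count is ``round(n_total * s_fraction)`` (half
    away from zero); in ``counts`` mode the exact (n_D, n_S) pair is drawn.
    Reads are sampled without replacement and shuffled; truth labels are
    forced to the source family.
    """
    if counts is not None:
        n_d, n_s = counts
    else:
        if s_fraction is None or n_total is None:
            raise ValueError("provide either counts or (s_fraction, n_total)")
        if not 0.0 <= s_fraction <= 1.0:
            raise ValueError("s_fraction must be in [0, 1]")
        n_s = int(math.floor(n_total * s_fraction + 0.5))
        n_d = n_total - n_s
    if n_d > len(d_reads) or n_s > len(s_reads):
        raise ValueError("insufficient source reads for the requested mixture")

    rng = np.random.default_rng(seed)
    d_pick = rng.choice(len(d_reads), size=n_d, replace=False)
    s_pick = rng.choice(len(s_reads), size=n_s, replace=False)
    mixed = []
    truth = {}
    for idx in d_pick:
        read = d_reads.reads[idx]
        new = Read(f"D_{read.id}", read.sequence, read.perr)
        mixed.append(new)
        truth[new.id] = "D"
    for idx in s_pick:
        read = s_reads.reads[idx]
        new = Read(f"S_{read.id}", read.sequence, read.perr)
        mixed.append(new)
        truth[new.id] = "S"
    order = rng.permutation(len(mixed))
    mixed = [mixed[i] for i in order]
    return ReadSet(reads=mixed, truth_labels=truth)


def make_default_units(
    seed: int = 0,
    spacer_divergence: float = 0.10,
    coding_divergence: float = 0.02,
    igs_divergence: float = 0.20,
) -> tuple[RDNAUnit, RDNAUnit]:
    """Build a homologous D/S unit pair with realistic divergence structure.

    The S unit is derived from the D unit subregion by subregion: coding
    genes diverge ~2%, ITS1/ITS2 ~10% (plus a 5-bp terminal insertion
    each), the IGS ~20% with a long length expansion.  The S unit carries
    no MluI motif anywhere, keeping the MluI CAPS assay D-diagnostic.
    """
    rng = np.random.default_rng(seed)
    d_unit = build_unit_template("D", seed=int(rng.integers(0, 2**31)))

    def diverge(sequence: str, rate: float) -> str:
        codes = _from_str(sequence)
        hits = np.flatnonzero(rng.random(len(codes)) < rate)
        for pos in hits:
            choices = [b for b in range(4) if b != codes[pos]]
            codes[pos] = choices[rng.integers(0, 3)]
        return _to_str(codes)

    def pad(sequence: str, target_len: int) -> str:
        extra = target_len - len(sequence)
        if extra <= 0:
            return sequence[:target_len]
        return sequence + _to_str(_random_sequence(rng, extra))

    parts = []
    for sub in SUBREGION_ORDER:
        d_seq = d_unit.subregion_sequence(sub)
        target = S_SUBREGION_LENGTHS[sub]
        if sub in CODING_SUBREGIONS:
            parts.append(pad(diverge(d_seq, coding_divergence), target))
        elif sub == "IGS":
            parts.append(pad(diverge(d_seq, igs_divergence), target))
        else:
            parts.append(pad(diverge(d_seq, spacer_divergence), target))
    s_backbone = "".join(parts)
    s_unit = build_unit_template(
        "S",
        seed=int(rng.integers(0, 2**31)),
        base_sequence=s_backbone,
        exclude_motifs=[ENZYME_MOTIFS["MluI"]],
    )
    return d_unit, s_unit


def aligned_its1_pair(d_unit: RDNAUnit, s_unit: RDNAUnit) -> tuple[str, str]:
    """Equal-length aligned ITS1 sequences for the two unit families.

    The default S ITS1 equals the D ITS1 backbone with terminal extra
    bases, so the alignment is the shared leading block; terminal length
    variation is excluded rather than represented as end gaps.
    """
    d_its1 = d_unit.subregion_sequence("ITS1")
    s_its1 = s_unit.subregion_sequence("ITS1")
    n = min(len(d_its1), len(s_its1))
    return d_its1[:n], s_its1[:n]


def write_fasta(units: list[RDNAUnit], path) -> None:
    records = [
        SeqRecord(Seq(u.sequence), id=u.name, description=u.genome_label)
        for u in units
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_subregions_tsv(unit: RDNAUnit, path) -> None:
    """Companion annotation table (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("unit\tsubregion\tstart\tend\n")
        for sub in SUBREGION_ORDER:
            start, end = unit.subregions[sub]
            handle.write(f"{unit.name}\t{sub}\t{start}\t{end}\n")
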