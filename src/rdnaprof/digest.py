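"""In-silico restriction digestion, methylation sensitivity and CAPS bands.

Digestion of a tandem array of identical units is computed from motif
start positions: in an array the start-to-start distance equals the
cut-to-cut distance regardless of the enzyme's intra-motif cut offset, so
offsets are not modelled.  Methylation-sensitive enzymes fail to cut
methylated sites: BglII (AGATCT) is insensitive, XhoI (CTCGAG) is blocked
when its designated second cytosine (a CG-context C) is methylated, and
PstI (CTGCAG) is blocked when either cytosine (CHG context) is
methylated.  For a single site per unit blocked independently with
probability b, fragment lengths follow the geometric law: a fragment of
k units has expected frequency (1-b) * b**(k-1).

CAPS (cleaved amplified polymorphic sequence) prediction digests linear
PCR amplicons per family and pools distinct fragment lengths into gel
lanes: the gDNA lane pools every family, the cDNA lane only the expressed
ones.  Band classes within 1% relative length merge, emulating gel
resolution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ENZYME_MOTIFS, RDNAUnit

INSENSITIVE = "insensitive"
BLOCKED_SECOND_C = "blocked_if_second_C_methylated"
BLOCKED_EITHER_C = "blocked_if_either_C_methylated"


@dataclass(frozen=True)
class Enzyme:
    name: str
    motif: str
    methylation_rule: str = INSENSITIVE
    #: 0-based offsets (within the motif) of the cytosines the rule reads.
    sensitive_c_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(b not in "ACGT" for b in self.motif):
            raise ValueError("motif must be over ACGT")
        for off in self.sensitive_c_offsets:
            if self.motif[off] != "C":
                raise ValueError(f"offset {off} of {self.motif} is not a C")


#: Built-in enzyme table used throughout the analysis.
ENZYMES = {
    "BglII": Enzyme("BglII", ENZYME_MOTIFS["BglII"], INSENSITIVE),
    "XhoI": Enzyme("XhoI", ENZYME_MOTIFS["XhoI"], BLOCKED_SECOND_C,
                   sensitive_c_offsets=(2,)),
    "PstI": Enzyme("PstI", ENZYME_MOTIFS["PstI"], BLOCKED_EITHER_C,
                   sensitive_c_offsets=(0, 3)),
    "MluI": Enzyme("MluI", ENZYME_MOTIFS["MluI"], INSENSITIVE),
}


@dataclass
class MethylState:
    """Cytosine methylation, stochastic (probability) or explicit (flags).

    ``probability`` methylates each relevant cytosine independently;
    ``methylated_positions`` lists 1-based sequence positions of
    methylated cytosines for the deterministic mode.  ``contexts``
    optionally annotates cytosines with their CG/CHG/CHH context.
    """

    probability: float | None = None
    methylated_positions: frozenset[int] | set[int] | None = None
    contexts: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError("methylation probability must be in [0, 1]")
        if self.probability is None and self.methylated_positions is None:
            raise ValueError("provide a probability or explicit positions")


@dataclass
class DigestPattern:
    """Multiset of fragment-length classes with methylation annotations."""

    classes: list[tuple[int, int, str]]  # (length_bp, count, annotation)

    @property
    def total_bp(self) -> int:
        return sum(length * count for length, count, _ in self.classes)

    def lengths(self) -> list[int]:
        return sorted({length for length, _, _ in self.classes})


def find_sites(sequence: str | RDNAUnit, enzyme: Enzyme | str) -> list[int]:
    """All exact motif occurrences as sorted 1-based start positions."""
    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme]
    seq = sequence.sequence if isinstance(sequence, RDNAUnit) else sequence
    sites = []
    found = seq.find(enzyme.motif)
    while found != -1:
        sites.append(found + 1)
        found = seq.find(enzyme.motif, found + 1)
    return sites


def digest_tandem(
    unit_length: int, cut_positions: list[int], n_units: int
) -> DigestPattern:
    """Complete digest of a tandem array of ``n_units`` identical units.

    Fragments are the differences of consecutive motif starts within a
    unit; the fragment spanning the unit junction has length
    ``unit_length - (last - first)``.  Zero cuts leave a single
    uncut high-molecular-weight class of the whole array.
    """
    if any(not 1 <= pos <= unit_length for pos in cut_positions):
        raise ValueError("cut positions must lie within [1, unit_length]")
    if not cut_positions:
        return DigestPattern([(unit_length * n_units, 1, "uncut_high_MW")])
    sites = sorted(cut_positions)
    lengths = [b - a for a, b in zip(sites, sites[1:])]
    lengths.append(unit_length - (sites[-1] - sites[0]))
    counts = Counter(lengths)
    return DigestPattern(
        [(length, count * n_units, "unmethylated_cut")
         for length, count in sorted(counts.items())]
    )


def _block_probability(enzyme: Enzyme, m: float) -> float:
    """Per-site block probability when each relevant C methylates i.i.d."""
    if enzyme.methylation_rule == INSENSITIVE:
        return 0.0
    if enzyme.methylation_rule == BLOCKED_SECOND_C:
        return m
    if enzyme.methylation_rule == BLOCKED_EITHER_C:
        return 1.0 - (1.0 - m) ** len(enzyme.sensitive_c_offsets)
    raise ValueError(f"unknown methylation rule {enzyme.methylation_rule!r}")


def apply_methylation(
    sites: list[int],
    enzyme: Enzyme | str,
    methyl_state: MethylState,
    seed: int = 0,
) -> list[bool]:
    """Per-site cut flags (True = cut, False = blocked).

    With explicit methylated positions the outcome is deterministic: a
    site is blocked when the rule-designated cytosine(s) of its motif are
    methylated.  With a probability, each relevant cytosine methylates
    independently (seeded).
    """
    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme]
    if enzyme.methylation_rule == INSENSITIVE:
        return [True] * len(sites)

    if methyl_state.methylated_positions is not None:
        methylated = set(methyl_state.methylated_positions)
        flags = []
        for site in sites:
            c_positions = [site + off for off in enzyme.sensitive_c_offsets]
            if enzyme.methylation_rule == BLOCKED_SECOND_C:
                blocked = c_positions[-1] in methylated
            else:
                blocked = any(pos in methylated for pos in c_positions)
            flags.append(not blocked)
        return flags

    rng = np.random.default_rng(seed)
    b = _block_probability(enzyme, methyl_state.probability)
    return [bool(rng.random() >= b) for _ in sites]


def fragment_distribution(
    unit: RDNAUnit | str,
    enzyme: Enzyme | str,
    m: float,
    n_units: int,
    n_simulations: int = 1,
    seed: int = 0,
) -> dict:
    """Fragment length-class frequencies of a partially methylated array.

    The array is circular with ``n_units`` units, each carrying the
    unit's sites; every site is independently blocked with the
    methylation-derived probability.  Fragment sizes are tallied in unit
    multiples for the single-site case; the analytic geometric
    expectation (1-b)*b**(k-1) accompanies the observation there (the
    multi-site case is simulation-only).  Returns
    ``{"observed": {k: freq}, "expected": {...}|None, "n_fragments": N,
    "block_probability": b}``.
    """
    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme]
    seq = unit.sequence if isinstance(unit, RDNAUnit) else unit
    unit_sites = find_sites(seq, enzyme)
    if not unit_sites:
        raise ValueError("unit has no site for this enzyme")
    b = _block_probability(enzyme, m)
    single_site = len(unit_sites) == 1
    rng = np.random.default_rng(seed)

    observed: Counter = Counter()
    total_fragments = 0
    uncut_arrays = 0
    for _ in range(n_simulations):
        cut = rng.random(n_units * len(unit_sites)) >= b
        n_cut = int(cut.sum())
        if n_cut == 0:
            uncut_arrays += 1
            continue
        cut_idx = np.flatnonzero(cut)
        if single_site:
            gaps = np.diff(cut_idx).tolist()
            gaps.append(int(len(cut) - (cut_idx[-1] - cut_idx[0])))
            observed.update(gaps)  # gap in site steps == fragment in units
        else:
            # multi-site: report in base pairs between consecutive cut sites
            positions = np.array(
                [u * len(seq) + s for u in range(n_units) for s in unit_sites]
            )
            cut_pos = positions[cut_idx]
            bp = [int(x) for x in np.diff(cut_pos)]
            bp.append(int(n_units * len(seq) - (cut_pos[-1] - cut_pos[0])))
            observed.update(bp)
        total_fragments += n_cut

    if total_fragments == 0:
        freq: dict[int, float] = {}
    else:
        freq = {int(k): v / total_fragments for k, v in sorted(observed.items())}
    expected = None
    if single_site:
        expected = {k: (1.0 - b) * b ** (k - 1) for k in sorted(freq)}
    return {
        "observed": freq,
        "expected": expected,
        "n_fragments": total_fragments,
        "uncut_arrays": uncut_arrays,
        "block_probability": b,
    }


def linear_fragments(sequence: str, enzyme: Enzyme | str) -> list[int]:
    """Fragment lengths of a linear molecule (PCR amplicon) digestion."""
    sites = find_sites(sequence, enzyme)
    if not sites:
        return [len(sequence)]
    cuts = [s - 1 for s in sites]  # cut at motif start
    bounds = [0] + cuts + [len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def gel_lane(lengths: list[int], tolerance: float = 0.01) -> list[int]:
    """Distinct band classes, merging lengths within 1% relative length."""
    bands: list[int] = []
    for length in sorted(set(lengths)):
        if bands and (length - bands[-1]) <= tolerance * bands[-1]:
            continue
        bands.append(length)
    return bands


def caps_predict(
    amplicons: list[tuple[str, str]],
    enzyme: Enzyme | str,
    expressed_labels: tuple[str, ...] = ("D",),
) -> dict[str, list[int]]:
    """Predicted CAPS band patterns per lane.

    ``amplicons`` are (family label, sequence) PCR products.  The gDNA
    lane pools the digestion fragments of every amplicon; the cDNA lane
    pools only the families in ``expressed_labels`` (the transcribed
    ones).  Bands within 1% relative length are merged.
    """
    per_label: dict[str, list[int]] = {}
    for label, seq in amplicons:
        per_label.setdefault(label, []).extend(linear_fragments(seq, enzyme))
    gdna = [length for lengths in per_label.values() for length in lengths]
    cdna = [
        length
        for label, lengths in per_label.items()
        if label in expressed_labels
        for length in lengths
    ]
    return {"gDNA": gel_lane(gdna), "cDNA": gel_lane(cdna)}


def render_gel(lanes: dict[str, list[int]], height: int = 20) -> str:
    """Crude text rendering of band positions on a log-length scale."""
    all_bands = [band for bands in lanes.values() for band in bands]
    if not all_bands:
        return "(empty gel)"
    lo, hi = np.log(min(all_bands)), np.log(max(all_bands) + 1)
    span = max(hi - lo, 1e-9)
    rows = []
    names = list(lanes)
    header = "bp      " + "  ".join(f"{name:>8}" for name in names)
    rows.append(header)
    for level in range(height, -1, -1):
        log_here = lo + span * level / height
        cells = []
        for name in names:
            hit = any(
                abs(np.log(band) - log_here) <= span / (2 * height)
                for band in lanes[name]
            )
            cells.append(f"{'========':>8}" if hit else f"{'':>8}")
        rows.append(f"{np.exp(log_here):7.0f} " + "  ".join(cells))
    return "\n".join(rows)


def write_pattern_tsv(pattern: DigestPattern, path) -> None:
    with open(path, "w") as handle:
        handle.write("length\tcount\tclass\n")
        for length, count, annotation in pattern.classes:
            handle.write(f"{length}\t{count}\t{annotation}\n")
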