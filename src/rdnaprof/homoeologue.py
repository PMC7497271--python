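"""Homoeologue ratio estimation through a diagnostic ITS1 window.

In an allopolyploid the two parental rDNA families are most easily told
apart in ITS1, where a short window (default 50 bp) diverges by ~10%
between the D- and S-family consensuses.  Reads containing the window are
recruited, trimmed to window coordinates, optionally subsampled, and
classified to the family whose window consensus they match more closely
(smaller Hamming distance; unit-cost edit distance with gap columns
counted as mismatches when an InDel changes the fragment length; exact
ties stay unassigned).  Haplotype diversity is the number of distinct
fragment sequences divided by the sample size, and two families are
compared with a Pearson chi-square on the 2x2 haplotype/non-haplotype
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.stats import chi2_contingency

from .synthetic import ReadSet

_BASES = "ACGT"


@dataclass
class DiagnosticWindow:
    d_consensus: str
    s_consensus: str
    start: int  # 1-based start within ITS1
    divergence: float
    width: int = 50
    warning: str | None = None

    def __post_init__(self) -> None:
        if len(self.d_consensus) != self.width or len(self.s_consensus) != self.width:
            raise ValueError("window consensuses must have length = width")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")


@dataclass
class FragmentSample:
    """Window-anchored fragments with (possibly pending) family labels."""

    fragments: list[tuple[str, str]] = field(default_factory=list)  # (id, seq)
    labels: dict[str, str] = field(default_factory=dict)
    truth_labels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class DiversityStat:
    n_sequences: int
    n_haplotypes: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_haplotypes <= self.n_sequences:
            raise ValueError("need 1 <= haplotypes <= sequences")

    @property
    def diversity(self) -> float:
        return self.n_haplotypes / self.n_sequences


def select_diagnostic_window(
    d_its1: str, s_its1: str, width: int = 50
) -> DiagnosticWindow:
    """Window of maximal column-wise divergence between aligned ITS1 pair.

    Inputs must be equal length (gaps allowed; a column differs when the
    two symbols differ, so a gap against a base counts as divergent).
    Leftmost window on ties.  A zero-divergence result carries a warning
    flag, since it cannot discriminate the families.
    """
    if len(d_its1) != len(s_its1):
        raise ValueError("ITS1 sequences must be aligned to equal length")
    if len(d_its1) < width:
        raise ValueError("ITS1 shorter than the window width")
    diffs = np.array([1 if a != b else 0 for a, b in zip(d_its1, s_its1)])
    window_sums = np.convolve(diffs, np.ones(width, dtype=int), mode="valid")
    best = int(window_sums.argmax())  # argmax returns the leftmost maximum
    divergence = window_sums[best] / width
    return DiagnosticWindow(
        d_consensus=d_its1[best : best + width].replace("-", "N"),
        s_consensus=s_its1[best : best + width].replace("-", "N"),
        start=best + 1,
        divergence=float(divergence),
        width=width,
        warning="window has zero divergence" if divergence == 0 else None,
    )


def recruit_fragments(
    reads: ReadSet,
    window: DiagnosticWindow,
    min_overlap: int = 50,
    max_edit_distance: int = 10,
) -> FragmentSample:
    """Recruit reads containing the diagnostic window and trim them to it.

    Each read is scanned for the best infix alignment of either window
    consensus (full window coverage; ``min_overlap`` guards against reads
    shorter than the window).  Reads whose best match exceeds
    ``max_edit_distance`` edits, or that contain ambiguous bases, are not
    recruited.  The fragment is the read substring spanning the matched
    window coordinates.
    """
    sample = FragmentSample()
    for read in reads:
        if len(read.sequence) < max(min_overlap, window.width):
            continue
        if any(b not in _BASES for b in read.sequence):
            continue
        best = None
        for consensus in (window.d_consensus, window.s_consensus):
            hit = edlib.align(consensus, read.sequence, mode="HW",
                              task="locations", k=max_edit_distance)
            if hit["editDistance"] == -1:
                continue
            if best is None or hit["editDistance"] < best["editDistance"]:
                best = hit
        if best is None:
            continue
        start, end = best["locations"][0]
        fragment = read.sequence[start : end + 1]
        sample.fragments.append((read.id, fragment))
        if read.id in reads.truth_labels:
            sample.truth_labels[read.id] = reads.truth_labels[read.id]
    return sample


def sample_fragments(sample: FragmentSample, n: int, seed: int = 0) -> FragmentSample:
    """Uniform subsample without replacement (seeded, order-preserving)."""
    if n > len(sample):
        raise ValueError(f"cannot sample {n} of {len(sample)} fragments")
    rng = np.random.default_rng(seed)
    picked = sorted(rng.choice(len(sample), size=n, replace=False))
    fragments = [sample.fragments[i] for i in picked]
    ids = {fid for fid, _ in fragments}
    return FragmentSample(
        fragments=fragments,
        labels={k: v for k, v in sample.labels.items() if k in ids},
        truth_labels={k: v for k, v in sample.truth_labels.items() if k in ids},
    )


def _fragment_distance(fragment: str, consensus: str) -> int:
    if len(fragment) == len(consensus):
        return sum(1 for a, b in zip(fragment, consensus) if a != b)
    # InDel-containing fragment: unit-cost edit distance, gaps = mismatches
    return edlib.align(fragment, consensus, mode="NW", task="distance")[
        "editDistance"
    ]


def classify_fragments(
    sample: FragmentSample, window: DiagnosticWindow
) -> tuple[FragmentSample, dict]:
    """Nearest-consensus classification of every fragment.

    Each fragment is labelled by the smaller distance to the D vs S window
    consensus; exact ties are left unassigned.  Percentages are over
    assigned fragments only.
    """
    n_d = n_s = n_un = 0
    for fid, seq in sample.fragments:
        dist_d = _fragment_distance(seq, window.d_consensus)
        dist_s = _fragment_distance(seq, window.s_consensus)
        if dist_d < dist_s:
            sample.labels[fid] = "D"
            n_d += 1
        elif dist_s < dist_d:
            sample.labels[fid] = "S"
            n_s += 1
        else:
            sample.labels[fid] = "unassigned"
            n_un += 1
    assigned = n_d + n_s
    summary = {
        "n_D": n_d,
        "n_S": n_s,
        "n_unassigned": n_un,
        "pct_D": 100.0 * n_d / assigned if assigned else float("nan"),
        "pct_S": 100.0 * n_s / assigned if assigned else float("nan"),
    }
    return sample, summary


def haplotype_diversity(sample: FragmentSample | list[str]) -> DiversityStat:
    """Distinct full-length sequences over sample size."""
    if isinstance(sample, FragmentSample):
        sequences = [seq for _, seq in sample.fragments]
    else:
        sequences = list(sample)
    if not sequences:
        raise ValueError("empty sample")
    return DiversityStat(
        n_sequences=len(sequences), n_haplotypes=len(set(sequences))
    )


def compare_diversity(
    stat_a: DiversityStat, stat_b: DiversityStat
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2
    [haplotypes, sequences - haplotypes] table of the two families."""
    table = np.array([
        [stat_a.n_haplotypes, stat_a.n_sequences - stat_a.n_haplotypes],
        [stat_b.n_haplotypes, stat_b.n_sequences - stat_b.n_haplotypes],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (zero row or column)")
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def simulate_fragment_sample(
    window: DiagnosticWindow,
    n_d: int,
    n_s: int,
    error_rate: float = 0.01,
    seed: int = 0,
) -> FragmentSample:
    """Draw window fragments from the two consensuses with truth labels.

    Each fragment is its family consensus with independent per-base
    substitution errors at ``error_rate`` — the generative model behind
    the ratio-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    sample = FragmentSample()
    plan = [("D", window.d_consensus)] * n_d + [("S", window.s_consensus)] * n_s
    for idx, (family, consensus) in enumerate(plan):
        seq = list(consensus)
        errors = np.flatnonzero(rng.random(len(seq)) < error_rate)
        for pos in errors:
            choices = [b for b in _BASES if b != seq[pos]]
            seq[pos] = choices[rng.integers(0, len(choices))]
        fid = f"frag_{family}_{idx}"
        sample.fragments.append((fid, "".join(seq)))
        sample.truth_labels[fid] = family
    return sample


def write_fragments_fasta(sample: FragmentSample, path) -> None:
    with open(path, "w") as handle:
        for fid, seq in sample.fragments:
            label = sample.labels.get(fid, "")
            header = f">{fid} {label}".rstrip()
            handle.write(f"{header}\n{seq}\n")
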