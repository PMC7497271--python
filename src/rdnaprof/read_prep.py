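"""Quality trimming and read filtering.

Trimming follows the modified-Mott algorithm: with an error-probability
limit ``q`` (default 0.05), each base scores ``q - p_err`` and the retained
read is the contiguous substring with the maximal score sum (empty when no
substring scores positive, leftmost on ties).  Filtering then removes reads
containing ambiguous bases and reads shorter than a minimum length, with an
additive removal report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import Read, ReadSet


@dataclass
class TrimConfig:
    quality_limit: float = 0.05
    min_length: int = 100
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.quality_limit < 1.0:
            raise ValueError("quality_limit must be in (0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def trim_read(read: Read, quality_limit: float = 0.05) -> Read:
    """Return the maximal-scoring contiguous subread (modified Mott).

    The score of a substring is ``sum(quality_limit - p_err)`` over its
    bases.  Ties between equal-scoring substrings resolve to the leftmost;
    a read with no positive-scoring substring trims to empty.
    """
    if read.perr is None or len(read.perr) != len(read.sequence):
        raise ValueError("read is missing per-base error probabilities")
    scores = quality_limit - np.asarray(read.perr, dtype=float)

    # Kadane with leftmost tie-break: strict improvement only.
    best_sum = 0.0
    best_range = (0, 0)
    running = 0.0
    start = 0
    for i, s in enumerate(scores):
        if running <= 0.0 and s > running + s:
            running = s
            start = i
        else:
            running += s
        if running > best_sum:
            best_sum = running
            best_range = (start, i + 1)
    lo, hi = best_range
    return Read(read.id, read.sequence[lo:hi], read.perr[lo:hi])


def filter_reads(
    reads: ReadSet, config: TrimConfig | None = None
) -> tuple[ReadSet, dict[str, int]]:
    """Trim and filter a read set; report removal counts by reason.

    Order of operations: quality trim, then the ambiguity filter on the
    retained sequence, then the length filter (applied post-trim).  The
    report satisfies ``kept + sum(removed) == input``.
    """
    config = config or TrimConfig()
    kept = []
    truth = {}
    report = {"input": len(reads), "kept": 0, "ambiguous": 0, "short": 0}
    for read in reads:
        trimmed = trim_read(read, config.quality_limit)
        if config.drop_ambiguous and any(b not in "ACGT" for b in trimmed.sequence):
            report["ambiguous"] += 1
            continue
        if len(trimmed) < config.min_length:
            report["short"] += 1
            continue
        kept.append(trimmed)
        if read.id in reads.truth_labels:
            truth[read.id] = reads.truth_labels[read.id]
        report["kept"] += 1
    return ReadSet(reads=kept, truth_labels=truth), report


def write_report_tsv(report: dict[str, int], path) -> None:
    with open(path, "w") as handle:
        handle.write("reason\tcount\n")
        for key, value in report.items():
            handle.write(f"{key}\t{value}\n")
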