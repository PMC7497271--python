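"""Diagnostic ITS1 window, fragment classification, haplotype diversity."""

import numpy as np
import pytest

from rdnaprof.homoeologue import (
    DiversityStat,
    FragmentSample,
    classify_fragments,
    compare_diversity,
    haplotype_diversity,
    recruit_fragments,
    sample_fragments,
    select_diagnostic_window,
    simulate_fragment_sample,
)
from rdnaprof.synthetic import ReadSet, aligned_its1_pair, simulate_reads


def window_with_divergence(n_diffs=5, width=50, seed=0):
    """A D/S consensus pair differing at exactly ``n_diffs`` positions."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    d = "".join(bases[i] for i in rng.integers(0, 4, width))
    s = list(d)
    for pos in rng.choice(width, size=n_diffs, replace=False):
        s[pos] = bases[(bases.index(s[pos]) + 1) % 4]
    return select_diagnostic_window(d, "".join(s), width=width)


def brute_force_best_window(d_seq, s_seq, width):
    best_start, best_div = 0, -1
    for start in range(len(d_seq) - width + 1):
        div = sum(
            a != b
            for a, b in zip(d_seq[start : start + width],
                            s_seq[start : start + width])
        )
        if div > best_div:
            best_start, best_div = start, div
    return best_start + 1, best_div / width


class TestSelectDiagnosticWindow:
    def test_identical_pair_flags_zero_divergence(self):
        window = select_diagnostic_window("ACGT" * 20, "ACGT" * 20)
        assert window.divergence == 0.0 and window.warning is not None

    def test_five_differences_give_ten_percent(self):
        window = window_with_divergence(n_diffs=5)
        assert window.divergence == pytest.approx(0.10)

    def test_matches_exhaustive_scan_oracle(self, default_units):
        d_its1, s_its1 = aligned_its1_pair(*default_units)
        window = select_diagnostic_window(d_its1, s_its1)
        start, divergence = brute_force_best_window(d_its1, s_its1, 50)
        assert window.start == start
        assert window.divergence == pytest.approx(divergence)

    def test_too_short_its1_raises(self):
        with pytest.raises(ValueError):
            select_diagnostic_window("ACGT", "ACGT", width=50)


class TestRecruitFragments:
    def test_read_containing_d_window_is_recruited(self):
        window = window_with_divergence()
        read_seq = "ACGT" * 10 + window.d_consensus + "TTTT" * 5
        reads = simulate_reads([read_seq + "A" * 60], None, 1, read_length=80,
                               error_rate=0.0, seed=1)
        # build a read set containing the window explicitly
        from rdnaprof.synthetic import Read

        rs = ReadSet([Read("hit", read_seq, np.full(len(read_seq), 0.01))])
        sample = recruit_fragments(rs, window)
        assert len(sample) == 1
        assert sample.fragments[0][1] == window.d_consensus

    def test_unrelated_read_not_recruited(self, rng):
        from rdnaprof.synthetic import Read

        window = window_with_divergence()
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        rs = ReadSet([Read("junk", seq, np.full(120, 0.01))])
        assert len(recruit_fragments(rs, window)) == 0

    def test_sensitivity_on_error_free_overlapping_reads(self, default_units):
        d_unit, s_unit = default_units
        d_its1, s_its1 = aligned_its1_pair(d_unit, s_unit)
        window = select_diagnostic_window(d_its1, s_its1)
        reads = simulate_reads([d_unit], None, 3000, read_length=100,
                               error_rate=0.0, seed=2)
        its1_start = d_unit.subregions["ITS1"][0]
        win_lo = its1_start + window.start - 1  # 1-based on the unit
        win_hi = win_lo + window.width - 1
        covering = {
            r.id
            for r in reads
            if _covers(r.sequence, d_unit.sequence, win_lo, win_hi)
        }
        recruited = {fid for fid, _ in recruit_fragments(reads, window).fragments}
        assert covering  # the simulation produced informative reads
        sensitivity = len(covering & recruited) / len(covering)
        assert sensitivity >= 0.99


def _covers(read_seq, unit_seq, lo, hi):
    doubled = unit_seq * 2
    start = doubled.find(read_seq)
    if start == -1:
        return False
    for offset in (0, len(unit_seq)):
        if start + 1 <= offset + lo and start + len(read_seq) >= offset + hi:
            return True
    return False


class TestSampleFragments:
    def build(self, n=400, seed=0):
        window = window_with_divergence()
        return window, simulate_fragment_sample(window, n // 2, n // 2,
                                                error_rate=0.01, seed=seed)

    def test_sampling_everything_is_identity(self):
        _, sample = self.build(100)
        assert sample_fragments(sample, 100, seed=1).fragments == sample.fragments

    def test_fixed_seed_reproducible(self):
        _, sample = self.build(300)
        a = sample_fragments(sample, 50, seed=9)
        b = sample_fragments(sample, 50, seed=9)
        assert a.fragments == b.fragments

    def test_oversampling_raises(self):
        _, sample = self.build(10)
        with pytest.raises(ValueError):
            sample_fragments(sample, 11)

    def test_subsample_proportions_hypergeometric(self):
        # truth-label proportions within 3 sigma of the source proportions
        window = window_with_divergence()
        sample = simulate_fragment_sample(window, 300, 100, seed=3)
        sub = sample_fragments(sample, 100, seed=4)
        n_d = sum(1 for v in sub.truth_labels.values() if v == "D")
        N, K, n = 400, 300, 100
        mean = n * K / N
        sigma = np.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
        assert abs(n_d - mean) < 3 * sigma


class TestClassifyFragments:
    def test_fragment_identical_to_s_consensus(self):
        window = window_with_divergence()
        sample = FragmentSample(fragments=[("f", window.s_consensus)])
        sample, summary = classify_fragments(sample, window)
        assert sample.labels["f"] == "S" and summary["n_S"] == 1

    def test_equidistant_fragment_unassigned(self):
        d = "A" * 50
        s = "A" * 48 + "CC"
        window = select_diagnostic_window(d, s)
        halfway = "A" * 49 + "C"  # one diff from each consensus
        sample = FragmentSample(fragments=[("tie", halfway)])
        sample, summary = classify_fragments(sample, window)
        assert sample.labels["tie"] == "unassigned"
        assert summary["n_unassigned"] == 1

    def test_published_mixture_ratio_recovered(self):
        # 165 D + 57 S fragments at 1% error -> 74% D (within 1 fragment)
        window = window_with_divergence(n_diffs=5)
        sample = simulate_fragment_sample(window, 165, 57, error_rate=0.01,
                                          seed=5)
        _, summary = classify_fragments(sample, window)
        assert abs(summary["n_D"] - 165) <= 1
        assert summary["pct_D"] == pytest.approx(100 * 165 / 222, abs=0.5)

    def test_percentages_sum_to_100_over_assigned(self):
        window = window_with_divergence()
        sample = simulate_fragment_sample(window, 80, 40, error_rate=0.02,
                                          seed=6)
        _, summary = classify_fragments(sample, window)
        assert summary["pct_D"] + summary["pct_S"] == pytest.approx(100.0)


class TestHaplotypeDiversity:
    def test_textbook_examples(self):
        assert haplotype_diversity(["AA", "AA", "AT", "TT"]).diversity == 0.75
        assert haplotype_diversity(["AC"] * 10).diversity == pytest.approx(0.1)
        assert haplotype_diversity(["AA", "AT", "TA", "TT"]).diversity == 1.0

    def test_invariant_under_reordering(self, rng):
        seqs = ["AAA", "AAT", "AAA", "TTT", "AAT", "AAA"]
        base = haplotype_diversity(seqs).diversity
        for _ in range(5):
            rng.shuffle(seqs)
            assert haplotype_diversity(seqs).diversity == base

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            haplotype_diversity([])


class TestCompareDiversity:
    def test_identical_tables_give_zero_chi2(self):
        a = DiversityStat(100, 30)
        chi2, p = compare_diversity(a, DiversityStat(100, 30))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self):
        # table [[30, 70], [50, 50]]
        a, b = DiversityStat(100, 30), DiversityStat(100, 50)
        chi2, p = compare_diversity(a, b)
        observed = np.array([[30, 70], [50, 50]], dtype=float)
        expected = (
            observed.sum(axis=1)[:, None] * observed.sum(axis=0)[None, :]
            / observed.sum()
        )
        hand = ((observed - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(hand)
        assert 0 < p < 0.05  # this table is clearly heterogeneous

    def test_p_monotone_decreasing_in_chi2(self):
        stats = [DiversityStat(100, k) for k in (30, 40, 45)]
        base = DiversityStat(100, 50)
        results = [compare_diversity(s, base) for s in stats]
        chis = [c for c, _ in results]
        ps = [p for _, p in results]
        assert chis == sorted(chis, reverse=True)
        assert ps == sorted(ps)

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError):
            compare_diversity(DiversityStat(10, 10), DiversityStat(8, 8))
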