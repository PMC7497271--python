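# Methods

`rdnaprof` reimplements, over a fully synthetic data generator, the
read-based workflow used to characterise 35S rDNA arrays in a plant
allopolyploid and its diploid progenitors: copy-number estimation from
whole-genome read proportions, intragenomic SNP profiling of the tandem
unit, homoeologue ratio estimation through a diagnostic ITS1 window,
haplotype diversity, and in-silico restriction/CAPS prediction with
methylation-sensitivity rules.  This note records the model, the
parameter choices, and the places where the design was genuinely open.

## The synthetic rDNA model

A 35S rDNA unit is the ordered concatenation
18S–ITS1–5.8S–ITS2–25S–IGS.  Two unit families are generated:

* **D-like unit, 8084 bp** and **S-like unit, 9215 bp** — the totals and
  the 18S length (1810 bp = 0.00181 Mb) are fixed by the reference
  consensus lengths the copy-number arithmetic is defined against.  The
  remaining subregion lengths are free parameters; the defaults
  (D: ITS1 220, 5.8S 164, ITS2 230, 25S 3376, IGS 2284;
  S: ITS1 225, ITS2 235, IGS 3405) are realistic for a grass and put
  the length difference between the families mostly into the IGS, where
  real length polymorphism concentrates.
* **Restriction-site plan.**  Both families carry two BglII sites inside
  the 25S gene at starts 3850 and 5185 (1335 bp apart, giving the
  1.3-kb / ~6.7–7.9-kb tandem fragment pair); PstI sits in ITS2 (plus a
  second IGS site in the S family, 3.9 kb downstream); each family has a
  single XhoI site in the 25S gene; MluI occurs only in the D ITS1 and
  nowhere in the S unit, which makes the MluI CAPS assay D-diagnostic.
  Motifs are planted at their planned starts and every spurious
  occurrence of a planned (or explicitly excluded) motif elsewhere is
  scrubbed by a single-base substitution, so site lists are exact by
  construction.
* **Inter-family divergence.**  The S unit is derived from the D unit
  subregion by subregion: ~2% substitution divergence in the coding
  genes (18S/5.8S/25S), ~10% in ITS1/ITS2, ~20% plus a length expansion
  in the IGS.  These defaults give the two properties the analysis
  needs: coding regions conserved enough to cross-map (as real 18S
  sequences do), and an ITS1 window diverged enough (~10–15%) to type
  homoeologues.

**Intragenomic heterogeneity** within an array uses two regimes.
`spacer_biased` confines substitutions to ITS1/ITS2/IGS — the signature
of concerted evolution, which homogenises coding sequence more strongly
than spacers.  `uniform` draws substitutions position-independently —
the signature of pseudogenised copies accumulating mutations free of
selection.  The per-site rate (default 0.002/site) is a free knob; the
regimes differ in *where*, not *how much*.

**Reads** are drawn from a circular tandem-unit model: a unit is one
turn of the array, so reads may span the IGS/18S junction (wrap-around
substrings).  Background (non-rDNA) reads are i.i.d. uniform random
sequence — only the mapped/unmapped dichotomy matters for the genome
proportion, so no effort is spent on realistic background composition.
Per-read substitution errors are applied at a constant rate; the
recorded per-base error probabilities are the Phred-quantised
equivalent, which makes FASTQ round-trips byte-exact.  InDel sequencing
errors are off by default (substitutions dominate short-read error
profiles, and the variant tables treat the two classes separately).
What the generator does **not** emulate: quality-score decay along the
read, GC bias, duplicates, paired-end structure, and real flanking
genome — so passing tests demonstrate the correctness of the
*computations*, not robustness to every artefact of real libraries.

## Read preparation

Quality trimming is modified-Mott: with error-probability limit
`q = 0.05`, each base scores `q − p_err` and the retained subread is the
contiguous substring with maximal score sum (leftmost on ties; empty if
no positive substring).  This is the de-facto meaning of a "quality
limit 0.05" in standard trimming tools, and it is oracle-checkable
against brute-force maximisation.  Filtering then removes reads with
any ambiguous base and reads shorter than the minimum length (100 nt
for 100-nt libraries, 150 nt for 150-nt libraries).  Both filters apply
*after* trimming — the length filter on the retained sequence is the
stricter, more defensible reading.

## Mapping

The aligner realises the classic mapping parameterisation — mismatch
cost 2, insertion cost 3, deletion cost 3, length fraction 0.5,
similarity fraction 0.8 — as a local alignment with match score +1,
mismatch −2, gap −3, and read ends soft-clipped at zero score.  A note
on why: "minimise 2·mismatches + 3·insertions + 3·deletions with free
read ends" is degenerate as stated (the empty alignment costs 0), and
the score form is the standard resolution: for any fixed aligned
region, score ranking and cost ranking coincide, and clipping becomes
well-defined.  Placements report the cost of their aligned region, the
aligned read fraction, and identity = matches / aligned columns (gap
columns included).  Acceptance is inclusive on both thresholds.

Implementation details that matter for reproducibility:

* **Wrap-around** uses the doubled-reference trick; coordinates are
  folded onto `[1, unit_length]`, and each read counts once.
* **Determinism**: ties resolve to the leftmost reference end position,
  and the traceback prefers diagonal over up over left.
* **Guided mapping**: `map_reads` first locates the candidate region
  with an edlib infix screen (full read within 0.30·L edits, or either
  half within 0.20·(L/2) for reference-boundary reads that need
  clipping) and runs the exact DP on a window around the hit.  Random
  unrelated reads sit near 0.40·L and are rejected without the DP.  The
  screen is exact for the read populations the generator produces
  (homologous reads with ≲10% divergence+error, boundary reads with a
  near-clean half, and unrelated background); `exhaustive=True` forces
  the full DP, and the oracle tests exercise `align_read`, which is
  always exact.
* **Consensus**: per-position majority base; exact ties and zero
  coverage fall back to the reference base.

## Variant calling

Calls come straight from the per-position allele tallies with three
thresholds: coverage ≥ 300, supporting reads ≥ 30, and allele frequency
≥ 0.10 (high-frequency calls) or ≥ 0.01 (low-frequency calls), where
frequency = supporting count / coverage at the position, computed per
alternative allele (never pooled).  A read spanning a deletion counts
as coverage at the deleted position; insertions are left-anchored to
the reference base on their left.  Calls at the 0.10 threshold are a
subset of calls at 0.01 by construction.  Windowed summaries count
variants in non-overlapping 100-bp windows `[1–100], [101–200], …` and
report the per-window maximum (the density-plot y-axis cap).

## Copy-number arithmetic

For a library of `total` reads with `mapped` reads on the 18S
reference:

    GP (%)        = 100 × mapped / total
    GS (Mb)       = genome size (Mb) × GP / 100
    copies per 1C = GS / 0.00181 Mb

with 1 pg = 978 Mb for genome-size conversion.  All arithmetic runs on
unrounded intermediates; GP and GS round to two decimals and copies
half-away-from-zero to an integer *only at reporting*.  With the
published read counts this chain reproduces 665 (Bd21), 463 (ABR5) and
410 (ABR114) exactly.  For the allotetraploid ABR113 row it yields 783,
not the printed 788; 788 is consistent with a chain computed on GP
pre-rounded to 0.23%, i.e. the printed table mixes rounding conventions
between rows.  This package deliberately does not emulate that
inconsistency — the unrounded chain is the defensible one — and the
discrepancy is surfaced in the analysis output instead.  Similarly, the
0.630 pg × 978 conversion gives 616 Mb, but the conventional ≈620 Mb
value is used for ABR113 computations, matching the published table.

## Homoeologue typing

The diagnostic window is the 50-bp window of maximal column-wise
divergence between the aligned D and S ITS1 consensuses (leftmost on
ties; a zero-divergence window is flagged as non-discriminating).  With
the default units the selected window diverges ~14%, bracketing the
~10% figure the assay needs.  Reads are recruited when either window
consensus aligns into them as a full-width infix within 10 edits
(ambiguous-base reads are discarded), then trimmed to the matched
window coordinates.  In the end-to-end pipeline the recruitment pool is
simulated directly from the ITS1 regions of the array variants — the
real workflow recruits window-homologous reads from the whole archive
with BLAST, and simulating the ITS1-overlapping subset gives the same
pool without generating the uninformative rest of the genome.

Classification is nearest-consensus: each fragment takes the family of
the window consensus at smaller Hamming distance (unit-cost edit
distance with gaps counted as mismatches when an InDel changed the
fragment length); exact ties stay unassigned, and percentages are over
assigned fragments.  The NJ tree is built for visualisation and
confirmation — branch assignment agrees with the nearest-consensus
classifier on ≥99% of clean fragments — but the classifier is the
operational instrument, because it is directly testable.

**Haplotype diversity** is the number of distinct full-length fragment
sequences divided by the sample size.  Two families are compared with a
Pearson chi-square (df = 1, no continuity correction) on the 2×2 table
`[[haplotypes, sequences − haplotypes]]` per family.  The original
chi-square construction is not specified anywhere; this concrete table
is the package's own choice and is documented as such.

## Trees

Distances are Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, with pairwise
deletion of gap/N columns (fragments are short; complete deletion would
discard too much) and saturation (`p ≥ 0.75`) mapped to a fixed maximum
of 5.0 substitutions/site.  Neighbour joining is Saitou–Nei with the
Studier–Keppler Q criterion; ties in Q resolve to the lexicographically
smallest label pair (internal nodes inherit the smallest leaf label
beneath them), negative branch lengths are clamped to zero and flagged,
and the final three nodes are resolved with the three-point formulas,
giving the canonical trifurcating-root unrooted tree.  NJ is exact on
additive matrices, which the tests exploit as an oracle, and the
implementation is cross-checked against an independent library NJ on
random additive metrics.  Bootstrap support resamples alignment columns
with replacement (default 100 replicates), rebuilds the tree, and
scores each internal edge by bipartition recovery.

Branch assignment cuts one edge on the path between a D and an S
reference leaf and labels every leaf by its side.  Which edge is "the"
inter-family edge is open in general; the rule here is the edge of
greatest branch length on the path (ties resolve towards the D
reference), which for two-cluster data is the long central edge.

## Restriction digestion, methylation and CAPS

Fragment lengths are measured between motif **start** positions: in a
tandem array of identical units the start-to-start distance equals the
cut-to-cut distance regardless of the enzyme's intra-motif cut offset,
so offsets are not modelled.  A complete digest of an `n`-unit array
with per-unit sites `s1 < … < sk` yields the inter-site differences
plus the junction fragment `L − (sk − s1)`, each `n` times; zero cuts
leave one uncut high-molecular-weight class.  Total length is conserved
under every digestion.

Methylation rules: BglII (AGATCT) cuts regardless; XhoI (CTCGAG) is
blocked iff its designated second cytosine (motif offset 2, a
CG-context C) is methylated; PstI (CTGCAG) is blocked iff either
cytosine (offsets 0 and 3, CHG context) is methylated.  With each
relevant cytosine methylated independently at probability `m`, the
per-site block probability is `b = m` for XhoI and `b = 1 − (1 − m)²`
for PstI.  For a single site per unit, the fragment of `k` units has
expected frequency `(1 − b)·b^(k−1)` — the geometric ladder whose
high-`k` tail is the high-molecular-weight smear seen on blots of
hypermethylated arrays.  The simulation (circular array, independent
site blocking) matches this law within binomial noise; the multi-site
case is simulation-only.

CAPS prediction digests linear PCR amplicons per family; the gDNA lane
pools every family's fragments and the cDNA lane only the expressed
families (default D, matching uniparental expression).  Band classes
within 1% relative length merge, emulating gel resolution and making
band counts well-defined.  Band *sizes* depend on the synthetic
amplicon geometry, so assertions are on counts: one MluI site in the D
amplicon and none in S gives three gDNA bands and two cDNA bands.

## Orchestration and reproducibility

`pipeline.run_profile` executes simulate → trim → map → variants →
dosage → homoeologue → digest in fixed order.  A single global seed is
fanned out into named per-stage substreams
(`SeedSequence([seed, stage_index])`), so each stage is reproducible
independently of execution order and a full run under a fixed seed is
byte-identical, which the tests assert on the canonical JSON summary.
Mixture weights are copy numbers: the S share of rDNA base pairs equals
the configured `s_fraction` while the array keeps its physical size, so
the background/rDNA split stays consistent with the genome size used by
the dosage stage.

## Problem sizes

The test suite and the analysis drivers run on deliberately scaled-down
instances — a 1200-bp mini unit with the same six-subregion
architecture for mapping-heavy checks, read sets of a few hundred to a
few thousand, fragment samples of 222 (the published sample size), and
bootstrap alignments of ~20–60 taxa.  These sizes were chosen so the
statistical assertions (3σ recovery bands, chi-square goodness-of-fit)
retain power while the whole suite stays fast; the full-size 8084/9215
bp units are used wherever the real geometry is the point (site maps,
digestion arithmetic, window selection, end-to-end runs).

## Known limitations

* Single-end reads only; no adapter trimming, no base-quality-aware
  alignment scoring, no mapping-quality model.
* Best-placement-only mapping with a leftmost tie-break; reads mapping
  equally well to both homoeologues (deep in coding regions) go to the
  reference they are mapped against, as in the original workflow.
* Per-site SNVs only; adjacent mismatches are not merged into MNVs.
* The chi-square haplotype comparison and the cut-edge rule for branch
  assignment are package choices where the original method is
  under-specified (see above).
* Re-processing the original sequencing archives is supported only in
  the sense that `run_profile` accepts a local FASTQ; no download
  machinery is included and no result depends on real data.
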