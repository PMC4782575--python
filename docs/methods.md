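# Methods

This note records the models, conventions and design choices behind
`amplitype`, in the order the pipeline applies them.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Read QC (Step I)

Reads are accepted or rejected whole; there is no quality trimming or
denoising.  The filters run in a fixed order — length, quality, primer/MID
location, barcode assignment, reference screen — and a read is charged to
the first stage that rejects it, so per-run attrition tables always
reconcile (`reads_in == kept + rejected + unassigned`).

* **Length/quality.** Keep iff `min_len ≤ L ≤ max_len` (defaults 150/400
  bp) and the fraction of bases with Phred **strictly below** `qual_floor`
  (default 20) is at most `max_low_qual_fraction` (default 0.05).  The
  5 % rule is "more than 5 %": exactly 5 % passes, and a base at exactly
  Phred 20 is not low-quality.
* **Primer/MID location.** The expected structure is
  `MID(10) + forward_primer + insert + revcomp(reverse_primer) +
  revcomp(MID)`.  Both the read and its reverse complement are tried, and
  inserts are canonicalized to forward orientation, which makes variant
  identity well defined (platform software may or may not have oriented
  the reads).  Primer matching is positional (immediately after/before the
  fixed-length MIDs), allows `max_primer_mismatches` (default 0), and
  expands degenerate IUPAC codes (the forward primer carries a W).  MID
  matching is exact: no error correction is attempted, because barcode
  error-correction rules would trade determinism for yield.
* **Demultiplexing.** A read is assigned iff its
  (forward MID, reverse MID, run) triple matches a sample-sheet entry
  exactly; everything else is counted unassigned.
* **Reference screen.** Keep iff the best identity against any catalog
  sequence is ≥ `min_reference_identity` (default 0.80, inclusive).
  Identity is computed on the unit-cost global (Needleman–Wunsch)
  alignment produced by edlib as `matched columns / aligned columns`.
  This is the deterministic stand-in for the multiple-aligner screen such
  protocols use; with unit costs, the distance-optimal alignment is the
  natural match-maximizing alignment for divergences in this range.

Internally all coordinates are 0-based half-open; reports print 1-based
inclusive positions.

## Variant clustering and chimera flagging (Step II)

Identical inserts collapse to variants.  Relative frequency uses the full
pre-discard amplicon depth (singletons included in the denominator), so
frequencies are proportions of the amplicon, not of the surviving reads.
Count ties order lexicographically by sequence, making every downstream
step permutation-invariant in read order.  Singletons are recorded as
`singleton_discarded` rather than dropped silently.

The chimera rule is a deterministic simplification of de-novo chimera
detection, adequate for a fixed-length locus where single crossovers
dominate: a candidate is flagged iff two distinct equal-length
higher-count parents exist with `count ≥ skew × candidate_count` (default
skew 2.0 — the abundance-skew ratio is a config knob, since PCR chimeras
form late and are rarer than either parent) and some breakpoint `k` gives
`candidate = parent_a[:k] + parent_b[k:]`, with at least
`min_diff_each_side` (default 1) differences from each parent on its
non-contributed side.  The smallest qualifying breakpoint is reported.
Multi-crossover and >2-parent chimeras are out of scope.  The
implementation is checked against an exhaustive two-parent × breakpoint
oracle in the tests.

Distances between variants are Hamming for equal lengths and unit-cost
edit distance otherwise (homopolymer indels change lengths).

## Classification and replicate resolution (Steps III–VI)

Within each amplicon (independently, one workflow step completed
cohort-wide before the next): the most frequent surviving variant is a
putative allele; a flagged chimera is a chimera candidate; any other
variant is classed by distance to its **parent**, the nearest more-frequent
variant (ties: higher count, then sequence) — ≤ 2 bp means putative
artifact, > 2 bp putative allele.  The parent-selection rule (nearest by
distance, then by count) is our choice; the underlying assumption is only
that artifacts occur less frequently than the allele that spawned them.
A variant must also exceed `min_rel_freq` (default 0.01) in at least one
of its individual's replicates; otherwise it is an artifact outright.

Chimera rescue: the same flagged sequence above the frequency floor in ≥ 2
independent replicates is better explained as a real allele (a chimeric
molecule arises anew in each PCR), and is reclassed as a putative allele
before resolution.

Replicate resolution per variant sequence within an individual:

| evidence across replicates | final class |
|---|---|
| putative allele wherever present, present in ≥ 2 replicates | allele |
| putative allele in ≥ 1 but not all replicates | low-efficiency allele |
| > 2 bp variant in exactly one replicate, no cross-individual support | unclassified |
| never a putative allele | artifact |

Cross-individual evidence is applied in a fixed, documented staging (the
step structure is genuinely open in workflows of this family; we declare
one): (1) multi-replicate individuals are resolved with no cross evidence;
(2) their alleles and low-efficiency alleles form the cross-index;
(3) unclassified variants with cross support are rescued to low-efficiency
alleles; (4) single-amplicon individuals are then classified — dominant
variant → allele (without this the one-amplicon path would be allele-less
by construction), cross-supported variant → allele, unsupported > 2 bp →
unclassified, near-parent/chimeric/sub-floor → artifact; (5) the
deep-coverage correction runs last against the full cross-index.

**Deep-coverage correction.** At extreme depth no variant may fulfil any
artifact criterion, leaving an implausibly rich, artifact-free genotype.
For any individual with more called alleles than `max_alleles`
(= 2 × copy_number, generalizing the observed 2× excess under a 4-copy
locus) and zero artifact-classed variants, every called allele private to
that individual is demoted to artifact.  If shared alleles still exceed
the cap, an anomaly is reported — never silently truncated.

Finally the classes collapse: {allele, low-efficiency allele} → genotype
membership; {unclassified} → artifact.  No genotype can contain an
artifact- or unclassified-classed variant (asserted in tests).

Depth thresholding is inclusive (`depth ≥ min_amplicon_depth`, default
120; 25/60/200 selectable), applied before everything else; individuals
whose every amplicon fails are reported `insufficient_reads`.

Novel alleles are named `<locus_tag>*NN`, zero-padded, continuing the
reference catalog's numbering, in order of first cohort-wide appearance
(amplicons ordered by sample-sheet individual order; ties lexicographic by
sequence).  The caller is seed-free and fully deterministic.

## Verifications

* **Trios.** Concordant iff every offspring allele occurs in a parent.
  On mismatch the orphan alleles are listed and a parent is flagged as the
  dropout suspect when it shares no allele with the offspring while the
  other parent shares some — the signature of allelic dropout in the
  parent's own genotype.
* **Saturation.** OLS of allele count on mean per-amplicon depth
  (scipy `linregress`); a significantly positive slope (one-sided
  p < 0.05) warns that deeper individuals still gain alleles.  Degenerate
  inputs (constant allele counts or depths) return slope 0, R² 0 without
  fitting.
* **Threshold sensitivity.** The same amplicons are re-genotyped at
  alternative depth thresholds sharing one allele catalog, so comparisons
  reflect sequence content rather than naming order.

## Selection statistics

Nei–Gojobori (1986) with fixed, documented conventions:

* Site counts: each codon contributes exactly 3 sites; the synonymous
  fraction per position enumerates the three one-step mutants, and a
  change creating a stop codon counts as nonsynonymous.  Pair site counts
  average the two sequences.
* Differences: codons differing at 2–3 positions average synonymous /
  nonsynonymous steps over **all** minimal mutational pathways with equal
  weights; pathways through stop intermediates are not excluded.  These
  conventions coincide with Biopython's NG86 implementation, which the
  tests use as an independent cross-check alongside a brute-force
  enumeration oracle (exact agreement on all 61 × 61 sense-codon pairs).
* Distances: both raw proportions (pN, pS) and Jukes–Cantor corrections
  (−3/4·ln(1 − 4p/3)) are available; the correction is undefined (NaN,
  flagged) at p ≥ 3/4.  dN and dS for an alignment are means over all
  sequence pairs of per-pair estimates — a ratio of means per pair, then
  averaged, not a ratio of grand totals.
* Uncertainty: standard errors come from resampling codon sites with
  replacement (default 1000 replicates, seeded);
  Z = (dN − dS)/SE_boot(dN − dS) with the one-tailed standard-normal
  upper-tail p-value, so only dN > dS counts as evidence of positive
  selection.
* Gaps/ambiguity codes use pairwise deletion (the codon column is skipped
  for that pair).  In-frame stop codons in input alleles are an error,
  reported with sequence and codon position.

The shipped ABS mask (15 of 57 codons) is a consensus-derived
approximation of the human DRB peptide-contact residues falling in this
window; it is labeled synthetic and user-overridable, and the ABS/non-ABS
partition is only as trustworthy as the mask supplied.

## Simulator

The generator reproduces the statistical structure the caller assumes,
with defaults set to the study conditions of the motivating system:

* **Pool.** 171-bp codon-structured, stop-free alleles descended from one
  random coding ancestor at `pool_divergence = 0.035` per base, giving
  mean pairwise differences near 2 × 0.035 × 171 ≈ 12 bp — the
  hypervariable-exon regime — rather than random-sequence distances;
  rejection-sampled so every pair differs by ≥ 3 bp, keeping true alleles
  out of each other's 1–2 bp artifact neighborhoods (set
  `pool_divergence=None` for fully random pools).
* **Genotypes.** `copy_number` (default 4) draws with replacement,
  uniform over the pool: 1–4 distinct alleles per individual.  Up to 7
  distinct observable alleles, as under a two-locus reading of the same
  data, can be emulated by raising `copy_number`.
* **Efficiency and depth.** Per-(individual, allele) amplification
  efficiency ~ uniform(0.5, 1.0) by default; template choice per read is
  proportional to copy dosage × efficiency — the minimal model producing
  allelic dropout and allele/artifact frequency overlap.  Depth per
  replicate is negative binomial (mean 500, dispersion 5 by default,
  reproducing wide real-world coverage ranges), optionally truncated below
  or overridden per amplicon (used by the marginal-depth scenarios).
* **Errors.** Substitutions at 1e-3/base; ±1 bp slips in homopolymer runs
  ≥ 3 at 5e-3/run; single-crossover chimeras (uniform breakpoint, parents
  dosage-weighted) at 2 % of reads; platform profiles are coarse
  multipliers (454-style doubles homopolymer indels; PGM-style halves
  substitutions), not flowgram simulations.  Qualities are drawn Q30–Q40,
  so quality filtering is exercised but rarely triggered.  Half the reads
  are emitted reverse-complemented.
* **Truth.** Every read records its source allele or chimera parents +
  breakpoint and its error counts; genotypes and efficiencies are emitted
  as TSV, so any genotyping miss can be attributed.

What the simulator does **not** emulate: flowgram-level error structure,
quality-score miscalibration, sample contamination, index hopping,
pseudogenes, copy-number variation between individuals, and
primer-binding-site variation.  Passing the end-to-end tests therefore
shows the workflow's logic is correct under its stated error model, not
that real platform data will match these recovery rates.

## Scenario sizes and numerical choices

The bundled validation scenarios use 50 individuals (noiseless,
depth 500), 100 individuals (noisy, depth ≥ 120), and 60 individuals
(marginal-depth threshold comparison, where a handful of individuals
receive only 65–110-read amplicons so the 60-read threshold admits them
and the 120/200 thresholds exclude them identically) — sizes chosen so the
whole validation runs in about a minute while keeping binomial sampling
noise far from the asserted margins.  Relative-frequency sums are checked
to 1e-9; NG86 oracle agreement to 1e-12; bootstrap reproducibility is
exact under a fixed seed.

## Known limitations

* Alleles cannot be phased to specific gene copies, and copy number is an
  input assumption, not an inference.
* The chimera rule misses chimeras whose parents differ only on one side
  of the breakpoint and all multi-crossover forms; the replicate
  comparison is the backstop.
* The reference screen can discard heavily chimeric reads between very
  divergent alleles (identity below threshold to both parents); these are
  artifacts in any case.
* A true allele within 2 bp of a more frequent allele of the same
  individual would be classed as its artifact; the simulator's pool
  spacing models the assumption, it does not remove it.
* MEGA-style analytical SEs are not provided; only bootstrap SEs.
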