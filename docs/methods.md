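# Methods

## Scope and model

neoscreen quantifies how likely the neopeptides generated by a missense
mutation are to be presented by HLA class I complexes across a population.
It deliberately stops at presentation: T-cell recognition, tolerance,
expression weighting and clonality are out of scope, as are HLA typing from
sequencing reads and the internals of the rank predictor.

The unit of input is a single amino-acid substitution ("isolated" — compound
mutations and zygosity are not modeled, since patient-level co-occurrence is
generally unavailable in public catalogs), a protein sequence it maps onto,
and a panel of individuals each typed at four-digit resolution for their six
class I allotypes. The unit of evidence is an eluted-ligand percentile rank
per (peptide, allotype), consumed from NetMHCpan-4.0 output or any source
honoring the same contract.

## Peptide windows

For a mutation at protein position *p* (1-based) on a protein of length
*N*, windows of length L ∈ {8, 9, 10, 11} with start in
[max(1, p−L+1), min(p, N−L+1)] are enumerated; each mutant window is paired
with the unmodified (wild-type) window. The count is 38 exactly when
p ∈ [11, N−10] and N ≥ 21, and the smaller closed-form count otherwise.
The "edge of transcript" condition is interpreted at the protein level
(positions ≤ 10 or > N−10), which is the reading consistent with the 38-pair
arithmetic. Windows containing a non-standard residue ('*', 'X', 'U' occur
in EnsEMBL peptide files) are skipped individually; the mutation is kept.

Mapping precedence: an explicit transcript id wins; otherwise the gene's
canonical transcript, then non-canonical transcripts, then any record for
the gene. A candidate is accepted only if its sequence carries the
wild-type residue at *p*; otherwise the mutation is discarded with a
reason (`no_transcript`, `residue_mismatch`, `position_out_of_range`).

## Score definitions and numerical choices

BR per (mutation, allotype) is the minimum rank over mutant windows whose
Icore spans the mutated residue. Where an Icore substring occurs at several
placements within the window, one spanning placement suffices. Two edge
rules are fixed here because the source conventions leave them open:

- **Sentinel BR = 100** when no window is eligible. 100 is the rank-scale
  maximum, preserves "not presented" semantics, and keeps harmonic means
  finite.
- **Ranks of exactly 0** (predictor rounding) are clamped to 1e-3 before
  harmonic means, with a log notice.

PHBR is the harmonic mean of the 2×|loci| BR values (all three loci by
default; the HLA-C pair can be dropped via the `loci` argument, reflecting
lower HLA-C surface expression). IBR is the minimum. PMHBR is the median
PHBR over the panel, midpoint convention for even panel sizes, no
deduplication of identical haplotypes. All presentation thresholds use
strict "<"; wild-type non-presentation uses "≥" — mirroring the asymmetry
in the criterion definitions. Percentages are reported unrounded
internally and to one decimal in text outputs.

For the mutant-vs-wild-type criteria, the mutant member's MinRank is taken
over the individual's allotypes restricted to records whose Icore spans the
mutation (the pair is ineligible if no such record exists); the wild-type
member's MinRank is over all the individual's allotypes. The mutant rank is
taken from the full-window record rather than re-queried on the bare Icore
sequence; this is the cheaper and more conservative of the two readings
(`icore_requery` would be the place to flip it, deliberately not exposed
until a use case demands it).

## Haplotype handling

Allotype names are normalized from the dialects in circulation ("A*03:01",
"HLA-A03:01", "HLA-A*03:01", colon-less "A0301", bare "03:01" with a
locus-bearing column) onto one canonical rendering; names without
four-digit resolution are rejected. Typing ambiguity ("/"-separated
alternatives) keeps the first entry. Individuals are dropped, and logged
with a reason, when any of their six allotypes is malformed, on a
configured exclusion list, or absent from the predictor's library.
Expression-suffixed names (e.g. N-nulls) are *not* globally rejected — only
via the exclusion list or library check — because the upstream exclusions
are specific names, not a suffix class. Duplicate individual ids keep the
first row. Allele frequencies are counts over 2× panel size per locus;
"common" alleles are those strictly above a frequency cutoff (default 1%),
ordered per locus by descending frequency, ties by name.

## Cohort statistics

Kruskal-Wallis (tie-corrected, chi-square reference), Dunn's all-pairs post
hoc on pooled mid-ranks with the standard tie term, adjusted by Bonferroni
multiplication capped at 1 (the adjustment used by common commercial
packages is unpublished; Bonferroni is the documented, conservative
stand-in), two-tailed Mann-Whitney, and two-tailed Wilcoxon signed-rank.
Exact branches: Mann-Whitney enumerates when the pooled sample is ≤ 12
without ties; Wilcoxon uses the exact distribution up to 15 nonzero pairs;
both switch points are module constants chosen where exact computation is
instantaneous. Degenerate inputs (all values identical) return H = 0,
p = 1 with a warning from the omnibus tests and raise a typed error from
the pairwise ones. Proportion-matched resampling draws with replacement
with per-stratum counts fixed by largest-remainder rounding, deterministic
under a seed. Mann-Whitney pairwise reports are deliberately unadjusted
while Dunn reports are adjusted; no unified FDR policy is imposed.

## Carrier screening

A VCF record is a carrier hit when position/ref/alt match a cataloged
target, FILTER is PASS, and the annotated transcript (configurable INFO
key; comma-separated lists accepted, version-insensitive) contains the
target transcript. VAF preference: per-sample allele depths
(alt/(ref+alt)), then a per-sample AF field, then a site AF, else missing
with a warning. Samples with two or more distinct target hits can be
excluded wholesale. Upstream curation steps that depend on private cohort
metadata (first-biopsy status, treatment matching, deduplication labels)
are a documented checklist for the analyst, not code.

## The synthetic-data generator

The generator emulates the shape of the real inputs, not their content:

- **Panels** are drawn under Hardy-Weinberg sampling (two independent
  draws per locus) from an allele-frequency spectrum. The default spectrum
  is Zipf-shaped (f_k ∝ 1/k) with 25/35/20 allotypes at A/B/C — a few
  common alleles and a long rare tail, HLA-B most diverse, as in population
  references. No linkage disequilibrium between loci.
- **Proteomes** are uniform random sequences; planted mutations always
  match the wild-type residue and cycle through position strata (first
  residue, N-terminal edge, interior, C-terminal edge, last residue) so
  window-count edge cases are always exercised.
- **Ranks** come from a seeded hash of (seed, peptide, allotype) mapped
  onto [0.01, 100] through a power-warped log-uniform transform,
  rank = lo·(hi/lo)^(u^α), with α calibrated so that P(rank < 0.5) equals a
  configurable strong-binder mass (default 0.005, i.e. 0.5% of random
  peptides are strong binders — percentile-rank-like semantics). Icore is
  the full peptide, so every background window spans its mutation.
- **Planted signals** give one chosen window of a mutation a target rank
  (< 0.5) on the designated strong allotypes, floor its wild-type
  counterpart at ≥ 0.5, and floor *every other* rank of that mutation's
  windows — on strong and non-strong allotypes alike — at 2.5, above the
  presentation threshold. The across-allotype floor is a deliberate design
  choice: it makes the Hardy-Weinberg carrier probability
  100 × (1 − Π_locus (1 − q_locus)²) the *exact* expected value of the
  pipeline's coverage estimate, so planted-recovery tests compare against
  a closed form rather than a second simulation.

What passing these tests shows: the score algebra, the eligibility and
sentinel rules, panel bookkeeping and the coverage estimators are correct,
and the full pipeline recovers planted ground truth within sampling error.
What they do not show: anything about real binding motifs (background ranks
are peptide-content-free hashes), real linkage or population structure, or
the accuracy of the upstream predictor.

## Problem sizes and determinism

Test and acceptance runs use panels of 30–2,000 individuals, proteomes of
up to 20 genes, and 2,000-replicate null calibrations — sizes at which each
check's sampling error is far below its assertion band while the whole
suite stays quick on one core. All randomness flows through explicit seeds
(numpy `default_rng` or seeded hashing); reruns with identical
configuration are byte-identical, and every CLI run writes a manifest with
a sha256 over its configuration.

## Known limitations

- Presentation rank is a weak proxy for immunogenicity; mutant-below-wild-
  type comparison is itself a rough tolerance heuristic.
- The NetMHCpan adapter records its command line but cannot validate the
  predictor's allotype library without invoking it.
- The COSMIC loader binds only gene/transcript/substitution/id columns;
  tissue and drug annotations pass through untyped because their column
  names drift across releases.
- Indels, frameshifts and fusion junction peptides are out of scope; only
  single amino-acid substitutions are modeled.
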