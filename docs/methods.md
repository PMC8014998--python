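# Methods

This note documents the models, conventions and numerical choices in
`ntails`, and what the synthetic ground-truth generator does and does
not emulate.

## Coordinates and positional categories

All protein coordinates are 1-based and inclusive (UniProt feature
convention). A cleavage "before position p" lies between residues p−1
(P1) and p (P1′); a feature spanning 1..k implies the mature protein
starts at k+1. A peptide start is *expected* when it matches position 1
or 2 of the protein model (translational start with or without
initiator-Met removal) or falls within ±`window` residues (default 5,
symmetric and inclusive) of the mature start implied by a signal
peptide (SP), mitochondrial targeting signal (MTS) or propeptide (PP)
feature; everything else is *unexpected*. On collisions the tag
precedence is P1/2 > SP > MTS > PP. The ±5 window absorbs both
annotation uncertainty and genuine one-to-few-residue aminopeptidase
trimming after processing-peptidase cleavage. Annotated and predicted
features are tagged but treated identically.

Peptide-to-protein mapping uses the evidence table's stated accession
and the first substring occurrence; multiple occurrences set an
ambiguity flag rather than being resolved. Unique termini are keyed by
(protein, start) — peptides differing only in C terminus, Lys label
state or N-terminal modification collapse, summing spectral counts and
keeping the modal N-terminal modification. Ragging clusters are maximal
runs of ≥2 termini with successive gaps ≤ `gap_max` (default 2; the
phenomenon is sequential single-residue trimming, and 2 keeps clusters
local while tolerating one unobserved intermediate); the most prevalent
member is the highest total spectral count, ties breaking to the most
N-terminal position.

## Evidence filters and QC

Three exclusion rules implement ArgC consistency for dimethyl-TAILS
data: pyro-Glu N termini (sample-preparation artifacts), peptides
without a C-terminal Arg (exempting peptides that end at the protein C
terminus, where ArgC cannot produce an Arg), and dimethyl reported on
N-terminal Pro (chemically implausible secondary amine labeling).
Labeling QC reports the fraction of Lys residues carrying either
dimethyl label (threshold ≥ 0.98) and the fraction of peptides flagged
as cleaved after a dimethylated Lys (threshold < 0.06); the
cleaved-after flag is taken from the input table since deriving it
needs the search engine's preceding-residue context. Protein-level
ratios from pre-enrichment samples are recomputed as the median over
Lys-containing quantified peptides (median of per-peptide medians;
robust, and the combiner convention of the upstream software).

## Quantification model

Per-replicate terminus ratios are the median over supporting peptides
quantified in that replicate. Normalization subtracts, per replicate,
the median ratio of expected-category termini of mitochondrial
proteins — the population expected at 1:1 — which removes run-to-run
differences in co-purified non-mitochondrial material; the reference
median is exactly 0 afterwards, and the operation is idempotent.
Replicates are combined by the arithmetic mean of normalized log2
ratios for termini quantified in ≥ `min_reps` (default 2) of
`total_reps` (default 3); others are `not_quantified`.

The expected/unexpected comparison uses a two-sided Mann–Whitney *U*.
For min(n) ≤ 8 the null distribution of U is enumerated over all
labelings of the pooled sample (valid under ties); larger samples use
the normal approximation with tie and continuity correction.

The differential cutoff is a Tukey fence: Q1 − k·IQR and Q3 + k·IQR
(k = 1.5) of the normalized ratios of termini mapping to proteins whose
independent LFQ quantification showed no significant change
(`significant_flag` false). Quartiles use linear interpolation
(quantile type 7), recorded in `CutoffBounds.method` because boxplot
conventions differ between tools. Calls are strict: a mean exactly at a
bound is `unchanged`. A fixed symmetric cutoff (e.g. ±0.9) is available
as a config override when no reference set exists. No multiple-testing
correction is applied across termini — calling is by effect-size
cutoff, not per-terminus testing.

## Cleavage logos and N-end-rule profile

Windows are P5..P1 | P1′..P5′ (configurable), padded with `-` beyond
protein ends; padding is excluded from per-position totals. Enrichment
per (position, residue) is 100·(observed − reference frequency), with
the reference model being the overall residue composition of the
in-scope proteome (mitochondrial-only by default for mitochondrial
analyses; configurable, and results are labeled with the reference
used). Significance is an exact binomial test, two-sided by doubling
the smaller tail — chosen over sampled-reference approaches for
determinism and oracle-testability; no correction across cells by
default (a BH option exists). The N-end-rule split uses a static
bacterial classification (stabilizing: A,S,T,G,M,V,I,C,P,H; secondary
destabilizing: D,E,N,Q; primary destabilizing: L,F,W,Y,R,K).

## Proteoform masses

Atomic and residue masses are hard-coded IUPAC/standard values in one
constants file; 13C and D are distinct elements so label compositions
with negative H counts (e.g. heavy dimethyl = 13C2 D6 H−2) recompute
exactly. Truncated-proteoform masses default to the average scale
(intact, kDa-range display); chains are computed unmodified, with
modification deltas exposed separately for callers that want them.

## Trapping screen

Missing LFQ values are imputed per column from
Normal(mean − 1.8·sd, (0.3·sd)²) of the observed values — the de-facto
default downshifted-normal model for intensity-dependent missingness —
once, with a recorded seed, before testing; a multi-seed
classification-stability mode reports sensitivity to the imputation
draw. One-way ANOVA per protein across NEG/WT/TRAP is BH-corrected over
all tested proteins (all-equal degenerate rows get p = 1 by
convention). Tukey HSD uses the pooled within-group mean square and the
studentized-range distribution (k = 3). Reported log2 enrichments are
differences of group means computed on observed values where available
(imputed cells excluded from the headline enrichment but included in
the test), avoiding imputation-inflated fold changes. Proteins detected
in ≥2 replicates of one condition and never in another are listed in a
presence/absence table, since impute-then-ANOVA can miss them.

## Synthetic data generator

The generator's defaults define the standard study conditions: 300
proteins, 70% mitochondrial; MTS lengths from a truncated
Normal(35, 10) on [15, 80]; mature-start residues drawn from a
stabilizing-biased mix (S 0.30, A 0.25, T 0.15, G 0.10, M 0.10, other
0.10); MTS cleavage motifs Arg-at-P2 with probability 0.6, Arg-at-P3
with 0.3 (with a Phe/Tyr/Leu at P1 in 80% of those, emulating
ICP55-style one-residue trimming), none 0.1. Mature lengths are uniform
on [100, 400]. Each mitochondrial protein yields its mature-start
terminus, ragged +1..+3 satellites with probability 0.5 (geometric
depth), and Poisson(2) internal neo termini carrying a global
+0.32 log2 shift; 10 substrate proteins add 2 strongly accumulating
(Normal(+2.0, 0.3)) and 2 strongly depleted (Normal(−2.0, 0.3)) termini
each, the depleted ones placed at Arg-P1 sites with probability 0.7.
15% of proteins get a protein-level abundance change (Normal(0, 0.8))
and are flagged significant in the emitted LFQ table, as are substrate
proteins, so the cutoff-reference selection is exercised end to end.
Observed replicate ratios are truth + Normal(0, 0.3); missingness
probability decays with the replicate's spectral count
(0.35·exp(−count/4) + 0.05), and spectral counts are Poisson with
tier-specific means (expected 6, substrate 4, neo 2). Termini whose
first residue is Pro are emitted with a free N terminus (dimethylation
does not occur on Pro). A small set of artifact peptides (pyro-Glu,
missing C-terminal Arg, Pro-dimethyl) exercises the filters.

The trap matrix has 185 null proteins, 10 substrates (+3.0 in TRAP
only) and 5 interactors (+2.5 in WT and TRAP) on a Normal(25, 2)
baseline with replicate noise sd 0.4; cells below the 0.15 quantile of
all intensities go missing with probability 0.8 (MNAR).

Randomness comes from seeded NumPy substreams
(`default_rng([seed, k])`, one per artifact) with a fixed draw order,
so a seed reproduces every file byte-identically. What the generator
does **not** emulate: peptide-level identification error and FDR,
charge/retention behaviour, shared peptides across protein groups,
correlated replicate structure, empirical (non-uniform) background
residue frequencies (uniform by default so binomial oracles are exact),
and isoform-level ambiguity. Passing tests therefore demonstrate
correctness of the statistical machinery under the planted model, not
robustness to every artifact of real LC-MS data.

## Problem sizes and measured quantities

The test suite and the acceptance script run the generator at its
default scale (~900 evidence rows, ~860 termini; 200-protein trap
matrix) and over 20 seeds where rates are averaged (null
false-discovery control, shift recovery). Recall and false-call rates
are measured among quantified termini: recall of planted substrate
termini over those quantified in ≥2 replicates, and false calls over
no-effect termini (expected/ragging termini on proteins with no
planted change) — neo termini carry the true global shift by
construction and are not nulls.

## Known limitations

* Mapping trusts the stated accession; many-to-many peptide/protein
  inference is out of scope.
* The uniqueness key (protein, start) merges in-vivo acetylated and
  labeled termini; a configurable key would be needed to separate
  co-translational acetylation biology.
* The exact Mann–Whitney path enumerates combinations and is
  exponential; it is restricted to min(n) ≤ 8.
* Imputation model assumes per-column Gaussian observed intensities;
  heavy-tailed columns will shift the imputed mean.
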