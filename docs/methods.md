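# Methods

`venomdyn` couples two scales of analysis of a venom expression
phenotype: comparative models of toxin-family expression across a
species phylogeny, and a microevolution toolkit for a clustered,
near-identical toxin gene family within one species (transcriptomic
variant recovery, amplicon haplotyping, qPCR copy number, locus
architecture). This note records the models, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## The venom expression phenotype

The phenotype of a sample is the vector of toxin-family fractions
`f_k = TPM_k / sum_j TPM_j`, where `TPM_k` is the cumulative TPM of all
transcripts annotated to family `k`. A family is *dominant* when its
fraction strictly exceeds the dominance threshold (default 0.5, i.e.
">50%"). Strict inequality means a family is dominant iff its expression
exceeds that of all other families combined, so no tie-break is needed
at the default threshold. Compositions with zero total annotated TPM are
flagged undefined rather than silently zero-filled. Species-level
composition is the mean of per-sample fractions, renormalized.

Toxin discovery itself (ORF calling, homology search, signal-peptide
prediction) is upstream of this package; the annotation table is an
input. Only the cysteine-framework check from that curation protocol is
implemented: a mature peptide's framework is the string
`C<g1>C<g2>...C` of inter-cysteine residue counts, and two frameworks
match when they have equal cysteine counts and gap-wise differences
within a tolerance.

## Trait-evolution models

All comparative models are parameterized on a rooted, time-calibrated
(ultrametric) phylogeny through its shared-path matrix `s_ij` (the
root-to-MRCA distance of tips i and j) and height `T`. Trees are
consumed already calibrated; a mean-path-length rescaling utility exists
for convenience but is not a substitute for proper dating. Expression
traits are analyzed on the `log(TPM + 1)` scale (expression spans orders
of magnitude); compositions are reconstructed on raw fractions.

* **BM** — displacement over a branch of length `t` is `N(0, sigma2 t)`.
  Tips are multivariate normal with covariance `sigma2 s_ij`. The
  likelihood is evaluated in O(n) by Felsenstein pruning; the ML fit is
  closed form (GLS root mean, rate with ML divisor n; k = 2).
* **OU** — pull `alpha` toward an optimum `theta`, with the root fixed
  at the optimum. This non-stationary variant is used because the
  stationary root is not identifiable on ultrametric trees. Covariance
  `V_ij = sigma2/(2 alpha) e^{-2 alpha (T - s_ij)} (1 - e^{-2 alpha s_ij})`;
  (theta, sigma2) are profiled analytically and `alpha` is maximized on
  a 40-point log grid over `[1e-4/T, 50/T]` refined by bounded scalar
  minimization (k = 3).
* **EB** — early burst, rate `sigma2 e^{r t}` with `r <= 0`; covariance
  `sigma2 (e^{r s_ij} - 1)/r`, with the `r -> 0` limit handled
  analytically as BM. Same profile-plus-grid optimizer over r (k = 3).
* **JN (pulsed)** — jump-normal Levy process: Brownian drift plus a
  Poisson(`jump_rate * t`) number of `N(0, jump_var)` jumps per branch.
  See numerics below (k = 4).

Model support is compared by Akaike weights
`w_i = exp(-(AIC_i - AIC_min)/2)`, normalized.

### Jump-normal numerics

The JN likelihood is computed by pruning where every partial message is
a finite mixture of normals:

* per branch, the Poisson jump count is truncated at the smallest K with
  tail mass `< 1e-8` (accumulated iteratively, no special functions);
* multiplying two child messages multiplies the mixtures component-wise
  (a product of two normal densities in the node state is a scaled
  normal);
* components with relative weight `< 1e-10` are dropped; above the
  component cap the mixture is reduced by a moment-matching merge.

Two merge tiers trade accuracy for speed. Fits on comparative-scale
trees use a cap of 256 components and a fast sort-free merge: the 128
highest-weight components are kept exact and the tail is binned on a
(mean, log-variance) grid, each bin replaced by its moment-matched
normal. Small problems (<= 8 tips), where likelihoods are checked
against quadrature/enumeration oracles at 1e-6, raise the internal cap
to 8192 — at moderate jump rates merges then essentially never fire and
the only error sources are the two quantified truncations — and use a
near-lossless greedy pairwise merge if one does. Outer products are
additionally capped at 4M entries to bound memory; at `jump_rate = 0`
every mixture has one component and the recursion reduces exactly to BM
pruning (agreement to 1e-8 is a test).

The ML fit optimizes `(log sigma2, log jump_rate, log jump_var, root)`
by Nelder-Mead, seeded by a coarse scan that splits the BM total rate
between drift and jumps at several jump rates. The jump rate is bounded
at `10/T`: beyond roughly ten expected jumps per tree height the pulsed
process is statistically indistinguishable from BM (jump effects
central-limit into Gaussian noise), so the bound costs nothing
statistically and keeps mixtures small. When the coarse scan finds no
likelihood gain over the BM submodel the polish budget is reduced and
the search confined to the identifiable low-rate region; the reported
JN likelihood is never allowed below its own BM submodel's.

### Ancestral states, signal, covariance

Ancestral reconstruction under BM is two-pass Gaussian message passing
(upward tip summaries, downward combination), which for a Gaussian model
equals the joint-ML / GLS predictions; reported variances scale with the
ML Brownian rate. Compositions are reconstructed per family fraction
independently, then clipped to [0, 1] and renormalized — an explicit
design choice; a logistic-normal treatment is out of scope.

Phylogenetic signal is reported as Pagel's lambda (off-diagonal scaling
of the BM covariance, ML over `[0, lambda_max]` with `lambda_max` the
positive-definiteness boundary found by bisection). Lambda is a closed,
testable definition of signal; it is not numerically identical to the
MCMC heritability some studies report, though both live on a [0, 1]
scale.

The multivariate evolutionary covariance `R` is estimated by ML
multivariate BM (GLS root mean, (n-1)-divisor covariance of the
C-whitened residuals). Uncertainty comes from a parametric bootstrap:
B datasets are simulated under the fitted matrix-normal model
(row covariance C, column covariance R), refit, and entry-wise 95%
percentile intervals taken; an off-diagonal entry is significant when
its interval excludes zero. This replaces a Bayesian mixed-model
treatment with a fully specified, desk-scale frequentist analogue; the
two need not agree numerically. The phylomorphospace is the
eigendecomposition of `R`: tip scores are centered traits projected on
the eigenvectors, ancestral scores are the BM reconstructions projected
into the same plane, and variance fractions are eigenvalues over the
trace.

## Transcriptomic variant recovery (collapsed gene model)

Reads from all copies of the near-identical gene family map to a single
collapsed gene model. Each mate of a pair is placed by glocal alignment
(global in the read, free end gaps in the model) with scores
match +1 / mismatch -1 / gap open -2 / gap extend -1, both strands
tried; a pair is rejected when the best identity over aligned bases
falls below 90%, mirroring mapper acceptance. Full dynamic programming
is used — at a few hundred bp a band is a speed heuristic with no
accuracy benefit. The pair consensus covers the union interval;
uncovered interior positions emit N; overlap disagreements resolve to
the higher-quality base when qualities are present, else N.

Consensi are trimmed to a common fully-covered region ("identical
sequences" is only well-defined on a shared interval), exact-clustered,
and retained when they fall in the most-abundant prefix holding 70% of
all sequences or carry >= 10 identical copies (the two routes combine as
a union; the source protocol's "or" is ambiguous and a dataset-specific
single-sample exception to this rule is deliberately not special-cased).
The Nv3-vs-Nv1 diagnostic classifies sequences by the signature motifs
AAACGCGGCTTTGCT (KRGFA) and AAACGCGGCATTCCT (KRGIP); both motifs in one
sequence is an error.

## Amplicon haplotyping

Joined amplicons are kept when 300-500 bp (inclusive) and free of
non-ACGT characters; primers are stripped from both ends allowing one
substitution each. Each sample is subsampled without replacement to
exactly 14,800 reads; shallower samples are excluded. A sequence is a
biological variant iff it reaches 100 reads in at least one individual
AND occurs in more than one individual (the alternative conjunction —
100 reads in two individuals — is available behind a flag). Samples are
clustered by `1 - Spearman rho` of abundance profiles with complete
linkage (the linkage is not stated by the source protocol; complete is
the common heatmap default) and deterministic ordering.

Core haplotypes — variant sets that travel together on one chromosome —
are deduced by exact search: candidates are the distinct observed
presence-sets (a homozygote's whole set is one haplotype), and the
result is the minimum-cardinality subset whose one-or-two-member unions
explain every individual, ties broken by maximizing homozygote-explained
individuals, then lexicographically. Presence is thresholded at the
variant-calling abundance; heterozygote dosage is deliberately not used.
Identifiability caveat: when one true haplotype's variant set equals the
union of two others, the minimal cover cannot distinguish that
homozygote from a heterozygote, and no presence/absence method can. The
recovery tests therefore simulate pools in which each haplotype carries
at least one private variant, which provably makes the cover unique.

## qPCR copy number

Within each triplicate and gene, reactions are kept when the maximum
pairwise Cq difference is <= 0.2 cycles; otherwise the single most
outlying reaction whose removal restores tolerance is dropped (for both
genes — the reactions are multiplexed), else the whole triplicate.
Per-reaction `dCt = Cq_target - Cq_control` is averaged per individual,
`ddCt` subtracts the calibrator's mean dCt, and
`copies = calibrator_copies * 2^(-ddCt)`, assuming efficiency exactly 2
for both assays once the dilution-series gate
(`E = 10^(-1/slope) - 1` within 90-110%) passes. Copy numbers are
reported as continuous values; rounding is presentation. Population
effects are tested by two-way ANOVA (copies ~ population * plate, Type
II sums of squares for unbalanced designs) with Tukey-Kramer pairwise
comparisons and a compact letter display.

The simulated plates draw one noise term per reaction shared by both
genes: the genes share a physical well, so template and pipetting noise
are common to the multiplexed pair and cancel in dCt — the property the
multiplex design exploits. An optional independent per-gene noise term
is available; it does propagate into dCt and, at realistic magnitudes,
makes integer-exact recovery of 20+ copies impossible (a 0.06-cycle dCt
error is a full copy at that scale).

## Locus architecture

A locus haplotype is an ordered array of gene copies with strands,
0-based half-open coordinates, pseudogene flags, and intergenic gaps.
Pseudogenes are flagged for premature stops, missing ORF starts, or
mature peptides shorter than 80% (configurable) of the expected length.

Tandem duplication units are maximal label-periodic runs (period u,
>= 2 unit copies) whose corresponding intergenic gaps agree within
max(20% relative, 500 bp absolute) — gap variation at a tandem locus is
on this order; runs are recorded from every start and overlap is
resolved by preferring smaller periods, then longer spans, then smaller
starts. Haplotypes are compared by breadth-first search for the minimal
number of tandem block duplications / contiguous block deletions
transforming one label sequence into the other, capped at a maximum
event count. Note that this event count is direction-dependent: one
block deletion can undo two nested duplications (`a -> aaaa` needs two
doublings, the reverse needs one deletion), so only single-event pairs
are guaranteed symmetric.

Non-B DNA motif scanning reports maximal exact inverted repeats (arm
>= 6 bp, loop <= 100 bp) and poly(G)/poly(C) runs >= 8 bp; thresholds
are declared defaults, not inferred from data. Breakpoint context lists
motifs overlapping a +/- 500 bp window with signed distances.

## Synthetic data: what it emulates, what it does not

The generator produces every input the pipeline consumes: pure-birth
trees scaled to unit height (with the Exp(n*lambda) waiting time after
the last birth appended so no branch is zero); traits simulated
*recursively along branches* — a code path independent of the pruning
likelihoods, so recovery tests are not circular; Hardy-Weinberg diploid
populations from a haplotype pool (optionally redrawn until every
haplotype has a homozygote); copy-number-proportional amplicon reads
with per-base substitution errors; triplicate multiplex Cq plates; and
paired reads from a cluster of expressed gene copies.

Not emulated: PCR chimeras, instrument-specific quality profiles, indel
errors, primer-site polymorphism, mapping ambiguity against a full
genome, and linkage between locus architecture and expression. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated generative assumptions, not robustness to every
artifact of real sequencing data.

## Problem sizes and tolerances in the test suite

Likelihood oracles run on 2-6 tip trees at 1e-6; model-selection
recovery uses 100 pure-birth trees of 64 tips per generating regime
(jump rate 0.5/T with jump variance 10 sigma2 T, and plain BM) — sizes
chosen to give the selection experiment adequate power while keeping the
suite desk-scale; copy-number recovery uses 1000 individuals at Cq noise
sd 0.05; haplotype deduction uses 50 populations of 2-6 haplotypes;
rule-equivalence checks run 100-500 randomized instances per operation
against brute-force reimplementations. All randomness is seeded; the
suite is deterministic.

## Known limitations

* The OU fit fixes the root at the optimum; ancestral OU optima and
  regime shifts are out of scope.
* The JN fit's jump-rate bound (10/T) means extremely frequent small
  jumps are reported as their BM limit, which is the correct statistical
  statement but collapses a formally distinct parameter region.
* Compositional ASR by clip-and-renormalize can distort near-boundary
  compositions; fractions remain valid but are not a generative model.
* The haplotype cover is exact only up to the identifiability limit of
  presence/absence data described above.
* The locus event distance is a parsimony count over two event types;
  it is not a likelihood and ignores gap lengths.
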