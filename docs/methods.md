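# Methods

This note records the models implemented in `mhc2popkit`, the numerical
choices behind them, and what the synthetic-data generator does and does not
emulate.

## Sequence model and conventions

The unit of analysis is a gap-free, in-frame nucleotide alignment whose
length is a multiple of three (default 198 sites = 66 codons, the MHC class
II β1 domain amplicon). Codons are numbered 1-based. Gaps are rejected
outright — the amplicon is length-invariant, so a `-` indicates an upstream
curation error rather than indel variation to be modelled. The only
ambiguity code accepted (behind an explicit flag) is `N`; codons containing
`N` translate to `X`, and sites carrying `N`/`X` are dropped pairwise in
distance and diversity calculations. No `N`s are expected in validated
haplotype sets.

The default peptide-binding-site (PBS) partition is the 20-codon set
{8–10, 12, 16, 17, 19, 20, 26, 39, 42, 43, 48, 49, 52, 53, 56, 60, 63, 66},
the codons under diversifying selection in the gull study system this
package models. Any other partition (for example a human-derived
binding-groove set) can be supplied as a plain codon list.

## Allele validation

Haplotype identity is exact nucleotide identity: no mismatch radius, no
chimera detection, no denoising beyond the count rules. Classification
precedence: a stop-bearing haplotype that satisfies either count rule is a
pseudogene (pseudogenes are real products of non-classical loci and are kept
as haplotypes, though excluded from coding-sequence statistics); a
stop-bearing haplotype that fails both count rules is still an artifact.
Independent PCRs are counted as distinct (individual, PCR) reactions, so a
haplotype seen once in each of two individuals has two independent
verifications. The two-PCR requirement applies to putative-true and unique
alleles alike and is configurable for pseudogenes, where protocols differ.

## Diversity statistics

* *S*: columns with ≥ 2 distinct non-`N` states.
* *K*: mean pairwise difference count; π = K / analyzed sites. Over a set
  of distinct haplotypes these are allele-level (unweighted) quantities;
  over one sequence per individual they are population-level
  (frequency-weighted). Both are meaningful and the caller chooses by what
  it passes in.
* *Hd* = n/(n−1)·(1 − Σ pᵢ²) over sequence frequencies.
* p-distances: mean pairwise proportion of differing positions, at the
  nucleotide or translated-peptide level. Standard errors come from a
  bootstrap that resamples **codons** (not sites), preserving the reading
  frame; 1000 replicates by default, seeded. For display tables values are
  rounded half-away-from-zero to 3 decimals.

## Nei–Gojobori dN/dS

Classic (unmodified) counting. Potential synonymous sites per codon:
s = Σ over the three positions of (synonymous fraction of the three
possible single-base changes); changes creating a stop codon count as
non-synonymous, which preserves s + n = 3 exactly for every sense codon.
Observed differences for codons differing at 2–3 positions are averaged
with equal weight over all substitution orderings; orderings that pass
through a stop codon are removed and the rest reweighted (if every ordering
is blocked, all are used, so syn + nonsyn always equals the number of
differing positions). Proportions pS = Sd/S̄, pN = Nd/N̄ use
pair-averaged potential sites; the Jukes–Cantor correction
d = −¾ ln(1 − 4p/3) is undefined at p ≥ 3/4, and saturated pairs are
excluded from the means and counted in the result.

A transition/transversion-weighted ("modified") variant is deliberately not
implemented: with equal pathway weights the classic estimator is exact,
transparent, and testable against exhaustive enumeration; the weighting
scheme adds a free parameter the data here cannot pin down. Variances for
the Z-test of dN = dS come from a codon-resampling bootstrap (1000
replicates, seeded), Z = (dN − dS)/√(Var dN + Var dS), with the two-tailed
normal p-value and one-tailed versions for the diversifying and purifying
alternatives. Bootstrap rather than the analytic NG variance was chosen so
that the same machinery serves any partition and correction; printed Z and
p values from other programs therefore match only to tolerance.

## Wu–Kabat variability

W = N·k/n per residue (N sequences, k distinct residues, n copies of the
commonest; `X` excluded), so invariant positions score exactly 1.
"Hypervariable" positions are those with W > 2 × mean W; conserved runs are
maximal stretches of ≥ 6 invariant residues (configurable).

## Neutrality tests

Tajima's D uses the standard a₁…e₂ constants. Fu's Fs evaluates
S′ = P(K ≥ k_obs) under the Ewens sampling formula at θ̂ = K (the
pairwise-difference estimate, per Fu's definition), with unsigned Stirling
numbers of the first kind computed by the log-space recurrence — stable to
n ≥ 100 — and Fs = ln(S′/(1−S′)). R2 attributes a singleton to the one
sequence carrying a site's minority state and requires n ≥ 4, which removes
the tie case entirely.

P-values come from simulated constant-size coalescent nulls. The default
conditioning draws the mutation count of each replicate as Poisson at
Watterson's estimate θ̂_W = S_obs/a₁; exact conditioning on S_obs is
available as an option. The default was chosen on calibration grounds:
with exact-S conditioning the null mean of Fs sits near −0.3 (a real
conditioning effect, reproducible across implementations), while
Poisson-at-θ̂_W keeps the null means of both D and Fs within ±0.1 of zero
at n = 30, S = 20. All three tests are left-tailed (low values signal
expansion).

## Mismatch distribution and the sudden-expansion model

Backward in time, in mutational units, the pairwise coalescence time T has
hazard 1/θ₁ on [0, τ) and 1/θ₀ beyond; the number of pairwise differences
is Poisson(T). The expected class probabilities have closed forms: the
recent epoch in regularized lower incomplete gamma functions, the ancient
epoch as a finite binomial series evaluated in log space (the naive
incomplete-gamma form overflows for small θ₀). With θ₀ = θ₁ = θ the
distribution collapses to the geometric θⁱ/(1+θ)ⁱ⁺¹ at machine precision,
which is one of the frozen test oracles; a 10⁶-pair Monte-Carlo simulation
is the other.

Fitting minimizes the sum of squared deviations between observed and
expected class frequencies (ordinary least squares — no weighting matrix,
since the class covariances of a single genealogy are not estimable from
one sample) over a coarse grid on (log₁₀ θ₀, log₁₀ θ₁, τ) followed by
Nelder–Mead refinement, with box constraints θ ∈ [10⁻³, 10²] and
τ ∈ [0, 3·d_max]. The θ upper bound reflects the data scale this package
targets (per-site diversity below ~0.5 over a few hundred sites); it also
keeps parametric-bootstrap replicates tractable.

Goodness of fit: SSD and the raggedness index rg = Σ(Fᵢ − Fᵢ₋₁)² over
observed classes (no wrap-around term; validated behaviorally — unimodal
curves score below multimodal ones — not bit-for-bit against any particular
program). P-values and percentile CIs come from a parametric bootstrap:
coalescent samples of the observed size simulated under the fitted model
and refit. Refits are **cold-started** (full grid search per replicate):
warm-starting at the fitted point visibly shrinks the replicate spread and
under-covers. The percentile CI was retained after a calibration study on
synthetic data against basic, log-basic and bias-corrected alternatives —
at the study conditions (τ = 5, θ₀ = 1, θ₁ = 30, n = 60) it covers the true
τ in roughly 90% of runs with 100 bootstrap replicates, and none of the
alternatives did better.

Expansion time: t = τ/(2uL) with u the per-site substitution rate and uL
the cumulative rate over the fragment; the result is reported in the units
of the supplied rate calibration (years before present for the avian
per-Myr rates, numerically taken as printed in the source calibrations).

## Haplotype networks and locus partition

The minimum spanning network is grown Kruskal-style by distance level: at
each Hamming distance, every edge joining components distinct at the start
of the level enters the network; a deterministic subset (ordered by ID)
forms the spanning tree, the co-minimal alternatives are kept flagged.
This is the ε = 0 convention; larger ε is out of scope. Total MST weight is
tested against brute-force enumeration over all spanning trees at small n.

The two-locus partition uses average-linkage hierarchical clustering on
nucleotide p-distance cut at k = 2, with per-cluster support the fraction
of 100 site-bootstrap replicates in which the exact member set recurs as a
cluster. This stands in for a gene tree, which is out of scope; on
synthetic two-pool data with realistic divergence it recovers the pools
exactly with support ≥ 0.95.

## Synthetic data

The clone-library generator emulates the structure of a two-locus MHC
cloning study: two ancestral sequences at ~10% divergence, allele pools of
23 + 36 variants derived by ≤ 6 accepted point mutations each,
nonsynonymous changes concentrated at the PBS codons by acceptance-
rejection thinning (synonymous proposals thinned 1/multiplier inside the
partition, nonsynonymous ones outside — a stand-in generative choice, not a
selection model), stop codons injected into a configurable fraction of
pool alleles (default 2/59), 1–6 haplotypes per individual, 8–24 clones per
individual over two PCR replicates, and i.i.d. per-base PCR error (default
10⁻⁴, a realistic Taq-scale rate). Clone allocation guarantees ≥ 3 clones
per assigned haplotype spread over ≥ 2 PCRs, so at zero error rate the
classification rules recover the truth table exactly — the closed-loop test.

What it does **not** emulate: chimera formation, template-switching, primer
bias, within-locus recombination or gene conversion, and realistic allele
frequency skew (assignment is uniform over the pool). Passing closed-loop
tests therefore demonstrates correctness of the counting rules, not
robustness to every artifact class real cloning data can contain.

The coalescent generator implements the n-coalescent with piecewise
pairwise rates (1/θ₁ recent, 1/θ₀ ancient, change at τ) in mutational time,
each lineage mutating at rate ½, mutations mapped without replacement onto
distinct sites (infinite-sites). Its mean pairwise difference matches the
analytic θ₁ + e^(−τ/θ₁)(θ₀ − θ₁) and its empirical mismatch distribution
converges to the closed-form expectation — both are standing tests.

## Problem sizes in the test suite

The suite runs the CI-coverage study at 50 runs × 100 bootstrap replicates,
null calibration at 10 000 replicates, and the Monte-Carlo mismatch oracle
at 10⁶ pairs; the full-data analyses in the library default to 1000
(bootstraps) and 10 000 (simulations) replicates. These sizes were chosen
so the whole suite completes in minutes while keeping every Monte-Carlo
tolerance at least three standard errors wide.

## Known limitations

* The dN/dS Z-test assumes approximate normality of the bootstrap
  distribution of dN − dS; with very few codons in a partition the test is
  conservative at best.
* Fu's Fs is undefined (reported as missing) when every sequence is
  identical or all are distinct with K pushing S′ to 1.
* The sudden-expansion fit is a three-parameter summary of a single
  genealogy; its parameters are weakly identified when the observed
  distribution is flat, and CIs at small n should be read as rough.
* Cross-species alignments must be curated (trimmed to a common in-frame
  window) by the caller; the package validates frame and length only.
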