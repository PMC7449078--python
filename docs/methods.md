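# Methods

`codonmutsel` analyses synonymous codon usage with a population-genetic
mutation-selection model, aimed at genomes that carry the signature of more
than one cellular environment — most prominently a host genome with a large,
fixed introgression whose codon usage still reflects its donor lineage.

## The stationary codon model

Within each synonymous codon family, the probability of observing codon *i*
in a gene with protein synthesis rate φ is

    p_i ∝ exp(−ΔM_i − Δη_i · φ)

* **ΔM** (mutation bias) sets the equilibrium usage of a gene that selection
  cannot see (φ = 0): p_i = exp(−ΔM_i)/Σ_j exp(−ΔM_j).
* **Δη** (selection bias) is the fitness difference between synonymous
  codons relative to drift for a gene of average expression, i.e. the
  composite 2·N_e·q·(η_i − η_j); N_e and the per-ATP cost q are not
  separately identifiable and are carried only inside Δη.
* **φ** (protein synthesis rate) is unitless with mean 1 over the fitted
  gene set, by convention; selection on a gene's codons scales with its φ.

Families are the 19 synonymous groups of the standard genetic code with
serine split into its two mutationally disconnected blocks (TCN = `S`,
AGY = `Z`; they are more than one nucleotide change apart, so a weak-mutation
model treats them as separate families), 59 codons in total. Under the
alternative yeast nuclear code CTG (serine there) is dropped outright and
leucine is flagged as excluded from cross-genome comparisons.

Only within-family contrasts are identifiable, so all reported parameters
are *recentered* — expressed as deviations from their family mean — which
makes results independent of the reference-codon choice. Likelihoods are
products of per-codon categorical probabilities given each gene's amino-acid
usage; the multinomial coefficient is constant in the parameters and
omitted, so absolute log-likelihoods are comparable only within this
package.

## Bayesian fit

`CodonUsageModel` is a Metropolis-within-Gibbs sampler over raw per-family
(ΔM, Δη) vectors (one reference codon pinned at 0 per family), per-gene
log-φ, and the spread σ_φ of the lognormal φ prior (location −σ_φ²/2 so the
prior mean of φ is 1; σ_φ gets a half-normal(2) hyperprior). Raw ΔM and Δη
carry weakly informative normal(0, 10²) priors. In `separated` mode the
endogenous and exogenous gene sets get their own (ΔM, Δη) while φ remains
per-gene.

The posterior geometry is treacherous in two specific ways, and the kernel
is built around them:

1. **Reflection mode.** (ΔM, Δη, φ) → (ΔM + 2Δη, −Δη, 2 − φ) preserves
   every logit for genes with φ < 2; only high-expression genes break the
   tie. The fit therefore runs several short pilot chains from dispersed
   starting values (the reference workflow for this model family used ten
   starting values) and keeps the state with the best log posterior; during
   burn-in the sampler also explicitly evaluates the reflected state and
   jumps if it is more probable.
2. **Exact rescaling degeneracy.** For any c > 0,
   (ΔM − (c−1)Δη, cΔη, 1 + (φ−1)/c) is a likelihood-preserving bijection;
   the scale of Δη vs the spread of φ is identified *only* by the lognormal
   prior on φ. The kernel includes a Metropolis rescale move with the exact
   Jacobian that travels along this direction (jointly rescaling σ_φ, since
   σ and the φ spread form a funnel), so the chain settles where the prior
   actually puts its mass instead of wherever it was initialized.

Family updates alternate a ΔM-only proposal with a "ridge" proposal
(δΔη = ε, δΔM = −ε) that moves along the weakly identified ΔM + Δη ≈ const
direction at φ ≈ 1; φ updates are vectorized over genes (conditionally
independent given the codon parameters). All proposal scales adapt toward a
0.2–0.4 acceptance rate during burn-in and are frozen afterwards.
Convergence is monitored by split-chain R̂ of the log posterior (warning
threshold 1.1) plus the exported trace. Defaults follow the reference
workflow where stated: thinning 50, final 10% of samples for posterior
summaries; the iteration count is configurable with a desk-scale default of
20,000. Posterior-mean φ is reported renormalized to mean 1; the
log-likelihood at the posterior mean is evaluated at the *unrenormalized*
posterior-mean φ, since rescaling φ without rescaling Δη would break the
fitted coupling.

**Small-sample caveat.** Below roughly 200–300 genes the collapsed end of
the rescaling degeneracy (φ compressed toward 1, Δη inflated, σ_φ ≈ 0) can
carry more posterior mass than the truth-like configuration — we measured a
~280-nat advantage for the collapsed mode at 120 genes × 250 codons of
synthetic data. This is a property of the model, not of the sampler: with
few genes the lognormal prior earns more density from a compressed φ than
it loses in its tails. Recovery tests therefore use ≥300 genes; at the
1,000-gene scale the truth-like mode dominates and simulated parameters are
recovered with ρ(ΔM) ≈ 0.998 and ρ(Δη) ≈ 0.994.

`estimate_selection=False` pins Δη at 0 (mutation-only fit; φ then drops
out of the likelihood). This supports mutation-bias-only analyses and gives
the test suite an exactly one-dimensional posterior to check against dense
grid integration.

## Model comparison

Marginal likelihoods come from a generalized harmonic mean estimator over
the retained trace: a multivariate normal importance density q is fitted to
the samples (mean; variances inflated by a scaling factor, default 1.1) and

    log M = −log( (1/S) Σ_s exp[ log q(θ_s) − log(prior × likelihood)(θ_s) ] )

evaluated with max-subtraction. The covariance is treated as diagonal: at
~10³ dimensions a full sample covariance is numerically fragile, and
diagonality affects estimator efficiency, not its target. The stored
unnormalized log posterior is reused; the likelihood is never re-evaluated.
Raising the variance scaling can only raise the estimate, so small scalings
give conservative Bayes factors — the default reporting choice. The Bayes
factor log K = log M_separated − log M_combined is complemented by a
chi-square likelihood-ratio test at the posterior-mean log-likelihoods.

## Parameter comparison and lineage ranking

Cross-environment and cross-genome comparisons use all recentered per-codon
values: Pearson correlation (two-sided t-based p), major-axis (type II)
regression — slope from the principal eigenvector of the 2×2 covariance,
line through the centroid — since both parameter sets carry estimation
error, and per-codon sign agreement. Per family, the mutationally favored
codon is argmin ΔM and the selectively favored codon argmin Δη; exact ties
are reported in full and flagged. Candidate donor lineages are ranked by
ρ(ΔM) against the exogenous set — mutation bias decays slowest and
discriminates best — with leucine excluded whenever one side uses the
alternative yeast nuclear code. GC content, synteny coverage and divergence
times are accepted as user-supplied annotation columns, never computed.

## Decay clock

For each two-codon family, the frequency c₁ of the alphabetically first
codon relaxes under mutation alone:

    dc₁/dt = −μ₁₂·c₁ + μ₂₁·(1 − c₁),   c₁* = 1/(1 + exp[ΔM_endo])
    μ₁₂ = μ₂₁ · exp[ΔM_endo]
    c₁(t) = c₁* + (c₁(0) − c₁*) · exp[−(μ₁₂ + μ₂₁)·t]

with ΔM_endo the host's pairwise contrast and μ₂₁ = 3.8×10⁻¹⁰ per
nucleotide per generation by default. The printed source for this clock
contains two typographical slips (a sign in the influx term and a
`1 + ΔM` where the steady state requires `1/(1 + exp[ΔM])`); the package
implements the canonical two-state solution above and verifies it against
direct numerical integration in the test suite. Initial frequencies come
from the donor lineage's contrasts, current frequencies from the exogenous
gene set's, the equilibrium from the host's. The age solves in closed form
per family; families whose current frequency does not lie between the
initial frequency and the equilibrium are excluded as "unreachable under
monotone decay". The genome-wide age is the mean over included families
± the standard error across families (the reproducible reading of a
headline "±"). The decay horizon solves the same equation for the time to
come within a tolerance of the host equilibrium — 1% *relative* to c₁* by
default, with an absolute-band option. Because μ₂₁ is attached to the
codon2→codon1 direction, codon labels are fixed alphabetically; relabelling
is only an invariance if μ₂₁ is transformed to μ₂₁·exp(contrast) alongside
it. Year conversions divide by 365 × generations/day at user-chosen bounds
(1 and 8 per day by default).

## Selection against codon mismatch

Per gene, with Δη′ = Δη/N_e (N_e default 1.36×10⁷):

    E[n_{g,i}] = P(c_i | ΔM, Δη, φ_g) · m_{a_i}
    s_g = Σ_i −κ · φ_g · Δη′_i · E[n_{g,i}]
    Δs_g = s_intro,g − s_endo,g

`s_intro` uses the donor environment's expected codon usage scored against
the host's Δη′ at κ = κ_intro; `s_endo` the host's own expected usage at
κ = 1. The gene's current amino-acid composition serves for both terms, and
φ is the endogenous-fit estimate (assumed unchanged by the transfer).
Δs vanishes identically when donor and host coincide; Δs_g > 0 marks an
*exapted* gene whose donor-shaped usage host selection happens to favor.

Because s_g is exactly linear in κ, the signed total Σ_g Δs_g is linear too
and has no interior optimum. "Minimizing the cost of the introgression" is
therefore operationalized as minimizing the total selection *against* the
introgressed genes, Σ_g max(0, −Δs_g), over a κ grid (default 0.1–10 by
0.1; ties resolve to the smallest κ; boundary optima warn). On data built
with donor selection at one-fifth the host's efficacy and mutation bias
orthogonal to selection bias, this objective recovers the efficacy
conversion κ* = 5 exactly in the weak-selection limit; with selection of
realistic magnitude the recovered κ* sits within a few grid steps of 5.
Signed-total and absolute-total objectives remain available as options and
the objective used is recorded in the output metadata.

Fixation probabilities π = (1 − exp[−Δs])/(1 − exp[−2·Δs·N_e]) are computed
piecewise in log space (via expm1/log1p and an asymptotic log(expm1(y)) ≈ y
for large y) so exponents of order −10³ and beyond are exact where naive
floating point underflows; Δs = 0 takes the neutral limit 1/(2N_e). The
implementation is cross-checked against 60-digit arbitrary-precision
arithmetic in the tests.

## Synthetic data

The generator emulates the stated world of the analysis: genomes of N genes
whose codons are drawn independently from the stationary model, per-gene φ
from a mean-1 lognormal (σ_φ default 1.5, renormalized to mean exactly 1
after sampling — the reference analysis does not print the expression
spread, and 1.5 gives the heavy-tailed, mostly-low-expression profile
typical of yeast), uniform amino-acid composition over the 19 families,
gene length default 300 codons. Two-environment genomes place endogenous
genes on chromosomes A/B and exogenous genes inside a ~1 Mb window of
chromosome C (positions 1–989,693), so the partition step is exercised
end-to-end. Truth presets mirror the qualitative structure of the study
system: `endogenous-like` mutation bias favors A/T-ending codons in ~95% of
families with mixed selection; `exogenous-like` favors G/C-ending mutation
with A/T-ending selection in ~89% of families. `simulate_counts` draws the
count sufficient statistics directly (distributionally identical to
sequence simulation and much faster); `simulate_genome` writes actual FASTA
with ATG/TAA bookends for the I/O path. `simulate_decayed_introgression`
advances each two-codon family's frequency with the decay clock and
converts back to contrasts, giving the clock an exact self-inversion test.

What the generator does *not* emulate: real amino-acid composition
heterogeneity, length variation correlated with expression, context or
codon-pair effects, nonstationary mutation, or within-gene φ variation. A
green recovery test therefore establishes that the inference machinery
inverts the model it states — not that the model captures every force
shaping real codon usage.

## Numerical choices

* Softmax probabilities always max-subtracted; log-likelihoods assembled in
  log space throughout.
* Family-blocked codon ordering lets all per-family reductions run as
  `np.*.reduceat` segment operations — no per-family Python loops in the
  likelihood; a 1,000-gene × 300-codon fit runs in ~30 s on one CPU at the
  desk-scale iteration budget.
* GHM requires ≥100 retained samples and rejects zero-variance dimensions.
* Ties in optimal-codon calls and κ grids resolve deterministically
  (report-all-flagged and smallest-κ respectively).
* Exact-equilibrium starts are excluded from clock inversion (no decay, the
  elapsed time is unidentifiable); boundary genes are assigned to the
  partition by start coordinate, 1-based inclusive.
* Seeds are mandatory for every stochastic entry point and recorded in
  traces and run manifests.

## Known limitations

* Absolute log-marginal likelihoods and parameter counts are reproducible
  only up to the omitted multinomial constant and the package's own
  parameterization; Bayes-factor *differences* on a fixed dataset are the
  meaningful quantity.
* The GHM estimator inherits the high variance of harmonic-mean methods;
  it is used with conservative variance scaling and its Monte Carlo noise
  (a few nats here) is small against the decisive Bayes factors this
  analysis produces, but it is not a general-purpose marginal-likelihood
  method.
* The decay clock treats each two-codon family independently with a single
  genome-wide μ₂₁ and ignores posterior uncertainty in the contrasts
  (point estimates, as in the reference analysis).
* Multi-codon (>2) families have no decay clock; the selection-cost module
  assumes additive fitness effects and no epistasis or recombination.
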