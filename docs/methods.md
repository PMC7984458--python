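# Methods

`tetraqtl` maps quantitative trait loci (QTLs) in the first segregating
generation (S1) of a cross between two outbred autotetraploid parents,
under a tetrasomic inheritance model that accommodates bivalent,
quadrivalent, and mixed homologous-chromosome pairing, including double
reduction. This note records the model, the numerical choices, and the
limits of what the test suite demonstrates.

## The meiosis model

Everything rests on one generative description of an autotetraploid
meiosis. A diploid gamete is a pair of chromatids; we track, at every
locus, which of the four homologues (origins 1–4) each chromatid copies.

* **Anchor locus.** At the centromere-proximal end of the linkage group the
  origin pair is identical — both chromatids are sister copies of the same
  homologue — with probability α (the coefficient of double reduction,
  0 ≤ α ≤ 1/4), uniformly over the four homologues; otherwise the ordered
  pair is uniform over the twelve distinct pairs. Double reduction cannot
  occur at the centromere itself, so a map whose origin sits at the
  centromere takes α = 0 there.
* **Quadrivalent pairing.** Moving along the chromosome, each chromatid
  origin evolves independently as a symmetric four-state Markov chain:
  unchanged with probability 1 − r across an interval with recombination
  fraction r, and switching to each of the other three origins with
  probability r/3. Because any origin can recombine with any other, r can
  reach 3/4, and two intervals compose according to
  r₁₂ = r₁ + r₂ − 4r₁r₂/3.
* **Bivalent pairing.** The four homologues pair two-by-two (three equally
  likely partitions per meiosis); the gamete receives one chromatid from
  each bivalent, and each chromatid's origin is a two-state chain within
  its own pair (switch probability r ≤ 1/2, composing as the classical
  r₁₂ = r₁ + r₂ − 2r₁r₂). Sister chromatids can never co-segregate, so
  double reduction is impossible and at most two homologues contribute to
  a gamete.
* **Mixed pairing.** Each meiosis is quadrivalent with probability λ and
  bivalent otherwise. The effective double-reduction coefficient is
  α′ = λα.

The closed-form two-locus gamete distribution (eleven structural classes
for a fully heterozygous parent), the three-locus marker–QTL–marker
distribution, the hidden-Markov transition kernels, and the simulator all
*derive from this one chain*, so marginal consistency between the two- and
three-point laws and agreement between simulated frequencies and analytic
probabilities hold by construction; the test suite still verifies both
independently (exact class probabilities against the closed forms, and χ²
goodness-of-fit on 10⁵ simulated meioses per condition).

Map distances convert to recombination fractions with no-interference map
functions consistent with the composition rules above: Haldane's
r(d) = (1 − e^(−d/50 cM))/2 for the two-state bivalent chain and its
four-state analogue r(d) = 3(1 − e^(−d/75 cM))/4 for the quadrivalent
chain. Using the diploid Haldane function inside the quadrivalent chain
would break the r₁₂ composition identity, so the tetrasomic form is not
optional.

Because the chain is first-order Markov with the anchor at one end, the
per-locus double-reduction coefficients at interior loci are *induced*:
α_{j+1} = α_j[(1−r)² + r²/3] + (1−α_j)[2r(1−r)/3 + 2r²/9], rising toward
the ceiling of 1/4 with centromere distance (`induced_alpha_profile`).
The package therefore parameterizes double reduction by the single anchor
value plus the map, rather than a free per-locus vector, which a
first-order chain could not honour anyway.

## Multipoint genotype probabilities

For each offspring the hidden state at a marker is the joint origin pair
of its two parental gametes (16 × 16 states under the quadrivalent model,
12 × 12 under bivalent, 28 × 28 mixed). Transitions factorize over the two
parental meioses; emissions compare the four allele labels implied by a
state with the observed marker phenotype — allele dosages (model I) or
presence/absence (model II) — exactly at genotyping error ε = 0, or with a
symmetric misclassification over the observable phenotype classes for
ε > 0. A scaled linear-space forward–backward pass (per-locus scaling
factors accumulate the log-likelihood; numerically equivalent to log-space
and stable for hundreds of markers) yields the phased two-locus
configuration posteriors at every adjacent marker pair, and, for a QTL at
map distance d₁/d₂ from its flanking markers, the exact posterior of the
offspring's QTL dosage given all markers on the group. The contraction
through the QTL was validated against exhaustive enumeration of the
three-locus zygote table (4,326,400 entries collapsed over allele
content); agreement is at machine precision.

An individual whose phenotype vector has likelihood zero under the assumed
pairing model is reported with a distinguishable status. Under the
bivalent model this is precisely the bivalent-incompatibility screen:
either a single-locus genotype requires double reduction (an A₁A₁ gamete
from an A₁A₂A₃A₄ parent), or the phenotypes jointly require a gamete
drawing on more than two parental chromosomes. The scan offers the two
published handling policies (remove the individual; or blank the offending
loci and keep it) plus a strict "keep" that refuses such data.

## The genetic model and the scan

Genotypic values of the five dosage classes k = 0..4 (k copies of the
trait-increasing allele Q) follow the orthogonal model
G_k = μ + Σ_j w_kj θ_j with monogenic…quadrigenic effects θ₁..θ₄. The
contrast scales w_kj are orthogonal polynomials of dosage under the
genotype-probability weights of the population (Σ_k p_k w_kj = 0,
Σ_k p_k w_kj w_kj′ = 0). Any fixed scaling of the contrasts leaves G_k,
likelihoods, LOD, BIC and the variance decomposition unchanged and only
sets the units of θ; this package uses monic polynomials divided by j!
(finite-difference scaling), under which θ_j is a j-th-order interaction
per unit dosage step and effect values of different orders are comparable.
We chose this scaling because, combined with the conventional simulation
effects (θ = 10, −6, 3, −1), it reproduces the residual-variance
progression of the published mixed-pairing study to within a few percent,
whereas raw monic contrasts would concentrate half the genetic variance on
the rare double-reduction classes — an architecture the published residual
SDs rule out. Crosses that segregate fewer than five dosage classes
(e.g. QQqq × qqqq, dosages {0, 1, 2}) determine only the lower-order
effects; the rest are reported as masked, never as zeros.

At a tested position the trait is a normal mixture over the five dosage
classes with individual-specific weights (the multipoint QTL posterior
under a candidate parental configuration). EM maximizes the likelihood:
E-step posterior memberships, M-step weighted means and the n-denominator
variance update; convergence at |Δlog L| < 1e-8 or 500 iterations;
initialization from the sample variance and 1-D K-means centres of the
trait (K = number of segregating classes, 10 restarts, centres assigned to
classes in ascending dosage order), with an automatic restart from the
no-QTL parameters whenever the fit would otherwise end below the null —
so LOD = log₁₀(L̂/L̃) ≥ 0 always, with the null likelihood at the trait
mean and maximum-likelihood variance. The contrast matrix is evaluated at
convergence from the E-step-aggregated genotype distribution; it does not
enter the EM updates themselves.

The parental QTL genotype and phase being unknown, the scan fits all 92
phase-labelled placements across the nine admissible dosage combinations
(P1 the higher-value parent) at every grid position (default 1 cM). The
selected configuration minimizes BIC = ln(n)k − 2lnL̂ subject to (a) the
estimated genotypic value of P1 exceeding P2's and (b) θ₁ > 0. The
parameter count k is 6 (mean, four genetic effects, residual variance) for
every configuration by default; counting only estimable effects
(`bic_k="estimable"`) is also available but systematically favours
three-class configurations by ln(n)·2 when the extreme dosage classes are
rare, which empirically misranks the true configuration in exactly the
regimes the method targets. The eight configurations in the (4,1) and
(3,0) dosage pairs duplicate the likelihood profile of a partner
configuration with the dosage classes reflected; the scan fits the partner
once and copies the surface (the duplication is therefore exact), and the
θ₁-sign rule resolves the pair.

Genome-wide significance uses permutation of trait values over the marker
data: each permutation replays the EM scan of the *selected* configuration
over the full position grid and records its maximum LOD; the threshold is
the 95% quantile (default 100 permutations). Replaying the entire
92-configuration search per permutation would be quadratically more
expensive; the reported observed statistic is itself a maximum over
configurations, so the threshold is mildly anti-conservative under a
global null (a fixed-configuration scan attains the nominal 5% type-I
rate, which the suite verifies). The variance decomposition reports
Vg% = V_G/(V_G + σ²)·100 with V_G the variance of the fitted genotype
means over the genotype distribution, and ρ = θ₁²Σp_k w_k1²/V_G·100, the
additive share, exact by contrast orthogonality.

## The simulator

`simulate_population` draws each parental meiosis's pairing mode
(quadrivalent with probability λ), samples the gamete origin pairs locus
by locus with the chain above (markers plus the QTL inserted at its map
position), assigns trait values y = G_k + N(0, σ²) with σ² set from the
realized genetic variance to hit the target heritability exactly, and
scores markers with or without dosage information. The truth record
(origins, pairing modes, double-reduction events, QTL dosages) never leaks
into the observed tables.

The mixed-pairing study design (`table3_config`) is 20 evenly spaced
biallelic markers on 100 cM, parental QTL QQQq × Qqqq at mid-chromosome,
n = 300, h² = 10%, effects (μ, θ) = (10, 10, −6, 3, −1). Where the
published description is silent the package fixes: parental marker dosages
uniform on {1, 2, 3} (simplex–triplex, the informative biallelic classes)
with random phase, redrawn per replicate; and the centromere at the left
map end (α = 0 there), so double reduction emerges along the chromosome
and reaches ≈ 0.23 at the far end — consistent with the expected fraction
of double-reduction carriers rising to ≈ 40% of individuals with
centromere distance. Under this design the bivalent-incompatibility screen
removes ≈ 32–33% of individuals at λ = 1.

What the generator does *not* emulate: genotyping error (ε is available in
the analysis but the study designs score markers without error), missing
data patterns of real assays, segregation-distorting viability selection,
crossover interference, multiple or linked QTLs, and linkage maps that are
themselves estimated with error. Passing tests therefore demonstrate
correctness of the inference machinery under the stated meiosis model, not
robustness to those real-data features.

## Numerical choices and degenerate inputs

* Probability normalization asserted to 1e-12; zero-probability
  conditioning events raise (tolerance 1e-14).
* α is validated to [0, 0.25]; single-locus estimates are clipped to the
  boundary; a flat likelihood (uninformative cross) returns "undefined"
  rather than a number.
* Collapsed genotype classes are keyed by sorted allele-content tuples;
  all tabular output is deterministically ordered; a single seed governs
  K-means restarts and permutations, and the simulate→scan→report pipeline
  is byte-identical under a fixed seed.
* Gamete-class counts for a single meiosis condition on the pairing
  configuration (one partition) under the bivalent model, since pairing is
  fixed within a meiosis: 136 two-locus and 2080 three-locus classes under
  quadrivalent pairing versus 64 bivalent, for a fully informative parent.
  Across-meiosis probabilities always average the three partitions.
* BIC ties across configurations break by higher peak LOD, then label.
* If no configuration satisfies the sign/ordering constraints (typical for
  null data), the BIC-best configuration is reported with a warning rather
  than failing the scan.

## Problem sizes used in the shipped studies

The reproduction script (`scripts/acceptance.py`) runs the mixed-pairing
study at 30 replicates for power (50 permutations each) and 50 replicates
for the removal fraction, localization accuracy, and
configuration-recovery rate, with a 3 cM scan grid; the test suite uses
8–50 replicates per statistic with the same design. These replication
levels were chosen as the smallest at which the Monte-Carlo standard
errors are meaningfully smaller than the effects being checked.

## Known limitations

* Localization accuracy at h² = 10% is limited by likelihood geometry: the
  expected LOD profile is smooth and centered on the QTL, but
  replicate-level peaks scatter with a mean absolute error of ≈ 7–11 cM
  (even under fully informative markers), although ≈ 2/3–3/4 of replicates
  land within 10 cM. Point localization a few-fold sharper than this is
  not achievable from these designs at this heritability.
* The permutation threshold is defined per selected configuration (see
  above); under a global null the full-search maximum sits slightly above
  it.
* One QTL per linkage group; no covariates; no epistasis between QTLs; λ
  is an input, not estimated from the data.
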