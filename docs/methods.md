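# Methods

## The age signal of selection

Both deleterious and beneficial alleles segregating at a given population
frequency are, on average, younger than neutral alleles at that same
frequency: a selected allele is unlikely to reach the frequency at all, and
when it does, it tends to have done so quickly.  The package works with this
effect at three levels — exact diffusion theory for constant population
size, forward simulation where theory is unavailable (changing population
size), and a haplotype statistic that serves as an observable proxy for age
on phased panels.

## Diffusion theory (`alleleclock.diffusion`)

The Wright–Fisher diffusion with genic selection is parameterised by the
scaled coefficient γ = 2Ns (additive fitness, no dominance; negative =
deleterious) with time in units of 2N generations.  With scale density
ψ(z) = e^(−2γz), scale function S(z) = ∫₀ᶻ ψ, and loss probability
h(z) = (S(1) − S(z))/S(1), the sojourn-time density of an allele observed
today at frequency x (new-mutation limit p₀ → 0) follows from time reversal
of the diffusion conditioned on loss:

    t(y) = 2 S(y) (S(1) − S(y)) e^(2γy) / (S(1) · y(1−y)),            y ≤ x
    t(y) = 2 S(x) (S(1) − S(y))² e^(2γy) / (S(1)(S(1) − S(x)) · y(1−y)),  y > x

and the mean age is ∫ t(y) dy.  Three analytic properties anchor the
implementation and its tests: at γ = 0 the density is flat (equal to 2)
below x and the age reduces to the classical −2·[x/(1−x)]·ln x; the density
and the age are exactly symmetric under γ → −γ; and selected alleles spend
progressively less time at higher past frequencies.

Numerical choices:

* both branches are evaluated entirely in log space through
  log|1 − e^(−u)| and log-scale-function differences, so |γ| up to 200 is
  supported without overflow; beyond that a `ValueError` is raised because
  the density concentrates so tightly near the boundary that fixed
  tolerances stop being meaningful;
* |γ| below 1e−8 is evaluated with the exact neutral branch (relative error
  O(γ));
* mean ages use adaptive quadrature split at y = x with a 1e−4 relative
  tolerance; failure to converge is an error that names the achieved
  tolerance, and profile grids whose trapezoid integral misses the
  quadrature age by more than the tolerance trigger a warning rather than
  silent inaccuracy.

For a non-zero origin frequency p₀ (exposed as an option) the implemented
density is the occupation time since the trajectory last left p₀,
conditional on the current frequency — the Green's function of the
diffusion on (p₀, 1) absorbed at p₀, h-transformed by the probability of
hitting p₀ before 1.  This equals the allelic age exactly in the
new-mutation limit, and is reported for y > p₀ only (time spent below the
origin frequency is not part of the path since origin in this
interpretation).

The theory-vs-simulation comparisons weight the theoretical age at each
frequency inside a bin by the stationary density of segregating alleles at
that frequency (`new_mutation_flux_density`), matching how simulated
alleles populate a bin.

## Forward simulation (`alleleclock.simulate`)

Individual-based Wright–Fisher with discrete generations: multiplicative
fitness across sites ((1+s)^g per site with dosage g, with s = γ/(2N₀) —
within-site multiplicativity differs from strict additivity by O(s²), far
below anything resolved here), random mating with selfing allowed, Poisson
crossovers at r = ρ/(4N₀) per bp per meiosis, Poisson infinite-sites
mutation at μ = θ/(4N₀) per bp per gamete, and an arbitrary diploid-size
schedule.  A `free_recombination` switch replaces crossovers by independent
per-site inheritance; the theory-agreement runs use it so that the
single-locus diffusion is the right reference (with linkage, background
selection would slightly depress neutral ages).

Every mutation ever introduced is registered with its origin generation and
γ, and (optionally, with a thinning memory guard) its per-generation count.
Age conditional on frequency is estimated from the *occupation ensemble*:
every (mutation, generation) pair inside the post-burn-in observation
window contributes one (age, frequency) observation.  This is the
stationary-ensemble quantity the diffusion predicts, and it extracts two to
three orders of magnitude more information from a run than the final
snapshot alone (snapshot mode is also available).  Standard errors treat
mutations — not the autocorrelated per-generation observations — as the
independent unit, via the cluster ratio-estimator formula; rank tests
between selection classes use one observation per mutation (its mean age
while inside the frequency band).  Sample-frequency conditioning draws a
binomial subsample of the requested panel size at each observation.

Default run protocol is a 10N-generation burn-in followed by 2.05N
generations of observation, with the expansion presets starting exponential
growth 2N generations after burn-in (fold-increase over the remaining
0.05N generations, default 5×) and the bottleneck preset halving the
population instantaneously at the same time point before identical growth.
At the desk scales used in the tests (N = 500–1000) the growth phase is a
few tens of generations — long enough to reproduce the qualitative ordering
(selected younger than neutral under every demography), but too short to
resolve the *attenuation* of the age gap that rapid growth produces at full
scale; the attenuation is therefore not asserted by the test suite.

Validation anchors: neutral fixation probability 1/(2N) over ≥10⁵
introduced mutations; occupation-ensemble ages within 3 Monte-Carlo SE of
the diffusion prediction per 1% frequency bin at N = 1000 (2N = 2000); an
exact-chain computation during development showed the residual
discrete-WF-versus-diffusion bias at this N is ≈1–2% in the 2–4% frequency
band, comfortably below the Monte-Carlo resolution of the tests.

## The Neighborhood-based Clock (`alleleclock.nc`)

For an index variant, scan outward in each direction and stop at the first
candidate that is either (a) past a detectable recombination event — the
four-gamete test between index and candidate sees all four two-locus
haplotypes — or (b) a *fully linked rarer* variant, whose carriers are a
strict non-empty subset of the index variant's carriers (a mutation that
arose later on the index haplotype).  NC = log₁₀(d_up + d_down) in bp.
Younger alleles sit on longer unbroken haplotypes, so they get larger NC.

Conventions, where the method description admits choices:

* the focal allele defining carrier sets is the **minor** allele (an option
  switches to derived-allele carriers where polarity is known);
* candidates are all segregating non-singleton variants of any functional
  class; singletons can be admitted by flag (off by default, matching the
  non-singleton analysis rule).  Note that for a MAC-2 index this means the
  subset rule can never fire — doubleton indexes stop only at recombination;
* the four-gamete test is applied directly between index and candidate (not
  between intervening pairs); it is invariant to allele-label flips, so it
  is evaluated on the focal-carrier encoding;
* distance is the 1-based position difference to the stopping variant
  itself, not to an inferred recombination midpoint;
* a direction that exhausts the contig is censored; censored variants carry
  NaN NC, are excluded from downstream statistics and counted in logs.

The production scan is a vectorised per-contig matrix computation; a
brute-force candidate-by-candidate reference implementation lives in the
test suite and the two are required to agree exactly on hundreds of random
panels.

## Category statistics (`alleleclock.stats`)

* **Deleterious fraction.**  Treating the synonymous spectrum as neutral,
  the expected category count at a MAC is total_cat · n_syn_mac/total_syn;
  the estimate is (observed − expected)/observed.  With the published
  counts (3102/39454 synonymous, 4335/46946 non-synonymous at MAC 2) this
  gives 14.85%, printed as 14.8% in the source (truncation).
* **Effect sizes** are (mean_cat − mean_syn)/SD_syn at the same MAC.
* **Rank test**: one-sided Mann–Whitney (alternative: category NC greater,
  i.e. younger), exact for two groups under 20 without ties, otherwise the
  tie-corrected normal approximation (NC values tie often — distances are
  integers).
* **Bootstrap CI**: percentile interval from 1000 within-group resamples of
  variants, recomputing the normalized difference each time.  Label
  permutation (a null distribution, not a CI) is the natural reading of
  "bootstrap permutations" only for testing; within-group resampling is
  what a percentile CI requires and is what is implemented.
* **Meta-analysis** across MAC classes: Stouffer's weighted Z with weights
  √n_i, n_i the compared-category count at MAC i (the weighting variable is
  not pinned down by the method description; category sample size is the
  natural choice and is documented here).
* **Spearman correlation** between NC and a continuous damage score,
  one-sided for ρ > 0.
* **Private fraction**: share of variants observed in exactly one
  population, per category and frequency class.

## Synthetic data (`alleleclock.synth`)

The motivating panel is access-restricted, so end-to-end checks run on
generated data: 188 phased haplotypes (94 diploids) sampled from forward
simulations over several independent 1 Mb contigs, 70% of new mutations
deleterious at γ = −10, θ = 5e−4 per bp (human-like 4Nμ), N = 300 diploids
at desk scale.  ρ = 5e−3 per bp is deliberately ten times the human-like
value: on chromosome-scale data the clock's stop distances (up to hundreds
of kb) are negligible against contig length, and compressing them to tens
of kb reproduces that regime on 1 Mb contigs — at matched θ and ρ the scans
would censor most MAC-2–3 indexes, truncating exactly the young,
large-NC tail the comparison needs.  Neutral variants draw neutral-like
labels (synonymous/benign), selected variants damaging labels, and damage
scores are Beta-distributed with mean increasing in |γ|, so scores
rank-correlate with selection strength by construction.  The simulated REF
allele is ancestral by definition (mutations create ALT), making
polarization exact; an optional error rate flips ancestral states.

What the generator does **not** emulate: exome structure and codon-level
mutation processes, realistic human demography, linkage between regions,
population structure, genotyping or phasing error.  Passing end-to-end
tests therefore demonstrate that the statistics recover a known generative
age signal through the full pipeline — not that effect sizes on real
cohorts will match.

## Problem sizes used by the test suite

Chosen so the full suite runs on a single CPU in well under half an hour:
theory-vs-simulation at N = 1000 with ≈2×10⁵ mutations; demography
orderings at N = 500; the synthetic panel at N = 300 over three 1 Mb
contigs (≈5000 variants, several hundred per selection class at MAC 2–6);
NC oracle equivalence on 200 random panels of ≤20 haplotypes × ≤50
variants.
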