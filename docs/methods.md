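# Methods

## The model

`selfpoly` studies polygenic adaptation to a shifting optimum in a diploid,
hermaphroditic population that reproduces by partial self-fertilisation: each
offspring derives from a single fitness-sampled parent with probability
&sigma; (two independent meioses, so recombination operates during selfing),
otherwise from two independent fitness-sampled parents.  At neutral
equilibrium the inbreeding coefficient is F = &sigma;/(2&minus;&sigma;).

A quantitative trait (or n pleiotropic traits) is controlled additively by
biallelic loci; fitness is Gaussian stabilising selection,
w(z) = exp(&minus;&frac12;&Sigma;<sub>i</sub>(z<sub>i</sub>&minus;z<sub>0,i</sub>)&sup2;/V<sub>s</sub>),
optionally multiplied by a deleterious-mutation component
(1&minus;h|s|)<sup>n_het</sup>(1&minus;|s|)<sup>n_hom</sup>.  The deleterious
selection coefficient is quoted as a magnitude: the literature convention of
writing s = &minus;0.02 with fitness (1&minus;hs) would *increase* fitness;
we implement the stated intent (partially recessive, deleterious).

The package has three layers:

1. **Two-locus engine** (`selfpoly.two_locus`) — an exact, deterministic
   (infinite-population) recursion on the full 4&times;4 genotype
   distribution, used as a brute-force oracle, plus the weak-selection closed
   forms for LD and allele-frequency dynamics.
2. **Multi-locus theory** (`selfpoly.theory`) — per-locus dynamics with
   background-association coefficients &beta;<sub>i</sub>, equilibrium
   frequencies and the equilibrium decomposition
   V<sub>G</sub> = V<sub>g</sub> + V<sub>I</sub> + C<sub>LD</sub>.
3. **Forward simulator and statistics** (`selfpoly.simulate`,
   `selfpoly.stats`) — a stochastic Wright–Fisher simulator with linked loci,
   three mutation classes and pleiotropy, and the downstream measurements.

## Two-locus engine: design choices

The genotype-from-haplotype transform
g<sub>ii</sub> = x<sub>i</sub>&sup2; + F x<sub>i</sub>(1&minus;x<sub>i</sub>),
g<sub>ij</sub> = 2x<sub>i</sub>x<sub>j</sub>(1&minus;F) ignores recombination
during self-fertilisation and degrades when selfing and recombination are
*both* high.  The oracle therefore does **not** use it dynamically: it
carries the genotype distribution forward explicitly, modelling selfing as
two independent meioses of one parent.  `genotypes_from_haplotypes` exposes
the F-transform separately for approximation checks, and
`exact_generation_step` uses it only to initialise a single step from
haplotype frequencies.

Validity regimes for the oracle-versus-closed-form tests are fixed in
advance from the transform's stated domain: the O(&zeta;&sup3;) error-scaling
grid avoids simultaneous high selfing and high recombination, and the
quasi-linkage-equilibrium comparisons require
&gamma; &#8810; r(1&minus;F).  The directional-phase LD form
&Delta;&delta; = &delta;(&kappa;(1+F) &minus; (1&minus;F)r) describes only the
&delta;-proportional dynamics; the one-step comparison therefore uses |&delta;|
large enough to dominate the O(&zeta;&sup2;) generation source term.

## Multi-locus theory: third moments and &beta;

The &beta;<sub>i</sub> are variables of the full dynamics, not parameters;
they enter as exogenous inputs, and
`estimate_background_coefficients` measures them from haplotypes as the mean
background deviation of carriers divided by (1&minus;x<sub>i</sub>).

The distance recursion involves third-order moments
&mu;&#8323;, &nu;<sub>2,1</sub>, &nu;<sub>1,2</sub>.  Their operational
definitions are pinned by an exactness requirement: with the per-locus
(linkage-equilibrium) estimators

  &mu;&#8323; = &Sigma; &alpha;&sup3; x q (q&minus;x),
  &nu;<sub>2,1</sub> = &Sigma; &alpha;&sup2;&beta; x q (q&minus;x),
  &nu;<sub>1,2</sub> = &Sigma; &alpha;&beta;&sup2; x q (q&minus;x),
  C<sub>LD</sub> = (1+F) &Sigma; 2&alpha;&beta; x q,

the distance recursion is *algebraically identical* to
&minus;&Sigma; 2&alpha;<sub>i</sub>&Delta;x<sub>i</sub> from the per-locus
allele recursion.  This consistency is asserted as a property test over
random architectures.  The stabilising factor is implemented as
(1 &minus; D&sup2;/(2V<sub>s</sub>)), the grouping consistent with the scaled
distance d = z/&radic;V<sub>s</sub>.

A note on monotonicities: at fixed &beta; &lt; 0 the equilibrium
C<sub>LD</sub> &prop; &minus;(1+F)/(1+3F) *shrinks in magnitude* as F grows;
the robust statement, which the tests assert, is that C<sub>LD</sub> grows
more negative as |&beta;| grows.

## Forward simulator

Full-scale defaults are the study conditions: N = 5,000; 25 Mb of
alternating 4 kb neutral buffers and 1 kb genes; per-nucleotide mutation rate
4&times;10&#8315;&#8312; and recombination rate 1.98&times;10&#8315;&#8311;
(genome-wide map length &asymp; 4.95 crossovers per meiosis); gene mutations
25% neutral / 65% deleterious / 10% trait; trait effects drawn
N(0, 0.25&sup2;/n) per trait; V<sub>s</sub> = 1; |s| = 0.02, h = 0.2; burn-in
of 10N generations at optimum zero, then a shift to 1/&radic;n per trait
(instantaneous, or ramped over 100 equal increments).  The 1/&radic;n
magnitude equalises the initial fitness drop across pleiotropy levels given
the per-trait effect variance 0.25&sup2;/n.  With these defaults the expected
trait-mutation input is 2NU<sub>t</sub> = 200 new trait mutations per
generation counting per gamete (100 per diploid); both conventions are
reported by `SimulationConfig.trait_mutation_input` because published
descriptions differ in which they quote.

Implementation: haplotypes are immutable, position-sorted sparse lists of
mutation ids into an append-only mutation table; gametes are built by
breakpoint merging (Poisson(rec&middot;(L&minus;1)) crossovers), de novo
mutation is Poisson(&mu;L) with a first-arrival stacking policy at occupied
sites, and mutations fixed on all 2N haplotypes are periodically swept into a
substitutions ledger whose effects remain part of every trait value.  Parent
sampling is fitness-proportional (soft selection, fixed N).  All randomness
flows through a single seeded `numpy.random.Generator`; identical seed and
configuration give bit-identical statistics streams.

### Workstation scale

Full-scale runs (N = 5,000, 25 Mb, 50,000-generation burn-ins) are
cluster-scale; the package's validation and property experiments run at a
reduced scale chosen once:

* `SimulationConfig.desk_scale(N, L, rate_scale)` keeps the 4:1 buffer/gene
  layout, chooses &mu; to preserve the per-gamete trait mutation rate
  U<sub>t</sub> (0.02 by default) and scales rec to preserve the genome-wide
  map length; `rate_scale=0.1` reproduces the 10-fold reduced-rate regime.
* The genic-variance validation (`pipeline.genic_variance_validation`) uses
  N = 400, L = 200 kb, U<sub>t</sub> = 0.002, outcrossing, one trait, no
  deleterious selection, burn-in 10N = 4,000 generations, V<sub>g</sub>
  time-averaged over the last 1,500 generations, 10 replicates.  N = 400 was
  chosen from the 200–500 range because the house-of-cards expectation
  4U<sub>t</sub>V<sub>s</sub> is a deterministic (drift-free) prediction and
  the finite-N deficit shrinks roughly as 1/(4Ns); at N = 400 effects with
  |&alpha;| &gt; 0.035 satisfy 4Ns &gt; 1, covering &gt;99% of the
  mutational variance.
* The selfing contrasts (`pipeline.selfing_contrast_experiment`) use
  N = 100, L = 100 kb with the full trait mutation input U<sub>t</sub> = 0.02,
  burn-in 10N, 400 post-shift generations, three replicates per selfing
  fraction, and time-average the post-shift rows at least 200 generations
  past the shift.

What these scaled runs do *not* show: weak-mutation coexistence of hundreds
of simultaneously segregating trait variants (the full-scale polygenic
regime), chromosome-scale LD block formation, or realistic fixation loads.
In particular, at N = 100 recessive deleterious mutations fix far more often
than at N = 5,000, so with the deleterious background the high-selfing
fitness advantage is not merely attenuated (as at full scale) but can
reverse; the tests assert only the attenuation and the preserved ordering of
inbreeding depression.

## Statistics

Variance decomposition per trait, over trait sites j with genotype
frequencies f&#8320;, f&#8321;, f&#8322; and effect a:

* V<sub>g</sub> = &Sigma; 2p(1&minus;p)a&sup2; (Hardy–Weinberg, no linkage);
* V<sub>I</sub> = &Sigma; (2f&#8322;f&#8320; &minus; &frac12;f&#8321;&sup2;)a&sup2;
  — this grouping vanishes at Hardy–Weinberg proportions and equals
  2Fpq&middot;a&sup2; under the single-locus inbreeding model, the defining
  properties of an inbreeding covariance;
* V<sub>G</sub> = variance of individual trait values (so cross-locus
  covariance is captured); the summed per-locus variances are kept as a
  diagnostic (equal to V<sub>g</sub>+V<sub>I</sub> under linkage
  equilibrium);
* C<sub>LD</sub> = V<sub>G</sub> &minus; V<sub>g</sub> &minus; V<sub>I</sub>
  by construction, so the identity holds to rounding error on every report.

Inbreeding depression is assayed as 1 &minus; w&#772;<sub>S</sub>/w&#772;<sub>O</sub>
over two transient cohorts of 500 offspring (obligately selfed / obligately
outcrossed with two distinct parents), mutation disabled, parents sampled
proportionally to fitness; cohorts are discarded.  For a single
Hardy–Weinberg locus this is near zero (selfing and random mating then
produce the same offspring genotype distribution); it becomes positive with
dominance once parental genotype frequencies deviate from the offspring
equilibrium, and through multi-locus homozygosity effects.

LD tables use a minor-allele-frequency filter (&ge; 0.1) followed by greedy
left-to-right thinning at a spacing of 2% of the genome length (0.5 Mb at
full scale) — deterministic, so tables are reproducible.  Decay curves bin
pair distances into 2%-of-genome windows up to half the genome, randomly
down-sample every occupied bin to the sparsest bin's count, and drop a
replicate entirely when that count is below 10.  r&sup2; is the squared
allelic correlation; |D&prime;| normalises D by its frequency-given bound.
An external thinning tool may break ties differently; equivalence with any
specific tool is not claimed.

Haplotype samples take 50 individuals, drop trait mutations fixed within the
sample, and thin to 100 sites prioritising segregating trait variants;
allele trajectories follow every trait mutation segregating in the whole
population just before the shift, reading fixation from the substitutions
ledger.  Bootstrap confidence intervals use 1,000 percentile replicates.

## Numerical notes and limitations

* The two-locus recursion is linear-algebraic (einsum over 4&times;4&times;4
  gamete tensors); frequencies are renormalised each generation and conserve
  &Sigma;x<sub>i</sub> = 1 to ~10&#8315;&sup1;&sup2; per step.
* Degenerate inputs: all-zero fitness raises an error (no silent rescue);
  QLE is undefined at F = 1 or r = 0; architectures with
  &alpha;<sub>i</sub>+&beta;<sub>i</sub> = 0 are rejected as effectively
  neutral.
* The simulator treats crossover counts as Poisson with mean
  rec&middot;(L&minus;1) (no interference) and mutation counts as Poisson
  with mean &mu;L; breakpoint and mutation positions are uniform.
* The closed-form allele-frequency expressions of the two-locus model beyond
  leading order are represented only through the oracle; no attempt is made
  to provide dynamic equations for V<sub>g</sub> or C<sub>LD</sub>.
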