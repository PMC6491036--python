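# Methods

`phylofoot` re-implements, as a tested pipeline, a comparative-evolutionary
analysis of anthropoid foot proportions: size-standardized morphometrics,
phylogenetic regression, multi-optima Ornstein-Uhlenbeck (OU) adaptive-
landscape model selection, stepwise regime discovery, simulation-based
power analysis, and heavy-tailed Bayesian ancestral-state estimation.
This note records the models, the conventions the package commits to where
the literature varies, the numerical choices, and the limits of what the
synthetic fixtures can demonstrate.

## Data model

The raw observation is an individual skeleton with six caliper lengths
(mm): maximum talar articular length, talar trochlea length, cuboid
length, and the lengths of MT1, MT5, and PP4.  Talar neck length is
derived as articular minus trochlea length, and the six variables carried
forward are trochlea, neck, cuboid, MT1, MT5, PP4.  Dividing each row by
its geometric mean removes isometric size, so each standardized row
multiplies to 1 exactly; PCA of the standardized variables is computed on
the covariance matrix (the variables are commensurate ratios), with each
loading column sign-fixed so its largest-magnitude entry is positive.
Species means of PC1-PC3 are the traits for all evolutionary analyses.

Trees are rooted, with branch lengths in Myr.  A fossil tip is grafted
onto an interior edge and keeps its true (shorter) root-to-tip depth;
every covariance downstream uses actual tip depths, so no ultrametric
correction is ever applied.  Polytomies are resolved arbitrarily with
zero-length edges at load time (and contracted again inside the MCMC
sampler, where a zero-length edge would otherwise pin two states
together).

## Hansen model and fitting

Along a branch in selective regime k, a trait follows
dX = alpha (theta_k - X) dt + sigma dB.  The tip mean is a weighted
combination of the regime optima, with weights obtained by integrating
alpha e^{-alpha (T - t)} along each root-to-tip path (rows sum to 1); the
tip covariance is the fixed-root OU kernel
sigma^2 / (2 alpha) e^{-alpha d_ij} (1 - e^{-2 alpha s_ij}), where s is
shared path time and d patristic separation, valid for fossil tips.
alpha = 0 recovers Brownian motion exactly and is always included in the
optimizer's candidate set, so OU fits never score below their nested
Brownian limit.

Conventions:

* **Root state** equals the root regime's optimum; no separate root
  parameter.  (Switchable in principle by painting a root-only regime.)
* **Traits** (PC1-PC3) are independent univariate processes sharing one
  painting; log-likelihoods and parameter counts are summed.
* **Parameters per trait**: alpha, sigma^2, and one theta per regime
  (Brownian motion: 2).  **AICc/SIC sample size** is the number of taxa
  for the a-priori hypothesis comparison, and taxa x traits inside the
  stepwise SURFACE search (the convention of the SURFACE method itself;
  with the taxa-only convention the AICc small-sample term diverges as
  soon as a few regimes are painted on a modest tree and the search can
  never accept a true shift).
* **Optimization**: theta is profiled by GLS given alpha, sigma^2 by its
  ML plug-in, leaving a 1-D concentrated likelihood in alpha maximised by
  a deterministic 25-point log-grid scan on [1e-6, 50]/Myr plus bounded
  refinement (tolerance 1e-8).  The 50/Myr ceiling prevents degenerate
  "every species at its own optimum" fits and is logged when active.

The a-priori hypotheses are encoded as regime paintings built from crown
groups (a clade's stem edge carries its regime): H1 Brownian motion, H2 a
single optimum, H3 bipedal / terrestrial / arboreal, H4 splits the
terrestrial regime into heel-strike plantigrade (African apes) versus
semiplantigrade (terrestrial cercopithecins), H5 adds a
climbing-plus-hindlimb-suspension regime (Pongo, atelids), H6 separates
active climbing (hylobatids, Alouatta, and by default Lagothrix) from
suspension (Pongo, Ateles).  The fossil's regime in H3-H6 is an explicit
per-hypothesis setting; the default places it with the African-ape
(terrestrial/plantigrade) regime, and `"bipedal"` places it with *Homo*.
The *Homo sapiens* terminal branch can be shortened
(`tree.shorten_terminal_branch`, suggested 0.1 Myr) to sharpen optimum
estimation; the packaged fixtures leave it untouched.

## Stepwise regime discovery (SURFACE)

The forward phase starts from one optimum and repeatedly tries a new
regime shift at the origin of every branch, keeping the best AICc
improvement; the backward phase greedily re-points shifts at shared
optima (including the ancestral regime) while AICc improves, which is how
convergent evolution is detected.  Ties break toward the deepest branch
origin, then the lowest branch index.

A forward step must improve AICc by more than 10 units (the conventional
"essentially no support for the simpler model" margin).  The permissive
any-improvement rule is available (`min_improvement=0`) but measured
behaviour argued against it as a default: maximising over every branch
of the tree inflates the apparent improvement of the best spurious
candidate, and on single-optimum null data the permissive rule accepted a
false shift about 9 times in 10, while the improvement from a genuine
shift of 5 stationary s.d. exceeds 60 AICc units.  The 10-unit margin
removes essentially all null acceptances without touching real shifts.
The backward phase accepts any improvement, since collapsing only removes
parameters.

## pGLS and phylogenetic signal

Scaling of log lengths on log body mass uses GLS whose error covariance
is the Brownian matrix with off-diagonals multiplied by Pagel's lambda,
profiled by ML on a 101-point grid with bounded refinement (tolerance
1e-5); p-values are two-tailed t with n - 2 df, and lambda's difference
from the 0 and 1 boundaries is flagged by likelihood-ratio tests against
chi-square with 1 df.  Fossil tips without body mass are pruned with a
warning.  Multivariate phylogenetic signal is the Kmult statistic (the
trace-based multivariate generalisation of Blomberg's K; expectation
about 1 under Brownian motion) with significance from 999 permutations of
taxa across tips; the univariate case is verified against an independent
R implementation.

## Power analysis

For two fitted models A and B, 1000 datasets (100 in tests) are simulated
from each model's exact Gaussian, both models are refitted to every
dataset with the same deterministic optimizer, and
delta = -2 (logL_A - logL_B) is collected under both generators.  Power
is the fraction of delta-under-B exceeding the 95th percentile of
delta-under-A, with a randomized tie rule at the criterion so the test
has exact 5% size even when the two models coincide and delta is
identically zero.  The four model ladders of increasing complexity
(Brownian vs single-optimum, then successive multi-optima pairs) run
end-to-end on the packaged fixture.

## Ancestral states

Under Brownian motion, node states are the conditional Gaussian means
given the tips, with the root treated as a GLS mean; intervals use the ML
plug-in rate plus the root-mean uncertainty.  Because a single rate is
assumed, an exceptionally derived lineage drags estimates toward itself.
The stable model replaces Gaussian branch increments with symmetric
alpha-stable ones: increment of x over a branch of length t has scale
c t^{1/a}, with global rate c (log-uniform prior on [1e-6, 1e3], bounded
away from zero) and stability index a uniform on (1, 2]; a = 2 is exactly
Brownian motion.  Heavy tails let single branches absorb jumps, which
attenuates the averaging effect.  A single global rate parameterisation
is used deliberately: per-branch rate multipliers would compete with the
tail index for the same signal and slow mixing without adding
identifiable structure.

Sampling is Metropolis-within-Gibbs: internal node states updated in two
parity-coloured blocks (parent and child never share a block, so
accept/reject is exact per node), one joint translation move of all free
node states (the overall level is the softest posterior direction), and
scalar moves for log c and the index.  Proposal scales adapt toward
20-40% acceptance during burn-in only.  The stable log-density is
evaluated from an FFT inversion of the characteristic function with
first-order de-aliasing and a power-law far tail, cached on a 0.01 index
grid; accuracy against quadrature references is ~1e-4 in the body and
~0.01 in log-density far into the tails.  The full protocol
(2,000,000 iterations, thinning 200, 600,000 burn-in, two chains) is the
default; tests run 6,000-30,000 iterations with proportional thinning and
burn-in.  Convergence is monitored by the classic Gelman-Rubin PSRF
(clamped at its asymptotic floor of 1, so identical chains report exactly
1.0) with runs flagged when any monitored parameter exceeds 1.2.  Node
estimates are medians with equal-tailed 95% credibility intervals from
pooled post-burn-in samples; intervals are per-axis marginals, so the
phylomorphospace credibility region is a rectangle.  Model comparison
uses a BPIC with the posterior-mean plug-in effective-dimension form,
BPIC = -2 E[log L] + 2 p_D with p_D = 2 (log L(theta-hat) - E[log L])
and theta-hat the posterior mean; lower is better, |difference| < 2 is
reported as a tie.

## Synthetic study fixtures

The packaged tree is a 45-taxon synthetic stand-in whose clade structure
mirrors hominoids, cercopithecoids, and platyrrhines with round
divergence dates (root 40 Myr); it is NOT the published consensus
phylogeny.  The fossil stand-in is grafted on the *Homo* stem with a
1.4-Myr terminal branch ending 4.4 Myr before present.  Scenarios evolve
the six log-shape components under a chosen hypothesis painting
(default: the heel-strike-plantigrade scenario, alpha = 2/Myr,
sigma^2 = 0.02/Myr on log-shape, regime contrasts of 0.05-0.35 log
units, i.e. roughly 4-7 stationary s.d.); the fossil's branch lies in
the African-ape regime, so the fixture reproduces the qualitative
headline — the fossil clusters with African apes — as a smoke test, not
as evidence.  Measurements are built as
intercept x mass^b x exp(shape) x lognormal noise (default 8 individuals
per species, noise s.d. 0.05, exponents slightly below the isometric 1/3
except the talar trochlea), and body masses are genus-typical constants.
Trait simulation is the exact branch-wise OU transition (no Euler error),
and also returns internal-node truths for coverage experiments.

What passing on these fixtures does and does not show: the pipeline's
estimators are consistent and calibrated under their own assumptions
(exact model match, balanced sampling, no measurement covariance between
variables beyond shared size, no intraspecific spatial or age structure).
Real morphometric data violate several of these; in particular the
fixtures cannot validate the anatomical measurement protocol, the choice
of the six variables, or the biological realism of the regime
assignments.

## Degenerate inputs and tie-breaks

Single-tip trees parse but are flagged degenerate; duplicate taxon rows
cluster at height zero with a warning; a UPGMA problem whose distances
are all tied reports an undefined (NaN) cophenetic correlation rather
than a fabricated one; unidentifiable regimes (no lineage retains weight
at the fitted alpha) are reported by name; Pagel's lambda above the
positive-definiteness limit raises.  UPGMA ties break toward the
lowest-index pair, matching the exhaustive-agglomeration oracle used in
tests.

## Problem sizes in the test suite

The suite exercises the exact study geometry (45 taxa, 6 measurements,
~8 individuals/species, PC1-PC3) for morphometrics, hypothesis fitting,
ladders, and ancestral estimation, and smaller trees (16-24 taxa) for the
stepwise-search and power operating-characteristic simulations, with
replicate counts of 100-200 where a rate is asserted and reduced MCMC
scales (6,000-30,000 iterations) chosen so the chains pass their own
PSRF checks.
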