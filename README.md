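# phylofoot

Comparative-evolutionary analysis of anthropoid foot proportions, built
to ask what kind of foot the last common ancestor (LCA) of humans and
chimpanzees walked on.  Given a time-calibrated phylogeny (with a fossil
stem hominin grafted as a short, non-contemporaneous tip), a table of six
linear foot measurements per individual, and per-taxon body masses, the
package:

* standardizes measurements by each individual's geometric mean and
  ordinates them by PCA;
* clusters taxa (UPGMA on Euclidean distances, validated by the
  cophenetic correlation);
* regresses log lengths on log body mass by phylogenetic GLS with
  maximum-likelihood Pagel's lambda;
* measures multivariate phylogenetic signal (Kmult);
* fits Brownian-motion, single-optimum, and multi-optima Hansen
  (Ornstein-Uhlenbeck) models encoding a-priori locomotor hypotheses,
  compared by AIC/AICc/SIC;
* discovers selective regimes without a-priori hypotheses by stepwise
  AICc (SURFACE-style forward addition and backward collapse, detecting
  convergence);
* quantifies model-selection power by parametric bootstrap of the
  likelihood-ratio statistic delta = -2 (logL_0 - logL_1);
* estimates ancestral states under Brownian motion and under a
  heavy-tailed alpha-stable increment model by MCMC (Gelman-Rubin PSRF
  diagnostics, BPIC model comparison), and assembles phylomorphospaces
  with a credibility box for the focal ancestor.

The core model is the Hansen process: along each branch, a trait obeys
dX(t) = alpha (theta - X(t)) dt + sigma dB(t), where theta is the
optimum of the selective regime painted on that branch, alpha (1/Myr) the
restraining force, and sigma^2 the diffusion; alpha = 0 is Brownian
motion.  Trait means are integrals of regime occupancy discounted by
e^(-alpha t), covariances are the fixed-root OU kernel, and both are
exact for fossil tips that end before the present.  See
`docs/methods.md` for conventions, priors, and numerical choices.

Everything runs on packaged synthetic fixtures with known ground truth —
a 45-taxon stand-in tree (44 extant anthropoids plus a fossil grafted
with a 1.4-Myr stem ending 4.4 Myr before present) and seeded generators
for traits and individual-level measurements — so the full pipeline is
testable without any data download.  User-supplied Newick/TSV data drop
into the same interfaces.

## Worked example

```python
import numpy as np
from phylofoot import morphometrics as M
from phylofoot.oufit import compare_models, fit_bm, fit_hansen
from phylofoot.signal import kmult
from phylofoot.synthetic import make_fixture

fx = make_fixture("h4", seed=1)        # traits generated under the
                                       # heel-strike-plantigrade hypothesis
std = M.geomean_standardize(fx.measurements)
res = M.pca(std)
print("percent variance (PC1-3):", np.round(res.percent_variance[:3], 1))

pc = M.species_means(res.scores)[["PC1", "PC2", "PC3"]]
sig = kmult(pc, fx.tree, n_perm=999, seed=1)
print(f"Kmult = {sig.K_mult:.3f} (p = {sig.p_value:.3f})")

fits = [fit_bm(pc, fx.tree, "H1")] + [
    fit_hansen(pc, fx.tree, fx.paintings[h], h)
    for h in ("H2", "H3", "H4", "H5", "H6")
]
print(compare_models(fits).round(1).to_string(index=False))
```

prints

```
percent variance (PC1-3): [61.3 17.4  9.3]
Kmult = 0.399 (p = 0.001)
model  K  logL  p    AIC   AICc    SIC  dAICc
   H4  4 151.2 18 -266.3 -240.0 -233.8    0.0
   H5  5 151.8 21 -261.5 -221.3 -223.6   18.7
   H6  6 155.2 24 -262.3 -202.3 -219.0   37.7
   H3  3 121.9 15 -213.8 -197.3 -186.7   42.7
   H2  1  95.0  9 -171.9 -166.8 -155.7   73.2
   H1  1  69.1  6 -126.2 -123.9 -115.3  116.0
```

The first three components carry 88% of the variance; phylogenetic
signal in the PC scores is well below the Brownian expectation of 1
(strong stabilizing selection erases signal), and the generating
four-regime hypothesis H4 (bipedal / heel-strike plantigrade /
semiplantigrade / arboreal) wins model selection decisively — a 116-unit
AICc gap to Brownian motion and 18.7 to the next (overparameterized)
hypothesis.  `phylofoot.ancestral.stable_mcmc` then estimates the
Homo-Pan-analog node with a 95% credibility interval, and
`phylofoot.ancestral.phylomorphospace` places it among the tips.

A command-line driver mirrors the stages
(`phylofoot run-all --scenario h4 --seed 1 --out results/`) and writes
every table plus a manifest of seeds and configuration; see
`phylofoot --help`.

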