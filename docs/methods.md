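# Methods

This note documents the models implemented in `clonefate`, the defaults and
why they were chosen, the numerical details that matter for reproducing
results, and what the synthetic data do and do not emulate.

## The birth–death transplant model

Haematopoiesis is modelled as a single well-mixed HSC compartment. Simulation
starts from one cell (the zygote) and grows without death until the target
pool size `n_hsc` is reached; thereafter every division is matched by a
uniformly chosen death, holding the population constant. Time advances in
fixed steps of `t_sym / 10` (0.1 years at the default symmetric-division
interval `t_sym = 1` year); each cell divides in a step with probability
`(dt / t_sym) · (1 + S)`, so a clone's selection coefficient *S* is its
excess symmetric-division rate per year. During the developmental growth
phase divisions run on a faster clock (`growth_division_years = 0.1`), so the
pool is established within the first year or two of life, as it is in vivo.

Driver mutations enter single cells at `driver_rate` events per year *at the
target pool size*; during growth the event rate is scaled by the current
population size so the per-cell rate stays constant (an unscaled
population-level rate would concentrate drivers in the handful of
developmental cells and fix macroscopic clones in almost every young
simulation). Each driver adds an increment *S* ~ Gamma(`gamma_shape`,
`gamma_rate`) to its host's coefficient, inherited by all progeny; nested
drivers accumulate additively.

At the donor's transplant age, `n_trans` cells move into a new recipient
compartment:

* **model 1** — uniform sampling without replacement (no transplant-specific
  selection);
* **model 2** — sampling weighted per cell by a clone-level engraftment
  fitness *S*<sub>engraftment</sub> ~ Gamma(0.5, 0.5) truncated to [0, 10]
  (the truncation is not specified in the source model; it bounds
  pathological weights), with non-driver cells weighted at the 30th centile
  of the drawn values, recomputed each simulation;
* **model 3** — uniform sampling, then each driver clone present in the
  recipient is boosted with probability U(0.10, 0.30) by a factor
  U(1.5, 7.0) on *S*, expiring exactly `growth_duration = 5` years after
  transplant (the multiplier lives in the recipient compartment only).

Weighted sampling without replacement uses exponential reservoir keys
(Efraimidis–Spirakis), which matches successive weighted draws without
replacement. The recipient pool regrows to `n_hsc` without death and both
compartments then age independently to the blood-draw age, when colonies are
sampled uniformly and the coalescent tree of the sample is extracted from the
recorded genealogy (internal nodes are ancestors reached by sampled lineages
through at least two distinct children; node height is the time that
ancestor divided).

**Defaults.** `n_hsc = 100,000` (mid-range of a log-uniform [25,000,
250,000] stand-in prior), `driver_rate = 2`/year, *S* ~ Gamma(0.5, 25) (mean
2%/year, heavy-tailed — a plausible clonal-haematopoiesis fitness
distribution), transplant at donor age 40 and sampling at 55, 150 colonies
per side. Reduced-scale analyses pass smaller pools explicitly; the analyses
in the test suite use `n_hsc` of 500–50,000 and 10–150 colonies per side to
fit a desk-scale compute budget, and the methods are scale-free apart from
drift (noted below).

## Molecular clock and time trees

Somatic SNVs accrue at `rate_per_year = 15.8` per HSPC per year in adult
life, with a burden of ~60 at birth; the synthetic clock draws
Poisson(15.8 × branch-years) per branch plus a developmental share of
Poisson(60) for branches overlapping the first 0.5 years. Converting an
observed molecular tree to a time tree follows four steps: subtract
per-branch sporadic-signature counts (platinum/APOBEC bursts, unlinked to
time); shorten terminal branches by 60 mutations (in vitro plus
differentiation-associated mutations); make the tree ultrametric; linearly
map heights so the first 60 mutations correspond to birth and tips sit at
the sampling age.

The ultrametric step uses an iteratively reweighted means scheme: per
iteration, each branch is rescaled by the mean of (target height / tip
height) over the leaves sharing it, so branches supported by many colonies
move less; iteration stops at relative tolerance 1e-6 (max 100 rounds) and a
final exact adjustment of terminal branches (clipped at zero, with a count
of clips reported) makes the result idempotent to 1e-9.

Branch-length sensitivity correction divides private branches by the
colony's somatic variant sensitivity `p_i` and shared branches by
`1 − Π(1 − p_i)` over the clade. For colonies with a VAF-density peak below
0.48 (purity < 96%) the sensitivity itself is estimated by Monte Carlo:
variant reads at germline-site depths are drawn Binomial(N, peak VAF) and
passed through an empirical call-probability matrix.

## Colony QC

Filters mirror the standard colony pipeline: purity by the Gaussian-KDE peak
(Silverman bandwidth, grid step 0.005) of positive-site VAFs, excluding
peaks < 0.4; clonality against the tree by per-branch pooled counts tested
one-sided against p = 0.425 (below-clonal) and p = 0.05 (above-absent), a
colony being excluded on one Bonferroni-significant branch or three
nominally inconsistent branches; duplicates as pairs with < 30 private
mutations in 8-neighbourhood-adjacent wells (dropping the later-sorted id);
ternary genotyping (positive: VAF > 0.15 and ≥ 2 reads; negative: 0 reads at
depth ≥ 6); retention thresholds (autosomes ≥ 3 reads, depth ≥ 6, VAF > 0.2;
XY in males ≥ 2, ≥ 4, > 0.4); and a germline/artefact step (aggregate
one-sided binomial test against VAF 0.5 with Bonferroni; beta-binomial
overdispersion ρ fitted by maximum likelihood with μ at the pooled VAF,
removing sites with ρ < 0.1). The exact parameterisations of the final two
filters are this package's own, as the originals are not published in
detail.

## ABC

The 13 engraftment statistics summarise a donor/recipient time-tree pair;
clades and singletons are defined by a common ancestor after the end of
development (5 years on the time scale, mirroring the 50-mutation definition
used for the molecular-time statistics). Epoch presets: the original
peri-HCT window is 10 years centred on transplant with the pre-HCT window
from age 5; variants divide either window, or use 5- and 15-year peri
windows. Distances are Euclidean after dividing each statistic by its median
absolute deviation (consistency constant 1.4826); zero-MAD statistics are
dropped with a warning. Rejection sampling is primary; local-linear, ridge
and neural-network (one hidden layer of 5 units, best of 10 seeded restarts)
adjustments regress accepted parameters on standardised statistics with
Epanechnikov weights and translate them to the observed point.

The joint prior is truncated to the feasible region `n_trans ≤ n_hsc` by
redrawing violating draws. At the reduced scale used in the test suite
(`n_hsc = 2,000`, 150 colonies per side, 2,000 reference simulations) the
acceptance quantile is 0.05 so that ~100 draws form the posterior; at the
full scale (100,000 simulations) the 1% quantile is the default. The
posterior-predictive p is the fraction of accepted simulations at least as
far from the accepted-set centroid as the observation (a calibration-tested
stand-in; the original construction is unpublished).

Phylogenetic age is inferred per individual from 7 statistics of the
molecular-time tree against simulations of normal ageing across ages 20–100,
accepting the top 5%.

## The tree-constrained Gibbs sampler

Per bulk sample, mutation VAFs ρ are sampled under the nesting constraints
of the phylogeny via data augmentation with per-branch bounds [κ, λ].
Block 1 is a per-mutation Metropolis–Hastings step with a truncated
Beta(ρσ/(1−ρ), σ) proposal (σ = 50), binomial likelihood on
π = ρ + ε − 2ρε, and the full proposal-density (Hastings) correction — the
proposal is asymmetric, so omitting it would bias the stationary
distribution. ρ is floored at 1e-9 inside the proposal to keep the chain
irreducible. Block 2 sweeps nodes root-to-tip, splitting each node's
unallocated VAF (inbound minimum minus the sum of outbound maxima) by
uniform order statistics: the first gap tightens the inbound κ, the next
gaps extend the outbound λs, and the final gap stays unallocated.

Two details are this package's own: a node is only processed when at least
one outbound subtree carries panel-covered mutations (with nothing to
allocate below, re-drawing bounds would only pinch the inbound branch's κ
against its own mutations, measurably biasing single-mutation branches); and
a unary zygote root pins its branch's λ at 0.5, while a multifurcating root
is processed with a virtual inbound of fixed VAF 0.5. With these choices the
sampler's marginal on an unconstrained branch matches the truncated
conjugate posterior to KS < 0.01 at 10,000 retained draws. Defaults: 20,000
iterations, 10,000 burn-in, thinning 100 (100 retained draws); sex-chromosome
depths are doubled in males; error rates come from control individuals via
the pseudo-count estimator (Σvariant + 0.5)/(Σdepth + 1).

Clone fractions: the molecular tree is cut at 100 mutations from the zygote;
each crossing branch's clone is represented by the covered mutation of rank
`round(f · m)` (at least 1; half-up rounding) by decreasing median posterior
clonal fraction, where `f` is the cut's fractional position along the branch
and `m` the covered count — e.g. a branch spanning 50→150 with 60 covered
and cut 100 selects rank 30. Fractions are 2ρ (heterozygosity); branches
with no covered mutation inherit the nearest covered ancestor's deepest
representative and are flagged. The Shannon index normalises fractions to
the captured total per draw; driver fold changes divide the recipient's
retained draws element-wise by the donor's.

A note on the clone cut: the cut height is measured from the root (the
zygote), since clones "originate at 100 mutations of molecular time" —
heights measured up from the tips would not be comparable across individuals
of different ages.

## Synthetic data: what it does and does not emulate

The generator reproduces the downstream products of the real study design:
10ish donor–recipient pairs with 96–230 colonies each are emulated by
configurable pair scenarios; heterozygous SNVs at 15.8/year + 60 at birth;
colony read counts at Poisson(11.5×) depth with Binomial(depth, 0.5 ·
purity · presence) variant reads; injected impure colonies (mixtures with a
clonally unrelated colony of the same individual at purity ~U(0.45, 0.55))
and technical duplicates in adjacent wells; APOBEC-like bursts of 200–2,000
extra mutations on ~2% of recipient terminal branches; targeted counts at
Poisson(1,720×) with log-normal per-site error rates around 3×10⁻⁴ and
matched error-only control samples. True clonal fractions are computed from
the full simulated population (each branch takes the fraction of cells
descending from its child end), with a per-cell-type multiplicative wobble
applied at compartment level so nesting is preserved.

Not modelled: trinucleotide context and signature composition (bursts are
count inflation only), read-level artefacts (the cruciform/low-input filter
has no synthetic counterpart), CNAs/SVs, multi-compartment progenitor
hierarchies, and spatial niche structure. Passing tests therefore show the
statistical machinery is correct under the generating model, not that the
filters would behave identically on real sequencing artefacts.

## Numerical and scale notes

* Simulation kernels are numba-compiled; buffers grow on demand, so strong
  selection cannot exhaust the genealogy table.
* Desk-scale drift: in pools of a few thousand cells, neutral clones can
  drift to a few percent; clone-expansion claims in the tests use pools of
  ≥ 8,000 cells where the 2% threshold is meaningfully selective.
* The model-2 engrafted-fraction expectation (w·f / (w·f + (1−f))) holds
  while the transplanted number is small relative to the weighted clone;
  sampling without replacement saturates rare heavy clones.
* Bootstrap branch lengths use NegBinom(mean = branch length, dispersion θ);
  θ → ∞ recovers Poisson.
* All stochastic entry points take explicit seeds; a pipeline seed expands
  into per-stage seeds through SeedSequence spawning, and manifests record
  seeds and output checksums.
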