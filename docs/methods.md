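# Methods

## Model

`sirethresh` fits a threshold (liability) model for a binary trait recorded
on daughters of sires. Each record has an unobserved liability

    l_i = beta_{c(i)} + s_{k(i)} + e_i,      e_i ~ N(0, 1),

where `beta` are fixed-effect class levels (e.g. herd-year classes), `s` are
sire transmitting abilities and the residual variance is fixed at 1 to set
the scale of the latent variable (the usual probit identification). The
observation is the sign indicator `y_i = 1(l_i > 0)`.

Priors:

* `s | A, sigma_u2 ~ N(0, A sigma_u2)`, with `A` the numerator relationship
  matrix of the sire-only pedigree;
* `sigma_u2 ~ scaled-inv-chi2(nu_u, S2_u)`; defaults `nu_u = 2` and `S2_u`
  set by the caller (in the simulation study it is set to the generating
  value, i.e. a weakly informative prior centred at the truth — users
  analysing real data should choose `S2_u` from prior knowledge and be aware
  the study's defaults are favourable in this respect);
* non-ECP fixed classes: `beta_j ~ N(0, 1e6)` (effectively flat);
* ECP fixed classes: a Zellner-style g-prior
  `beta_ECP ~ N(beta0 1, [g X'X_ECP]^{-1})`.

An **extreme case problem (ECP)** class is one whose responses are all 0 or
all 1. Such a class effect is unidentified by the likelihood
(quasi-complete separation on the liability scale): the data are equally
consistent with any sufficiently extreme value, so under a flat or very
vague prior its conditional wanders and the sire variance absorbs spurious
signal. The g-prior shrinks these effects toward a reference level `beta0`
with a strength `g` proportional to the class's information content `X'X`
(here the class size `n_j`), giving the conditional

    beta_j | rest ~ N( (bhat_j + g beta0) / (1 + g),  1 / ((1 + g) n_j) ),

with `bhat_j` the class mean of the sire-adjusted residuals `l - Zs`.
`g = 0` recovers the flat-prior conditional, i.e. the plain normal-prior
(NP) analysis. `beta0` is by default recomputed each iteration as the
average of the current non-ECP solutions; `GibbsConfig.beta0_fixed` pins it
to a user constant instead. The ECP set is determined once from the
observed responses before sampling (it is a function of `y` only). Datasets
in which *every* class is extreme are rejected: `beta0` — and the location
of the whole liability scale — would be unidentifiable.

## Gibbs sampler

All full conditionals are closed-form (truncated-normal data augmentation):

1. liabilities: independent `N(beta_c + s_k, 1)` truncated to `(0, inf)` for
   `y = 1`, `(-inf, 0]` for `y = 0`, sampled by inverse CDF through the
   nearer tail for numerical accuracy at extreme means;
2. non-ECP `beta`: independent normals (vague normal prior);
3. `beta0`: average of the non-ECP solutions (unless fixed);
4. ECP `beta`: the g-prior conditional above;
5. `s`: one joint multivariate-normal draw with precision
   `Z'Z + A^{-1}/sigma_u2`, via a one-time generalized eigendecomposition of
   `(Z'Z, A^{-1})`, so each iteration costs two dense mat-vecs regardless of
   the current variance;
6. a recentring (interweaving) step, below;
7. `sigma_u2`: scaled-inv-chi2 with df `q + nu_u` and scale
   `(s'A^{-1}s + nu_u S2_u)/(q + nu_u)`.

`A^{-1}` is built directly from the pedigree by Henderson's rules with one
known parent and no inbreeding: Mendelian-sampling variance `d_i = 1`
(parent unknown) or `3/4` (parent known); contributions `1/d_i` at `(i,i)`,
`-1/(2 d_i)` at `(i,p)`, `1/(4 d_i)` at `(p,p)`.

### The recentring step (and why it exists)

The direction "add a constant to every `beta`, subtract it from every `s`"
leaves every liability mean — hence the whole likelihood — unchanged; only
the priors identify it. A plain alternating scan updates this direction by
a slow random walk, and at high ECP fractions with `g > 0` it couples with
the variance draw into a quasi-absorbing runaway: the truncation hazard of
the all-zero block pushes the sire solutions down coherently, the quadratic
form inflates `sigma_u2`, weaker shrinkage lets the shift grow further, and
the chain ends up stuck at `sigma_u2` of the order of the fixed-effect
prior variance. (Holding `sigma_u2` fixed removes the runaway entirely,
which isolates the feedback loop as the cause.)

Step 6 therefore draws the shift `delta` from its exact Gaussian
conditional under the priors (the likelihood term is constant along the
direction) and applies `beta + delta`, `s - delta`. This is a standard
interweaving/ancillarity move: it leaves the stationary distribution
unchanged and restores practical ergodicity. It is on by default
(`GibbsConfig.recenter`); disabling it reproduces the plain scan.

A consequence worth knowing: with an ergodic sampler the most extreme
scenario (75% ECP classes) behaves differently from what a drifting chain
reports. There the g-prior genuinely re-routes the all-zero block's
information into the sire solutions: posterior means of `sigma_u2` can fall
slightly below the generating value, and sire/fixed-effect correlations
decline somewhat as `g` grows, instead of being exactly invariant. At 5-30%
ECP the familiar pattern holds: monotone shrinkage of `sigma_u2` in `g`,
large fixed-effect-recovery gains, and g-insensitive sire rankings.

Initialization is deterministic: `beta = 0`, `s = 0`, `sigma_u2 = S2_u`,
liabilities from one truncated-normal draw at those values. Chains are fully
reproducible given the seed. Defaults are 75 000 iterations with a 25 000
burn-in, retained without thinning; single-chain bulk ESS and a Geweke-style
z-score are available for convergence checks (`posterior.effective_sample_size`,
`posterior.geweke_z`). In this package's own test runs the burn-in needed
was far shorter than the default, so the reduced chains used by the test
suite (5 000-15 000 iterations) were verified to give the same posterior
means as 75 000-iteration chains.

## Simulator

The generator mirrors a classical overlapping-generations sire design:

* pedigree: `n_base` unrelated base sires plus `n_generations` generations of
  `n_per_generation` sires whose own sire is uniform over all earlier sires
  (defaults 50 + 3 x 150 = 500);
* transmitting abilities: base `N(0, sigma_u2)`; descendants
  `N(0.5 s_parent, 0.75 sigma_u2)`, preserving the marginal variance;
* records (default 5000) assigned uniformly at random to 200 fixed classes
  (~25 per class) and to the 500 sires (~10 per sire); assignment is
  multinomial, so balance holds in expectation, not exactly;
* class effects `Uniform(lower, upper)`; liability = class effect + sire
  effect + standard-normal residual; `y = 1(l > 0)`.

Dams are unmodelled (daughter records are exchangeable given the sire), no
selection or non-random mating, a single binary trait — features of real
livestock data that this generator deliberately omits, so passing tests
demonstrate correct inference under the stated model, not robustness to
model misspecification.

### Calibration of the class-effect bounds

The target is a given fraction of ECP classes. The upper bound is held at
+0.6 and the lower bound found by bisection: pushing it down the negative
axis makes more classes all-zero. The Monte-Carlo objective (mean ECP
fraction over simulated datasets) uses common random numbers, making it
monotone in the bound and the search deterministic given the seed; a fresh
confirmation run must land within +/-1.5 percentage points of the target.
With the upper bound at +0.6 the implied overall incidence ranges from
about 9% (75% ECP target) to about 34% (5% target), matching the regime the
method is meant for. Within a scenario, bounds are calibrated once and
reused across replicates (only the seed changes between replicates).

## Study runner

The factorial study crosses ECP targets {5, 10, 20, 30, 75}% x priors
{NP, 5G, 10G, 15G} x true sire variances {0.05, 0.02} x 5 replicates. All
four priors are fit to the same dataset within a replicate (paired
comparisons). Seeds derive from a master seed through counter-based
`SeedSequence` keys `(master, scenario, replicate, role, chain)`, so adding
a scenario never perturbs another's random streams.

`scale_factor` shrinks records, pedigree, classes and chain length
proportionally (records-per-class and records-per-sire are preserved, so the
ECP mechanics are unchanged); the package's test suite and the acceptance
script use `scale_factor = 0.2` — 1000 records, 100 sires, 40 classes,
15 000-iteration chains — with 3 replicates. At that size the qualitative
patterns (shrinkage ordering, NP inflation, recovery gains) are stable but
individual cells carry Monte-Carlo noise of roughly +/-0.01 on `sigma_u2`
and +/-0.02 on correlations; scaled cells should be read for ordering and
approximate magnitude, not digit-level equality.

## Posterior summaries

* HPD intervals by the shortest-sorted-window method: the narrowest
  contiguous window of `ceil(0.95 n)` sorted draws (the standard algorithm
  for unimodal chains; it is never wider than the equal-tailed interval).
* Point estimates are posterior means; SDs use the n-1 denominator.
* Recovery metrics: Pearson correlations between true effects and posterior
  means (fixed and sire blocks separately) and relative bias
  `(posterior mean - truth)/truth` of the sire variance, flagged when the
  truth falls outside the HPD interval.

## Calibration of the posterior, and what coverage to expect

The sampler was checked by simulation-based calibration: drawing the
generating sire variance and effects from the sampler's own priors and
refitting, the posterior rank of the true `sigma_u2` is uniform (KS p ≈ 0.6
over 40 replicates) and the 95% HPD interval covers the drawn truth at the
nominal rate. The chain therefore targets the exact posterior.

Frequentist coverage at a *fixed* truth is a different quantity. With the
study's default prior — scaled-inv-chi2 with `nu_u = 2` centred at the true
value, which has median 1.44x its centre and an infinite mean — and the
modest information a few thousand binary records carry about a
liability-scale variance, the posterior on some datasets settles well above
the generating value even with no ECP classes at all. In our runs the 95%
HPD covered a fixed truth of 0.05 in roughly 80-85% of replicate datasets,
with every miss on the high side. Users wanting calibrated fixed-truth
coverage should use a larger `nu_u` (a lighter-tailed prior) or more
informative designs; the study defaults follow the original experimental
setup.

## Numerical notes and edge cases

* Truncated-normal sampling inverts through the tail nearest the threshold;
  when the conditional mean is >~38 SD beyond the threshold the uniform
  variate is floored at the smallest subnormal and the draw clamps to the
  threshold — exactly where the conditional mass concentrates in that
  regime.
* The sire-draw eigendecomposition is computed once per chain; eigenvalues
  are clipped at zero against round-off.
* Classes with a single record are allowed (an ECP class of size one is
  legitimate); empty classes are rejected when the ECP set is computed.
* `sample_sire_variance` with zero sires returns a pure prior draw.
* Pearson correlations reject zero-variance inputs; HPD intervals require at
  least 10 draws.
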