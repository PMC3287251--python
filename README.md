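# sirethresh

Bayesian threshold (liability) sire model for binary traits, with a
Zellner-style g-prior for fixed-effect classes that suffer **extreme case
problems** (ECP) — classes in which every record is 0 or every record is 1.

## The problem

Binary traits in animal breeding (calving difficulty, disease incidence,
survival) are routinely analysed with a threshold model: a latent liability
`l = X beta + Z s + e` with `e ~ N(0, I)` determines the observation through
`y = 1(l > 0)`; sire transmitting abilities `s` have prior
`N(0, A sigma_u2)` with `A` the pedigree relationship matrix, and the sire
variance `sigma_u2` carries the genetic signal (liability heritability
`h2 = 4 sigma_u2 / (sigma_u2 + 1)`).

With many small fixed-effect classes, some classes end up all-0 or all-1.
Those class effects are unidentified by the likelihood (quasi-complete
separation), their Gibbs solutions drift toward extreme values even under a
vague normal prior, and the sire variance picks up the damage: point
estimates become severely inflated as the ECP fraction grows.

`sirethresh` implements the remedy: a **g-prior** on the ECP classes,

    beta_ECP | beta0 ~ N(beta0 1, [g X'X_ECP]^(-1)),

which shrinks each unidentified class effect toward a reference level
`beta0` (the average of the identified, non-ECP solutions) with relative
weight `g` between 0 and 1. The full conditional is

    beta_j | rest ~ N( (bhat_j + g beta0)/(1 + g),  1/((1 + g) n_j) ),

so `g = 0` recovers the plain normal-prior analysis ("NP") and small weights
(5-15%) are enough to stabilize the variance component. The package
provides the Gibbs sampler (truncated-normal data augmentation, joint sire
updates, Henderson-rule `A^{-1}`), a calibrated simulator for liability-scale
binary data with a controlled ECP fraction, posterior summaries (mean, SD,
95% HPD), recovery metrics against simulation truth, and a study runner
that reproduces the full ECP x prior x variance factorial experiment.

See `docs/methods.md` for the model, the sampler (including an interweaving
step that keeps the chain ergodic at extreme ECP fractions), and all
numerical choices.

## Worked example

Simulate a dataset with ~20% ECP classes and analyse it with the normal
prior and with a 15% g-prior:

```python
import sirethresh as st

ped = st.build_pedigree(n_base=50, n_per_generation=150, n_generations=3, seed=1)
bounds = st.calibrate_fixed_effect_bounds(
    target_ecp=0.20, n_classes=200, records_per_class=25, sigma_u2=0.05,
    seed=2, pedigree=ped,
)
data, truth = st.simulate_dataset(ped, 5000, 200, bounds, sigma_u2=0.05, seed=3)
print(f"ECP fraction {st.ecp_fraction(data):.3f}, incidence {data.y.mean():.3f}")

for g in (0.0, 0.15):
    cfg = st.GibbsConfig(g_weight=g, S2_u=0.05, n_iterations=20000, burn_in=5000, seed=4)
    res = st.run_chain(data, ped, cfg)
    summ = st.summarize_chain(res.sigma_u2_draws)
    pf = st.pearson_true_vs_estimated(truth.beta_true, res.beta_mean)
    print(f"g={g:.2f}: sigma_u2 {summ.mean:.3f} (sd {summ.sd:.3f}), "
          f"HPD95 ({summ.hpd_lower:.3f}, {summ.hpd_upper:.3f}), fixed-effect r {pf:.3f}")
```

Output:

```
ECP fraction 0.185, incidence 0.245
g=0.00: sigma_u2 0.083 (sd 0.025), HPD95 (0.034, 0.132), fixed-effect r 0.444
g=0.15: sigma_u2 0.053 (sd 0.019), HPD95 (0.017, 0.089), fixed-effect r 0.909
```

The true sire variance is 0.05. With a plain normal prior the 37 extreme
classes drift, the sire variance is overestimated by two thirds, and the
correlation between the 200 true and estimated class effects is only 0.44;
the 15% g-prior moves the point estimate next to the truth and lifts that
correlation to 0.91.

The same analysis is available from the shell:

```bash
sirethresh simulate --out-prefix run/toy --ecp-target 0.2 --seed 1
sirethresh fit --data run/toy.data.tsv --pedigree run/toy.pedigree.tsv \
    --g-weight 0.15 --iterations 20000 --burn-in 5000 --seed 2 --out run/fit15
sirethresh study --out-dir run/study --master-seed 1 --scale-factor 0.2
```

`study` reproduces the factorial experiment (5 ECP levels x 4 priors x 2
sire variances x replicates) and writes `table1.csv` / `table2.csv`
(sire-variance posterior summaries at true values 0.05 / 0.02) and
`table3.csv` (correlations between true and estimated effects).

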