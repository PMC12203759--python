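# mbtrans

Latent transition analysis of adolescents' 24-hour movement behaviours
between schooldays and weekends, and the association of those transitions
with health-related quality of life (HRQoL) and well-being.

## The problem

A day is a closed budget: minutes spent in vigorous physical activity (VPA),
moderate PA (MPA), light PA (LPA), sedentary behaviour (SB) and sleep sum to
1440. Such compositional data live on a simplex, so the package expresses
each 5-part composition in isometric log-ratio (ilr) coordinates — an
orthonormal log-ratio basis mapping a composition to 4 unconstrained real
coordinates — before any statistics are computed. Each participant
contributes two compositions: an average over valid schooldays and an
average over valid weekend days.

The core model is a two-timepoint latent transition model (a hidden-Markov
mixture): participant *i* occupies latent profile *k* on schooldays with
probability `pi_k`, moves to weekend profile *l* with probability `T_kl`,
and the observed ilr vectors are Gaussian given the profile,

    z_i1 | k ~ N(mu_k1, Sigma_k1),    z_i2 | l ~ N(mu_l2, Sigma_l2),

with means and full covariances free to differ across profiles *and*
timepoints (the least-restricted structure). The marginal likelihood per
participant is `sum_{k,l} pi_k T_kl N(z_i1; mu_k1, Sigma_k1) N(z_i2; mu_l2,
Sigma_l2)`, maximised by EM over multiple clustering-based starts; the
number of profiles is chosen by BIC alongside relative entropy and minimal
profile size. Modal profile pairs define transition categories
(e.g. `Excellent->Good`), which are regressed — with chained-equations
multiple imputation of missing covariates and Rubin's-rules pooling — on
PedsQL HRQoL and WHO-5 well-being scores, adjusted for age, sex, BMI
z-score and maternal education.

A calibrated synthetic-data generator (`mbtrans.synthetic`) emulates the
cohort structure the analysis assumes, so the entire pipeline is testable
without any restricted data.

## Worked example

```python
from mbtrans import (GeneratorConfig, generate, build_weeks_table,
                     LatentTransitionModel, prepare_weeks)

study = generate(GeneratorConfig(n=1070, seed=1))          # synthetic cohort
weeks = prepare_weeks(build_weeks_table(study.days))        # validity + zeros
model = LatentTransitionModel.from_weeks(weeks)             # ilr coordinates
print(model.select_profiles(range(2, 6), n_starts=50, seed=1).round(2))
res = model.fit(n_profiles=4, n_starts=50, seed=1)
print(res.summary())
```

The selection table printed by this exact run:

```
 n_profiles  loglik  n_params     bic     aic  entropy  min_profile_size_pct
          2 -795.39        59 2000.02 1708.77     0.99                 27.79
          3 -153.88        92  945.91  491.76     0.99                 28.33
          4  -32.38       127  945.67  318.76     0.99                 14.92
          5   12.51       164 1112.54  302.98     0.94                 14.92
```

BIC is minimised at 4 profiles. The fitted 4-profile summary (abridged):

```
Profile proportions (%):
           schoolday_pct  weekend_pct
Excellent           30.4          3.1
Good                41.3         27.2
Fair                26.8         41.4
Poor                 1.5         28.3

Transition probabilities (%, rows = schoolday profile):
                To Excellent  To Good  To Fair  To Poor
From Excellent          10.1     89.0      0.6      0.3
From Good                0.0      0.4     97.1      2.5
From Fair                0.0      0.0      4.1     95.9
From Poor                0.0      0.0      0.0    100.0
```

Read: 30.4% of participants show the most active, least sedentary profile
("Excellent") on schooldays, but 89% of them shift to the "Good" profile on
weekends; almost everyone moves at least one profile down, and the "Poor"
profile swells from 1.5% to 28.3% on weekends. Back-transformed emission
means (`res.profile_mean_compositions(t)`) report each profile in min/day.
Regressing the overall HRQoL score on the modal transition categories
(schoolday Fair and Poor merged, rare transitions excluded) with m = 5
imputations gives, from the same run:

```
            category       B  ci_low  ci_high     p  reference
Excellent->Excellent   0.000     NaN      NaN   NaN       True
     Excellent->Good  -3.916  -9.167    1.334 0.143      False
  Fair-or-Poor->Fair -10.234 -19.410   -1.058 0.029      False
  Fair-or-Poor->Poor  -9.353 -14.591   -4.116 0.000      False
          Good->Fair  -6.553 -11.700   -1.406 0.013      False
          Good->Poor -12.024 -21.176   -2.872 0.010      False
```

(On this draw two extra transition pairs cleared the 1% threshold and are
retained alongside the four dominant categories.)

Participants sliding from "Good" schooldays to "Fair" weekends score 6.6
HRQoL points below those staying "Excellent" all week (the generating
effect was −6.4); the slide into "Poor" costs 9.4 points (generating value
−9.5).

A thin CLI mirrors these stages:

```bash
mbtrans simulate --n 1070 --seed 1 --out sim/
mbtrans preprocess --days sim/days.csv --out weeks.csv
mbtrans fit --weeks weeks.csv --k-range 2:5 --starts 50 --seed 1 --out fit/
mbtrans associate --posteriors fit/posteriors.csv --items sim/items.csv \
    --covariates sim/covariates.csv --m 5 --seed 1 --out effects.csv
```

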