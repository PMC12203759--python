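# Methods

## Compositional representation

Daily time use is a 5-part composition (VPA, MPA, LPA, SB, sleep; fixed
order) closed to 1440 min. All modelling happens in isometric log-ratio
(ilr) coordinates. The default contrast basis is the pivot (sequential
binary partition) basis peeling parts off in the stated order,
`basis_id="pivot-vpa-first"`:

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gm(x_{j+1..D}) ),  j = 1..4.

Any orthonormal basis differs from this one by a rotation, Gaussian
likelihoods are rotation-invariant, and back-transformed compositions are
basis-independent, so the choice affects nothing downstream; the pivot
basis is simply reproducible, and its first coordinate isolates VPA, which
the zero-imputation step exploits. Compositions are always re-closed to
1440 even when device rounding makes recorded minutes sum slightly off;
ilr is scale-invariant so this only standardises reporting.

**Rounded zeros.** VPA can be recorded as an exact zero. A zero is treated
as a value censored below a detection limit of 0.5 min/day (half the
smallest daily average resolvable from a single 15-s epoch over two days;
the limit is a package default, not an empirical estimate — callers can
override it). In the pivot basis a zero VPA leaves coordinates 2–4
observed and left-censors coordinate 1, so the log-ratio EM algorithm fits
a multivariate normal with one left-censored coordinate: the E-step
replaces the censored coordinate by its conditional truncated-normal
moments, iterating until the relative observed-data log-likelihood change
is below 1e-6, and imputation uses the converged conditional mean. Imputed
VPA lands in (0, 0.5) min and the remaining parts are shrunk to preserve
each composition's total. The default pipeline (`prepare_weeks`) instead
*drops* zero-containing participant compositions; imputation is opt-in
(`zeros="impute"`), because imputed near-zero VPA values tend to spawn a
spurious tiny profile in the mixture.

## Accelerometry preprocessing

Epoch-level ENMO (mg) is classified by wrist cut-points — SB < 35.6,
LPA [35.6, 201.4), MPA [201.4, 707], VPA > 707 — with epochs inside the
supplied sleep window counted as sleep regardless of acceleration and
nonwear epochs discarded (nonwear time is reported, never redistributed).
A day is valid unless sleep < 180 min, wake time < 240 min, wear time
< 960 min, or sleep efficiency < 0.5. Participants are retained with at
least 5 valid days including 3 schooldays and both weekend days; retained
participants get one schoolday and one weekend composition, each the
arithmetic per-behaviour mean over valid days of that type, closed to
1440 (geometric averaging would also be defensible; arithmetic matches
how wear-time averages are conventionally reported, and the two differ
negligibly at day-to-day dispersions seen here). Raw signal processing —
autocalibration, nonwear detection, sleep-window detection — is upstream:
sleep windows and wear flags are inputs.

## Latent transition model

For participant i with ilr vectors (z_i1, z_i2):

    P(z_i1, z_i2) = sum_{k,l} pi_k T_kl N(z_i1; mu[k,1], Sigma[k,1])
                                       N(z_i2; mu[l,2], Sigma[l,2])

with K profiles, initial probabilities pi, row-stochastic transition
matrix T, and full per-profile, per-timepoint covariances (the
least-restricted structure). Free parameters:
(K−1) + K(K−1) + 2K·4 + 2K·10.

**EM.** Joint responsibilities γ_ikl ∝ pi_k T_kl φ1 φ2 are computed in log
space; the M-step updates pi and T from γ and the emission moments from
the timepoint-marginal responsibilities. Covariance eigenvalues are floored
at 1e-8 of the mean variance to keep the least-restricted covariances from
collapsing onto single points; a component whose effective weight falls
below 1e-8·n aborts the start and a fresh initialisation is drawn. The
log-likelihood is monotone non-decreasing within every start (asserted in
tests at 1e-8 relative slack).

**Initialisation and multistart.** Because emissions differ freely across
timepoints, each timepoint is clustered separately — alternating k-means
and full-covariance Gaussian-mixture starts — and T is initialised from the
smoothed cross-tabulation of the two cluster labellings. This replaces a
pooled-clustering, near-identity-T initialisation, which systematically
missed the global optimum here: weekend compositions are shifted wholesale
towards sleep, so pooled clusters mix timepoints and near-identity T
contradicts the strongly asymmetric transitions in these data. Defaults:
50 starts, each run 60 iterations, the best 5 polished to convergence
(relative tolerance 1e-8, max 1000 iterations); the seed is mandatory for
reproducibility.

**Identifiability and labelling.** With time-varying emissions the
timepoint-2 state labels are identified only up to a simultaneous
permutation of T's columns and the weekend emissions. Profiles are
therefore relabelled substantively: states at each timepoint are sorted by
descending moderate-to-vigorous PA of the back-transformed emission mean,
and named Excellent/Good/Fair/Poor for K = 4. This is a pure relabelling;
likelihood, BIC, AIC and entropy are invariant (tested).

**Selection.** BIC = −2ll + p·ln(n) is the default selector, reported with
AIC, relative entropy 1 − E[−Σ p ln p]/ln K averaged over the two
timepoint-marginal posteriors (1 by convention at K = 1; joint-state
entropy over K² states is available via the posterior joints), and the
minimal modal profile share averaged over timepoints — solutions with
profiles under ~2% deserve substantive scrutiny even when BIC prefers
them. Posterior-weighted descriptives (weighted means/SDs, proportions,
compositional means) use the timepoint-marginal posteriors as weights.

## Questionnaires

PedsQL 4.0: 23 items, 0–4, four domains (physical 8, emotional 5, social
5, school 5); items map to 100 − 25·raw. Missing items are imputed by the
mean of the answered items in their domain provided at least half that
domain was answered (the standard PedsQL completeness rule; the imputation
threshold is a convention, chosen here because the emulated cohort's item
missingness is under 1%). Physical functioning = physical-domain mean;
psychosocial = mean of the 15 emotional+social+school items; total = mean
of all 23. WHO-5: five items, 0–5, score = 4 × item sum; any missing item
makes the score missing (no proration).

## Transition-category regression

Modal profile pairs (schoolday → weekend) are tallied after optional
merging of sparse schoolday profiles (e.g. Fair and Poor into
"Fair-or-Poor"); pairs under 1% of participants are excluded — their
participants are dropped, never reassigned. Each outcome (overall HRQoL,
physical, psychosocial, well-being — four separate models) is regressed by
OLS on category indicators against the stable `Excellent->Excellent`
reference plus age, sex (girls = 1), BMI z-score and maternal education
(university or higher = 1). Missing BMI z and education are imputed by
chained equations (10 cycles): Bayesian-draw linear regression with
predictive mean matching (5 donors) for BMI z, a logistic draw with
posterior parameter perturbation for education; m = 5 completed datasets
are fitted and pooled by Rubin's rules with Barnard–Rubin degrees of
freedom. With no missingness the m fits are identical and pooling
reproduces single-fit OLS exactly (tested against statsmodels). No
multiplicity adjustment is applied across the four outcome models.

## Synthetic-data generator

The generator emulates the cohort the pipeline expects, with defaults
calibrated to the published summary tables of the study population it
mimics: K = 4 profiles; schoolday shares (29.7, 43.0, 25.8, 1.6)%;
strongly asymmetric transition rows; profile mean compositions in min/day
at both timepoints; outcome effects (0, −2.5, −6.4, −9.5) on the overall
HRQoL scale (analogous vectors for the other outcomes) around reference
intercepts, with covariate effects (age −0.5/yr, girls −2.0, BMI z −0.5,
high education +1.5 — plausible small effects, fixed once) and residual
SDs of 11/11/13/18 points; covariates age ~ N(13.8, 2.2²) clipped to
[10, 19], 55.6% girls, BMI z ~ N(0.22, 1.12²), 41.6% high education; MCAR
missingness 5% (BMI z) and 15% (education); HRQoL respondents a 451/484
subset of the 484/1070 well-being respondents.

Dispersions: between-person within-profile SD 0.15 and day-level SD 0.25
per ilr coordinate (diagonal), with 5 schooldays and 2 weekend days per
participant, so participant-level weekly averages carry SD ≈ 0.19
(school) and 0.23 (weekend) per coordinate. The published tables report no
within-profile dispersion; these values are calibration choices. Day-level
compositions are back-transformed to minutes and closed to 1440; a
participant-timepoint VPA is zeroed with probability 0.016 (≈34 of 2140
observations) to exercise the zero-handling paths. Questionnaire items are
discretised from latent 0–100 scores (physical items from the physical
score, the 15 psychosocial items from the psychosocial score, WHO-5 items
from the well-being score) with item-level Gaussian noise (SD 0.8) and
rounding, so scored questionnaires track the configured means to within a
few points. All ground truth (labels, person-level ilr means, latent
scores, complete covariates) is returned for recovery tests; output is a
pure function of the seed.

**What the generator does not emulate:** circadian epoch-level structure
(epoch series are only synthesised in unit tests of the cut-point path),
informative missingness, school-level clustering, covariate–profile
correlations (age gradients across profiles exist in real cohorts but are
not generated), and non-Gaussian within-profile dispersion. Passing
recovery tests therefore show the estimators work under the model's own
assumptions at realistic sizes — not that real accelerometer data meet
those assumptions.

## Known limitations

- At the calibrated dispersions the weekend Excellent and Good emission
  means are only ≈2.8 within-profile SDs apart while holding ≈6% and ≈24%
  of weekend mass; at n ≈ 1070 the maximum-likelihood boundary between
  them is unstable, so transitions out of schoolday Excellent can be
  mis-apportioned between `To Excellent` and `To Good` on individual
  draws even when the global optimum is found (the K = 4 vs K = 3 BIC
  margin is correspondingly small on some draws). This is a property of
  the data-generating configuration, not of the optimizer; it is
  quantified in the acceptance suite.
- The schoolday Poor profile holds 1.6% of participants (~17 of 1070), so
  its transition row is estimated from ~17 people and carries binomial
  noise of ±7 percentage points even under perfect classification.
- Entropy on default synthetic data (≈0.95–0.99) is higher than typically
  seen in field cohorts (~0.7): Gaussian profiles with diagonal
  within-profile dispersion separate more cleanly than real behaviour.
- The lrEM implementation supports censoring in the VPA part only, which
  is the only part where rounded zeros occur in this design.
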