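"""Synthetic study generator with the structure the analysis assumes.

Emulates a two-timepoint (schoolday/weekend) cohort of adolescents: each
participant belongs to one of K latent movement-behaviour profiles on
schooldays (drawn from ``pi``), transitions to a weekend profile via the
row-stochastic matrix ``T``, and their day-level 5-part time-use
compositions scatter in ilr space around profile-specific means. HRQoL and
well-being questionnaire items are discretised from latent scores with
transition-category effects, and covariates carry MCAR missingness. Defaults
are calibrated to the observed cohort structure: four profiles with
schoolday shares (29.7, 43.0, 25.8, 1.6)%, strongly asymmetric weekend
transitions, profile mean compositions in minutes, outcome effects
(0, -2.5, -6.4, -9.5) on the overall HRQoL scale, and 5%/15% missingness in
BMI z-score / maternal education.

All ground truth (profile labels, participant-level ilr means, latent
outcome scores) is returned so recovery tests can compare estimates against
the generating values. Output is fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import transition_label
from .compositions import DAY_MINUTES, PART_NAMES, close, ilr, ilr_inverse, pivot_basis
from .lta import PROFILE_NAMES_4

__all__ = ["GeneratorConfig", "SyntheticStudy", "generate"]

# Profile mean compositions (min/day), order VPA, MPA, LPA, SB, sleep;
# profiles ordered most to least active: Excellent, Good, Fair, Poor.
SCHOOL_PROFILE_MEANS = np.array(
    [
        [7.6, 57.0, 313.1, 556.6, 505.7],
        [3.7, 41.2, 267.5, 647.7, 479.9],
        [1.1, 24.8, 229.7, 734.2, 450.3],
        [0.3, 11.9, 183.3, 838.6, 406.0],
    ]
)
WEEKEND_PROFILE_MEANS = np.array(
    [
        [12.1, 72.6, 342.3, 455.6, 557.5],
        [6.0, 53.6, 298.6, 541.4, 540.4],
        [1.8, 32.9, 261.6, 626.3, 517.4],
        [0.4, 16.1, 213.7, 732.2, 477.5],
    ]
)
DEFAULT_PI = np.array([0.297, 0.430, 0.258, 0.016])
DEFAULT_T = np.array(
    [
        [0.196, 0.800, 0.001, 0.003],
        [0.000, 0.008, 0.953, 0.039],
        [0.000, 0.001, 0.047, 0.952],
        [0.004, 0.065, 0.009, 0.922],
    ]
)

# Outcome calibration: reference intercepts and per-category effects for
# (hrqol_total, hrqol_physical, hrqol_psychosocial, wellbeing).
OUTCOME_NAMES = ("hrqol_total", "hrqol_physical", "hrqol_psychosocial", "wellbeing")
DEFAULT_INTERCEPTS = {
    "hrqol_total": 79.0,
    "hrqol_physical": 86.0,
    "hrqol_psychosocial": 75.0,
    "wellbeing": 65.0,
}
DEFAULT_NOISE_SD = {
    "hrqol_total": 11.0,
    "hrqol_physical": 11.0,
    "hrqol_psychosocial": 13.0,
    "wellbeing": 18.0,
}
# Effects by weekend destination profile (the dominant transitions are
# Excellent->Excellent, Excellent->Good, Good->Fair, Fair/Poor->Poor, so the
# destination indexes the category effect).
DEFAULT_EFFECTS = {
    "Excellent": {"hrqol_total": 0.0, "hrqol_physical": 0.0, "hrqol_psychosocial": 0.0, "wellbeing": 0.0},
    "Good": {"hrqol_total": -2.5, "hrqol_physical": -0.9, "hrqol_psychosocial": -3.3, "wellbeing": -5.1},
    "Fair": {"hrqol_total": -6.4, "hrqol_physical": -4.3, "hrqol_psychosocial": -7.4, "wellbeing": -9.8},
    "Poor": {"hrqol_total": -9.5, "hrqol_physical": -7.2, "hrqol_psychosocial": -10.8, "wellbeing": -14.4},
}
DEFAULT_COVARIATE_EFFECTS = {"age": -0.5, "sex": -2.0, "bmi_z": -0.5, "maternal_education": 1.5}


@dataclass
class GeneratorConfig:
    """Study-design and calibration knobs for the generator.

    ilr dispersion defaults: 0.15 between-person SD within a profile and
    0.25 day-level SD (per ilr coordinate, diagonal covariance). Days per
    participant: 5 schooldays and 2 weekend days. ``zero_rate`` is the
    probability that a participant-timepoint VPA is recorded as a rounded
    zero (roughly 34 of 2140 observations in the emulated cohort).
    """

    n: int = 1070
    seed: int = 0
    pi: np.ndarray = field(default_factory=lambda: DEFAULT_PI.copy())
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_T.copy())
    school_means: np.ndarray = field(default_factory=lambda: SCHOOL_PROFILE_MEANS.copy())
    weekend_means: np.ndarray = field(default_factory=lambda: WEEKEND_PROFILE_MEANS.copy())
    profile_names: tuple = PROFILE_NAMES_4
    between_sd: float = 0.15
    day_sd: float = 0.25
    n_school_days: int = 5
    n_weekend_days: int = 2
    zero_rate: float = 0.016
    zero_threshold: float = 0.5
    # outcomes
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()})
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    item_sd: float = 0.8
    wellbeing_rate: float = 484 / 1070
    hrqol_given_wellbeing: float = 451 / 484
    pedsql_item_missing_rate: float = 0.002
    # covariates
    age_mean: float = 13.8
    age_sd: float = 2.2
    girls_rate: float = 0.556
    bmi_mean: float = 0.22
    bmi_sd: float = 1.12
    high_education_rate: float = 0.416
    bmi_missing_rate: float = 0.05
    education_missing_rate: float = 0.15

    def validate(self) -> None:
        pi = np.asarray(self.pi, float)
        T = np.asarray(self.transition, float)
        K = len(pi)
        # printed percentages round to 0.1, so allow slack and renormalise later
        if not np.isclose(pi.sum(), 1.0, atol=1e-2) or np.any(pi < 0):
            raise ValueError("pi must be a probability vector")
        if T.shape != (K, K) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-2) or np.any(T < 0):
            raise ValueError("transition matrix must be K x K row-stochastic")
        if self.school_means.shape != (K, 5) or self.weekend_means.shape != (K, 5):
            raise ValueError("profile mean arrays must be (K, 5)")
        if len(self.profile_names) != K:
            raise ValueError("profile_names length must match K")
        if self.between_sd < 0 or self.day_sd < 0:
            raise ValueError("SDs must be nonnegative")
        for r in (self.zero_rate, self.bmi_missing_rate, self.education_missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class SyntheticStudy:
    """Generated tables plus the ground truth that produced them."""

    days: pd.DataFrame  # day-level behaviour records
    items: pd.DataFrame  # questionnaire item responses (NaN = not administered)
    covariates: pd.DataFrame  # age, sex, bmi_z, maternal_education with missingness
    truth: dict  # profiles, ilr means, latent scores, complete covariates


def generate(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Draw one synthetic study according to the configuration."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    K = len(cfg.pi)
    basis = pivot_basis()
    pi = np.asarray(cfg.pi, float)
    pi = pi / pi.sum()
    T = np.asarray(cfg.transition, float)
    T = T / T.sum(axis=1, keepdims=True)

    prof1 = rng.choice(K, size=n, p=pi)
    # vectorised row-wise categorical draw from T[prof1]
    u = rng.random(n)
    prof2 = (u[:, None] > np.cumsum(T, axis=1)[prof1]).sum(axis=1)

    mu_school = ilr(close(cfg.school_means), basis)
    mu_weekend = ilr(close(cfg.weekend_means), basis)

    # participant-level ilr means: profile mean + between-person scatter
    person_ilr = np.empty((n, 2, 4))
    person_ilr[:, 0, :] = mu_school[prof1] + rng.normal(0, cfg.between_sd, (n, 4))
    person_ilr[:, 1, :] = mu_weekend[prof2] + rng.normal(0, cfg.between_sd, (n, 4))

    zero1 = rng.random(n) < cfg.zero_rate
    zero2 = rng.random(n) < cfg.zero_rate

    pids = np.array([f"P{i:04d}" for i in range(n)])
    n_days = cfg.n_school_days + cfg.n_weekend_days
    t_of_day = np.array([0] * cfg.n_school_days + [1] * cfg.n_weekend_days)
    # (n, n_days, 4): participant mean for the day's timepoint + day scatter
    z_days = person_ilr[:, t_of_day, :] + rng.normal(0, cfg.day_sd, (n, n_days, 4))
    comp = ilr_inverse(z_days.reshape(-1, 4), basis, DAY_MINUTES).reshape(n, n_days, 5)
    zero_mask = np.where(t_of_day[None, :] == 0, zero1[:, None], zero2[:, None])
    if zero_mask.any():
        rest = close(comp[zero_mask][:, 1:], DAY_MINUTES)
        comp[zero_mask] = np.concatenate([np.zeros((len(rest), 1)), rest], axis=1)
    flat = comp.reshape(-1, 5)
    days = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, n_days),
            "date": np.tile(np.arange(n_days), n),
            "day_type": np.tile(
                np.where(t_of_day == 0, "schoolday", "weekend"), n
            ),
            **{f"{p}_min": flat[:, j] for j, p in enumerate(PART_NAMES)},
            "wear_min": DAY_MINUTES,
            "wake_min": DAY_MINUTES - flat[:, 4],
            "sleep_eff": 0.95,
        }
    )

    # ------------------------------------------------------- covariates
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 10.0, 19.0)
    sex = (rng.random(n) < cfg.girls_rate).astype(float)  # girls = 1
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, n)
    edu = (rng.random(n) < cfg.high_education_rate).astype(float)  # high = 1
    cov_complete = pd.DataFrame(
        {"participant_id": pids, "age": age, "sex": sex, "bmi_z": bmi, "maternal_education": edu}
    )
    covariates = cov_complete.copy()
    covariates.loc[rng.random(n) < cfg.bmi_missing_rate, "bmi_z"] = np.nan
    covariates.loc[rng.random(n) < cfg.education_missing_rate, "maternal_education"] = np.nan

    # --------------------------------------------------------- outcomes
    names = list(cfg.profile_names)
    dest = [names[k] for k in prof2]
    scores = {}
    for out_name in OUTCOME_NAMES:
        eff = np.array([cfg.effects[d][out_name] for d in dest])
        ce = cfg.covariate_effects
        latent = (
            cfg.intercepts[out_name]
            + eff
            + ce["age"] * (age - cfg.age_mean)
            + ce["sex"] * sex
            + ce["bmi_z"] * bmi
            + ce["maternal_education"] * edu
            + rng.normal(0, cfg.noise_sd[out_name], n)
        )
        scores[out_name] = latent

    has_wb = rng.random(n) < cfg.wellbeing_rate
    has_hrqol = has_wb & (rng.random(n) < cfg.hrqol_given_wellbeing)
    items = _items_from_scores(scores, has_hrqol, has_wb, cfg, rng)
    items.insert(0, "participant_id", pids)

    truth = {
        "config": cfg,
        "participant_id": pids,
        "profile1": prof1,
        "profile2": prof2,
        "profile1_name": np.array(names, object)[prof1],
        "profile2_name": np.array(names, object)[prof2],
        "transition_category": np.array(
            [transition_label(names[a], names[b]) for a, b in zip(prof1, prof2)], object
        ),
        "person_ilr": person_ilr,
        "zero_school": zero1,
        "zero_weekend": zero2,
        "latent_scores": pd.DataFrame(scores),
        "covariates_complete": cov_complete,
        "has_hrqol": has_hrqol,
        "has_wellbeing": has_wb,
        "pi": pi,
        "transition": T,
        "mu_ilr": np.stack([mu_school, mu_weekend], axis=1),
        "basis": basis,
    }
    return SyntheticStudy(days=days, items=items, covariates=covariates, truth=truth)


def _items_from_scores(scores, has_hrqol, has_wb, cfg, rng) -> pd.DataFrame:
    """Discretise latent 0-100 scores into questionnaire item responses.

    PedsQL items: raw = round(4 - score/25 + noise) clipped to 0..4, using
    the physical score for the 8 physical items and the psychosocial score
    for the 15 others (the total then emerges from the 23 items). WHO-5:
    raw = round(score/20 + noise) clipped to 0..5.
    """
    from .questionnaires import PEDSQL_COLUMNS, WHO5_COLUMNS

    n = len(has_wb)
    out = pd.DataFrame(index=range(n))
    phys = scores["hrqol_physical"]
    psych = scores["hrqol_psychosocial"]
    for col in PEDSQL_COLUMNS:
        s = phys if col.startswith("pedsql_p") else psych
        raw = np.clip(np.round(4.0 - s / 25.0 + rng.normal(0, cfg.item_sd, n)), 0, 4)
        raw[~has_hrqol] = np.nan
        miss = rng.random(n) < cfg.pedsql_item_missing_rate
        raw[miss & has_hrqol] = np.nan
        out[col] = raw
    wb = scores["wellbeing"]
    for col in WHO5_COLUMNS:
        raw = np.clip(np.round(wb / 20.0 + rng.normal(0, cfg.item_sd, n)), 0, 5)
        raw[~has_wb] = np.nan
        out[col] = raw
    return out
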