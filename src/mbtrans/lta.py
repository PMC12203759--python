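"""Two-timepoint latent transition analysis with Gaussian emissions.

The model is a hidden-Markov-type mixture for paired observations
``(z_i1, z_i2)`` — here the ilr coordinates of a participant's schoolday and
weekend 24-h movement composition. Each participant occupies a latent
profile k at timepoint 1 with probability ``pi_k``, moves to profile l at
timepoint 2 with probability ``T_kl``, and emits

    z_1 | k ~ N(mu[k,1], Sigma[k,1]),   z_2 | l ~ N(mu[l,2], Sigma[l,2])

with the least-restricted covariance structure: full covariance matrices
free to differ across profiles and across timepoints. The marginal
likelihood of one participant is

    sum_{k,l} pi_k T_kl N(z_1; mu[k,1], Sigma[k,1]) N(z_2; mu[l,2], Sigma[l,2])

maximised by EM over joint responsibilities gamma_{i,kl}. Because any two
orthonormal ilr bases differ by a rotation and the Gaussian family is closed
under rotation, the fitted log-likelihood does not depend on the basis.

Usage follows the Model/Results convention::

    model = LatentTransitionModel(Z)          # Z: (n, 2, q) ilr array
    res = model.fit(n_profiles=4, n_starts=50, seed=7)
    res.summary()
    res.transition_table()
    sel = model.select_profiles(range(1, 6), seed=7)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .compositions import ContrastBasis, PART_NAMES, ilr, ilr_inverse, pivot_basis

PROFILE_NAMES_4 = ("Excellent", "Good", "Fair", "Poor")

__all__ = [
    "LatentTransitionModel",
    "LatentTransitionResults",
    "PosteriorAssignment",
    "lta_loglik",
    "n_free_parameters",
    "weeks_to_ilr",
    "prepare_weeks",
]


def weeks_to_ilr(weeks_df: pd.DataFrame, basis: ContrastBasis | None = None) -> np.ndarray:
    """Stack a participant-week table into an (n, 2, q) ilr array.

    Expects schoolday_/weekend_ prefixed minute columns in the fixed
    behaviour order (vpa, mpa, lpa, sb, sleep).
    """
    school = weeks_df[[f"schoolday_{p}_min" for p in PART_NAMES]].to_numpy(float)
    weekend = weeks_df[[f"weekend_{p}_min" for p in PART_NAMES]].to_numpy(float)
    return np.stack([ilr(school, basis), ilr(weekend, basis)], axis=1)


def prepare_weeks(weeks_df: pd.DataFrame, zeros: str = "drop") -> pd.DataFrame:
    """Resolve rounded zeros in a participant-week table before ilr.

    ``zeros='drop'`` (default) removes participants whose schoolday or
    weekend composition contains a zero part; ``zeros='impute'`` replaces
    zero VPA values by log-ratio-EM imputation across the pooled
    schoolday+weekend compositions instead.
    """
    from .compositions import lrem_impute_zeros

    school_cols = [f"schoolday_{p}_min" for p in PART_NAMES]
    weekend_cols = [f"weekend_{p}_min" for p in PART_NAMES]
    school = weeks_df[school_cols].to_numpy(float)
    weekend = weeks_df[weekend_cols].to_numpy(float)
    if zeros == "drop":
        keep = (school > 0).all(axis=1) & (weekend > 0).all(axis=1)
        return weeks_df.loc[keep].reset_index(drop=True)
    if zeros == "impute":
        pooled = np.vstack([school, weekend])
        if not (pooled == 0).any():
            return weeks_df.copy()
        imputed = lrem_impute_zeros(pooled)
        out = weeks_df.copy()
        out[school_cols] = imputed[: len(school)]
        out[weekend_cols] = imputed[len(school) :]
        return out
    raise ValueError("zeros must be 'drop' or 'impute'")


def n_free_parameters(K: int, q: int = 4) -> int:
    """Free parameters: (K-1) initial + K(K-1) transition + per-profile,
    per-timepoint mean (q) and full covariance (q(q+1)/2)."""
    return (K - 1) + K * (K - 1) + 2 * K * q + 2 * K * (q * (q + 1) // 2)


def _chol_logpdf(Z: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Multivariate normal log density of rows of Z (n, q)."""
    q = Z.shape[1]
    L = np.linalg.cholesky(Sigma)
    W = solve_triangular(L, (Z - mu).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (q * np.log(2.0 * np.pi) + logdet + np.einsum("ij,ij->j", W, W))


def _log_emissions(Z: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n, K) log emission densities at each timepoint."""
    n, _, q = Z.shape
    K = mu.shape[0]
    logB1 = np.empty((n, K))
    logB2 = np.empty((n, K))
    for k in range(K):
        logB1[:, k] = _chol_logpdf(Z[:, 0, :], mu[k, 0], Sigma[k, 0])
        logB2[:, k] = _chol_logpdf(Z[:, 1, :], mu[k, 1], Sigma[k, 1])
    return logB1, logB2


def _joint_log(pi, T, logB1, logB2):
    with np.errstate(divide="ignore"):
        lp = np.log(pi)[None, :, None] + np.log(T)[None, :, :]
    return lp + logB1[:, :, None] + logB2[:, None, :]


def lta_loglik(pi, T, mu, Sigma, Z) -> float:
    """Observed-data log-likelihood of the latent transition model.

    Computed stably in log space; raises on a singular emission covariance.
    """
    pi = np.asarray(pi, float)
    T = np.asarray(T, float)
    logB1, logB2 = _log_emissions(np.asarray(Z, float), np.asarray(mu, float), np.asarray(Sigma, float))
    lj = _joint_log(pi, T, logB1, logB2)
    return float(logsumexp(lj.reshape(len(Z), -1), axis=1).sum())


def _floor_cov(S: np.ndarray, rel_floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at ``rel_floor`` of the mean variance (SPD guard)."""
    S = 0.5 * (S + S.T)
    floor = rel_floor * max(np.mean(np.diag(S)), 1e-300)
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


@dataclass
class PosteriorAssignment:
    """Per-participant posterior profile membership.

    ``joint[i]`` is the K x K matrix P(profile1 = k, profile2 = l | data_i);
    marginals are its row/column sums and modal labels their argmax.
    """

    joint: np.ndarray  # (n, K, K)
    marginal1: np.ndarray  # (n, K)
    marginal2: np.ndarray  # (n, K)
    modal1: np.ndarray  # (n,) int
    modal2: np.ndarray  # (n,) int
    profile_names: tuple[str, ...]

    @property
    def modal1_names(self) -> np.ndarray:
        return np.asarray(self.profile_names, object)[self.modal1]

    @property
    def modal2_names(self) -> np.ndarray:
        return np.asarray(self.profile_names, object)[self.modal2]


class LatentTransitionModel:
    """Two-timepoint latent transition model on (n, 2, q) coordinate data.

    Parameters
    ----------
    Z : array (n, 2, q)
        Per-participant coordinates at the two timepoints (schoolday,
        weekend). Typically ilr coordinates of 5-part compositions (q = 4).
    """

    def __init__(self, Z: np.ndarray):
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 3 or Z.shape[1] != 2:
            raise ValueError("Z must have shape (n, 2, q)")
        if not np.all(np.isfinite(Z)):
            raise ValueError("Z must be finite")
        self.Z = Z
        self.nobs, _, self.n_coords = Z.shape

    @classmethod
    def from_weeks(cls, weeks_df: pd.DataFrame, basis: ContrastBasis | None = None) -> "LatentTransitionModel":
        """Build the model from a participant-week minutes table."""
        return cls(weeks_to_ilr(weeks_df, basis))

    # ------------------------------------------------------------------ EM

    def _init_params(self, K: int, rng: np.random.Generator, jitter: float, flavour: str = "kmeans"):
        """Per-timepoint clustering initialisation.

        Emission means and covariances are free to differ across timepoints,
        so each timepoint is clustered separately (k-means, or a marginal
        Gaussian mixture which is better at isolating small components); the
        transition matrix starts at the (smoothed) cross-tabulation of the
        two cluster assignments, which couples the otherwise independent
        timepoint labellings.
        """
        from sklearn.mixture import GaussianMixture

        n, q = self.nobs, self.n_coords
        mu = np.empty((K, 2, q))
        Sigma = np.empty((K, 2, q, q))
        labels = []
        for t in range(2):
            Zt = self.Z[:, t, :]
            rs = int(rng.integers(2**31 - 1))
            ridge = 1e-6 * np.trace(np.cov(Zt.T)) / q * np.eye(q)
            if flavour == "gmm":
                gm = GaussianMixture(
                    K, covariance_type="full", n_init=5, random_state=rs, reg_covar=1e-6
                ).fit(Zt)
                mu[:, t] = gm.means_
                for k in range(K):
                    Sigma[k, t] = _floor_cov(gm.covariances_[k] + ridge)
                labels.append(gm.predict(Zt))
            else:
                km = KMeans(K, n_init=1, random_state=rs).fit(Zt)
                centers = km.cluster_centers_
                if jitter > 0:
                    centers = centers + rng.normal(0.0, jitter * Zt.std(axis=0), centers.shape)
                for k in range(K):
                    pts = Zt[km.labels_ == k]
                    S = np.cov(pts.T) if len(pts) > q else np.cov(Zt.T)
                    mu[k, t] = centers[k]
                    Sigma[k, t] = _floor_cov(S + ridge)
                labels.append(km.labels_)
        pi = np.bincount(labels[0], minlength=K).astype(float) + 0.5
        pi /= pi.sum()
        cross = np.full((K, K), 0.5)
        np.add.at(cross, (labels[0], labels[1]), 1.0)
        T = cross / cross.sum(axis=1, keepdims=True)
        return pi, T, mu, Sigma

    def _em_once(self, K, pi, T, mu, Sigma, tol, max_iter):
        Z = self.Z
        n = self.nobs
        q = self.n_coords
        ll_prev = -np.inf
        ll_path = []
        for it in range(max_iter):
            logB1, logB2 = _log_emissions(Z, mu, Sigma)
            lj = _joint_log(pi, T, logB1, logB2)
            lse = logsumexp(lj.reshape(n, -1), axis=1)
            ll = float(lse.sum())
            ll_path.append(ll)
            gamma = np.exp(lj - lse[:, None, None])  # (n, K, K)

            r1 = gamma.sum(axis=2)  # (n, K) timepoint-1 responsibilities
            r2 = gamma.sum(axis=1)  # (n, K)
            w1 = r1.sum(axis=0)
            w2 = r2.sum(axis=0)
            if np.min(w1) < 1e-8 * n or np.min(w2) < 1e-8 * n:
                return None  # empty component; caller restarts

            pi = w1 / n
            gsum = gamma.sum(axis=0)  # (K, K)
            T = gsum / gsum.sum(axis=1, keepdims=True)
            for k in range(K):
                for t, (r, w) in enumerate(((r1, w1), (r2, w2))):
                    zk = Z[:, t, :]
                    m = (r[:, k] @ zk) / w[k]
                    dev = zk - m
                    S = (dev.T * r[:, k]) @ dev / w[k]
                    mu[k, t] = m
                    Sigma[k, t] = _floor_cov(S)

            if np.isfinite(ll_prev) and ll - ll_prev <= tol * abs(ll_prev):
                break
            ll_prev = ll
        ll = lta_loglik(pi, T, mu, Sigma, Z)
        ll_path.append(ll)
        return pi, T, mu, Sigma, ll, np.array(ll_path), it + 1

    def fit(
        self,
        n_profiles: int,
        n_starts: int = 50,
        seed: int | None = None,
        tol: float = 1e-8,
        max_iter: int = 1000,
        short_iter: int = 60,
        n_final: int = 5,
        profile_names: tuple[str, ...] | None = None,
        sort_profiles: bool = True,
        basis: ContrastBasis | None = None,
    ) -> "LatentTransitionResults":
        """Fit by EM from ``n_starts`` clustering-based initialisations.

        Starts alternate between k-means and marginal-Gaussian-mixture
        initialisations. Each start first runs up to ``short_iter`` EM
        iterations; the ``n_final`` most promising are then iterated to
        convergence (relative log-likelihood change below ``tol``) and the
        best retained, so the log-likelihood is non-decreasing within every
        start. Profiles are ordered by descending moderate-to-vigorous PA of
        the back-transformed emission means at each timepoint, so that for
        K = 4 the first profile is the most active ("Excellent") and the
        last the least ("Poor"). ``seed`` controls all randomness.
        """
        K = int(n_profiles)
        if K < 1:
            raise ValueError("n_profiles must be >= 1")
        if self.nobs < 5 * K:
            raise ValueError("need at least 5 observations per profile")
        rng = np.random.default_rng(seed)
        n_starts_eff = 1 if K == 1 else n_starts  # K=1 MLE has no local optima
        stage1 = []
        for s in range(n_starts_eff):
            flavour = "gmm" if s % 2 else "kmeans"
            jitter = 0.0 if s < 2 else 0.25
            out = None
            for _attempt in range(4):
                init = self._init_params(K, rng, jitter, flavour)
                out = self._em_once(K, *init, tol=tol, max_iter=short_iter)
                if out is not None:
                    break
                jitter = max(jitter, 0.25)
            if out is not None:
                stage1.append(out)
        if not stage1:
            raise RuntimeError("all EM starts degenerate")
        stage1.sort(key=lambda o: -o[4])
        best = None
        for cand in stage1[: max(n_final, 1)]:
            pi0, T0, mu0, Sigma0 = cand[0], cand[1], cand[2], cand[3]
            out = self._em_once(
                K, pi0.copy(), T0.copy(), mu0.copy(), Sigma0.copy(), tol=tol, max_iter=max_iter
            )
            if out is None:
                out = cand
            if best is None or out[4] > best[4]:
                best = out
        pi, T, mu, Sigma, ll, ll_path, n_iter = best
        res = LatentTransitionResults(
            model=self,
            pi=pi,
            transition=T,
            mu=mu,
            Sigma=Sigma,
            loglik=ll,
            loglik_path=ll_path,
            n_iter=n_iter,
            basis=basis if basis is not None else (pivot_basis() if self.n_coords == 4 else None),
            profile_names=profile_names,
        )
        if sort_profiles and self.n_coords == 4:
            res = res.sorted_by_activity()
        return res

    def select_profiles(
        self,
        k_range=range(1, 6),
        n_starts: int = 50,
        seed: int | None = None,
        **fit_kw,
    ) -> pd.DataFrame:
        """Model-selection table over a range of profile counts.

        Returns one row per K with loglik, n_params, BIC, AIC, relative
        entropy and minimal modal profile size (%, averaged over the two
        timepoints). BIC is the default selector; profile size and entropy
        are reported so implausibly small or poorly separated solutions can
        be rejected on substantive grounds.
        """
        rows = []
        for K in k_range:
            res = self.fit(K, n_starts=n_starts, seed=seed, **fit_kw)
            rows.append(
                {
                    "n_profiles": K,
                    "loglik": res.loglik,
                    "n_params": res.n_params,
                    "bic": res.bic,
                    "aic": res.aic,
                    "entropy": res.entropy,
                    "min_profile_size_pct": res.min_profile_size_pct,
                }
            )
        return pd.DataFrame(rows)


class LatentTransitionResults:
    """Fitted latent transition model: estimates, criteria and tables."""

    def __init__(
        self,
        model: LatentTransitionModel,
        pi: np.ndarray,
        transition: np.ndarray,
        mu: np.ndarray,
        Sigma: np.ndarray,
        loglik: float,
        loglik_path: np.ndarray | None = None,
        n_iter: int | None = None,
        basis: ContrastBasis | None = None,
        profile_names: tuple[str, ...] | None = None,
    ):
        self.model = model
        self.pi = np.asarray(pi, float)
        self.transition = np.asarray(transition, float)
        self.mu = np.asarray(mu, float)
        self.Sigma = np.asarray(Sigma, float)
        self.loglik = float(loglik)
        self.loglik_path = loglik_path
        self.n_iter = n_iter
        self.basis = basis
        self.n_profiles = len(self.pi)
        if profile_names is None:
            if self.n_profiles == 4:
                profile_names = PROFILE_NAMES_4
            else:
                profile_names = tuple(f"P{i+1}" for i in range(self.n_profiles))
        self.profile_names = tuple(profile_names)
        self._posteriors: PosteriorAssignment | None = None

    # ----------------------------------------------------------- criteria

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_params(self) -> int:
        return n_free_parameters(self.n_profiles, self.model.n_coords)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.nobs)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def entropy(self) -> float:
        """Relative entropy of classification, averaged over timepoints.

        1 - (average posterior Shannon entropy) / ln K per timepoint-marginal
        posterior; 1 means perfectly separated profiles, 0 uninformative.
        By convention 1.0 for a single profile.
        """
        K = self.n_profiles
        if K == 1:
            return 1.0
        post = self.posteriors()
        vals = []
        for p in (post.marginal1, post.marginal2):
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(p > 0, p * np.log(p), 0.0)
            ent = -plogp.sum(axis=1).mean()
            vals.append(1.0 - ent / np.log(K))
        return float(np.mean(vals))

    @property
    def min_profile_size_pct(self) -> float:
        """Smallest modal profile share (%), averaged over the timepoints."""
        post = self.posteriors()
        n = self.nobs
        sizes = []
        for modal in (post.modal1, post.modal2):
            counts = np.bincount(modal, minlength=self.n_profiles)
            sizes.append(counts / n * 100.0)
        return float(np.mean(np.stack(sizes), axis=0).min())

    # --------------------------------------------------------- posteriors

    def posteriors(self) -> PosteriorAssignment:
        """Joint and marginal posterior profile probabilities per participant."""
        if self._posteriors is None:
            logB1, logB2 = _log_emissions(self.model.Z, self.mu, self.Sigma)
            lj = _joint_log(self.pi, self.transition, logB1, logB2)
            lse = logsumexp(lj.reshape(self.nobs, -1), axis=1)
            joint = np.exp(lj - lse[:, None, None])
            m1 = joint.sum(axis=2)
            m2 = joint.sum(axis=1)
            self._posteriors = PosteriorAssignment(
                joint=joint,
                marginal1=m1,
                marginal2=m2,
                modal1=m1.argmax(axis=1),
                modal2=m2.argmax(axis=1),
                profile_names=self.profile_names,
            )
        return self._posteriors

    # ------------------------------------------------------------- tables

    def sorted_by_activity(self) -> "LatentTransitionResults":
        """Reorder profiles by descending MVPA of the emission means.

        Because emissions are free to differ across timepoints, the
        timepoint-2 labels are identified only up to a permutation of the
        transition matrix's columns; the substantive labelling therefore
        sorts each timepoint's states by that timepoint's
        moderate-to-vigorous PA (minutes of the back-transformed emission
        mean), so "Excellent" means the most active profile on both
        schooldays and weekends. Pure relabelling: the likelihood and all
        selection criteria are invariant.
        """
        if self.basis is None:
            raise ValueError("needs a contrast basis to back-transform means")
        orders = []
        for t in range(2):
            comps = ilr_inverse(self.mu[:, t, :], self.basis)
            mvpa = comps[:, 0] + comps[:, 1]  # VPA + MPA minutes
            orders.append(np.argsort(-mvpa))
        return self.permuted(orders[0], orders[1])

    def permuted(self, order1: np.ndarray, order2: np.ndarray | None = None) -> "LatentTransitionResults":
        """Relabel profiles; ``order2`` permutes the timepoint-2 states.

        Permuting timepoint-1 states reorders pi, the transition rows and
        the timepoint-1 emissions; permuting timepoint-2 states reorders the
        transition columns and timepoint-2 emissions. Both leave the
        likelihood unchanged.
        """
        order1 = np.asarray(order1, int)
        order2 = order1 if order2 is None else np.asarray(order2, int)
        mu = self.mu.copy()
        Sigma = self.Sigma.copy()
        mu[:, 0], mu[:, 1] = self.mu[order1, 0], self.mu[order2, 1]
        Sigma[:, 0], Sigma[:, 1] = self.Sigma[order1, 0], self.Sigma[order2, 1]
        return LatentTransitionResults(
            model=self.model,
            pi=self.pi[order1],
            transition=self.transition[np.ix_(order1, order2)],
            mu=mu,
            Sigma=Sigma,
            loglik=self.loglik,
            loglik_path=self.loglik_path,
            n_iter=self.n_iter,
            basis=self.basis,
            profile_names=None,
        )

    def profile_mean_compositions(self, timepoint: int) -> pd.DataFrame:
        """Emission means back-transformed to minutes/day (per profile)."""
        if self.basis is None:
            raise ValueError("needs a contrast basis")
        comps = ilr_inverse(self.mu[:, timepoint, :], self.basis)
        return pd.DataFrame(comps, index=list(self.profile_names), columns=list(PART_NAMES))

    def transition_table(self, kind: str = "model") -> pd.DataFrame:
        """Transition probabilities (%) plus marginal profile proportions.

        ``kind='model'`` reports the estimated transition matrix and the
        model-implied marginals (schoolday = pi, weekend = pi @ T);
        ``kind='empirical'`` cross-tabulates modal assignments.
        """
        names = list(self.profile_names)
        if kind == "model":
            T = self.transition * 100.0
            school = self.pi * 100.0
            weekend = self.pi @ self.transition * 100.0
        elif kind == "empirical":
            post = self.posteriors()
            K = self.n_profiles
            counts = np.zeros((K, K))
            for a, b in zip(post.modal1, post.modal2):
                counts[a, b] += 1
            row_tot = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                T = np.where(row_tot > 0, counts / row_tot, np.nan) * 100.0
            school = counts.sum(axis=1) / self.nobs * 100.0
            weekend = counts.sum(axis=0) / self.nobs * 100.0
        else:
            raise ValueError("kind must be 'model' or 'empirical'")
        df = pd.DataFrame(T, index=[f"From {n}" for n in names], columns=[f"To {n}" for n in names])
        df.insert(0, "schoolday_pct", school)
        df.attrs["weekend_pct"] = dict(zip(names, weekend))
        return df

    def marginal_proportions(self, kind: str = "model") -> pd.DataFrame:
        """Schoolday and weekend profile proportions (%)."""
        if kind == "model":
            school = self.pi * 100.0
            weekend = self.pi @ self.transition * 100.0
        else:
            post = self.posteriors()
            school = np.bincount(post.modal1, minlength=self.n_profiles) / self.nobs * 100.0
            weekend = np.bincount(post.modal2, minlength=self.n_profiles) / self.nobs * 100.0
        return pd.DataFrame(
            {"schoolday_pct": school, "weekend_pct": weekend}, index=list(self.profile_names)
        )

    def weighted_profile_descriptives(
        self, data: pd.DataFrame, timepoint: int, composition_columns: list[str] | None = None
    ) -> pd.DataFrame:
        """Posterior-weighted per-profile descriptives of participant columns.

        Continuous columns get weighted means and SDs, boolean/binary columns
        weighted proportions (%), and ``composition_columns`` (5 minute
        columns in behaviour order) a posterior-weighted compositional mean.
        Weights are the timepoint-marginal posterior membership
        probabilities; a profile with zero total weight yields NaNs.
        """
        from .compositions import compositional_mean

        post = self.posteriors()
        W = post.marginal1 if timepoint == 0 else post.marginal2
        if len(data) != self.nobs:
            raise ValueError("data must have one row per participant")
        rows = {}
        for k, name in enumerate(self.profile_names):
            w = W[:, k]
            tot = w.sum()
            row: dict[str, float] = {"weight_sum": tot, "size_pct": tot / self.nobs * 100.0}
            for col in data.columns:
                x = data[col]
                if composition_columns and col in composition_columns:
                    continue
                vals = x.to_numpy(dtype=float)
                ok = np.isfinite(vals)
                wv, vv = w[ok], vals[ok]
                if tot <= 0 or wv.sum() <= 0:
                    row[f"{col}_mean"] = np.nan
                    continue
                m = np.average(vv, weights=wv)
                uniq = np.unique(vv)
                if set(uniq).issubset({0.0, 1.0}):
                    row[f"{col}_pct"] = m * 100.0
                else:
                    var = np.average((vv - m) ** 2, weights=wv)
                    row[f"{col}_mean"] = m
                    row[f"{col}_sd"] = np.sqrt(var)
            if composition_columns:
                comp = data[composition_columns].to_numpy(dtype=float)
                if tot > 0:
                    cm = compositional_mean(comp, weights=w)
                    for cname, val in zip(composition_columns, cm):
                        row[f"{cname}_compmean"] = val
                else:
                    for cname in composition_columns:
                        row[f"{cname}_compmean"] = np.nan
            rows[name] = row
        return pd.DataFrame(rows).T

    # ------------------------------------------------------------ summary

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        lines = []
        lines.append("Latent transition model (2 timepoints, Gaussian emissions)")
        lines.append(f"n = {self.nobs}, profiles = {self.n_profiles}, coords = {self.model.n_coords}")
        lines.append(
            f"loglik = {self.loglik:.2f}, params = {self.n_params}, "
            f"BIC = {self.bic:.1f}, AIC = {self.aic:.1f}, entropy = {self.entropy:.3f}"
        )
        props = self.marginal_proportions()
        lines.append("\nProfile proportions (%):")
        lines.append(props.round(1).to_string())
        lines.append("\nTransition probabilities (%, rows = schoolday profile):")
        lines.append(pd.DataFrame(
            self.transition * 100.0,
            index=[f"From {n}" for n in self.profile_names],
            columns=[f"To {n}" for n in self.profile_names],
        ).round(1).to_string())
        if self.basis is not None and self.model.n_coords == 4:
            lines.append("\nProfile mean compositions, schooldays (min/day):")
            lines.append(self.profile_mean_compositions(0).round(1).to_string())
            lines.append("\nProfile mean compositions, weekends (min/day):")
            lines.append(self.profile_mean_compositions(1).round(1).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable parameter dump."""
        return {
            "n_profiles": self.n_profiles,
            "profile_names": list(self.profile_names),
            "pi": self.pi.tolist(),
            "transition": self.transition.tolist(),
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "aic": self.aic,
            "entropy": self.entropy,
        }
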