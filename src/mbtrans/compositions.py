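"""Compositional machinery for 5-part 24-h time-use vectors.

A day is treated as a composition of five mutually exclusive behaviours
(vigorous PA, moderate PA, light PA, sedentary behaviour, sleep) summing to
1440 min. All statistics act on isometric log-ratio (ilr) coordinates, the
orthonormal log-ratio coordinate system in which a D-part composition becomes
an unconstrained real (D-1)-vector; Euclidean geometry there is the Aitchison
geometry of the simplex.

The default contrast basis is the pivot (sequential binary partition) basis
that peels parts off in the fixed order VPA, MPA, LPA, SB, sleep:

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gm(x_{j+1}, ..., x_D) )

Because the model likelihood is invariant to the choice of orthonormal basis,
any other basis gives the same fit; the pivot basis is simply a reproducible
default, recorded as ``basis_id="pivot-vpa-first"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

PART_NAMES = ("vpa", "mpa", "lpa", "sb", "sleep")
N_PARTS = 5
DAY_MINUTES = 1440.0

__all__ = [
    "PART_NAMES",
    "DAY_MINUTES",
    "ContrastBasis",
    "pivot_basis",
    "close",
    "clr",
    "ilr",
    "ilr_inverse",
    "compositional_mean",
    "lrem_impute_zeros",
]


@dataclass(frozen=True)
class ContrastBasis:
    """Orthonormal contrast matrix defining an ilr coordinate system.

    ``matrix`` is D x (D-1); its columns are orthonormal and each sums to
    zero, so they span the clr subspace.
    """

    matrix: np.ndarray
    basis_id: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != m.shape[0] - 1:
            raise ValueError("basis must be D x (D-1)")
        if not np.allclose(m.sum(axis=0), 0.0, atol=1e-10):
            raise ValueError("basis columns must sum to zero")
        if not np.allclose(m.T @ m, np.eye(m.shape[1]), atol=1e-10):
            raise ValueError("basis columns must be orthonormal")
        object.__setattr__(self, "matrix", m)

    @property
    def n_parts(self) -> int:
        return self.matrix.shape[0]


def pivot_basis(n_parts: int = N_PARTS) -> ContrastBasis:
    """Pivot (sequential binary partition) basis peeling parts in order.

    Column j contrasts part j against the geometric mean of parts j+1..D.
    """
    D = n_parts
    V = np.zeros((D, D - 1))
    for j in range(D - 1):
        r = D - j - 1  # number of parts in the denominator
        V[j, j] = np.sqrt(r / (r + 1))
        V[j + 1 :, j] = -np.sqrt(r / (r + 1)) / r
    return ContrastBasis(V, basis_id="pivot-vpa-first" if D == N_PARTS else f"pivot-{D}")


def close(parts: np.ndarray, total: float = DAY_MINUTES) -> np.ndarray:
    """Rescale nonnegative parts to sum to ``total`` (closure).

    Accepts a single composition or an (n, D) array; raises on negative parts
    or an all-zero vector.
    """
    x = np.asarray(parts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative part in composition")
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("degenerate composition: all parts zero")
    return x * (total / s)


def clr(x: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform; requires strictly positive parts."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("zero part; impute or drop before log-ratio transforms")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def ilr(x: np.ndarray, basis: ContrastBasis | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates ``basis.T @ clr(x)``.

    Scale-invariant: closing ``x`` first does not change the coordinates.
    """
    if basis is None:
        basis = pivot_basis()
    return clr(x) @ basis.matrix


def ilr_inverse(
    z: np.ndarray, basis: ContrastBasis | None = None, total: float = DAY_MINUTES
) -> np.ndarray:
    """Map ilr coordinates back to a composition summing to ``total``."""
    if basis is None:
        basis = pivot_basis()
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite ilr coordinates")
    return close(np.exp(z @ basis.matrix.T), total)


def compositional_mean(
    xs: np.ndarray, weights: np.ndarray | None = None, total: float = DAY_MINUTES
) -> np.ndarray:
    """Closed (weighted) geometric mean per part over an (n, D) array.

    Equals the ilr-inverse of the weighted arithmetic mean of the ilr
    coordinates, for any orthonormal basis.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.ndim == 1:
        xs = xs[None, :]
    if np.any(xs <= 0):
        raise ValueError("zero part; impute or drop before averaging")
    if weights is None:
        weights = np.ones(xs.shape[0])
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    logmean = (w[:, None] * np.log(xs)).sum(axis=0) / w.sum()
    return close(np.exp(logmean), total)


def _censoring_thresholds(
    X: np.ndarray, zero_mask: np.ndarray, detection_limit: float, basis: ContrastBasis
) -> np.ndarray:
    """First-pivot-coordinate upper bounds implied by VPA < detection limit."""
    D = X.shape[1]
    r = D - 1
    gm_rest = np.exp(np.mean(np.log(X[zero_mask, 1:]), axis=1))
    return np.sqrt(r / (r + 1)) * np.log(detection_limit / gm_rest)


def lrem_impute_zeros(
    xs: np.ndarray,
    detection_limit: float = 0.5,
    total: float = DAY_MINUTES,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Replace rounded zeros in the first part (VPA) by log-ratio EM.

    Rounded zeros are understood as values censored below ``detection_limit``
    (min/day). In the pivot basis the first ilr coordinate isolates VPA
    against the remaining parts, while the other coordinates do not involve
    VPA at all; a zero VPA therefore leaves coordinates 2..D-1 observed and
    left-censors coordinate 1 at the threshold implied by the limit. The EM
    algorithm fits a multivariate normal in ilr space, replacing the censored
    coordinate in the E-step by its conditional truncated-normal mean, and on
    convergence imputes that conditional mean. Imputed VPA values land in
    (0, detection_limit); the remaining parts are rescaled so each
    composition's total is preserved.

    Only zeros in the first part are supported; a part that is zero in every
    observation is unidentifiable and raises.
    """
    X = np.asarray(xs, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_PARTS:
        raise ValueError(f"expected (n, {N_PARTS}) array")
    if detection_limit <= 0:
        raise ValueError("detection limit must be positive")
    if np.any(X < 0):
        raise ValueError("negative part in composition")
    zero_any = X == 0
    if np.any(zero_any.all(axis=0)):
        raise ValueError("part unidentifiable: zero in all observations")
    if not zero_any.any():
        return X.copy()
    if np.any(zero_any[:, 1:]):
        raise ValueError("only zeros in the first part (VPA) are supported")
    if np.any(zero_any.sum(axis=1) > 1):
        raise ValueError("at most one zero part per observation is supported")

    basis = pivot_basis()
    cens = zero_any[:, 0]
    obs = ~cens

    # ilr coords; censored rows get a placeholder VPA at the detection limit
    # (only their first coordinate is treated as missing below).
    Xw = X.copy()
    Xw[cens, 0] = detection_limit
    Z = ilr(Xw, basis)
    c = _censoring_thresholds(Xw, cens, detection_limit, basis)

    n, q = Z.shape
    mu = Z[obs].mean(axis=0) if obs.any() else Z.mean(axis=0)
    Sigma = np.cov(Z[obs].T) if obs.sum() > q else np.cov(Z.T)
    Sigma = Sigma + 1e-8 * np.trace(Sigma) / q * np.eye(q)

    prev_ll = -np.inf
    Zc = Z.copy()
    for _ in range(max_iter):
        # conditional distribution of z1 | z2..zq for censored rows
        s11 = Sigma[0, 0]
        s12 = Sigma[0, 1:]
        S22 = Sigma[1:, 1:]
        beta = np.linalg.solve(S22, s12)
        cond_var = max(s11 - s12 @ beta, 1e-12)
        cond_sd = np.sqrt(cond_var)
        cond_mean = mu[0] + (Z[cens, 1:] - mu[1:]) @ beta

        a = (c - cond_mean) / cond_sd  # upper truncation points (standardised)
        logcdf = norm.logcdf(a)
        lam = np.exp(norm.logpdf(a) - logcdf)  # inverse Mills ratio
        ez = cond_mean - cond_sd * lam  # E[z1 | z1 < c, rest]
        # E[z1^2 | ...] for the censored second moment
        vz = cond_var * (1.0 - a * lam - lam**2)

        Zc[cens, 0] = ez

        # observed-data log-likelihood: full density for complete rows,
        # marginal-of-rest x censored-prob for zero rows
        ll = _mvn_loglik(Z[obs], mu, Sigma).sum() if obs.any() else 0.0
        if cens.any():
            ll += _mvn_loglik(Z[cens, 1:], mu[1:], S22).sum()
            ll += logcdf.sum()

        # M-step: mean/cov with conditional moments for the censored entry
        mu_new = Zc.mean(axis=0)
        Dev = Zc - mu_new
        S = Dev.T @ Dev
        # correction: replace (z1 - mu1)^2 for censored rows by its expectation
        extra = vz.sum() if cens.any() else 0.0
        S[0, 0] += extra
        Sigma_new = S / n
        Sigma_new = Sigma_new + 1e-10 * np.trace(Sigma_new) / q * np.eye(q)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            mu, Sigma = mu_new, Sigma_new
            break
        prev_ll = ll
        mu, Sigma = mu_new, Sigma_new

    # impute: conditional mean in the first coordinate, clipped under the limit
    z1 = np.minimum(Zc[cens, 0], c - 1e-9)
    out = X.copy()
    D = N_PARTS
    r = D - 1
    gm_rest = np.exp(np.mean(np.log(X[cens, 1:]), axis=1))
    vpa = gm_rest * np.exp(z1 / np.sqrt(r / (r + 1)))
    vpa = np.clip(vpa, np.finfo(float).tiny, detection_limit * (1 - 1e-9))
    # preserve each row's original total by shrinking the nonzero parts
    totals = X[cens].sum(axis=1)
    out[cens, 1:] *= ((totals - vpa) / totals)[:, None]
    out[cens, 0] = vpa
    return out


def _mvn_loglik(Z: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Row-wise multivariate normal log density."""
    from scipy.linalg import solve_triangular

    Z = np.atleast_2d(Z)
    q = Z.shape[1]
    L = np.linalg.cholesky(Sigma)
    W = solve_triangular(L, (Z - mu).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (q * np.log(2 * np.pi) + logdet + np.sum(W**2, axis=0))
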