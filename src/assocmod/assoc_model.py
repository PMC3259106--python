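"""The conditional log-linear model of passenger expression given drivers.

A passenger expression state y is encoded on the ordered levels {-1, 0, +1}
and modeled as

    P(y | x) = exp(sum_i lambda_i f_i(x_i) y) / Z(x),   lambda_i >= 0,

with scalar feature functions f_i(x_i) = s_i x_i whose sign s_i encodes
whether the aberration activates (+) or represses (-) the passenger, and
Z(x) the three-state partition function.  Soft trinary passenger states
enter through an expected log-likelihood over their probability triples;
soft drivers enter through the scalar expectation p_high - p_low.  The
nonnegativity constraint makes activating and repressive features
non-interchangeable and keeps nested model comparisons one-sided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

LAMBDA_CAP = 20.0
FIT_TOL = 1e-8
MIN_SAMPLES = 8

LN3 = float(np.log(3.0))


def driver_expectation(feature: np.ndarray) -> np.ndarray:
    """Scalar driver value per sample.

    Trinary rows (n, 3) map to ``p_high - p_low`` in [-1, 1]; binary
    mutation vectors pass through as {0, 1} with NaN for missing.
    """
    f = np.asarray(feature, dtype=float)
    if f.ndim == 2 and f.shape[-1] == 3:
        return f[..., 2] - f[..., 0]
    if f.ndim == 1:
        ok = np.isfinite(f)
        if not np.isin(f[ok], (0.0, 1.0)).all():
            raise ValueError("1-D driver must be a binary mutation vector")
        return f
    raise ValueError("expected an (n, 3) trinary row or binary vector")


def _log_z(eta: np.ndarray) -> np.ndarray:
    """log(e^eta + 1 + e^-eta), overflow-safe."""
    a = np.abs(eta)
    return a + np.log1p(np.exp(-a) + np.exp(-2.0 * a))


def _moments(eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """E[y | eta] and Var[y | eta] under the three-state model."""
    a = np.abs(eta)
    e1, e2 = np.exp(-a), np.exp(-2.0 * a)
    z = 1.0 + e1 + e2
    mu = np.sign(eta) * (1.0 - e2) / z
    ey2 = (1.0 + e2) / z
    return mu, ey2 - mu * mu


@dataclass
class AssociationModel:
    """A fitted driver set for one passenger."""

    passenger_id: str
    driver_ids: tuple[str, ...]
    signs: tuple[int, ...]
    lambdas: np.ndarray
    loglik: float
    n_samples: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if (self.lambdas < -1e-12).any():
            raise ValueError("weights must be nonnegative")
        if len(self.driver_ids) != len(self.signs) or len(self.signs) != self.lambdas.size:
            raise ValueError("drivers, signs and weights must align")

    def to_json(self) -> str:
        return json.dumps({
            "passenger": self.passenger_id,
            "drivers": list(self.driver_ids),
            "signs": list(self.signs),
            "lambda": [float(v) for v in self.lambdas],
            "loglik": float(self.loglik),
            "n_samples": int(self.n_samples),
            "degenerate": self.degenerate,
        })


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio comparison of nested driver sets."""

    llr: float
    df: int
    p_value: float


def _usable(X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return np.isfinite(X).all(axis=0) & np.isfinite(Q).all(axis=-1)


def loglik(lambdas: Sequence[float], signs: Sequence[int],
           X: np.ndarray, Q: np.ndarray) -> float:
    """Expected log-likelihood of passenger triples ``Q`` given drivers ``X``.

    ``X`` is (k, n) driver values, ``Q`` is (n, 3) passenger probability
    triples; samples with any missing entry are dropped.
    """
    lam = np.asarray(lambdas, dtype=float)
    s = np.asarray(signs, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Q = np.asarray(Q, dtype=float)
    ok = _usable(X, Q)
    if not ok.any():
        raise ValueError("zero usable samples")
    eta = (lam * s) @ X[:, ok]
    ybar = Q[ok, 2] - Q[ok, 0]
    return float(np.sum(eta * ybar - _log_z(eta)))


def fit(passenger_id: str, driver_ids: Sequence[str], signs: Sequence[int],
        X: np.ndarray, Q: np.ndarray, lam_cap: float = LAMBDA_CAP,
        tol: float = FIT_TOL, min_samples: int = MIN_SAMPLES) -> AssociationModel:
    """Maximize the expected log-likelihood over the box [0, lam_cap]^k.

    Deterministic bounded L-BFGS-B from lambda = 0 with the analytic
    gradient; the objective is concave, so the box optimum is global.
    Constant drivers are unidentifiable and are pinned at 0 (flagged).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Q = np.asarray(Q, dtype=float)
    s = np.asarray(signs, dtype=float)
    ok = _usable(X, Q)
    n = int(ok.sum())
    if n < min_samples:
        raise ValueError(f"only {n} usable samples (< {min_samples})")
    Xs, ybar = X[:, ok], Q[ok, 2] - Q[ok, 0]
    F = s[:, None] * Xs

    const = np.nanstd(Xs, axis=1) < 1e-12
    degenerate = bool(const.any())

    def neg(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta = lam @ F
        mu, _ = _moments(eta)
        ll = np.sum(eta * ybar - _log_z(eta))
        grad = F @ (ybar - mu)
        return -ll, -grad

    if not np.isfinite(F).all():
        raise ValueError("non-finite likelihood inputs")
    k = F.shape[0]
    bounds = [(0.0, 0.0) if const[i] else (0.0, lam_cap) for i in range(k)]
    res = minimize(neg, np.zeros(k), jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"ftol": tol, "gtol": 1e-10,
                                           "maxiter": 500})
    lam = np.clip(res.x, 0.0, lam_cap)
    ll = -neg(lam)[0]
    ll0 = -n * LN3
    if ll < ll0:                       # optimizer never below the null
        lam, ll = np.zeros(k), ll0
    return AssociationModel(passenger_id, tuple(driver_ids),
                            tuple(int(v) for v in signs), lam, float(ll), n,
                            degenerate=degenerate)


def lrt(null: AssociationModel, alt: AssociationModel,
        mixture: bool = False) -> LrtResult:
    """Likelihood-ratio test of a nested driver pair fitted on one sample set.

    The statistic 2(ll_alt - ll_null) is clipped at 0 and referred to a
    chi-square with df = number of added weights; with ``mixture=True`` the
    50:50 point-mass/chi-square reference for boundary-constrained weights
    is used instead (less conservative).
    """
    null_set = set(zip(null.driver_ids, null.signs))
    alt_set = set(zip(alt.driver_ids, alt.signs))
    if not null_set <= alt_set:
        raise ValueError("models are not nested")
    if null.n_samples != alt.n_samples:
        raise ValueError("models fitted on different sample sets")
    df = len(alt.driver_ids) - len(null.driver_ids)
    llr = max(0.0, 2.0 * (alt.loglik - null.loglik))
    if df == 0:
        return LrtResult(llr, 0, 1.0)
    p = float(chi2.sf(llr, df))
    if mixture:
        p = 0.5 * p + 0.5 * float(chi2.sf(llr, max(df - 1, 1e-9))) if df > 1 \
            else (0.5 * p if llr > 0 else 1.0)
    return LrtResult(llr, df, min(p, 1.0))


def null_model(passenger_id: str, Q: np.ndarray,
               n_samples: int | None = None) -> AssociationModel:
    """The driver-free model: uniform conditional, loglik = -n ln 3."""
    if n_samples is None:
        n_samples = int(np.isfinite(np.asarray(Q)).all(axis=-1).sum())
    return AssociationModel(passenger_id, (), (), np.zeros(0),
                            -n_samples * LN3, n_samples)


def screen_single_driver(x: np.ndarray, Q: np.ndarray, sign: int,
                         lam_cap: float = LAMBDA_CAP, tol: float = 1e-10,
                         max_iter: int = 200, mixture: bool = False
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit one driver against many passengers at once.

    ``x`` is the (n,) driver profile and ``Q`` the (P, n, 3) passenger
    triples.  Solves the 1-D concave box problem per passenger by projected
    Newton steps, which matches :func:`fit` to optimizer tolerance.  Returns
    (lambda, llr, p_value, n_usable) arrays of length P.
    """
    x = np.asarray(x, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 2:
        Q = Q[None, ...]
    ybar = Q[..., 2] - Q[..., 0]                     # (P, n)
    w = (np.isfinite(x)[None, :] & np.isfinite(ybar)).astype(float)
    f = np.where(np.isfinite(x), sign * x, 0.0)[None, :]
    ybar = np.where(w > 0, ybar, 0.0)

    n_use = w.sum(axis=1)
    fw = f * w
    # constant-over-usable-samples drivers are unidentifiable: pin at 0
    fmax = np.where(w > 0, f, -np.inf).max(axis=1)
    fmin = np.where(w > 0, f, np.inf).min(axis=1)
    identifiable = (fmax - fmin) > 1e-12

    lam = np.zeros(Q.shape[0])
    for _ in range(max_iter):
        eta = lam[:, None] * f
        mu, var = _moments(eta)
        g = np.sum(fw * (ybar - mu), axis=1)
        h = np.sum(fw * f * var, axis=1)
        step = np.where(h > 1e-12, g / np.maximum(h, 1e-12), 0.0)
        new = np.clip(lam + step, 0.0, lam_cap)
        new = np.where(identifiable, new, 0.0)
        if np.max(np.abs(new - lam)) < tol:
            lam = new
            break
        lam = new

    eta = lam[:, None] * f
    ll = np.sum(w * (eta * ybar - _log_z(eta)), axis=1)
    llr = np.maximum(0.0, 2.0 * (ll + n_use * LN3))
    p = chi2.sf(llr, 1)
    if mixture:        # exact one-sided null: 0.5*delta_0 + 0.5*chi2_1
        p = np.where(llr > 0, 0.5 * p, 1.0)
    return lam, llr, p, n_use.astype(int)
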