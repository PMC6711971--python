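"""Fast profiled-REML fitter for the random-intercept linear mixed model.

The differential pipeline fits the same small mixed model

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, s2_u),  e_ij ~ N(0, s2_e)

hundreds of thousands of times (one fit per feature per permutation), so the
fitter is specialised for the single-variance-component case: the REML
log-likelihood is profiled down to a one-dimensional search over the variance
ratio lambda = s2_u / s2_e, and every evaluation is a handful of dense matrix
products on an n x p design (n = samples in one transition, p ~ 12).

With V = I + lambda * Z Z' and Z the subject indicator matrix, each subject
block of V^-1 is I - (lambda / (1 + lambda * n_i)) J, so X' V^-1 X, X' V^-1 y
and y' V^-1 y reduce to per-subject column sums.  Agreement with
statsmodels MixedLM is exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["RandomInterceptWorkspace", "LMMFit"]

# lambda searched on a log grid wide enough to cover s2_u/s2_e from ~1e-8
# (effectively OLS) to ~1e8 (subject intercepts dominate).
_LOG_LAM_LO = -18.0
_LOG_LAM_HI = 18.0

# large finite penalty keeps the bounded scalar optimiser off inf arithmetic
_BIG = 1e300


@dataclass
class LMMFit:
    """Result of one random-intercept fit.

    ``method`` is ``"reml"`` for a converged mixed-model fit,
    ``"ols_within"`` for the subject-mean-centred least-squares fallback and
    ``"constant"`` for a response with zero variance.
    """

    beta: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    method: str

    @property
    def converged(self) -> bool:
        return self.method == "reml"


class RandomInterceptWorkspace:
    """Precomputed subject structure shared across features and permutations.

    Parameters
    ----------
    group_codes
        Integer subject codes in ``[0, n_groups)``, one per sample row.
    n_groups
        Number of distinct subjects.
    """

    def __init__(self, group_codes: np.ndarray, n_groups: int):
        group_codes = np.asarray(group_codes, dtype=np.intp)
        n = group_codes.shape[0]
        if n_groups <= 0 or n == 0:
            raise ValueError("empty design")
        # dense one-hot subject matrix; n and G are both small
        gmat = np.zeros((n_groups, n))
        gmat[group_codes, np.arange(n)] = 1.0
        self.group_codes = group_codes
        self.n_groups = n_groups
        self.n_obs = n
        self._gmat = gmat
        self._group_sizes = gmat.sum(axis=1)

    # -- profiled REML ----------------------------------------------------

    def _crit_parts(self, lam: float, X, y, XtX, Xty, yty, GX, Gy):
        """-2 profile REML log-likelihood (up to a constant) and GLS pieces."""
        w = lam / (1.0 + lam * self._group_sizes)  # per-subject shrinkage
        A = XtX - (GX.T * w) @ GX
        b = Xty - GX.T @ (w * Gy)
        yVy = yty - Gy @ (w * Gy)
        try:
            c = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return _BIG, None, None
        beta = np.linalg.solve(A, b)
        rss = yVy - b @ beta
        n, p = X.shape
        if rss <= 0 or not np.isfinite(rss):
            return _BIG, None, None
        logdet_A = 2.0 * np.sum(np.log(np.diag(c)))
        logdet_V = np.sum(np.log1p(lam * self._group_sizes))
        crit = (n - p) * np.log(rss) + logdet_V + logdet_A
        if not np.isfinite(crit):
            crit = -_BIG if crit < 0 else _BIG
        return crit, beta, rss

    def fit(self, y: np.ndarray, X: np.ndarray) -> LMMFit:
        """Fit the random-intercept model by profiled REML.

        Falls back to within-subject OLS when the REML surface is degenerate
        (e.g. a response that is constant within every subject).
        """
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if np.ptp(y) == 0.0:
            return LMMFit(np.zeros(p), 0.0, 0.0, "constant")

        XtX = X.T @ X
        Xty = X.T @ y
        yty = y @ y
        GX = self._gmat @ X
        Gy = self._gmat @ y

        def crit(loglam: float) -> float:
            return self._crit_parts(np.exp(loglam), X, y, XtX, Xty, yty, GX, Gy)[0]

        c0 = crit(_LOG_LAM_LO)  # ~OLS boundary
        if c0 >= _BIG:
            return self._fallback(y, X)
        res = optimize.minimize_scalar(
            crit, bounds=(_LOG_LAM_LO, _LOG_LAM_HI), method="bounded",
            options={"xatol": 1e-6},
        )
        loglam = float(res.x) if res.fun <= c0 else _LOG_LAM_LO
        lam = np.exp(loglam)
        _, beta, rss = self._crit_parts(lam, X, y, XtX, Xty, yty, GX, Gy)
        if beta is None:
            return self._fallback(y, X)
        sigma2_e = rss / (n - p)
        # treat the lower search boundary as a zero variance component
        sigma2_u = 0.0 if loglam <= _LOG_LAM_LO + 1e-9 else lam * sigma2_e
        return LMMFit(beta, float(sigma2_u), float(sigma2_e), "reml")

    def _fallback(self, y: np.ndarray, X: np.ndarray) -> LMMFit:
        """Within-subject (subject-mean-centred) OLS, flagged as such."""
        yc = y - (self._gmat.T @ ((self._gmat @ y) / self._group_sizes))
        Xc = X - (self._gmat.T @ ((self._gmat @ X) / self._group_sizes[:, None]))
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        resid = yc - Xc @ beta
        dof = max(self.n_obs - self.n_groups - np.linalg.matrix_rank(Xc), 1)
        return LMMFit(beta, 0.0, float(resid @ resid / dof), "ols_within")
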