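"""Maximum-likelihood negative binomial log-linear regression.

Model: counts ``y_j ~ NB2(mu_j, phi_j)`` with ``log(mu_j) = offset_j +
x_j' beta`` and the NB2 dispersion ``phi_j`` following one of several
dispersion models expressed through the fitted relative frequency
``pi_j = exp(x_j' beta)``:

* ``nb2``     constant dispersion, ``log(phi) = a0``;
* ``nbp``     log-linear,          ``log(phi_j) = a0 + a1 log(pi_j)``;
* ``nbq``     log-quadratic,       ``log(phi_j) = a0 + a1 log(pi_j) + a2 log(pi_j)^2``;
* ``plugin``  per-observation dispersions supplied and treated as known.

The NBP family with variance ``mu + phi* mu**alpha`` corresponds to the
log-linear model with slope ``a1 = alpha - 2``, so all three parametric
kinds are nested polynomial dispersion models.

Estimation is block coordinate ascent on the joint log-likelihood:
iteratively reweighted least squares (IRLS, Fisher scoring) for ``beta``
given the dispersions, then golden-section coordinate maximization of the
dispersion coefficients given the fitted means, iterated until the
log-likelihood stabilizes.  All routines are vectorized over a batch of
response vectors sharing one design matrix, which is what makes the
Monte Carlo refitting in the goodness-of-fit test affordable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from nbdiag.nb_models import nb_log_pmf_arrays, POISSON_PHI_FLOOR

logger = logging.getLogger(__name__)

_DISPERSION_DEGREE = {"nb2": 0, "nbp": 1, "nbq": 2}

# Dispersion coefficients are optimized on the log scale within these
# brackets; a solution on the boundary is flagged as non-converged.
_LOG_PHI_LO, _LOG_PHI_HI = np.log(1e-8), np.log(1e4)
_SLOPE_LO, _SLOPE_HI = -4.0, 4.0
_ETA_CLIP = 35.0

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class DesignSpec:
    """Design matrix and offsets for a single-response NB regression.

    ``X`` is n x p (include an intercept column explicitly if wanted);
    ``offset`` holds ``log(s_j) + log(R_j)`` and defaults to zero.
    """

    X: np.ndarray
    offset: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n, p = self.X.shape
        if self.offset is None:
            self.offset = np.zeros(n)
        else:
            self.offset = np.asarray(self.offset, dtype=float)
            if self.offset.shape != (n,):
                raise ValueError("offset length must match number of rows of X")
        if n < p:
            raise ValueError(f"need at least as many observations ({n}) as columns ({p})")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class DispersionModel:
    """Specification (and, after fitting, estimate) of a dispersion model.

    ``kind`` is one of ``"nb2"``, ``"nbp"``, ``"nbq"``, ``"plugin"``.
    ``alpha`` holds the coefficients ``(a0[, a1[, a2]])`` of the
    log-polynomial in ``log(pi)``; leave ``None`` to estimate.  ``fixed``
    pins individual coefficients by index (e.g. ``{1: 0.0}`` constrains the
    NBP slope to zero).  ``phi_values`` supplies known per-observation NB2
    dispersions for the plug-in kind.
    """

    kind: str = "nb2"
    alpha: Optional[tuple] = None
    fixed: dict = field(default_factory=dict)
    phi_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("nb2", "nbp", "nbq", "plugin"):
            raise ValueError(f"unknown dispersion model kind {self.kind!r}")
        if self.kind == "plugin":
            if self.phi_values is None:
                raise ValueError("plugin dispersion model needs phi_values")
            self.phi_values = np.asarray(self.phi_values, dtype=float)
            if np.any(self.phi_values < 0):
                raise ValueError("plug-in dispersions must be nonnegative")

    @property
    def n_coef(self) -> int:
        return 0 if self.kind == "plugin" else _DISPERSION_DEGREE[self.kind] + 1

    def phi_of_logpi(self, log_pi: np.ndarray, coefs: np.ndarray) -> np.ndarray:
        """Evaluate per-observation NB2 dispersion at ``log(pi)``."""
        if self.kind == "plugin":
            return np.broadcast_to(self.phi_values, log_pi.shape)
        deg = _DISPERSION_DEGREE[self.kind]
        coefs = np.atleast_2d(coefs)
        log_phi = coefs[..., :1] * np.ones_like(log_pi)
        for k in range(1, deg + 1):
            log_phi = log_phi + coefs[..., k : k + 1] * log_pi**k
        return np.exp(np.clip(log_phi, _LOG_PHI_LO - 5, _LOG_PHI_HI + 5))


@dataclass
class RegressionFit:
    """Result of a single-response NB regression fit."""

    beta: np.ndarray
    beta_se: np.ndarray
    mu_hat: np.ndarray
    phi_hat: np.ndarray
    dispersion: DispersionModel
    log_likelihood: float
    converged: bool
    design: DesignSpec

    def to_dict(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "beta": self.beta.tolist(),
            "beta_se": self.beta_se.tolist(),
            "dispersion_kind": self.dispersion.kind,
            "dispersion_alpha": None
            if self.dispersion.alpha is None
            else list(self.dispersion.alpha),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
        }


def _irls(Y, X, offset, phi, beta, n_iter=25, tol=1e-10):
    """Vectorized Fisher scoring for beta given per-observation dispersions.

    Y: (B, n); X: (n, p); offset: (n,); phi: (B, n) NB2 dispersions;
    beta: (B, p) starting values.  Returns updated (beta, mu).
    """
    Y = np.asarray(Y, dtype=float)
    for _ in range(n_iter):
        eta = np.clip(offset + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + phi * mu)
        z = (eta - offset) + (Y - mu) / mu
        XtWX = np.einsum("bn,ni,nj->bij", W, X, X, optimize=True)
        XtWz = np.einsum("bn,ni->bi", W * z, X, optimize=True)
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            XtWX = XtWX + 1e-8 * np.eye(X.shape[1])
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < tol:
            break
    eta = np.clip(offset + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    return beta, np.exp(eta)


def _loglik(Y, mu, phi):
    """Summed NB2 log-likelihood per batch row; (B,)."""
    return nb_log_pmf_arrays(Y, mu, phi).sum(axis=-1)


def _coef_loglik(Y, mu, log_pi, model, coefs, idx, values):
    """Log-likelihood as a function of one dispersion coefficient (batch)."""
    trial = coefs.copy()
    trial[:, idx] = values
    phi = model.phi_of_logpi(log_pi, trial)
    return _loglik(Y, mu, phi)


def _golden_max(f, lo, hi, tol=1e-5, max_iter=60):
    """Vectorized golden-section maximization on per-row brackets.

    ``f`` maps a (B,) vector of abscissae to a (B,) vector of objective
    values; ``lo``/``hi`` are (B,) brackets.  Returns the (B,) argmax.
    """
    lo = lo.copy()
    hi = hi.copy()
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1 = f(x1)
    f2 = f(x2)
    for _ in range(max_iter):
        if np.max(hi - lo) < tol:
            break
        take_left = f1 >= f2
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
        x1_new = hi - _GOLDEN * (hi - lo)
        x2_new = lo + _GOLDEN * (hi - lo)
        # Golden-ratio invariant: the retained interior point coincides with
        # one of the freshly computed coordinates, so only f_new is evaluated.
        f_new = f(np.where(take_left, x1_new, x2_new))
        f1, f2 = (
            np.where(take_left, f_new, f2),
            np.where(take_left, f1, f_new),
        )
        x1, x2 = x1_new, x2_new
    return (lo + hi) / 2.0


def _coef_bounds(idx: int):
    if idx == 0:
        return _LOG_PHI_LO, _LOG_PHI_HI
    return _SLOPE_LO, _SLOPE_HI


def _moment_phi(Y, mu):
    """Batch method-of-moments NB2 dispersion, floored for use as a start."""
    num = ((Y - mu) ** 2 - mu).sum(axis=-1)
    den = (mu**2).sum(axis=-1)
    return np.maximum(num / np.maximum(den, 1e-300), 1e-4)


def fit_nb_batch(
    Y: np.ndarray,
    design: DesignSpec,
    model: DispersionModel,
    *,
    tol: float = 1e-8,
    max_outer: int = 100,
    beta0: Optional[np.ndarray] = None,
    disp0: Optional[np.ndarray] = None,
) -> dict:
    """Fit the NB regression to every row of ``Y`` (B x n) at once.

    Returns a dict with ``beta`` (B, p), ``mu`` (B, n), ``phi`` (B, n) NB2
    dispersions, ``coefs`` (B, k) dispersion coefficients (empty for
    plug-in), ``loglik`` (B,) and ``converged`` (B,) flags.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    X, offset = design.X, design.offset

    # Poisson start for beta.
    if beta0 is None:
        beta0 = np.zeros((B, design.p))
        ybar = np.maximum(Y.mean(axis=1), 0.1)
        if np.allclose(X[:, 0], 1.0):
            beta0[:, 0] = np.log(ybar) - offset.mean()
        beta, mu = _irls(Y, X, offset, np.zeros((B, n)), beta0, n_iter=30)
    else:
        beta, mu = _irls(Y, X, offset, np.zeros((B, n)), beta0, n_iter=10)

    if model.kind == "plugin":
        phi = np.broadcast_to(model.phi_values, (B, n))
        beta, mu = _irls(Y, X, offset, phi, beta, n_iter=50)
        return {
            "beta": beta,
            "mu": mu,
            "phi": np.array(phi),
            "coefs": np.empty((B, 0)),
            "loglik": _loglik(Y, mu, phi),
            "converged": np.ones(B, dtype=bool),
        }

    k = model.n_coef
    coefs = np.zeros((B, k))
    coefs[:, 0] = np.log(_moment_phi(Y, mu))
    warm = disp0 is not None

    # The dispersion polynomial is optimized in log(pi) centered at its
    # per-row mean (fixed after the initial beta): this decorrelates the
    # intercept and slope coordinates.  Reported coefficients are mapped
    # back to the raw log(pi) scale at the end.
    if k > 1:
        center = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP).mean(axis=1, keepdims=True)
    else:
        center = np.zeros((B, 1))
    if warm:
        # Raw-scale starting coefficients (e.g. from the fit being
        # bootstrapped) mapped into the centered parameterization; the wide
        # first bracket sweep is skipped.
        a = np.broadcast_to(np.atleast_2d(disp0), (B, k)).astype(float)
        c = center[:, 0]
        coefs = a.copy()
        if k >= 3:
            coefs[:, 1] = a[:, 1] + 2.0 * a[:, 2] * c
        if k >= 2:
            coefs[:, 0] = a[:, 0] + a[:, 1] * c + (a[:, 2] * c**2 if k >= 3 else 0.0)
    _apply_fixed_centered(coefs, model.fixed, center[:, 0], k)

    free = [i for i in range(k) if i not in model.fixed]
    ll = np.full(B, -np.inf)
    converged = np.zeros(B, dtype=bool)
    ll_hist = []
    window, osc_eps = 5, 1e-4
    first = not warm
    for it in range(max_outer):
        log_pi = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP) - center
        # Dispersion block: golden-section sweeps per free coefficient,
        # means held fixed.  Wide brackets on the first pass, then local.
        sweeps = 2 if first and len(free) > 1 else 1
        for _ in range(sweeps):
            for idx in free:
                blo, bhi = _coef_bounds(idx)
                if first:
                    lo = np.full(B, blo)
                    hi = np.full(B, bhi)
                else:
                    lo = np.maximum(coefs[:, idx] - 1.0, blo)
                    hi = np.minimum(coefs[:, idx] + 1.0, bhi)
                coefs[:, idx] = _golden_max(
                    lambda v, i=idx: _coef_loglik(Y, mu, log_pi, model, coefs, i, v),
                    lo,
                    hi,
                )
        first = False
        phi = model.phi_of_logpi(log_pi, coefs)
        beta, mu = _irls(Y, X, offset, phi, beta, n_iter=25)
        log_pi = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP) - center
        phi = model.phi_of_logpi(log_pi, coefs)
        new_ll = _loglik(Y, mu, phi)
        done = np.abs(new_ll - ll) < tol * (1.0 + np.abs(new_ll))
        # Block ascent is monotone up to optimizer noise: rows whose
        # likelihood has not improved materially over the last few outer
        # iterations are stationary even if they wobble above `tol`.
        ll_hist.append(new_ll)
        if it >= window:
            done |= (new_ll - ll_hist[it - window]) < osc_eps
        ll = new_ll
        converged = done
        if np.all(done):
            break
    # Upper-boundary dispersion solutions are flagged (the lower boundary
    # is the legitimate Poisson limit).
    on_edge = np.abs(coefs[:, 0] - _LOG_PHI_HI) < 1e-3
    converged &= ~on_edge
    return {
        "beta": beta,
        "mu": mu,
        "phi": phi,
        "coefs": _uncenter_coefs(coefs, center[:, 0], k),
        "loglik": ll,
        "converged": converged,
    }


def _apply_fixed_centered(coefs, fixed, center, k):
    """Impose raw-scale fixed coefficients in the centered parameterization.

    The centered polynomial c0 + c1 z + c2 z^2 in z = u - c equals the raw
    polynomial a0 + a1 u + a2 u^2 with c2 = a2, c1 = a1 + 2 a2 c and
    c0 = a0 + a1 c + a2 c^2.  A raw coefficient can be pinned only if all
    higher-order coefficients are pinned too (always true for the
    trailing-coefficient constraints used to express model nesting).
    """
    if not fixed:
        return
    order = sorted(fixed, reverse=True)
    if order != list(range(k - 1, k - 1 - len(order), -1)):
        raise NotImplementedError(
            "fixed dispersion coefficients must be the trailing ones"
        )
    a = {i: fixed[i] for i in order}
    if 2 in a:
        coefs[:, 2] = a[2]
    if 1 in a:
        c2 = a.get(2, 0.0)
        coefs[:, 1] = a[1] + 2.0 * c2 * center
    if 0 in a:
        c1 = coefs[:, 1] if k > 1 else 0.0
        c2 = a.get(2, 0.0)
        coefs[:, 0] = a[0] + c1 * center - c2 * center**2


def _uncenter_coefs(coefs, center, k):
    """Map centered-log-pi polynomial coefficients to the raw scale."""
    out = coefs.copy()
    if k >= 3:
        c2 = coefs[:, 2]
    else:
        c2 = 0.0
    if k >= 2:
        out[:, 0] = coefs[:, 0] - coefs[:, 1] * center + c2 * center**2
        out[:, 1] = coefs[:, 1] - 2.0 * c2 * center
    return out


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("y must be a vector")
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must contain nonnegative integers")
    if not np.any(y > 0):
        raise ValueError("all-zero response vector cannot be fit")
    return y.astype(float)


def fit_nb_regression(
    y: np.ndarray,
    d: DesignSpec,
    model: DispersionModel,
    *,
    tol: float = 1e-8,
    max_outer: int = 100,
) -> RegressionFit:
    """Joint MLE of regression coefficients and dispersion parameters.

    For plug-in dispersion models only ``beta`` is estimated and the
    supplied dispersions are held fixed.  Raises on rank-deficient designs,
    all-zero responses, or non-integer counts; non-convergence is reported
    through the ``converged`` flag with a logged warning.
    """
    y = _validate_counts(y)
    if d.n <= d.p:
        raise ValueError("need more observations than regression parameters")
    if model.kind != "plugin" and model.alpha is not None:
        # Fully specified dispersion: evaluate as plug-in on fitted pi,
        # iterating since phi depends on beta through pi.
        coefs = np.asarray(model.alpha, dtype=float)[None, :]
        beta = None
        for _ in range(20):
            log_pi = (
                np.zeros((1, d.n)) if beta is None else np.clip(beta @ d.X.T, -_ETA_CLIP, _ETA_CLIP)
            )
            phi = model.phi_of_logpi(log_pi, coefs)
            res = fit_nb_batch(y[None, :], d, DispersionModel(kind="plugin", phi_values=phi[0]),
                               beta0=beta)
            if beta is not None and np.max(np.abs(res["beta"] - beta)) < 1e-10:
                beta = res["beta"]
                break
            beta = res["beta"]
        res["coefs"] = coefs
        res["phi"] = model.phi_of_logpi(np.clip(beta @ d.X.T, -_ETA_CLIP, _ETA_CLIP), coefs)
        res["loglik"] = _loglik(y[None, :], res["mu"], res["phi"])
        fitted_model = model
    else:
        res = fit_nb_batch(y[None, :], d, model, tol=tol, max_outer=max_outer)
        if model.kind == "plugin":
            fitted_model = model
        else:
            fitted_model = DispersionModel(
                kind=model.kind, alpha=tuple(res["coefs"][0]), fixed=dict(model.fixed)
            )
    beta = res["beta"][0]
    mu = res["mu"][0]
    phi = res["phi"][0]
    if not bool(np.all(res["converged"])):
        logger.warning("NBFIT-NONCONVERGED: fit did not reach tolerance")
    W = mu / (1.0 + phi * mu)
    cov = np.linalg.inv(d.X.T @ (W[:, None] * d.X))
    return RegressionFit(
        beta=beta,
        beta_se=np.sqrt(np.diag(cov)),
        mu_hat=mu,
        phi_hat=phi,
        dispersion=fitted_model,
        log_likelihood=float(res["loglik"][0]),
        converged=bool(np.all(res["converged"])),
        design=d,
    )


def pearson_residuals(fit: RegressionFit, y: np.ndarray) -> np.ndarray:
    """Pearson residuals ``(y - mu) / sqrt(mu + phi mu^2)`` under the fit."""
    y = np.asarray(y, dtype=float)
    if y.shape != fit.mu_hat.shape:
        raise ValueError("y and fitted means are not conformable")
    if np.any(fit.mu_hat <= 0):
        raise FloatingPointError("fitted mean of zero; residuals undefined")
    sd = np.sqrt(fit.mu_hat + fit.phi_hat * fit.mu_hat**2)
    return (y - fit.mu_hat) / sd


def pearson_residuals_batch(Y, mu, phi):
    """Batch Pearson residuals for (B, n) arrays."""
    return (np.asarray(Y, dtype=float) - mu) / np.sqrt(mu + phi * mu**2)
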