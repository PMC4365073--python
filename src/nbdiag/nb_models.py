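"""Negative binomial distribution family: NB2 / NB1 / NBP parameterizations.

The family is indexed by a mean ``mu``, a dispersion ``phi`` and a variance
exponent ``alpha``, with

    Var(Y) = mu + phi * mu**alpha.

``alpha = 2`` is the conventional NB2 parameterization (size parameter
``theta = 1/phi``), ``alpha = 1`` is NB1, and general ``alpha`` is the NBP
family in which ``theta = mu**(2 - alpha) / phi``.  ``phi = 0`` degenerates
to a Poisson distribution.

Sampling uses the gamma-Poisson composition: ``v ~ Gamma(shape=theta,
scale=mu/theta)`` followed by ``Y | v ~ Poisson(v)``, which marginally gives
NB with mean ``mu`` and variance ``mu + mu**2/theta``.  The composition is
valid for any positive real ``theta``, including the non-integer sizes that
arise under NBP dispersion models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

# Dispersions below this are numerically indistinguishable from Poisson and
# would overflow theta = 1/phi; treated as exactly Poisson.
POISSON_PHI_FLOOR = 1e-12


@dataclass(frozen=True)
class NBParameterization:
    """A point in the NB mean-variance family.

    Parameters
    ----------
    mu : float
        Expected count, must be positive.
    phi : float
        Dispersion, must be nonnegative.  ``phi = 0`` means Poisson.
    alpha : float
        Variance exponent: variance is ``mu + phi * mu**alpha``.
    """

    mu: float
    phi: float
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.phi < 0:
            raise ValueError(f"phi must be nonnegative, got {self.phi}")

    @property
    def theta(self) -> float:
        """NB size parameter, ``mu**(2 - alpha) / phi`` (inf for Poisson)."""
        if self.phi < POISSON_PHI_FLOOR:
            return np.inf
        return self.mu ** (2.0 - self.alpha) / self.phi

    @property
    def phi_nb2(self) -> float:
        """Equivalent NB2 dispersion ``1/theta = phi * mu**(alpha - 2)``."""
        if self.phi < POISSON_PHI_FLOOR:
            return 0.0
        return self.phi * self.mu ** (self.alpha - 2.0)


def nb_variance(p: NBParameterization) -> float:
    """Variance ``mu + phi * mu**alpha`` of the parameterization."""
    return p.mu + p.phi * p.mu**p.alpha


def nb_log_pmf(y, p: NBParameterization):
    """Log probability mass of counts ``y`` under the NB family.

    Evaluates the gamma-function form

        log f(y) = lgamma(y + theta) - lgamma(theta) - lgamma(y + 1)
                   + theta * log(theta / (mu + theta))
                   + y * log(mu / (mu + theta))

    with ``theta`` given by the parameterization; for ``phi`` below the
    Poisson floor the Poisson log-pmf (the ``theta -> inf`` limit) is
    returned.  ``y`` may be a scalar or array of nonnegative integers.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be integers")
    y = y.astype(float)
    mu = p.mu
    if p.phi < POISSON_PHI_FLOOR:
        out = y * np.log(mu) - mu - gammaln(y + 1.0)
    else:
        theta = p.theta
        out = (
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (mu + theta))
            + y * np.log(mu / (mu + theta))
        )
    return out if out.ndim else float(out)


def nb_log_pmf_arrays(y, mu, phi_nb2):
    """Vectorized NB2 log-pmf with per-element mean and NB2 dispersion.

    Workhorse for likelihood evaluation during fitting.  Arrays broadcast;
    elements with ``phi_nb2`` below the Poisson floor use the Poisson limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.maximum(np.asarray(phi_nb2, dtype=float), 0.0)
    pois = phi < POISSON_PHI_FLOOR
    theta = 1.0 / np.where(pois, 1.0, phi)  # placeholder where Poisson
    with np.errstate(divide="ignore", invalid="ignore"):
        nb = (
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (mu + theta))
            + y * np.log(mu / (mu + theta))
        )
    poisson = y * np.log(mu) - mu - gammaln(y + 1.0)
    return np.where(pois, poisson, nb)


def simulate_nb(p: NBParameterization, size: int, rng: np.random.Generator):
    """Draw ``size`` i.i.d. counts from the parameterization.

    Uses gamma-Poisson composition so that non-integer ``theta`` and
    extreme means are handled; ``phi`` below the floor draws Poisson
    directly.  All randomness comes from the injected generator.
    """
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    return simulate_nb_arrays(p.mu, p.phi_nb2, rng, size=size)


def simulate_nb_arrays(mu, phi_nb2, rng: np.random.Generator, size=None):
    """Vectorized NB2 sampler with per-element mean and NB2 dispersion.

    ``mu`` and ``phi_nb2`` broadcast; ``size`` overrides the output shape
    (numpy semantics).  Gamma-Poisson composition throughout.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi_nb2, dtype=float)
    mu, phi = np.broadcast_arrays(mu, phi)
    if size is None:
        size = mu.shape
    pois = phi < POISSON_PHI_FLOOR
    if np.all(pois):
        return rng.poisson(np.broadcast_to(mu, size))
    theta = 1.0 / np.where(pois, 1.0, phi)
    lam = rng.gamma(shape=np.broadcast_to(theta, size),
                    scale=np.broadcast_to(mu / theta, size))
    lam = np.where(np.broadcast_to(pois, size), np.broadcast_to(mu, size), lam)
    return rng.poisson(lam)
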