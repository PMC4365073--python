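"""Parametric-bootstrap goodness-of-fit test for NB regression.

The test fits an NB regression model, simulates ``R`` replicate datasets
from the fitted model, refits the same model to every replicate, and
compares the observed value of a test statistic with its Monte Carlo null
distribution.  Two statistics are used:

* the Pearson statistic, the sum of squared Pearson residuals (deviations
  of the ordered residuals about the y = 0 line);
* the squared vertical distance, the sum of squared deviations of the
  ordered residuals from the per-rank medians of their simulated sampling
  distributions (deviations about the y = x line of the empirical
  probability plot).

One-sided Monte Carlo p-values are computed as

    p = (#{simulated statistic >= observed} + 1) / (R + 1),

which is slightly biased but has the correct Type-I error rate.  The same
simulations yield the empirical probability plot: observed ordered
residuals against Monte Carlo medians, with a 95% pointwise prediction
envelope and a simulation-calibrated simultaneous prediction band.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from nbdiag.nb_fit import (
    DesignSpec,
    DispersionModel,
    RegressionFit,
    fit_nb_batch,
    fit_nb_regression,
    pearson_residuals,
    pearson_residuals_batch,
)
from nbdiag.nb_models import simulate_nb_arrays

logger = logging.getLogger(__name__)

# Empirical quantile convention used throughout (numpy "linear" =
# Hyndman-Fan type 7); recorded here as a config constant.
QUANTILE_METHOD = "linear"


@dataclass
class EnvelopeTable:
    """Per-rank envelope of ordered-residual null distributions.

    ``median``, ``lower``, ``upper`` are the per-rank Monte Carlo median
    and pointwise prediction limits; ``sim_lower``/``sim_upper`` bound the
    simultaneous prediction band; ``gamma`` is the calibrated per-rank
    pointwise level of the simultaneous band.  ``flags`` (set once an
    observed residual vector is supplied) take values ``"inside"``,
    ``"outside-pointwise"`` and ``"outside-simultaneous"``.
    """

    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    sim_lower: np.ndarray
    sim_upper: np.ndarray
    level: float
    gamma: float
    flags: Optional[np.ndarray] = None

    def flag(self, r_ordered: np.ndarray) -> np.ndarray:
        """Classify each ordered residual against the two bands."""
        r = np.sort(np.asarray(r_ordered, dtype=float))
        out = np.full(r.shape, "inside", dtype=object)
        outside_pw = (r < self.lower) | (r > self.upper)
        outside_sim = (r < self.sim_lower) | (r > self.sim_upper)
        out[outside_pw] = "outside-pointwise"
        out[outside_sim] = "outside-simultaneous"
        self.flags = out
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.median) + 1),
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
                "sim_lower": self.sim_lower,
                "sim_upper": self.sim_upper,
                "flag": self.flags if self.flags is not None else "",
            }
        )


@dataclass
class GOFResult:
    """Everything the GOF test produced for one response vector."""

    r_obs: np.ndarray
    stat_vert_obs: float
    stat_pearson_obs: float
    stat_vert_sim: np.ndarray
    stat_pearson_sim: np.ndarray
    p_vert: float
    p_pearson: float
    envelope: EnvelopeTable
    R: int
    seed: Optional[int]
    fit: RegressionFit
    n_dropped: int = 0
    unreliable: bool = False

    def to_dict(self) -> dict:
        return {
            "p_vert": self.p_vert,
            "p_pearson": self.p_pearson,
            "stat_vert_obs": self.stat_vert_obs,
            "stat_pearson_obs": self.stat_pearson_obs,
            "R": self.R,
            "n_dropped": self.n_dropped,
            "unreliable": self.unreliable,
            "seed": self.seed,
            "fit": self.fit.to_dict(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def mc_pvalue(stat_sim: np.ndarray, stat_obs: float) -> float:
    """One-sided Monte Carlo p-value (#{sim >= obs} + 1) / (R + 1)."""
    stat_sim = np.asarray(stat_sim, dtype=float)
    return float((np.sum(stat_sim >= stat_obs) + 1.0) / (stat_sim.size + 1.0))


def pearson_stat(r: np.ndarray) -> float:
    """Sum of squared Pearson residuals."""
    r = np.asarray(r, dtype=float)
    return float(np.sum(r * r))


def vertical_distance_stat(r: np.ndarray, medians: np.ndarray) -> float:
    """Sum of squared deviations of ordered residuals from rank medians.

    The input residuals are sorted first, so the statistic is invariant to
    observation order; ``medians`` must already be in rank order.
    """
    r = np.asarray(r, dtype=float)
    medians = np.asarray(medians, dtype=float)
    if r.shape != medians.shape:
        raise ValueError("residuals and medians must have equal length")
    d = np.sort(r) - medians
    return float(np.sum(d * d))


def envelope(
    sim_residuals: np.ndarray, level: float = 0.95, method: str = "calibrated"
) -> EnvelopeTable:
    """Pointwise and simultaneous prediction bands from simulated residuals.

    ``sim_residuals`` is an R x n matrix whose rows are ordered residual
    vectors from replicates of the fitted model.  The pointwise band
    connects the per-rank ``(1-level)/2`` and ``1-(1-level)/2`` empirical
    quantiles.  The simultaneous band calibrates a common per-rank tail
    probability ``gamma`` (by bisection) such that at least ``level`` of
    the replicate vectors lie entirely inside the band; with
    ``method="max-deviation"`` the band is instead built from the
    replicates' maximum median-relative deviations.
    """
    S = np.atleast_2d(np.asarray(sim_residuals, dtype=float))
    R, n = S.shape
    min_R = int(np.ceil(2.0 / (1.0 - level))) - 1
    if R < min_R:
        raise ValueError(f"need at least {min_R} replicates for a {level:.0%} envelope")
    tail = (1.0 - level) / 2.0
    med = np.quantile(S, 0.5, axis=0, method=QUANTILE_METHOD)
    lower = np.quantile(S, tail, axis=0, method=QUANTILE_METHOD)
    upper = np.quantile(S, 1.0 - tail, axis=0, method=QUANTILE_METHOD)

    if method == "max-deviation":
        # Scale the pointwise half-widths until `level` of the replicates'
        # max standardized deviations are covered.
        half_lo = np.maximum(med - lower, 1e-12)
        half_hi = np.maximum(upper - med, 1e-12)
        dev = np.maximum((med - S) / half_lo, (S - med) / half_hi).max(axis=1)
        c = np.quantile(dev, level, method=QUANTILE_METHOD)
        sim_lower, sim_upper = med - c * half_lo, med + c * half_hi
        gamma = float("nan")
    else:
        def coverage(g: float) -> float:
            lo = np.quantile(S, g, axis=0, method=QUANTILE_METHOD)
            hi = np.quantile(S, 1.0 - g, axis=0, method=QUANTILE_METHOD)
            inside = np.all((S >= lo) & (S <= hi), axis=1)
            return float(inside.mean())

        g_lo, g_hi = 1e-9, tail  # coverage(g_lo) ~ 1, decreasing in g
        if coverage(g_hi) >= level:
            g = g_hi
        else:
            for _ in range(40):
                g_mid = 0.5 * (g_lo + g_hi)
                if coverage(g_mid) >= level:
                    g_lo = g_mid
                else:
                    g_hi = g_mid
            g = g_lo
        sim_lower = np.quantile(S, g, axis=0, method=QUANTILE_METHOD)
        sim_upper = np.quantile(S, 1.0 - g, axis=0, method=QUANTILE_METHOD)
        gamma = 2.0 * g
    sim_lower = np.minimum(sim_lower, lower)
    sim_upper = np.maximum(sim_upper, upper)
    return EnvelopeTable(
        median=med,
        lower=lower,
        upper=upper,
        sim_lower=sim_lower,
        sim_upper=sim_upper,
        level=level,
        gamma=gamma,
    )


def _refit_replicates(Y, design, model, fit, max_retries=2):
    """Refit the model to each simulated replicate, with fallback starts.

    Returns (mu, phi, converged) batch arrays.  Replicates that fail after
    the fallback initializations are reported through ``converged``.
    """
    disp0 = None
    if model.kind != "plugin" and model.alpha is not None:
        # Fully specified dispersion coefficients are treated as known.
        model = DispersionModel(
            kind=model.kind,
            fixed={i: a for i, a in enumerate(model.alpha)},
        )
    elif model.kind != "plugin" and fit.dispersion.alpha is not None:
        disp0 = np.asarray(fit.dispersion.alpha)
    beta0 = np.tile(fit.beta, (Y.shape[0], 1))
    res = fit_nb_batch(Y, design, model, beta0=beta0, disp0=disp0)
    bad = ~res["converged"]
    tries = 0
    while np.any(bad) and tries < max_retries:
        tries += 1
        if tries == 1:
            retry = fit_nb_batch(Y[bad], design, model, max_outer=200)
        else:
            b0 = np.tile(fit.beta, (int(bad.sum()), 1)) + 0.1
            retry = fit_nb_batch(Y[bad], design, model, beta0=b0, max_outer=200)
        for key in ("beta", "mu", "phi", "coefs"):
            res[key][bad] = retry[key]
        res["loglik"][bad] = retry["loglik"]
        res["converged"][bad] = retry["converged"]
        bad = ~res["converged"]
    return res


def gof_test(
    y: np.ndarray,
    d: DesignSpec,
    model: DispersionModel,
    R: int = 999,
    seed: Optional[int] = None,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> GOFResult:
    """Monte Carlo GOF test of an NB regression model.

    Fits the model, simulates ``R`` datasets from the fitted parameters,
    refits the same model to each (re-estimating every free parameter;
    plug-in dispersions are re-supplied as known), and returns one-sided
    Monte Carlo p-values for both the squared-vertical-distance and the
    Pearson statistics, together with the envelope table for the
    empirical probability plot.
    """
    if R < 19:
        raise ValueError("R must be at least 19")
    if rng is None:
        rng = np.random.default_rng(seed)

    fit = fit_nb_regression(y, d, model)
    r_obs = np.sort(pearson_residuals(fit, y))
    n = len(r_obs)

    Y = simulate_nb_arrays(fit.mu_hat, fit.phi_hat, rng, size=(R, n))
    res = _refit_replicates(Y, d, model, fit)
    keep = res["converged"]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("NBDIAG-DROPPED: %d of %d replicate fits dropped", n_dropped, R)
    R_eff = R - n_dropped
    unreliable = n_dropped > 0.05 * R

    sims = np.sort(
        pearson_residuals_batch(Y[keep], res["mu"][keep], res["phi"][keep]), axis=1
    )
    min_R = int(np.ceil(2.0 / (1.0 - level))) - 1
    if R_eff >= min_R:
        env = envelope(sims, level=level)
    else:
        # Too few replicates for prediction bands at this level; the rank
        # medians (and hence both statistics) are still available.
        med = np.quantile(sims, 0.5, axis=0, method=QUANTILE_METHOD)
        inf = np.full(n, np.inf)
        env = EnvelopeTable(median=med, lower=-inf, upper=inf,
                            sim_lower=-inf, sim_upper=inf, level=level,
                            gamma=float("nan"))
    env.flag(r_obs)

    d_sim = np.sum((sims - env.median) ** 2, axis=1)
    d_obs = vertical_distance_stat(r_obs, env.median)
    pe_sim = np.sum(sims**2, axis=1)
    pe_obs = pearson_stat(r_obs)

    p_vert = mc_pvalue(d_sim, d_obs)
    p_pearson = mc_pvalue(pe_sim, pe_obs)

    return GOFResult(
        r_obs=r_obs,
        stat_vert_obs=d_obs,
        stat_pearson_obs=pe_obs,
        stat_vert_sim=d_sim,
        stat_pearson_sim=pe_sim,
        p_vert=float(p_vert),
        p_pearson=float(p_pearson),
        envelope=env,
        R=R_eff,
        seed=seed,
        fit=fit,
        n_dropped=n_dropped,
        unreliable=unreliable,
    )


def empirical_probability_plot(res: GOFResult, out) -> str:
    """Write the empirical probability plot for a GOF result.

    Observed ordered residuals against Monte Carlo medians; dashed
    pointwise envelope, solid simultaneous band, dotted y = x reference;
    points outside the pointwise envelope drawn as triangles and points
    outside the simultaneous band as crosses; both p-values annotated.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    env = res.envelope
    flags = env.flags if env.flags is not None else env.flag(res.r_obs)
    med = env.median
    fig, ax = plt.subplots(figsize=(5, 5))
    inside = flags == "inside"
    out_pw = flags == "outside-pointwise"
    out_sim = flags == "outside-simultaneous"
    ax.plot(med[inside], res.r_obs[inside], "o", color="black", ms=4, label="residual")
    if out_pw.any():
        ax.plot(med[out_pw], res.r_obs[out_pw], "^", color="tab:blue", ms=6,
                label="outside envelope")
    if out_sim.any():
        ax.plot(med[out_sim], res.r_obs[out_sim], "x", color="tab:red", ms=7,
                label="outside simultaneous band")
    ax.plot(med, env.lower, "--", color="tab:blue", lw=1)
    ax.plot(med, env.upper, "--", color="tab:blue", lw=1)
    ax.plot(med, env.sim_lower, "-", color="tab:red", lw=1)
    ax.plot(med, env.sim_upper, "-", color="tab:red", lw=1)
    lims = [min(med.min(), res.r_obs.min()), max(med.max(), res.r_obs.max())]
    ax.plot(lims, lims, ":", color="gray", lw=1)
    ax.set_xlabel("Monte Carlo median of ordered Pearson residuals")
    ax.set_ylabel("observed ordered Pearson residuals")
    ax.annotate(
        f"p (sq. vert. dist.) = {res.p_vert:.3g}\np (Pearson) = {res.p_pearson:.3g}",
        xy=(0.03, 0.97), xycoords="axes fraction", va="top", fontsize=9,
    )
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return str(out)
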