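"""Multi-gene RNA-Seq diagnostics for NB dispersion models.

An RNA-Seq count matrix (m genes x n samples) is modeled gene by gene as
``Y_ij ~ NB2(mu_ij, phi_ij)`` with ``log(mu_ij) = log(s_j) + log(R_j) +
log(pi_ij)``, where ``s_j`` is the library size, ``R_j`` an optional
normalization factor treated as known, and ``pi_ij = exp(x_j' beta_i)``
the mean relative frequency (the gene's expression level).  The NB2
dispersions ``phi_ij`` follow a global model fitted across all genes:

* ``common``    one dispersion for all genes;
* ``genewise``  one free dispersion per gene;
* ``nbp``       log-linear trend in log(pi);
* ``nbq``       log-quadratic trend in log(pi);
* ``trended``   non-parametric: a local-regression smooth of log
  moment-dispersions on log mean relative frequency, then treated as known;
* ``plugin``    per-gene dispersions supplied externally (e.g. empirical
  Bayes shrunken estimates) and treated as known.

Model adequacy is judged by running the single-gene Monte Carlo GOF test
on a random subsample of genes with the global dispersions plugged in,
then combining the per-gene p-values with Fisher's method and inspecting
their uniform QQ plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from nbdiag.nb_fit import (
    DesignSpec,
    DispersionModel,
    _irls,
    _loglik,
    fit_nb_batch,
)
from nbdiag.gof import gof_test

logger = logging.getLogger(__name__)

_ETA_CLIP = 35.0


@dataclass
class CountMatrix:
    """Genes x samples count matrix with library sizes and norm factors."""

    counts: np.ndarray
    lib_sizes: Optional[np.ndarray] = None
    norm_factors: Optional[np.ndarray] = None
    gene_ids: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        m, n = self.counts.shape
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if self.norm_factors is None:
            self.norm_factors = np.ones(n)
        else:
            self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if self.lib_sizes.shape != (n,) or self.norm_factors.shape != (n,):
            raise ValueError("lib_sizes / norm_factors must have one entry per sample")
        if np.any(self.lib_sizes <= 0) or np.any(self.norm_factors <= 0):
            raise ValueError("lib_sizes and norm_factors must be positive")
        if self.gene_ids is None:
            self.gene_ids = [f"g{i}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{j}" for j in range(n)]

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    @property
    def offset(self) -> np.ndarray:
        """Per-sample offset log(s_j) + log(R_j)."""
        return np.log(self.lib_sizes) + np.log(self.norm_factors)

    def filtered(self, min_total: int = 1) -> "CountMatrix":
        """Drop genes whose total count across samples is below threshold."""
        keep = self.counts.sum(axis=1) >= min_total
        return CountMatrix(
            counts=self.counts[keep],
            lib_sizes=self.lib_sizes,
            norm_factors=self.norm_factors,
            gene_ids=[g for g, k in zip(self.gene_ids, keep) if k],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class GlobalDispersionFit:
    """A fitted global dispersion model, evaluable per gene/observation."""

    kind: str
    alpha: Optional[tuple] = None          # common / nbp / nbq coefficients
    phi_gene: Optional[np.ndarray] = None  # genewise / trended / plugin, (m,)
    trend: Optional[Callable] = None       # log mean rel. freq. -> log phi
    beta: Optional[np.ndarray] = None      # (m, p) fitted coefficients
    log_pi: Optional[np.ndarray] = None    # (m, n) fitted log rel. freq.
    log_likelihood: float = float("nan")
    meta: dict = field(default_factory=dict)

    def phi_for_gene(self, i: int) -> np.ndarray:
        """Per-observation NB2 dispersions for gene ``i`` (treated as known)."""
        if self.kind in ("genewise", "trended", "plugin"):
            n = self.log_pi.shape[1] if self.log_pi is not None else 1
            return np.full(n, self.phi_gene[i])
        lp = self.log_pi[i]
        a = self.alpha
        log_phi = a[0] + sum(a[k] * lp**k for k in range(1, len(a)))
        return np.exp(log_phi)


def moment_dispersion(counts_row: np.ndarray, mu_row: np.ndarray) -> float:
    """Method-of-moments NB2 dispersion for one gene.

    phi_hat = max(0, sum[(y_j - mu_j)^2 - mu_j] / sum[mu_j^2]), the
    generalization of (s^2 - ybar)/ybar^2 to unequal means.
    """
    y = np.asarray(counts_row, dtype=float)
    mu = np.asarray(mu_row, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    if not np.any(mu > 0):
        raise ValueError("all fitted means are zero")
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return float(max(0.0, num / den))


def _poisson_betas(cm: CountMatrix, design: DesignSpec) -> tuple:
    """Per-gene Poisson fits: beta (m,p), mu (m,n) with offsets applied."""
    d = DesignSpec(design.X, cm.offset + (design.offset if design.offset is not None else 0))
    Y = cm.counts.astype(float)
    beta0 = np.zeros((cm.m, d.p))
    if np.allclose(d.X[:, 0], 1.0):
        beta0[:, 0] = np.log(np.maximum(Y.mean(axis=1), 0.5)) - d.offset.mean()
    beta, mu = _irls(Y, d.X, d.offset, np.zeros_like(Y), beta0, n_iter=50)
    return beta, mu, d


def _batch_irls_phi(Y, d, phi, beta):
    beta, mu = _irls(Y, d.X, d.offset, phi, beta, n_iter=30)
    return beta, mu, float(_loglik(Y, mu, phi).sum())


def moment_dispersions(cm: CountMatrix, design: DesignSpec):
    """Per-gene moment dispersions and mean log relative frequencies.

    Means come from per-gene Poisson fits; returns (phi_hat (m,),
    log_pi_bar (m,), beta (m,p), mu (m,n)).
    """
    beta, mu, d = _poisson_betas(cm, design)
    Y = cm.counts.astype(float)
    num = ((Y - mu) ** 2 - mu).sum(axis=1)
    den = (mu**2).sum(axis=1)
    phi_hat = np.maximum(num / np.maximum(den, 1e-300), 0.0)
    log_pi_bar = (beta @ design.X.T).mean(axis=1)
    return phi_hat, log_pi_bar, beta, mu


def fit_global_dispersion(
    cm: CountMatrix,
    design: DesignSpec,
    kind: str,
    *,
    span: float = 0.5,
    phi_gene: Optional[np.ndarray] = None,
    min_total: int = 1,
    with_se: bool = False,
    dof_correction: bool = True,
) -> GlobalDispersionFit:
    """Fit one of the global dispersion models to a count matrix.

    For ``common``, ``nbp`` and ``nbq`` the dispersion coefficients
    maximize the summed NB log-likelihood over all genes, with each gene's
    regression coefficients profiled out.  Because every gene contributes
    ``p`` estimated mean parameters, the joint-ML dispersion is biased
    low by a factor of about ``(n - p)/n`` (the count analogue of the
    ML variance bias); with ``dof_correction`` (default) the reported
    dispersion curve is rescaled by ``n/(n - p)`` to first order.
    ``genewise`` is the per-gene NB2 MLE, reported uncorrected.
    ``trended`` smooths log moment-dispersions on log mean relative
    frequency (lowess, tricube weights) and treats the result as known.
    ``plugin`` accepts externally computed per-gene dispersions.
    """
    cm = cm.filtered(min_total)
    Y = cm.counts.astype(float)
    m, n = Y.shape
    d_off = DesignSpec(design.X, cm.offset + (design.offset if design.offset is not None else 0))

    if kind == "plugin":
        if phi_gene is None:
            raise ValueError("plugin requires phi_gene")
        phi_gene = np.asarray(phi_gene, dtype=float)
        if phi_gene.shape != (m,):
            raise ValueError("phi_gene must have one value per (filtered) gene")
        beta0, mu0, _ = _poisson_betas(cm, design)
        beta, mu, ll = _batch_irls_phi(Y, d_off, phi_gene[:, None] * np.ones((1, n)), beta0)
        return GlobalDispersionFit(
            kind=kind, phi_gene=phi_gene, beta=beta,
            log_pi=beta @ design.X.T, log_likelihood=ll,
        )

    if kind == "genewise":
        res = fit_nb_batch(Y, d_off, DispersionModel("nb2"))
        return GlobalDispersionFit(
            kind=kind,
            phi_gene=np.exp(res["coefs"][:, 0]),
            beta=res["beta"],
            log_pi=res["beta"] @ design.X.T,
            log_likelihood=float(res["loglik"].sum()),
        )

    if kind == "trended":
        phi_hat, log_pi_bar, beta0, _ = moment_dispersions(cm, design)
        pos = phi_hat > 0
        if pos.sum() < 50:
            raise ValueError("trended fit needs >= 50 genes with positive moment dispersion")
        from statsmodels.nonparametric.smoothers_lowess import lowess

        sm = lowess(np.log(phi_hat[pos]), log_pi_bar[pos], frac=span, return_sorted=True)
        xs, ys = sm[:, 0], sm[:, 1]

        def trend(logpi):
            return np.interp(logpi, xs, ys)

        phi_gene = np.exp(trend(log_pi_bar))
        beta, mu, ll = _batch_irls_phi(Y, d_off, phi_gene[:, None] * np.ones((1, n)), beta0)
        return GlobalDispersionFit(
            kind=kind, phi_gene=phi_gene, trend=trend, beta=beta,
            log_pi=beta @ design.X.T, log_likelihood=ll,
            meta={"span": span, "n_positive": int(pos.sum())},
        )

    if kind not in ("common", "nbp", "nbq"):
        raise ValueError(f"unknown dispersion model kind {kind!r}")

    # Parametric kinds: profile the summed log-likelihood over the
    # dispersion coefficients, re-running the batch IRLS for the betas at
    # every evaluation (warm-started).
    n_coef = {"common": 1, "nbp": 2, "nbq": 3}[kind]
    beta0, mu0, _ = _poisson_betas(cm, design)
    state = {"beta": beta0}
    center = float((beta0 @ design.X.T).mean())

    phi_start = np.maximum(
        (((Y - mu0) ** 2 - mu0).sum() / np.maximum((mu0**2).sum(), 1e-300)), 1e-4
    )

    def phi_of(coefs, log_pi):
        z = log_pi - center
        log_phi = coefs[0] + sum(coefs[k] * z**k for k in range(1, n_coef))
        return np.exp(np.clip(log_phi, -25.0, 12.0))

    def negprof(coefs):
        beta = state["beta"]
        for _ in range(3):
            log_pi = np.clip(beta @ design.X.T, -_ETA_CLIP, _ETA_CLIP)
            phi = phi_of(coefs, log_pi)
            beta, mu = _irls(Y, d_off.X, d_off.offset, phi, beta, n_iter=8)
        state["beta"] = beta
        log_pi = np.clip(beta @ design.X.T, -_ETA_CLIP, _ETA_CLIP)
        phi = phi_of(coefs, log_pi)
        return -float(_loglik(Y, mu, phi).sum())

    x0 = np.zeros(n_coef)
    x0[0] = np.log(phi_start)
    if n_coef == 1:
        r = optimize.minimize_scalar(
            lambda v: negprof(np.array([v])),
            bounds=(np.log(1e-8), np.log(1e4)), method="bounded",
            options={"xatol": 1e-7},
        )
        coefs = np.array([r.x])
        ll = -r.fun
    else:
        r = optimize.minimize(
            negprof, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-7, "maxiter": 600},
        )
        coefs = r.x
        ll = -r.fun
    beta = state["beta"]
    log_pi = beta @ design.X.T
    # Un-center the polynomial coefficients: a = J' c with the triangular
    # change of basis between polynomials in z and in u = z + center.
    J = np.eye(n_coef)
    if n_coef >= 2:
        J[1, 0] = -center
    if n_coef >= 3:
        J[2, 0] = center**2
        J[2, 1] = -2.0 * center
    a = J.T @ coefs
    meta = {}
    if dof_correction:
        a[0] += np.log(n / (n - design.p))
        meta["dof_correction"] = n / (n - design.p)
    if with_se:
        # Profile-likelihood covariance by finite-difference Hessian of the
        # centered coefficients, mapped to the raw scale.
        h = 1e-3
        H = np.zeros((n_coef, n_coef))
        f0 = negprof(coefs)
        for i in range(n_coef):
            for j in range(i, n_coef):
                ei = np.eye(n_coef)[i] * h
                ej = np.eye(n_coef)[j] * h
                if i == j:
                    H[i, i] = (negprof(coefs + ei) - 2 * f0 + negprof(coefs - ei)) / h**2
                else:
                    H[i, j] = H[j, i] = (
                        negprof(coefs + ei + ej)
                        - negprof(coefs + ei - ej)
                        - negprof(coefs - ei + ej)
                        + negprof(coefs - ei - ej)
                    ) / (4 * h**2)
        cov_c = np.linalg.inv(H)
        cov_a = J.T @ cov_c @ J
        meta["alpha_se"] = np.sqrt(np.maximum(np.diag(cov_a), 0.0))
        meta["alpha_cov"] = cov_a
    return GlobalDispersionFit(
        kind=kind, alpha=tuple(a), beta=beta, log_pi=log_pi,
        log_likelihood=float(ll), meta=meta,
    )


@dataclass
class MultiGeneGOFResult:
    """Per-gene GOF p-values and their Fisher combination."""

    gene_subset: list
    p_values: np.ndarray
    fisher_X2: float
    fisher_p: float
    qq: pd.DataFrame
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "m_star": len(self.p_values),
            "fisher_X2": self.fisher_X2,
            "fisher_p": self.fisher_p,
            "n_failed": self.n_failed,
        }


def fisher_combine(p: np.ndarray, R: Optional[int] = None) -> tuple:
    """Fisher's combined probability test.

    Returns ``(X2, p_combined)`` with ``X2 = -2 sum log p_i`` referred to a
    chi-square distribution with 2m degrees of freedom.  Zero p-values
    (impossible for Monte Carlo p-values) are clipped to ``1/(R+1)`` with a
    warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        floor = 1.0 / ((R or 999) + 1.0)
        logger.warning("NBDIAG-PCLIP: zero p-values clipped to %.3g", floor)
        p = np.maximum(p, floor)
    X2 = float(-2.0 * np.sum(np.log(p)))
    return X2, float(stats.chi2.sf(X2, 2 * p.size))


def uniform_qq(p: np.ndarray) -> pd.DataFrame:
    """Uniform QQ coordinates: ordered p-values vs (i - 0.5)/m positions."""
    p = np.sort(np.asarray(p, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    pos = (np.arange(1, p.size + 1) - 0.5) / p.size
    return pd.DataFrame({"theoretical": pos, "observed": p})


def plot_uniform_qq(p: np.ndarray, out, title: str = "") -> str:
    """Render the uniform QQ plot with a y = x reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qq = uniform_qq(p)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(qq["theoretical"], qq["observed"], "o", ms=3, color="black")
    ax.plot([0, 1], [0, 1], "-", color="tab:red", lw=1)
    ax.set_xlabel("uniform quantiles")
    ax.set_ylabel("ordered GOF p-values")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return str(out)


def per_gene_gof(
    cm: CountMatrix,
    design: DesignSpec,
    gfit: GlobalDispersionFit,
    m_star: int = 1000,
    R: int = 999,
    seed: Optional[int] = None,
    min_total: int = 1,
) -> MultiGeneGOFResult:
    """Per-gene Monte Carlo GOF under a global dispersion model.

    Samples ``m_star`` genes uniformly without replacement; for each, runs
    the single-gene GOF test with the gene's NB2 dispersions fixed at the
    global-model values (plug-in) while re-estimating the gene's
    regression coefficients in every Monte Carlo replicate.  Only the
    squared-vertical-distance p-values are collected; they are combined
    with Fisher's method.
    """
    cm = cm.filtered(min_total)
    if cm.m < m_star:
        raise ValueError(f"m_star={m_star} exceeds the {cm.m} genes available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(cm.m, size=m_star, replace=False)) if m_star < cm.m \
        else np.arange(cm.m)
    d = DesignSpec(design.X, cm.offset + (design.offset if design.offset is not None else 0))

    pvals, genes = [], []
    n_failed = 0
    for i in idx:
        phi_row = gfit.phi_for_gene(i)
        try:
            res = gof_test(
                cm.counts[i], d,
                DispersionModel("plugin", phi_values=phi_row),
                R=R, rng=rng,
            )
            pvals.append(res.p_vert)
            genes.append(cm.gene_ids[i])
        except (ValueError, FloatingPointError) as exc:  # e.g. degenerate gene
            n_failed += 1
            logger.warning("NBDIAG-GENEFAIL: gene %s skipped (%s)", cm.gene_ids[i], exc)
    if n_failed:
        logger.warning("NBDIAG-GENEFAIL: %d of %d genes excluded from Fisher combination",
                       n_failed, len(idx))
    pvals = np.asarray(pvals)
    X2, p_comb = fisher_combine(pvals, R=R)
    return MultiGeneGOFResult(
        gene_subset=genes,
        p_values=pvals,
        fisher_X2=X2,
        fisher_p=p_comb,
        qq=uniform_qq(pvals),
        n_failed=n_failed,
    )


def trend_exploration(
    cm: CountMatrix,
    design: DesignSpec,
    max_degree: int = 3,
    min_positive: int = 100,
) -> pd.DataFrame:
    """Polynomial gamma log-linear regression of moment dispersions on log pi.

    Quick-and-dirty quantification of the dispersion trend: fits gamma
    GLMs (log link) of the per-gene moment dispersion estimates on
    polynomials of log mean relative frequency for degrees 1..max_degree.
    Reports per-degree deviance-based percent of variability explained,
    the increment over the previous degree, and the Wald p-value of the
    highest-order term.
    """
    import statsmodels.api as sm_api

    phi_hat, log_pi_bar, _, _ = moment_dispersions(cm, design)
    pos = phi_hat > 0
    if pos.sum() < min_positive:
        raise ValueError(
            f"need >= {min_positive} genes with positive moment dispersions, "
            f"got {int(pos.sum())}"
        )
    y = phi_hat[pos]
    x = log_pi_bar[pos] - log_pi_bar[pos].mean()

    null = sm_api.GLM(y, np.ones((y.size, 1)),
                      family=sm_api.families.Gamma(sm_api.families.links.Log())).fit()
    rows = []
    prev_explained = 0.0
    for deg in range(1, max_degree + 1):
        Xp = np.column_stack([x**k for k in range(deg + 1)])
        fit = sm_api.GLM(y, Xp,
                         family=sm_api.families.Gamma(sm_api.families.links.Log())).fit()
        explained = 100.0 * (1.0 - fit.deviance / null.deviance)
        rows.append(
            {
                "degree": deg,
                "pct_explained": explained,
                "pct_additional": explained - prev_explained,
                "top_term_p": float(fit.pvalues[deg]),
                "deviance": float(fit.deviance),
            }
        )
        prev_explained = explained
    return pd.DataFrame(rows)


def plot_mean_dispersion(
    cm: CountMatrix,
    design: DesignSpec,
    fits: Sequence[GlobalDispersionFit],
    out,
) -> str:
    """Mean-dispersion scatter (log-log) with fitted dispersion models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phi_hat, log_pi_bar, _, _ = moment_dispersions(cm, design)
    pos = phi_hat > 0
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.plot(log_pi_bar[pos] / np.log(10), np.log10(phi_hat[pos]), ".",
            ms=2, alpha=0.4, color="gray", label="moment estimates")
    grid = np.linspace(log_pi_bar[pos].min(), log_pi_bar[pos].max(), 200)
    for f in fits:
        if f.kind in ("common", "nbp", "nbq"):
            a = f.alpha
            curve = np.full_like(grid, a[0]) + sum(
                a[k] * grid**k for k in range(1, len(a)))
        elif f.kind == "trended" and f.trend is not None:
            curve = f.trend(grid)
        else:
            continue
        ax.plot(grid / np.log(10), curve / np.log(10), lw=1.5, label=f.kind)
    ax.set_xlabel("log10 mean relative frequency")
    ax.set_ylabel("log10 NB2 dispersion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return str(out)
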