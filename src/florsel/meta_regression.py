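"""Across-population meta-regression of selection on herbivory intensity.

Each population contributes one summary point: its mean HP herbivory
intensity ``x`` (untransformed), a response ``y`` — either the opportunity
for selection ``I`` or the absolute herbivore-mediated gradient
``|delta_beta|`` — and, for gradient responses, a known sampling SE.

Two fitting routes mirror how each response is measured:

* **OLS with AIC** (models "A" linear / "B" quadratic) for the opportunity
  for selection, which is computed from a full census of each population
  and is therefore treated as free of sampling error;
* **Bayesian measurement-error regression with DIC** (models "C" linear /
  "D" quadratic) for ``|delta_beta|``, whose per-population sampling SE is
  known. The hierarchical model is ``y_j ~ N(theta_j, se_j^2)`` with
  ``theta_j ~ N(c0 + c1 x_j [+ c2 x_j^2], sigma2)``; all full conditionals
  are conjugate, so the posterior is sampled by Gibbs.

Because gradient differences can be negative, their absolute values are
the response; the matching sampling variance is recomputed from the
folded normal distribution of ``|X|``, X ~ N(delta_beta, SE^2).

A quadratic fit's vertex ``x* = -c1 / (2 c2)`` locates the herbivory
intensity at which the response peaks (when ``c2 < 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BayesianMetaRegression",
    "MetaFit",
    "MetaPoint",
    "NoVertexError",
    "OLSMetaRegression",
    "bayes_meta",
    "curve_vertex",
    "fold_points",
    "fold_value",
    "folded_moments",
    "ols_meta",
]


class NoVertexError(ValueError):
    """The fit has no quadratic curvature; the vertex is undefined."""


@dataclass(frozen=True)
class MetaPoint:
    """One population's (intensity, response, known sampling SE) summary."""

    x: float
    y: float
    se: float = 0.0
    population: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"intensity x must lie in [0, 1], got {self.x}")
        if self.se < 0:
            raise ValueError("sampling SE must be >= 0")


@dataclass
class MetaFit:
    """A fitted across-population model.

    ``coefficients`` are ``(c0, c1)`` or ``(c0, c1, c2)``; ``uncertainty``
    holds coefficient SEs (OLS) or 95% credible intervals of shape (k, 2)
    (Bayes); ``ic`` is the AIC or DIC; ``vertex`` is ``-c1/(2 c2)`` for
    quadratic fits with nonzero curvature, flagged as a maximum when
    ``c2 < 0``.
    """

    model: str  # "linear" | "quadratic"
    method: str  # "ols" | "bayes"
    coefficients: np.ndarray
    uncertainty: np.ndarray
    ic: float
    n: int
    vertex: float | None = None
    vertex_kind: str | None = None  # "maximum" | "minimum"
    p: float | None = None
    diagnostics: dict = field(default_factory=dict)


def folded_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and variance of |X| for X ~ Normal(mu, sigma^2).

    ``mean = sigma*sqrt(2/pi)*exp(-mu^2/(2 sigma^2)) + mu*(1 - 2*Phi(-mu/sigma))``
    and ``variance = mu^2 + sigma^2 - mean^2``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    ratio = mu / sigma
    mean = sigma * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * ratio**2) + mu * (
        1.0 - 2.0 * stats.norm.cdf(-ratio)
    )
    variance = mu**2 + sigma**2 - mean**2
    return float(mean), float(max(variance, 0.0))


def fold_value(delta: float, se: float) -> tuple[float, float]:
    """Absolute effect size with its folded-normal sampling SE.

    The response is ``|delta|`` (the absolute point estimate, not the
    folded mean); its sampling variance is the variance of
    ``|X|, X ~ N(delta, se^2)``.
    """
    _, var = folded_moments(delta, se)
    return abs(delta), float(np.sqrt(var))


def fold_points(
    estimates: Sequence,
    trait: str,
    intensity: Mapping[str, float],
) -> list[MetaPoint]:
    """Fold per-population mediated-selection contrasts into meta points.

    Parameters
    ----------
    estimates
        :class:`~florsel.anova_ancova.MediatedSelection` objects, one per
        population.
    trait
        Which trait's ``delta_beta`` to fold.
    intensity
        Population label -> mean HP herbivory intensity (the x axis).
    """
    if len(estimates) == 0:
        raise ValueError("no mediated-selection estimates supplied")
    points = []
    for est in estimates:
        y, se = fold_value(
            float(est.delta_beta[trait]), float(est.se[trait])
        )
        points.append(
            MetaPoint(
                x=float(intensity[est.population]),
                y=y,
                se=se,
                population=est.population,
            )
        )
    return points


def _design(x: np.ndarray, degree: int) -> np.ndarray:
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    cols = [np.ones_like(x), x] + ([x**2] if degree == 2 else [])
    return np.column_stack(cols)


def _vertex(coef: np.ndarray) -> tuple[float | None, str | None]:
    if len(coef) < 3 or coef[2] == 0.0:
        return None, None
    return float(-coef[1] / (2.0 * coef[2])), (
        "maximum" if coef[2] < 0 else "minimum"
    )


class OLSMetaRegression(RegressorMixin, BaseEstimator):
    """Polynomial OLS of a summary response on herbivory intensity.

    AIC is computed as ``n*ln(RSS/n) + 2k`` with ``k`` counting the
    regression coefficients plus the error variance; the additive Gaussian
    constant is shared by all candidate models at fixed n and dropped.

    Attributes
    ----------
    coef_ : ndarray, (degree+1,)
        ``(c0, c1[, c2])`` — intercept first.
    se_ : ndarray
        Coefficient standard errors.
    aic_ : float
    pvalue_ : float
        Overall regression F-test p-value.
    vertex_ : float or None
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) != len(y):
            raise ValueError("x and y have mismatched lengths")
        if len(x) < self.degree + 2:
            raise ValueError(
                f"need >= {self.degree + 2} points for degree {self.degree}"
            )
        design = _design(x, self.degree)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "design is rank-deficient (duplicated x values?)"
            )
        res = sm.OLS(y, design).fit()
        n = len(y)
        k = self.degree + 2  # coefficients + error variance
        self.coef_ = np.asarray(res.params)
        self.se_ = np.asarray(res.bse)
        rss = max(float(res.ssr), 1e-300)
        self.aic_ = float(n * np.log(rss / n) + 2 * k)
        self.pvalue_ = float(res.f_pvalue)
        self.vertex_, self.vertex_kind_ = _vertex(self.coef_)
        self.n_ = n
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return _design(x, self.degree) @ self.coef_


class BayesianMetaRegression(RegressorMixin, BaseEstimator):
    """Bayesian polynomial regression with known per-point sampling error.

    Model: ``y_j | theta_j ~ N(theta_j, se_j^2)`` (se_j fixed, known);
    ``theta_j ~ N(X_j c, sigma2)``; priors ``c ~ N(0, prior_coef_var * I)``
    and ``sigma2 ~ InvGamma(prior_ig_shape, prior_ig_scale)``. All full
    conditionals are conjugate and the posterior is explored by Gibbs
    sampling; runs are exactly reproducible for a fixed ``seed``.

    DIC uses the Spiegelhalter construction ``DIC = Dbar + pD`` with
    ``pD = Dbar - D(posterior means)``, where the deviance is evaluated on
    the marginal likelihood ``y_j ~ N(X_j c, sigma2 + se_j^2)`` (latent
    means integrated out) so that it reflects the regression part being
    compared.

    Attributes
    ----------
    coef_ : ndarray
        Posterior means of ``(c0, c1[, c2])``.
    ci_ : ndarray, (k, 2)
        Central 95% credible intervals.
    dic_, pd_ : float
    sigma2_ : float
        Posterior mean residual variance among latent means.
    rhat_, ess_ : ndarray
        Split-R-hat and bulk effective sample size per coefficient
        (R-hat is NaN with a single chain).
    converged_ : bool
        False when any coefficient R-hat exceeds 1.1 (a warning is
        emitted as well).
    """

    def __init__(
        self,
        degree: int = 2,
        n_chains: int = 2,
        n_iter: int = 13000,
        burn_in: int = 3000,
        thin: int = 10,
        prior_coef_var: float = 1e8,
        prior_ig_shape: float = 0.001,
        prior_ig_scale: float = 0.001,
        seed: int | None = None,
    ):
        self.degree = degree
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_coef_var = prior_coef_var
        self.prior_ig_shape = prior_ig_shape
        self.prior_ig_scale = prior_ig_scale
        self.seed = seed

    def _gibbs_chain(self, rng, design, y, se2):
        # Blocked Gibbs: (c, theta) are updated jointly — c is drawn from
        # its conditional with theta integrated out (y ~ N(Xc, sigma2 +
        # se^2) is Gaussian with known diagonal variance), then theta given
        # c. A naive one-at-a-time scan mixes arbitrarily slowly as
        # sigma2 -> 0, which is the operative regime when points carry
        # little residual scatter.
        n, k = design.shape
        prior_prec = np.eye(k) / self.prior_coef_var
        n_keep = (self.n_iter - self.burn_in) // self.thin
        coef_draws = np.empty((n_keep, k))
        sig2_draws = np.empty(n_keep)
        coef = np.linalg.lstsq(design, y, rcond=None)[0]
        sigma2 = max(float(np.var(y - design @ coef)), 1e-8)
        kept = 0
        for it in range(self.n_iter):
            # c | sigma2, y (theta marginalized): weighted least squares
            w = 1.0 / (sigma2 + se2)
            xtw = design.T * w
            prec = xtw @ design + prior_prec
            cov = np.linalg.inv(prec)
            mean = cov @ (xtw @ y)
            coef = rng.multivariate_normal(mean, cov, method="cholesky")
            # theta | c, sigma2, y
            mu_reg = design @ coef
            post_prec = 1.0 / se2.clip(min=1e-300) + 1.0 / sigma2
            post_mean = np.where(
                se2 > 0,
                (y / se2.clip(min=1e-300) + mu_reg / sigma2) / post_prec,
                y,
            )
            post_sd = np.where(se2 > 0, np.sqrt(1.0 / post_prec), 0.0)
            theta = post_mean + post_sd * rng.standard_normal(n)
            # sigma2 | theta, c
            resid = theta - mu_reg
            a = self.prior_ig_shape + 0.5 * n
            b = self.prior_ig_scale + 0.5 * float(resid @ resid)
            sigma2 = b / rng.gamma(a)
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                coef_draws[kept] = coef
                sig2_draws[kept] = sigma2
                kept += 1
        return coef_draws[:kept], sig2_draws[:kept]

    @staticmethod
    def _marginal_deviance(design, y, se2, coef, sigma2):
        var = sigma2 + se2
        resid = y - design @ coef
        return float(np.sum(np.log(2.0 * np.pi * var) + resid**2 / var))

    def fit(self, X, y, se=None):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        se = (
            np.zeros_like(y)
            if se is None
            else np.asarray(se, dtype=float).ravel()
        )
        if not (len(x) == len(y) == len(se)):
            raise ValueError("x, y, se have mismatched lengths")
        if len(x) < self.degree + 2:
            raise ValueError(
                f"need >= {self.degree + 2} points for degree {self.degree}"
            )
        if (se < 0).any():
            raise ValueError("sampling SEs must be >= 0")
        design = _design(x, self.degree)
        se2 = se**2

        root = np.random.SeedSequence(
            self.seed if self.seed is not None else 0
        )
        chains = []
        for child in root.spawn(self.n_chains):
            rng = np.random.default_rng(child)
            chains.append(self._gibbs_chain(rng, design, y, se2))
        coef_chains = np.stack([c for c, _ in chains])  # (chain, draw, k)
        sig2_chains = np.stack([s for _, s in chains])

        coef_flat = coef_chains.reshape(-1, design.shape[1])
        sig2_flat = sig2_chains.ravel()
        self.coef_ = coef_flat.mean(axis=0)
        self.ci_ = np.percentile(coef_flat, [2.5, 97.5], axis=0).T
        self.sigma2_ = float(sig2_flat.mean())

        devs = np.array(
            [
                self._marginal_deviance(design, y, se2, c, s)
                for c, s in zip(coef_flat, sig2_flat)
            ]
        )
        dbar = float(devs.mean())
        dhat = self._marginal_deviance(
            design, y, se2, self.coef_, self.sigma2_
        )
        self.pd_ = dbar - dhat
        self.dic_ = dbar + self.pd_

        names = [f"c{j}" for j in range(design.shape[1])]
        idata = az.from_dict(
            {nm: coef_chains[:, :, j] for j, nm in enumerate(names)}
        )
        if self.n_chains >= 2:
            rhat = az.rhat(idata)
            self.rhat_ = np.array([float(rhat[nm]) for nm in names])
        else:
            self.rhat_ = np.full(design.shape[1], np.nan)
        ess = az.ess(idata)
        self.ess_ = np.array([float(ess[nm]) for nm in names])
        self.converged_ = bool(
            np.all(np.isnan(self.rhat_)) or np.nanmax(self.rhat_) <= 1.1
        )
        if not self.converged_:
            warnings.warn(
                f"MCMC convergence suspect: max R-hat = {np.nanmax(self.rhat_):.3f}",
                RuntimeWarning,
                stacklevel=2,
            )
        self.vertex_, self.vertex_kind_ = _vertex(self.coef_)
        self.coef_draws_ = coef_chains
        self.n_ = len(y)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return _design(x, self.degree) @ self.coef_


def _points_to_arrays(points: Sequence[MetaPoint]):
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    se = np.array([p.se for p in points])
    return x, y, se


def ols_meta(points: Sequence[MetaPoint], degree: int) -> MetaFit:
    """OLS meta-regression (model "A" when linear, "B" when quadratic)."""
    x, y, _ = _points_to_arrays(points)
    est = OLSMetaRegression(degree=degree).fit(x, y)
    return MetaFit(
        model="linear" if degree == 1 else "quadratic",
        method="ols",
        coefficients=est.coef_,
        uncertainty=est.se_,
        ic=est.aic_,
        n=est.n_,
        vertex=est.vertex_,
        vertex_kind=est.vertex_kind_,
        p=est.pvalue_,
    )


def bayes_meta(
    points: Sequence[MetaPoint],
    degree: int,
    mcmc: dict | None = None,
    seed: int | None = None,
) -> MetaFit:
    """Bayesian meta-regression (model "C" linear, "D" quadratic).

    ``mcmc`` may override chain settings (``n_chains``, ``n_iter``,
    ``burn_in``, ``thin``, priors).
    """
    x, y, se = _points_to_arrays(points)
    est = BayesianMetaRegression(degree=degree, seed=seed, **(mcmc or {}))
    est.fit(x, y, se)
    return MetaFit(
        model="linear" if degree == 1 else "quadratic",
        method="bayes",
        coefficients=est.coef_,
        uncertainty=est.ci_,
        ic=est.dic_,
        n=est.n_,
        vertex=est.vertex_,
        vertex_kind=est.vertex_kind_,
        diagnostics={
            "p_d": est.pd_,
            "rhat": est.rhat_.tolist(),
            "ess": est.ess_.tolist(),
            "sigma2_resid": est.sigma2_,
            "converged": est.converged_,
        },
    )


def curve_vertex(fit) -> float:
    """Vertex ``x* = -c1 / (2 c2)`` of a quadratic fit or coefficient triple."""
    coef = (
        np.asarray(fit, dtype=float)
        if not isinstance(fit, MetaFit)
        else np.asarray(fit.coefficients, dtype=float)
    )
    if len(coef) < 3 or coef[2] == 0.0:
        raise NoVertexError("vertex requires a quadratic fit with c2 != 0")
    return float(-coef[1] / (2.0 * coef[2]))
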