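"""Lande-Arnold selection analysis per population x treatment slice.

Directional selection gradients ``beta_i`` are the partial regression
coefficients of relative fitness (individual seed set divided by the slice
mean) on variance-standardized traits; quadratic gradients ``gamma_ii``
are twice the squared-term coefficients and quantify stabilizing or
disruptive selection. The opportunity for selection ``I`` is the variance
of relative fitness and bounds the intensity of selection from above.

The regression is exposed as a scikit-learn style estimator
(:class:`SelectionGradientRegression`); :func:`selection_gradients` and
:func:`gradients_table` are thin wrappers that feed it standardized
population x treatment slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from sklearn.base import BaseEstimator, RegressorMixin

from florsel.data_model import TRAIT_COLUMNS, Dataset

#: Residual sum of squares below which the fit is treated as exact and
#: coefficient p-values are reported as undefined.
_EXACT_FIT_RSS = 1e-12

#: VIF thresholds: informational note at 1.8, multicollinearity warning at 5.
VIF_NOTE = 1.8
VIF_WARN = 5.0


class DegenerateSliceError(ValueError):
    """All fitness values are zero; relative fitness is undefined."""


class DegenerateTraitError(ValueError):
    """A trait has zero variance within the slice; names the trait."""


class InsufficientDataError(ValueError):
    """Too few plants for the requested statistic."""


class CollinearityError(ValueError):
    """The design matrix is rank-deficient; lists dependent columns."""


@dataclass
class StandardizedSlice:
    """Relative fitness and standardized traits of one pop x treatment slice."""

    relative_fitness: np.ndarray
    traits: np.ndarray  # (n, k), column order = trait_names
    trait_names: list[str]
    slice_key: tuple[str, str]

    @property
    def n(self) -> int:
        return len(self.relative_fitness)


@dataclass
class SelectionGradients:
    """Directional (and optionally quadratic) gradients for one slice."""

    beta: pd.Series  # index = trait names
    se: pd.Series
    p: pd.Series
    vif: pd.Series
    n: int
    slice_key: tuple[str, str]
    gamma: pd.Series | None = None
    gamma_se: pd.Series | None = None
    gamma_p: pd.Series | None = None


@dataclass
class OpportunityForSelection:
    """Variance of relative fitness (dimensionless) for one slice."""

    I: float
    n: int
    slice_key: tuple[str, str]


def relativize_fitness(seeds_total: Sequence[float]) -> np.ndarray:
    """Divide each fitness value by the group mean (output mean exactly 1)."""
    w = np.asarray(seeds_total, dtype=float)
    mean = w.mean()
    if mean <= 0:
        raise DegenerateSliceError(
            "cannot relativize fitness: group mean is zero (all fitness zero)"
        )
    return w / mean

def standardize_traits(
    values, names: Sequence[str] | None = None, reference=None
) -> np.ndarray:
    """Column-wise z-scores, (x - mean) / sd with the n-1 sample SD.

    ``reference`` optionally supplies the matrix whose moments are used
    (e.g. a whole population when slices should share a scale); by default
    each column is standardized by its own moments.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.ndim(values) == 1:
        x = x.T
    if x.shape[0] < 2:
        raise InsufficientDataError("standardization needs n >= 2")
    ref = x if reference is None else np.asarray(reference, dtype=float)
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        j = int(np.flatnonzero(sd <= 0)[0])
        label = names[j] if names is not None else f"column {j}"
        raise DegenerateTraitError(f"trait {label!r} has zero variance")
    return (x - mean) / sd


def standardize_slice(
    df: pd.DataFrame,
    slice_key: tuple[str, str],
    traits: Sequence[str] = tuple(TRAIT_COLUMNS),
    reference: pd.DataFrame | None = None,
) -> StandardizedSlice:
    """Build relative fitness + standardized traits for one slice.

    ``reference`` switches the trait (and fitness) moments to a wider frame,
    e.g. the whole population pooled over treatments; the default uses the
    slice's own moments, matching per-(population, treatment) analysis.
    """
    if reference is None:
        w = relativize_fitness(df["seeds_total"].to_numpy())
    else:
        ref_mean = reference["seeds_total"].to_numpy().mean()
        if ref_mean <= 0:
            raise DegenerateSliceError("reference mean fitness is zero")
        w = df["seeds_total"].to_numpy() / ref_mean
    z = standardize_traits(
        df[list(traits)].to_numpy(),
        names=list(traits),
        reference=None if reference is None else reference[list(traits)].to_numpy(),
    )
    return StandardizedSlice(
        relative_fitness=w,
        traits=z,
        trait_names=list(traits),
        slice_key=slice_key,
    )


def vif(design) -> np.ndarray:
    """Variance inflation factor per column of a predictor matrix.

    ``VIF_k = 1 / (1 - R^2_k)`` where ``R^2_k`` comes from regressing
    column k on the remaining columns (with intercept). Perfectly
    collinear columns are flagged with ``inf`` rather than raising.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("vif needs a matrix with >= 2 predictor columns")
    out = np.empty(x.shape[1])
    for k in range(x.shape[1]):
        others = sm.add_constant(np.delete(x, k, axis=1))
        r2 = sm.OLS(x[:, k], others).fit().rsquared
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def opportunity_for_selection(
    relative_fitness, slice_key: tuple[str, str] = ("", "")
) -> OpportunityForSelection:
    """Sample variance (n-1) of relative fitness."""
    w = np.asarray(relative_fitness, dtype=float)
    if len(w) < 2:
        raise InsufficientDataError("opportunity for selection needs n >= 2")
    return OpportunityForSelection(
        I=float(w.var(ddof=1)), n=len(w), slice_key=slice_key
    )


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, piv = qr(x, pivoting=True)
        dependent = sorted(names[j] for j in piv[rank:])
        raise CollinearityError(
            f"design matrix is rank-deficient; dependent column(s): "
            f"{', '.join(dependent)}"
        )


class SelectionGradientRegression(RegressorMixin, BaseEstimator):
    """Multiple regression of relative fitness on standardized traits.

    Parameters
    ----------
    include_quadratic : bool, default False
        Add squared-trait terms; quadratic gradients use the doubling
        convention ``gamma_ii = 2 * fitted coefficient``.
    trait_names : sequence of str, optional
        Labels for the columns of X; defaults to ``z0, z1, ...``.

    Attributes
    ----------
    beta_ : ndarray of shape (k,)
        Directional selection gradients (linear coefficients).
    se_, pvalues_ : ndarray
        Coefficient standard errors and two-sided t-test p-values
        (p is NaN when the fit is exact and the error variance is zero).
    gamma_, gamma_se_, gamma_pvalues_ : ndarray or None
        Quadratic gradients (doubled coefficients) when requested.
    vif_ : ndarray
        Variance inflation factor per model term (linear then quadratic).
    intercept_ : float
    n_ : int
    """

    def __init__(self, include_quadratic: bool = False, trait_names=None):
        self.include_quadratic = include_quadratic
        self.trait_names = trait_names

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and np.ndim(y) == 1 and len(y) > 1:
            X = X.T
        y = np.asarray(y, dtype=float)
        if X.shape[0] != len(y):
            raise ValueError("X and y have mismatched lengths")
        names = (
            list(self.trait_names)
            if self.trait_names is not None
            else [f"z{j}" for j in range(X.shape[1])]
        )
        if len(names) != X.shape[1]:
            raise ValueError("trait_names length must match number of columns")
        terms = X
        term_names = list(names)
        if self.include_quadratic:
            terms = np.column_stack([X, X**2])
            term_names += [f"{nm}^2" for nm in names]
        n, k = terms.shape
        if n <= k + 1:
            raise InsufficientDataError(
                f"need n > {k + 1} observations for {k} model terms, got {n}"
            )
        _check_rank(np.column_stack([np.ones(n), terms]), ["const"] + term_names)

        res = sm.OLS(y, sm.add_constant(terms)).fit()
        exact = res.ssr < _EXACT_FIT_RSS
        params, bse = res.params, res.bse
        pvals = np.full(k + 1, np.nan) if exact else np.asarray(res.pvalues)

        nk = len(names)
        self.intercept_ = float(params[0])
        self.beta_ = np.asarray(params[1 : nk + 1])
        self.se_ = np.asarray(bse[1 : nk + 1])
        self.pvalues_ = np.asarray(pvals[1 : nk + 1])
        if self.include_quadratic:
            self.gamma_ = 2.0 * np.asarray(params[nk + 1 :])
            self.gamma_se_ = 2.0 * np.asarray(bse[nk + 1 :])
            self.gamma_pvalues_ = np.asarray(pvals[nk + 1 :])
        else:
            self.gamma_ = self.gamma_se_ = self.gamma_pvalues_ = None
        self.vif_ = vif(terms) if k >= 2 else np.ones(k)
        self.term_names_ = term_names
        self.n_ = n
        self.residual_ss_ = float(res.ssr)
        self._coef_full = np.asarray(params)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        terms = np.column_stack([X, X**2]) if self.include_quadratic else X
        return self._coef_full[0] + terms @ self._coef_full[1:]


def selection_gradients(
    sl: StandardizedSlice, include_quadratic: bool = False
) -> SelectionGradients:
    """Fit the fitness regression on a standardized slice."""
    est = SelectionGradientRegression(
        include_quadratic=include_quadratic, trait_names=sl.trait_names
    ).fit(sl.traits, sl.relative_fitness)
    idx = pd.Index(sl.trait_names, name="trait")
    nk = len(sl.trait_names)
    return SelectionGradients(
        beta=pd.Series(est.beta_, index=idx),
        se=pd.Series(est.se_, index=idx),
        p=pd.Series(est.pvalues_, index=idx),
        vif=pd.Series(est.vif_[:nk], index=idx),
        n=est.n_,
        slice_key=sl.slice_key,
        gamma=None if est.gamma_ is None else pd.Series(est.gamma_, index=idx),
        gamma_se=None
        if est.gamma_se_ is None
        else pd.Series(est.gamma_se_, index=idx),
        gamma_p=None
        if est.gamma_pvalues_ is None
        else pd.Series(est.gamma_pvalues_, index=idx),
    )


def gradients_table(
    data: Dataset,
    traits: Sequence[str] = tuple(TRAIT_COLUMNS),
    include_quadratic: bool = False,
    pooled_standardization: bool = False,
) -> dict[tuple[str, str], SelectionGradients]:
    """Selection gradients for every population x treatment slice.

    ``pooled_standardization=True`` standardizes traits with each
    population's pooled (both-treatment) moments instead of slice moments.
    """
    data = data.flowering()
    out: dict[tuple[str, str], SelectionGradients] = {}
    for pop in data.populations():
        pooled = data.slice(pop) if pooled_standardization else None
        for trt in ("HP", "HE"):
            sl = standardize_slice(
                data.slice(pop, trt), (pop, trt), traits, reference=pooled
            )
            out[(pop, trt)] = selection_gradients(sl, include_quadratic)
    return out


def opportunity_table(
    data: Dataset,
) -> dict[tuple[str, str], OpportunityForSelection]:
    """Opportunity for selection for every population x treatment slice."""
    data = data.flowering()
    out = {}
    for pop in data.populations():
        for trt in ("HP", "HE"):
            sliced = data.slice(pop, trt)
            w = relativize_fitness(sliced["seeds_total"].to_numpy())
            out[(pop, trt)] = opportunity_for_selection(w, (pop, trt))
    return out
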