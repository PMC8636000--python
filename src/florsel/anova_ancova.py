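"""Two-way ANOVAs, ANCOVA interaction tests, and the mediated contrast.

Three related analyses of the paired-treatment design:

* two-way ANOVAs of each trait / fitness / intensity response on
  population, treatment and their interaction (on a variance-stabilizing
  transform scale);
* ANCOVAs of relative fitness on standardized traits with population and
  treatment factors — the trait x population x treatment term tests
  whether herbivore-mediated selection differs among populations, and a
  per-population trait x treatment term tests whether it is nonzero there;
* the herbivore-mediated selection contrast ``delta_beta = beta_HP -
  beta_HE`` per trait and population, with its root-sum-of-squares
  standard error ``sqrt(SE_HP^2 + SE_HE^2)``.

Sums of squares are sequential (Type I) by default, accumulated in the
exact order the model statement is written — all main effects, then all
two-way interactions, then the three-way interactions — so that
interaction F tests are conditioned on every lower-order term. A marginal
(Type II) option is available; the two coincide for balanced designs.
Each term's F is the nested-model identity
``((RSS_reduced - RSS_full) / delta_df) / (RSS_full / df_resid)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from florsel.data_model import TRAIT_COLUMNS, Dataset, intensity_column
from florsel.selection_core import SelectionGradients, standardize_slice


class DesignError(ValueError):
    """The factorial design cannot support the requested model."""


@dataclass
class AnovaTable:
    """Per-term ANOVA/ANCOVA results on the (possibly transformed) scale.

    ``terms`` has one row per model term (plus the residual) with columns
    ``name, df, ss, F, p, df_resid``.
    """

    terms: pd.DataFrame
    response: str
    transform: str = "none"
    ss_type: int = 1

    def p(self, name: str) -> float:
        """p-value of a term, matched on the cleaned term name."""
        row = self.terms[self.terms["name"] == name]
        if row.empty:
            raise KeyError(
                f"no term {name!r}; available: {list(self.terms['name'])}"
            )
        return float(row["p"].iloc[0])

    def F(self, name: str) -> float:
        row = self.terms[self.terms["name"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r}")
        return float(row["F"].iloc[0])


@dataclass
class MediatedSelection:
    """Herbivore-mediated selection contrast for one population.

    ``delta_beta`` is ``beta_HP - beta_HE`` per trait; ``se`` its
    root-sum-of-squares standard error. Two p-values are carried:
    ``p_interaction`` from the per-population trait x treatment ANCOVA
    term (authoritative) and ``p_z`` from the normal test of
    ``delta_beta / se`` (reported for comparison).
    """

    delta_beta: pd.Series
    se: pd.Series
    p_interaction: pd.Series | None
    p_z: pd.Series
    population: str
    n_hp: int = 0
    n_he: int = 0


def _clean_term(name: str) -> str:
    return name.replace("C(population_id)", "population").replace(
        "C(treatment)", "treatment"
    )


def _rss_rank(cols: list[np.ndarray], y: np.ndarray) -> tuple[float, int]:
    x = np.column_stack(cols)
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:  # rank-deficient path: residual not returned by lstsq
        rss = float(np.sum((y - x @ beta) ** 2))
    return rss, int(rank)


def sequential_anova(
    data: pd.DataFrame,
    response: str,
    term_exprs: Sequence[str],
    ss_type: int = 1,
) -> pd.DataFrame:
    """Per-term F table with terms entering in the order written.

    Each term's columns are built with full dummy coding and added to the
    running design; its degrees of freedom are the rank increase and its
    sum of squares the drop in residual SS (Type I). Type II instead
    compares the full model against the model with the term and every
    higher-order term containing it removed.
    """
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    term_cols = {
        expr: np.asarray(dmatrix(f"0 + {expr}", data)) for expr in term_exprs
    }
    base = [np.ones((n, 1))]
    rss_full, rank_full = _rss_rank(
        base + [term_cols[e] for e in term_exprs], y
    )
    df_resid = n - rank_full
    if df_resid <= 0:
        raise DesignError("model is saturated: no residual degrees of freedom")
    mse = rss_full / df_resid

    rows = []
    if ss_type == 1:
        cols = list(base)
        rss_prev, rank_prev = _rss_rank(cols, y)
        for expr in term_exprs:
            cols.append(term_cols[expr])
            rss_cur, rank_cur = _rss_rank(cols, y)
            df_t = rank_cur - rank_prev
            ss = rss_prev - rss_cur
            rows.append((expr, df_t, ss))
            rss_prev, rank_prev = rss_cur, rank_cur
    elif ss_type == 2:
        for expr in term_exprs:
            factors = set(expr.split(":"))
            # Reduced model: drop the term and everything containing it.
            keep = [
                e for e in term_exprs if not factors <= set(e.split(":"))
            ]
            rss_red, rank_red = _rss_rank(
                base + [term_cols[e] for e in keep], y
            )
            rss_with, rank_with = _rss_rank(
                base + [term_cols[e] for e in keep] + [term_cols[expr]], y
            )
            rows.append((expr, rank_with - rank_red, rss_red - rss_with))
    else:
        raise ValueError("ss_type must be 1 or 2")

    out = []
    for expr, df_t, ss in rows:
        if df_t <= 0:
            raise DesignError(
                f"term {expr!r} adds no estimable degrees of freedom "
                "(empty cell or aliased factor level)"
            )
        ss = max(ss, 0.0)  # guard float roundoff; SS is nonnegative
        f_stat = (ss / df_t) / mse
        out.append(
            {
                "name": _clean_term(expr),
                "df": float(df_t),
                "ss": float(ss),
                "F": float(f_stat),
                "p": float(stats.f.sf(f_stat, df_t, df_resid)),
                "df_resid": float(df_resid),
            }
        )
    out.append(
        {
            "name": "residual",
            "df": float(df_resid),
            "ss": float(rss_full),
            "F": np.nan,
            "p": np.nan,
            "df_resid": float(df_resid),
        }
    )
    return pd.DataFrame(out)


def _apply_transform(values: pd.Series, transform: str) -> tuple[pd.Series, str]:
    if transform == "none":
        return values.astype(float), "none"
    if transform == "sqrt":
        if (values < 0).any():
            raise DesignError("sqrt transform needs nonnegative values")
        return np.sqrt(values.astype(float)), "sqrt"
    if transform == "log10":
        v = values.astype(float)
        if (v < 0).any():
            raise DesignError("log10 transform needs nonnegative values")
        # Counts that can be zero (fruits, seeds) get a +1 offset.
        if (v == 0).any():
            return np.log10(v + 1.0), "log10(x+1)"
        return np.log10(v), "log10"
    raise ValueError(f"unknown transform {transform!r}")


def two_way_anova(
    data: Dataset, response: str, transform: str = "none", ss_type: int = 1
) -> AnovaTable:
    """Two-way ANOVA: response ~ population + treatment + interaction.

    ``response`` is any plant-table column or ``"herbivory_intensity"``
    (computed per plant over its flowers). ``transform`` is one of
    ``none``, ``log10`` (with a +1 offset when zeros are present) and
    ``sqrt``, applied before fitting.
    """
    data = data.flowering()
    df = data.df.copy()
    if response == "herbivory_intensity":
        df[response] = intensity_column(df)
    elif response not in df.columns:
        raise KeyError(f"unknown response {response!r}")
    for factor in ("population_id", "treatment"):
        if df[factor].nunique() < 2:
            raise DesignError(f"factor {factor!r} has a single level")
    df["_y"], tname = _apply_transform(df[response], transform)
    terms = [
        "C(population_id)",
        "C(treatment)",
        "C(population_id):C(treatment)",
    ]
    table = sequential_anova(df, "_y", terms, ss_type)
    return AnovaTable(table, response, tname, ss_type)


def _standardized_long_frame(
    data: Dataset, traits: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Stack slice-standardized (w, z) rows over populations x treatments."""
    data = data.flowering()
    zcols = [f"z_{t}" for t in traits]
    parts = []
    for pop in data.populations():
        for trt in ("HP", "HE"):
            sliced = data.slice(pop, trt)
            sl = standardize_slice(sliced, (pop, trt), traits)
            part = pd.DataFrame(sl.traits, columns=zcols)
            part["w"] = sl.relative_fitness
            part["population_id"] = pop
            part["treatment"] = trt
            parts.append(part)
    return pd.concat(parts, ignore_index=True), zcols


def ancova_variation(
    data: Dataset,
    scope: str = "mediated_full",
    traits: Sequence[str] = tuple(TRAIT_COLUMNS),
    ss_type: int = 1,
) -> AnovaTable:
    """ANCOVA tests for spatial / treatment variation in selection.

    ``scope="mediated_full"`` fits, on both treatments,
    ``w ~ traits + population + treatment + trait:population +
    trait:treatment + trait:population:treatment``; a significant
    trait x population x treatment term for a trait means
    herbivore-mediated selection on it varies among populations.

    ``scope="net_HP_only"`` fits, on HP plants only,
    ``w ~ traits + population + trait:population``; the trait x population
    terms test spatial variation in net directional selection.

    Relative fitness and standardized traits are computed slice-wise
    (per population x treatment) before pooling, and terms enter in the
    order written above (mains, then two-way, then three-way).
    """
    long, zcols = _standardized_long_frame(data, traits)
    if scope == "net_HP_only":
        long = long[long["treatment"] == "HP"].reset_index(drop=True)
        if long["population_id"].nunique() < 2:
            raise DesignError("need >= 2 populations")
        terms = (
            zcols
            + ["C(population_id)"]
            + [f"{z}:C(population_id)" for z in zcols]
        )
    elif scope == "mediated_full":
        counts = long.groupby(["population_id", "treatment"]).size()
        for pop in long["population_id"].unique():
            for trt in ("HP", "HE"):
                if (pop, trt) not in counts.index:
                    raise DesignError(f"empty cell ({pop}, {trt})")
        terms = (
            zcols
            + ["C(population_id)", "C(treatment)"]
            + [f"{z}:C(population_id)" for z in zcols]
            + [f"{z}:C(treatment)" for z in zcols]
            + [f"{z}:C(population_id):C(treatment)" for z in zcols]
        )
    else:
        raise ValueError("scope must be 'mediated_full' or 'net_HP_only'")
    table = sequential_anova(long, "w", terms, ss_type)
    return AnovaTable(table, "relative_fitness", "none", ss_type)


def per_population_ancova(
    data: Dataset,
    population: str,
    traits: Sequence[str] = tuple(TRAIT_COLUMNS),
    ss_type: int = 1,
) -> AnovaTable:
    """Within one population: w ~ traits + treatment + trait:treatment.

    The trait x treatment term is the per-population significance test of
    herbivore-mediated selection on that trait.
    """
    sub = Dataset.__new__(Dataset)
    sub.df = data.flowering().slice(population).reset_index(drop=True)
    sub.metadata = {}
    long, zcols = _standardized_long_frame(sub, traits)
    terms = (
        zcols + ["C(treatment)"] + [f"{z}:C(treatment)" for z in zcols]
    )
    table = sequential_anova(long, "w", terms, ss_type)
    return AnovaTable(table, "relative_fitness", "none", ss_type)


def mediated_selection(
    grad_hp: SelectionGradients,
    grad_he: SelectionGradients,
    p_from: AnovaTable | None = None,
) -> MediatedSelection:
    """Herbivore-mediated contrast ``delta_beta = beta_HP - beta_HE``.

    ``p_from`` is the population's trait x treatment ANCOVA (from
    :func:`per_population_ancova`); when given, its interaction p-values
    are attached per trait. A z-test of ``delta_beta / se`` is always
    reported alongside.
    """
    if list(grad_hp.beta.index) != list(grad_he.beta.index):
        raise ValueError(
            "mismatched trait sets: "
            f"{list(grad_hp.beta.index)} vs {list(grad_he.beta.index)}"
        )
    if grad_hp.slice_key[0] != grad_he.slice_key[0]:
        raise ValueError(
            "gradients come from different populations: "
            f"{grad_hp.slice_key[0]!r} vs {grad_he.slice_key[0]!r}"
        )
    delta = grad_hp.beta - grad_he.beta
    se = np.sqrt(grad_hp.se**2 + grad_he.se**2)
    z = delta / se.replace(0.0, np.nan)
    p_z = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=delta.index)
    p_int = None
    if p_from is not None:
        p_int = pd.Series(
            {t: p_from.p(f"z_{t}:treatment") for t in delta.index},
            name="p_interaction",
        )
    return MediatedSelection(
        delta_beta=delta,
        se=se,
        p_interaction=p_int,
        p_z=p_z,
        population=grad_hp.slice_key[0],
        n_hp=grad_hp.n,
        n_he=grad_he.n,
    )
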