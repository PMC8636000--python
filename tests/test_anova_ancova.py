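"""Factorial ANOVAs, ANCOVA interaction tests, and the mediated contrast."""

import numpy as np
import pandas as pd
import pytest

from florsel.anova_ancova import (
    AnovaTable,
    DesignError,
    ancova_variation,
    mediated_selection,
    per_population_ancova,
    sequential_anova,
    two_way_anova,
)
from florsel.data_model import Dataset
from florsel.selection_core import SelectionGradients, gradients_table
from florsel.synthetic_data import SimulationConfig, simulate_study


def _factorial_frame(cell_values):
    """Plant-table frame with a prescribed seeds_total pattern per cell."""
    rows = []
    for (pop, trt), values in cell_values.items():
        for i, v in enumerate(values):
            rows.append(
                dict(
                    population_id=pop,
                    pair_id=f"pair{i + 1}",
                    treatment=trt,
                    flowering_start=180 + i,
                    n_flowers=20,
                    corolla_size=28.0 + i,
                    n_fruits=10,
                    seeds_per_fruit=v / 10,
                    seeds_total=float(v),
                    n_damaged_flowers=2 if trt == "HP" else 0,
                )
            )
    return Dataset(pd.DataFrame(rows))


def manual_sequential_oracle(df, y_col, dummy_builders):
    """Brute-force sequential SS with hand-built dummy columns and
    projection via pseudo-inverse — independent of the patsy machinery."""
    y = df[y_col].to_numpy(float)
    n = len(y)

    def rss(mat):
        proj = mat @ np.linalg.pinv(mat)
        r = y - proj @ y
        return float(r @ r), int(np.round(np.trace(proj)))

    cols = [np.ones((n, 1))]
    rss_prev, rank_prev = rss(np.column_stack(cols))
    steps = []
    for build in dummy_builders:
        cols.append(build(df))
        rss_cur, rank_cur = rss(np.column_stack(cols))
        steps.append((rss_prev - rss_cur, rank_cur - rank_prev))
        rss_prev, rank_prev = rss_cur, rank_cur
    df_resid = n - rank_prev
    mse = rss_prev / df_resid
    return [(ss / dfree) / mse for ss, dfree in steps]


def _dummies(col):
    def build(df):
        return pd.get_dummies(df[col]).to_numpy(float)

    return build


def _interaction(col_a, col_b):
    def build(df):
        d = pd.get_dummies(df[col_a].astype(str) + "|" + df[col_b].astype(str))
        return d.to_numpy(float)

    return build


class TestTwoWayAnova:
    def test_identical_cells_give_zero_f(self):
        base = [100.0, 140.0, 180.0]
        data = _factorial_frame(
            {(p, t): base for p in ("p1", "p2") for t in ("HP", "HE")}
        )
        table = two_way_anova(data, "seeds_total")
        for term in ("population", "treatment", "population:treatment"):
            assert table.F(term) == pytest.approx(0.0, abs=1e-9)
            assert table.p(term) == pytest.approx(1.0)

    def test_pure_treatment_shift_detected(self):
        rng = np.random.default_rng(5)
        cells = {}
        for p in ("p1", "p2"):
            noise = rng.normal(0, 5, 12)
            cells[(p, "HP")] = list(100 + noise)
            cells[(p, "HE")] = list(160 + noise)  # shift, no interaction
        table = two_way_anova(_factorial_frame(cells), "seeds_total")
        assert table.p("treatment") < 1e-6
        assert table.p("population:treatment") > 0.2

    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(9)
        cells = {
            (p, t): list(rng.gamma(4, 30, 3))
            for p in ("p1", "p2")
            for t in ("HP", "HE")
        }
        data = _factorial_frame(cells)  # 12 rows
        table = two_way_anova(data, "seeds_total")
        oracle = manual_sequential_oracle(
            data.df,
            "seeds_total",
            [
                _dummies("population_id"),
                _dummies("treatment"),
                _interaction("population_id", "treatment"),
            ],
        )
        got = [
            table.F("population"),
            table.F("treatment"),
            table.F("population:treatment"),
        ]
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_log10_offset_applied_when_zeros(self):
        cells = {
            (p, t): [0.0, 50.0, 100.0]
            for p in ("p1", "p2")
            for t in ("HP", "HE")
        }
        table = two_way_anova(_factorial_frame(cells), "seeds_total", "log10")
        assert table.transform == "log10(x+1)"

    def test_sqrt_rejects_negative(self, small_study):
        df = small_study.df.copy()
        df.loc[0, "seeds_per_fruit"] = -1.0
        with pytest.raises(Exception):
            two_way_anova(Dataset(df), "seeds_per_fruit", "sqrt")

    def test_single_level_factor_rejected(self):
        cells = {("p1", t): [1.0, 2.0, 3.0] for t in ("HP", "HE")}
        rows = _factorial_frame(cells)
        with pytest.raises(DesignError, match="single level"):
            two_way_anova(rows, "seeds_total")

    def test_herbivory_intensity_response(self, small_study):
        table = two_way_anova(small_study, "herbivory_intensity", "sqrt")
        # exclusion is the dominant effect by construction
        assert table.p("treatment") < 1e-10

    def test_type2_equals_type1_when_balanced(self):
        rng = np.random.default_rng(3)
        cells = {
            (p, t): list(rng.gamma(4, 30, 5))
            for p in ("p1", "p2", "p3")
            for t in ("HP", "HE")
        }
        data = _factorial_frame(cells)
        t1 = two_way_anova(data, "seeds_total", ss_type=1)
        t2 = two_way_anova(data, "seeds_total", ss_type=2)
        for term in ("population", "treatment", "population:treatment"):
            assert t1.F(term) == pytest.approx(t2.F(term), rel=1e-10)


class TestAncovaVariation:
    @pytest.fixture(scope="class")
    def study(self):
        return simulate_study(
            SimulationConfig(n_populations=3, pairs_per_population=50, seed=23)
        )

    def test_mediated_full_terms_present(self, study):
        table = ancova_variation(study, "mediated_full")
        names = set(table.terms["name"])
        for t in ("flowering_start", "n_flowers", "corolla_size"):
            assert f"z_{t}" in names
            assert f"z_{t}:population" in names
            assert f"z_{t}:treatment" in names
            assert f"z_{t}:population:treatment" in names

    def test_three_way_df(self, study):
        table = ancova_variation(study, "mediated_full")
        row = table.terms[table.terms["name"] == "z_n_flowers:population:treatment"]
        assert float(row["df"].iloc[0]) == 2.0  # (3 pops - 1) x (2 trt - 1)

    def test_net_hp_only_df(self, study):
        table = ancova_variation(study, "net_HP_only")
        row = table.terms[table.terms["name"] == "z_flowering_start:population"]
        assert float(row["df"].iloc[0]) == 2.0

    def test_nested_rss_identity(self, study):
        """F of the last-entered term equals the nested-model formula."""
        from florsel.anova_ancova import _standardized_long_frame

        long, zcols = _standardized_long_frame(study, ["n_flowers"])
        terms = ["z_n_flowers", "C(treatment)", "z_n_flowers:C(treatment)"]
        table = sequential_anova(long, "w", terms)
        from patsy import dmatrix

        def rss_of(exprs):
            mats = [np.ones((len(long), 1))] + [
                np.asarray(dmatrix(f"0 + {e}", long)) for e in exprs
            ]
            x = np.column_stack(mats)
            beta, _, rank, _ = np.linalg.lstsq(x, long["w"], rcond=None)
            r = long["w"].to_numpy() - x @ beta
            return float(r @ r), rank

        rss_red, _ = rss_of(terms[:2])
        rss_full, rank_full = rss_of(terms)
        df_resid = len(long) - rank_full
        f_expected = ((rss_red - rss_full) / 1.0) / (rss_full / df_resid)
        row = table[table["name"] == "z_n_flowers:treatment"]
        assert float(row["F"].iloc[0]) == pytest.approx(f_expected, rel=1e-10)

    def test_bad_scope_rejected(self, study):
        with pytest.raises(ValueError, match="scope"):
            ancova_variation(study, "everything")

    def test_spatially_varying_selection_detection_power(self):
        """A single population whose herbivores prefer many-flowered
        plants much more strongly (frozen effect: b_flowers = 2.0 there,
        0 elsewhere; 3 populations x 80 pairs) lights up the three-way
        interaction in the large majority of replicates."""
        hits = 0
        n_rep = 60
        for r in range(n_rep):
            quiet = simulate_study(
                SimulationConfig(
                    n_populations=3, pairs_per_population=80,
                    attack_preference=(0.0, 0.0, 0.0), seed=300_000 + r,
                )
            )
            loud = simulate_study(
                SimulationConfig(
                    n_populations=3, pairs_per_population=80,
                    attack_preference=(2.0, 0.0, 0.0), seed=300_000 + r,
                )
            )
            # splice: populations 1-2 without preference, population 3 with
            df = pd.concat(
                [
                    quiet.df[quiet.df["population_id"] != "pop3"],
                    loud.df[loud.df["population_id"] == "pop3"],
                ],
                ignore_index=True,
            )
            table = ancova_variation(Dataset(df), "mediated_full")
            hits += table.p("z_n_flowers:population:treatment") < 0.05
        assert hits / n_rep > 0.8


class TestMediatedSelection:
    def _grad(self, pop, trt, beta, se):
        idx = pd.Index(["flowering_start", "n_flowers"], name="trait")
        return SelectionGradients(
            beta=pd.Series(beta, index=idx),
            se=pd.Series(se, index=idx),
            p=pd.Series([0.5, 0.5], index=idx),
            vif=pd.Series([1.0, 1.0], index=idx),
            n=50,
            slice_key=(pop, trt),
        )

    def test_three_four_five_se(self):
        hp = self._grad("p1", "HP", [0.5, 0.2], [0.3, 0.3])
        he = self._grad("p1", "HE", [0.1, 0.2], [0.4, 0.4])
        med = mediated_selection(hp, he)
        assert med.se["flowering_start"] == pytest.approx(0.5, abs=1e-15)

    def test_equal_gradients_give_zero(self):
        g = self._grad("p1", "HP", [0.3, -0.1], [0.1, 0.1])
        h = self._grad("p1", "HE", [0.3, -0.1], [0.2, 0.2])
        med = mediated_selection(g, h)
        assert (med.delta_beta == 0).all()

    def test_antisymmetry_and_se_symmetry(self):
        hp = self._grad("p1", "HP", [0.479, 0.2], [0.06, 0.1])
        he = self._grad("p1", "HE", [0.349, -0.1], [0.082, 0.2])
        fwd = mediated_selection(hp, he)
        rev = mediated_selection(he, hp)
        pd.testing.assert_series_equal(fwd.delta_beta, -rev.delta_beta)
        pd.testing.assert_series_equal(fwd.se, rev.se)
        assert fwd.delta_beta["flowering_start"] == pytest.approx(0.130)

    def test_propagated_se_dominates_components(self):
        hp = self._grad("p1", "HP", [0.1, 0.1], [0.25, 0.11])
        he = self._grad("p1", "HE", [0.0, 0.0], [0.13, 0.02])
        med = mediated_selection(hp, he)
        assert (med.se >= hp.se).all() and (med.se >= he.se).all()

    def test_trait_mismatch_rejected(self):
        hp = self._grad("p1", "HP", [0.1, 0.1], [0.1, 0.1])
        he = self._grad("p1", "HE", [0.1, 0.1], [0.1, 0.1])
        he.beta.index = pd.Index(["a", "b"], name="trait")
        with pytest.raises(ValueError, match="mismatched trait"):
            mediated_selection(hp, he)

    def test_population_mismatch_rejected(self):
        hp = self._grad("p1", "HP", [0.1, 0.1], [0.1, 0.1])
        he = self._grad("p2", "HE", [0.1, 0.1], [0.1, 0.1])
        with pytest.raises(ValueError, match="different populations"):
            mediated_selection(hp, he)

    def test_interaction_p_wired_from_ancova(self, small_study):
        grads = gradients_table(small_study)
        pop = small_study.populations()[0]
        anc = per_population_ancova(small_study, pop)
        med = mediated_selection(grads[(pop, "HP")], grads[(pop, "HE")], anc)
        assert med.p_interaction is not None
        for trait in med.delta_beta.index:
            assert 0.0 <= med.p_interaction[trait] <= 1.0
            assert med.p_interaction[trait] == anc.p(f"z_{trait}:treatment")
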