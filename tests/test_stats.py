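"""GLM decoupling, post-hoc contrasts, line comparison, clustering, tSNE."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from memascope.design import (
    ComponentClass,
    Design,
    MicroenvironmentComponent,
    MicroenvironmentCondition,
)
from memascope.stats import (
    SeparationError,
    StatsError,
    compare_lines,
    embed_conditions,
    fit_component_glm,
    posthoc_contrasts,
    rank_factor_effects,
    zscore_cluster,
)
from memascope.synthetic import ConditionEffectModel, simulate_spot_counts


def _ecm_design(levels=("COL1", "COL4", "LAM1", "LAM5x")):
    comps = {
        name: MicroenvironmentComponent(name, ComponentClass.ECM, 100.0)
        for name in levels
    }
    conds = [MicroenvironmentCondition(f"{n}|", frozenset({n})) for n in levels]
    return Design(components=comps, conditions=conds)


def _spots(design, probs, replicates=10, cells=200, seed=0):
    model = ConditionEffectModel(baseline_logit=0.0, component_effects={})
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for cond in design.conditions:
        p = probs[cond.condition_id]
        for _ in range(replicates):
            n = int(rng.poisson(cells))
            k = int(rng.binomial(n, p)) if n else 0
            rows.append(
                {"spot_index": i, "condition_id": cond.condition_id, "n_cells": n, "n_double_positive": k}
            )
            i += 1
    return pd.DataFrame(rows)


class TestFitComponentGlm:
    def test_two_level_mle_matches_grid_search_oracle(self):
        """Brute-force oracle: direct minimization of the binomial negative
        log-likelihood over (intercept, effect) matches the IRLS fit."""
        design = _ecm_design(("COL1", "COL4"))
        spots = _spots(design, {"COL1|": 0.4, "COL4|": 0.12}, replicates=6, cells=80, seed=3)
        fit = fit_component_glm(spots, design)

        k = spots["n_double_positive"].to_numpy()
        n = spots["n_cells"].to_numpy()
        x = (spots["condition_id"] == "COL1|").to_numpy(float)

        def nll(theta):
            eta = theta[0] + theta[1] * x
            return -np.sum(k * eta - n * np.logaddexp(0.0, eta))

        oracle = minimize(nll, [0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
        assert fit.params["Intercept"] == pytest.approx(oracle.x[0], abs=1e-3)
        assert fit.params["ecm[COL1]"] == pytest.approx(oracle.x[1], abs=1e-3)

    def test_aggregation_sufficiency(self):
        """Binomial sufficiency: pooling a condition's spots into one row
        leaves the coefficient estimates unchanged (to 1e-6)."""
        design = _ecm_design(("COL1", "COL4"))
        spots = _spots(design, {"COL1|": 0.35, "COL4|": 0.1}, replicates=8, cells=100, seed=4)
        agg = (
            spots.groupby("condition_id", as_index=False)[["n_cells", "n_double_positive"]]
            .sum()
            .assign(spot_index=lambda d: range(len(d)))
        )
        # pooled rows need >=2 per level for the precondition; duplicate halves
        half1 = spots[spots["spot_index"] % 2 == 0]
        half2 = spots[spots["spot_index"] % 2 == 1]
        pooled = pd.concat(
            [
                h.groupby("condition_id", as_index=False)[["n_cells", "n_double_positive"]].sum()
                for h in (half1, half2)
            ],
            ignore_index=True,
        ).assign(spot_index=lambda d: range(len(d)))
        f_spot = fit_component_glm(spots, design)
        f_pool = fit_component_glm(pooled, design)
        for term in f_spot.params.index:
            assert f_spot.params[term] == pytest.approx(f_pool.params[term], abs=1e-6)

    def test_single_condition_rejected(self):
        design = _ecm_design(("COL1",))
        spots = _spots(design, {"COL1|": 0.3}, replicates=4, cells=50)
        with pytest.raises(StatsError, match="ECM levels"):
            fit_component_glm(spots, design)

    def test_null_coefficients_within_two_se(self):
        """Under a shared planted probability, non-intercept estimates stay
        within 2 SE of zero in at least 90% of simulations."""
        design = _ecm_design()
        probs = {c.condition_id: 0.2 for c in design.conditions}
        ok = 0
        n_sims = 100
        for s in range(n_sims):
            spots = _spots(design, probs, replicates=8, cells=150, seed=1000 + s)
            fit = fit_component_glm(spots, design)
            non_int = [t for t in fit.params.index if t != "Intercept"]
            if all(abs(fit.params[t]) <= 2 * fit.bse[t] for t in non_int):
                ok += 1
        assert ok >= 0.90 * n_sims

    def test_separation_raises_and_firth_recovers(self):
        design = _ecm_design(("COL1", "COL4"))
        spots = pd.DataFrame(
            {
                "spot_index": range(8),
                "condition_id": ["COL1|"] * 4 + ["COL4|"] * 4,
                "n_cells": [30] * 8,
                "n_double_positive": [30, 30, 30, 30, 0, 0, 0, 0],
            }
        )
        with pytest.raises(SeparationError, match="firth"):
            fit_component_glm(spots, design)
        fit = fit_component_glm(spots, design, method="firth")
        assert np.isfinite(fit.params).all()
        assert abs(fit.params["ecm[COL1]"]) < 15


class TestPosthocContrasts:
    @pytest.fixture(scope="class")
    def four_level_fit(self):
        design = _ecm_design()
        probs = {"COL1|": 0.4, "COL4|": 0.12, "LAM1|": 0.25, "LAM5x|": 0.2}
        spots = _spots(design, probs, replicates=10, cells=200, seed=7)
        return design, fit_component_glm(spots, design)

    def test_six_rows_for_four_levels(self, four_level_fit):
        _, fit = four_level_fit
        table = posthoc_contrasts(fit)
        assert len(table) == 6
        assert set(table.columns) >= {"pair", "estimate", "adjusted_p", "significant"}

    def test_contrast_triangle_consistency(self, four_level_fit):
        """est(A-B) = est(A-C) - est(B-C) for every level triple, which
        implies antisymmetry est(A-B) = -est(B-A)."""
        _, fit = four_level_fit
        table = posthoc_contrasts(fit).set_index("pair")["estimate"]
        levels = sorted(fit.ecm_levels)

        def est(a, b):
            if f"{a}-{b}" in table.index:
                return table[f"{a}-{b}"]
            return -table[f"{b}-{a}"]

        for a in levels:
            for b in levels:
                if a == b:
                    continue
                for c in levels:
                    if c in (a, b):
                        continue
                    assert est(a, b) == pytest.approx(est(a, c) - est(b, c), abs=1e-10)

    def test_contrast_matches_direct_coefficient(self, four_level_fit):
        _, fit = four_level_fit
        table = posthoc_contrasts(fit).set_index("pair")["estimate"]
        assert table["COL1-COL4"] == pytest.approx(fit.params["ecm[COL1]"])

    def test_adjusted_p_monotone_in_z(self, four_level_fit):
        _, fit = four_level_fit
        table = posthoc_contrasts(fit)
        z = (table["estimate"] / table["se"]).abs()
        order = np.argsort(-z.to_numpy())
        p_sorted = table["adjusted_p"].to_numpy()[order]
        assert (np.diff(p_sorted) >= -1e-12).all()

    def test_two_levels_minimum(self):
        design = _ecm_design(("COL1", "COL4"))
        spots = _spots(design, {"COL1|": 0.4, "COL4|": 0.1}, seed=2)
        fit = fit_component_glm(spots, design)
        assert len(posthoc_contrasts(fit)) == 1


class TestRankFactorEffects:
    def test_planted_factors_rank_top(self, small_design, effect_model):
        spots = simulate_spot_counts(small_design, effect_model, replicates=8, cells_per_spot=120, seed=13)
        fit = fit_component_glm(spots, small_design)
        ranking = rank_factor_effects(fit)
        assert set(ranking.head(3)["factor"]) == {"OPN", "IL-8", "COL6A3"}

    def test_no_factor_terms_error(self):
        design = _ecm_design(("COL1", "COL4"))
        spots = _spots(design, {"COL1|": 0.4, "COL4|": 0.1}, seed=2)
        fit = fit_component_glm(spots, design)
        with pytest.raises(StatsError, match="factor"):
            rank_factor_effects(fit)

    def test_sparse_factor_excluded_with_warning(self, caplog):
        comps = {
            "COL1": MicroenvironmentComponent("COL1", ComponentClass.ECM, 100.0),
            "COL4": MicroenvironmentComponent("COL4", ComponentClass.ECM, 100.0),
            "OPN": MicroenvironmentComponent("OPN", ComponentClass.SOLUBLE, 1.0),
        }
        conds = [
            MicroenvironmentCondition("COL1|", frozenset({"COL1"})),
            MicroenvironmentCondition("COL4|", frozenset({"COL4"})),
            MicroenvironmentCondition("COL1|OPN", frozenset({"COL1"}), frozenset({"OPN"})),
        ]
        design = Design(components=comps, conditions=conds)
        spots = pd.DataFrame(
            {
                "spot_index": range(9),
                "condition_id": ["COL1|"] * 4 + ["COL4|"] * 4 + ["COL1|OPN"],
                "n_cells": [100] * 9,
                "n_double_positive": [40, 38, 42, 41, 10, 12, 11, 9, 55],
            }
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="memascope.stats"):
            fit = fit_component_glm(spots, design)
        assert "OPN" not in fit.factor_names
        assert any("OPN" in rec.message for rec in caplog.records)


class TestCompareLines:
    def _paired_spots(self, shift_col1=0.0, seed=0):
        design = _ecm_design()
        base = {"COL1|": 0.3, "COL4|": 0.1, "LAM1|": 0.2, "LAM5x|": 0.15}
        logit = lambda p: np.log(p / (1 - p))
        shifted = {
            cid: float(expit(logit(p) + (shift_col1 if cid == "COL1|" else 0.0)))
            for cid, p in base.items()
        }
        a = _spots(design, base, replicates=10, cells=150, seed=seed)
        b = _spots(design, shifted, replicates=10, cells=150, seed=seed + 5000)
        return design, a, b

    def test_identical_lines(self):
        design, a, _ = self._paired_spots(seed=1)
        result = compare_lines(a, a.copy(), design)
        assert result.diff_variance == 0.0
        assert result.lr_p > 0.05

    def test_col1_shift_detected(self):
        detected = 0
        n_sims = 30
        for s in range(n_sims):
            design, a, b = self._paired_spots(shift_col1=2.0, seed=100 + s)
            result = compare_lines(a, b, design)
            detected += result.lr_p < 0.05
        assert detected >= 0.90 * n_sims

    def test_mismatched_condition_sets_error(self):
        design, a, b = self._paired_spots(seed=2)
        b = b[b["condition_id"] != "LAM1|"]
        with pytest.raises(StatsError, match="LAM1"):
            compare_lines(a, b, design)


class TestZscoreCluster:
    def test_columns_standardized(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(5, 2, (20, 4)), columns=list("abcd"))
        out = zscore_cluster(m)
        np.testing.assert_allclose(out["z"].mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out["z"].std(ddof=1), 1.0, atol=1e-12)

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(0, 0.1, (10, 5))
        g2 = rng.normal(8, 0.1, (10, 5))
        m = pd.DataFrame(
            np.vstack([g1, g2]),
            index=[f"c{i:02d}" for i in range(20)],
        )
        out = zscore_cluster(m)
        labels = out["cut"](2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_single_row_rejected(self):
        with pytest.raises(StatsError):
            zscore_cluster(pd.DataFrame([[1.0, 2.0]]))

    def test_all_constant_rejected(self):
        m = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(StatsError, match="constant"):
            zscore_cluster(m)

    def test_constant_feature_dropped(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({"a": rng.normal(size=10), "b": 1.0})
        out = zscore_cluster(m)
        assert list(out["z"].columns) == ["a"]


class TestEmbedConditions:
    @pytest.fixture(scope="class")
    def planted_phenotypes(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(0, 0.2, (12, 6))
        g2 = rng.normal(5, 0.2, (12, 6))
        return pd.DataFrame(
            np.vstack([g1, g2]), index=[f"c{i:02d}" for i in range(24)]
        )

    def test_output_shape(self, planted_phenotypes):
        coords = embed_conditions(planted_phenotypes, perplexity=5, seed=0)
        assert coords.shape == (24, 2)
        assert list(coords.columns) == ["x", "y"]

    def test_seed_determinism_bitwise(self, planted_phenotypes):
        c1 = embed_conditions(planted_phenotypes, perplexity=5, seed=3)
        c2 = embed_conditions(planted_phenotypes, perplexity=5, seed=3)
        assert c1.to_numpy().tobytes() == c2.to_numpy().tobytes()

    def test_planted_clusters_separate(self, planted_phenotypes):
        from sklearn.metrics import silhouette_score

        coords = embed_conditions(planted_phenotypes, perplexity=5, seed=0)
        labels = [0] * 12 + [1] * 12
        assert silhouette_score(coords.to_numpy(), labels) > 0

    def test_too_few_conditions_error(self, planted_phenotypes):
        with pytest.raises(StatsError, match="perplexity"):
            embed_conditions(planted_phenotypes.head(10), perplexity=30, seed=0)
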