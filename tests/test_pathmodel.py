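import numpy as np
import pandas as pd
import pytest

from aeropath.pathmodel import (
    PathDAG,
    PathModelError,
    akaike_weights,
    backward_eliminate,
    basis_set,
    fishers_c,
    fit_components,
    fit_path,
    path_aicc,
    path_claims,
    standardize_table,
)
from aeropath.simulate import simulate_path_table


class TestStandardize:
    def _raw(self, n=12):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "tag_id": [f"T{i}" for i in range(n)],
                "nest_id": [f"N{i // 2}" for i in range(n)],
                "individual_id": [f"T{i}" for i in range(n)],
                "age": ["adult", "juvenile"] * (n // 2),
                "stage": ["ocean"] * (n // 2) + ["coast"] * (n // 2),
                "tailwind_ms": rng.normal(2, 3, n),
                "crosswind_ms": rng.normal(0, 2, n),
                "duration_min": rng.uniform(30, 120, n),
                "groundspeed_ms": rng.uniform(5, 20, n),
            }
        )

    def test_zero_mean_unit_sd(self):
        t = standardize_table(self._raw())
        for col in ("tailwind", "crosswind", "flight_duration", "log_groundspeed"):
            assert t[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert t[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_hand_example(self):
        x = pd.Series([2.0, 4.0, 6.0])
        z = (x - x.mean()) / x.std(ddof=1)
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_reference_coding(self):
        t = standardize_table(self._raw())
        raw = self._raw()
        assert set(t.loc[raw["age"] == "adult", "age"]) == {1.0}
        assert set(t.loc[raw["stage"] == "ocean", "stage"]) == {1.0}

    def test_constant_column_rejected(self):
        raw = self._raw()
        raw["tailwind_ms"] = 3.0
        with pytest.raises(PathModelError):
            standardize_table(raw)

    def test_groundspeed_log_transformed(self):
        raw = self._raw()
        t = standardize_table(raw)
        lg = np.log(raw["groundspeed_ms"])
        expected = (lg - lg.mean()) / lg.std(ddof=1)
        np.testing.assert_allclose(t["log_groundspeed"], expected, rtol=1e-12)


class TestBasisSet:
    def test_saturated_dag_empty(self):
        claims = basis_set("ABC", [("A", "B"), ("A", "C"), ("B", "C")])
        assert claims == []
        assert fishers_c([p for p in []]) == 0.0

    def test_chain(self):
        claims = basis_set("ABC", [("A", "B"), ("B", "C")])
        assert len(claims) == 1
        c = claims[0]
        assert (c.predictor, c.target, c.cond) == ("A", "C", ("B",))

    def test_cycle_rejected(self):
        with pytest.raises(PathModelError):
            basis_set("AB", [("A", "B"), ("B", "A")])

    def test_exogenous_pairs_skipped(self):
        claims = basis_set("ABC", [("A", "C"), ("B", "C")])
        assert claims == []  # A-B both parentless: no causal order

    def test_final_duration_dag_claims(self):
        dag = PathDAG(
            response="flight_duration",
            tailwind_terms=("stage", "age"),
            crosswind_terms=(),
            response_terms=("tailwind", "tailwind^2"),
        )
        claims = {(c.predictor, c.target, c.cond) for c in path_claims(dag)}
        assert ("age", "flight_duration", ("tailwind", "tailwind^2")) in claims
        assert ("stage", "flight_duration", ("tailwind", "tailwind^2")) in claims
        # crosswind is in the node set, so its claims are present too
        assert any("crosswind" in (c.predictor, c.target) for c in path_claims(dag))


class TestFishersC:
    def test_empty(self):
        assert fishers_c([]) == 0.0

    def test_half(self):
        assert fishers_c([0.5]) == pytest.approx(1.386, abs=1e-3)

    def test_two_values(self):
        assert fishers_c([0.1, 0.2]) == pytest.approx(7.824, abs=1e-3)

    def test_all_ones_is_zero(self):
        assert fishers_c([1.0, 1.0, 1.0]) == 0.0

    def test_monotone_decreasing_in_p(self):
        assert fishers_c([0.2, 0.5]) > fishers_c([0.3, 0.5])

    def test_nonpositive_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            c = fishers_c([0.0, 0.5])
        assert np.isfinite(c)

    def test_above_one_rejected(self):
        with pytest.raises(PathModelError):
            fishers_c([1.5])


class TestPathAICc:
    @pytest.mark.parametrize(
        "c,k,expected",
        [
            (22.09, 16, 71.64),
            (17.97, 17, 72.37),
            (13.86, 19, 79.00),
            (79.31, 14, 120.04),
            (17.81, 16, 67.36),
            (14.94, 17, 69.34),
        ],
    )
    def test_published_rows(self, c, k, expected):
        assert round(path_aicc(c, k, 48), 2) == expected

    def test_small_sample_guard(self):
        with pytest.raises(PathModelError):
            path_aicc(10.0, 47, 48)


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_equal_pair(self):
        assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_sum_to_one_and_monotone(self, rng):
        a = np.sort(rng.uniform(50, 150, 10))
        w = akaike_weights(a)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(w[i] >= w[i + 1] for i in range(len(w) - 1))

    def test_overflow_safe(self):
        w = akaike_weights([10.0, 5000.0])
        assert w == pytest.approx([1.0, 0.0], abs=1e-12)


class TestFitComponents:
    def test_recovers_generating_coefficients_within_3se(self):
        truth = {
            ("tailwind", "age"): 0.80,
            ("tailwind", "stage"): -0.70,
            ("flight_duration", "tailwind"): -0.69,
            ("flight_duration", "tailwind^2"): 0.23,
        }
        dag = PathDAG(
            response="flight_duration",
            tailwind_terms=("stage", "age"),
            crosswind_terms=(),
            response_terms=("tailwind", "tailwind^2"),
        )
        for seed in (101, 202, 303):
            comps = fit_components(dag, simulate_path_table(seed))
            for (node, term), value in truth.items():
                res = comps[node].result
                assert abs(res.coef(term) - value) < 3 * res.coef_se(term), (
                    seed, node, term,
                )

    def test_choosy_adults_give_positive_age_effect(self):
        comps = fit_components(PathDAG(), simulate_path_table(7))
        assert comps["tailwind"].result.coef("age") > 0

    def test_null_simulation_band(self):
        # with no true effects, standardized coefficients stay small
        zeros = {
            "tailwind_age": 0.0, "tailwind_stage": 0.0,
            "duration_tailwind": 0.0, "duration_tailwind2": 0.0,
        }
        dag = PathDAG(
            response="flight_duration",
            tailwind_terms=("stage", "age"),
            crosswind_terms=(),
            response_terms=("tailwind",),
        )
        n_seeds, ok = 200, 0
        for seed in range(n_seeds):
            tab = simulate_path_table(seed, coefficients=zeros, n_individuals=100)
            comps = fit_components(dag, tab)
            coefs = [
                comps["tailwind"].result.coef("age"),
                comps["tailwind"].result.coef("stage"),
                comps["flight_duration"].result.coef("tailwind"),
            ]
            ok += all(abs(c) < 0.5 for c in coefs)
        assert ok >= 0.95 * n_seeds


class TestDAGValidation:
    def test_quadratic_requires_linear(self):
        with pytest.raises(PathModelError):
            PathDAG(response_terms=("tailwind^2",))

    def test_interaction_requires_mains(self):
        with pytest.raises(PathModelError):
            PathDAG(response_terms=("tailwind", "tailwind:crosswind"))

    def test_wind_submodels_exogenous_only(self):
        with pytest.raises(PathModelError):
            PathDAG(tailwind_terms=("crosswind",))


class TestBackwardElimination:
    def test_structure_recovery_duration(self):
        tab = simulate_path_table(1)
        res = backward_eliminate(tab, "flight_duration")
        dag = res.final.dag
        assert set(dag.tailwind_terms) == {"stage", "age"}
        assert "tailwind" in dag.response_terms
        assert "tailwind^2" in dag.response_terms
        assert "age" not in dag.response_terms

    def test_structure_recovery_groundspeed_keeps_stage(self):
        tab = simulate_path_table(1)
        res = backward_eliminate(tab, "log_groundspeed")
        dag = res.final.dag
        assert "stage" in dag.response_terms
        assert "tailwind" in dag.response_terms
        assert "tailwind^2" not in dag.response_terms  # quadratic off by default

    def test_pure_noise_strips_predictors(self):
        zeros = {k: 0.0 for k in (
            "tailwind_intercept", "tailwind_age", "tailwind_stage",
            "duration_intercept", "duration_tailwind", "duration_tailwind2",
        )}
        for seed in (0, 2, 3):
            tab = simulate_path_table(seed, coefficients=zeros)
            res = backward_eliminate(tab, "flight_duration")
            dag = res.final.dag
            assert dag.response_terms == ()
            assert dag.tailwind_terms == ()
            assert dag.crosswind_terms == ()

    def test_deterministic(self):
        tab = simulate_path_table(4)
        a = backward_eliminate(tab, "flight_duration")
        b = backward_eliminate(tab, "flight_duration")
        pd.testing.assert_frame_equal(a.selection_table, b.selection_table)

    def test_final_not_much_worse_than_full(self):
        tab = simulate_path_table(5)
        res = backward_eliminate(tab, "flight_duration")
        full = max(res.history, key=lambda f: len(f.dag.response_terms))
        assert res.final.aicc <= full.aicc + 2.0

    def test_selection_table_invariants(self):
        tab = simulate_path_table(6)
        res = backward_eliminate(tab, "flight_duration")
        st = res.selection_table
        assert st["W"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (st["AICc"].diff().dropna() >= -1e-12).all()
        assert st["dAICc"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert st["cumW"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
        # the null model (no paths into the response) is always tabulated
        assert any(
            "flight_duration ~ 1" in eq for eq in st["model_equations"]
        )

    def test_interactions_prescreened_out_under_null(self):
        tab = simulate_path_table(9)
        res = backward_eliminate(tab, "flight_duration")
        for fit in [res.final]:
            assert "tailwind:crosswind" not in fit.dag.response_terms
            assert "tailwind:stage" not in fit.dag.response_terms


class TestFitPath:
    def test_k_bookkeeping_matches_published_convention(self):
        # top published duration model: tailwind ~ stage + age (6),
        # intercept-only crosswind (4), response ~ tailwind + tailwind^2 (6)
        tab = simulate_path_table(3)
        dag = PathDAG(
            response="flight_duration",
            tailwind_terms=("stage", "age"),
            crosswind_terms=(),
            response_terms=("tailwind", "tailwind^2"),
        )
        fit = fit_path(dag, tab)
        assert fit.k == 16
        null = PathDAG(
            response="flight_duration",
            tailwind_terms=("stage", "age"),
            crosswind_terms=(),
            response_terms=(),
        )
        assert fit_path(null, tab).k == 14

    def test_aicc_consistent_with_c_and_k(self):
        tab = simulate_path_table(2)
        fit = fit_path(PathDAG(), tab)
        assert fit.aicc == pytest.approx(path_aicc(fit.fishers_c, fit.k, fit.n))
        assert fit.fishers_c >= 0.0
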