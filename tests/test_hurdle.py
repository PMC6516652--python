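import math

import numpy as np
import pandas as pd
import pytest

from defaunation import hurdle
from defaunation.hurdle import (ModelFormula, all_subset_formulas, bic,
                                build_design, fit_binomial_stage,
                                fit_gaussian_stage, load_fit,
                                paper_best_formulas, predict_stage,
                                r2_marginal_conditional, save_fit,
                                select_stage, semipartial_r2)
from defaunation.simulate import SyntheticConfig, generate_database


@pytest.fixture(scope="module")
def db():
    df, truth = generate_database(
        SyntheticConfig(n_countries=5, n_studies=12, n_species=15,
                        n_records=500), seed=21)
    return df, truth


class TestModelFormula:
    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError):
            ModelFormula("gaussian", ("body_mass:distance_access",))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            ModelFormula("binomial", ("elevation",))

    def test_drop_term_under_interaction_fails(self):
        f = ModelFormula("gaussian", ("body_mass", "distance_access",
                                      "body_mass:distance_access"))
        with pytest.raises(ValueError):
            f.drop_term("body_mass")

    def test_diet_guild_expands_to_dummies(self, db):
        df, _ = db
        X, names = build_design(df, ("diet_guild",))
        assert names[0] == "(Intercept)"
        assert sum(n.startswith("diet_guild[") for n in names) == 4

    def test_body_mass_is_log_scale(self, db):
        df, _ = db
        X, names = build_design(df, ("body_mass",))
        np.testing.assert_allclose(X[:, 1], np.log(df["body_mass"]))


class TestBIC:
    def test_hand_arithmetic(self):
        # BIC = -2 logL + k ln(n) with logL=-100, k=3, n=100
        assert -2 * (-100) + 3 * math.log(100) == pytest.approx(213.8155, abs=1e-3)

    def test_bic_on_fit_matches_formula(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula("gaussian", ("distance_access",)),
                                criterion="ML")
        expected = -2 * st.fit.loglik + st.fit.n_params * math.log(st.fit.n_obs)
        assert bic(st) == pytest.approx(expected, abs=1e-9)

    def test_reml_fit_rejected(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula("gaussian", ("distance_access",)),
                                criterion="REML")
        with pytest.raises(ValueError):
            bic(st)

    def test_identical_fits_identical_bic(self, db):
        df, _ = db
        f = ModelFormula("gaussian", ("distance_access",))
        b1 = bic(fit_gaussian_stage(df, f, criterion="ML"))
        b2 = bic(fit_gaussian_stage(df, f, criterion="ML"))
        assert b1 == pytest.approx(b2, abs=1e-6)


class TestSelection:
    def test_single_candidate(self, db):
        df, _ = db
        sel = select_stage(df, [ModelFormula("gaussian", ("distance_access",))])
        assert sel.table["delta_bic"].iloc[0] == 0.0
        assert sel.table["weight"].iloc[0] == pytest.approx(1.0)
        assert sel.table["supported"].all()

    def test_identical_candidates_tie_broken_by_order(self, db):
        df, _ = db
        f = ModelFormula("gaussian", ("distance_access",))
        sel = select_stage(df, [f, f])
        assert sel.best is f
        assert int(sel.table.iloc[0]["index"]) in (0, 1)
        np.testing.assert_allclose(sel.table["weight"].sum(), 1.0)

    def test_supported_set_and_min_delta(self, db):
        df, _ = db
        cands = [ModelFormula("gaussian", t) for t in
                 [(), ("distance_access",), ("distance_access", "body_mass")]]
        sel = select_stage(df, cands)
        assert sel.table["delta_bic"].min() == 0.0
        assert sel.table["weight"].sum() == pytest.approx(1.0)

    def test_all_subsets_interaction_hierarchy(self):
        cands = all_subset_formulas("gaussian",
                                    ("distance_access", "body_mass"))
        with_int = [c for c in cands
                    if "body_mass:distance_access" in c.terms]
        assert len(cands) == 5    # {}, {d}, {b}, {d,b}, {d,b,dxb}
        for c in with_int:
            assert {"body_mass", "distance_access"} <= set(c.terms)


class TestR2:
    def test_no_random_variance_marginal_equals_conditional(self, db):
        df, _ = db
        st = fit_gaussian_stage(
            df, ModelFormula("gaussian", ("distance_access",)),
            var_fixed={"country": 0.0, "study": 0.0, "species": 0.0})
        m, c = r2_marginal_conditional(st)
        assert m == pytest.approx(c, abs=1e-12)

    def test_intercept_only_marginal_zero(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula("gaussian", ()))
        m, c = r2_marginal_conditional(st)
        assert m == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= m <= c <= 1.0

    def test_arithmetic_oracle(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, paper_best_formulas()["gaussian"])
        m, c = r2_marginal_conditional(st)
        var_f = float(np.var(st._X @ st.fit.beta))
        var_r = sum(st.fit.vc.values())
        denom = var_f + var_r + st.fit.sigma2
        assert m == pytest.approx(var_f / denom, abs=1e-9)
        assert c == pytest.approx((var_f + var_r) / denom, abs=1e-9)

    def test_semipartial_term_absent_errors(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula("gaussian", ("distance_access",)))
        with pytest.raises(ValueError):
            semipartial_r2(st, "hpd")

    def test_semipartial_noise_term_near_zero(self, db):
        df, _ = db
        df = df.copy()
        rng = np.random.default_rng(9)
        df["travel_time"] = rng.uniform(0, 1000, len(df))  # pure noise
        st = fit_gaussian_stage(
            df, ModelFormula("gaussian", ("distance_access", "travel_time")))
        assert abs(semipartial_r2(st, "travel_time")) < 0.01

    def test_semipartial_interaction_hierarchy_error(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula(
            "gaussian",
            ("distance_access", "body_mass", "body_mass:distance_access")))
        with pytest.raises(ValueError):
            semipartial_r2(st, "distance_access")


class TestPredict:
    def test_intercept_only_probability_half(self, db):
        df, _ = db
        st = fit_binomial_stage(df, ModelFormula("binomial", ()),
                                var_fixed={"country": 0.0, "study": 0.0,
                                           "species": 0.0})
        st.fit.beta[:] = 0.0
        p = predict_stage(st, df.head(3))
        np.testing.assert_allclose(p, 0.5)

    def test_unknown_levels_fixed_effect_only(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula("gaussian", ("distance_access",)),
                                standardize=False)
        new = pd.DataFrame({"distance_access": [10.0],
                            "species_id": ["never-seen"],
                            "country_id": ["nowhere"],
                            "study_id": ["none"]})
        eta = predict_stage(st, new)
        expected = st.fit.beta[0] + st.fit.beta[1] * 10.0
        assert eta[0] == pytest.approx(expected, abs=1e-12)

    def test_hand_set_coefficients_and_u(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula("gaussian", ("distance_access",)),
                                standardize=False)
        st.fit.beta[:] = [1.0, -0.2]
        sp = st.fit.levels["species"][0]
        st.fit.u["species"][:] = 0.0
        st.fit.u["species"][0] = 0.7
        new = pd.DataFrame({"distance_access": [5.0, 5.0],
                            "species_id": [sp, "unknown"]})
        eta = predict_stage(st, new)
        assert eta[0] == pytest.approx(1.0 - 1.0 + 0.7, abs=1e-12)
        assert eta[1] == pytest.approx(0.0, abs=1e-12)

    def test_missing_covariate_named(self, db):
        df, _ = db
        st = fit_gaussian_stage(df, ModelFormula("gaussian", ("hpd",)))
        with pytest.raises(KeyError, match="hpd"):
            predict_stage(st, pd.DataFrame({"distance_access": [1.0]}))

    def test_probabilities_in_unit_interval(self, db):
        df, _ = db
        st = fit_binomial_stage(df, paper_best_formulas()["binomial"],
                                standardize=False)
        p = predict_stage(st, df)
        assert ((p > 0) & (p < 1)).all()


class TestSerialization:
    def test_round_trip(self, db, tmp_path):
        df, _ = db
        st = fit_gaussian_stage(df, paper_best_formulas()["gaussian"],
                                standardize=False)
        path = tmp_path / "fit.json"
        save_fit(st, path)
        back = load_fit(path)
        np.testing.assert_allclose(back.fit.beta, st.fit.beta)
        assert back.formula == st.formula
        new = df.head(5)
        np.testing.assert_allclose(predict_stage(back, new),
                                   predict_stage(st, new), atol=1e-12)


class TestStandardization:
    def test_standardized_and_raw_fits_agree_on_predictions(self, db):
        # fixed-effect fit is equivariant under affine covariate rescaling
        df, _ = db
        f = ModelFormula("gaussian", ("distance_access", "hpd"))
        pinned = {"country": 0.0, "study": 0.0, "species": 0.0}
        st_std = fit_gaussian_stage(df, f, criterion="ML", standardize=True,
                                    var_fixed=pinned)
        st_raw = fit_gaussian_stage(df, f, criterion="ML", standardize=False,
                                    var_fixed=pinned)
        np.testing.assert_allclose(predict_stage(st_std, df.head(20)),
                                   predict_stage(st_raw, df.head(20)),
                                   atol=1e-6)
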