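import subprocess

import numpy as np
import pandas as pd
import pytest

from killscan import published
from killscan.models import (
    SeparationError,
    aicc,
    all_subsets_rank,
    build_design,
    classification_report,
    fit_random_intercept_logit,
    predict_population,
    score_published,
)
from killscan.synthetic import simulate_cluster_table


class TestAicc:
    def test_reference_model_rows(self):
        # printed LL/K/n of the top-ranked field models reproduce the
        # printed AICc to one decimal
        assert aicc(-60.5, 7, 335) == pytest.approx(135.3, abs=0.05)
        assert aicc(-29.8, 4, 54) == pytest.approx(68.4, abs=0.05)
        assert aicc(-61.9, 6, 335) == pytest.approx(136.0, abs=0.06)
        assert aicc(-61.1, 7, 335) == pytest.approx(136.5, abs=0.05)

    def test_no_parameters_no_penalty(self):
        assert aicc(-10.0, 0, 50) == 20.0

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 10, 11)


class TestBuildDesign:
    def test_factor_coding_reference_levels(self):
        df = pd.DataFrame(
            {
                "sex": ["male", "female"],
                "stod": ["night", "day"],
                "season": ["spring", "fall"],
                "age_class": ["subadult", "adult"],
                "n_gps_obs": [10, 20],
                "duration": [10, 20],
            }
        )
        X, names = build_design(df, ["log10_n_gps_obs", "sex", "stod", "season"])
        assert names == [
            "intercept", "log10_n_gps_obs", "sex_male", "stod_night",
            "stod_twilight", "season_spring", "season_summer",
        ]
        assert X[0, 2] == 1.0 and X[1, 2] == 0.0  # male dummy
        assert X[:, 0].tolist() == [1.0, 1.0]

    def test_interactions_are_dummy_products(self):
        df = pd.DataFrame({"age_class": ["subadult"], "sex": ["male"]})
        X, names = build_design(df, ["age_class", "sex", "age_class:sex"])
        assert "age_class_subadult:sex_male" in names
        assert X[0, names.index("age_class_subadult:sex_male")] == 1.0

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            build_design(pd.DataFrame({"a": [1]}), ["no_such_term"])


class TestFitRandomInterceptLogit:
    def test_single_animal_matches_plain_logit_oracle(self):
        import statsmodels.api as sm

        terms = ["log10_n_gps_obs", "sex"]
        df, _ = simulate_cluster_table(600, 1, terms, [-0.8, 1.5, 0.6], 0.0, seed=11)
        m = fit_random_intercept_logit(df, "y", terms)
        assert m.sigma2 == 0.0
        X, names = build_design(df, terms)
        oracle = sm.Logit(df["y"], X).fit(disp=0)
        for nm, ref in zip(names, oracle.params.values):
            assert m.coef[nm] == pytest.approx(ref, abs=1e-4)

    def test_matches_lme4_adaptive_quadrature(self, tmp_path):
        terms = ["log10_n_gps_obs", "sex"]
        df, _ = simulate_cluster_table(800, 12, terms, [-0.6, 1.2, 0.7], 0.5, seed=21)
        m = fit_random_intercept_logit(df, "y", terms)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        r_code = f"""
        d <- read.csv("{csv}")
        d$lng <- log10(d$n_gps_obs); d$male <- as.numeric(d$sex == "male")
        suppressMessages(library(lme4))
        f <- glmer(y ~ lng + male + (1 | animal_id), data = d,
                   family = binomial, nAGQ = 15)
        cat(fixef(f), as.data.frame(VarCorr(f))$vcov, logLik(f), sep = ",")
        """
        res = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        b0, b1, b2, s2, ll = map(float, res.stdout.strip().split(","))
        assert m.coef["intercept"] == pytest.approx(b0, abs=2e-3)
        assert m.coef["log10_n_gps_obs"] == pytest.approx(b1, abs=2e-3)
        assert m.coef["sex_male"] == pytest.approx(b2, abs=2e-3)
        assert m.sigma2 == pytest.approx(s2, abs=5e-3)
        assert m.ll == pytest.approx(ll, abs=1e-2)

    def test_constant_outcome_rejected(self):
        df, _ = simulate_cluster_table(50, 5, ["sex"], [0.0, 0.0], 0.0, seed=3)
        df["y"] = 1
        with pytest.raises(ValueError, match="variation"):
            fit_random_intercept_logit(df, "y", ["sex"])

    def test_complete_separation_reported_with_term(self):
        df, _ = simulate_cluster_table(200, 5, ["sex"], [0.0, 0.0], 0.0, seed=4)
        df["y"] = (df["sex"] == "male").astype(int)
        with pytest.raises(SeparationError, match="sex_male"):
            fit_random_intercept_logit(df, "y", ["sex"])


class TestAllSubsetsRank:
    def test_two_candidates_four_models(self):
        df, _ = simulate_cluster_table(300, 6, ["log10_n_gps_obs", "sex"],
                                       [-0.5, 1.0, 0.5], 0.2, seed=5)
        ranked = all_subsets_rank(df, ["log10_n_gps_obs", "sex"], "y")
        assert len(ranked) == 4  # {}, {ngps}, {sex}, {ngps, sex}
        assert sum(m.weight for m in ranked) == pytest.approx(1.0, abs=1e-9)
        assert [m.aicc for m in ranked] == sorted(m.aicc for m in ranked)
        assert sum(m.preferred for m in ranked) == 1

    def test_interaction_requires_main_effects(self):
        df, _ = simulate_cluster_table(300, 6, ["sex"], [0.0, 0.3], 0.1, seed=6)
        ranked = all_subsets_rank(df, ["age_class", "sex", "age_class:sex"], "y")
        for m in ranked:
            if "age_class:sex" in m.terms:
                assert "age_class" in m.terms and "sex" in m.terms

    def test_true_model_reaches_top_three(self):
        # 2-term truth among 5 candidates at n = 2000: the generating model
        # should rank in the top 3 in nearly every replicate
        hits = 0
        for r in range(10):
            df, _ = simulate_cluster_table(
                2000, 20, ["log10_n_gps_obs", "sex"], [-0.6, 1.2, 0.8], 0.3,
                seed=700 + r,
            )
            ranked = all_subsets_rank(
                df,
                ["log10_n_gps_obs", "sex", "spread", "occupation", "return_events"],
                "y",
            )
            for m in ranked[:3]:
                if {"log10_n_gps_obs", "sex"} <= set(m.terms):
                    hits += 1
                    break
        assert hits >= 9


class TestClassificationReport:
    def test_perfect_separation(self):
        rep = classification_report([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.sensitivity[0] == 1.0 and rep.specificity[0] == 1.0
        assert rep.auc == 1.0

    def test_three_of_four_concordant_pairs(self):
        rep = classification_report([0.9, 0.6, 0.7, 0.1], [1, 1, 0, 0])
        assert rep.auc == pytest.approx(0.75)

    def test_all_ties_auc_half(self):
        rep = classification_report([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert rep.auc == pytest.approx(0.5)

    def test_sensitivity_non_increasing_in_threshold(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(size=200)
        y = rng.binomial(1, s)
        rep = classification_report(s, y)
        assert all(b <= a + 1e-12 for a, b in zip(rep.sensitivity, rep.sensitivity[1:]))

    def test_auc_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            s = np.round(rng.uniform(size=n), 2)  # rounded -> ties occur
            y = rng.binomial(1, 0.4, size=n)
            if y.min() == y.max():
                continue
            rep = classification_report(s, y)
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert rep.auc == pytest.approx(conc / (len(pos) * len(neg)), rel=1e-12)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            classification_report([0.1, 0.9], [1, 1])


class TestScorePublished:
    def test_probability_at_no_predation_means(self):
        p = score_published(
            {"n_gps_obs": 7.1, "duration": 18.8, "sex": "female", "stod": "day"},
            model="predation",
        )
        assert p == pytest.approx(0.0456, abs=2e-3)

    def test_probability_at_predation_means_male(self):
        p = score_published(
            {"n_gps_obs": 24.7, "duration": 41.1, "sex": "male", "stod": "day"},
            model="predation",
        )
        assert p == pytest.approx(0.98, abs=5e-3)

    def test_odds_ratios_match_printed_values(self):
        for term, orr in published.PREDATION_MODEL_ODDS_RATIOS.items():
            beta = published.PREDATION_MODEL[term]
            assert np.exp(beta) == pytest.approx(orr, rel=5e-3)

    def test_strictly_increasing_in_ngps(self):
        base = {"duration": 30.0, "sex": "female", "stod": "day"}
        probs = [
            score_published({**base, "n_gps_obs": n}, model="predation")
            for n in [3, 6, 12, 24, 48]
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_carcass_model_scores(self):
        p = score_published(
            {"season": "summer", "stod": "day", "n_gps_obs": 20.5, "spread": 19.6},
            model="carcass",
        )
        assert 0.0 < p < 1.0
        # summer shifts odds toward small/medium vs fall
        p_fall = score_published(
            {"season": "fall", "stod": "day", "n_gps_obs": 20.5, "spread": 19.6},
            model="carcass",
        )
        assert p > p_fall

    def test_missing_term_reported(self):
        with pytest.raises(KeyError, match="duration"):
            score_published({"n_gps_obs": 10, "sex": "male", "stod": "day"},
                            model="predation")

    def test_dataframe_input(self):
        df = pd.DataFrame(
            {
                "n_gps_obs": [7.1, 24.7],
                "duration": [18.8, 41.1],
                "sex": ["female", "male"],
                "stod": ["day", "day"],
            }
        )
        probs = score_published(df, model="predation")
        assert probs.shape == (2,) and probs[1] > probs[0]


class TestRefitApproachesGeneratingAUC:
    def test_auc_recovery_from_published_truth(self):
        # simulate outcomes from the packaged predation coefficients, refit,
        # and compare the refit model's AUC with the generating model's
        rng = np.random.default_rng(15)
        n = 5000
        df = pd.DataFrame(
            {
                "animal_id": [f"bear{i % 15:02d}" for i in range(n)],
                "n_gps_obs": np.round(10 ** rng.normal(0.95, 0.3, n)).clip(2),
                "duration": np.round(10 ** rng.normal(1.3, 0.28, n)).clip(1),
                "sex": rng.choice(["male", "female"], n),
                "stod": rng.choice(["day", "night", "twilight"], n,
                                   p=[0.4, 0.5, 0.1]),
            }
        )
        p_true = score_published(df, model="predation")
        df["y"] = rng.binomial(1, p_true)
        terms = ["log10_n_gps_obs", "log10_duration", "sex", "stod"]
        m = fit_random_intercept_logit(df, "y", terms)
        auc_true = classification_report(p_true, df["y"]).auc
        auc_refit = classification_report(predict_population(m, df), df["y"]).auc
        assert abs(auc_refit - auc_true) < 0.03
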