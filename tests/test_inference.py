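"""Association model: design, profiled-ML fitter, summaries."""

import numpy as np
import pandas as pd
import pytest

from gazelang.inference import (
    _profiled_ml,
    binned_summary,
    build_design,
    fit_association_model,
    model_terms,
    phase_association,
    similarity_correlation,
    term_name,
)


def make_pair_table(n, rng, languages=("en", "ja"), scenes=("s1", "s2", "s3")):
    df = pd.DataFrame({
        "trial_id_1": [f"a{i}" for i in range(n)],
        "trial_id_2": [f"b{i}" for i in range(n)],
        "phase": rng.choice(["before", "during"], n),
        "sem_sim": rng.normal(0, 1, n),
        "syn_sim": rng.uniform(0, 1, n),
        "same_scene": rng.random(n) < 0.3,
        "same_language": rng.random(n) < 0.5,
        "participant_pair": rng.choice([f"p{i}|p{j}" for i in range(6) for j in range(i, 6)], n),
        "item_pair": rng.choice([f"{a}|{b}" for a in scenes for b in scenes], n),
        "cue_pair": rng.choice(["c1|c1", "c1|c2", "c2|c2"], n),
    })
    df["scan_sim"] = 0.2 + 0.05 * df.sem_sim + rng.normal(0, 0.05, n)
    return df


class TestDesign:
    def test_full_interaction_structure(self):
        combos = model_terms(5)
        assert len(combos) == 31  # all nonempty subsets of 5 terms
        assert term_name(combos[0]) == "Semantics"
        assert term_name(combos[-1]) == "Semantics x Syntax x Language x Scene x Phase"

    def test_interaction_columns_are_products(self):
        rng = np.random.default_rng(0)
        df = make_pair_table(50, rng)
        X, names = build_design(df)
        assert X.shape == (50, 32)
        i_sem = names.index("Semantics")
        i_phase = names.index("Phase")
        i_int = names.index("Semantics x Phase")
        assert np.allclose(X[:, i_int], X[:, i_sem] * X[:, i_phase])

    def test_treatment_coding_reference_levels(self):
        rng = np.random.default_rng(0)
        df = make_pair_table(50, rng)
        X, names = build_design(df)
        lang = X[:, names.index("Language")]
        assert set(np.unique(lang)) <= {0.0, 1.0}
        assert np.array_equal(lang == 1.0, df.same_language.to_numpy())

    def test_standardized_coding(self):
        rng = np.random.default_rng(0)
        df = make_pair_table(200, rng)
        X, names = build_design(df, standardized=True)
        sem = X[:, names.index("Semantics")]
        assert sem.mean() == pytest.approx(0.0, abs=1e-10)
        assert sem.std() == pytest.approx(1.0, rel=1e-10)
        assert set(np.round(np.unique(X[:, names.index("Phase")]), 6)) == {-0.5, 0.5}


class TestProfiledML:
    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM with the same crossed
        variance-component structure, on a problem where it converges."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        n = 1200
        f1 = rng.integers(0, 15, n)
        f2 = rng.integers(0, 8, n)
        f3 = rng.integers(0, 6, n)
        u1 = rng.normal(0, 0.5, 15)
        u2 = rng.normal(0, 0.3, 8)
        u3 = rng.normal(0, 0.2, 6)
        x1 = rng.normal(0, 1, n)
        x2 = rng.uniform(0, 1, n)
        y = 1.0 + 0.5 * x1 - 0.3 * x2 + u1[f1] + u2[f2] + u3[f3] + rng.normal(0, 0.4, n)
        X = np.column_stack([np.ones(n), x1, x2])

        mine = _profiled_ml(y, X, [f1, f2, f3], [15, 8, 6])

        df = pd.DataFrame(dict(y=y, x1=x1, x2=x2, f1=f1.astype(str),
                               f2=f2.astype(str), f3=f3.astype(str)))
        ref = smf.mixedlm(
            "y ~ x1 + x2", df, groups=np.ones(n), re_formula="0",
            vc_formula={"f1": "0+C(f1)", "f2": "0+C(f2)", "f3": "0+C(f3)"},
        ).fit(reml=False)

        assert mine.beta == pytest.approx(ref.fe_params.values, abs=1e-4)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert mine.sigma2 == pytest.approx(ref.scale, rel=1e-3)
        assert mine.sigma2 * mine.gammas == pytest.approx(ref.vcomp, rel=5e-3)
        assert np.sqrt(np.diag(mine.cov_beta))[1:] == pytest.approx(
            ref.bse_fe.values[1:], rel=1e-2
        )

    def test_ols_limit_without_factors(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 0.1, 100)
        fit = _profiled_ml(y, X, [], [])
        expect, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.beta == pytest.approx(expect)


class TestFitAssociationModel:
    def test_constant_response_gives_zero_slopes(self):
        rng = np.random.default_rng(1)
        df = make_pair_table(60, rng)
        df["scan_sim"] = 0.37
        fit = fit_association_model(df)
        assert fit.coef("(Intercept)") == pytest.approx(0.37)
        assert all(abs(b) < 1e-12 for b in fit.beta[1:])

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(2)
        df = make_pair_table(4000, rng)
        fit = fit_association_model(df)
        est, _, lo, hi = fit.linear_combination({"Semantics": 1.0})
        assert lo < 0.05 < hi or est == pytest.approx(0.05, abs=0.02)
        assert fit.converged

    def test_single_level_factor_dropped_and_reported(self):
        rng = np.random.default_rng(3)
        df = make_pair_table(300, rng)
        df["same_language"] = True  # single-language study
        fit = fit_association_model(df)
        assert "Language" in fit.dropped_terms
        assert "Language" not in fit.terms

    def test_ci_brackets_beta(self, default_result):
        fit = default_result.fit
        assert np.all(fit.ci_low <= fit.beta)
        assert np.all(fit.beta <= fit.ci_high)
        assert len(fit.terms) == len(fit.beta)

    def test_variance_components_nonnegative(self, default_result):
        fit = default_result.fit
        assert all(v >= 0 for v in fit.variance_components.values())
        assert fit.residual_variance > 0
        assert set(fit.variance_components) == {
            "participant_pair", "item_pair", "cue_pair",
        }

    def test_slope_by_phase_composition(self, default_result):
        fit = default_result.fit
        slopes = fit.slope_by_phase("Semantics")
        assert slopes["before"][0] == pytest.approx(fit.coef("Semantics"))
        assert slopes["during"][0] == pytest.approx(
            fit.coef("Semantics") + fit.coef("Semantics x Phase")
        )


class TestBinnedSummary:
    def test_single_record(self):
        df = pd.DataFrame({
            "scan_sim": [0.4], "sem_sim": [0.55], "syn_sim": [0.5],
            "phase": ["before"], "same_scene": [True], "same_language": [True],
        })
        out = binned_summary(df, "sem_sim")
        assert len(out) == 1
        row = out.iloc[0]
        assert row.mean_scan_sim == 0.4 and row.n == 1
        assert row.bin_low == pytest.approx(0.5)

    def test_hand_computed_means(self):
        df = pd.DataFrame({
            "scan_sim": [0.1, 0.3, 0.5, 0.7, 0.2],
            "sem_sim": [0.05, 0.05, 0.15, 0.15, 0.15],
            "syn_sim": 0.5, "phase": "before",
            "same_scene": False, "same_language": False,
        })
        out = binned_summary(df, "sem_sim")
        assert len(out) == 2
        assert out.iloc[0].mean_scan_sim == pytest.approx(0.2)   # (0.1+0.3)/2
        assert out.iloc[1].mean_scan_sim == pytest.approx(1.4 / 3)

    def test_counts_conserved_per_stratum(self, default_result):
        pt = default_result.pair_table
        out = binned_summary(pt, "syn_sim")
        per_stratum = out.groupby(["same_scene", "same_language", "phase"],
                                  observed=True)["n"].sum()
        expect = pt.groupby(["same_scene", "same_language", "phase"],
                            observed=True)["scan_sim"].count()
        assert per_stratum.sort_index().equals(expect.sort_index())

    def test_rescaling_flag_for_unbounded_predictor(self, default_result):
        out = binned_summary(default_result.pair_table, "sem_sim")
        assert out.attrs["rescaled"] in (True, False)
        assert (out.bin_low >= 0).all() and (out.bin_high <= 1 + 1e-9).all()


class TestCorrelations:
    def _df(self, sem, syn, same_language=True):
        n = len(sem)
        return pd.DataFrame({
            "trial_id_1": [f"a{i}" for i in range(n)],
            "trial_id_2": [f"b{i}" for i in range(n)],
            "sem_sim": sem, "syn_sim": syn, "scan_sim": 0.5,
            "phase": "before", "same_scene": False,
            "same_language": same_language,
        })

    def test_perfect_positive(self):
        sem = np.linspace(0, 1, 10)
        out = similarity_correlation(self._df(sem, sem))
        assert out["within_language"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        sem = np.linspace(0, 1, 10)
        out = similarity_correlation(self._df(sem, -sem))
        assert out["within_language"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        out = similarity_correlation(self._df(np.ones(5), np.linspace(0, 1, 5)))
        assert np.isnan(out["within_language"])
        assert out["within_language_undefined"]

    def test_phase_association_handles_degenerate(self):
        df = self._df(np.linspace(0, 1, 5), np.ones(5))
        assert np.isnan(phase_association(df, "syn_sim")["before"])


class TestModelRawAgreement:
    def test_predicted_bin_means_track_raw_bin_means(self, default_result):
        """Population-level predictions reproduce the binned raw means."""
        from scipy.stats import spearmanr

        pt = default_result.pair_table.copy()
        pt["pred"] = default_result.fit.predict(pt)
        v = pt["sem_sim"].to_numpy()
        v = (v - v.min()) / (v.max() - v.min())
        pt["bin"] = np.clip((v / 0.1).astype(int), 0, 9)
        grouped = pt.groupby(["same_scene", "phase", "bin"], observed=True).agg(
            raw=("scan_sim", "mean"), model=("pred", "mean"), n=("pred", "count")
        )
        grouped = grouped[grouped.n >= 30]
        rho = spearmanr(grouped.raw, grouped.model).statistic
        assert rho > 0.9
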