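import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytonuc.regression import (assemble_rate_table, fit_linear_model,
                                fit_summary, mt_cy_rate_correlation,
                                nested_f_test, read_rate_table,
                                select_most_parsimonious, write_rate_table)
from cytonuc.simulate import simulate_rate_table

from .oracles import pinv_ols


class TestAssembleRateTable:
    def test_basic_join(self):
        aars = {("A", "mt"): 0.5, ("A", "cy"): 0.3, ("G", "mt"): 0.7}
        trna = {"A": 0.2, "G": 0.4}
        tab = assemble_rate_table(aars, trna)
        assert len(tab) == 3
        row = tab[(tab.specificity == "A") & (tab.delta_mt == 1)].iloc[0]
        assert row.X == 0.2 and row.Y == 0.5

    def test_missing_trna_rejected(self):
        with pytest.raises(ValueError, match="mt-tRNA"):
            assemble_rate_table({("A", "mt"): 0.5}, {})

    def test_bad_lineage_rejected(self):
        with pytest.raises(ValueError, match="lineage"):
            assemble_rate_table({("A", "organellar"): 0.5}, {"A": 0.1})

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(ValueError):
            assemble_rate_table({("A", "mt"): float("nan")}, {"A": 0.1})


class TestFitLinearModel:
    def test_noiseless_exact_recovery(self):
        betas = (0.10, 0.39, 0.38, 0.07)
        tab = simulate_rate_table(betas, n_specificities=20, sigma=0.0, seed=1)
        fit = fit_linear_model(tab, "full")
        for name, truth in zip(("b0", "b1", "b2", "b3"), betas):
            assert fit.coefficients[name] == pytest.approx(truth, abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_pseudoinverse_oracle(self):
        tab = simulate_rate_table(n_specificities=15, sigma=0.05, seed=2)
        fit = fit_linear_model(tab, "full")
        D = np.column_stack([np.ones(len(tab)), tab.delta_mt, tab.X,
                             tab.X * tab.delta_mt])
        beta = pinv_ols(D, tab.Y.to_numpy())
        got = [fit.coefficients[k] for k in ("b0", "b1", "b2", "b3")]
        assert np.abs(np.array(got) - beta).max() < 1e-10

    def test_nested_models_have_fewer_params(self):
        tab = simulate_rate_table(n_specificities=10, seed=3)
        full = fit_linear_model(tab, "full")
        noi = fit_linear_model(tab, "no_interaction")
        ionly = fit_linear_model(tab, "intercepts_only")
        assert full.n_params == 4 and noi.n_params == 3 and ionly.n_params == 2
        assert ionly.sse >= noi.sse >= full.sse

    def test_too_few_rows_rejected(self):
        tab = simulate_rate_table(n_specificities=2, sigma=0.05, seed=4)
        with pytest.raises(ValueError):
            fit_linear_model(tab.head(4), "full")

    def test_rank_deficient_rejected(self):
        tab = pd.DataFrame({"specificity": list("ABCDE"),
                            "delta_mt": [1, 1, 1, 1, 1],
                            "X": [0.1, 0.2, 0.3, 0.4, 0.5],
                            "Y": [0.2, 0.3, 0.4, 0.5, 0.6]})
        with pytest.raises(ValueError, match="rank"):
            fit_linear_model(tab, "full")

    def test_unknown_tag_rejected(self):
        tab = simulate_rate_table(n_specificities=5, seed=5)
        with pytest.raises(ValueError):
            fit_linear_model(tab, "quadratic")


class TestNestedFTest:
    def test_manual_formula(self):
        tab = simulate_rate_table(n_specificities=12, sigma=0.05, seed=6)
        full = fit_linear_model(tab, "full")
        noi = fit_linear_model(tab, "no_interaction")
        cmp = nested_f_test(noi, full)
        f_manual = ((noi.sse - full.sse) / 1) / (full.sse / full.residual_df)
        assert cmp.f_statistic == pytest.approx(f_manual)
        assert cmp.df_num == 1 and cmp.df_den == full.residual_df
        assert 0.0 <= cmp.p_value <= 1.0

    def test_wrong_nesting_rejected(self):
        tab = simulate_rate_table(n_specificities=12, seed=7)
        full = fit_linear_model(tab, "full")
        noi = fit_linear_model(tab, "no_interaction")
        with pytest.raises(ValueError):
            nested_f_test(full, noi)

    def test_strong_interaction_detected(self):
        tab = simulate_rate_table((0.1, 0.4, 0.4, 1.5), n_specificities=30,
                                  sigma=0.02, seed=8)
        full = fit_linear_model(tab, "full")
        noi = fit_linear_model(tab, "no_interaction")
        assert nested_f_test(noi, full).p_value < 1e-6

    def test_null_interaction_usually_retained(self):
        # under b3 = 0 the interaction term should rarely be kept
        rejections = 0
        for seed in range(40):
            tab = simulate_rate_table((0.1, 0.4, 0.4, 0.0), 20, 0.05, seed=seed)
            full = fit_linear_model(tab, "full")
            noi = fit_linear_model(tab, "no_interaction")
            rejections += nested_f_test(noi, full).p_value < 0.05
        assert rejections <= 8  # ~5% expected; allow generous binomial slack


class TestSelection:
    def test_selects_full_when_interaction_strong(self):
        tab = simulate_rate_table((0.1, 0.4, 0.4, 2.0), 30, 0.02, seed=9)
        selected, fits = select_most_parsimonious(tab)
        assert selected.model_tag == "full"
        assert set(fits) == {"full", "no_interaction", "intercepts_only"}

    def test_selects_intercepts_when_no_slope(self):
        tab = simulate_rate_table((0.2, 0.4, 0.0, 0.0), 30, 0.05, seed=10)
        selected, _ = select_most_parsimonious(tab)
        assert selected.model_tag == "intercepts_only"

    def test_selects_no_interaction_for_additive_truth(self):
        tab = simulate_rate_table((0.1, 0.4, 0.5, 0.0), 40, 0.02, seed=11)
        selected, _ = select_most_parsimonious(tab)
        assert selected.model_tag in {"no_interaction", "full"}


class TestCorrelation:
    def test_perfectly_coupled_rates(self):
        rows = []
        for i, x in enumerate(np.linspace(0.1, 0.9, 10)):
            rows.append({"specificity": f"s{i}", "delta_mt": 1, "X": x, "Y": 2 * x})
            rows.append({"specificity": f"s{i}", "delta_mt": 0, "X": x, "Y": x})
        r, p = mt_cy_rate_correlation(pd.DataFrame(rows))
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_positive_under_compensatory_generator(self):
        tab = simulate_rate_table(n_specificities=40, sigma=0.05, seed=12)
        r, p = mt_cy_rate_correlation(tab)
        assert r > 0.5 and p < 0.01

    def test_matches_scipy(self):
        from scipy import stats
        tab = simulate_rate_table(n_specificities=10, sigma=0.1, seed=13)
        r, p = mt_cy_rate_correlation(tab)
        mt = tab[tab.delta_mt == 1].set_index("specificity").Y
        cy = tab[tab.delta_mt == 0].set_index("specificity").Y
        r2, p2 = stats.pearsonr(mt, cy.loc[mt.index])
        assert r == pytest.approx(float(r2)) and p == pytest.approx(float(p2))

    def test_too_few_pairs_rejected(self):
        tab = simulate_rate_table(n_specificities=2, sigma=0.05, seed=14)
        with pytest.raises(ValueError):
            mt_cy_rate_correlation(tab)


class TestTableIO:
    def test_roundtrip(self, tmp_path):
        tab = simulate_rate_table(n_specificities=8, seed=15)
        p = tmp_path / "rates.tsv"
        write_rate_table(tab, p, header_note="synthetic")
        back = read_rate_table(p)
        pd.testing.assert_frame_equal(back, tab)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="columns"):
            read_rate_table(p)

    def test_summary_mentions_all_coefficients(self):
        tab = simulate_rate_table(n_specificities=8, seed=16)
        text = fit_summary(fit_linear_model(tab, "full"))
        for name in ("b0", "b1", "b2", "b3", "r_squared"):
            assert name in text


class TestRecoveryProperties:
    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=20)
    def test_noiseless_recovery_any_seed(self, seed):
        betas = (0.05, 0.3, 0.5, 0.1)
        tab = simulate_rate_table(betas, n_specificities=10, sigma=0.0, seed=seed)
        fit = fit_linear_model(tab, "full")
        for name, truth in zip(("b0", "b1", "b2", "b3"), betas):
            assert fit.coefficients[name] == pytest.approx(truth, abs=1e-8)
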