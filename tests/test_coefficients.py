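"""Summary tabulation and conversion-coefficient machinery."""

import numpy as np
import pandas as pd
import pytest

from sibsurv.coefficients import (
    CoefficientTable,
    SimObservation,
    SummaryTabulation,
    apply_coefficients,
    fit_eq4_coefficients,
    tabulate_summary,
)


class TestTabulation:
    def test_hand_countable_single_respondent(self, tiny_ssh):
        tab = tabulate_summary(tiny_ssh).table
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row.age_group == "25-29"
        assert row.reached15 == 2 and row.died == 1 and row.died_last5 == 1
        assert row.ratio == pytest.approx(0.5)
        assert row.s_t == pytest.approx(0.5) and row.s_tm5 == pytest.approx(1.0)

    def test_matches_independent_recount(self, small_full_ssh):
        sub = small_full_ssh.head(100)
        tab = tabulate_summary(sub).table
        # independent pass over the raw rows
        t = sub.interview_cmc.iloc[0]
        counts = {}
        for _, r in sub.iterrows():
            age = t - r.resp_birth_cmc
            if not 180 <= age < 600:
                continue
            g = f"{(age // 60) * 5}-{(age // 60) * 5 + 4}"
            key = (g, r.sib_sex)
            R = D = D5 = 0
            b15 = r.sib_birth_cmc + 180
            if b15 <= t and (pd.isna(r.sib_death_cmc) or r.sib_death_cmc >= b15):
                R = 1
                if not pd.isna(r.sib_death_cmc) and r.sib_death_cmc < t:
                    D = 1
                    if r.sib_death_cmc >= t - 60:
                        D5 = 1
            c = counts.setdefault(key, [0, 0, 0])
            c[0] += R; c[1] += D; c[2] += D5
        for _, row in tab.iterrows():
            exp = counts.get((row.age_group, row.sib_sex), [0, 0, 0])
            assert [row.reached15, row.died, row.died_last5] == exp

    def test_row_order_invariance(self, small_full_ssh):
        a = tabulate_summary(small_full_ssh).table
        shuffled = small_full_ssh.sample(frac=1.0, random_state=0)
        b = tabulate_summary(shuffled).table
        pd.testing.assert_frame_equal(a, b)

    def test_unit_weights_match_unweighted(self, small_full_ssh):
        a = tabulate_summary(small_full_ssh, weights=None).table
        b = tabulate_summary(small_full_ssh.assign(weight=1.0)).table
        pd.testing.assert_frame_equal(a, b)

    def test_respondents_out_of_range_excluded_and_counted(self, tiny_ssh):
        extra = tiny_ssh.copy()
        extra.loc[:, "resp_birth_cmc"] = extra.interview_cmc - 700  # aged 58
        tab = tabulate_summary(pd.concat([tiny_ssh, extra]))
        assert tab.table.attrs["excluded_weight"] == pytest.approx(2.0)
        assert tab.table.reached15.sum() == 2

    def test_invariant_d5_le_d_le_r(self):
        bad = pd.DataFrame(
            {"n": [15], "age_group": ["15-19"], "sib_sex": ["f"],
             "reached15": [2.0], "died": [3.0], "died_last5": [0.0],
             "s_t": [0.0], "s_tm5": [0.0], "ratio": [1.0]}
        )
        with pytest.raises(ValueError):
            SummaryTabulation(table=bad)

    def test_from_proportions_round_trip(self, table5):
        tab = SummaryTabulation.from_proportions(
            table5.age_group, table5.s_t, table5.s_tm5
        )
        np.testing.assert_allclose(tab.table.s_t, table5.s_t, atol=1e-12)
        np.testing.assert_allclose(tab.table.s_tm5, table5.s_tm5, atol=1e-12)


class TestCoefficientFitting:
    def _obs(self, rng, n_obs, noise=0.0):
        out = []
        for _ in range(n_obs):
            ratio = pd.Series(rng.uniform(0.9, 0.999, 7), index=range(15, 50, 5))
            true = 0.1 + 0.9 * ratio + noise * rng.normal(size=7)
            out.append(SimObservation(ratio=ratio, true_5pn=true.clip(0.01, 0.999)))
        return out

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        coef = fit_eq4_coefficients(self._obs(rng, 30))
        assert np.allclose(coef.table.beta0, 0.1, atol=1e-10)
        assert np.allclose(coef.table.beta1, 0.9, atol=1e-10)
        assert np.allclose(coef.table.r_squared, 1.0)

    def test_ols_equals_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        obs = self._obs(rng, 20, noise=0.002)
        coef = fit_eq4_coefficients(obs).table.set_index("n")
        for n in range(15, 50, 5):
            x = np.array([o.ratio[n] for o in obs])
            y = np.array([o.true_5pn[n] for o in obs])
            X = np.column_stack([np.ones_like(x), x])
            b = np.linalg.solve(X.T @ X, X.T @ y)
            assert coef.loc[n, "beta0"] == pytest.approx(b[0], abs=1e-10)
            assert coef.loc[n, "beta1"] == pytest.approx(b[1], abs=1e-10)

    def test_constant_ratios_rejected(self):
        obs = []
        for _ in range(12):
            ratio = pd.Series(0.95, index=range(15, 50, 5))
            obs.append(SimObservation(ratio=ratio, true_5pn=ratio * 0.99))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_eq4_coefficients(obs)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="at least"):
            fit_eq4_coefficients(self._obs(rng, 5))

    def test_reliability_correction_undoes_attenuation(self):
        rng = np.random.default_rng(3)
        obs = []
        for _ in range(400):
            signal = pd.Series(rng.uniform(0.9, 0.999, 7), index=range(15, 50, 5))
            noisy = signal + rng.normal(0, 0.01, 7)
            obs.append(SimObservation(ratio=noisy,
                                      true_5pn=(0.1 + 0.9 * signal).clip(0, 0.999)))
        naive = fit_eq4_coefficients(obs).table.set_index("n")
        var_sig = np.var([o.ratio.iloc[0] for o in obs]) - 0.01**2
        lam = var_sig / (var_sig + 0.01**2)
        rel = pd.Series(lam, index=range(15, 50, 5))
        fixed = fit_eq4_coefficients(obs, reliability=rel).table.set_index("n")
        # attenuated slope is pulled back toward the generating 0.9
        assert abs(fixed.beta1.mean() - 0.9) < abs(naive.beta1.mean() - 0.9)
        assert fixed.beta1.mean() == pytest.approx(0.9, abs=0.03)


class TestApplyCoefficients:
    def test_identity_coefficients_pass_ratio_through(self):
        ident = CoefficientTable(
            pd.DataFrame({"n": list(range(15, 50, 5)),
                          "age_group": [f"{n}-{n+4}" for n in range(15, 50, 5)],
                          "beta0": 0.0, "beta1": 1.0}),
            "eq4_recent",
        )
        rows = pd.DataFrame({"n": [15], "age_group": ["15-19"], "ratio": [1.0]})
        out = apply_coefficients(rows, ident)
        assert out.p5.iloc[0] == 1.0 and out.q5.iloc[0] == 0.0

    @pytest.mark.parametrize(
        "n,s_t,s_tm5,printed_p5",
        [(15, 0.963, 0.982, 981.1), (20, 0.946, 0.968, 971.4)],
    )
    def test_published_rows_reproduce_printed_survival(self, n, s_t, s_tm5, printed_p5):
        coef = CoefficientTable.published_recent()
        b0, b1 = coef.lookup(n)
        p5 = b0 + b1 * (s_t / s_tm5)
        assert p5 * 1000 == pytest.approx(printed_p5, abs=0.1)

    def test_missing_age_group_raises_with_gap_list(self):
        coef = CoefficientTable.published_recent()
        rows = pd.DataFrame({"n": [15, 50], "age_group": ["15-19", "50-54"],
                             "ratio": [0.99, 0.99]})
        with pytest.raises(KeyError, match="50"):
            apply_coefficients(rows, coef)

    def test_coefficient_table_round_trip(self, tmp_path):
        coef = CoefficientTable.published_recent()
        path = tmp_path / "coef.csv"
        coef.to_csv(path)
        back = CoefficientTable.from_csv(path)
        assert back.method == coef.method
        pd.testing.assert_frame_equal(back.table, coef.table)

    def test_beta1_must_be_positive(self):
        with pytest.raises(ValueError):
            CoefficientTable(
                pd.DataFrame({"n": [15], "age_group": ["15-19"],
                              "beta0": [0.0], "beta1": [-1.0]}),
                "eq4_recent",
            )
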