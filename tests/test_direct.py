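"""Direct estimation: exposure arithmetic, rates, jackknife."""

import numpy as np
import pandas as pd
import pytest

from sibsurv.direct import (
    deaths_and_exposure,
    direct_estimates,
    estimates_from_counts,
    jackknife_ci,
    jackknife_se,
    validate_ssh,
)


def _row(v, birth, death=np.nan, weight=1.0, cluster=0, stratum=0):
    return {
        "resp_id": 0, "resp_birth_cmc": v - 300, "cluster": cluster,
        "stratum": stratum, "weight": weight, "interview_cmc": v,
        "sib_sex": "f", "sib_alive": np.isnan(death),
        "sib_birth_cmc": birth, "sib_death_cmc": death,
    }


class TestExposure:
    def test_sibling_aged_exactly_twenty_spends_window_in_15_19(self):
        v = 1200
        df = pd.DataFrame([_row(v, v - 240)])  # 240 months = exact age 20
        out = deaths_and_exposure(df, 5)
        assert out.set_index("age_group").person_years["15-19"] == pytest.approx(5.0)
        assert out[out.age_group != "15-19"].person_years.sum() == 0.0

    def test_matches_month_by_month_brute_force(self):
        rng = np.random.default_rng(4)
        v = 1400
        rows = []
        for _ in range(50):
            birth = v - rng.integers(60, 700)
            if rng.random() < 0.4:
                death = birth + rng.integers(0, v - birth + 1)
            else:
                death = np.nan
            rows.append(_row(v, birth, death, weight=rng.uniform(0.5, 2.0)))
        df = pd.DataFrame(rows)
        out = deaths_and_exposure(df, 5).set_index("age_group")

        # brute force: loop months of the window for every row
        months = {g: 0.0 for g in out.index}
        deaths = {g: 0.0 for g in out.index}
        for _, r in df.iterrows():
            for m in range(v - 60, v):
                age = m - r.sib_birth_cmc
                g = f"{(age // 60) * 5}-{(age // 60) * 5 + 4}"
                if g not in months or age < 180:
                    continue
                if np.isnan(r.sib_death_cmc) or m < r.sib_death_cmc:
                    months[g] += r.weight
                elif m == r.sib_death_cmc:
                    months[g] += 0.5 * r.weight
                    deaths[g] += r.weight
        for g in months:
            assert out.person_years[g] == pytest.approx(months[g] / 12.0, abs=1e-9)
            assert out.deaths[g] == pytest.approx(deaths[g], abs=1e-9)

    def test_exposure_conservation(self, small_full_ssh):
        out = deaths_and_exposure(small_full_ssh, 5)
        v = small_full_ssh.interview_cmc.iloc[0]
        b = small_full_ssh.sib_birth_cmc.to_numpy(float)
        d = small_full_ssh.sib_death_cmc.to_numpy(float)
        w = small_full_ssh.weight.to_numpy(float)
        lo = np.maximum(b + 180, v - 60)
        hi = np.minimum.reduce([b + 600, np.where(np.isnan(d), v, d), np.full_like(b, v)])
        full = np.clip(hi - lo, 0, None)
        # `full` excludes the death month; dying in an eligible cell adds half
        in_win = (~np.isnan(d)) & (d >= lo) & (d < np.minimum(b + 600, v))
        months = (full + 0.5 * in_win) * w
        assert out.person_years.sum() == pytest.approx(months.sum() / 12.0, rel=1e-9)

    def test_all_censored_dataset_gives_zero_mortality(self):
        v = 1300
        df = pd.DataFrame([_row(v, v - 250 - 30 * i) for i in range(12)])
        est = direct_estimates(df, 5)
        assert est.q35_15 == 0.0
        assert (est.by_age.q5 == 0).all()

    def test_empty_age_cell_refuses_to_chain(self):
        v = 1200
        df = pd.DataFrame([_row(v, v - 240)])  # only 15-19 exposure
        with pytest.raises(ValueError, match="no exposure"):
            direct_estimates(df, 5)


class TestWeightsAndValidation:
    def test_doubling_weights_changes_nothing(self, small_full_ssh):
        est1 = direct_estimates(small_full_ssh, 5)
        est2 = direct_estimates(small_full_ssh.assign(weight=2.0), 5)
        np.testing.assert_allclose(est1.by_age.nmx, est2.by_age.nmx, rtol=1e-12)
        assert est1.q35_15 == pytest.approx(est2.q35_15, abs=1e-12)

    def test_validation_flags_bad_rows_without_dropping_silently(self):
        v = 1200
        good = _row(v, v - 300, v - 10)
        bad = _row(v, v - 300, v - 400)  # death before birth
        df = pd.DataFrame([good, bad])
        df.loc[1, "sib_alive"] = False
        df.loc[0, "sib_alive"] = False
        valid, rejects = validate_ssh(df)
        assert len(valid) == 1 and len(rejects) == 1
        assert rejects.reject_reason.iloc[0] == "death before birth"


class TestJackknife:
    def _clustered(self, n_clusters, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        v = 1300
        rows = []
        for c in range(n_clusters):
            local = np.random.default_rng(0 if identical else seed + c)
            for _ in range(30):
                birth = v - local.integers(200, 620)
                death = birth + local.integers(180, v - birth + 1) \
                    if local.random() < 0.35 else np.nan
                rows.append(_row(v, birth, death, cluster=c))
        return pd.DataFrame(rows)

    def test_identical_clusters_have_zero_variance(self):
        df = self._clustered(6, identical=True)
        se = jackknife_se(df, lambda d: np.array([d.weight.sum() / len(d)]))
        assert se[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_cluster_variance_equals_hand_calculation(self):
        df = self._clustered(2, seed=3)

        def stat(d):
            return np.array([d.sib_alive.mean()])

        t0 = stat(df[df.cluster != 0])[0]
        t1 = stat(df[df.cluster != 1])[0]
        mean = (t0 + t1) / 2
        var_hand = (2 - 1) / 2 * ((t0 - mean) ** 2 + (t1 - mean) ** 2)
        se = jackknife_se(df, stat)
        assert se[0] == pytest.approx(np.sqrt(var_hand), abs=1e-12)

    def test_single_cluster_stratum_collapsed(self):
        df = self._clustered(4, seed=5)
        df.loc[df.cluster == 3, "stratum"] = 1  # stratum 1 has one cluster
        se = jackknife_se(df, lambda d: np.array([d.sib_alive.mean()]))
        assert np.isfinite(se[0])

    def test_ci_frame_is_clipped_and_ordered(self):
        df = self._clustered(8, seed=6)
        ci = jackknife_ci(df, lambda d: np.array([d.sib_alive.mean()]))
        assert 0.0 <= ci.lower[0] <= ci.estimate[0] <= ci.upper[0] <= 1.0

    def test_full_pipeline_ci_brackets_point_estimate(self, small_full_ssh):
        est = direct_estimates(small_full_ssh, 5, ci="jackknife")
        lo, hi = est.q35_15_ci
        assert lo < est.q35_15 < hi
        assert est.ci.shape[0] == 8  # seven age groups plus the summary index
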