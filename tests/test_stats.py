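"""Gated tests, mixed models, BH adjustment, analysis drivers."""

import numpy as np
import pandas as pd
import pytest

from cvawear.markers import MARKER_NAMES
from cvawear.stats import (FAMILIES, bh_adjust, dose_correlation, gate_group,
                           gate_paired, lmm_group_effect, lmm_state_effect,
                           run_clinic_analysis, run_home_analysis)


def brute_force_bh(p):
    """Independent oracle: literal min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(ps[j] * m / (j + 1) for j in range(i, m))
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestFamilyPartition:
    def test_partition_covers_all_13_markers_disjointly(self):
        all_members = [m for fam in FAMILIES.values() for m in fam]
        assert sorted(all_members) == sorted(MARKER_NAMES)
        assert len(set(all_members)) == 13


class TestGatePaired:
    def test_heavy_tailed_differences_choose_nonparametric(self):
        chosen = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            off = 100 + rng.lognormal(0.0, 1.0, 14)
            on = off + rng.lognormal(1.0, 1.2, 14)
            chosen.append(gate_paired(off, on)["test"])
        assert np.mean([c == "wilcoxon_signed" for c in chosen]) >= 0.90

    def test_paired_cohens_d_worked_example(self):
        off = np.array([10.0, 10.0, 10.0])
        on = off + np.array([1.0, 2.0, 3.0])
        assert gate_paired(off, on)["effect_size"] == pytest.approx(2.0)

    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10)
        g = gate_paired(x, x)
        assert g["test"] == "degenerate"
        assert g["p"] == 1.0
        assert g["effect_size"] == 0.0

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError):
            gate_paired([1.0, 2.0], [2.0, 3.0])


class TestGateGroup:
    def test_one_sd_shift_recovers_unit_cohens_d(self):
        ds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.0, 1.0, 7)
            b = rng.normal(0.0, 1.0, 7)
            ds.append(gate_group(a, b)["effect_size"])
        assert np.mean(ds) == pytest.approx(1.0, abs=0.15)

    def test_identical_groups_zero_effect(self):
        x = np.arange(5.0)
        assert gate_group(x, x)["effect_size"] == 0.0

    def test_binary_data_routes_to_nonparametric(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 12).astype(float)
        b = rng.integers(0, 2, 12).astype(float)
        assert gate_group(a, b)["test"] == "mann_whitney"


class TestDoseCorrelation:
    def test_perfectly_linear_gives_pearson_one(self):
        dose = np.array([50.0, 100.0, 150.0, 200.0, 250.0])
        g = dose_correlation(2.0 * dose + 3.0, dose)
        assert g["test"] == "pearson"
        assert g["statistic"] == pytest.approx(1.0)

    def test_monotone_nonlinear_gives_spearman_one(self):
        dose = np.linspace(50, 400, 12)
        delta = np.exp(dose / 60.0)  # heavily skewed: fails normality
        g = dose_correlation(delta, dose)
        assert g["test"] == "spearman"
        assert g["statistic"] == pytest.approx(1.0)

    def test_permuted_pairing_mostly_null(self):
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            dose = rng.normal(150, 40, 20)
            delta = rng.permutation(dose) * 0.1 + rng.normal(0, 5, 20)
            g = dose_correlation(delta, dose)
            ok += (g["p"] > 0.05)
        assert ok / 50 >= 0.80

    def test_constant_dose_reported_undefined(self):
        g = dose_correlation(np.arange(6.0), np.full(6, 150.0))
        assert g["test"] == "undefined"
        assert np.isnan(g["p"])


def _home_df(seed, effect=-10.0, n_sub=12, n_pairs=3, sub_sd=15.0,
             res_sd=5.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        b = rng.normal(0, sub_sd)
        for _ in range(n_pairs):
            rows.append({"subject": f"S{s}", "state": "OFF",
                         "value": 100 + b + rng.normal(0, res_sd)})
            rows.append({"subject": f"S{s}", "state": "ON",
                         "value": 100 + b + effect + rng.normal(0, res_sd)})
    return pd.DataFrame(rows)


class TestMixedModels:
    def test_state_effect_recovered_over_seeds(self):
        """12 subjects x 3 OFF/ON pairs, true effect -10 ms, subject SD 15,
        residual SD 5: coefficient lands in [-13, -7] (20 seeded fits)."""
        coefs = [lmm_state_effect(_home_df(s))["effect_size"]
                 for s in range(20)]
        assert np.mean([(-13 <= c <= -7) for c in coefs]) >= 0.90

    def test_single_response_matches_paired_mean_difference(self):
        df = _home_df(3, n_pairs=1)
        g = lmm_state_effect(df)
        piv = df.pivot_table(index="subject", columns="state",
                             values="value")
        assert g["effect_size"] == pytest.approx(
            float((piv["ON"] - piv["OFF"]).mean()), abs=1e-5)

    def test_group_effect_recovered(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(12):
            oh = s < 6
            b = rng.normal(0, 5)
            for w in range(3):
                rows.append({"subject": f"S{s}", "window_id": w, "oh": oh,
                             "delta": b + (-8.0 if oh else 0.0)
                             + rng.normal(0, 3)})
        g = lmm_group_effect(pd.DataFrame(rows))
        assert g["effect_size"] == pytest.approx(-8.0, abs=4.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            lmm_state_effect(_home_df(0, n_sub=1))

    def test_singular_fit_falls_back_with_warning(self):
        # zero between-subject variance and zero residual: degenerate
        rows = []
        for s in range(4):
            for _ in range(2):
                rows.append({"subject": f"S{s}", "state": "OFF",
                             "value": 100.0})
                rows.append({"subject": f"S{s}", "state": "ON",
                             "value": 90.0})
        with pytest.warns(UserWarning, match="singular"):
            g = lmm_state_effect(pd.DataFrame(rows))
        assert g["effect_size"] == pytest.approx(-10.0)


class TestBH:
    def test_worked_example_all_point_oh_four(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_matches_brute_force_on_random_vectors_exactly(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 15))
            assert np.array_equal(bh_adjust(p), brute_force_bh(p))

    def test_agrees_with_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=13)
            assert np.allclose(bh_adjust(p),
                               multipletests(p, method="fdr_bh")[1],
                               atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


BASE = {"HR": 70, "RMSSD": 25, "SDNN": 35, "LF": 600, "HF": 400,
        "LF_HF": 1.5, "PEP": 90, "LVETi": 410, "PEP_LVETi": 0.22,
        "SCGamp": 1.0, "PPGamp": 1.0, "PAT": 210, "PTT": 120}


def marker_level_table(seed, pep_effect=0.0, rmssd_oh_effect=0.0, n=14,
                      sub_sd=15.0, res_sd=5.0, n_windows=1,
                      dose_spread=False):
    """Marker table with the study's generative structure, no waveforms."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        oh = s < n // 2
        dose = float(rng.choice([100, 150, 200, 250])) if dose_spread \
            else 150.0
        inter = {m: rng.normal(0, sub_sd) for m in MARKER_NAMES}
        for w in range(n_windows):
            for state in ("OFF", "ON"):
                r = {"subject": f"S{s:02d}", "state": state, "oh": oh,
                     "dose_mg": dose, "window_id": w, "setting": "clinic"}
                for m in MARKER_NAMES:
                    v = BASE[m] + inter[m] + rng.normal(0, res_sd)
                    if m == "PEP" and state == "ON":
                        v += pep_effect
                    if m == "RMSSD" and state == "ON" and oh:
                        v += rmssd_oh_effect
                    r[m] = v
                rows.append(r)
    return pd.DataFrame(rows)


class TestAnalysisDrivers:
    def test_injected_pep_effect_flagged_in_cardiomech_family_only(self):
        res = run_clinic_analysis(marker_level_table(0, pep_effect=12.0))
        paired = res[res["analysis"] == "paired_state"].set_index("marker")
        assert paired.loc["PEP", "p_adj"] < 0.05
        hrv = paired[paired["family"] == "hr_hrv"]
        assert (hrv["p_adj"] >= 0.05).all()

    def test_oh_rmssd_suppression_flagged_by_group_comparison(self):
        res = run_clinic_analysis(
            marker_level_table(1, rmssd_oh_effect=-25.0, res_sd=3.0,
                               sub_sd=5.0))
        grp = res[res["analysis"] == "group_delta"].set_index("marker")
        assert grp.loc["RMSSD", "p_adj"] < 0.05

    def test_p_adj_never_below_p_raw(self):
        res = run_clinic_analysis(marker_level_table(2, dose_spread=True))
        ok = np.isfinite(res["p_adj"])
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p_raw"] - 1e-12).all()

    def test_home_analysis_recovers_state_effect(self):
        res = run_home_analysis(
            marker_level_table(3, pep_effect=10.0, n=12, n_windows=3))
        lmm = res[res["analysis"] == "lmm_state"].set_index("marker")
        assert lmm.loc["PEP", "effect_size"] == pytest.approx(10.0, abs=3.0)
        assert lmm.loc["PEP", "p_adj"] < 0.05

    def test_too_few_subjects_refused(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            run_clinic_analysis(marker_level_table(4, n=2))
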