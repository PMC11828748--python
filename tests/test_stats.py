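"""Wilcoxon protocol, LRT, contrasts, AIC selection, cluster purity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import gaitrhythm as gr
from gaitrhythm import stats as st
from gaitrhythm.betamixed import fit_beta_mixed_formula


def exact_wilcoxon_enumeration(diffs):
    """Independent oracle: two-sided signed-rank p by enumerating all 2^n
    sign assignments of the ranked absolute differences."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        s = np.array(signs, bool)
        w = min(ranks[s].sum(), ranks[~s].sum())
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def _counts_frame(on, off):
    n = len(on)
    return pd.DataFrame({
        "horse": [f"H{i}" for i in range(n)],
        "hoof": "fore", "saddle": "english", "gait": "walk",
        "on_count": on, "off_count": off,
    })


class TestWilcoxon:
    def test_all_on_greater_gives_minimal_statistic(self):
        df = _counts_frame(on=np.arange(10, 23), off=np.arange(0, 13))
        (res,) = gr.wilcoxon_on_off(df)
        assert res.statistic == 0.0
        assert res.p_value < 0.001

    def test_antisymmetric_differences_give_p_one(self):
        on = np.array([10, 12, 14, 16, 11, 13, 15, 17.0])
        off = on + np.array([1, -1, 2, -2, 3, -3, 4, -4.0])
        df = _counts_frame(on, off)
        (res,) = gr.wilcoxon_on_off(df)
        assert res.method == "wilcoxon/exact"
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_flagged_undefined(self):
        df = _counts_frame(np.full(8, 5.0), np.full(8, 5.0))
        (res,) = gr.wilcoxon_on_off(df)
        assert not res.defined
        assert "all differences zero" in res.flags

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_full_sign_enumeration(self, seed):
        """For n <= 12 the exact test equals brute-force enumeration of
        all sign assignments."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        d = np.round(rng.normal(0, 3, size=n), 2)
        d = d[d != 0]
        while np.unique(np.abs(d)).size < d.size:  # oracle assumes no rank ties
            d = np.round(rng.normal(0, 3, size=n), 3)
            d = d[d != 0]
        off = np.full(d.size, 10.0)
        df = _counts_frame(off + d, off)
        (res,) = gr.wilcoxon_on_off(df)
        assert res.p_value == pytest.approx(exact_wilcoxon_enumeration(d), abs=1e-12)


@pytest.fixture(scope="module")
def fits():
    rng = np.random.default_rng(7)
    G, n = 8, 20
    g = np.repeat(np.arange(G), n)
    gait = np.tile(np.repeat(["walk", "trot", "canter"], n // 3 + 1)[:n], G)
    hoof = np.tile(["fore", "hind"], g.size // 2)
    u = rng.normal(0, 0.3, G)
    eta = -1.0 + 0.6 * (gait == "trot") + u[g]
    y = rng.beta(expit(eta) * 30, (1 - expit(eta)) * 30)
    df = pd.DataFrame({"y": y, "gait": gait, "hoof": hoof, "horse": g})
    full = fit_beta_mixed_formula(df, "y ~ gait * hoof", "horse")
    gait_only = fit_beta_mixed_formula(df, "y ~ gait", "horse")
    null = fit_beta_mixed_formula(df, "y ~ 1", "horse")
    return df, full, gait_only, null


class TestLrtAndSelection:
    def test_identical_models_give_chi2_zero_p_one(self, fits):
        _, full, _, _ = fits
        res = gr.lrt_vs_null(full, full)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_df_accounting_gait_hoof_interaction(self, fits):
        """gait (2 dummies) + hoof (1) + interaction (2) vs null -> df 5."""
        _, full, _, null = fits
        res = gr.lrt_vs_null(full, null)
        assert res.df == 5

    def test_strong_effect_detected(self, fits):
        df, _, gait_only, null = fits
        res = gr.lrt_vs_null(gait_only, null)
        assert res.p_value < 1e-6

    def test_different_data_rejected(self, fits):
        df, full, _, _ = fits
        other = fit_beta_mixed_formula(df.iloc[:100], "y ~ 1", "horse")
        with pytest.raises(ValueError, match="different data"):
            gr.lrt_vs_null(full, other)

    def test_aic_selects_minimum_then_smaller(self, fits):
        _, full, gait_only, null = fits
        best = gr.select_by_aic([full, gait_only, null])
        assert best.aic == min(f.aic for f in (full, gait_only, null))
        tie = gr.select_by_aic([full, full])
        assert tie is full

    def test_no_converged_candidate_rejected(self, fits):
        import dataclasses
        _, full, _, _ = fits
        broken = dataclasses.replace(full, converged=False)
        with pytest.raises(ValueError, match="no converged"):
            gr.select_by_aic([broken])

    def test_pairwise_contrasts_three_levels(self, fits):
        df, full, _, _ = fits
        res = gr.pairwise_contrasts(full, "gait", df)
        assert len(res) == 3  # C(3,2)
        raws = np.array([r.p_value for r in res])
        adjs = np.array([r.p_adjusted for r in res])
        assert np.all(adjs >= raws - 1e-15)
        assert np.all((adjs >= 0) & (adjs <= 1))
        # trot differs from both other gaits in this simulation
        sig = {r.label: r.p_adjusted for r in res}
        trot_contrasts = [p for lab, p in sig.items() if "trot" in lab]
        assert all(p < 0.01 for p in trot_contrasts)

    def test_level_with_itself_is_null_contrast(self, fits):
        df, full, _, _ = fits
        res = st.contrast_level_with_itself(full, "gait", "walk", df)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_absent_factor_rejected(self, fits):
        df, full, _, _ = fits
        with pytest.raises(ValueError, match="breed"):
            gr.pairwise_contrasts(full, "breed", df)


class TestDurationScalingAndClusters:
    def test_scale_to_unit_maps_into_open_interval(self):
        x = np.array([0.4, 1.0, 2.0])
        y, scale = st.scale_to_unit(x)
        assert scale == pytest.approx(2.1)
        assert np.all((y > 0) & (y < 1))
        assert np.allclose(y * scale, x)

    def test_fhi_hfi_model_separates_gaits(self, small_cohort_tables):
        """The FHI~HFI beta mixed model strongly beats the null: gait and
        coordination structure explain fore-cycle duration."""
        res = st.fit_fhi_hfi(small_cohort_tables["intervals"],
                             formula_rhs="hfi_u + gait", n_quad=9)
        assert res["full"].converged
        assert res["lrt"].p_value < 1e-6
        assert res["fhi_scale_s"] > res["data"]["fhi_s"].max()

    def test_gait_clusters_in_hfi_fhi_plane(self, small_cohort_tables):
        """The three gaits form distinct clusters of (HFI, FHI) points;
        nearest-centroid purity exceeds 95%."""
        iv = small_cohort_tables["intervals"]
        hfi = iv[iv["kind"] == "HFI"]
        df = pd.DataFrame({
            "hfi_s": hfi["value_s"].to_numpy(),
            "fhi_s": hfi["cycle_s"].to_numpy(),
            "gait": hfi["gait"].to_numpy(),
        })
        assert st.gait_cluster_purity(df) >= 0.95
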