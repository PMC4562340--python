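"""Beta/M transforms, BH, two-sample t, and the moderated-t engine."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import adipometh as am
from adipometh.diffmeth import (
    beta_to_m,
    estimate_variance_prior,
    m_to_beta,
    moderated_lm,
)


class TestTransforms:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)
        assert m_to_beta(m) == pytest.approx(beta, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(-0.1)
        with pytest.raises(ValueError):
            beta_to_m(1.2)

    def test_boundary_values_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            m = beta_to_m(np.array([0.0, 1.0]))
        assert np.all(np.isfinite(m))

    def test_round_trip_on_random_betas(self, rng):
        betas = rng.uniform(1e-5, 1 - 1e-5, size=1000)
        assert np.max(np.abs(m_to_beta(beta_to_m(betas)) - betas)) < 1e-12

    @given(st.floats(1e-6, 1 - 1e-6))
    def test_bijection_property(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)


def bh_oracle(p):
    # O(m^2) definitional step-up: adj_i = min over j with p_j >= p_i of m*p_j/rank_j
    p = np.asarray(p, dtype=float)
    m = len(p)
    ranks = np.array([np.sum(p <= pi) for pi in p])
    adj = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBhAdjust:
    def test_closed_form_triplet(self):
        assert am.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert am.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            am.bh_adjust([0.5, 1.5])

    def test_matches_definitional_oracle_and_statsmodels(self, rng):
        for m in (1, 2, 17, 400, 1000):
            p = rng.uniform(size=m)
            if m > 4:
                p[:3] = p[3]  # exercise ties
            ours = am.bh_adjust(p)
            assert ours == pytest.approx(bh_oracle(p), abs=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(sm, abs=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=500)
        assert np.all(am.bh_adjust(p) >= p - 1e-15)


class TestTwoSampleT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = am.two_sample_t(x, x)
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_pooled_matches_textbook_formula(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        res = am.two_sample_t(x, y, variant="pooled")
        sp2 = ((9 * x.var(ddof=1)) + (11 * y.var(ddof=1))) / 20
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 10 + 1 / 12))
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == 20
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 20), abs=1e-12)

    def test_cohort_weight_comparison_from_summaries(self):
        # control weight 69 +/- 7 kg (n=14) vs case 115 +/- 11 kg (n=15):
        # the printed p is 3.4e-13; rounded summary inputs land on that order
        res = am.two_sample_t_from_stats(69, 7, 14, 115, 11, 15)
        assert 1e-14 < res.p < 1e-12

    def test_zero_variance_degenerate_cases(self):
        a = np.array([1.0, 1.0, 1.0])
        assert am.two_sample_t(a, a).p == 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            res = am.two_sample_t(a, a + 1)
        assert res.p == 0.0

    def test_one_sided_halves_symmetric_two_sided(self, rng):
        x, y = rng.normal(1, 1, 8), rng.normal(0, 1, 8)
        two = am.two_sample_t(x, y, sided="two")
        oriented = am.two_sample_t(x, y, sided="greater" if two.t > 0 else "less")
        assert oriented.p == pytest.approx(two.p / 2)
        assert am.two_sample_t(x, y, sided="less").p == pytest.approx(
            1 - am.two_sample_t(x, y, sided="greater").p
        )


def ols_t_oracle(Y, X, coef_index=1):
    """Per-feature ordinary-least-squares t via statsmodels, row by row."""
    import statsmodels.api as sm

    ts = []
    for row in Y:
        fit = sm.OLS(row, X).fit()
        ts.append(fit.tvalues[coef_index])
    return np.array(ts)


def small_m_fixture(rng, n_probes=40, n_case=6, n_control=6):
    n = n_case + n_control
    sheet = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "group": ["case"] * n_case + ["control"] * n_control,
            "age": rng.uniform(30, 60, n).round(1),
        }
    )
    Y = rng.normal(0, 1, (n_probes, n)) * rng.uniform(0.3, 1.5, n_probes)[:, None]
    M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)], columns=sheet["sample_id"])
    return M, sheet


class TestModeratedFit:
    def test_d0_zero_equals_per_probe_ols(self, rng):
        M, sheet = small_m_fixture(rng)
        res = am.fit_moderated(M, sheet, prior_df=0)
        X = np.column_stack(
            [
                np.ones(len(sheet)),
                (sheet["group"] == "case").to_numpy(float),
                sheet["age"].to_numpy(float),
            ]
        )
        oracle = ols_t_oracle(M.to_numpy(), X)
        assert np.max(np.abs(res.table["t_mod"].to_numpy() - oracle)) < 1e-10

    def test_d0_infinite_is_fixed_variance_limit(self, rng):
        M, sheet = small_m_fixture(rng)
        s0 = 0.7
        res = am.fit_moderated(M, sheet, prior_df=np.inf, prior_var=s0**2)
        X = np.column_stack(
            [
                np.ones(len(sheet)),
                (sheet["group"] == "case").to_numpy(float),
                sheet["age"].to_numpy(float),
            ]
        )
        v = np.linalg.inv(X.T @ X)[1, 1]
        expected = res.table["coef_group"].to_numpy() / (s0 * np.sqrt(v))
        assert res.table["t_mod"].to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_moderated_t_interpolates_monotonically_in_d0(self, rng):
        M, sheet = small_m_fixture(rng, n_probes=15)
        limit = am.fit_moderated(M, sheet, prior_df=np.inf, prior_var=0.5).table[
            "t_mod"
        ].to_numpy()
        prev = None
        for d0 in (0.0, 1.0, 4.0, 16.0, 256.0):
            t = am.fit_moderated(M, sheet, prior_df=d0, prior_var=0.5).table[
                "t_mod"
            ].to_numpy()
            if prev is not None:
                # each probe's t moves monotonically toward the fixed-variance limit
                assert np.all(np.abs(t - limit) <= np.abs(prev - limit) + 1e-12)
            prev = t

    def test_group_swap_negates_effect_keeps_p(self, rng):
        M, sheet = small_m_fixture(rng)
        swapped = sheet.assign(
            group=sheet["group"].map({"case": "control", "control": "case"})
        )
        a = am.fit_moderated(M, sheet)
        b = am.fit_moderated(M, swapped)
        assert a.table["coef_group"].to_numpy() == pytest.approx(
            -b.table["coef_group"].to_numpy(), abs=1e-10
        )
        assert a.table["delta_beta"].to_numpy() == pytest.approx(
            -b.table["delta_beta"].to_numpy(), abs=1e-12
        )
        assert a.table["p_raw"].to_numpy() == pytest.approx(
            b.table["p_raw"].to_numpy(), abs=1e-12
        )

    def test_rank_deficient_design_rejected(self, rng):
        M, sheet = small_m_fixture(rng)
        sheet["dup"] = sheet["age"]
        with pytest.raises(ValueError, match="rank"):
            am.fit_moderated(M, sheet, covariates=("age", "dup"))

    def test_too_few_residual_df_rejected(self, rng):
        M, sheet = small_m_fixture(rng, n_probes=5, n_case=2, n_control=2)
        with pytest.raises(ValueError, match="residual df"):
            am.fit_moderated(M, sheet)

    def test_matches_bioconductor_limma(self, rng, tmp_path):
        """Independent oracle: limma's lmFit + eBayes on the same data."""
        M, sheet = small_m_fixture(rng, n_probes=60)
        res = am.fit_moderated(M, sheet)
        M.to_csv(tmp_path / "m.tsv", sep="\t")
        sheet.to_csv(tmp_path / "sheet.tsv", sep="\t", index=False)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'M <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1, check.names=FALSE))\n'
            f'sheet <- read.delim("{tmp_path}/sheet.tsv")\n'
            "design <- model.matrix(~ factor(sheet$group, levels=c('control','case')) + sheet$age)\n"
            "fit <- eBayes(lmFit(M, design))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior)\n"
            f'write.table(out, "{tmp_path}/r.tsv", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, text=True
        )
        r = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
        assert res.d0 == pytest.approx(r["d0"].iloc[0], rel=1e-4)
        assert np.max(np.abs(res.table["t_mod"].to_numpy() - r["t"].to_numpy())) < 1e-6
        assert np.max(np.abs(res.table["p_raw"].to_numpy() - r["p"].to_numpy())) < 1e-6


class TestCallDms:
    def test_all_p_one_gives_empty(self, rng):
        M, sheet = small_m_fixture(rng, n_probes=5)
        res = am.fit_moderated(M, sheet)
        res.table["p_adj"] = 1.0
        assert am.call_dms(res, 0.01) == []

    def test_probe_below_threshold_included(self, rng):
        M, sheet = small_m_fixture(rng, n_probes=5)
        res = am.fit_moderated(M, sheet)
        res.table.loc["p0", "p_adj"] = 0.005
        assert "p0" in am.call_dms(res, 0.01)

    def test_fdr_out_of_range_rejected(self, rng):
        M, sheet = small_m_fixture(rng, n_probes=5)
        res = am.fit_moderated(M, sheet)
        with pytest.raises(ValueError):
            am.call_dms(res, 1.5)


class TestAgeAdjustment:
    def test_age_confounding_inflates_unadjusted_model_only(self):
        """With age correlated with group and real age effects, the
        age-adjusted model keeps type-I error near nominal at probes with no
        group effect while the unadjusted model inflates."""
        rng = np.random.default_rng(5)
        n_probes, n_case, n_control = 2000, 15, 14
        ages = np.concatenate([rng.uniform(45, 60, n_case), rng.uniform(30, 45, n_control)])
        sheet = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n_case + n_control)],
                "group": ["case"] * n_case + ["control"] * n_control,
                "age": ages,
            }
        )
        slopes = rng.normal(0, 0.02, n_probes)
        Y = slopes[:, None] * (ages[None, :] - 45) + rng.normal(
            0, 0.3, (n_probes, n_case + n_control)
        )
        M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)], columns=sheet["sample_id"])
        adj = am.fit_moderated(M, sheet, covariates=("age",))
        unadj = am.fit_moderated(M, sheet, covariates=())
        rate_adj = (adj.table["p_raw"] < 0.05).mean()
        rate_unadj = (unadj.table["p_raw"] < 0.05).mean()
        assert rate_unadj > rate_adj
        assert 0.03 < rate_adj < 0.07


class TestGlobalAndRegionMeans:
    def test_identical_groups_give_zero_differences(self, default_cohort):
        c = default_cohort
        half = c.betas.copy()
        case_ids = c.sheet.loc[c.sheet["group"] == "case", "sample_id"]
        ctrl_ids = c.sheet.loc[c.sheet["group"] == "control", "sample_id"]
        n = min(len(case_ids), len(ctrl_ids))
        half[case_ids[:n].tolist()] = half[ctrl_ids[:n].tolist()].to_numpy()
        sheet = c.sheet[c.sheet["sample_id"].isin(case_ids[:n].tolist() + ctrl_ids[:n].tolist())]
        out = am.global_and_region_means(half[sheet["sample_id"].tolist()], sheet, c.manifest)
        assert out.loc["global", "diff"] == pytest.approx(0.0, abs=1e-15)
        assert out.loc["global", "p"] == pytest.approx(1.0)

    def test_planted_global_shift_recovered(self):
        diffs = []
        for seed in range(10):
            c = am.simulate_cohort(
                am.SimulationConfig(n_probes=2000, frac_dms=0.0, frac_de=0.0, seed=300 + seed)
            )
            betas = c.betas.copy()
            case_ids = c.sheet.loc[c.sheet["group"] == "case", "sample_id"].tolist()
            betas[case_ids] = (betas[case_ids] + 0.005).clip(upper=1 - 1e-6)
            out = am.global_and_region_means(betas, c.sheet, c.manifest)
            diffs.append(out.loc["global", "diff"])
        assert np.mean(diffs) == pytest.approx(0.005, abs=0.002)

    def test_null_strata_differences_below_one_percent(self, default_cohort):
        """With no planted global effect all per-stratum group differences are
        small in absolute beta units (the sub-1 % regime)."""
        c = am.simulate_cohort(am.SimulationConfig(n_probes=4000, frac_dms=0.0, seed=77))
        out = am.global_and_region_means(c.betas, c.sheet, c.manifest)
        assert (out["abs_diff"].dropna() < 0.01).all()
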