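"""Factorial proteomics statistics: imputation, ANOVA, screen, clusters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from acidhif.proteomics import (
    DataError,
    acid_selective_cluster,
    cluster_hypoxic_responses,
    correlate_with_reference,
    fisher_enrichment,
    fit_factorial_anova,
    impute_minprob,
    standardize_rows,
)
from acidhif.simulate import (
    EffectClass,
    ProteomicsSimSpec,
    make_abundance_matrix,
    make_design,
)


@pytest.fixture(scope="module")
def null_matrix():
    spec = ProteomicsSimSpec(
        n_proteins=5000, effect_classes={}, censor_max_prob=0.0, seed=21
    )
    mat, design, _ = make_abundance_matrix(spec)
    return mat, design


class TestImputation:
    def test_complete_matrix_unchanged(self):
        mat, design, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=50, censor_max_prob=0.0, seed=1)
        )
        out, mask = impute_minprob(mat, seed=0)
        assert out.equals(mat) and not mask.any().any()

    def test_observed_entries_preserved_bit_exactly(self):
        mat, _, _ = make_abundance_matrix(ProteomicsSimSpec(n_proteins=400, seed=2))
        out, mask = impute_minprob(mat, seed=3)
        obs = ~mat.isna()
        assert np.array_equal(out.values[obs.values], mat.values[obs.values])

    def test_imputed_values_center_near_low_quantile(self):
        mat, _, _ = make_abundance_matrix(ProteomicsSimSpec(n_proteins=2000, seed=4))
        out, mask = impute_minprob(mat, q=0.01, seed=5)
        for col in mat.columns[:4]:
            if not mask[col].any():
                continue
            target = np.quantile(mat[col].dropna(), 0.01)
            imputed = out.loc[mask[col], col]
            assert imputed.mean() == pytest.approx(target, abs=0.2)
            assert imputed.mean() < mat[col].mean()

    def test_fully_missing_sample_rejected(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(DataError):
            impute_minprob(mat)

    def test_seeded_reproducibility(self):
        mat, _, _ = make_abundance_matrix(ProteomicsSimSpec(n_proteins=200, seed=6))
        a, _ = impute_minprob(mat, seed=7)
        b, _ = impute_minprob(mat, seed=7)
        assert a.equals(b)


class TestFactorialAnova:
    def test_constant_row_flagged_not_significant(self):
        design = make_design()
        mat, _, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=20, censor_max_prob=0.0, seed=8)
        )
        mat.iloc[0] = 5.0
        res = fit_factorial_anova(mat, design)
        assert res.anova["flag_constant"].iloc[0]
        assert res.anova["p_acidosis"].iloc[0] == 1.0

    def test_global_null_type_one_error_calibrated(self, null_matrix):
        mat, design = null_matrix
        res = fit_factorial_anova(mat, design)
        n = len(mat)
        se3 = 3 * math.sqrt(0.05 * 0.95 / n)
        for eff in ("acidosis", "hypoxia", "interaction"):
            rate = float((res.anova[f"p_{eff}"] < 0.05).mean())
            assert abs(rate - 0.05) < se3
            assert int((res.anova[f"q_{eff}"] < 0.05).sum()) <= 2

    def test_interaction_power_meets_noncentral_f_oracle(self):
        # interaction of 2 log2 units at residual sd 0.5 in a 2x2x3 design:
        # ncp = delta^2 / (4 sigma^2 / 3) = 12; with moderated (shared)
        # variances the moderated test approaches the chi-square bound
        from scipy import stats as sps

        spec = ProteomicsSimSpec(
            n_proteins=1000,
            residual_sd=0.5,
            batch_sd=0.3,
            censor_max_prob=0.0,
            effect_classes={"X": EffectClass(1.0, 0.0, 2.0, 0.0)},
            seed=22,
        )
        mat, design, labels = make_abundance_matrix(spec)
        res = fit_factorial_anova(mat, design, moderated=True)
        power = float((res.anova["q_interaction"] < 0.05).mean())
        assert power >= 0.9
        # oracle: at the BH-effective per-test level the noncentral bound holds
        ncp = 2.0**2 / (4 * 0.5**2 / 3)
        upper = float(sps.ncx2.sf(sps.chi2.isf(0.05, 1), 1, ncp))
        assert power <= upper + 0.03

    def test_balanced_f_statistics_match_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        design = make_design()
        mat, _, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=8, censor_max_prob=0.0, seed=9)
        )
        res = fit_factorial_anova(mat, design)
        for i in range(len(mat)):
            df = design.copy()
            df["y"] = mat.iloc[i].to_numpy()
            model = smf.ols(
                "y ~ C(ph, Sum) * C(o2, Sum) + C(batch, Sum)", data=df
            ).fit()
            tab = sm.stats.anova_lm(model, typ=3)
            assert res.anova["F_acidosis"].iloc[i] == pytest.approx(
                tab.loc["C(ph, Sum)", "F"], rel=1e-6
            )
            assert res.anova["F_hypoxia"].iloc[i] == pytest.approx(
                tab.loc["C(o2, Sum)", "F"], rel=1e-6
            )
            assert res.anova["F_interaction"].iloc[i] == pytest.approx(
                tab.loc["C(ph, Sum):C(o2, Sum)", "F"], rel=1e-6
            )

    def test_contrast_fold_changes_recover_planted_effects(self):
        spec = ProteomicsSimSpec(
            n_proteins=400,
            residual_sd=0.2,
            censor_max_prob=0.0,
            effect_classes={"A": EffectClass(0.5, 2.0, 0.3, 0.0)},
            seed=10,
        )
        mat, design, labels = make_abundance_matrix(spec)
        res = fit_factorial_anova(mat, design)
        sel = (labels == "A").to_numpy()
        assert res.contrasts.loc[sel, "log2fc_hypoxia_alkaline"].mean() == pytest.approx(2.0, abs=0.05)
        assert res.contrasts.loc[sel, "log2fc_hypoxia_acidic"].mean() == pytest.approx(0.3, abs=0.05)

    def test_missing_values_rejected(self):
        mat, design, _ = make_abundance_matrix(ProteomicsSimSpec(n_proteins=50, seed=11))
        with pytest.raises(DataError):
            fit_factorial_anova(mat, design)


class TestBenjaminiHochberg:
    @staticmethod
    def bh_stepup(p, alpha):
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p)
        thresh = alpha * np.arange(1, n + 1) / n
        below = p[order] <= thresh
        rej = np.zeros(n, dtype=bool)
        if below.any():
            k = int(np.max(np.nonzero(below)[0])) + 1
            rej[order[:k]] = True
        return rej

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=60))
    @settings(deadline=None, max_examples=80)
    def test_q_values_monotone_and_match_direct_stepup(self, pvals):
        p = np.asarray(pvals)
        q = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)
        for alpha in (0.01, 0.05, 0.2):
            assert np.array_equal(q <= alpha, self.bh_stepup(p, alpha))


class TestCorrelationScreen:
    def test_identity_and_sign_flip(self):
        mat, design, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=30, censor_max_prob=0.0, seed=12)
        )
        mat.loc["P00001"] = mat.loc["P00000"]
        mat.loc["P00002"] = -mat.loc["P00000"]
        screen = correlate_with_reference(mat, "P00000")
        assert screen.loc["P00001", "r"] == pytest.approx(1.0)
        assert screen.loc["P00002", "r"] == pytest.approx(-1.0)
        assert "P00000" not in screen.index

    def test_null_screen_finds_nothing(self):
        # iid null: no planted effects and no batch blocks, so Pearson
        # p-values are exactly calibrated
        spec = ProteomicsSimSpec(
            n_proteins=800, effect_classes={}, censor_max_prob=0.0, batch_sd=0.0, seed=13
        )
        mat, _, _ = make_abundance_matrix(spec)
        screen = correlate_with_reference(mat, "P00000")
        assert (screen["q"] < 0.05).sum() == 0

    def test_zero_variance_rows_excluded(self):
        mat, _, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=20, censor_max_prob=0.0, seed=14)
        )
        mat.loc["P00005"] = 3.0
        screen = correlate_with_reference(mat, "P00000")
        assert screen.loc["P00005", "excluded"]
        assert np.isnan(screen.loc["P00005", "r"])

    def test_spearman_option(self):
        mat, _, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=30, censor_max_prob=0.0, seed=15)
        )
        screen = correlate_with_reference(mat, "P00000", method="spearman")
        assert screen["r"].abs().max() <= 1.0


@pytest.fixture(scope="module")
def clustered_run():
    spec = ProteomicsSimSpec(
        n_proteins=600,
        residual_sd=0.25,
        censor_max_prob=0.0,
        effect_classes={
            "A": EffectClass(0.08, 2.0, 0.2, 0.0),
            "B": EffectClass(0.08, 2.0, 1.2, 0.0),
            "C": EffectClass(0.08, 1.5, 2.8, 0.5),
            "D": EffectClass(0.08, -1.8, -1.8, 0.0),
        },
        seed=16,
    )
    mat, design, labels = make_abundance_matrix(spec)
    res = fit_factorial_anova(mat, design, moderated=True)
    return mat, design, res, labels


class TestClustering:
    def test_standardized_rows_zero_mean_unit_sd(self):
        mat, _, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=40, censor_max_prob=0.0, seed=17)
        )
        z = standardize_rows(mat)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_two_archetypes_perfect_membership(self):
        design = make_design()
        rng = np.random.default_rng(0)
        up = np.where(design["o2"] == "hypoxia", 2.0, 0.0)
        down = np.where(design["o2"] == "hypoxia", -2.0, 0.0)
        rows = [up + rng.normal(0, 0.05, 12) for _ in range(10)] + [
            down + rng.normal(0, 0.05, 12) for _ in range(10)
        ]
        mat = pd.DataFrame(rows, index=[f"P{i}" for i in range(20)], columns=design["sample"])
        mat += 20.0
        res = fit_factorial_anova(mat, design)
        clusters = cluster_hypoxic_responses(mat, design, res, n_clusters=2)
        lab = clusters.labels
        assert lab.iloc[:10].nunique() == 1 and lab.iloc[10:].nunique() == 1
        assert lab.iloc[0] != lab.iloc[-1]

    def test_archetype_recovery_adjusted_rand(self, clustered_run):
        from sklearn.metrics import adjusted_rand_score

        mat, design, res, labels = clustered_run
        clusters = cluster_hypoxic_responses(mat, design, res, n_clusters=4)
        truth = labels.loc[clusters.labels.index]
        # selection is dominated by the four planted archetypes
        assert (truth != "null").mean() > 0.95
        keep = truth != "null"
        ari = adjusted_rand_score(truth[keep], clusters.labels[keep])
        assert ari >= 0.8

    def test_downregulated_archetype_lands_in_negative_cluster(self, clustered_run):
        mat, design, res, labels = clustered_run
        clusters = cluster_hypoxic_responses(mat, design, res, n_clusters=4)
        truth = labels.loc[clusters.labels.index]
        d_cluster = clusters.labels[truth == "D"].mode().iloc[0]
        means = clusters.scatter.groupby("cluster")[
            ["log2fc_hypoxia_alkaline", "log2fc_hypoxia_acidic"]
        ].mean()
        assert means.loc[d_cluster, "log2fc_hypoxia_alkaline"] < 0
        assert means.loc[d_cluster, "log2fc_hypoxia_acidic"] < 0

    def test_interaction_mode_extracts_acid_selective_group(self):
        spec = ProteomicsSimSpec(
            n_proteins=500,
            residual_sd=0.25,
            censor_max_prob=0.0,
            effect_classes={
                "B": EffectClass(0.1, 2.0, 1.2, 0.0),
                "E": EffectClass(0.1, 0.0, 2.5, 0.0),
            },
            seed=18,
        )
        mat, design, labels = make_abundance_matrix(spec)
        res = fit_factorial_anova(mat, design, moderated=True)
        clusters = cluster_hypoxic_responses(
            mat, design, res, selection="interaction", n_clusters=2
        )
        e_id = acid_selective_cluster(clusters)
        truth = labels.loc[clusters.labels.index]
        members = clusters.labels[clusters.labels == e_id].index
        assert (truth.loc[members] == "E").mean() >= 0.8
        selected_e = truth[truth == "E"].index
        recall = clusters.labels.loc[selected_e].eq(e_id).mean()
        assert recall >= 0.9

    def test_too_few_selected_proteins_raises(self):
        mat, design, _ = make_abundance_matrix(
            ProteomicsSimSpec(n_proteins=30, effect_classes={}, censor_max_prob=0.0, seed=19)
        )
        res = fit_factorial_anova(mat, design)
        with pytest.raises(DataError):
            cluster_hypoxic_responses(mat, design, res, n_clusters=4)


class TestFisherEnrichment:
    def test_proportional_set_odds_near_one(self):
        universe = [f"P{i}" for i in range(1000)]
        category = universe[:100]
        prot_set = universe[::10]  # 10% of universe, 10% of category
        res = fisher_enrichment(universe, prot_set, category)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.35)
        assert res.p_value > 0.3

    def test_toy_table_matches_brute_force_hypergeometric_tail(self):
        universe = [f"P{i}" for i in range(1000)]
        prot_set = universe[:100]
        category = universe[70:150]  # overlap 30, category size 80
        res = fisher_enrichment(universe, prot_set, category)
        N, K, n = 1000, 80, 100
        tail = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(30, min(K, n) + 1)
        )
        assert res.p_value == pytest.approx(tail, rel=1e-9)
        assert res.counts["set_and_category"] == 30

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError):
            fisher_enrichment([], ["a"], ["a"])
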