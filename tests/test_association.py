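import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import bh_adjust_brute

from microvar import association, diversity, variability
from microvar.exceptions import DomainError, InsufficientDataError
from microvar.formats_io import CohortMetadata, FeatureTable, PatientInfo
from microvar.synthetic import CohortConfig, generate_cohort


class TestRelativeAbundance:
    def test_column_normalized(self):
        table = FeatureTable(
            ["t1", "t2"], ["s1", "s2"], np.array([[2, 1], [2, 3]]),
            {"t1": "G", "t2": "G"},
        )
        rel = association.relative_abundance(table)
        assert rel["s1"].tolist() == [0.5, 0.5]
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_total_rejected(self):
        table = FeatureTable(
            ["t1"], ["s1", "s2"], np.array([[1, 0]]), {"t1": "G"}
        )
        with pytest.raises(DomainError, match="s2"):
            association.relative_abundance(table)


class TestAggregateGenus:
    def test_sums_by_genus(self):
        table = FeatureTable(
            ["t1", "t2"], ["s1", "s2"], np.array([[2, 0], [3, 5]]),
            {"t1": "G", "t2": "G"},
        )
        agg = association.aggregate_genus(table)
        assert agg.taxon_ids == ["G"]
        assert agg.counts.tolist() == [[5, 5]]

    def test_preserves_sample_totals(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(6, 4))
        counts[0] += 1
        table = FeatureTable(
            [f"t{i}" for i in range(6)],
            [f"s{j}" for j in range(4)],
            counts,
            {f"t{i}": f"g{i % 3}" for i in range(6)},
        )
        agg = association.aggregate_genus(table)
        assert np.array_equal(agg.sample_totals(), table.sample_totals())

    def test_unclassified_kept_separate(self):
        table = FeatureTable(
            ["t1", "t2"], ["s1"], np.array([[2], [3]]),
            {"t1": "unclassified", "t2": "G"},
        )
        agg = association.aggregate_genus(table)
        assert set(agg.taxon_ids) == {"unclassified", "G"}


class TestPearson:
    def test_perfect_positive(self):
        r, _ = association.pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = association.pearson([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_partial(self):
        r, _ = association.pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_constant_rejected(self):
        with pytest.raises(DomainError):
            association.pearson([1, 1, 1], [1, 2, 3])


class TestKruskalWallis:
    def test_separated_groups(self):
        h, _ = association.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857142857, abs=1e-6)

    def test_equal_rank_sums(self):
        h, p = association.kruskal_wallis([[1, 4], [2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            association.kruskal_wallis([[1, 2], []])

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            association.kruskal_wallis([[1, 2, 3]])

    def test_all_identical_degenerate(self):
        h, p = association.kruskal_wallis([[2, 2], [2, 2, 2]])
        assert h == 0.0
        assert p == 1.0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_two_group_consistency_with_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, 13.0))  # tie-free
        a, b = pooled[:6], pooled[6:]
        _, p_kw = association.kruskal_wallis([a, b])
        _, p_mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                     use_continuity=False)
        assert (p_kw < 0.05) == (p_mw < 0.05)


class TestWelchT:
    def test_identical_groups(self):
        t, _, p = association.welch_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_case(self):
        t, df, _ = association.welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674234614, abs=1e-6)
        assert df == pytest.approx(4.0)

    def test_antisymmetry(self):
        t1, _, p1 = association.welch_t([1, 2, 3], [4, 6, 8])
        t2, _, p2 = association.welch_t([4, 6, 8], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_undersized_group(self):
        with pytest.raises(InsufficientDataError):
            association.welch_t([1], [2, 3])


class TestMannWhitney:
    def test_exact_extreme(self):
        u, p = association.mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3, abs=1e-9)

    def test_interleaved(self):
        # pair counting: only 3 > 2, so U_a = 1, U_b = 3, min = 1
        u, _ = association.mann_whitney([1, 3], [2, 4])
        assert u == pytest.approx(1.0)

    def test_identical_multisets(self):
        values = [1.0, 2.0, 3.0]
        u, _ = association.mann_whitney(values, values)
        assert u == pytest.approx(len(values) ** 2 / 2)

    def test_empty_group(self):
        with pytest.raises(InsufficientDataError):
            association.mann_whitney([], [1, 2])

    def test_large_sample_uses_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.random(20)
        b = rng.random(20) + 0.5
        u, p = association.mann_whitney(a, b)
        assert 0 <= p <= 1


class TestBenjaminiHochberg:
    def test_equal_ladder(self):
        adj = association.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert association.benjamini_hochberg([0.05]).tolist() == [0.05]

    def test_step_up_with_cummin(self):
        adj = association.benjamini_hochberg([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            association.benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_brute_force_and_invariants(self, p):
        adj = association.benjamini_hochberg(p)
        assert np.allclose(adj, bh_adjust_brute(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_idempotent_on_uniform_ladder(self):
        # the flat ladder is a fixed point of the step-up adjustment
        ladder = [0.04, 0.04, 0.04, 0.04]
        assert np.allclose(association.benjamini_hochberg(ladder), ladder)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(40)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(association.benjamini_hochberg(p), adj_sm, atol=1e-12)


# ---------------------------------------------------------------------------
# Screen-level tests on synthetic cohorts
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = CohortConfig(n_patients=24, depth=2000.0, seed=123)
    table, tree, meta, truth = generate_cohort(cfg)
    alpha = diversity.alpha_table(table)
    dm_wu = diversity.beta_matrix(table, tree, "weighted_normalized")
    profiles = variability.build_profiles(alpha, {"wu": dm_wu}, meta)
    genus_rel = association.relative_abundance(association.aggregate_genus(table))
    return table, meta, truth, profiles, genus_rel


class TestGenusCvCorrelation:
    def test_planted_signs(self, planted_cohort):
        _, meta, _, profiles, genus_rel = planted_cohort
        res = association.genus_cv_correlation(
            genus_rel, profiles, meta, "cv_wu", "stool"
        ).set_index("feature")
        assert res.loc["Staphylococcus", "statistic"] > 0
        assert res.loc["Akkermansia", "statistic"] < 0

    def test_sorted_by_r_descending(self, planted_cohort):
        _, meta, _, profiles, genus_rel = planted_cohort
        res = association.genus_cv_correlation(genus_rel, profiles, meta, "cv_wu", "oral")
        assert (np.diff(res["statistic"]) <= 1e-12).all()

    def test_constant_genus_excluded(self, planted_cohort):
        _, meta, _, profiles, genus_rel = planted_cohort
        doctored = genus_rel.copy()
        doctored.loc["Bacteroides"] = 0.01
        res = association.genus_cv_correlation(doctored, profiles, meta, "cv_wu", "stool")
        assert "Bacteroides" not in set(res["feature"])

    def test_permutation_null_calibration(self, planted_cohort):
        _, meta, _, profiles, genus_rel = planted_cohort
        rng = np.random.default_rng(9)
        rates = []
        for _ in range(40):
            shuffled = profiles.copy()
            for site in ("oral", "stool"):
                mask = shuffled["site"] == site
                shuffled.loc[mask, "cv_wu"] = rng.permutation(
                    shuffled.loc[mask, "cv_wu"].to_numpy()
                )
            res = association.genus_cv_correlation(
                genus_rel, shuffled, meta, "cv_wu", "stool", level="patient_mean"
            )
            rates.extend((res["p_raw"] < 0.05).tolist())
        # ~0.05 within a generous binomial band
        assert 0.01 <= np.mean(rates) <= 0.10


class TestGenusCategoryTests:
    def test_planted_destabilizer_detected(self, planted_cohort):
        _, meta, _, profiles, genus_rel = planted_cohort
        cats = variability.categorize(profiles, "cv_wu")
        res = association.genus_category_tests(genus_rel, cats, meta, "stool")
        assert "stars" in res.columns
        row = res.set_index("feature").loc["Staphylococcus"]
        assert row["p_adj"] <= 0.1  # strong planting at these settings

    def test_identical_abundance_h_zero(self, planted_cohort):
        _, meta, _, profiles, genus_rel = planted_cohort
        cats = variability.categorize(profiles, "cv_wu")
        flat = genus_rel.copy()
        flat.loc["Bacteroides"] = 0.02
        res = association.genus_category_tests(flat, cats, meta, "stool").set_index("feature")
        assert res.loc["Bacteroides", "statistic"] == 0.0
        assert res.loc["Bacteroides", "p_adj"] == 1.0

    def test_empty_category_errors(self, planted_cohort):
        _, meta, _, profiles, genus_rel = planted_cohort
        cats = variability.categorize(profiles, "cv_wu")
        broken = cats[cats["category"] != "variable"]
        with pytest.raises(InsufficientDataError, match="variable"):
            association.genus_category_tests(genus_rel, broken, meta, "stool")


class TestOutcomeComparisons:
    def test_planted_infection_effect(self, planted_cohort):
        _, meta, truth, profiles, _ = planted_cohort
        res = association.outcome_comparisons(
            profiles, meta, "infection_during_ic_any", "cv_shannon", "oral"
        )
        assert res.statistic_name == "welch_t"
        assert 0 <= res.p_raw <= 1

    def test_single_group_errors(self, planted_cohort):
        _, meta, _, profiles, _ = planted_cohort
        all_pos = CohortMetadata(
            samples=dict(meta.samples),
            patients={
                pid: PatientInfo(
                    **{**vars(info), "infection_during_ic": "MDI"}
                )
                for pid, info in meta.patients.items()
            },
        )
        with pytest.raises(InsufficientDataError):
            association.outcome_comparisons(
                profiles, all_pos, "infection_during_ic_any", "cv_shannon", "oral"
            )

    def test_missing_outcome_patients_skipped(self):
        profiles = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(6)],
                "site": "oral",
                "n_samples": 4,
                "cv_shannon": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            }
        )
        for m in variability.CV_MEASURES:
            if m not in profiles:
                profiles[m] = np.nan
        patients = {
            f"P{i}": PatientInfo(infection_during_ic=v)
            for i, v in enumerate(["MDI", "none", "clinical", "none", None, "none"])
        }
        meta = CohortMetadata(samples={}, patients=patients)
        res = association.outcome_comparisons(
            profiles, meta, "infection_during_ic_any", "cv_shannon", "oral"
        )
        assert res.n == 5  # P4 has no label

    def test_genus_outcome_mann_whitney(self, planted_cohort):
        _, meta, _, _, genus_rel = planted_cohort
        res = association.genus_outcome_tests(
            genus_rel, meta, "infection_during_ic_any", "oral",
            ["Streptococcus", "Stenotrophomonas", "Staphylococcus"],
        )
        assert set(res["statistic_name"]) == {"mannwhitney_U"}
        assert len(res) == 3


class TestMultivariableOLS:
    def _profiles_meta(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        patients = {}
        for i in range(n):
            patients[f"P{i:02d}"] = PatientInfo(
                age=float(rng.integers(30, 80)),
                days_all_abx=float(rng.integers(10, 40)),
                days_treatment_abx=float(rng.integers(0, 25)),
                n_antibiotics=int(rng.integers(1, 9)),
                pip_tazo_gt72h=bool(rng.random() < 0.3),
                cefepime_gt72h=bool(rng.random() < 0.4),
                carbapenem_gt72h=bool(rng.random() < 0.6),
                chemo_category=str(
                    rng.choice(
                        ["fludarabine", "non_fludarabine_high_intensity",
                         "hypomethylator", "other"]
                    )
                ),
            )
        meta = CohortMetadata(samples={}, patients=patients)
        profiles = pd.DataFrame(
            {
                "patient_id": list(patients),
                "site": "oral",
                "n_samples": 5,
                "cv_shannon": [
                    0.05 + 0.01 * patients[p].days_all_abx for p in patients
                ],
            }
        )
        for m in variability.CV_MEASURES:
            if m not in profiles:
                profiles[m] = np.nan
        return profiles, meta

    def test_exact_linear_recovery(self):
        profiles, meta = self._profiles_meta()
        res = association.multivariable_ols(profiles, meta, "oral", "cv_shannon")
        res = res.set_index("covariate")
        assert res.loc["days_all_abx", "coef"] == pytest.approx(0.01, abs=1e-10)
        others = [c for c in association.REGRESSION_COVARIATES if c != "days_all_abx"]
        assert np.allclose(res.loc[others, "coef"], 0.0, atol=1e-9)

    def test_missing_covariates_named(self):
        profiles, meta = self._profiles_meta()
        meta.patients["P03"].age = None
        with pytest.raises(DomainError, match="P03"):
            association.multivariable_ols(profiles, meta, "oral", "cv_shannon")

    def test_rank_deficiency_detected(self):
        profiles, meta = self._profiles_meta()
        for info in meta.patients.values():
            info.days_treatment_abx = info.days_all_abx  # duplicate column
        with pytest.raises(DomainError, match="collinear"):
            association.multivariable_ols(profiles, meta, "oral", "cv_shannon")

    def test_unbiased_under_noise(self):
        coefs = []
        for seed in range(30):
            profiles, meta = self._profiles_meta(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            profiles["cv_shannon"] += rng.normal(0, 0.02, size=len(profiles))
            res = association.multivariable_ols(
                profiles, meta, "oral", "cv_shannon"
            ).set_index("covariate")
            coefs.append(res.loc["days_all_abx", "coef"])
        assert np.mean(coefs) == pytest.approx(0.01, abs=0.002)
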