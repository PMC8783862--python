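"""Selection cascade: concordance, association, direction, autosome, lookup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from testoscreen import (
    AssociationVariantSelector,
    CohortSpec,
    ScreenConfig,
    VariantSpec,
    autosome_filter,
    bonferroni_threshold,
    lookup_filter,
    nominal_direction_filter,
    per_variant_association,
    sex_concordance_filter,
    simulate_discovery_panel,
    simulate_genotypes,
)


def _stats(rows):
    return pd.DataFrame(rows, columns=["rsid", "sex", "beta"])


class TestSexConcordance:
    def test_synthetic_panel_count(self):
        panel = simulate_discovery_panel(855, 33, seed=17)
        assert len(sex_concordance_filter(panel)) == 822

    def test_concordant_kept_discordant_dropped(self):
        stats = _stats(
            [("rs1", "male", 0.1), ("rs1", "female", 0.2),
             ("rs2", "male", 0.1), ("rs2", "female", -0.1),
             ("rs3", "male", -0.3), ("rs3", "female", -0.1)]
        )
        assert sex_concordance_filter(stats) == ["rs1", "rs3"]

    def test_zero_beta_is_excluded(self):
        stats = _stats([("rs1", "male", 0.0), ("rs1", "female", 0.2)])
        assert sex_concordance_filter(stats) == []

    def test_missing_stratum_raises(self):
        stats = _stats([("rs1", "male", 0.1)])
        with pytest.raises(ValueError, match="female"):
            sex_concordance_filter(stats)

    def test_idempotent_on_own_output(self):
        panel = simulate_discovery_panel(100, 20, seed=3)
        kept = sex_concordance_filter(panel)
        again = sex_concordance_filter(panel[panel["rsid"].isin(kept)])
        assert again == kept


class TestPerVariantAssociation:
    def test_noiseless_linear_trait_recovers_slope_exactly(self, small_genotypes):
        y = 2.0 + 3.0 * small_genotypes.dosages[:, 0]
        res = per_variant_association(small_genotypes, y)
        row = res.iloc[0]
        assert row["beta"] == pytest.approx(3.0, abs=1e-8)
        assert row["p"] < 1e-12

    def test_matches_normal_equations_oracle(self):
        # <= 20-row instance checked against an explicit (X'X)^-1 X'y solve
        rng = np.random.default_rng(0)
        n = 18
        d = rng.integers(0, 3, size=n).astype(float)
        cov = rng.normal(size=n)
        y = 1.0 + 0.7 * d - 0.4 * cov + rng.normal(size=n)
        panel = [VariantSpec("rs1", "1", 1, "A", "G", 0.3)]
        from testoscreen.genio import GenotypeTable

        gt = GenotypeTable([f"i{i}" for i in range(n)], panel, d.reshape(-1, 1))
        res = per_variant_association(
            gt, pd.Series(y, index=gt.individual_ids),
            pd.DataFrame({"cov": cov}, index=gt.individual_ids),
        )
        X = np.column_stack([np.ones(n), d, cov])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert res["beta"].iloc[0] == pytest.approx(beta_oracle, rel=1e-8)

    def test_constant_dosage_flagged_untestable(self):
        panel = [VariantSpec("rs1", "1", 1, "A", "G", 0.0)]
        gt = simulate_genotypes(CohortSpec(n=30, panel=panel, seed=0))
        y = np.random.default_rng(1).normal(size=30)
        res = per_variant_association(gt, y)
        assert not res["testable"].iloc[0]
        assert not res["passed"].iloc[0]

    def test_collinear_covariates_raise_with_names(self, small_genotypes):
        n = len(small_genotypes.individual_ids)
        rng = np.random.default_rng(2)
        z = rng.normal(size=n)
        cov = pd.DataFrame({"z": z, "z2": 2 * z}, index=small_genotypes.individual_ids)
        with pytest.raises(ValueError, match="z2"):
            per_variant_association(small_genotypes, rng.normal(size=n), cov)

    def test_listwise_deletion_counts_complete_cases(self, small_genotypes):
        y = np.random.default_rng(3).normal(size=40)
        y[:5] = np.nan
        res = per_variant_association(small_genotypes, y)
        assert (res["n_used"] <= 35).all()

    def test_logistic_model_runs_on_median_split(self, athlete_panel):
        from testoscreen.simulate import default_csa_model, simulate_cohort

        spec = CohortSpec(
            n=800, panel=athlete_panel,
            trait_models=[default_csa_model(athlete_panel)], seed=12,
        )
        gt, pheno = simulate_cohort(spec)
        cfg = ScreenConfig(model="logistic")
        res = per_variant_association(gt, pheno["csa_fast_twitch"], config=cfg)
        assert res["p"].between(0, 1).all()
        # log-odds betas, not um^2: magnitudes far below the linear-scale effects
        assert res["beta"].abs().max() < 10


class TestSelectorEstimator:
    def test_sklearn_contract(self, small_genotypes):
        from sklearn.base import clone

        sel = AssociationVariantSelector(alpha=0.01, direction=-1)
        params = sel.get_params()
        assert params["alpha"] == 0.01
        sel2 = clone(sel).set_params(alpha=0.05)
        assert sel2.get_params()["direction"] == -1

    def test_transform_selects_passing_columns(self, small_genotypes):
        X = small_genotypes.to_frame()
        y = 10.0 + 5.0 * X["rs34706136"].to_numpy()
        sel = AssociationVariantSelector().fit(X, y)
        kept = sel.transform(X)
        assert "rs34706136" in kept.columns
        assert sel.get_support().sum() == kept.shape[1]


class TestNominalDirectionFilter:
    def test_reported_csa_rows_all_pass(self, reported_stats):
        res = reported_stats[reported_stats["trait"] == "csa_fast_twitch"].copy()
        assert len(nominal_direction_filter(res)) == 5

    def test_significant_wrong_direction_excluded(self):
        res = pd.DataFrame({"rsid": ["rs1"], "beta": [-2.0], "p": [0.001]})
        assert nominal_direction_filter(res) == []

    def test_p_exactly_alpha_excluded(self):
        res = pd.DataFrame({"rsid": ["rs1"], "beta": [1.0], "p": [0.05]})
        assert nominal_direction_filter(res) == []

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(4)
        res = pd.DataFrame(
            {"rsid": [f"rs{i}" for i in range(50)],
             "beta": rng.normal(size=50), "p": rng.uniform(size=50)}
        )
        kept = nominal_direction_filter(res)
        assert set(kept) <= set(res["rsid"])
        again = nominal_direction_filter(res[res["rsid"].isin(kept)])
        assert again == kept


class TestAutosomeFilter:
    def test_x_variants_dropped(self):
        variants = [VariantSpec(f"rs{i}", c, 1, "A", "G")
                    for i, c in enumerate(["1", "22", "X", "chrX", "7"])]
        variants[3] = VariantSpec("rs3", "chrX", 1, "A", "G")  # 'chr' spelling
        assert autosome_filter(variants) == ["rs0", "rs1", "rs4"]

    def test_31_to_28_shape(self):
        variants = [VariantSpec(f"rs{i}", "X" if i < 3 else str(1 + i % 22), 1, "A", "G")
                    for i in range(31)]
        assert len(autosome_filter(variants)) == 28

    def test_unrecognized_label_raises(self):
        with pytest.raises(ValueError, match="weird"):
            autosome_filter(pd.DataFrame({"rsid": ["rs1"], "chrom": ["weird"]}))


class TestLookupFilter:
    def test_reported_two_trait_lookup_keeps_all_five(self, reported_stats):
        rsids = list(dict.fromkeys(reported_stats["rsid"]))
        kept = lookup_filter(rsids, reported_stats, ("handgrip", "fat_free_mass"))
        assert len(kept) == 5

    def test_nonsignificant_trait_excludes(self, reported_stats):
        stats = reported_stats.copy()
        stats.loc[
            (stats["rsid"] == "rs850294") & (stats["trait"] == "handgrip"), "p"
        ] = 0.2
        kept = lookup_filter(["rs850294"], stats, ("handgrip", "fat_free_mass"))
        assert kept == []

    def test_variant_missing_from_stats_excluded_with_warning(self, reported_stats, caplog):
        with caplog.at_level("WARNING"):
            kept = lookup_filter(["rs_unknown"], reported_stats, ("handgrip",))
        assert kept == []
        assert "rs_unknown" in caplog.text

    def test_absent_trait_raises(self, reported_stats):
        with pytest.raises(ValueError, match="grip_strength"):
            lookup_filter(["rs850294"], reported_stats, ("grip_strength",))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,t,expected",
        [(0.05, 822, 3, 0.05 / 2466), (0.05, 1, 1, 0.05), (0.05, 10, 2, 0.0025)],
    )
    def test_closed_form(self, alpha, m, t, expected):
        assert bonferroni_threshold(alpha, m, t) == pytest.approx(expected)

    def test_published_threshold_prints_as_0_00002(self):
        assert f"{bonferroni_threshold(0.05, 822, 3):.5f}" == "0.00002"

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0, 3)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n_total=st.integers(min_value=1, max_value=60),
    data=st.data(),
)
def test_concordance_filter_count_matches_construction(n_total, data):
    n_disc = data.draw(st.integers(min_value=0, max_value=n_total))
    panel = simulate_discovery_panel(n_total, n_disc, seed=99)
    assert len(sex_concordance_filter(panel)) == n_total - n_disc
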