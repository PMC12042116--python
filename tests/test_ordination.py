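"""VIF pruning, CCA, variation partitioning, taxa-environment correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biogeo import ordination
from biogeo._utils import BiogeoError

from conftest import random_count_table


@pytest.fixture()
def env(rng):
    n = 40
    return pd.DataFrame(
        rng.normal(size=(n, 3)),
        index=[f"s{i}" for i in range(n)],
        columns=["temperature", "salinity", "pH"],
    )


class TestVif:
    def test_single_variable_kept_with_vif_one(self, env):
        kept, trace = ordination.vif_prune(env[["temperature"]])
        assert kept == ["temperature"]
        assert trace["vif"].iloc[0] == pytest.approx(1.0)

    def test_duplicated_variable_removed(self, env):
        dup = env.copy()
        dup["salinity_copy"] = dup["salinity"]
        kept, trace = ordination.vif_prune(dup)
        assert "salinity" in kept
        assert "salinity_copy" not in kept
        assert len(kept) == 3

    def test_independent_variables_all_kept(self, rng):
        x = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        kept, trace = ordination.vif_prune(x)
        assert kept == list("abc")
        assert (trace["vif"] < 1.5).all()

    def test_vif_matches_direct_regression(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        x["b"] = x["a"] * 0.8 + x["b"] * 0.3  # induce collinearity
        vifs = ordination.variance_inflation(x)
        # direct R^2 computation for column a
        import statsmodels.api as sm
        fit = sm.OLS(x["a"], sm.add_constant(x[["b", "c"]])).fit()
        assert vifs["a"] == pytest.approx(1 / (1 - fit.rsquared), rel=1e-9)


def _gradient_table(rng, n=60, m=15, noise=0.0):
    """Community driven by one latent gradient (unimodal responses)."""
    grad = np.linspace(0, 1, n)
    optima = np.linspace(0, 1, m)
    mu = 200 * np.exp(-((grad[:, None] - optima[None, :]) ** 2) / 0.05)
    counts = np.rint(mu + noise * rng.normal(size=mu.shape)).clip(0).astype(int)
    table = pd.DataFrame(counts, index=[f"s{i}" for i in range(n)],
                         columns=[f"o{j}" for j in range(m)])
    env = pd.DataFrame({"gradient": grad, "junk": rng.normal(size=n)},
                       index=table.index)
    return table, env


class TestCca:
    def test_total_inertia_equals_chi_square_over_total(self, rng):
        table = random_count_table(rng, 15, 10) + 1
        env = pd.DataFrame(rng.normal(size=(15, 2)), index=table.index,
                           columns=["a", "b"])
        res = ordination.cca(table, env, n_perm=9, seed=0)
        chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)[0]
        assert res.total_inertia == pytest.approx(
            chi2 / table.to_numpy().sum(), abs=1e-9)

    def test_constrained_proportion_scale_invariant(self, rng):
        table = random_count_table(rng, 15, 10) + 1
        env = pd.DataFrame(rng.normal(size=(15, 2)), index=table.index,
                           columns=["a", "b"])
        r1 = ordination.cca(table, env, n_perm=9, seed=0)
        r2 = ordination.cca(table * 11, env, n_perm=9, seed=0)
        assert r1.constrained_proportion == pytest.approx(
            r2.constrained_proportion, abs=1e-9)

    def test_eigenvalues_nonnegative_nonincreasing(self, rng):
        table = random_count_table(rng, 20, 15) + 1
        env = pd.DataFrame(rng.normal(size=(20, 3)), index=table.index,
                           columns=list("abc"))
        res = ordination.cca(table, env, n_perm=9, seed=0)
        eig = res.constrained_eigenvalues
        assert (eig >= 0).all()
        assert (np.diff(eig) <= 1e-12).all()
        assert res.constrained_proportion == pytest.approx(
            eig.sum() / res.total_inertia)

    def test_single_gradient_dominates_first_axis(self, rng):
        table, env = _gradient_table(rng)
        res = ordination.cca(table, env, n_perm=9, seed=0)
        eig = res.constrained_eigenvalues
        assert eig[0] / eig.sum() > 0.95

    def test_shuffled_env_explains_little(self, rng):
        table, env = _gradient_table(rng)
        shuffled = env.sample(frac=1, random_state=1).set_index(env.index)
        strong = ordination.cca(table, env, n_perm=99, seed=0)
        weak = ordination.cca(table, shuffled, n_perm=99, seed=0)
        assert weak.constrained_proportion < strong.constrained_proportion / 3
        assert strong.permutation_p == pytest.approx(1 / 100)

    def test_duplicate_env_column_pruned_to_same_result(self, rng):
        table = random_count_table(rng, 15, 10) + 1
        env = pd.DataFrame(rng.normal(size=(15, 2)), index=table.index,
                           columns=["a", "b"])
        dup = env.copy()
        dup["a_copy"] = dup["a"]
        r1 = ordination.cca(table, env, n_perm=9, seed=0)
        r2 = ordination.cca(table, dup, n_perm=9, seed=0)
        assert r1.constrained_proportion == pytest.approx(
            r2.constrained_proportion, abs=1e-9)

    def test_too_few_samples_rejected(self, rng):
        table = random_count_table(rng, 3, 5) + 1
        env = pd.DataFrame(rng.normal(size=(3, 3)), index=table.index,
                           columns=list("abc"))
        with pytest.raises(BiogeoError, match="more samples"):
            ordination.cca(table, env, n_perm=9, seed=0)

    def test_matches_scikit_bio_cca(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        table = random_count_table(rng, 15, 10) + 1
        env = pd.DataFrame(rng.normal(size=(15, 2)), index=table.index,
                           columns=["a", "b"])
        mine = ordination.cca(table, env, n_perm=9, seed=0)
        theirs = skbio_ord.cca(table.astype(float), env)
        prop = theirs.proportion_explained[: len(mine.constrained_eigenvalues)]
        np.testing.assert_allclose(
            mine.constrained_eigenvalues / mine.total_inertia,
            prop.to_numpy(), atol=1e-9)


class TestVpa:
    def test_fractions_sum_to_one_on_random_instances(self, rng):
        for _ in range(3):
            table = random_count_table(rng, 25, 12) + 1
            env = pd.DataFrame(rng.normal(size=(25, 2)), index=table.index,
                               columns=["a", "b"])
            spa = pd.DataFrame(rng.normal(size=(25, 2)), index=table.index,
                               columns=["x", "y"])
            res = ordination.variation_partition(table, env, spa, n_perm=49, seed=0)
            total = (res.frac_E_pure + res.frac_S_pure + res.frac_shared
                     + res.frac_residual)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_identical_matrices_share_everything(self, rng):
        table, env = _gradient_table(rng)
        env = env[["gradient"]]
        res = ordination.variation_partition(table, env, env.copy(), n_perm=99, seed=0)
        assert res.frac_E_pure == pytest.approx(0.0, abs=1e-9)
        assert res.frac_S_pure == pytest.approx(0.0, abs=1e-9)
        assert res.frac_shared == pytest.approx(res.adj_r2_E, abs=1e-9)

    def test_null_community_all_fractions_near_zero(self, rng):
        n = 72
        table = pd.DataFrame(rng.integers(1, 60, size=(n, 30)),
                             index=[f"s{i}" for i in range(n)])
        table.columns = [f"o{j}" for j in range(30)]
        env = pd.DataFrame(rng.normal(size=(n, 3)), index=table.index,
                           columns=list("abc"))
        spa = pd.DataFrame(rng.normal(size=(n, 3)), index=table.index,
                           columns=list("xyz"))
        res = ordination.variation_partition(table, env, spa, n_perm=199, seed=0)
        for frac in (res.frac_E_pure, res.frac_S_pure, res.frac_shared):
            assert abs(frac) < 0.05


class TestForwardSelection:
    def test_picks_the_real_gradient(self, rng):
        table, env = _gradient_table(rng)
        selected = ordination.forward_select(table, env, alpha=0.01,
                                             n_perm=199, seed=0)
        assert selected[0] == "gradient"
        assert "junk" not in selected


class TestTaxaEnvCorrelations:
    def test_monotone_taxon_has_rho_one(self, rng):
        n = 20
        meta = pd.DataFrame({"salinity": np.linspace(30, 35, n)},
                            index=[f"s{i}" for i in range(n)])
        agg = pd.DataFrame({"TaxA": np.exp(meta["salinity"]),
                            "TaxB": rng.uniform(size=n)}, index=meta.index)
        out = ordination.taxa_env_correlations(agg, meta)
        row = out[(out.taxon == "TaxA") & (out.variable == "salinity")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert row.stars == "***"

    def test_constant_taxon_reported_na(self, rng):
        n = 12
        meta = pd.DataFrame({"pH": rng.normal(8, 0.1, n)},
                            index=[f"s{i}" for i in range(n)])
        agg = pd.DataFrame({"Flat": np.ones(n)}, index=meta.index)
        out = ordination.taxa_env_correlations(agg, meta)
        assert out["rho"].isna().all()
        assert (out["stars"] == "").all()

    @pytest.mark.parametrize("p,stars", [(0.04, "*"), (0.004, "**"),
                                         (0.0004, "***"), (0.2, ""),
                                         (float("nan"), "")])
    def test_star_thresholds(self, p, stars):
        assert ordination.significance_stars(p) == stars

    def test_null_taxa_rarely_significant(self, rng):
        # independent taxon/variable pairs: ~5% of raw p-values below 0.05
        n, reps = 30, 200
        hits = 0
        for _ in range(reps):
            t = rng.normal(size=n)
            e = rng.normal(size=n)
            _, p = stats.spearmanr(t, e)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_top_n_selection(self, rng):
        n = 15
        meta = pd.DataFrame({"pH": rng.normal(size=n)},
                            index=[f"s{i}" for i in range(n)])
        agg = pd.DataFrame(
            {"big": rng.uniform(0.5, 1.0, n), "mid": rng.uniform(0.1, 0.2, n),
             "tiny": rng.uniform(0, 0.01, n)},
            index=meta.index)
        out = ordination.taxa_env_correlations(agg, meta, top_n=2)
        assert set(out["taxon"]) == {"big", "mid"}
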