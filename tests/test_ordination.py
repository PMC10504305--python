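import numpy as np
import pandas as pd
import pytest

from microgeo.formats import ValidationError
from microgeo.ordination import (OrdinationResult, envfit, genomic_pca,
                                 nutrient_vectors, top_loadings)

from conftest import make_coverage


def random_table(n=12, p=8, seed=0, normalized=True):
    rng = np.random.default_rng(seed)
    return make_coverage(rng.uniform(0.5, 3.0, (n, p)), sccg=[False] * p,
                         normalized=normalized)


def ordination_from_scores(scores: np.ndarray) -> OrdinationResult:
    n, k = scores.shape
    cols = [f"PC{i+1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, columns=cols),
        loadings=pd.DataFrame(np.eye(k), columns=cols,
                              index=[f"g{i}" for i in range(k)]),
        var_explained=np.full(k, 1.0 / k), component_count=k,
        input_gene_ids=[f"g{i}" for i in range(k)])


class TestGenomicPca:
    def test_collinear_data_one_component(self):
        rng = np.random.default_rng(1)
        t_vec = rng.normal(size=10)
        base = np.outer(t_vec, rng.uniform(0.5, 2.0, 6)) + 10.0
        t = make_coverage(base, sccg=[False] * 6, normalized=True)
        res = genomic_pca(t, exclude_sccg=False)
        assert res.var_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_var_explained_sums_to_one(self):
        res = genomic_pca(random_table(), exclude_sccg=False)
        assert res.var_explained.sum() == pytest.approx(1.0)

    def test_reconstruction_of_zscored_input(self):
        t = random_table(seed=2)
        res = genomic_pca(t, exclude_sccg=False)
        z = (t.values - t.values.mean()) / t.values.std(ddof=1)
        rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(rec, z.to_numpy(), atol=1e-8)

    def test_matches_covariance_eigendecomposition(self):
        t = random_table(n=6, p=10, seed=3)
        res = genomic_pca(t, exclude_sccg=False)
        z = ((t.values - t.values.mean()) / t.values.std(ddof=1)).to_numpy()
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(z.T)))[::-1]
        lam = (np.linalg.svd(z, compute_uv=False) ** 2) / (6 - 1)
        np.testing.assert_allclose(lam[:res.component_count],
                                   eigvals[:res.component_count], atol=1e-10)
        # loadings orthonormal; scores orthogonal
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        S = res.scores.to_numpy()
        off = S.T @ S - np.diag(np.diag(S.T @ S))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        res = genomic_pca(random_table(seed=4), exclude_sccg=False)
        for col in res.loadings:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_sccg_excluded_by_default(self):
        t = make_coverage(np.random.default_rng(5).uniform(0.5, 2, (8, 5)),
                          sccg=[True, True, False, False, False],
                          normalized=True)
        res = genomic_pca(t)
        assert res.input_gene_ids == ["g2", "g3", "g4"]

    def test_planted_axis_recovered_across_seeds(self):
        """A single PC tracks the planted P-limitation field (>=8/10 seeds)."""
        from microgeo import SimConfig, simulate_community
        from microgeo.omega import normalize_by_sccg
        hits = 0
        for seed in range(10):
            cov, _, _, truth = simulate_community(SimConfig(seed=seed))
            res = genomic_pca(normalize_by_sccg(cov))
            best = max(abs(np.corrcoef(res.scores.iloc[:, i],
                                       truth.env_p_limitation)[0, 1])
                       for i in range(6))
            hits += best >= 0.8
        assert hits >= 8


class TestTopLoadings:
    def test_single_max_gene(self):
        res = genomic_pca(random_table(seed=6), exclude_sccg=False)
        top, _ = top_loadings(res, pc=1, n=1)
        col = res.loadings["PC1"].abs()
        assert top == [col.idxmax()]

    def test_tie_falls_back_to_gene_id_order(self):
        cols = ["PC1"]
        loadings = pd.DataFrame({"PC1": [0.5, 0.5, 0.5]},
                                index=["gb", "ga", "gc"])
        o = OrdinationResult(scores=pd.DataFrame(np.zeros((3, 1)), columns=cols),
                             loadings=loadings, var_explained=np.array([1.0]),
                             component_count=1,
                             input_gene_ids=list(loadings.index))
        top, _ = top_loadings(o, pc=1, n=3)
        assert top == ["ga", "gb", "gc"]

    def test_n_clamped_and_cog_counts(self):
        t = random_table(seed=7, p=5)
        res = genomic_pca(t, exclude_sccg=False)
        top, cogs = top_loadings(res, pc=1, n=100, gene_meta=t.gene_meta)
        assert len(top) == 5
        assert sum(cogs.values()) == 5

    def test_planted_temperature_genes_enriched(self):
        """SST-coupled genes are over-represented in the top loadings of the
        temperature-correlated component (hypergeometric p < 0.01)."""
        from scipy.stats import hypergeom
        from microgeo import SimConfig, simulate_community
        from microgeo.omega import normalize_by_sccg
        cov, _, meta, truth = simulate_community(SimConfig(seed=21))
        res = genomic_pca(normalize_by_sccg(cov))
        rs = [abs(np.corrcoef(res.scores.iloc[:, i], meta["sst"])[0, 1])
              for i in range(4)]
        pc = int(np.argmax(rs)) + 1
        top, _ = top_loadings(res, pc=pc, n=100)
        planted = set(truth.effect_table.index[
            truth.effect_table["effect"] == "sst_slope"])
        k = len(planted & set(top))
        M = len(res.input_gene_ids)
        p = hypergeom.sf(k - 1, M, len(planted), 100)
        assert p < 0.01


class TestEnvfit:
    def test_env_equals_first_axis(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=(30, 2))
        o = ordination_from_scores(scores)
        arrow = envfit(o, scores[:, 0], n_perm=99, seed=0)
        np.testing.assert_allclose(arrow.direction, [1.0, 0.0], atol=1e-8)
        assert arrow.r_squared == pytest.approx(1.0)
        assert arrow.p_value <= 0.05

    def test_diagonal_combination(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(30, 2))
        # equalize scale so the coefficient vector is symmetric
        scores = (scores - scores.mean(0)) / scores.std(0)
        o = ordination_from_scores(scores)
        arrow = envfit(o, scores[:, 0] + scores[:, 1], n_perm=9, seed=0)
        np.testing.assert_allclose(arrow.direction,
                                   [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-6)

    def test_r_squared_matches_ols_oracle(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=(25, 2))
        env = 0.3 * scores[:, 0] - 1.2 * scores[:, 1] + rng.normal(size=25)
        o = ordination_from_scores(scores)
        arrow = envfit(o, env, n_perm=9, seed=0)
        X = np.column_stack([np.ones(25), scores])
        beta, res_ss, *_ = np.linalg.lstsq(X, env, rcond=None)
        fitted = X @ beta
        r2 = 1 - ((env - fitted) ** 2).sum() / ((env - env.mean()) ** 2).sum()
        assert arrow.r_squared == pytest.approx(r2, abs=1e-10)

    def test_constant_env_rejected(self):
        o = ordination_from_scores(np.random.default_rng(11).normal(size=(10, 2)))
        with pytest.raises(ValidationError, match="constant"):
            envfit(o, np.ones(10), n_perm=9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(20, 2))
        o = ordination_from_scores(scores)
        env = rng.normal(size=20)
        a1 = envfit(o, env, n_perm=99, seed=7)
        a2 = envfit(o, env, n_perm=99, seed=7)
        assert a1.p_value == a2.p_value


class TestNutrientVectors:
    def meta(self, mapping):
        return pd.DataFrame({
            "is_sccg": False,
            "nutrient_group": [mapping.get(g, "none") for g in mapping],
            "cog_category": "unknown",
        }, index=list(mapping))

    def test_single_gene_magnitude_and_angle(self):
        loadings = pd.DataFrame({"PC1": [0.3], "PC2": [0.4]}, index=["phoA"])
        o = OrdinationResult(scores=pd.DataFrame(np.zeros((3, 2)),
                                                 columns=["PC1", "PC2"]),
                             loadings=loadings,
                             var_explained=np.array([0.6, 0.4]),
                             component_count=2, input_gene_ids=["phoA"])
        gm = self.meta({"phoA": "P"})
        vec = nutrient_vectors(o, gm)["P"]
        assert vec.mean_magnitude == pytest.approx(0.5)
        assert vec.mean_angle == pytest.approx(np.arctan2(0.4, 0.3))
        assert vec.n_genes == 1

    def test_symmetric_angles_average_to_zero(self):
        theta = 0.7
        loadings = pd.DataFrame(
            {"PC1": [np.cos(theta), np.cos(theta)],
             "PC2": [np.sin(theta), -np.sin(theta)]},
            index=["cirA", "tonB"])
        o = OrdinationResult(scores=pd.DataFrame(np.zeros((3, 2)),
                                                 columns=["PC1", "PC2"]),
                             loadings=loadings,
                             var_explained=np.array([0.5, 0.5]),
                             component_count=2,
                             input_gene_ids=["cirA", "tonB"])
        gm = self.meta({"cirA": "Fe", "tonB": "Fe"})
        assert nutrient_vectors(o, gm)["Fe"].mean_angle == pytest.approx(0.0)

    def test_empty_group_omitted_with_warning(self, caplog):
        import logging
        loadings = pd.DataFrame({"PC1": [0.1], "PC2": [0.2]}, index=["narB"])
        o = OrdinationResult(scores=pd.DataFrame(np.zeros((3, 2)),
                                                 columns=["PC1", "PC2"]),
                             loadings=loadings,
                             var_explained=np.array([0.5, 0.5]),
                             component_count=2, input_gene_ids=["narB"])
        gm = self.meta({"narB": "N"})
        with caplog.at_level(logging.WARNING, logger="microgeo.ordination"):
            out = nutrient_vectors(o, gm)
        assert set(out) == {"N"}
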