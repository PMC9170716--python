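"""Multi-view assembly, factor model recovery, projection, GSEA, target ANOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest

import orgaprofiler as op
from orgaprofiler import synthetic_data as sd
from orgaprofiler.factors import (
    FactorModel,
    MultiViewDataset,
    fit_lognormal_size,
    scale_view,
    select_high_cv_genes,
    subspace_correlations,
    total_variance_explained,
)


def _scaled_dataset(views, samples):
    scaled, scaling = {}, {}
    for v, df in views.items():
        scaled[v], scaling[v] = scale_view(df)
    return MultiViewDataset(scaled, list(samples), scaling)


class TestViewAssembly:
    def test_size_view_recovers_large_component_location(self):
        rng = np.random.default_rng(0)
        n = 5000
        small = rng.normal(4.0, 0.35, int(0.4 * n))
        large = rng.normal(6.5, 0.45, n - len(small))
        areas = np.exp(np.concatenate([small, large]))
        assert abs(fit_lognormal_size(areas, seed=0) - 6.5) < 0.05

    def test_equal_cv_genes_selected_by_id_order(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10.0, 1.0, size=(30, 1))
        expr = pd.DataFrame(
            np.repeat(base, 20, axis=1),
            columns=[f"g{i:02d}" for i in range(20)],
        )
        kept = select_high_cv_genes(expr, 0.10)
        assert list(kept.columns) == ["g00", "g01"]

    def test_inactive_drugs_excluded_from_activity_view(self):
        activity = pd.DataFrame(
            {
                "sample": ["s1", "s2"] * 2,
                "unit": ["a", "a", "b", "b"],
                "auroc": [0.9, 0.95, 0.6, 0.7],
                "active": [True, True, False, False],
            }
        )
        ds = op.assemble_views(activity=activity)
        assert list(ds.views["drug_activity"].columns) == ["a"]

    def test_scaling_is_idempotent_and_unit_total_variance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 6)))
        df.columns = [f"f{i}" for i in range(6)]
        once, sc = scale_view(df)
        assert np.isclose(once.var(ddof=0).sum(), 1.0)
        again = sc.apply(df)
        assert np.allclose(once.to_numpy(), again.to_numpy())


class TestFactorModel:
    def test_noiseless_factors_lie_in_estimated_subspace(self):
        views, truth = op.simulate_multiview(noise_sd=0.0, seed=3)
        ds = _scaled_dataset(views, truth.factor_scores.index)
        model = op.fit_factor_model(ds, k=3, seed=0)
        corr = subspace_correlations(truth.factor_scores, model.scores)
        assert corr.min() >= 0.99

    def test_noisy_recovery_and_variance_decomposition(self, multiview_noisy):
        views, truth = multiview_noisy
        ds = _scaled_dataset(views, truth.factor_scores.index)
        model = op.fit_factor_model(ds, k=3, seed=0)
        corr = subspace_correlations(truth.factor_scores, model.scores)
        assert corr.min() >= 0.9
        tve_est = total_variance_explained(model.scores, ds.views, ds.samples)
        tve_true = total_variance_explained(
            truth.factor_scores, ds.views, ds.samples
        )
        assert np.abs(tve_est - tve_true).max() <= 10.0

    def test_variance_explained_table_is_a_valid_decomposition(self, multiview_noisy):
        views, truth = multiview_noisy
        ds = _scaled_dataset(views, truth.factor_scores.index)
        model = op.fit_factor_model(ds, k=3, seed=0)
        ve = model.variance_explained.to_numpy()
        assert ve.min() >= 0.0
        assert ve.max() <= 100.0
        assert (ve.sum(axis=0) <= 100.0 + 1e-6).all()

    def test_view_independent_of_factors_explains_little(self):
        views, truth = op.simulate_multiview(noise_sd=0.2, seed=4)
        rng = np.random.default_rng(0)
        views["independent"] = pd.DataFrame(
            rng.normal(size=(22, 30)),
            index=truth.factor_scores.index,
            columns=[f"ind_{i}" for i in range(30)],
        )
        ds = _scaled_dataset(views, truth.factor_scores.index)
        model = op.fit_factor_model(ds, k=3, seed=0)
        # chance level for an OLS refit with k=3, n=22 is k/(n-1) ~ 14%
        assert model.variance_explained["independent"].sum() < 20.0

    def test_objective_never_increases(self, multiview_noisy):
        views, truth = multiview_noisy
        ds = _scaled_dataset(views, truth.factor_scores.index)
        model = op.fit_factor_model(ds, k=3, seed=0)
        assert np.all(np.diff(model.objective_trace) <= 1e-9)

    def test_too_many_factors_rejected(self):
        views, truth = op.simulate_multiview(n_samples=8, k=2, view_dims={"a": 5}, seed=0)
        ds = _scaled_dataset(views, truth.factor_scores.index)
        with pytest.raises(ValueError):
            op.fit_factor_model(ds, k=8)


class TestProjection:
    def test_self_projection_reproduces_training_scores(self, multiview_noisy):
        views, truth = multiview_noisy
        ds = _scaled_dataset(views, truth.factor_scores.index)
        model = op.fit_factor_model(ds, k=3, seed=0)
        proj = op.project_onto_factors(model, views["morphology"])
        for f in model.scores.columns:
            assert np.corrcoef(proj[f], model.scores[f])[0, 1] >= 0.95

    def test_noiseless_continuous_self_projection_is_exact(self):
        views, truth = op.simulate_multiview(
            noise_sd=0.0, seed=6,
            view_dims={"size": 1, "expression": 60, "morphology": 25, "drug_activity": 40},
        )
        ds = _scaled_dataset(views, truth.factor_scores.index)
        model = op.fit_factor_model(ds, k=3, seed=0)
        proj = op.project_onto_factors(model, views["morphology"])
        scale = np.abs(model.scores.to_numpy()).max()
        assert np.abs(proj.to_numpy() - model.scores.to_numpy()).max() < 1e-8 * scale

    def test_zero_profile_projects_to_origin(self):
        w = np.linalg.qr(np.random.default_rng(0).normal(size=(25, 3)))[0]
        model = _toy_model(w)
        zero = pd.DataFrame(
            np.zeros((1, 25)), columns=model.loadings["morphology"].index
        )
        proj = op.project_onto_factors(model, zero)
        assert np.allclose(proj.to_numpy(), 0.0)

    def test_loading_column_projects_to_unit_vector(self):
        w = np.linalg.qr(np.random.default_rng(1).normal(size=(25, 3)))[0]
        model = _toy_model(w)
        profile = pd.DataFrame(
            w[:, 1][None, :], columns=model.loadings["morphology"].index
        )
        proj = op.project_onto_factors(model, profile)
        assert np.allclose(proj.to_numpy(), [[0.0, 1.0, 0.0]], atol=1e-10)


def _toy_model(w):
    cols = [f"F{j + 1}" for j in range(w.shape[1])]
    feats = [f"PC{i + 1:02d}" for i in range(w.shape[0])]
    return FactorModel(
        k=w.shape[1],
        scores=pd.DataFrame(np.zeros((4, w.shape[1])), columns=cols),
        loadings={"morphology": pd.DataFrame(w, index=feats, columns=cols)},
        noise_variance={},
        variance_explained=pd.DataFrame(
            np.zeros((w.shape[1], 1)), index=cols, columns=["morphology"]
        ),
        scaling=None,
    )


def gsea_oracle_es(ranked: pd.Series, gene_set, weight=1.0):
    """Brute-force running sum over the full ranking."""
    scores = ranked.sort_values(ascending=False)
    hits = np.array([g in gene_set for g in scores.index])
    r = np.abs(scores.to_numpy()) ** weight
    p_hit = np.cumsum(np.where(hits, r, 0.0))
    p_hit = p_hit / p_hit[-1]
    p_miss = np.cumsum(~hits) / (len(scores) - hits.sum())
    dev = np.concatenate([[0.0], p_hit - p_miss])
    return float(dev[np.argmax(np.abs(dev))])


class TestGsea:
    def test_top_ranked_set_maximally_enriched(self):
        rng = np.random.default_rng(0)
        ranked = pd.Series(
            np.sort(rng.normal(size=1000))[::-1], index=[f"g{i}" for i in range(1000)]
        )
        res = op.gsea_preranked(ranked, set(ranked.index[:20]), n_perm=1000, seed=1)
        assert res.es > 0.9
        assert res.p_value < 0.005  # minimum attainable at this permutation count
        assert np.sign(res.nes) == np.sign(res.es)

    def test_es_matches_running_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(20, 51))
            ranked = pd.Series(rng.normal(size=n), index=[f"x{i}" for i in range(n)])
            members = set(rng.choice(ranked.index, int(rng.integers(5, 10)), replace=False))
            res = op.gsea_preranked(ranked, members, n_perm=10, seed=0)
            assert np.isclose(res.es, gsea_oracle_es(ranked, members), atol=1e-12)

    def test_p_value_floor_respected(self):
        rng = np.random.default_rng(2)
        ranked = pd.Series(np.sort(rng.normal(size=300))[::-1],
                           index=[f"g{i}" for i in range(300)])
        res = op.gsea_preranked(ranked, set(ranked.index[:15]), n_perm=200, seed=0)
        assert res.p_value >= 1.0 / (res.n_permutations + 1)

    def test_degenerate_sets_rejected(self):
        ranked = pd.Series(
            np.linspace(1, -1, 50), index=[f"g{i}" for i in range(50)]
        )
        with pytest.raises(ValueError):
            op.gsea_preranked(ranked, set(ranked.index), n_perm=10)  # whole ranking
        with pytest.raises(ValueError):
            op.gsea_preranked(ranked, set(ranked.index[:3]), n_perm=10)  # < 5 overlap


class TestTargetAssociation:
    def test_shifted_target_group_detected(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.normal(size=25), index=[f"d{i}" for i in range(25)])
        annotations = {f"d{i}": "background" for i in range(25)}
        for i in range(5):
            values.iloc[i] += 2.0
            annotations[f"d{i}"] = "MEK"
        res = op.test_target_association(values, annotations).set_index("target")
        assert res.loc["MEK", "t"] > 3.0
        assert res.loc["MEK", "fdr"] < 0.05

    def test_zero_variance_flagged_not_tested(self):
        values = pd.Series(1.0, index=[f"d{i}" for i in range(10)])
        annotations = {f"d{i}": ("A" if i < 5 else "B") for i in range(10)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = op.test_target_association(values, annotations)
        assert res["zero_variance"].all()
        assert res["p_value"].isna().all()

    def test_targets_below_minimum_drug_count_excluded(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(size=12), index=[f"d{i}" for i in range(12)])
        annotations = {f"d{i}": "A" for i in range(5)}
        annotations.update({f"d{i}": "B" for i in range(5, 7)})  # only 2 drugs
        annotations.update({f"d{i}": "C" for i in range(7, 12)})
        res = op.test_target_association(values, annotations, min_drugs=3)
        assert set(res["target"]) == {"A", "C"}
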