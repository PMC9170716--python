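"""Feature extraction, well-definedness filtering, PCA, focus flagging."""

import numpy as np
import pandas as pd
import pytest

import orgaprofiler as op
from orgaprofiler.features import (
    FeatureMatrix,
    PipelineError,
    filter_and_center_features,
    fit_pca_transform,
)
from orgaprofiler.imaging import ProjectedImage

from conftest import solid_field


def _disk_image(intensity=None, texture=None, radius=15, size=48):
    """One centred disk; optional per-pixel intensity pattern inside it."""
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= radius**2
    img = np.zeros((3, size, size))
    fill = 100.0 if intensity is None else intensity
    for c in range(3):
        img[c][disk] = fill
    if texture is not None:
        img[0][disk] = texture[disk]
    mask = disk.astype(np.int32)
    return ProjectedImage(img, np.zeros_like(img, dtype=int)), mask


class TestExtraction:
    def test_uniform_disk_has_zero_intensity_spread(self):
        img, mask = _disk_image()
        fm = op.extract_organoid_features(img, mask)
        assert len(fm) == 1
        for ch in ("dna", "actin", "permeability"):
            assert fm.features[f"intensity_{ch}_sd"].iloc[0] == 0.0
            assert fm.features[f"intensity_{ch}_mean"].iloc[0] == 100.0

    def test_ellipse_more_eccentric_than_circle(self):
        size = 64
        yy, xx = np.mgrid[0:size, 0:size]
        circle = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 144).astype(np.int32)
        ellipse = (((yy - 32) / 6.9) ** 2 + ((xx - 32) / 20.8) ** 2 <= 1).astype(np.int32)
        img = np.full((3, size, size), 50.0)
        pi = ProjectedImage(img, np.zeros_like(img, dtype=int))
        ecc_c = op.extract_organoid_features(pi, circle).features["eccentricity"].iloc[0]
        ecc_e = op.extract_organoid_features(pi, ellipse).features["eccentricity"].iloc[0]
        assert ecc_c < ecc_e

    def test_checkerboard_has_higher_haralick_contrast_than_uniform(self):
        size = 48
        yy, xx = np.mgrid[0:size, 0:size]
        checker = 100.0 * ((yy + xx) % 2) + 50.0
        img_t, mask = _disk_image(texture=checker)
        img_u, _ = _disk_image()
        f_t = op.extract_organoid_features(img_t, mask).features
        f_u = op.extract_organoid_features(img_u, mask).features
        assert (
            f_t["texture_dna_o1_contrast"].iloc[0]
            > f_u["texture_dna_o1_contrast"].iloc[0]
        )
        assert f_u["texture_dna_o1_contrast"].iloc[0] == 0.0


def _toy_feature_matrix(rng=None):
    rng = rng or np.random.default_rng(0)
    idx = [f"o{i}" for i in range(12)]
    feats = pd.DataFrame(
        {
            "constant": 1.0,
            "half_same": [5.0] * 6 + [1.0, 2.0, 3.0, 4.0, 6.0, 7.0],
            "most_same": [5.0] * 7 + [1.0, 2.0, 3.0, 7.0, 8.0],
            "with_nan": [np.nan] + list(rng.normal(size=11)),
            "shifted": np.r_[rng.normal(0, 1, 6), rng.normal(10, 1, 6)],
            "texture_dna_o8_contrast": rng.normal(size=12),
            "texture_dna_o1_contrast": rng.normal(size=12),
        },
        index=idx,
    )
    meta = pd.DataFrame(
        {"batch_id": ["a"] * 6 + ["b"] * 6, "area_px": 20},  # diameter ~5 px
        index=idx,
    )
    return FeatureMatrix(feats, meta)


class TestFilterAndCenter:
    def test_mad_rules_and_missing_values(self):
        out = filter_and_center_features(_toy_feature_matrix())
        names = set(out.feature_names)
        assert "constant" not in names  # MAD = 0
        assert "most_same" not in names  # more than half identical -> MAD = 0
        assert "half_same" in names  # exactly half identical -> MAD > 0
        assert "with_nan" not in names
        assert not out.features.isna().any().any()

    def test_texture_offsets_beyond_smallest_organoid_dropped(self):
        out = filter_and_center_features(_toy_feature_matrix())
        assert "texture_dna_o8_contrast" not in out.feature_names  # offset 8 > ~5 px
        assert "texture_dna_o1_contrast" in out.feature_names

    def test_batch_centering_zeroes_batch_means(self):
        fm = _toy_feature_matrix()
        out = filter_and_center_features(fm)
        means = out.features.groupby(fm.meta["batch_id"].values).mean()
        assert np.allclose(means.to_numpy(), 0.0, atol=1e-12)

    def test_idempotent(self):
        once = filter_and_center_features(_toy_feature_matrix())
        twice = filter_and_center_features(once)
        assert once.feature_names == twice.feature_names
        assert np.allclose(once.features.to_numpy(), twice.features.to_numpy())

    def test_everything_dropped_raises_pipeline_error(self):
        idx = ["o1", "o2", "o3"]
        fm = FeatureMatrix(
            pd.DataFrame({"constant": [1.0, 1.0, 1.0]}, index=idx),
            pd.DataFrame({"batch_id": "a", "area_px": 400}, index=idx),
        )
        with pytest.raises(PipelineError):
            filter_and_center_features(fm)


class TestPCA:
    def test_rank_deficient_data_puts_no_variance_past_true_rank(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(3, 40))
        x = rng.normal(size=(300, 3)) @ basis
        df = pd.DataFrame(x, columns=[f"f{i}" for i in range(40)])
        model, _ = fit_pca_transform(df, n_components=25)
        assert model.explained_variance_ratio[:3].sum() > 1 - 1e-10
        assert model.explained_variance_ratio[3:].max() < 1e-10

    def test_isotropic_gaussian_matches_random_matrix_oracle(self):
        # At n = 10^4 and p = 528 the top sample eigenvalues of an isotropic
        # Gaussian are inflated above 1 (Marchenko-Pastur spread with
        # p/n ~ 0.053), so the top-25 variance fraction sits above the naive
        # 25/528; compare against an independent eigendecomposition oracle.
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10_000, 528)))
        df.columns = [f"f{i}" for i in range(528)]
        model, _ = fit_pca_transform(df, n_components=25)
        frac = model.explained_variance_ratio.sum()
        oracle = np.random.default_rng(77).normal(size=(10_000, 528))
        eig = np.linalg.eigvalsh(np.cov(oracle.T))
        frac_oracle = eig[-25:].sum() / eig.sum()
        assert abs(frac - frac_oracle) / frac_oracle < 0.05
        assert 25 / 528 < frac < 2 * 25 / 528

    def test_incremental_fit_matches_full_batch(self):
        rng = np.random.default_rng(3)
        scales = 1.3 ** -np.arange(100)
        df = pd.DataFrame(
            rng.normal(size=(5000, 100)) * scales,
            columns=[f"f{i}" for i in range(100)],
        )
        _, full = fit_pca_transform(df, 25)
        _, chunked = fit_pca_transform(df, 25, incremental_chunk=1000)
        for i in range(25):
            r = abs(np.corrcoef(full.iloc[:, i], chunked.iloc[:, i])[0, 1])
            assert r >= 0.999

    def test_scores_are_centered(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(5.0, 2.0, size=(500, 30)))
        df.columns = [f"f{i}" for i in range(30)]
        _, scores = fit_pca_transform(df, 10)
        assert np.abs(scores.mean()).max() < 1e-8

    def test_too_many_components_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 10)))
        df.columns = [f"f{i}" for i in range(10)]
        with pytest.raises(ValueError):
            fit_pca_transform(df, 25)


class TestFocusFlagging:
    @pytest.fixture(scope="class")
    def focus_features(self):
        frames = []
        for blurred, seeds in ((False, (0, 1)), (True, (2, 3))):
            for seed in seeds:
                field = solid_field(seed=seed, psf_sigma=8.0 if blurred else 1.0)
                proj = op.max_contrast_project(field.stack)
                fm = op.extract_organoid_features(
                    proj, field.mask, meta={"plate_id": f"p{seed}", "field": seed}
                )
                fm.meta["blurred"] = blurred
                frames.append(fm)
        feats = pd.concat([f.features for f in frames])
        meta = pd.concat([f.meta for f in frames])
        return FeatureMatrix(feats, meta)

    def test_blur_classifier_separates_held_out_fields(self, focus_features):
        fm = focus_features
        train = fm.meta["plate_id"].isin(["p0", "p2"])
        labels = fm.meta.loc[train[train].index, "blurred"].astype(bool)
        flags = op.flag_out_of_focus(fm, labels, seed=0)
        held = ~train
        acc = (flags[held] == fm.meta.loc[held, "blurred"]).mean()
        assert acc >= 0.95

    def test_training_rows_not_flagged_when_all_sharp_labelled(self, focus_features):
        fm = focus_features
        labels = fm.meta["blurred"].astype(bool)
        flags = op.flag_out_of_focus(fm, labels, seed=0)
        sharp_train = labels.index[~labels]
        assert not flags[sharp_train].any()

    def test_single_class_labels_rejected(self, focus_features):
        fm = focus_features
        labels = pd.Series(False, index=fm.features.index[:10])
        with pytest.raises(ValueError):
            op.flag_out_of_focus(fm, labels)
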