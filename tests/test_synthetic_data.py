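"""Generators: plate layouts, image fields, feature tables, multi-view data."""

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

import orgaprofiler as op
from orgaprofiler import synthetic_data as sd


class TestPlateLayout:
    def test_clinical_library_well_arithmetic(self):
        plates = op.generate_plate_layout(1, sd.clinical_library_spec(), seed=1)
        assert len(plates) == 1
        plate = plates[0]
        # 63 drugs x 5 concentrations + 16 DMSO + 8 positive controls
        assert plate.n_assigned == 63 * 5 + 16 + 8 == 339
        assert plate.n_empty == 45

    def test_layout_invariants(self):
        plate = op.generate_plate_layout(1, sd.clinical_library_spec(), seed=3)[0]
        w = plate.wells
        assert not w.duplicated(["row", "col"]).any()
        neg = w[w["role"] == "negative_control"]
        assert (neg["treatment"] == "DMSO").all()
        pos = w[w["role"] == "positive_control"]
        assert set(pos["treatment"]) <= {"bortezomib", "SN-38"}
        lib = w[w["role"] == "library"]
        assert (lib.groupby("treatment")["concentration"].nunique() == 5).all()

    def test_same_seed_reproduces_layout(self):
        a = op.generate_plate_layout(2, sd.clinical_library_spec(), seed=9)
        b = op.generate_plate_layout(2, sd.clinical_library_spec(), seed=9)
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa.wells, pb.wells)

    def test_large_library_splits_across_plates_with_controls(self):
        plates = op.generate_plate_layout(1, sd.kistem_library_spec(), seed=1)
        assert len(plates) >= 2
        for plate in plates:
            roles = plate.wells["role"].value_counts()
            assert roles.get("negative_control", 0) == 16
            assert roles.get("positive_control", 0) == 8
        n_lib = sum((p.wells["role"] == "library").sum() for p in plates)
        assert n_lib == 464

    def test_controls_exceeding_capacity_raise(self):
        with pytest.raises(sd.CapacityError):
            op.generate_plate_layout(1, sd.clinical_library_spec(), controls_per_plate=380)


class TestImageSimulation:
    def test_zero_organoids_gives_background_only(self):
        field = op.simulate_image_stacks(
            None, op.ImageSimParams(n_organoids=0), seed=0
        )[0]
        assert field.mask.max() == 0
        assert field.stack.pixels.shape == (3, 16, 160, 160)

    def test_solid_disks_have_expected_mask_areas(self):
        params = op.ImageSimParams(n_organoids=10, noise_sd=0.0, psf_sigma=0.0, mode="solid")
        field = op.simulate_image_stacks(None, params, seed=2)[0]
        assert field.mask.max() == 10
        areas = np.bincount(field.mask.ravel())[1:]
        expected = np.pi * field.organoids["radius"].to_numpy() ** 2
        assert np.all(np.abs(areas - expected) / expected < 0.05)

    def test_cystic_ring_brighter_than_lumen(self):
        params = op.ImageSimParams(
            n_organoids=4, noise_sd=0.0, psf_sigma=0.0, mode="cystic",
            radius_range=(14.0, 18.0), lumen_fraction=0.15, background=0.0,
        )
        field = op.simulate_image_stacks(None, params, seed=4)[0]
        actin = field.stack.pixels[1].max(axis=0)  # in-focus content per pixel
        yy, xx = np.mgrid[0 : actin.shape[0], 0 : actin.shape[1]]
        for o in field.organoids.itertuples():
            d2 = (yy - o.cy) ** 2 + (xx - o.cx) ** 2
            ring = (d2 <= o.radius**2) & (d2 > (o.radius - 2) ** 2)
            lumen = d2 <= (o.radius - params.ring_width - 2) ** 2
            assert actin[ring].mean() > 3.0 * max(actin[lumen].mean(), 1e-9)

    def test_dead_organoids_carry_permeability_signal(self):
        params = op.ImageSimParams(n_organoids=8, dead_fraction=1.0, noise_sd=0.0, psf_sigma=0.0)
        field = op.simulate_image_stacks(None, params, seed=1)[0]
        perm = field.stack.pixels[2].max(axis=0)
        assert perm[field.mask > 0].mean() > 10 * perm[field.mask == 0].mean()

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(sd.ConfigError):
            op.simulate_image_stacks(None, op.ImageSimParams(shape=(0, 100)), seed=0)


def _dmso_only_layout(n_wells=16, n_per_well=650):
    lib = pd.DataFrame({"drug": [], "target": [], "concentrations": []})
    plate = op.generate_plate_layout(
        ["D001T"], lib, controls_per_plate=n_wells, seed=0
    )[0]
    return plate


class TestFeatureTable:
    def test_full_lethality_sends_all_positive_controls_to_dead_cluster(self):
        plate = _dmso_only_layout()
        cfg = op.EffectConfig(n_per_well=40, baseline_death=0.0, control_lethality=1.0)
        fm, truth = op.simulate_feature_table(plate, cfg, seed=0)
        pos = fm.meta["role"] == "positive_control"
        assert truth.per_organoid.loc[pos[pos].index, "true_dead"].all()
        assert not truth.per_organoid.loc[(~pos)[~pos].index, "true_dead"].any()

    def test_orthogonal_moa_groups_have_orthogonal_realized_shifts(self):
        drugs = {
            "a1": sd.DrugEffect(moa="A", shift_sd=2.0),
            "b1": sd.DrugEffect(moa="B", shift_sd=2.0),
        }
        lib = pd.DataFrame(
            {"drug": list(drugs), "target": ["A", "B"], "concentrations": [(1e-6,)] * 2}
        )
        plates = op.generate_plate_layout(["D001T"], lib, controls_per_plate=10, seed=0)
        cfg = op.EffectConfig(n_per_well=500, drug_effects=drugs, baseline_death=0.0)
        fm, truth = op.simulate_feature_table(plates, cfg, seed=3)
        morph = [c for c in fm.features.columns if c.startswith("morph_")]
        base = fm.features.loc[fm.meta["treatment"] == "DMSO", morph].mean()
        shifts = {
            d: (fm.features.loc[fm.meta["treatment"] == d, morph].mean() - base).to_numpy()
            for d in drugs
        }
        cos = shifts["a1"] @ shifts["b1"] / (
            np.linalg.norm(shifts["a1"]) * np.linalg.norm(shifts["b1"])
        )
        assert abs(cos) < 0.1

    def test_size_mixture_parameters_recoverable_by_em(self):
        plate = _dmso_only_layout()
        mix = sd.SizeMixture(w_small=0.4, mu_small=4.0, mu_large=6.5)
        cfg = op.EffectConfig(
            n_per_well=650, baseline_death=0.0, line_mixtures={"D001T": mix}
        )
        fm, _ = op.simulate_feature_table(plate, cfg, seed=1)
        log_sizes = np.log(fm.features.loc[fm.meta["treatment"] == "DMSO", "area"])
        assert len(log_sizes) >= 10_000
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        gm.fit(log_sizes.to_numpy().reshape(-1, 1))
        mus = np.sort(gm.means_.ravel())
        assert abs(mus[0] - 4.0) < 0.1
        assert abs(mus[1] - 6.5) < 0.1

    def test_within_moa_cosine_exceeds_between(self, clinical_screen):
        _, cfg, _, truth = clinical_screen
        dirs = truth.shift_vectors
        groups = truth.moa_groups
        same = [
            dirs[a] @ dirs[b]
            for a in dirs
            for b in dirs
            if a < b and groups.get(a) and groups.get(a) == groups.get(b)
        ]
        diff = [
            dirs[a] @ dirs[b]
            for a in dirs
            for b in dirs
            if a < b and groups.get(a) and groups.get(b) and groups[a] != groups[b]
        ]
        assert min(same) > 0.9
        assert np.mean(same) > np.mean(diff) + 0.5

    def test_generator_is_deterministic(self, clinical_screen):
        plates, cfg, fm, _ = clinical_screen
        fm2, _ = op.simulate_feature_table(plates, cfg, seed=7)
        pd.testing.assert_frame_equal(fm.features, fm2.features)

    def test_invalid_death_fraction_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.DrugEffect(lethality=1.5)


class TestMultiView:
    def test_default_view_dimensions_match_design(self):
        views, _ = op.simulate_multiview(seed=0)
        assert views["size"].shape == (22, 1)
        assert views["mutations"].shape == (20, 12)
        assert views["expression"].shape == (22, 3222)
        assert views["morphology"].shape == (22, 25)
        assert views["drug_activity"].shape == (22, 252)
        assert set(views["mutations"].to_numpy().ravel()) <= {0.0, 1.0}

    def test_noiseless_continuous_views_have_rank_k(self):
        views, _ = op.simulate_multiview(noise_sd=0.0, k=3, seed=5)
        for name in ("size", "expression", "morphology", "drug_activity"):
            rank = np.linalg.matrix_rank(views[name].to_numpy(), tol=1e-8)
            assert rank <= 3

    def test_bitwise_deterministic(self):
        a, ta = op.simulate_multiview(seed=42)
        b, tb = op.simulate_multiview(seed=42)
        for v in a:
            assert np.array_equal(a[v].to_numpy(), b[v].to_numpy())
        assert np.array_equal(
            ta.factor_scores.to_numpy(), tb.factor_scores.to_numpy()
        )

    def test_replicates_share_line_scores(self):
        _, truth = op.simulate_multiview(seed=3, replicate_jitter=0.05)
        z = truth.factor_scores
        r1 = z.loc[[s for s in z.index if s.endswith("_r1")]].to_numpy()
        r2 = z.loc[[s for s in z.index if s.endswith("_r2")]].to_numpy()
        assert np.abs(r1 - r2).max() < 0.5  # jitter-scale, not independent draws

    def test_too_few_samples_rejected(self):
        with pytest.raises(sd.ConfigError):
            op.simulate_multiview(n_samples=3, k=3, seed=0)
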