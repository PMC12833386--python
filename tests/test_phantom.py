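"""Phantom generators: determinism, analytic oracles, geometry truth."""
from __future__ import annotations

import numpy as np
import pytest

from spinedvc.metrics import disc_heights, segmental_lordosis
from spinedvc.phantom import (
    AnalyticTexture,
    DeformationSpec,
    DiscGeometry,
    SpineGeometry,
    make_speckle_phantom,
    make_spine_phantom,
    make_synthetic_cohort,
    sample_texture,
    warp_volume,
)
from spinedvc.stats import backward_fit, vif_screen


class TestSpecklePhantom:
    def test_seed_determinism_is_bitwise(self):
        a, _ = make_speckle_phantom(48, 0.58, 500, seed=1)
        b, _ = make_speckle_phantom(48, 0.58, 500, seed=1)
        c, _ = make_speckle_phantom(48, 0.58, 500, seed=2)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_zero_blobs_gives_uniform_background(self):
        vol, tex = make_speckle_phantom(48, 0.58, 0, seed=0, background=0.1)
        assert np.allclose(vol.data, 0.1)

    def test_variance_grows_with_amplitude_scale(self):
        # independently recompute the variance over an amplitude sweep
        variances = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            vol, _ = make_speckle_phantom(48, 0.58, 500, seed=3,
                                          amplitude_scale=scale)
            variances.append(vol.data.var())
        assert all(b > a for a, b in zip(variances, variances[1:]))

    def test_undersized_volume_rejected(self):
        with pytest.raises(ValueError, match="48"):
            make_speckle_phantom(32, 0.58, 100, seed=0)


class TestDeformationSpec:
    def test_identity_spec_warp_is_identity(self, speckle64):
        vol, tex = speckle64
        warped, _ = warp_volume(tex, DeformationSpec(), vol.dims, vol.spacing)
        assert np.allclose(warped.data, vol.data)

    def test_pure_translation_truth_is_constant(self):
        spec = DeformationSpec(translation=np.array([1.16, 0.0, 0.0]))
        pts = np.random.default_rng(0).uniform(0, 30, size=(50, 3))
        u = spec.displacement(pts)
        assert np.allclose(u, [1.16, 0.0, 0.0])
        assert np.allclose(spec.strain(pts), 0.0, atol=1e-14)

    def test_affine_truth_matches_closed_form(self):
        spec = DeformationSpec(affine=np.diag([0.02, 0.0, 0.0]))
        E = spec.strain(np.zeros((4, 3)))
        assert np.allclose(E[:, 0, 0], 0.5 * (1.02 ** 2 - 1.0))  # 0.0202
        assert np.allclose(E[:, 1:, 1:], 0.0, atol=1e-15)

    def test_rigid_only_strain_oracle_is_zero(self):
        spec = DeformationSpec(translation=[1.0, -2.0, 0.5],
                               rotation_axis=[1, 1, 0], rotation_deg=7.0,
                               centre=[10.0, 10.0, 10.0])
        pts = np.random.default_rng(1).uniform(0, 30, size=(40, 3))
        assert np.abs(spec.strain(pts)).max() < 1e-12

    def test_quadratic_inverse_round_trips(self):
        q = np.zeros((3, 3, 3))
        q[0, 1, 1] = 2e-4
        spec = DeformationSpec(translation=[0.5, 0, 0], quadratic=q,
                               centre=[15.0, 15.0, 15.0])
        pts = np.random.default_rng(2).uniform(0, 30, size=(30, 3))
        back = spec.inverse(spec.map(pts))
        assert np.abs(back - pts).max() < 1e-8

    def test_non_invertible_spec_rejected(self, speckle64):
        vol, tex = speckle64
        spec = DeformationSpec(affine=-1.5 * np.eye(3))   # det F < 0
        with pytest.raises(ValueError, match="invertible"):
            warp_volume(tex, spec, vol.dims, vol.spacing)


class TestSpinePhantom:
    def test_label_counts(self):
        _, mask, _, _ = make_spine_phantom(level_count=5, spacing=1.5, seed=0)
        assert len(mask.vertebra_names) == 6
        assert len(mask.disc_names) == 5
        for name in mask.labels:
            assert np.any(mask.data == mask.labels[name])

    def test_prescribed_heights_recovered_on_landmarks(self):
        geom = SpineGeometry(discs=(DiscGeometry(12.0, 8.0),))
        _, _, lms, _ = make_spine_phantom(1, geom, spacing=1.0, seed=0)
        h = disc_heights(lms, "L5-S1")
        assert h.anterior == pytest.approx(12.0, abs=1e-9)
        assert h.posterior == pytest.approx(8.0, abs=1e-9)
        assert h.ap_ratio == pytest.approx(1.5, abs=1e-9)

    def test_prescribed_lordosis_recovered(self):
        geom = SpineGeometry(
            discs=(DiscGeometry.from_angle(10.0, 8.0, 32.0),
                   DiscGeometry.from_angle(10.0, 5.0, 32.0)))
        _, _, lms, truth = make_spine_phantom(2, geom, spacing=1.0, seed=0)
        assert segmental_lordosis(lms, "L5-S1") == pytest.approx(8.0, abs=0.1)
        assert segmental_lordosis(lms, "L4-L5") == pytest.approx(5.0, abs=0.1)
        assert truth.metrics["lumbar_lordosis_deg"] == pytest.approx(13.0, abs=1e-6)

    @pytest.mark.parametrize("build", [
        lambda: DiscGeometry(0.0, 8.0),                    # zero height
        lambda: DiscGeometry(-2.0, 8.0),                   # negative height
        lambda: DiscGeometry.from_angle(10.0, 60.0, 32.0),  # wedge > 45 deg
        lambda: DiscGeometry(40.0, 1.0).wedge_deg(18.0),   # wedge vs depth
        lambda: SpineGeometry(discs=(DiscGeometry(10.0, 10.0),),
                              sacral_slope_deg=50.0),      # slope > 45 deg
        lambda: SpineGeometry(discs=(DiscGeometry(10.0, 10.0),),
                              vertebra_height=-5.0),
    ])
    def test_invalid_geometry_rejected(self, build):
        with pytest.raises(ValueError):
            build()

    def test_every_label_rasterises_non_empty_even_for_thin_discs(self):
        geom = SpineGeometry(discs=(DiscGeometry(0.5, 0.5),),
                             vertebra_height=30.0)
        _, mask, _, _ = make_spine_phantom(1, geom, spacing=2.0, seed=0)
        for name, label in mask.labels.items():
            assert np.any(mask.data == label), name


class TestSyntheticCohort:
    def test_noise_free_cohort_recovers_betas_exactly(self):
        betas = {"intercept": 2.0, "ap_ratio": 5.0, "age": -0.4}
        table, truth = make_synthetic_cohort(40, betas, noise_sd=0.0, seed=7)
        model = backward_fit(table, "outcome",
                             ["ap_ratio", "age", "bmi", "gender_male"],
                             p_out=0.10)
        assert set(model.retained) >= {"ap_ratio", "age"}
        assert model.coef["ap_ratio"] == pytest.approx(5.0, abs=1e-8)
        assert model.coef["age"] == pytest.approx(-0.4, abs=1e-8)
        assert model.coef["intercept"] == pytest.approx(2.0, abs=1e-6)

    def test_duplicated_predictor_removed_by_vif(self):
        table, _ = make_synthetic_cohort(30, {"age": 1.0}, 1.0, seed=0)
        table["age_copy"] = table["age"]
        retained, ledger = vif_screen(table, ["age", "age_copy", "bmi"])
        assert len(retained) == 2
        assert sum(r in retained for r in ("age", "age_copy")) == 1
        assert len(ledger) == 1

    def test_seed_reproducibility(self):
        a, _ = make_synthetic_cohort(20, {"age": 1.0}, 0.5, seed=11)
        b, _ = make_synthetic_cohort(20, {"age": 1.0}, 0.5, seed=11)
        assert a.equals(b)

    @pytest.mark.parametrize("bad", [
        {"n": 5, "noise": 1.0},            # fewer rows than predictors + 2
        {"n": 30, "noise": -1.0},          # negative noise
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            make_synthetic_cohort(bad["n"], {"age": 1.0}, bad["noise"], seed=0)

    def test_null_model_type_one_rate_matches_reference_run(self):
        """With all-zero effects, the share of cohorts retaining >=1
        predictor must match the same elimination run on plain Gaussian
        designs (the Monte-Carlo reference)."""
        preds = ["age", "gender_male", "bmi", "avg_disc_height", "ap_ratio",
                 "degen_D", "degen_SD", "segmental_lordosis"]
        n_sim = 120
        hits = 0
        for k in range(n_sim):
            table, _ = make_synthetic_cohort(15, {}, 1.0, seed=1000 + k)
            m = backward_fit(table, "outcome", preds, p_out=0.10)
            hits += bool(m.retained)
        rate = hits / n_sim
        # reference: identical procedure on iid standard-normal predictors
        rng = np.random.default_rng(99)
        ref_hits = 0
        for k in range(n_sim):
            import pandas as pd
            X = pd.DataFrame(rng.standard_normal((15, 8)), columns=preds)
            X["outcome"] = rng.standard_normal(15)
            m = backward_fit(X, "outcome", preds, p_out=0.10)
            ref_hits += bool(m.retained)
        ref_rate = ref_hits / n_sim
        assert abs(rate - ref_rate) < 0.18
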