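"""Forward model and cohort generator."""

import numpy as np
import pytest

from ctpstroke.phantom import (
    AIFModel,
    GridSpec,
    LesionGeometry,
    TissueClass,
    brain_mask_for_grid,
    build_phantom,
    ellipsoid_mask,
    fit_lognormal_to_quartiles,
    geometry_for_volumes,
    load_preset,
    make_aif,
    make_followup_ct,
    sample_cohort,
    tissue_curve,
    HEALTHY_GM,
    PENUMBRA,
    CORE,
)


class TestAIF:
    def test_zero_amplitude_gives_zero_curve(self):
        t = np.arange(60.0)
        curve = make_aif(t, AIFModel(amplitude=0.0))
        assert np.all(curve == 0)

    def test_curve_is_zero_before_arrival(self):
        t = np.arange(0.0, 5.0, 0.5)  # entirely before t0 = 5 s
        assert np.all(make_aif(t, AIFModel.with_peak()) == 0)

    def test_peak_at_t0_plus_alpha_beta(self):
        t = np.arange(0.0, 60.0, 0.01)
        model = AIFModel.with_peak(peak_hu=300.0, t0=5.0, alpha=3.0, beta=1.5)
        curve = make_aif(t, model)
        assert t[np.argmax(curve)] == pytest.approx(9.5, abs=0.02)
        assert curve.max() == pytest.approx(300.0, rel=1e-6)

    def test_non_uniform_axis_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            make_aif(np.array([0.0, 1.0, 3.0]), AIFModel.with_peak())


class TestTissueKinetics:
    def test_central_volume_enforced_at_construction(self):
        with pytest.raises(ValueError, match="central volume"):
            TissueClass(name="bad", cbf=60.0, cbv=3.0, mtt=4.0)
        for cls in (HEALTHY_GM, PENUMBRA, CORE):
            assert abs(cls.cbv - cls.cbf * cls.mtt / 60.0) < 1e-9

    def test_no_flow_no_enhancement(self):
        t = np.arange(60.0)
        aif = make_aif(t, AIFModel.with_peak())
        cls = TissueClass.from_cbv_mtt("still", cbv=0.0, mtt=4.0)
        assert np.all(tissue_curve(aif, cls, 1.0) == 0)

    @pytest.mark.parametrize("mtt", [2.0, 4.0, 8.0])
    def test_auc_conservation(self, mtt):
        # discrete AUC(tissue)/AUC(aif) = CBV/100 within 1% on a long axis
        t = np.arange(90.0)
        aif = make_aif(t, AIFModel.with_peak())
        cls = TissueClass.from_cbv_mtt("x", cbv=4.0, mtt=mtt)
        ratio = tissue_curve(aif, cls, 1.0).sum() / aif.sum()
        assert ratio == pytest.approx(0.04, rel=0.01)

    def test_linearity_in_flow(self):
        t = np.arange(60.0)
        aif = make_aif(t, AIFModel.with_peak())
        c1 = tissue_curve(aif, TissueClass.from_cbv_mtt("a", 2.0, 8.0), 1.0)
        c2 = tissue_curve(aif, TissueClass.from_cbv_mtt("b", 4.0, 8.0), 1.0)
        assert np.allclose(c2, 2.0 * c1)

    def test_non_positive_mtt_rejected(self):
        t = np.arange(10.0)
        aif = make_aif(t, AIFModel.with_peak())
        with pytest.raises(ValueError):
            tissue_curve(aif, TissueClass(name="zero", cbf=0.0, cbv=0.0, mtt=-1.0), 1.0)


class TestPhantomConstruction:
    def test_noiseless_voxels_equal_class_curves(self, grid, brain, noiseless_phantom):
        ph = noiseless_phantom
        aif = ph.aif_curve()
        for mask, cls in [
            (ph.core_mask, CORE),
            (ph.penumbra_only_mask, PENUMBRA),
            (brain & ~ph.penumbra_mask, HEALTHY_GM),
        ]:
            expected = tissue_curve(aif, cls, grid.dt).astype(np.float32)
            assert np.array_equal(ph.data[mask][0], expected)
            assert np.allclose(ph.data[mask], expected[None, :])

    def test_same_seed_bit_identical(self, grid, brain):
        geom, _ = geometry_for_volumes(40.0, 10.0, grid, brain=brain)
        a = build_phantom(geom, grid=grid, noise_sigma=2.0, seed=7, brain=brain)
        b = build_phantom(geom, grid=grid, noise_sigma=2.0, seed=7, brain=brain)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.core_mask, b.core_mask)

    def test_contralateral_hemisphere_is_healthy(self, grid, noiseless_phantom):
        ph = noiseless_phantom
        mid = grid.midline_index
        assert not ph.penumbra_mask[:mid].any()
        assert np.all(ph.mtt_map[:mid][ph.brain_mask[:mid]] == HEALTHY_GM.mtt)

    def test_explicit_midline_crossing_raises(self, grid, brain):
        center = (grid.shape[0] * grid.spacing[0] / 2.0 + 5.0,
                  grid.shape[1] * grid.spacing[1] / 2.0, 20.0)
        geom = LesionGeometry(center_mm=center, core_semi_mm=(5, 5, 5),
                              penumbra_semi_mm=(30, 30, 15), side="right")
        with pytest.raises(ValueError, match="midline"):
            build_phantom(geom, grid=grid, noise_sigma=0.0, brain=brain)

    def test_rasterized_ellipsoid_volume_converges(self):
        # semi-axes (20, 15, 10) mm -> 4/3 pi abc ~ 12.57 ml; halving the
        # voxel size at least halves the error.
        analytic = 4.0 / 3.0 * np.pi * 20 * 15 * 10 / 1000.0
        errors = {}
        for h in (2.0, 1.0):
            n = int(64 / h)
            g = GridSpec(shape=(n, n, n), spacing=(h, h, h), n_time=2)
            center = (n * h / 2.0,) * 3
            vol = ellipsoid_mask(g, center, (20, 15, 10)).sum() * g.voxel_volume_ml
            errors[h] = abs(vol - analytic)
        assert errors[1.0] <= max(errors[2.0] / 2.0, 0.02 * analytic)
        assert errors[1.0] <= 1.0 * 0.001 * 64  # within a voxel-count layer

    def test_geometry_solver_matches_requested_volume(self, grid, brain):
        for target in (18.5, 83.3):
            geom, capped = geometry_for_volumes(target, target / 3.0, grid, brain=brain)
            assert not capped
            ph = build_phantom(geom, grid=grid, noise_sigma=0.0, brain=brain)
            # voxels rasterise in symmetric shells, so the best achievable
            # match is a fraction of a shell (~0.5 ml on this grid)
            tv = ph.true_volumes_ml()
            assert tv["total"] == pytest.approx(target, abs=0.5)
            assert tv["core"] == pytest.approx(target / 3.0, abs=0.5)


class TestFollowupCT:
    def test_zero_delta_zero_noise_uniform(self):
        mask = np.zeros((10, 10, 4), dtype=bool)
        mask[4:6, 4:6, 1:3] = True
        ct = make_followup_ct(mask, base_hu=30.0, delta_hu=0.0, noise_sigma=0.0)
        assert np.all(ct == 30.0)

    def test_noiseless_infarct_level(self):
        mask = np.zeros((10, 10, 4), dtype=bool)
        mask[4:6, 4:6, 1:3] = True
        ct = make_followup_ct(mask, base_hu=30.0, delta_hu=15.0, noise_sigma=0.0)
        assert np.all(ct[mask] == 15.0)
        assert np.all(ct[~mask] == 30.0)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            make_followup_ct(np.zeros((2, 2, 2), bool), delta_hu=-1.0)


class TestCohortSampling:
    def test_empty_cohort(self):
        spec = load_preset("covid_2020")
        from ctpstroke.phantom import scaled_spec

        assert sample_cohort(scaled_spec(spec, 0), seed=0) == []

    def test_seed_determinism(self):
        spec = load_preset("covid_2020")
        a = sample_cohort(spec, seed=3)
        b = sample_cohort(spec, seed=3)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_large_sample_median_matches_fitted_distribution(self):
        from ctpstroke.phantom import scaled_spec

        spec = scaled_spec(load_preset("covid_2020"), 5000)
        records = sample_cohort(spec, seed=11)
        totals = np.array([r.total_true for r in records])
        assert np.median(totals) == pytest.approx(83.3, rel=0.05)
        cores = np.array([r.core_true for r in records])
        assert np.mean(cores == 0) == pytest.approx(0.25, abs=0.02)
        assert np.median(cores) == pytest.approx(27.8, rel=0.08)

    def test_core_never_exceeds_total(self):
        records = sample_cohort(load_preset("no_covid_2019"), seed=5)
        assert all(r.core_true <= r.total_true + 1e-12 for r in records)
        assert all(0.0 <= r.mismatch_true <= 1.0 for r in records)

    def test_infeasible_quartiles_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_to_quartiles(median=5.0, q1=8.0, q3=10.0)

    def test_stratified_cohort_median_is_the_distribution_median(self):
        spec = load_preset("covid_2020")
        records = sample_cohort(spec, seed=1, stratified=True)
        totals = np.array([r.total_true for r in records])
        assert np.median(totals) == pytest.approx(83.3, rel=0.03)
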