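"""Synthetic-data generator: determinism, template construction, and the
flagship noise-free round trip of the whole pipeline."""

import numpy as np
import pytest

from nbtherm import synthetic as syn
from nbtherm.chemdenat import (
    fit_chem_two_state_global,
    intensity_ratio,
    spectral_center_of_mass,
)
from nbtherm.dsc import calorimetric_enthalpy, fit_thermal_two_state, reversibility
from nbtherm.models import GibbsHelmholtzParams, gibbs_helmholtz_dG
from nbtherm.stability import assemble_dg_points, fit_stability_curve


class TestDeterminism:
    def test_identical_ground_truth_gives_identical_scans(self):
        a = syn.gen_dsc_scan(syn.default_ground_truth("NB-AGT-1", seed=42))
        b = syn.gen_dsc_scan(syn.default_ground_truth("NB-AGT-1", seed=42))
        np.testing.assert_array_equal(a.cp_app, b.cp_app)

    def test_different_seeds_differ(self):
        a = syn.gen_dsc_scan(syn.default_ground_truth("NB-AGT-1", seed=1))
        b = syn.gen_dsc_scan(syn.default_ground_truth("NB-AGT-1", seed=2))
        assert not np.array_equal(a.cp_app, b.cp_app)

    def test_upscan_and_rescan_use_independent_noise(self):
        gt = syn.default_ground_truth("NB-AGT-1", seed=1)
        up = syn.gen_dsc_scan(gt)
        re = syn.gen_dsc_scan(gt, kind="rescan")
        assert not np.array_equal(up.cp_app - np.mean(up.cp_app),
                                  re.cp_app - np.mean(re.cp_app))

    def test_bundle_regeneration_is_byte_identical(self, tmp_path):
        for name in ("a", "b"):
            gt = syn.default_ground_truth("NB-AGT-6", seed=9)
            syn.write_bundle(syn.gen_stability_dataset(gt), tmp_path / name)
        files_a = sorted((tmp_path / "a").rglob("*.csv"))
        assert files_a
        for fa in files_a:
            fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
            assert fa.read_bytes() == fb.read_bytes()

    def test_ground_truth_yaml_round_trip(self, tmp_path):
        gt = syn.default_ground_truth("NB-AGT-2", seed=5)
        path = tmp_path / "gt.yaml"
        syn.save_ground_truth(path, gt)
        back = syn.load_ground_truth(path)
        assert back.thermal == gt.thermal
        assert back.gh == gt.gh
        assert back.chem_per_T == pytest.approx(gt.chem_per_T)
        assert back.seed == gt.seed


class TestEmissionTemplates:
    def test_red_shift_on_unfolding(self):
        lam = syn.WAVELENGTH_GRID
        native, unfolded = syn.emission_templates()

        def scm(I):
            return (I * lam).sum() / I.sum()

        assert scm(native) < scm(unfolded)
        assert scm(native) == pytest.approx(335.0, abs=1.0)
        assert scm(unfolded) == pytest.approx(355.0, abs=1.5)

    def test_shared_total_and_335nm_intensity(self):
        lam = syn.WAVELENGTH_GRID
        native, unfolded = syn.emission_templates()
        assert unfolded.sum() == pytest.approx(native.sum(), rel=1e-10)
        n335 = np.interp(335.0, lam, native)
        u335 = np.interp(335.0, lam, unfolded)
        assert u335 == pytest.approx(n335, rel=1e-10)

    def test_templates_positive(self):
        native, unfolded = syn.emission_templates()
        assert np.all(native >= 0) and np.all(unfolded >= 0)


class TestGenerators:
    def test_noise_free_scan_is_exact_model_curve(self, nb1_clean):
        from nbtherm.models import apparent_heat_capacity
        scan = syn.gen_dsc_scan(nb1_clean)
        np.testing.assert_allclose(
            scan.cp_app, apparent_heat_capacity(scan.temperature, nb1_clean.thermal),
            rtol=1e-12)

    def test_short_grid_rejected(self, nb1_clean):
        with pytest.raises(ValueError, match="not spanned"):
            syn.gen_dsc_scan(nb1_clean, grid=np.linspace(293.15, 333.15, 100))

    def test_rescan_enthalpy_ratio_tracks_reversibility(self, nb1_clean):
        up = syn.gen_dsc_scan(nb1_clean)
        re = syn.gen_dsc_scan(nb1_clean, kind="rescan")
        assert 100 * calorimetric_enthalpy(re) / calorimetric_enthalpy(up) == \
            pytest.approx(47.0, abs=1.0)

    def test_observables_at_cm_sit_at_midpoint(self, nb2_clean):
        T = sorted(nb2_clean.chem_per_T)[0]
        _, cm = syn.chem_params_at(nb2_clean, T)
        grid = np.sort(np.append(np.linspace(0, 6, 12), cm))  # Cm on-grid
        series = syn.gen_emission_spectra(nb2_clean, T, denaturant_grid=grid,
                                          amplitude_drift_per_M=0.0)
        i_cm = int(np.argmin(np.abs(series.denaturant - cm)))
        native, unfolded = syn.emission_templates()
        lam = syn.WAVELENGTH_GRID

        def as_spectrum(I):
            from nbtherm.chemdenat import EmissionSpectrum
            return EmissionSpectrum(lam, I, 0.0, T)

        scm_mid = 0.5 * (spectral_center_of_mass(as_spectrum(native))
                         + spectral_center_of_mass(as_spectrum(unfolded)))
        ratio_mid = 0.5 * (intensity_ratio(as_spectrum(native))
                           + intensity_ratio(as_spectrum(unfolded)))
        assert series.scm[i_cm] == pytest.approx(scm_mid, abs=0.01)
        assert series.ratio[i_cm] == pytest.approx(ratio_mid, abs=0.01)

    def test_cm_outside_grid_warns_but_generates(self, nb2_clean):
        T = sorted(nb2_clean.chem_per_T)[0]
        with pytest.warns(UserWarning, match="outside the denaturant grid"):
            series = syn.gen_emission_spectra(
                nb2_clean, T, denaturant_grid=np.linspace(3.0, 6.0, 9))
        assert len(series.spectra) == 9

    def test_kirchhoff_points_follow_generating_dcp(self, nb1_clean):
        pts = syn.gen_kirchhoff_points(nb1_clean)  # dh_cal_sigma = 0
        slope = np.polyfit([p.tm for p in pts], [p.dh_cal for p in pts], 1)[0]
        assert slope == pytest.approx(nb1_clean.gh.dcp, rel=1e-9)

    def test_inconsistent_ground_truth_rejected(self, nb1_clean):
        bad = syn.GroundTruth(
            thermal=nb1_clean.thermal,
            chem_per_T={298.15: (3.1, 1.0)},  # dG=3.1, curve says ~11
            gh=nb1_clean.gh, reversibility_fraction=0.5)
        with pytest.raises(ValueError, match="T=298.15"):
            syn.gen_stability_dataset(bad)


@pytest.fixture(scope="module")
def recovered(nb1_clean):
    dataset = syn.gen_stability_dataset(nb1_clean)
    thermal = fit_thermal_two_state(dataset.upscan)
    rev = reversibility(dataset.upscan, dataset.rescan)
    chem = [fit_chem_two_state_global(s) for s in dataset.series]
    return dataset, thermal, rev, chem


class TestNoiseFreeFixedPoint:
    """Flagship round trip: the noise-free bundle is a fixed point of the
    analysis pipeline."""

    def test_thermal_parameters_recovered(self, nb1_clean, recovered):
        _, thermal, _, _ = recovered
        t, p = nb1_clean.thermal, thermal.params
        assert p.tm == pytest.approx(t.tm, rel=1e-3)
        assert p.dh_cal == pytest.approx(t.dh_cal, rel=1e-3)
        assert p.dh_vh == pytest.approx(t.dh_vh, rel=1e-3)

    def test_reversibility_recovered(self, nb1_clean, recovered):
        _, _, rev, _ = recovered
        assert rev.percent == pytest.approx(
            100 * nb1_clean.reversibility_fraction, abs=1.0)

    def test_chemical_parameters_recovered(self, nb1_clean, recovered):
        _, _, _, chem = recovered
        for fit in chem:
            m_true, cm_true = syn.chem_params_at(nb1_clean, fit.temperature)
            assert fit.m_eq == pytest.approx(m_true, rel=1e-3)
            assert fit.cm == pytest.approx(cm_true, rel=1e-3)

    def test_stability_curve_recovered_from_chemical_route(self, nb1_clean, recovered):
        # chemical points + (Tm, 0) anchor sit exactly on the generating
        # curve, so this route is a true fixed point
        from nbtherm.stability import DGPoint
        _, thermal, _, chem = recovered
        pts = [DGPoint(T=c.temperature, dG=c.dG, source="chemical") for c in chem]
        pts.append(DGPoint(T=thermal.params.tm, dG=0.0, source="dsc"))
        fit = fit_stability_curve(pts, tm=thermal.params.tm)
        assert fit.params.dh == pytest.approx(nb1_clean.gh.dh, rel=1e-3)
        assert fit.params.dcp == pytest.approx(nb1_clean.gh.dcp, rel=1e-3)

    def test_stability_curve_via_full_assembly_carries_small_bias(
            self, nb1_clean, recovered):
        # the default assembly adds Van't Hoff thermal points, whose
        # ΔCp-free ΔG biases the curve parameters by the documented
        # magnitudes (ΔH ≲ 0.5 %, ΔCp ≲ 2 %)
        _, thermal, _, chem = recovered
        pts = assemble_dg_points(thermal, chem)
        fit = fit_stability_curve(pts, tm=thermal.params.tm)
        assert fit.params.dh == pytest.approx(nb1_clean.gh.dh, rel=5e-3)
        assert fit.params.dcp == pytest.approx(nb1_clean.gh.dcp, rel=0.02)

    def test_expected_dg_points_vanish_at_tm(self, nb1_clean):
        dataset = syn.gen_stability_dataset(nb1_clean)
        anchors = [p for p in dataset.expected_dg if abs(p.T - nb1_clean.gh.tm) < 1e-9]
        assert anchors and anchors[0].dG == 0.0
        for p in dataset.expected_dg:
            assert p.dG == pytest.approx(
                float(gibbs_helmholtz_dG(p.T, nb1_clean.gh)), abs=1e-12)
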