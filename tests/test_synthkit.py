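"""Synthetic generators: kinetic simulation, spectra, scenes, tables, physics."""

import numpy as np
import pytest

from tmmspect.spectra import MetaboliteWindow, integrate_window
from tmmspect.synthkit import (
    CLASS_PARAMS,
    DEFAULT_PEAKS,
    METABOLITES,
    AcquisitionSchedule,
    BolusInput,
    GroupEffectSpec,
    KineticParams,
    SceneConfig,
    default_cell_schedule,
    default_scene,
    polarization_enhancement,
    simulate_kinetics,
    synth_ct_table,
    synth_dynamic_spectra,
    synth_epsi_scene,
    synth_metabolite_table,
    thermal_polarization,
)


class TestKineticParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            KineticParams(m0=0.0)
        with pytest.raises(ValueError):
            KineticParams(k_ap=-0.1)
        with pytest.raises(ValueError):
            KineticParams(t1_a=0.0)
        with pytest.raises(ValueError):
            KineticParams(pol=1.5)

    def test_infinite_t1_allowed(self):
        p = KineticParams(t1_a=np.inf, t1_p=np.inf, t1_l=np.inf)
        assert np.all(p.r1 == 0.0)


class TestAcquisitionSchedule:
    def test_flip_spellings_equivalent(self):
        scalar = AcquisitionSchedule(tr=3.0, n_acq=5, flip=13.0)
        seq = AcquisitionSchedule(tr=3.0, n_acq=5, flip=[13.0, 13.0, 13.0])
        mapping = AcquisitionSchedule(
            tr=3.0, n_acq=5, flip={"alanine": 13.0, "pyruvate": 13.0, "lactate": 13.0}
        )
        assert np.array_equal(scalar.flip, seq.flip)
        assert np.array_equal(scalar.flip, mapping.flip)

    def test_flip_range_enforced(self):
        with pytest.raises(ValueError, match="90"):
            AcquisitionSchedule(tr=3.0, n_acq=5, flip=91.0)
        with pytest.raises(ValueError):
            AcquisitionSchedule(tr=3.0, n_acq=5, flip=-1.0)

    def test_n_acq_at_least_one(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule(tr=3.0, n_acq=0)

    def test_times(self):
        sched = AcquisitionSchedule(tr=3.0, n_acq=4, t0=1.0)
        assert np.allclose(sched.times, [1.0, 4.0, 7.0, 10.0])


class TestBolusInput:
    def test_duration_zero_iff_instantaneous(self):
        with pytest.raises(ValueError):
            BolusInput(shape="trapezoid", duration=0.0)
        with pytest.raises(ValueError):
            BolusInput(shape="instantaneous", duration=5.0)

    def test_trapezoid_profile_area_equals_dose(self):
        b = BolusInput(shape="trapezoid", duration=12.0)
        t, u = b.profile(dose=2.5)
        assert np.trapezoid(u, t) == pytest.approx(2.5)
        assert u[0] == 0.0 and u[-1] == 0.0

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            BolusInput(shape="box", duration=1.0)


class TestSimulateKinetics:
    def test_substrate_only_closed_form(self, cell_sched):
        """s(n) = m0 sin(theta) (exp(-TR/T1) cos(theta))^n, exactly."""
        params = KineticParams(m0=2.0, t1_a=44.0)
        mag = simulate_kinetics(params, cell_sched)
        theta = np.radians(13.0)
        n = np.arange(cell_sched.n_acq)
        expected = 2.0 * np.sin(theta) * (np.exp(-3.0 / 44.0) * np.cos(theta)) ** n
        assert np.allclose(mag.signal("alanine"), expected, rtol=1e-9, atol=0)
        assert np.all(mag.signal("pyruvate") == 0.0)
        assert np.all(mag.signal("lactate") == 0.0)

    def test_conservation_zero_flip_infinite_t1(self):
        sched = AcquisitionSchedule(tr=3.0, n_acq=50, flip=0.0)
        params = KineticParams(
            m0=1.0, k_ap=0.03, k_pl=0.05, t1_a=np.inf, t1_p=np.inf, t1_l=np.inf
        )
        mag = simulate_kinetics(params, sched)
        totals = mag.m.sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-12)

    def test_conservation_with_trapezoid_bolus(self):
        sched = AcquisitionSchedule(tr=3.0, n_acq=30, flip=0.0)
        params = KineticParams(
            m0=1.0, k_ap=0.03, k_pl=0.05, t1_a=np.inf, t1_p=np.inf, t1_l=np.inf
        )
        bolus = BolusInput(shape="trapezoid", duration=12.0)
        mag = simulate_kinetics(params, sched, bolus)
        # after the bolus has fully arrived, total magnetization equals the dose
        after = mag.times >= 12.0
        assert np.allclose(mag.m[after].sum(axis=1), 1.0, atol=1e-12)

    def test_signal_is_sine_of_magnetization(self, tert_params, invivo_sched):
        mag = simulate_kinetics(tert_params, invivo_sched)
        sin_f = np.sin(np.radians(invivo_sched.flip))
        assert np.allclose(mag.s, mag.m * sin_f)
        assert np.all(mag.m >= 0) and np.all(mag.s >= 0)

    @pytest.mark.parametrize("k_ap,k_pl", [(0.008, 0.08), (0.008, 0.002), (0.02, 0.03)])
    def test_temporal_ordering_with_finite_bolus(self, k_ap, k_pl, invivo_sched):
        params = KineticParams(m0=1.0, k_ap=k_ap, k_pl=k_pl)
        bolus = BolusInput(shape="trapezoid", duration=12.0)
        mag = simulate_kinetics(params, invivo_sched, bolus)
        t = {m: mag.times[np.argmax(mag.signal(m))] for m in METABOLITES}
        assert t["alanine"] < t["pyruvate"] < t["lactate"]


class TestSynthDynamicSpectra:
    def test_noise_free_peak_area_equals_signal(self, tert_params, cell_sched):
        mag = simulate_kinetics(tert_params, cell_sched)
        series = synth_dynamic_spectra(mag)
        # integrate the whole alanine Lorentzian: area ~= signal up to the
        # axis truncation of the tails (< 1% for a 0.12 ppm line on 20 ppm)
        w = MetaboliteWindow("alanine", 176.5, 8.0)
        got = integrate_window(series.spectra[0], series.axis, w, mode="real")
        assert got == pytest.approx(mag.signal("alanine")[0], rel=0.01)

    def test_seeded_determinism(self, tert_params, cell_sched):
        mag = simulate_kinetics(tert_params, cell_sched)
        a = synth_dynamic_spectra(mag, noise_sigma=0.01, seed=7)
        b = synth_dynamic_spectra(mag, noise_sigma=0.01, seed=7)
        c = synth_dynamic_spectra(mag, noise_sigma=0.01, seed=8)
        assert np.array_equal(a.spectra, b.spectra)
        assert not np.array_equal(a.spectra, c.spectra)

    def test_peak_outside_axis_rejected(self, tert_params, cell_sched):
        mag = simulate_kinetics(tert_params, cell_sched)
        peaks = dict(DEFAULT_PEAKS)
        peaks["alanine"] = (200.0, 0.12)
        with pytest.raises(ValueError, match="outside axis"):
            synth_dynamic_spectra(mag, peaks=peaks)


class TestSceneConfig:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SceneConfig(
                regions={
                    "tumor": (((1, 1),), CLASS_PARAMS["TERT"]),
                    "contralateral": (((1, 1),), CLASS_PARAMS["CONTROL"]),
                }
            )

    def test_noise_region_must_be_signal_free(self):
        with pytest.raises(ValueError, match="noise region"):
            SceneConfig(regions={"noise": (((0, 0),), CLASS_PARAMS["TERT"])})

    def test_voxel_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SceneConfig(regions={"tumor": (((9, 0),), CLASS_PARAMS["TERT"])})

    def test_default_voxel_size(self):
        scene = default_scene("TERT")
        assert scene.voxel_mm == (pytest.approx(5.375), pytest.approx(5.375))


class TestSynthEpsiScene:
    def test_scene_layout(self):
        ds = synth_epsi_scene(default_scene("TERT", noise_sigma=0.0, n_time=10))
        # masks disjoint
        total = sum(m.astype(int) for m in ds.masks.values())
        assert total.max() <= 1
        # noise voxels carry no signal when noise_sigma = 0
        assert np.all(ds.data[ds.masks["noise"]] == 0)
        # contralateral voxels: alanine only, no product peaks
        x, y = np.argwhere(ds.masks["contralateral"])[0]
        voxel = ds.data[x, y]
        w_lac = MetaboliteWindow("lactate", 183.2, 0.5)
        w_ala = MetaboliteWindow("alanine", 176.5, 0.5)
        lac = integrate_window(voxel[:, -1], ds.axis, w_lac, mode="magnitude")
        ala = integrate_window(voxel[:, -1], ds.axis, w_ala, mode="magnitude")
        # the lactate window sees only the far tail of the alanine peak
        assert lac < 1e-3 * ala

    def test_seeded_determinism(self):
        a = synth_epsi_scene(default_scene("ALT", noise_sigma=0.01, seed=3, n_time=5))
        b = synth_epsi_scene(default_scene("ALT", noise_sigma=0.01, seed=3, n_time=5))
        assert np.array_equal(a.data, b.data)


class TestSynthMetaboliteTable:
    def test_cv_zero_reproduces_means(self):
        spec = GroupEffectSpec(
            metabolites=("a", "b"),
            group_means={"CONTROL": [1.0, 2.0], "TERT": [3.0, 4.0]},
            cv=0.0,
            n_per_group=3,
        )
        table = synth_metabolite_table(spec)
        assert len(table) == 6
        control = table[table["group"] == "CONTROL"]
        assert np.allclose(control[["a", "b"]].to_numpy(), [1.0, 2.0])

    def test_lognormal_mean_matches_target(self):
        spec = GroupEffectSpec(
            metabolites=("a",),
            group_means={"CONTROL": [10.0], "TERT": [10.0]},
            cv=0.2,
            n_per_group=2000,
            seed=11,
        )
        table = synth_metabolite_table(spec)
        assert table["a"].mean() == pytest.approx(10.0, rel=0.05)

    def test_invalid_group_label_rejected(self):
        with pytest.raises(ValueError, match="group label"):
            GroupEffectSpec(metabolites=("a",), group_means={"TUMOR": [1.0]})

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError, match="means"):
            GroupEffectSpec(metabolites=("a",), group_means={"CONTROL": [0.0]})


class TestSynthCtTable:
    def test_structure_and_pairing(self):
        ct = synth_ct_table(0.25, 0.015625, n=3)
        assert len(ct) == 6
        for _, grp in ct.groupby("sample"):
            assert set(grp["condition"]) == {"with_phi29", "without_phi29"}

    def test_nonpositive_rq_rejected(self):
        with pytest.raises(ValueError):
            synth_ct_table(0.0, 0.1)


class TestPolarization:
    def test_thermal_polarization_monotone_in_field(self):
        p1 = thermal_polarization(1.0, 298.0)
        p14 = thermal_polarization(14.0, 298.0)
        assert 0 < p1 < p14 < 1

    def test_enhancement_definition(self):
        p = thermal_polarization(14.0, 298.0)
        assert polarization_enhancement(0.12) == pytest.approx(0.12 / p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            thermal_polarization(-1.0, 298.0)
        with pytest.raises(ValueError):
            polarization_enhancement(0.0)
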