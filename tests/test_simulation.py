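"""Synthetic input functions, noise, identifiability and sensitivity studies."""

import numpy as np
import pytest

import htrpet as hp
from htrpet.simulation import (
    correlation_from_sensitivities,
    hill_parent_fraction,
    tracer_representative_params,
)


class TestAif:
    def test_pure_bolus_starts_at_zero_and_peaks_on_time(self, schedule):
        cfg = hp.AIFConfig(recirc_fraction=0.0, tail_fraction=0.0)
        aif = hp.generate_aif(cfg, schedule)
        assert aif.fine_whole_blood[0] == 0.0
        t_peak = aif.fine_times[np.argmax(aif.fine_whole_blood)]
        assert abs(t_peak - cfg.time_to_peak) <= 0.05 + 1e-9

    def test_amplitude_scales_linearly(self, schedule):
        a1 = hp.generate_aif(hp.AIFConfig(amplitude=300.0), schedule)
        a2 = hp.generate_aif(hp.AIFConfig(amplitude=600.0), schedule)
        assert np.allclose(a2.fine_whole_blood, 2 * a1.fine_whole_blood, rtol=1e-12)
        assert np.allclose(a2.whole_blood.values, 2 * a1.whole_blood.values, rtol=1e-12)

    def test_whole_blood_equals_plasma_with_unit_parent_fraction(self, aif):
        assert np.array_equal(aif.whole_blood.values, aif.plasma.values)
        assert np.all(aif.parent_fraction == 1.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            hp.AIFConfig(amplitude=0.0)
        with pytest.raises(ValueError):
            hp.AIFConfig(time_to_peak=5.0)
        with pytest.raises(ValueError):
            hp.AIFConfig(recirc_fraction=1.0)


class TestDispersion:
    def test_unit_step_gives_closed_form(self, schedule):
        t_fine = np.arange(0, 120.05, 0.05)
        step = np.ones_like(t_fine)
        wb = hp.TimeSeriesCurve(schedule, np.interp(schedule.mid_times, t_fine, step))
        inp = hp.InputFunction(
            wb, wb.with_values(wb.values.copy()), fine_times=t_fine, fine_whole_blood=step, fine_plasma=step.copy()
        )
        kd = 10.0
        d = hp.apply_dispersion(inp, kd)
        expected = -np.expm1(-(kd / 60.0) * d.fine_times)
        assert np.max(np.abs(d.fine_whole_blood - expected)) < 1e-6

    def test_very_fast_kernel_is_identity(self, schedule, aif):
        d = hp.apply_dispersion(aif, 6000.0)
        peak = aif.whole_blood.values.max()
        assert np.max(np.abs(d.whole_blood.values - aif.whole_blood.values)) / peak < 0.005

    def test_area_preserved_and_peak_monotone_in_dispersion(self, aif):
        area0 = np.trapezoid(aif.fine_whole_blood, aif.fine_times)
        peaks = [aif.fine_whole_blood.max()]
        for kd in (30.0, 10.0, 5.0):  # the study's dispersion levels
            d = hp.apply_dispersion(aif, kd)
            # compare areas up to the horizon minus the kernel tail leakage
            area = np.trapezoid(d.fine_whole_blood, d.fine_times)
            kd_s = kd / 60.0
            assert area <= area0 + 1e-9
            assert area > 0.8 * area0
            peaks.append(d.fine_whole_blood.max())
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_long_horizon_area_preserved(self, schedule):
        """On a horizon much longer than the kernel, the unit-area kernel
        conserves the time integral to 0.1%."""
        long_sched = hp.FrameSchedule(np.arange(0, 600, 2.0), np.full(300, 2.0))
        # compactly supported input (no constant tail feeding past the horizon)
        aif = hp.generate_aif(hp.AIFConfig(tail_fraction=0.0), long_sched)
        d = hp.apply_dispersion(aif, 10.0)
        a0 = np.trapezoid(aif.fine_whole_blood, aif.fine_times)
        a1 = np.trapezoid(d.fine_whole_blood, d.fine_times)
        assert a1 == pytest.approx(a0, rel=1e-3)

    def test_nonpositive_rate_rejected(self, aif):
        with pytest.raises(ValueError):
            hp.apply_dispersion(aif, 0.0)


class TestParentFraction:
    def test_default_model_leaves_80pct_at_two_minutes(self):
        assert hill_parent_fraction(0.0) == 1.0
        assert hill_parent_fraction(120.0) == pytest.approx(0.80, abs=1e-9)
        t = np.linspace(0, 120, 200)
        assert np.all(np.diff(hill_parent_fraction(t)) <= 0)

    def test_unit_parent_fraction_is_identity(self, aif, schedule):
        out = hp.apply_parent_fraction(aif, lambda t: np.ones_like(np.asarray(t, dtype=float)))
        assert np.all(out.parent_fraction == 1.0)
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        assert np.array_equal(
            hp.generate_aath_tac(p, out, schedule).values, hp.generate_aath_tac(p, aif, schedule).values
        )

    def test_invalid_models_rejected(self, aif):
        with pytest.raises(ValueError):
            hp.apply_parent_fraction(aif, lambda t: 1.0 + 0.1 * np.asarray(t, dtype=float))  # increasing
        with pytest.raises(ValueError):
            hp.apply_parent_fraction(aif, lambda t: 1.0 - 0.02 * np.asarray(t, dtype=float))  # below 0


class TestNoise:
    def test_zero_scale_is_identity(self, schedule, aif):
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        clean = hp.generate_aath_tac(p, aif, schedule)
        noisy = hp.add_noise(clean, hp.NoiseModel(sc=0.0, seed=1), 2)
        assert np.array_equal(noisy[0], clean.values)

    def test_fixed_seed_is_bit_reproducible(self, schedule, aif):
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        clean = hp.generate_aath_tac(p, aif, schedule)
        a = hp.add_noise(clean, hp.NoiseModel(sc=4.8, seed=7), 3)
        b = hp.add_noise(clean, hp.NoiseModel(sc=4.8, seed=7), 3)
        assert np.array_equal(a, b)
        c = hp.add_noise(clean, hp.NoiseModel(sc=4.8, seed=7), 2, realization_offset=1)
        assert np.array_equal(a[1:], c)  # derived seeds allow chunked resumption

    def test_empirical_sd_matches_model(self, schedule, aif):
        """Monte-Carlo check of the generator: per-frame SD over 4096
        realizations within 5% of the analytic sigma_m."""
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        clean = hp.generate_aath_tac(p, aif, schedule)
        noise = hp.NoiseModel(sc=4.8, seed=11)
        noisy = hp.add_noise(clean, noise, 4096)
        emp = noisy.std(axis=0, ddof=1)
        sig = hp.noise_sigma(clean, noise)
        assert np.max(np.abs(emp - sig) / sig) < 0.05

    def test_decay_constant_inflates_late_noise_for_short_isotopes(self, schedule, aif):
        p = hp.AATHParams(cbf=0.5, k1=0.475, k2=0.6, tc=7.0, td=2.0)
        clean = hp.generate_aath_tac(p, aif, schedule)
        s_f18 = hp.noise_sigma(clean, hp.NoiseModel(sc=4.8, isotope="18F"))
        s_c11 = hp.noise_sigma(clean, hp.NoiseModel(sc=4.8, isotope="11C"))
        assert s_c11[-1] / s_c11[0] > s_f18[-1] / s_f18[0]

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            hp.NoiseModel(sc=-1.0)


class TestIdentifiability:
    def test_zero_noise_recovers_exactly_on_grid(self, aif, small_spec, fdg_like):
        rep = hp.run_identifiability(fdg_like, aif, small_spec, hp.NoiseModel(sc=0.0, seed=1), n_realizations=4)
        finite_bias = [abs(v) for v in rep.bias_pct.values() if np.isfinite(v)]
        finite_sd = [abs(v) for v in rep.sd_pct.values() if np.isfinite(v)]
        assert max(finite_bias) < 1e-9
        assert max(finite_sd) < 1e-9

    def test_minimum_realizations_enforced(self, aif, small_spec, fdg_like):
        with pytest.raises(ValueError):
            hp.run_identifiability(fdg_like, aif, small_spec, hp.NoiseModel(), n_realizations=1)

    def test_report_has_correlation_matrix(self, aif, small_spec, fdg_like):
        rep = hp.run_identifiability(fdg_like, aif, small_spec, hp.NoiseModel(seed=2), n_realizations=16)
        c = rep.correlation.to_numpy()
        assert c.shape == (5, 5)
        assert np.allclose(c, c.T, equal_nan=True)
        assert np.allclose(np.diag(c), 1.0)

    def test_low_extraction_degrades_ps_identifiability(self, aif, small_spec, schedule):
        """PS error spread is worse at E = 0.01 than at E = 0.33."""
        noise = hp.NoiseModel(sc=4.8, seed=9)
        basis = hp.precompute_bases(small_spec, aif, schedule, "aath")
        k2g = small_spec.k2_values()
        sds = {}
        for e in (0.01, 0.33):
            k1 = 0.5 * e
            k2 = float(k2g[np.argmin(np.abs(k2g - k1 / 0.5))])
            p = hp.AATHParams(cbf=0.5, k1=k1, k2=k2, tc=7.0, td=2.0)
            rep = hp.run_identifiability(p, aif, small_spec, noise, n_realizations=96, basis=basis)
            sds[e] = rep.sd_pct["ps"]
        assert sds[0.01] > sds[0.33]

    def test_fixed_ps_sweep_improves_with_flow(self, aif, small_spec):
        noise = hp.NoiseModel(sc=4.8, seed=13)
        table = hp.run_fixed_ps_sweep(aif, small_spec, noise, cbf_values=(0.25, 0.75), n_realizations=64)
        assert abs(table.ps_bias_pct.iloc[1]) <= abs(table.ps_bias_pct.iloc[0])
        assert table.ps_sd_pct.iloc[1] <= table.ps_sd_pct.iloc[0]

    def test_fixed_ps_sweep_zero_noise_is_exact(self, aif, small_spec):
        k2_on_grid = float(small_spec.k2_values()[3])
        table = hp.run_fixed_ps_sweep(
            aif, small_spec, hp.NoiseModel(sc=0.0, seed=1), cbf_values=(0.5,), tc=7.0, k2=k2_on_grid, n_realizations=4
        )
        assert abs(table.ps_bias_pct.iloc[0]) < 1e-6
        assert table.ps_sd_pct.iloc[0] < 1e-9

    def test_uncorrected_metabolites_bias_transport_upward(self, schedule, aif, small_spec):
        """Systematic direction: ignoring the parent fraction overestimates
        PS, K1 and E (k2 absorbs most, but not all, of the input mismatch)."""
        corrected = hp.apply_parent_fraction(aif)
        # a fine k2 grid is needed so quantization does not mask the shift
        spec = hp.GridSpec(td_range=(1.0, 3.0), td_step=0.5, tc_range=(5.0, 9.0), tc_step=0.5, n_k2=100)
        k2g = spec.k2_values()
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=float(k2g[np.argmin(np.abs(k2g - 0.33))]), tc=7.0, td=2.0)
        tac = hp.generate_aath_tac(p, corrected, schedule)
        res = hp.fit_curve(tac, aif, schedule, spec)
        true_ps = hp.extraction_to_ps(p.extraction, p.cbf)
        assert res.derived.ps > true_ps
        assert res.params.k1 > p.k1
        assert res.derived.e > p.extraction

    def test_tracer_representative_sets_span_extractions(self, small_spec):
        sets = tracer_representative_params(small_spec)
        es = [p.extraction for p, _ in sets.values()]
        assert es == pytest.approx([0.05, 0.33, 0.95])
        k2g = small_spec.k2_values()
        for p, _ in sets.values():
            assert np.min(np.abs(k2g - p.k2)) < 1e-12  # k2 on the grid


class TestSensitivity:
    def test_correlation_matrix_properties(self, aif, schedule):
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        rep = hp.sensitivity_analysis(p, aif, schedule)
        c = rep.correlation.to_numpy()
        assert np.allclose(c, c.T, atol=1e-10)
        assert np.allclose(np.diag(c), 1.0)
        assert np.all(np.abs(c) <= 1 + 1e-9)
        # flow and transport are separately estimable
        assert abs(rep.correlation.loc["cbf", "k1"]) < 0.9

    def test_duplicated_parameter_is_singular(self, aif, schedule):
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        rep = hp.sensitivity_analysis(p, aif, schedule)
        dup = np.vstack([rep.sensitivities, rep.sensitivities[0]])
        _, corr, used_pinv = correlation_from_sensitivities(dup, rep.times)
        assert used_pinv or abs(corr[0, -1]) > 1 - 1e-6

    def test_nonpositive_parameters_rejected(self, aif, schedule):
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.0, tc=7.0, td=2.0)
        with pytest.raises(ValueError):
            hp.sensitivity_analysis(p, aif, schedule)


class TestPhantom:
    def test_noiseless_regions_carry_exact_model_curves(self, schedule, aif):
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        img, masks = hp.generate_phantom({"grey_matter": p}, aif, schedule, shape=(16, 16, 8))
        model = hp.generate_aath_tac(p, aif, schedule).values
        roi = img.data[masks["grey_matter"]].mean(axis=0)
        assert np.allclose(roi, model, atol=1e-9)
        aorta = img.data[masks["aorta"]].mean(axis=0)
        assert np.allclose(aorta, aif.whole_blood.values, atol=1e-9)

    def test_default_phantom_dimensions(self, schedule, aif):
        img, masks = hp.generate_phantom({}, aif, schedule)
        assert img.data.shape == (32, 32, 16, 90)
        stack = sum(m.astype(int) for m in masks.values())
        assert stack.max() == 1  # disjoint regions

    def test_overlapping_masks_rejected(self, schedule, aif):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        with pytest.raises(ValueError):
            hp.generate_phantom({}, aif, schedule, shape=(4, 4, 4), masks={"a": m, "b": m})

    def test_voxel_noise_is_seeded_and_independent(self, schedule, aif):
        p = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
        noise = hp.NoiseModel(sc=4.8, seed=3)
        img1, masks = hp.generate_phantom({"grey_matter": p}, aif, schedule, noise=noise, shape=(8, 8, 4))
        img2, _ = hp.generate_phantom({"grey_matter": p}, aif, schedule, noise=noise, shape=(8, 8, 4))
        assert np.array_equal(img1.data, img2.data)
        gm = img1.data[masks["grey_matter"]]
        assert not np.array_equal(gm[0], gm[1])
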