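import dataclasses

import numpy as np
import pytest

from editfit.preprocess import (
    PreprocessConfig,
    model_edited_shapes,
    align_subspectra,
    eddy_correct,
    hsvd_filter,
    preprocess_scan,
    register_transients,
    weighted_average,
)
from editfit.signal_model import (
    Fid,
    Multiplet,
    SpectralLine,
    hadamard_combine,
    synth_fid,
    to_spectrum,
)
from editfit.synthetic_cohort import NoiseConfig, simulate_scan

FAST = PreprocessConfig(zerofill=4096, hsvd_points=512, hsvd_rank=15)


def _apply(fid, df, phi_deg):
    t = fid.acq.time_axis(len(fid.samples))
    return Fid(
        fid.samples * np.exp(1j * (2 * np.pi * df * t + np.deg2rad(phi_deg))),
        fid.acq,
        fid.label,
    )


class TestEddyCorrect:
    def test_zero_phase_water_is_identity(self, acq):
        rng = np.random.default_rng(0)
        fid = Fid(rng.normal(size=2048) + 1j * rng.normal(size=2048), acq)
        water = Fid(np.abs(rng.normal(size=2048)) + 1.0 + 0j, acq)
        out = eddy_correct(fid, water)
        assert np.allclose(out.samples, fid.samples, atol=1e-12)

    def test_known_phase_inverted_to_machine_precision(self, acq, truth, hermes_catalog):
        base = synth_fid(hermes_catalog.multiplets_for("A"), truth, acq)
        t = acq.time_axis()
        phi = 0.5 * np.exp(-t / 0.05)
        water_mag = np.exp(-t / 0.1) * 100.0
        distorted = Fid(base.samples * np.exp(1j * phi), acq)
        water = Fid(water_mag * np.exp(1j * phi), acq)
        out = eddy_correct(distorted, water)
        assert np.max(np.abs(out.samples - base.samples)) < 1e-10

    def test_water_self_correction_is_real_nonnegative(self, acq):
        t = acq.time_axis()
        water = Fid(50 * np.exp(-t / 0.1) * np.exp(1j * (0.3 + 2 * t)), acq)
        out = eddy_correct(water, water)
        assert np.max(np.abs(out.samples.imag)) < 1e-10
        assert np.min(out.samples.real) >= 0

    def test_zero_magnitude_water_warns(self, acq):
        fid = Fid(np.ones(2048, dtype=complex), acq)
        wsamp = np.ones(2048, dtype=complex)
        wsamp[100:110] = 0.0
        with pytest.warns(UserWarning):
            eddy_correct(fid, Fid(wsamp, acq))

    def test_length_mismatch_rejected(self, acq):
        with pytest.raises(ValueError):
            eddy_correct(
                Fid(np.ones(10, dtype=complex), acq),
                Fid(np.ones(20, dtype=complex), acq),
            )


class TestRegistration:
    def _clean_transients(self, acq, truth, catalog, n=8, noise=0.2, seed=0):
        base = synth_fid(catalog.multiplets_for("A"), truth, acq)
        rng = np.random.default_rng(seed)
        return [
            Fid(
                base.samples
                + noise * (rng.normal(size=2048) + 1j * rng.normal(size=2048)),
                acq,
                "A",
            )
            for _ in range(n)
        ]

    def test_prealigned_transients_get_negligible_shifts(
        self, acq, truth, hermes_catalog
    ):
        fids = self._clean_transients(acq, truth, hermes_catalog)
        _, reg = register_transients(fids)
        assert np.max(np.abs(reg.shifts_hz)) < 0.01

    def test_known_displacement_recovered(self, acq, truth, hermes_catalog):
        fids = self._clean_transients(acq, truth, hermes_catalog)
        fids[3] = _apply(fids[3], 3.0, 20.0)
        _, reg = register_transients(fids)
        rel_shift = reg.shifts_hz[3] - np.median(np.delete(reg.shifts_hz, 3))
        rel_phase = reg.phases_deg[3] - np.median(np.delete(reg.phases_deg, 3))
        assert rel_shift == pytest.approx(-3.0, abs=0.05)
        assert rel_phase == pytest.approx(-20.0, abs=1.0)

    def test_registration_reduces_spectral_variance_of_noisy_scan(
        self, acq_map, truth, hermes_catalog
    ):
        raw = simulate_scan(
            truth,
            acq_map["HERMES80"],
            hermes_catalog,
            NoiseConfig(drift_hz_per_transient=0.3, jitter_hz_sd=1.0),
            21,
        )
        fids = raw.transients["A"]

        def spectral_var(fids):
            specs = np.array(
                [to_spectrum(f, 2048, 3.0).intensities for f in fids]
            )
            return float(np.mean(np.var(specs.real, axis=0)))

        aligned, _ = register_transients(fids)
        assert spectral_var(aligned) < spectral_var(fids)

    def test_noise_floor_not_inflated_on_drift_free_data(
        self, acq_map, truth, hermes_catalog
    ):
        noise = NoiseConfig(
            noise_sd=4.0,
            drift_hz_per_transient=0.0,
            jitter_hz_sd=0.0,
            phase_jitter_deg_sd=0.0,
            baseline_wobble=0.0,
            eddy_phase_amp_rad=0.0,
        )
        raw = simulate_scan(truth, acq_map["HERMES80"], hermes_catalog, noise, 31)
        fids = raw.transients["A"]

        def floor(avg):
            spec = to_spectrum(avg, 8192, 3.0)
            sel = spec.slice_ppm(0.0, 0.5)  # signal-free region
            return float(np.std(spec.intensities[sel].real))

        naive = Fid(np.mean([f.samples for f in fids], axis=0), raw.acq)
        aligned, _ = register_transients(fids)
        processed = weighted_average(aligned)
        assert floor(processed) < 1.05 * floor(naive)

    def test_rejects_single_transient_and_nonfinite(self, acq):
        with pytest.raises(ValueError):
            register_transients([Fid(np.ones(64, dtype=complex), acq)])
        bad = [Fid(np.ones(64, dtype=complex), acq) for _ in range(2)]
        bad[0].samples[3] = np.nan
        with pytest.raises(ValueError):
            register_transients(bad)


class TestWeightedAverage:
    def test_identical_transients_give_plain_mean(self, acq):
        fid = Fid(np.linspace(1, 2, 64) + 0j, acq)
        out = weighted_average([fid.copy() for _ in range(5)])
        assert np.allclose(out.samples, fid.samples)

    def test_outlier_gets_smallest_weight(self, acq):
        rng = np.random.default_rng(3)
        clean = [
            Fid(np.ones(64) + 0.01 * rng.normal(size=64) + 0j, acq)
            for _ in range(8)
        ]
        clean.append(Fid(np.ones(64) * 5.0 + 0j, acq))
        out = weighted_average(clean)
        w = out._weights
        assert np.argmin(w) == 8
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_transient_returned_unchanged(self, acq):
        fid = Fid(np.arange(8) + 0j, acq)
        out = weighted_average([fid])
        assert np.array_equal(out.samples, fid.samples)


class TestAlignSubspectra:
    def _quartet(self, acq, truth, catalog):
        return {
            lab: synth_fid(catalog.multiplets_for(lab), truth, acq, lab)
            for lab in "ABCD"
        }

    def test_aligned_quartet_needs_no_correction(self, acq, truth, hermes_catalog):
        q = self._quartet(acq, truth, hermes_catalog)
        shapes = model_edited_shapes(hermes_catalog, acq)
        _, adjust = align_subspectra(q, "HERMES", shapes)
        for df, ph in adjust.values():
            assert abs(df) < 0.02
            assert abs(ph) < 0.2

    def test_displacement_of_c_recovered(self, acq, truth, hermes_catalog):
        q = self._quartet(acq, truth, hermes_catalog)
        q["C"] = _apply(q["C"], 2.0, 0.0)
        shapes = model_edited_shapes(hermes_catalog, acq)
        _, adjust = align_subspectra(q, "HERMES", shapes)
        assert adjust["C"][0] == pytest.approx(-2.0, abs=0.1)

    def test_alignment_reduces_naa_residual_of_displaced_quartet(
        self, acq, truth, hermes_catalog
    ):
        q = self._quartet(acq, truth, hermes_catalog)
        q["C"] = _apply(q["C"], 0.8, 1.0)

        def naa_residual(quartet):
            diff = hadamard_combine(quartet, "GSH")
            spec = to_spectrum(diff, 8192, 3.0)
            sel = spec.slice_ppm(1.95, 2.07)
            return float(np.sum(np.abs(spec.intensities[sel])))

        before = naa_residual(q)
        shapes = model_edited_shapes(hermes_catalog, acq)
        aligned, _ = align_subspectra(q, "HERMES", shapes)
        # the residual after alignment returns to the undisplaced floor
        # (set by genuinely edited signal in the window, not by NAA)
        q0 = self._quartet(acq, truth, hermes_catalog)
        aligned0, _ = align_subspectra(q0, "HERMES", shapes)
        floor = naa_residual(aligned0)
        assert naa_residual(aligned) < before
        assert naa_residual(aligned) < 1.1 * floor

    def test_mega_alignment_minimizes_tnaa_in_difference(
        self, acq, truth, mega_catalog
    ):
        subs = {
            lab: synth_fid(mega_catalog.multiplets_for(lab), truth, acq, lab)
            for lab in ("ON", "OFF")
        }
        subs["ON"] = _apply(subs["ON"], 0.6, 0.8)
        shapes = model_edited_shapes(mega_catalog, acq)
        aligned, adjust = align_subspectra(subs, "MEGA", shapes)
        assert adjust["ON"][0] == pytest.approx(-0.6, abs=0.1)
        assert adjust["ON"][1] == pytest.approx(-0.8, abs=0.2)

    def test_missing_labels_rejected(self, acq):
        fid = Fid(np.zeros(2048, dtype=complex), acq)
        with pytest.raises(ValueError):
            align_subspectra({"A": fid, "B": fid}, "HERMES")
        with pytest.raises(ValueError):
            align_subspectra({"ON": fid, "OFF": fid}, "PRESS")


class TestHsvd:
    def _damped(self, acq, ppm, amp, t2):
        t = acq.time_axis()
        f = (ppm - acq.center_ppm) * acq.transmitter_frequency
        return amp * np.exp(1j * 2 * np.pi * f * t) * np.exp(-t / t2)

    def test_single_inband_component_removed_to_numerical_zero(self, acq):
        sig = self._damped(acq, 4.7, 5.0, 0.1)
        out = hsvd_filter(Fid(sig, acq), rank=5, model_points=512)
        assert np.sum(np.abs(out.samples) ** 2) / np.sum(np.abs(sig) ** 2) < 1e-8

    def test_out_of_band_signal_untouched(self, acq):
        sig = self._damped(acq, 3.0, 2.0, 0.2)
        out = hsvd_filter(Fid(sig, acq), rank=5, model_points=512)
        assert np.max(np.abs(out.samples - sig)) / np.max(np.abs(sig)) < 1e-6

    def test_mixed_components_separated(self, acq):
        inband = self._damped(acq, 4.68, 5.0, 0.08)
        outband = self._damped(acq, 3.0, 2.0, 0.2)
        out = hsvd_filter(Fid(inband + outband, acq), rank=8, model_points=512)
        assert np.max(np.abs(out.samples - outband)) / np.max(np.abs(outband)) < 1e-3

    def test_matches_least_squares_oracle_on_known_poles(self, acq):
        """HSVD amplitude of an in-band pole equals a direct regression of
        the known damped sinusoids."""
        inband = self._damped(acq, 4.7, 3.0, 0.09)
        outband = self._damped(acq, 2.5, 1.0, 0.15)
        x = inband + outband
        # oracle: regress x on the two known basis signals
        A = np.column_stack(
            [self._damped(acq, 4.7, 1.0, 0.09), self._damped(acq, 2.5, 1.0, 0.15)]
        )
        coef, *_ = np.linalg.lstsq(A, x, rcond=None)
        removed = x - hsvd_filter(Fid(x, acq), rank=6, model_points=512).samples
        est_amp = np.abs(removed[0])
        assert est_amp == pytest.approx(np.abs(coef[0]), rel=1e-3)

    def test_rank_bounds_enforced(self, acq):
        with pytest.raises(ValueError):
            hsvd_filter(Fid(np.ones(2048, dtype=complex), acq), rank=300, model_points=512)


class TestPreprocessScan:
    def test_noiseless_chain_matches_direct_prediction(
        self, acq_map, truth, hermes_catalog, zero_noise
    ):
        """Without the (bias-documented) sub-spectrum alignment, the chain
        on a distortion-free scan is an exact identity."""
        acq = acq_map["HERMES80"]
        raw = simulate_scan(truth, acq, hermes_catalog, zero_noise, 5)
        cfg = dataclasses.replace(
            FAST, targets=("GSH",), do_align=False, do_hsvd=False
        )
        proc = preprocess_scan(raw, cfg)
        subs = {
            lab: synth_fid(hermes_catalog.multiplets_for(lab), truth, acq, lab)
            for lab in "ABCD"
        }
        direct = to_spectrum(hadamard_combine(subs, "GSH"), cfg.zerofill, cfg.lb_hz)
        err = np.max(np.abs(proc.diff_spectra["GSH"].intensities - direct.intensities))
        assert err / np.max(np.abs(direct.intensities)) < 1e-6

    def test_full_chain_on_noiseless_scan_stays_close_to_prediction(
        self, acq_map, truth, hermes_catalog, zero_noise, quiet
    ):
        """The complete default chain (alignment + HSVD) reproduces the
        water-free catalog prediction over the GSH fit range to ~1%."""
        acq = acq_map["HERMES80"]
        raw = simulate_scan(truth, acq, hermes_catalog, zero_noise, 5)
        proc = preprocess_scan(raw, dataclasses.replace(FAST, targets=("GSH",)))
        t_nowater = dict(truth)
        t_nowater["H2O"] = 0.0
        subs = {
            lab: synth_fid(hermes_catalog.multiplets_for(lab), t_nowater, acq, lab)
            for lab in "ABCD"
        }
        direct = to_spectrum(hadamard_combine(subs, "GSH"), FAST.zerofill, FAST.lb_hz)
        sel = direct.slice_ppm(2.25, 3.5)
        err = np.max(
            np.abs(proc.diff_spectra["GSH"].intensities[sel] - direct.intensities[sel])
        )
        assert err / np.max(np.abs(direct.intensities[sel])) < 0.02

    def test_determinism(self, acq_map, truth, hermes_catalog, quiet):
        raw = simulate_scan(
            truth, acq_map["HERMES80"], hermes_catalog, NoiseConfig(), 8
        )
        cfg = dataclasses.replace(FAST, targets=("GSH",))
        a = preprocess_scan(raw, cfg)
        b = preprocess_scan(raw, cfg)
        assert np.array_equal(
            a.diff_spectra["GSH"].intensities, b.diff_spectra["GSH"].intensities
        )

    def test_transient_order_equivariance(self, acq_map, truth, hermes_catalog, quiet):
        raw = simulate_scan(
            truth, acq_map["HERMES80"], hermes_catalog, NoiseConfig(), 12
        )
        cfg = dataclasses.replace(FAST, targets=("GSH",))
        a = preprocess_scan(raw, cfg)
        rng = np.random.default_rng(0)
        for lab in raw.transients:
            rng.shuffle(raw.transients[lab])
        b = preprocess_scan(raw, cfg)
        scale = np.max(np.abs(a.diff_spectra["GSH"].intensities))
        assert np.allclose(
            a.diff_spectra["GSH"].intensities,
            b.diff_spectra["GSH"].intensities,
            atol=1e-6 * scale,
        )

    def test_hsvd_suppresses_residual_water(self, acq_map, truth, hermes_catalog, quiet):
        raw = simulate_scan(
            truth, acq_map["HERMES80"], hermes_catalog, NoiseConfig(), 9
        )
        with_ = preprocess_scan(raw, dataclasses.replace(FAST, targets=("GSH",)))
        without = preprocess_scan(
            raw, dataclasses.replace(FAST, targets=("GSH",), do_hsvd=False)
        )
        sel = with_.diff_spectra["GSH"].slice_ppm(4.5, 4.9)
        a = np.max(np.abs(with_.diff_spectra["GSH"].intensities[sel]))
        b = np.max(np.abs(without.diff_spectra["GSH"].intensities[sel]))
        assert a < 0.05 * b

    def test_provenance_lists_every_step(self, acq_map, truth, mega_catalog, quiet):
        raw = simulate_scan(truth, acq_map["MEGA120"], mega_catalog, NoiseConfig(), 2)
        proc = preprocess_scan(raw, FAST)
        steps = [p["step"] for p in proc.provenance]
        assert steps == [
            "eddy_correct",
            "register_transients",
            "weighted_average",
            "align_subspectra",
            "combine",
            "hsvd_filter",
            "to_spectrum",
        ]
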