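"""Phasor transform identities, calibration, universal-circle geometry,
ROI-based fine lifetime separation and two-component unmixing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flimsep as fs
from flimsep.synthetic_scene import wrapped_decay_pdf

from conftest import noiseless_image, uniform_phantom


def _calibrated_noiseless(tau, optics, reference_tau=3.55, total=1e7):
    """Calibrated phasor field of a noiseless mono-exponential decay."""
    ref = noiseless_image([(reference_tau, 1.0)], optics, total)
    img = noiseless_image([(tau, 1.0)], optics, total)
    field = fs.phasor_transform(img)
    return fs.calibrate_phasor(field, ref, reference_tau)


# ---------------------------------------------------------------------------
# transform identities
# ---------------------------------------------------------------------------


class TestPhasorTransform:
    def test_delta_decay_maps_near_one_zero(self, optics):
        counts = np.zeros((1, 1, optics.n_time_bins))
        counts[0, 0, 0] = 1000
        f = fs.phasor_transform(fs.TCSPCImage(counts, optics))
        # within the half-bin phase of the midpoint convention
        assert f.g[0, 0] == pytest.approx(1.0, abs=0.02)
        assert f.s[0, 0] == pytest.approx(0.0, abs=0.02)

    def test_uniform_decay_maps_to_origin(self, optics):
        counts = np.ones((1, 1, optics.n_time_bins))
        f = fs.phasor_transform(fs.TCSPCImage(counts, optics))
        assert abs(f.g[0, 0]) < 1e-10
        assert abs(f.s[0, 0]) < 1e-10

    def test_apex_at_omega_tau_one(self, optics):
        tau = 1.0 / optics.omega
        f = _calibrated_noiseless(tau, optics)
        assert f.g[0, 0] == pytest.approx(0.5, abs=1e-3)
        assert f.s[0, 0] == pytest.approx(0.5, abs=1e-3)

    def test_harmonic_validation(self, optics):
        img = noiseless_image([(2.0, 1.0)], optics, 100)
        with pytest.raises(ValueError, match="harmonic"):
            fs.phasor_transform(img, harmonic=0)

    def test_empty_pixels_are_nan(self, optics):
        counts = np.zeros((2, 1, optics.n_time_bins))
        counts[0, 0, 5] = 10
        f = fs.phasor_transform(fs.TCSPCImage(counts, optics))
        assert np.isnan(f.g[1, 0]) and np.isnan(f.s[1, 0])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class TestCalibration:
    def test_universal_circle_residence(self, optics):
        """Noiseless mono-exponential pixels sit on the universal circle
        (g - 1/2)^2 + s^2 = 1/4 after calibration, to < 1e-6."""
        for tau in (0.493, 0.7, 1.122, 1.845, 2.161, 3.196, 3.85):
            f = _calibrated_noiseless(tau, optics)
            dev = abs((f.g[0, 0] - 0.5) ** 2 + f.s[0, 0] ** 2 - 0.25)
            assert dev < 1e-6

    def test_zero_width_irf_gives_identity_correction(self):
        """With a delta IRF the calibration correction is the identity; at
        4096 bins the finite-bin factor is < 1e-6 so raw and calibrated
        coordinates agree to that tolerance."""
        optics = fs.OpticsConfig(n_time_bins=4096)
        tau_ref = 2.5
        t = optics.bin_centers
        decay = np.exp(-t / tau_ref)
        img = fs.TCSPCImage((1e7 * decay / decay.sum()).reshape(1, 1, -1), optics)
        raw = fs.phasor_transform(img)
        cal = fs.calibrate_phasor(raw, img, tau_ref)
        assert cal.g[0, 0] == pytest.approx(raw.g[0, 0], abs=1e-6)
        assert cal.s[0, 0] == pytest.approx(raw.s[0, 0], abs=1e-6)

    def test_irf_offset_appears_as_phase(self, optics):
        """A reference acquired with an IRF centered at t0 needs a phase
        correction of omega * t0 (shift theorem)."""
        ref = noiseless_image([(2.5, 1.0)], optics, 1e7)
        raw = fs.phasor_transform(ref)
        cal = fs.calibrate_phasor(raw, ref, 2.5)
        z_raw = complex(raw.g[0, 0], raw.s[0, 0])
        z_cal = complex(cal.g[0, 0], cal.s[0, 0])
        correction_phase = abs(np.angle(z_cal / z_raw))
        # the correction rotates back by the IRF offset phase omega * t0;
        # the midpoint convention's half-bin phase (omega * dt / 2) is
        # absorbed by the same correction
        expected = optics.omega * optics.irf_offset
        half_bin = optics.omega * optics.bin_width / 2
        assert correction_phase == pytest.approx(expected, abs=half_bin + 1e-6)

    def test_zero_modulation_reference_rejected(self, optics):
        counts = np.ones((1, 1, optics.n_time_bins))
        flat = fs.TCSPCImage(counts, optics)
        field = fs.phasor_transform(flat)
        with pytest.raises(ValueError, match="modulation"):
            fs.calibrate_phasor(field, flat, 2.0)

    def test_simulated_reference_recovers_fluorescein_tau(
        self, optics, reference_img
    ):
        """After calibration a fluorescein-like simulation's pooled phasor
        sits on the universal circle at its reference lifetime."""
        img = fs.simulate_confocal_tcspc(uniform_phantom(3.55, 48), optics, 100, 77)
        f = fs.calibrate_phasor(fs.phasor_transform(img), reference_img, 3.55)
        g, s = f.pooled()
        tau_phase, tau_mod = fs.tau_from_phasor((g, s), optics.omega)
        assert tau_phase == pytest.approx(3.55, rel=0.02)
        assert tau_mod == pytest.approx(3.55, rel=0.02)


# ---------------------------------------------------------------------------
# lifetime coordinates
# ---------------------------------------------------------------------------


class TestTauFromPhasor:
    def test_zero_lifetime_corner(self, optics):
        assert fs.tau_from_phasor((1.0, 0.0), optics.omega) == (0.0, 0.0)

    def test_apex_gives_one_over_omega(self, optics):
        tp, tm = fs.tau_from_phasor((0.5, 0.5), optics.omega)
        assert tp == pytest.approx(1 / optics.omega, rel=1e-12)
        assert tm == pytest.approx(1 / optics.omega, rel=1e-12)

    def test_phase_equals_modulation_on_circle(self, optics):
        for tau in np.geomspace(0.05, 20, 25):
            z = fs.model_phasor(tau, optics.omega)
            tp, tm = fs.tau_from_phasor((z.real, z.imag), optics.omega)
            assert tp == pytest.approx(tm, rel=1e-9)

    def test_invalid_points_flagged(self, optics):
        tp, _ = fs.tau_from_phasor((-0.1, 0.3), optics.omega)
        assert math.isnan(tp)
        _, tm = fs.tau_from_phasor((0.9, 0.9), optics.omega)
        assert math.isnan(tm)


# ---------------------------------------------------------------------------
# mixing linearity (property)
# ---------------------------------------------------------------------------


class TestMixingLinearity:
    @settings(max_examples=25, deadline=None)
    @given(
        tau1=st.floats(0.3, 4.0),
        tau2=st.floats(0.3, 4.0),
        frac=st.floats(0.05, 0.95),
    )
    def test_mixture_phasor_is_weighted_mean(self, tau1, tau2, frac):
        """The phasor of a photon-weighted mixture equals the photon-weighted
        mean of the component phasors (exact on noiseless input)."""
        optics = fs.OpticsConfig()
        irf = fs.make_irf(optics)
        p1 = wrapped_decay_pdf([(tau1, 1.0)], irf, optics.repetition_period)
        p2 = wrapped_decay_pdf([(tau2, 1.0)], irf, optics.repetition_period)
        mix = frac * p1 + (1 - frac) * p2
        stack = np.stack([p1, p2, mix]).reshape(3, 1, -1) * 1e6
        f = fs.phasor_transform(fs.TCSPCImage(stack, optics))
        g_mix = frac * f.g[0, 0] + (1 - frac) * f.g[1, 0]
        s_mix = frac * f.s[0, 0] + (1 - frac) * f.s[1, 0]
        assert f.g[2, 0] == pytest.approx(g_mix, abs=1e-9)
        assert f.s[2, 0] == pytest.approx(s_mix, abs=1e-9)


# ---------------------------------------------------------------------------
# median filtering
# ---------------------------------------------------------------------------


class TestMedianFilter:
    def test_reduces_scatter_without_moving_centroid(self, optics, reference_img):
        img = fs.simulate_confocal_tcspc(uniform_phantom(2.0, 48), optics, 100, 81)
        raw = fs.calibrate_phasor(fs.phasor_transform(img, 1, 0), reference_img, 3.55)
        filt = fs.calibrate_phasor(fs.phasor_transform(img, 1, 3), reference_img, 3.55)
        assert np.nanvar(filt.g) < np.nanvar(raw.g)
        assert np.nanvar(filt.s) < np.nanvar(raw.s)
        g0, s0 = raw.pooled()
        g1, s1 = filt.pooled()
        assert abs(g1 - g0) / abs(g0) < 0.01
        assert abs(s1 - s0) / abs(s0) < 0.01

    def test_even_size_rejected(self, optics):
        img = noiseless_image([(2.0, 1.0)], optics, 100)
        with pytest.raises(ValueError, match="odd"):
            fs.phasor_transform(img, spatial_median=4)


# ---------------------------------------------------------------------------
# ROI separation
# ---------------------------------------------------------------------------


class TestSeparateByRoi:
    def _two_structure(self, optics, reference_img):
        specs = [
            fs.StructureSpec("actin", "filament", [(1.845, 1.0)], n=6),
            fs.StructureSpec("mito", "granule", [(1.244, 1.0)], n=25, radius=3.0),
        ]
        ph = fs.make_cell_phantom(128, specs, seed=7)
        img = fs.simulate_confocal_tcspc(ph, optics, 300, seed=8)
        f = fs.calibrate_phasor(fs.phasor_transform(img, 1, 3), reference_img, 3.55)
        return ph, img, f

    def test_exhaustive_roi_captures_everything(self, optics, reference_img):
        _, img, f = self._two_structure(optics, reference_img)
        roi = fs.PhasorROI("all", center=(0.5, 0.2), radius=5.0)
        channels, assignment = fs.separate_by_roi(f, img.intensity(), [roi])
        np.testing.assert_array_equal(channels[0], img.intensity())

    def test_close_pair_assignment_accuracy(self, optics, reference_img):
        """Fine separation of the spectrally inseparable 1.845 / 1.244 ns
        pair: >= 90% per-structure pixel assignment accuracy at 300
        photons/pixel with a 3x3 phasor median filter."""
        ph, img, f = self._two_structure(optics, reference_img)
        rois = [
            fs.PhasorROI("actin", target_tau=1.845, tolerance=0.3),
            fs.PhasorROI("mito", target_tau=1.244, tolerance=0.3),
        ]
        _, assignment = fs.separate_by_roi(f, img.intensity(), rois)
        for lab, idx in ((1, 0), (2, 1)):
            mask = ph.label_map == lab
            assert (assignment[mask] == idx).mean() >= 0.90

    def test_nearest_policy_conserves_intensity(self, optics, reference_img):
        _, img, f = self._two_structure(optics, reference_img)
        rois = [
            fs.PhasorROI("a", target_tau=1.845, tolerance=0.05),
            fs.PhasorROI("b", target_tau=1.244, tolerance=0.05),
        ]
        channels, _ = fs.separate_by_roi(
            f, img.intensity(), rois, unassigned_policy="nearest"
        )
        np.testing.assert_array_equal(sum(channels), img.intensity())

    def test_four_class_matches_bruteforce_classifier(self, optics, reference_img):
        """ROI assignment with 'nearest' policy reproduces a brute-force
        nearest-universal-circle-point classifier on the same (g, s)."""
        taus = [2.161, 1.719, 1.398, 1.122]
        specs = [
            fs.StructureSpec(f"v{i}", "granule", [(t, 1.0)], n=12, radius=2.5)
            for i, t in enumerate(taus)
        ]
        ph = fs.make_cell_phantom(128, specs, seed=21)
        img = fs.simulate_confocal_tcspc(ph, optics, 300, seed=22)
        f = fs.calibrate_phasor(fs.phasor_transform(img, 1, 3), reference_img, 3.55)
        rois = [
            fs.PhasorROI(f"v{i}", target_tau=t, tolerance=1e-3) for i, t in enumerate(taus)
        ]
        _, assignment = fs.separate_by_roi(
            f, img.intensity(), rois, unassigned_policy="nearest"
        )
        centers = np.array(
            [
                [c.real, c.imag]
                for c in (
                    fs.model_phasor(t, optics.omega, 1, optics.bin_width)
                    for t in taus
                )
            ]
        )
        valid = np.isfinite(f.g)
        d2 = (f.g[valid, None] - centers[None, :, 0]) ** 2 + (
            f.s[valid, None] - centers[None, :, 1]
        ) ** 2
        brute = np.argmin(d2, axis=1)
        agree = (assignment[valid] == brute).mean()
        assert agree > 0.999

    def test_requires_calibration_and_rois(self, optics):
        img = noiseless_image([(2.0, 1.0)], optics, 100)
        f = fs.phasor_transform(img)
        with pytest.raises(ValueError, match="calibrat"):
            fs.separate_by_roi(f, img.intensity(), [fs.PhasorROI("x", (0.5, 0.3), 0.1)])
        f2 = _calibrated_noiseless(2.0, optics)
        with pytest.raises(ValueError, match="ROI"):
            fs.separate_by_roi(f2, img.intensity(), [])


# ---------------------------------------------------------------------------
# two-component unmixing
# ---------------------------------------------------------------------------


class TestUnmix:
    def _points(self, optics):
        z1 = fs.model_phasor(3.196, optics.omega, 1, optics.bin_width)
        z2 = fs.model_phasor(1.122, optics.omega, 1, optics.bin_width)
        return (z1.real, z1.imag), (z2.real, z2.imag)

    def test_endpoint_and_midpoint(self, optics):
        p1, p2 = self._points(optics)
        f = _calibrated_noiseless(3.196, optics)
        f1, f2 = fs.unmix_two_components(f, f.photons, p1, p2)
        assert f1[0, 0] == pytest.approx(1.0, abs=1e-6)
        irf = fs.make_irf(optics)
        mid = 0.5 * wrapped_decay_pdf([(3.196, 1.0)], irf, 12.5) + 0.5 * (
            wrapped_decay_pdf([(1.122, 1.0)], irf, 12.5)
        )
        img = fs.TCSPCImage((1e6 * mid).reshape(1, 1, -1), optics)
        ref = noiseless_image([(3.55, 1.0)], optics, 1e7)
        fm = fs.calibrate_phasor(fs.phasor_transform(img), ref, 3.55)
        m1, m2 = fs.unmix_two_components(fm, img.intensity(), p1, p2)
        assert m1[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert m2[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_70_30_mixture_recovered(self, optics, reference_img):
        """A 70/30 photon mixture unmixes to 0.70/0.30 within 0.03 at ~1e4
        photons per pixel."""
        p1, p2 = self._points(optics)
        ph = fs.Phantom(
            np.ones((24, 24), np.int32),
            {1: ((3.196, 0.7), (1.122, 0.3))},
            {1: 1.0},
            {1: "mix"},
        )
        img = fs.simulate_confocal_tcspc(ph, fs.OpticsConfig(), 10000, seed=91)
        f = fs.calibrate_phasor(fs.phasor_transform(img), reference_img, 3.55)
        f1, f2 = fs.unmix_two_components(f, img.intensity(), p1, p2)
        assert np.nanmean(f1) == pytest.approx(0.70, abs=0.03)
        assert np.nanmean(f2) == pytest.approx(0.30, abs=0.03)

    def test_degenerate_chord_rejected(self, optics):
        f = _calibrated_noiseless(2.0, optics)
        with pytest.raises(ValueError, match="degenerate"):
            fs.unmix_two_components(f, f.photons, (0.5, 0.3), (0.5, 0.3))
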