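"""Azimuthal orientation: background subtraction, Gaussian fit, reorientation."""

import numpy as np
import pytest

from osteoquant import orientation as orient
from osteoquant import pipeline, saxd, synth
from osteoquant.orientation import (
    FWHM_FACTOR,
    AzimuthalProfile,
    OrientationFit,
    azimuthal_profile,
    collagen_azimuth,
    default_q_bands,
    fit_orientation,
    mineral_background,
    reorientation_rate,
)


def _gauss_profile(chi0=0.0, dchi0=10.0, amp=100.0, kind="collagen"):
    chi = np.arange(-89.5, 90.0, 1.0)
    d = np.mod(chi - chi0 + 90.0, 180.0) - 90.0
    return AzimuthalProfile(chi, amp * np.exp(-(d**2) / (2 * dchi0**2)), (0.27, 0.29), kind)


class TestAzimuthalProfile:
    def test_isotropic_ring_constant(self, maps):
        q_map, _ = maps
        ring = np.exp(-((q_map - 0.28) ** 2) / (2 * 0.03**2))
        prof = azimuthal_profile(ring, maps, (0.26, 0.30), chi_bins=60)
        vals = prof.intensity[prof.valid]
        assert vals.std() / vals.mean() < 0.02

    def test_peak_at_loading_axis(self, maps, noiseless_wt_sequence):
        frame = noiseless_wt_sequence.frames[0]
        prof = azimuthal_profile(frame, maps, (0.26, 0.30))
        assert abs(prof.chi[np.argmax(prof.intensity)]) < 2.0

    def test_band_off_detector_raises(self, maps):
        with pytest.raises(ValueError):
            azimuthal_profile(np.ones((384, 384)), maps, (40.0, 50.0))


class TestMineralBackground:
    def test_background_only_frame_matches_peak_band(self, maps, noiseless_wt_sequence):
        """Without a collagen ring the flanking-band estimate reproduces the
        peak-band profile (the diffuse background is smooth in q)."""
        bg_img = noiseless_wt_sequence.components["background"]
        pb, lb, hb = default_q_bands(saxd.Q0_THIRD_ORDER, 0.03)
        total = azimuthal_profile(bg_img, maps, pb)
        est = mineral_background(bg_img, maps, lb, hb)
        ok = total.valid & est.valid
        assert np.allclose(est.intensity[ok], total.intensity[ok], rtol=0.02)

    def test_subtraction_removes_95pct_of_diffuse(self, maps, noiseless_wt_sequence):
        seq = noiseless_wt_sequence
        frame = seq.frames[0]
        pb, lb, hb = default_q_bands(saxd.Q0_THIRD_ORDER, 0.03)
        total = azimuthal_profile(frame, maps, pb)
        bg_est = mineral_background(frame, maps, lb, hb, peak_band=pb)
        bg_true = azimuthal_profile(seq.components["background"], maps, pb)
        removed = 1.0 - abs(
            (bg_true.intensity - bg_est.intensity).mean() / bg_true.intensity.mean()
        )
        assert removed >= 0.95

    def test_zero_frame_zero_profile(self, maps):
        prof = mineral_background(np.zeros((384, 384)), maps, (0.2, 0.23), (0.33, 0.36))
        assert np.allclose(prof.intensity, 0.0)

    def test_band_overlapping_peak_raises(self, maps):
        with pytest.raises(ValueError):
            mineral_background(
                np.ones((384, 384)), maps, (0.26, 0.29), (0.33, 0.36), peak_band=(0.27, 0.30)
            )


class TestCollagenAzimuth:
    def test_zero_background_is_identity(self):
        total = _gauss_profile(kind="total")
        zero = AzimuthalProfile(total.chi, np.zeros_like(total.chi), total.q_band, "mineral_background")
        col = collagen_azimuth(total, zero)
        assert np.array_equal(col.intensity, total.intensity)
        assert col.kind == "collagen"

    def test_total_equals_background_gives_zero(self):
        total = _gauss_profile(kind="total")
        bg = AzimuthalProfile(total.chi, total.intensity.copy(), total.q_band, "mineral_background")
        assert np.allclose(collagen_azimuth(total, bg).intensity, 0.0)

    def test_negative_values_retained(self):
        total = _gauss_profile(amp=1.0, kind="total")
        bg = AzimuthalProfile(total.chi, np.full_like(total.chi, 0.5), total.q_band, "mineral_background")
        col = collagen_azimuth(total, bg)
        assert col.intensity.min() < 0

    def test_grid_mismatch_raises(self):
        total = _gauss_profile(kind="total")
        other = AzimuthalProfile(total.chi + 0.5, total.intensity, total.q_band, "mineral_background")
        with pytest.raises(ValueError):
            collagen_azimuth(total, other)

    def test_collagen_area_within_5pct_of_ring_area(self, maps, noiseless_wt_sequence):
        seq = noiseless_wt_sequence
        pb, lb, hb = default_q_bands(saxd.Q0_THIRD_ORDER, 0.03)
        total = azimuthal_profile(seq.frames[0], maps, pb)
        bg = mineral_background(seq.frames[0], maps, lb, hb, peak_band=pb)
        col = collagen_azimuth(total, bg)
        true_col = azimuthal_profile(seq.components["collagen"], maps, pb)
        assert col.intensity.sum() == pytest.approx(true_col.intensity.sum(), rel=0.05)


class TestFitOrientation:
    def test_fwhm_identity_2p3548(self):
        fit = fit_orientation(_gauss_profile(dchi0=10.0))
        assert fit.converged
        assert fit.fwhm == pytest.approx(23.548, abs=1e-2)
        assert fit.fwhm == pytest.approx(FWHM_FACTOR * fit.delta_chi0, rel=1e-12)

    def test_chi0_90_recovered(self):
        fit = fit_orientation(_gauss_profile(chi0=90.0, dchi0=12.0))
        assert fit.converged
        assert abs(abs(fit.chi0) - 90.0) < 0.1

    def test_constant_profile_not_converged(self):
        chi = np.arange(-89.5, 90.0, 1.0)
        prof = AzimuthalProfile(chi, np.full_like(chi, 5.0), (0.27, 0.29), "collagen")
        assert not fit_orientation(prof).converged

    def test_requires_collagen_kind(self):
        with pytest.raises(ValueError):
            fit_orientation(_gauss_profile(kind="total"))


class TestReorientation:
    def _fits(self, fwhms):
        return [
            OrientationFit(0.0, f / FWHM_FACTOR, 1.0, converged=np.isfinite(f))
            for f in fwhms
        ]

    def test_constant_fwhm_rate_zero(self):
        eps = np.arange(5) * 0.1
        res = reorientation_rate(self._fits([30.0] * 5), eps)
        assert res.rate == pytest.approx(0.0, abs=1e-12)

    def test_linear_decrease_5deg_per_pct(self):
        """FWHM dropping 5 deg per 1% strain from a 100-deg start: both the
        percent-change slope and the degree slope equal -5."""
        eps = np.linspace(0, 2, 9)
        res = reorientation_rate(self._fits(list(100.0 - 5.0 * eps)), eps)
        assert res.rate_deg == pytest.approx(-5.0, rel=1e-9)
        assert res.rate == pytest.approx(-5.0, rel=1e-9)
        assert res.pct_change[0] == 0.0

    def test_fewer_than_3_converged_raises(self):
        with pytest.raises(ValueError):
            reorientation_rate(self._fits([30.0, np.nan, np.nan, 29.0]), np.arange(4.0))


class TestPipelineRecovery:
    def test_wt_recovery_over_seeds(self):
        """Mean unloaded FWHM within 2% and reorientation rate within 10%
        of generator truth over a seeded WT batch."""
        f0s, rates = [], []
        for s in range(50):
            res = pipeline.analyze_orientation_sample(synth.WT, s, n_frames=12)
            f0s.append(res["fwhm0"])
            rates.append(res["rate"])
        assert np.mean(f0s) == pytest.approx(synth.WT.orientation_fwhm0, rel=0.02)
        assert np.mean(rates) == pytest.approx(synth.WT.reorientation_rate, rel=0.10)

    def test_wt_rate_more_negative_than_crh(self):
        """Healthy bone reorients faster under load than steroid-exposed bone."""
        wt = pipeline.analyze_orientation_sample(synth.WT, 3, n_frames=12)
        crh = pipeline.analyze_orientation_sample(synth.CRH, 3, n_frames=12)
        assert wt["rate"] < crh["rate"] < 0

    def test_fwhm_percent_change_nonpositive_under_load(self):
        """Stress-induced alignment: FWHM percent change <= 0 on every frame
        (noiseless sequence; photon noise only blurs this at single frames)."""
        noise = synth.NoiseModel(photon_scale=np.inf, detector_sd=0.0, seed=0)
        seq = synth.gen_saxd_sequence(synth.WT, noise=noise, n_frames=8)
        from osteoquant.geometry import q_chi_map

        maps = q_chi_map(seq.geometry, seq.frames[0].intensity.shape)
        prof0 = saxd.sector_integrate(seq.frames[0], maps)
        fit0 = saxd.fit_third_order_peak(prof0)
        pb, lb, hb = default_q_bands(fit0.q0, fit0.width)
        fits = []
        for fr in seq.frames:
            total = azimuthal_profile(fr, maps, pb)
            bg = mineral_background(fr, maps, lb, hb, peak_band=pb)
            fits.append(fit_orientation(collagen_azimuth(total, bg)))
        eps = seq.truth.tissue_strain.to_numpy()
        res = reorientation_rate(fits, eps)
        assert np.all(res.pct_change <= 1e-6)

    def test_order_10pct_reduction_at_1pct_strain(self):
        """The large (order 10%) FWHM reduction at ~1% tissue strain is
        reproduced by the full pipeline on the WT preset."""
        res = pipeline.analyze_orientation_sample(synth.WT, 5, n_frames=21)
        eps = res["truth"].tissue_strain.to_numpy()
        assert eps[-1] == pytest.approx(1.0)
        final_drop = -res["pct_change"][-1]
        assert 5.0 <= final_drop <= 20.0
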