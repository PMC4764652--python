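"""Mechanics: strain, porosity-corrected stress, yield detection, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoquant import mechanics as mech
from osteoquant import pipeline, synth
from osteoquant.mechanics import (
    MechanicalRecord,
    corrected_stress,
    elastic_region,
    summarize_mechanics,
    tissue_strain,
)


def _record(separations, load=None):
    n = len(separations)
    markers = np.column_stack([np.zeros(n), np.asarray(separations)])
    return MechanicalRecord(
        time=np.arange(n, dtype=float),
        load=np.zeros(n) if load is None else np.asarray(load, float),
        marker_positions=markers,
        cross_section=(1.0, 0.2),
    )


class TestTissueStrain:
    def test_constant_separation_zero(self):
        assert np.allclose(tissue_strain(_record([5.0, 5.0, 5.0])), 0.0)

    def test_half_percent(self):
        eps = tissue_strain(_record([5.000, 5.025]))
        assert eps[1] == pytest.approx(0.5, rel=1e-12)

    def test_nonpositive_separation_raises(self):
        with pytest.raises(ValueError):
            tissue_strain(_record([5.0, -0.1]))

    def test_generated_record_matches_truth_zero_noise(self):
        rec, truth = synth.gen_mech_record(
            synth.WT, n_points=15, noise=synth.NoiseModel(detector_sd=0.0, seed=0)
        )
        np.testing.assert_allclose(tissue_strain(rec), truth.tissue_strain, atol=1e-10)


class TestCorrectedStress:
    def test_nominal(self):
        assert corrected_stress(2.0, (1.0, 0.2)) == pytest.approx(10.0)

    def test_porosity_30pct(self):
        assert corrected_stress(2.0, (1.0, 0.2), 0.30) == pytest.approx(10.0 / 0.7)

    def test_zero_porosity_identity(self):
        load = np.array([1.0, 2.0, 3.0])
        assert np.allclose(
            corrected_stress(load, (1.0, 0.2), 0.0), corrected_stress(load, (1.0, 0.2))
        )

    def test_porosity_one_rejected(self):
        with pytest.raises(ValueError):
            corrected_stress(1.0, (1.0, 0.2), 1.0)

    @given(p=st.floats(min_value=0.0, max_value=0.95))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_porosity(self, p):
        assert corrected_stress(2.0, (1.0, 0.2), p) >= corrected_stress(2.0, (1.0, 0.2), 0.0)


def _bilinear(eps, modulus, eps_y, factor):
    return np.where(
        eps <= eps_y,
        modulus * eps / 100.0,
        modulus * eps_y / 100.0 + factor * modulus * (eps - eps_y) / 100.0,
    )


class TestElasticRegion:
    eps = 0.05 * np.arange(20)

    def test_perfectly_linear_whole_series(self):
        region = elastic_region(70.0 * self.eps, self.eps)
        assert not region.triggered
        assert (region.start, region.end) == (0, 19)

    def test_bilinear_50pct_drop_detected_at_kink(self):
        """Slope halving at 0.4% strain: detected end within one frame."""
        stress = _bilinear(self.eps, 7000.0, 0.40, 0.5)
        region = elastic_region(stress, self.eps)
        assert region.triggered
        assert abs(self.eps[region.end] - 0.40) <= 0.05 + 1e-12

    def test_5pct_drop_stays_elastic(self):
        """A slope reduction below the 10% criterion is not yield."""
        stress = _bilinear(self.eps, 7000.0, 0.40, 0.95)
        region = elastic_region(stress, self.eps)
        assert not region.triggered
        assert region.end == 19

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            elastic_region(np.arange(4.0), np.arange(4.0))


class TestSummarize:
    def test_exact_linear_fibril_modulus_30gpa(self):
        eps_t = 0.05 * np.arange(12)
        eps_f = 0.5 * eps_t
        stress = 30000.0 * eps_f / 100.0
        s = summarize_mechanics(stress, eps_t, eps_f)
        assert s.fibril_modulus == pytest.approx(30000.0, rel=1e-9)

    def test_exact_ratio_0p57(self):
        eps_t = 0.05 * np.arange(12)
        eps_f = 0.57 * eps_t
        stress = 7000.0 * eps_t / 100.0
        s = summarize_mechanics(stress, eps_t, eps_f)
        assert s.strain_ratio == pytest.approx(0.57, rel=1e-12)

    def test_consistency_identity_ratio_equals_moduli_quotient(self):
        """For exactly linear data d(eps_F)/d(eps_T) = E_T / E_f identically."""
        eps_t = 0.05 * np.arange(10)
        eps_f = 0.83 * eps_t
        stress = 5400.0 * eps_t / 100.0
        s = summarize_mechanics(stress, eps_t, eps_f)
        assert s.strain_ratio == pytest.approx(s.tissue_modulus / s.fibril_modulus, rel=1e-10)

    def test_insufficient_converged_raises(self):
        eps_t = 0.05 * np.arange(10)
        eps_f = np.full(10, np.nan)
        eps_f[:2] = [0.0, 0.05]
        with pytest.raises(ValueError):
            summarize_mechanics(70.0 * eps_t, eps_t, eps_f)

    def test_max_fibril_strain_over_full_test(self):
        eps_t = 0.05 * np.arange(20)
        eps_f = np.minimum(0.57 * eps_t, 0.30)
        stress = _bilinear(eps_t, 7000.0, 0.403, 0.5)
        s = summarize_mechanics(stress, eps_t, eps_f)
        assert s.max_fibril_strain == pytest.approx(0.30)


class TestRecordRoundTrip:
    def test_stress_roundtrip_reproduces_truth(self, tmp_path):
        """Writing the record, re-reading it and recomputing stress from load,
        cross-section and porosity reproduces the stored ground truth."""
        from osteoquant import io

        rec, truth = synth.gen_mech_record(
            synth.CRH, n_points=14, noise=synth.NoiseModel(detector_sd=0.0, seed=9)
        )
        path = io.write_mech_record(rec, tmp_path / "rec.csv", truth)
        rec2 = io.read_mech_record(path)
        stress = corrected_stress(rec2.load, rec2.cross_section, rec2.porosity)
        np.testing.assert_allclose(stress, truth.stress_true, atol=1e-8)

    def test_zero_noise_slope_equals_modulus(self):
        rec, truth = synth.gen_mech_record(
            synth.WT, n_points=12, noise=synth.NoiseModel(detector_sd=0.0, seed=0)
        )
        eps = tissue_strain(rec)
        stress = corrected_stress(rec.load, rec.cross_section, rec.porosity)
        pre = eps <= truth.attrs["yield_strain"]
        slope = np.polyfit(eps[pre] / 100.0, stress[pre], 1)[0]
        assert slope == pytest.approx(synth.WT.tissue_modulus, rel=1e-9)


class TestParameterRecovery:
    @pytest.mark.parametrize("preset", [synth.WT, synth.CRH], ids=["wt", "crh"])
    def test_mean_recovery_within_5pct(self, preset):
        """Over seeded records, mean recovered tissue modulus and yield stress
        stay within 5% of the preset truth."""
        mods, yields = [], []
        for i in range(50):
            rec, _ = synth.gen_mech_record(
                preset, n_points=20, noise=synth.NoiseModel(seed=1000 + i)
            )
            eps = tissue_strain(rec)
            stress = corrected_stress(rec.load, rec.cross_section, rec.porosity)
            region = elastic_region(stress, eps)
            sl = region.slice()
            mods.append(np.polyfit(eps[sl] / 100.0, stress[sl], 1)[0])
            yields.append(stress[region.end])
        assert np.mean(mods) == pytest.approx(preset.tissue_modulus, rel=0.05)
        assert np.mean(yields) == pytest.approx(preset.yield_stress, rel=0.05)
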