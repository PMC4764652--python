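"""Voxel morphometry: segmentation, classification, densities, invariants."""

import dataclasses

import numpy as np
import pytest

from osteoquant import morphometry as morpho
from osteoquant import pipeline, synth

ZERO_NOISE = dict(noise=synth.NoiseModel(detector_sd=0.0, seed=0))


def _solid_preset():
    return dataclasses.replace(
        synth.WT, porosity=0.0, cavity_vf=0.0, lacuna_density=0.0, canal_density=0.0
    )


@pytest.fixture(scope="module")
def wt_volume():
    return synth.gen_microct_volume(
        synth.WT, shape=(96, 160, 160), noise=synth.NoiseModel(detector_sd=0.0, seed=5)
    )


@pytest.fixture(scope="module")
def crh_volume():
    return synth.gen_microct_volume(
        synth.CRH, shape=(128, 192, 192), noise=synth.NoiseModel(detector_sd=0.0, seed=5)
    )


class TestSegmentPores:
    def test_solid_annulus_zero_components(self):
        vol = synth.gen_microct_volume(_solid_preset(), shape=(48, 96, 96), **ZERO_NOISE)
        labeled = morpho.segment_pores(vol.volume, 100.0)
        assert labeled.n_components == 0
        summary = morpho.summarize_morphometry(
            labeled, morpho.classify_components(labeled)
        )
        assert summary.porosity == 0.0

    def test_pore_voxels_match_truth_zero_noise(self, wt_volume):
        labeled = morpho.segment_pores(wt_volume.volume, 100.0)
        assert (labeled.labels > 0).sum() == wt_volume.truth.voxels.sum()

    def test_threshold_below_all_grays_zero_pores(self, wt_volume):
        labeled = morpho.segment_pores(wt_volume.volume, float(wt_volume.volume.min()))
        assert labeled.n_components == 0

    def test_threshold_outside_range_raises(self, wt_volume):
        with pytest.raises(ValueError):
            morpho.segment_pores(wt_volume.volume, 300.0)

    def test_medullary_cavity_not_counted_as_pore(self, wt_volume):
        labeled = morpho.segment_pores(wt_volume.volume, 100.0)
        nz, ny, nx = labeled.labels.shape
        assert not labeled.bone_mask[nz // 2, ny // 2, nx // 2]
        assert labeled.labels[nz // 2, ny // 2, nx // 2] == 0


class TestClassify:
    def test_counts_match_generator_classes(self, wt_volume):
        labeled = morpho.segment_pores(wt_volume.volume, 100.0)
        classes = morpho.classify_components(labeled)
        truth_counts = wt_volume.truth["class"].value_counts()
        got = classes["class"].value_counts()
        assert got.get("lacuna", 0) == truth_counts.get("lacuna", 0)
        assert got.get("canal", 0) == truth_counts.get("canal", 0)

    def test_ellipsoids_and_cylinders_constructed(self):
        """100 ellipsoids + 3 full-length cylinders -> (100 lacunae, 3 canals)."""
        rng = np.random.default_rng(7)
        shape = (96, 220, 220)
        labels = np.zeros(shape, dtype=np.int32)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        next_id = 1
        cols = np.array([40, 110, 180])
        for c in cols:  # canals, radius 5 voxels (8 um at 1.6 um voxels)
            labels[(yy - 110) ** 2 + (xx - c) ** 2 <= 5**2] = next_id
            next_id += 1
        placed = 0
        while placed < 100:
            cz = rng.integers(8, shape[0] - 8)
            cy = rng.integers(8, shape[1] - 8)
            cx = rng.integers(8, shape[2] - 8)
            a, b, c_ = rng.uniform(2, 3.5, 3)
            sub = (
                ((zz - cz) / c_) ** 2 + ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2
            ) <= 1
            if np.any(labels[sub] > 0):
                continue
            # keep a clear 1-voxel moat so 26-connectivity cannot merge
            grown = (
                ((zz - cz) / (c_ + 1.6)) ** 2
                + ((yy - cy) / (b + 1.6)) ** 2
                + ((xx - cx) / (a + 1.6)) ** 2
            ) <= 1
            if np.any(labels[grown] > 0):
                continue
            labels[sub] = next_id
            next_id += 1
            placed += 1
        bone_mask = np.ones(shape, dtype=bool)
        lv = morpho.LabeledVolume(labels, bone_mask, 1.6, next_id - 1)
        classes = morpho.classify_components(lv)
        counts = classes["class"].value_counts()
        assert counts.get("lacuna", 0) == 100
        assert counts.get("canal", 0) == 3
        assert counts.get("cavity", 0) == 0

    def test_empty_volume_all_counts_zero(self):
        lv = morpho.LabeledVolume(np.zeros((10, 10, 10), np.int32), np.ones((10, 10, 10), bool), 1.6, 0)
        classes = morpho.classify_components(lv)
        assert len(classes) == 0
        s = morpho.summarize_morphometry(lv, classes)
        assert (s.n_lacunae, s.n_canals, s.n_cavities) == (0, 0, 0)

    def test_crh_has_cavities_and_fewer_lacunae(self, wt_volume, crh_volume):
        crh_labeled = morpho.segment_pores(crh_volume.volume, 100.0)
        crh_classes = morpho.classify_components(crh_labeled)
        crh_summary = morpho.summarize_morphometry(crh_labeled, crh_classes)
        wt_labeled = morpho.segment_pores(wt_volume.volume, 100.0)
        wt_summary = morpho.summarize_morphometry(
            wt_labeled, morpho.classify_components(wt_labeled)
        )
        assert crh_summary.n_cavities > 0
        assert crh_summary.lacuna_density < wt_summary.lacuna_density
        assert crh_summary.canal_density < wt_summary.canal_density


class TestSummaries:
    def test_density_arithmetic(self):
        """100 lacuna-sized components in 0.001 mm^3 of mask -> 1e5 per mm^3."""
        shape = (20, 50, 50)
        voxel = 2.0  # um; 50000 voxels * 8 um^3 = 4e-4 mm^3
        labels = np.zeros(shape, np.int32)
        zz, yy, xx = np.mgrid[:20, :50, :50]
        k = 1
        for z in range(2, 20, 4):
            for y in range(2, 50, 5):
                for x in range(2, 50, 10):
                    if k > 100:
                        break
                    labels[z, y, x] = k
                    k += 1
        mask = np.ones(shape, bool)
        lv = morpho.LabeledVolume(labels, mask, voxel, 100)
        s = morpho.summarize_morphometry(lv, morpho.classify_components(lv))
        expected = 100 / (shape[0] * shape[1] * shape[2] * (voxel * 1e-3) ** 3)
        assert s.lacuna_density == pytest.approx(expected)

    def test_conservation_pore_voxels(self, crh_volume):
        """Pore voxels = lacuna + canal + cavity voxels exactly."""
        labeled = morpho.segment_pores(crh_volume.volume, 100.0)
        classes = morpho.classify_components(labeled)
        assert classes.voxels.sum() == (labeled.labels > 0).sum()

    def test_crh_porosity_and_cavity_fraction(self, crh_volume):
        labeled = morpho.segment_pores(crh_volume.volume, 100.0)
        classes = morpho.classify_components(labeled)
        s = morpho.summarize_morphometry(labeled, classes)
        assert s.porosity == pytest.approx(0.30, rel=0.10)
        assert s.cavity_volume_fraction == pytest.approx(0.025, rel=0.15)


class TestScaleInvariance:
    def test_halving_voxel_size_preserves_counts(self):
        """The same physical microstructure rasterized at 3.2 and 1.6 um
        yields the same component counts (within 2%) and densities."""
        kwargs = dict(noise=synth.NoiseModel(detector_sd=0.0, seed=11))
        coarse = synth.gen_microct_volume(synth.WT, shape=(48, 128, 128), voxel_size=3.2, **kwargs)
        fine = synth.gen_microct_volume(synth.WT, shape=(96, 256, 256), voxel_size=1.6, **kwargs)
        res = {}
        for name, vol in (("coarse", coarse), ("fine", fine)):
            labeled = morpho.segment_pores(vol.volume, 100.0, vol.voxel_size)
            s = morpho.summarize_morphometry(labeled, morpho.classify_components(labeled))
            res[name] = s
        n_c = res["coarse"].n_lacunae + res["coarse"].n_canals
        n_f = res["fine"].n_lacunae + res["fine"].n_canals
        assert abs(n_c - n_f) <= max(0.02 * n_f, 1)
        assert res["coarse"].lacuna_density == pytest.approx(res["fine"].lacuna_density, rel=0.02)


class TestRecovery:
    @pytest.mark.parametrize(
        "preset,shape",
        [(synth.WT, (96, 160, 160)), (synth.CRH, (128, 192, 192))],
        ids=["wt", "crh"],
    )
    def test_counts_and_fractions_over_seeds(self, preset, shape):
        """Over seeded volumes: per-class counts within +/-2 of the placed
        truth and pore volume fractions within 10% relative."""
        n_seeds = 20
        for s in range(n_seeds):
            vol = synth.gen_microct_volume(
                preset, shape=shape, noise=synth.NoiseModel(detector_sd=8.0, seed=200 + s)
            )
            labeled = morpho.segment_pores(vol.volume, 100.0, vol.voxel_size)
            classes = morpho.classify_components(labeled)
            got = classes["class"].value_counts()
            want = vol.truth["class"].value_counts()
            for cls in ("lacuna", "canal", "cavity"):
                assert abs(got.get(cls, 0) - want.get(cls, 0)) <= 2
            summary = morpho.summarize_morphometry(labeled, classes)
            assert summary.porosity == pytest.approx(vol.achieved_porosity, rel=0.10)
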