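"""End-to-end orchestration: generate/ingest cohorts, run every analysis
stage, assemble group tables and the statistical report.

The per-sample entry points (`analyze_sample`, `analyze_orientation_sample`,
`analyze_qbse_specimen`, `analyze_microct`) are also the building blocks of
the acceptance checks; `run_pipeline` wires them into a full two-cohort
report with the group comparisons (t-tests between cohorts, ANOVA + Tukey
across mineralization regions).
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mechanics as mech
from . import morphometry as morpho
from . import orientation as orient
from . import qbse
from . import saxd
from . import stats as ost
from . import synth
from .geometry import q_chi_map

__all__ = [
    "child_seed",
    "analyze_sample",
    "analyze_orientation_sample",
    "analyze_qbse_specimen",
    "analyze_microct",
    "run_cohort_mechanics",
    "run_qbse_cohort",
    "run_pipeline",
]


def child_seed(seed: int, *keys) -> int:
    """Deterministic sub-seed (< 2**31) for a named pipeline stage.

    Stable across processes (uses crc32, not Python's randomized hash).
    """
    h = np.random.SeedSequence(
        entropy=int(seed),
        spawn_key=tuple(zlib.crc32(repr(k).encode()) for k in keys),
    )
    return int(h.generate_state(1)[0] % 2**31)


def analyze_sample(
    preset: synth.CohortPreset,
    seed: int,
    n_frames: int = 20,
    shape: tuple[int, int] = (384, 384),
    photon_scale: float = 1.0e4,
) -> dict:
    """Full single-sample nanomechanics: SAXD reduction joined with mechanics.

    Generates one SAXD loading sequence and its synchronized mechanical
    record, reduces every frame to a fibril strain, computes porosity-corrected
    stress and extensometric tissue strain, detects the elastic region and
    returns the mechanical summary (moduli, strain ratio, yield point,
    maximum fibril strain).
    """
    noise_x = synth.NoiseModel(photon_scale=photon_scale, seed=child_seed(seed, "saxd"))
    noise_m = synth.NoiseModel(seed=child_seed(seed, "mech"))
    seq = synth.gen_saxd_sequence(preset, noise=noise_x, n_frames=n_frames, shape=shape)
    record, _ = synth.gen_mech_record(preset, n_points=n_frames, noise=noise_m)

    eps_t = mech.tissue_strain(record)
    stress = mech.corrected_stress(record.load, record.cross_section, record.porosity)
    table = saxd.reduce_sequence(seq.frames, seq.geometry)
    table["tissue_strain"] = eps_t
    region = mech.elastic_region(stress, eps_t)
    summary = mech.summarize_mechanics(
        stress, eps_t, table["fibril_strain"].to_numpy(), region
    )
    return {
        "strain_ratio": summary.strain_ratio,
        "tissue_modulus": summary.tissue_modulus,
        "fibril_modulus": summary.fibril_modulus,
        "yield_stress": summary.yield_stress,
        "yield_strain": summary.yield_strain,
        "max_fibril_strain": summary.max_fibril_strain,
        "elastic_end": summary.elastic_region.end,
        "r_squared": summary.r_squared,
        "table": table,
    }


def analyze_orientation_sample(
    preset: synth.CohortPreset,
    seed: int,
    n_frames: int = 20,
    shape: tuple[int, int] = (384, 384),
    photon_scale: float = 1.0e4,
) -> dict:
    """Fibrillar orientation under load for one generated sequence.

    Fits the third-order peak on the unloaded frame to place the collagen and
    mineral-background q bands, then tracks the background-subtracted
    azimuthal Gaussian FWHM across the sequence and regresses its percent
    change on tissue strain.
    """
    noise_x = synth.NoiseModel(photon_scale=photon_scale, seed=child_seed(seed, "saxd"))
    seq = synth.gen_saxd_sequence(preset, noise=noise_x, n_frames=n_frames, shape=shape)
    maps = q_chi_map(seq.geometry, shape)
    prof0 = saxd.sector_integrate(seq.frames[0], maps)
    fit0 = saxd.fit_third_order_peak(prof0)
    if not fit0.converged:
        raise RuntimeError("third-order peak fit failed on the unloaded frame")
    peak_band, low_band, high_band = orient.default_q_bands(fit0.q0, fit0.width)
    fits = []
    for frame in seq.frames:
        total = orient.azimuthal_profile(frame, maps, peak_band)
        background = orient.mineral_background(
            frame, maps, low_band, high_band, peak_band=peak_band
        )
        collagen = orient.collagen_azimuth(total, background)
        fits.append(orient.fit_orientation(collagen))
    eps_t = np.array([f.tissue_strain for f in seq.frames])
    result = orient.reorientation_rate(fits, eps_t)
    fwhm0 = next(f.fwhm for f in fits if f.converged)
    return {
        "rate": result.rate,
        "rate_deg": result.rate_deg,
        "fwhm0": fwhm0,
        "pct_change": result.pct_change,
        "r_squared": result.r_squared,
        "fits": fits,
        "truth": seq.truth,
    }


def analyze_qbse_specimen(
    region: synth.MineralRegion,
    seed: int,
    size: tuple[int, int] = (560, 560),
) -> dict:
    """BMDD statistics of one specimen image: mean over its ROIs."""
    img = synth.gen_qbse_image(
        region.camean,
        region.sd,
        noise=synth.NoiseModel(detector_sd=200.0, seed=child_seed(seed, "qbse")),
        size=size,
    )
    ca_map, _ = qbse.calibrate(img.image, img.calibration)
    rois = qbse.extract_rois(ca_map, img.roi_centers, img.pixel_size_um)
    hists = [qbse.bmdd(r) for r in rois]
    return {
        "ca_mean": float(np.mean([h.ca_mean for h in hists])),
        "fwhm": float(np.mean([h.fwhm for h in hists])),
        "per_roi": hists,
        "truth": img.truth,
    }


def analyze_microct(
    preset: synth.CohortPreset,
    seed: int,
    shape: tuple[int, int, int] = (128, 256, 256),
    voxel_size: float = 1.6,
    threshold: float = 100.0,
) -> dict:
    """Morphometry of one generated cortical volume."""
    vol = synth.gen_microct_volume(
        preset, shape=shape, voxel_size=voxel_size,
        noise=synth.NoiseModel(detector_sd=8.0, seed=child_seed(seed, "ct")),
    )
    labeled = morpho.segment_pores(vol.volume, threshold, voxel_size)
    classes = morpho.classify_components(labeled)
    summary = morpho.summarize_morphometry(labeled, classes)
    return {"summary": summary, "classes": classes, "generated": vol}


def run_cohort_mechanics(
    preset: synth.CohortPreset,
    n_samples: int | None = None,
    base_seed: int = 0,
    n_frames: int = 20,
) -> pd.DataFrame:
    """Per-sample mechanical metrics for one cohort (one row per specimen)."""
    n = n_samples or preset.n_samples
    rows = []
    for i in range(n):
        res = analyze_sample(preset, child_seed(base_seed, preset.label, i), n_frames)
        rows.append(
            {
                "sample": f"{preset.label}_{i}",
                "group": preset.label,
                **{k: res[k] for k in (
                    "strain_ratio",
                    "tissue_modulus",
                    "fibril_modulus",
                    "yield_stress",
                    "yield_strain",
                    "max_fibril_strain",
                )},
            }
        )
    return pd.DataFrame(rows)


def run_qbse_cohort(
    region: synth.MineralRegion, n_specimens: int = 5, base_seed: int = 0
) -> pd.DataFrame:
    rows = []
    for i in range(n_specimens):
        res = analyze_qbse_specimen(region, child_seed(base_seed, region.label, i))
        rows.append(
            {
                "sample": f"{region.label}_{i}",
                "group": region.label,
                "ca_mean": res["ca_mean"],
                "fwhm": res["fwhm"],
            }
        )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


DEFAULT_CONFIG = {
    "seed": 0,
    "n_frames": 20,
    "cohorts": {"wt": None, "crh": None},  # None -> preset n_samples
    "qbse": {"regions": ["wt", "halo", "periosteal"], "n_specimens": 5},
    "microct": {"presets": ["wt", "crh"], "shape": [64, 160, 160]},
    "alpha": 0.05,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full multiscale pipeline and assemble the report.

    ``config`` is a dict or a YAML path; missing keys fall back to
    ``DEFAULT_CONFIG``.  When ``out_dir`` is given, writes ``report.json``
    and per-metric group tables as CSV.  Identical config (same seeds) gives
    an identical report.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    report: dict = {"config": _jsonable(cfg), "metrics": {}, "tests": {}}
    group_tables: dict[str, pd.DataFrame] = {}

    # --- nanomechanics cohorts ---------------------------------------------
    cohort_frames = []
    for label, n in cfg["cohorts"].items():
        preset = synth.PRESETS[label]
        cohort_frames.append(
            run_cohort_mechanics(preset, n, child_seed(seed, "mech", label),
                                 cfg["n_frames"])
        )
    mech_table = pd.concat(cohort_frames, ignore_index=True)
    group_tables["mechanics"] = mech_table
    labels = list(cfg["cohorts"])
    for metric in (
        "strain_ratio",
        "tissue_modulus",
        "fibril_modulus",
        "yield_stress",
        "max_fibril_strain",
    ):
        groups = {
            lab: mech_table.loc[mech_table.group == lab, metric].to_numpy()
            for lab in labels
        }
        report["metrics"][metric] = {
            lab: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            for lab, v in groups.items()
        }
        if len(labels) == 2:
            a, b = labels
            res = ost.student_t(groups[a], groups[b])
            report["tests"][metric] = {
                "test": res.test,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }

    # --- BMDD regions -------------------------------------------------------
    qcfg = cfg["qbse"]
    region_frames = [
        run_qbse_cohort(
            synth.QBSE_REGIONS[r], qcfg["n_specimens"], child_seed(seed, "qbse", r)
        )
        for r in qcfg["regions"]
    ]
    bmdd_table = pd.concat(region_frames, ignore_index=True)
    group_tables["bmdd"] = bmdd_table
    for metric in ("ca_mean", "fwhm"):
        groups = {
            r: bmdd_table.loc[bmdd_table.group == r, metric].to_numpy()
            for r in qcfg["regions"]
        }
        report["metrics"][f"bmdd_{metric}"] = {
            r: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            for r, v in groups.items()
        }
        if len(groups) >= 3:
            res = ost.anova_tukey(groups)
            report["tests"][f"bmdd_{metric}"] = {
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "pairwise": _jsonable(res.pairwise),
            }

    # --- microCT morphometry ------------------------------------------------
    ct_rows = []
    for label in cfg["microct"]["presets"]:
        preset = synth.PRESETS[label]
        res = analyze_microct(
            preset, child_seed(seed, "ct", label),
            shape=tuple(cfg["microct"]["shape"]),
        )
        s = res["summary"]
        ct_rows.append(
            {
                "group": label,
                "porosity": s.porosity,
                "cavity_volume_fraction": s.cavity_volume_fraction,
                "lacuna_density": s.lacuna_density,
                "canal_density": s.canal_density,
                "n_lacunae": s.n_lacunae,
                "n_canals": s.n_canals,
                "n_cavities": s.n_cavities,
            }
        )
    ct_table = pd.DataFrame(ct_rows)
    group_tables["morphometry"] = ct_table
    report["metrics"]["morphometry"] = _jsonable(ct_table)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "group_tables").mkdir(exist_ok=True)
        for name, table in group_tables.items():
            table.to_csv(out / "group_tables" / f"{name}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
    report["group_tables"] = group_tables
    return report
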