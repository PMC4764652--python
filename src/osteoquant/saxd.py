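"""Reduction of 2D SAXD frames to fibril strain.

The collagen fibril axial periodicity (D-period, ~67 nm) produces meridional
reflections at q = 2*pi*n/D.  This module reduces detector frames to 1D radial
profiles over a sector parallel to the loading axis, fits the third-order
reflection (q0 ~ 0.281 nm^-1) with a Gaussian plus linear background, converts
the peak position to the D-period via D = 6*pi/q0 and expresses fibril strain
as the percentage increase of D relative to the unstressed reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import AcquisitionGeometry, q_chi_map

__all__ = [
    "DetectorFrame",
    "RadialProfile",
    "PeakFit",
    "FibrilStrainPoint",
    "D0_NM",
    "Q0_THIRD_ORDER",
    "sector_integrate",
    "fit_third_order_peak",
    "d_period",
    "fibril_strain_series",
    "reduce_sequence",
]

#: canonical unloaded collagen axial period, nm
D0_NM = 67.0
#: nominal third-order meridional peak position for D0, nm^-1
Q0_THIRD_ORDER = 6.0 * np.pi / D0_NM


@dataclass
class DetectorFrame:
    """A single 2D scattering exposure.

    ``tissue_strain`` (percent) is attached from the synchronized mechanical
    record; it is carried, not computed, by this module.
    """

    intensity: np.ndarray
    frame_index: int = 0
    tissue_strain: float = np.nan

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("frame intensities must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("frame intensities must be non-negative")


@dataclass
class RadialProfile:
    """1D intensity vs q, integrated over a +/- sector about a center azimuth."""

    q: np.ndarray
    intensity: np.ndarray
    sector_center: float
    sector_halfwidth: float
    valid: np.ndarray = None  # True where the bin contained pixels

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have the same length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones_like(self.q, dtype=bool)


@dataclass
class PeakFit:
    """Gaussian + linear-background fit of one meridional reflection."""

    q0: float
    amplitude: float
    width: float
    background_slope: float
    background_intercept: float
    fit_rss: float
    converged: bool
    q0_stderr: float = np.nan


@dataclass
class FibrilStrainPoint:
    frame_index: int
    D: float
    fibril_strain: float
    tissue_strain: float = np.nan
    converged: bool = True


def _wrap_deg(a):
    return np.mod(np.asarray(a) + 180.0, 360.0) - 180.0


def sector_integrate(
    frame: DetectorFrame | np.ndarray,
    maps: tuple[np.ndarray, np.ndarray],
    sector_center: float = 0.0,
    sector_width: float = 20.0,
    q_bins: int = 64,
    q_range: tuple[float, float] | None = None,
) -> RadialProfile:
    """Radially integrate a frame over a sector (mirror sectors pooled).

    Pixels with ``|wrap(chi - sector_center)| <= sector_width/2`` — or within
    the mirror sector at ``sector_center + 180`` — are averaged in ``q_bins``
    uniform q bins.  The reported q of each bin is the mean q of its
    contributing pixels (sub-bin accurate); empty bins are flagged invalid.

    Parameters
    ----------
    sector_width : float
        Total angular width in degrees (the conventional "20 degree sector"
        is +/-10 degrees about the loading axis).
    q_range : optional
        (q_min, q_max) to histogram; default spans the sector's pixel range.
    """
    intensity = frame.intensity if isinstance(frame, DetectorFrame) else np.asarray(frame, float)
    if sector_width <= 0:
        raise ValueError("sector_width must be positive")
    if q_bins < 16:
        raise ValueError("q_bins must be at least 16")
    q_map, chi_map = maps
    d = np.abs(_wrap_deg(chi_map - sector_center))
    in_sector = (d <= sector_width / 2.0) | (d >= 180.0 - sector_width / 2.0)
    if not np.any(in_sector):
        raise ValueError("sector contains zero pixels")
    q_sel = q_map[in_sector]
    i_sel = intensity[in_sector]
    if q_range is None:
        q_lo, q_hi = float(q_sel.min()), float(q_sel.max())
    else:
        q_lo, q_hi = map(float, q_range)
        keep = (q_sel >= q_lo) & (q_sel <= q_hi)
        if not np.any(keep):
            raise ValueError("sector contains zero pixels in the q range")
        q_sel, i_sel = q_sel[keep], i_sel[keep]
    edges = np.linspace(q_lo, q_hi, q_bins + 1)
    idx = np.clip(np.searchsorted(edges, q_sel, side="right") - 1, 0, q_bins - 1)
    counts = np.bincount(idx, minlength=q_bins)
    sum_i = np.bincount(idx, weights=i_sel, minlength=q_bins)
    sum_q = np.bincount(idx, weights=q_sel, minlength=q_bins)
    valid = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    q_out = np.where(valid, sum_q / np.maximum(counts, 1), centers)
    i_out = np.where(valid, sum_i / np.maximum(counts, 1), 0.0)
    # enforce strict monotonicity (mean-q can coincide only in degenerate bins)
    order = np.argsort(q_out, kind="stable")
    q_out, i_out, valid = q_out[order], i_out[order], valid[order]
    if np.any(np.diff(q_out) <= 0):
        keep = np.concatenate([[True], np.diff(q_out) > 0])
        q_out, i_out, valid = q_out[keep], i_out[keep], valid[keep]
    return RadialProfile(q_out, i_out, sector_center, sector_width / 2.0, valid)


def _gauss_linear(q, amp, q0, width, slope, intercept):
    return amp * np.exp(-((q - q0) ** 2) / (2.0 * width**2)) + slope * q + intercept


def fit_third_order_peak(
    profile: RadialProfile,
    window: tuple[float, float] | None = None,
    q0_guess: float = Q0_THIRD_ORDER,
    width_guess: float | None = None,
) -> PeakFit:
    """Fit I(q) = A exp(-(q-q0)^2 / 2w^2) + m q + b inside a q window.

    The window defaults to ``q0_guess +/- 5 * width_guess`` (width_guess
    defaults to 0.03 nm^-1, a typical third-order radial width at this
    camera length).  Initialisation is derivative-free and deterministic:
    q0 from the windowed argmax, width from a tenth of the window, background
    from the window endpoints.  Never raises on fit failure; returns
    ``converged=False`` instead (also when the fitted amplitude is <= 0 or
    the center escapes the window).
    """
    if width_guess is None:
        width_guess = 0.03
    if window is None:
        window = (q0_guess - 5.0 * width_guess, q0_guess + 5.0 * width_guess)
    lo, hi = window
    sel = (profile.q >= lo) & (profile.q <= hi) & profile.valid
    q = profile.q[sel]
    y = profile.intensity[sel]
    if q.size < 8:
        raise ValueError("fit window must contain at least 8 bins")
    failed = PeakFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    if np.ptp(y) == 0:  # flat profile: no peak to fit
        return failed

    # deterministic start
    slope0 = (y[-1] - y[0]) / (q[-1] - q[0]) if q[-1] > q[0] else 0.0
    intercept0 = y[0] - slope0 * q[0]
    resid = y - (slope0 * q + intercept0)
    i_max = int(np.argmax(resid))
    amp0 = max(float(resid[i_max]), 1e-12)
    p0 = [amp0, float(q[i_max]), (hi - lo) / 10.0, slope0, intercept0]
    try:
        popt, pcov = curve_fit(
            _gauss_linear,
            q,
            y,
            p0=p0,
            bounds=(
                [0.0, lo, 1e-6, -np.inf, -np.inf],
                [np.inf, hi, (hi - lo), np.inf, np.inf],
            ),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return failed
    amp, q0, width, slope, intercept = popt
    if amp <= 0 or not (lo < q0 < hi):
        return failed
    rss = float(np.sum((y - _gauss_linear(q, *popt)) ** 2))
    q0_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return PeakFit(
        q0=float(q0),
        amplitude=float(amp),
        width=float(width),
        background_slope=float(slope),
        background_intercept=float(intercept),
        fit_rss=rss,
        converged=True,
        q0_stderr=q0_err,
    )


def d_period(q0: float | np.ndarray) -> float | np.ndarray:
    """Axial fibrillar periodicity D = 6*pi/q0 (nm) from the third order."""
    q0 = np.asarray(q0, dtype=float)
    if np.any(q0 <= 0):
        raise ValueError("q0 must be positive")
    out = 6.0 * np.pi / q0
    return float(out) if out.ndim == 0 else out


def fibril_strain_series(
    fits: list[PeakFit],
    reference: int = 0,
    tissue_strain: np.ndarray | None = None,
) -> list[FibrilStrainPoint]:
    """Convert per-frame peak fits to fibril strain relative to a reference.

    ``fibril_strain = 100 * (D - D_ref) / D_ref`` with ``D = 6*pi/q0``.
    Non-converged frames are emitted with NaN strain and ``converged=False``.
    """
    if not any(f.converged for f in fits):
        raise ValueError("no converged frames")
    if not fits[reference].converged:
        raise ValueError("reference frame fit did not converge")
    d_ref = d_period(fits[reference].q0)
    out = []
    for k, f in enumerate(fits):
        eps_t = float(tissue_strain[k]) if tissue_strain is not None else np.nan
        if f.converged:
            d_k = d_period(f.q0)
            out.append(
                FibrilStrainPoint(k, d_k, 100.0 * (d_k - d_ref) / d_ref, eps_t, True)
            )
        else:
            out.append(FibrilStrainPoint(k, np.nan, np.nan, eps_t, False))
    return out


def reduce_sequence(
    frames: list[DetectorFrame],
    geometry: AcquisitionGeometry,
    sector_center: float = 0.0,
    sector_width: float = 20.0,
    q_bins: int = 64,
    window: tuple[float, float] | None = None,
    reference: int = 0,
) -> pd.DataFrame:
    """Full per-sample reduction: frames -> fibril-strain table.

    Returns a DataFrame with columns ``frame_index, q0, D, fibril_strain,
    tissue_strain, converged``.
    """
    if not frames:
        raise ValueError("no frames supplied")
    maps = q_chi_map(geometry, frames[0].intensity.shape)
    if window is None:
        w = 0.03
        window = (Q0_THIRD_ORDER - 5 * w, Q0_THIRD_ORDER + 5 * w)
    fits = []
    for fr in frames:
        prof = sector_integrate(
            fr, maps, sector_center, sector_width, q_bins, q_range=window
        )
        fits.append(fit_third_order_peak(prof, window=window))
    eps_t = np.array([fr.tissue_strain for fr in frames])
    pts = fibril_strain_series(fits, reference=reference, tissue_strain=eps_t)
    return pd.DataFrame(
        {
            "frame_index": [p.frame_index for p in pts],
            "q0": [f.q0 for f in fits],
            "D": [p.D for p in pts],
            "fibril_strain": [p.fibril_strain for p in pts],
            "tissue_strain": [p.tissue_strain for p in pts],
            "converged": [p.converged for p in pts],
        }
    )
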