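"""Degree of fibrillar orientation from azimuthal intensity profiles.

The azimuthal spread of the third-order collagen reflection encodes the
orientation dispersion of the mineralized fibrils about the loading axis.
The diffuse mineral scattering is removed by subtracting the mean azimuthal
profile of two flanking q bands (below and above the collagen peak); the
remaining collagen profile is fitted to a Gaussian

    I(chi) = I0 * exp(-((chi - chi0) / dchi0)^2 / 2)

deliberately WITHOUT a baseline term: an artificial baseline systematically
narrows the fitted peak, so it is only available behind an explicit flag for
sensitivity analysis.  FWHM = 2*sqrt(2 ln 2) * dchi0.  Loading narrows the
distribution (stress-induced alignment); the reorientation rate is the slope
of the FWHM percent change against tissue strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .saxd import DetectorFrame

__all__ = [
    "AzimuthalProfile",
    "OrientationFit",
    "ReorientationResult",
    "FWHM_FACTOR",
    "azimuthal_profile",
    "mineral_background",
    "collagen_azimuth",
    "fit_orientation",
    "reorientation_rate",
    "default_q_bands",
]

#: FWHM of a unit-sigma Gaussian: 2*sqrt(2*ln 2)
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class AzimuthalProfile:
    """Intensity vs azimuth in a narrow q band.

    ``kind`` is one of ``total`` (at the collagen peak), ``mineral_background``
    (flanking-band average) or ``collagen`` (difference).  When folded, chi
    covers [-90, 90) with the mirror half-circle pooled (meridional patterns
    are centrosymmetric).
    """

    chi: np.ndarray
    intensity: np.ndarray
    q_band: tuple[float, float]
    kind: str = "total"
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.chi.shape != self.intensity.shape:
            raise ValueError("chi and intensity must have the same length")
        if np.any(np.diff(self.chi) <= 0):
            raise ValueError("chi grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.valid is None:
            self.valid = np.ones_like(self.chi, dtype=bool)


@dataclass
class OrientationFit:
    chi0: float
    delta_chi0: float  # Gaussian scale, degrees
    amplitude: float
    converged: bool

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.delta_chi0


@dataclass
class ReorientationResult:
    rate: float  # % change in FWHM per % tissue strain
    rate_deg: float  # degrees of FWHM per % tissue strain
    pct_change: np.ndarray  # per converged frame, 0 at the reference
    tissue_strain: np.ndarray
    r_squared: float


def _fold_chi(chi):
    """Fold azimuth to [-90, 90): chi and chi+180 are equivalent."""
    return np.mod(np.asarray(chi) + 90.0, 180.0) - 90.0


def azimuthal_profile(
    frame: DetectorFrame | np.ndarray,
    maps: tuple[np.ndarray, np.ndarray],
    q_band: tuple[float, float],
    chi_bins: int = 180,
    fold: bool = True,
    kind: str = "total",
) -> AzimuthalProfile:
    """Mean intensity per azimuth bin over pixels with q inside ``q_band``.

    Default binning is 1 degree/bin over the folded half-circle.
    """
    intensity = frame.intensity if isinstance(frame, DetectorFrame) else np.asarray(frame, float)
    q_map, chi_map = maps
    lo, hi = q_band
    if not hi > lo:
        raise ValueError("empty q band")
    sel = (q_map >= lo) & (q_map <= hi)
    if not np.any(sel):
        raise ValueError("q band contains no detector pixels (band off-detector)")
    chi = _fold_chi(chi_map[sel]) if fold else chi_map[sel]
    span = (-90.0, 90.0) if fold else (-180.0, 180.0)
    edges = np.linspace(span[0], span[1], chi_bins + 1)
    idx = np.clip(np.searchsorted(edges, chi, side="right") - 1, 0, chi_bins - 1)
    counts = np.bincount(idx, minlength=chi_bins)
    sums = np.bincount(idx, weights=intensity[sel], minlength=chi_bins)
    valid = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    prof = np.where(valid, sums / np.maximum(counts, 1), 0.0)
    return AzimuthalProfile(centers, prof, (lo, hi), kind, valid)


def default_q_bands(q0: float, peak_width: float):
    """Default band placement around a fitted peak (q0, radial width w).

    The collagen band is q0 +/- 2w.  The two mineral-background bands have
    the same width (2w), placed below and above with a guard gap of half a
    band width (w): [q0-5w, q0-3w] and [q0+3w, q0+5w].  Keeping the flanking
    bands close to the peak minimizes the bias a curved (non-linear in q)
    mineral background leaves in the arithmetic two-band average.
    """
    w = peak_width
    return (
        (q0 - 2 * w, q0 + 2 * w),
        (q0 - 5 * w, q0 - 3 * w),
        (q0 + 3 * w, q0 + 5 * w),
    )


def mineral_background(
    frame,
    maps,
    q_low_band: tuple[float, float],
    q_high_band: tuple[float, float],
    chi_bins: int = 180,
    fold: bool = True,
    peak_band: tuple[float, float] | None = None,
) -> AzimuthalProfile:
    """Azimuthal mineral-scattering background: mean of two flanking bands.

    If ``peak_band`` is given, both flanking bands must exclude it.
    """
    if peak_band is not None:
        for band in (q_low_band, q_high_band):
            if band[1] > peak_band[0] and band[0] < peak_band[1]:
                raise ValueError("background band overlaps the collagen peak band")
    lo = azimuthal_profile(frame, maps, q_low_band, chi_bins, fold)
    hi = azimuthal_profile(frame, maps, q_high_band, chi_bins, fold)
    both = lo.valid & hi.valid
    prof = 0.5 * (lo.intensity + hi.intensity)
    # where only one band has pixels, use it alone
    only_lo = lo.valid & ~hi.valid
    only_hi = hi.valid & ~lo.valid
    prof[only_lo] = lo.intensity[only_lo]
    prof[only_hi] = hi.intensity[only_hi]
    return AzimuthalProfile(
        lo.chi,
        prof,
        (q_low_band[0], q_high_band[1]),
        "mineral_background",
        both | only_lo | only_hi,
    )


def collagen_azimuth(
    total: AzimuthalProfile, background: AzimuthalProfile
) -> AzimuthalProfile:
    """Background-subtracted collagen profile (negative values retained)."""
    if total.chi.shape != background.chi.shape or not np.allclose(
        total.chi, background.chi
    ):
        raise ValueError("total and background profiles must share a chi grid")
    return AzimuthalProfile(
        total.chi.copy(),
        total.intensity - background.intensity,
        total.q_band,
        "collagen",
        total.valid & background.valid,
    )


def _gauss_nobase(chi, amp, chi0, dchi0):
    return amp * np.exp(-(((chi - chi0) / dchi0) ** 2) / 2.0)


def fit_orientation(
    profile: AzimuthalProfile, with_baseline: bool = False
) -> OrientationFit:
    """Fit the collagen azimuthal profile to a baseline-free Gaussian.

    The profile is circularly re-centred on its argmax before fitting so a
    peak near the fold boundary (chi ~ +/-90) is handled seamlessly; the
    returned chi0 lies within half a period of the argmax.  ``with_baseline``
    adds a constant offset, for sensitivity analysis only.
    """
    if profile.kind != "collagen":
        raise ValueError("fit_orientation expects a collagen (background-subtracted) profile")
    chi = profile.chi[profile.valid]
    y = profile.intensity[profile.valid]
    failed = OrientationFit(np.nan, np.nan, np.nan, False)
    if chi.size < 5 or np.ptp(y) == 0:
        return failed
    period = 180.0
    i_max = int(np.argmax(y))
    center = chi[i_max]
    # unwrap chi into (center - 90, center + 90]
    chi_u = center + np.mod(chi - center + 90.0, period) - 90.0
    order = np.argsort(chi_u, kind="stable")
    chi_u, y_u = chi_u[order], y[order]
    p0 = [float(y[i_max]), float(center), 15.0]
    model = _gauss_nobase
    if with_baseline:
        model = lambda c, a, c0, d, b: _gauss_nobase(c, a, c0, d) + b  # noqa: E731
        p0 = p0 + [float(np.min(y))]
    try:
        with warnings.catch_warnings():
            # noiseless profiles make the covariance singular; we only need popt
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, chi_u, y_u, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError):
        return failed
    amp, chi0, dchi0 = popt[0], popt[1], abs(popt[2])
    if amp <= 0 or dchi0 <= 0 or dchi0 >= period or not np.isfinite(chi0):
        return failed
    # report within (-90, 90]
    chi0 = -np.mod(-chi0 + 90.0, period) + 90.0
    return OrientationFit(float(chi0), float(dchi0), float(amp), True)


def reorientation_rate(
    fits: list[OrientationFit], tissue_strain_pct: np.ndarray
) -> ReorientationResult:
    """Slope of FWHM (and its percent change) against tissue strain.

    The reference for the percent change is the first converged (unloaded)
    frame.  Requires at least 3 converged frames.
    """
    eps = np.asarray(tissue_strain_pct, float)
    ok = np.array([f.converged for f in fits])
    if ok.sum() < 3:
        raise ValueError("need at least 3 converged orientation fits")
    fwhm = np.array([f.fwhm if f.converged else np.nan for f in fits])
    x = eps[ok]
    y = fwhm[ok]
    ref = y[0]
    pct = 100.0 * (y - ref) / ref
    xm, ym = x.mean(), pct.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("tissue strain is constant")
    rate = float(np.sum((x - xm) * (pct - ym)) / sxx)
    rate_deg = float(np.sum((x - xm) * (y - y.mean())) / sxx)
    resid = pct - (rate * (x - xm) + ym)
    syy = np.sum((pct - ym) ** 2)
    r2 = float(1.0 - np.sum(resid**2) / syy) if syy > 0 else 1.0
    return ReorientationResult(rate, rate_deg, pct, x, r2)
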