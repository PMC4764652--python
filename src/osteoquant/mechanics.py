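"""Macroscopic and fibril-level mechanics.

Stress is porosity-corrected (load over load-bearing area), tissue strain
comes from optical-marker video extensometry, and the elastic region is
detected with the >10% slope-reduction rule on the stress-strain curve.
Moduli and the fibril/tissue strain-partitioning ratio are ordinary
least-squares slopes over the elastic region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MechanicalRecord",
    "ElasticRegion",
    "MechanicalSummary",
    "tissue_strain",
    "corrected_stress",
    "elastic_region",
    "summarize_mechanics",
]


@dataclass
class MechanicalRecord:
    """Synchronized time series of one in situ tensile test.

    Attributes
    ----------
    time : ndarray
        Seconds from test start, one entry per acquired frame.
    load : ndarray
        Applied load in newtons.
    marker_positions : ndarray, shape (n, 2)
        Axial coordinates (mm) of the two optical extensometry markers.
    cross_section : tuple
        (width_mm, thickness_mm) of the gauge region.
    porosity : float
        Intracortical porosity used for the effective-area stress correction.
    """

    time: np.ndarray
    load: np.ndarray
    marker_positions: np.ndarray
    cross_section: tuple[float, float]
    porosity: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.marker_positions = np.asarray(self.marker_positions, dtype=float)
        if self.marker_positions.ndim != 2 or self.marker_positions.shape[1] != 2:
            raise ValueError("marker_positions must have shape (n, 2)")
        if not 0.0 <= self.porosity < 1.0:
            raise ValueError("porosity must be in [0, 1)")


@dataclass
class ElasticRegion:
    start: int
    end: int  # inclusive index of the last elastic frame
    baseline_slope: float
    triggered: bool  # False if the whole series stayed elastic

    def slice(self) -> slice:
        return slice(self.start, self.end + 1)


@dataclass
class MechanicalSummary:
    tissue_modulus: float  # MPa, d(sigma)/d(eps_T), eps as a fraction
    fibril_modulus: float  # MPa, d(sigma)/d(eps_F)
    strain_ratio: float  # d(eps_F)/d(eps_T), dimensionless
    yield_stress: float  # MPa
    yield_strain: float  # %
    max_fibril_strain: float  # %, over the full test
    elastic_region: ElasticRegion
    r_squared: dict = field(default_factory=dict)


def tissue_strain(record: MechanicalRecord) -> np.ndarray:
    """Extensometric tissue strain in percent from marker separation."""
    sep = record.marker_positions[:, 1] - record.marker_positions[:, 0]
    if np.any(sep <= 0):
        raise ValueError("marker separation must be positive")
    return 100.0 * (sep - sep[0]) / sep[0]


def corrected_stress(
    load: np.ndarray | float,
    cross_section: tuple[float, float],
    porosity: float = 0.0,
):
    """Porosity-corrected stress in MPa: load / (area * (1 - porosity)).

    ``cross_section`` is (width_mm, thickness_mm); load is in newtons, so
    N / mm^2 = MPa.  Dividing by the load-bearing area fraction (1 - porosity)
    is the standard effective-area correction.
    """
    w, t = cross_section
    area = w * t
    if area <= 0:
        raise ValueError("cross-section area must be positive")
    if not 0.0 <= porosity < 1.0:
        raise ValueError("porosity must be in [0, 1)")
    out = np.asarray(load, dtype=float) / (area * (1.0 - porosity))
    return float(out) if out.ndim == 0 else out


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope with free intercept; returns (slope, intercept, r2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate abscissa")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    syy = np.sum((y - ym) ** 2)
    r2 = 1.0 - np.sum(resid**2) / syy if syy > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def _window_slope(x, y, i, j):
    return _ols_slope(x[i : j + 1], y[i : j + 1])[0]


def _sse(x, y, i, j) -> float:
    s, b, _ = _ols_slope(x[i : j + 1], y[i : j + 1])
    r = y[i : j + 1] - (s * x[i : j + 1] + b)
    return float(np.sum(r**2))


def elastic_region(
    stress: np.ndarray,
    strain: np.ndarray,
    n0: int = 5,
    drop: float = 0.10,
) -> ElasticRegion:
    """Detect the elastic region with the >10% slope-reduction rule.

    The baseline slope is the least-squares slope over the first ``n0``
    frames.  A running window of ``n0`` frames is slid forward; the first
    window whose slope falls below ``(1 - drop) * baseline`` marks yielding.
    The exact end frame is then refined inside that window as the breakpoint
    of a two-segment least-squares fit (which recovers the kink of a bilinear
    curve exactly, rather than to within the window length).  If no window
    drops, the whole series is elastic.
    """
    stress = np.asarray(stress, float)
    strain = np.asarray(strain, float)
    n = stress.size
    if n != strain.size:
        raise ValueError("stress and strain must have equal length")
    if n < max(n0 + 1, 6):
        raise ValueError(f"need at least {max(n0 + 1, 6)} points")
    baseline = _window_slope(strain, stress, 0, n0 - 1)
    threshold = (1.0 - drop) * baseline
    trigger = None
    for k in range(n0 - 1, n):
        if _window_slope(strain, stress, k - n0 + 1, k) < threshold:
            trigger = k
            break
    if trigger is None:
        return ElasticRegion(0, n - 1, baseline, triggered=False)
    # A window can dip below threshold from measurement noise alone, and a
    # window straddling the kink localizes it only to +/- its own length.
    # Refine with a global two-segment least-squares breakpoint and keep the
    # yield call only if the post-breakpoint slope shows a sustained drop.
    best_j, best_sse = None, np.inf
    for j in range(2, n - 2):
        sse = _sse(strain, stress, 0, j) + _sse(strain, stress, j, n - 1)
        if sse < best_sse:
            best_j, best_sse = j, sse
    pre = _window_slope(strain, stress, 0, best_j)
    post = _window_slope(strain, stress, best_j, n - 1)
    if post < (1.0 - drop) * pre:
        return ElasticRegion(0, best_j, baseline, triggered=True)
    return ElasticRegion(0, n - 1, baseline, triggered=False)


def summarize_mechanics(
    stress: np.ndarray,
    tissue_strain_pct: np.ndarray,
    fibril_strain_pct: np.ndarray,
    region: ElasticRegion | None = None,
) -> MechanicalSummary:
    """Elastic-region moduli, strain partitioning and yield point.

    All slopes are free-intercept least squares over the elastic region,
    restricted to frames with a converged (finite) fibril strain for the
    fibril-level quantities.  ``max_fibril_strain`` is taken over the whole
    test.  Moduli are reported in MPa with strain as a fraction (percent
    strains are divided by 100 internally).
    """
    stress = np.asarray(stress, float)
    eps_t = np.asarray(tissue_strain_pct, float)
    eps_f = np.asarray(fibril_strain_pct, float)
    if region is None:
        region = elastic_region(stress, eps_t)
    sl = region.slice()
    ok = np.isfinite(eps_f[sl])
    if ok.sum() < 3:
        raise ValueError("need >= 3 converged fibril-strain frames in the elastic region")
    s_el, t_el, f_el = stress[sl][ok], eps_t[sl][ok], eps_f[sl][ok]
    e_t, _, r2_t = _ols_slope(t_el / 100.0, s_el)
    e_f, _, r2_f = _ols_slope(f_el / 100.0, s_el)
    ratio, _, r2_r = _ols_slope(t_el, f_el)
    return MechanicalSummary(
        tissue_modulus=e_t,
        fibril_modulus=e_f,
        strain_ratio=ratio,
        yield_stress=float(stress[region.end]),
        yield_strain=float(eps_t[region.end]),
        max_fibril_strain=float(np.nanmax(eps_f)),
        elastic_region=region,
        r_squared={"tissue": r2_t, "fibril": r2_f, "ratio": r2_r},
    )
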