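"""Detector geometry for small-angle X-ray diffraction frames.

Maps detector pixels to scattering wavevector magnitude ``q`` (nm^-1) and
azimuthal angle ``chi`` (degrees, measured counter-clockwise from the tensile
loading axis).  All public quantities use the unit conventions of the rest of
the package: wavelength is supplied in Angstrom and converted internally,
``q`` is always nm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["AcquisitionGeometry", "q_chi_map", "q_of_radius", "radius_of_q"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical acquisition geometry of a 2D scattering frame.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in Angstrom.
    sample_detector_distance : float
        Sample-to-detector distance in metres.
    pixel_size : float
        Square pixel edge length in metres.
    beam_center : tuple of float
        Beam center as (row, col) in pixel coordinates.
    loading_axis_angle : float
        Orientation of the tensile loading axis on the detector, degrees
        counter-clockwise from the +col direction. ``chi`` is measured from
        this axis.
    """

    wavelength: float
    sample_detector_distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    loading_axis_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.sample_detector_distance <= 0:
            raise ValueError("sample_detector_distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def wavelength_nm(self) -> float:
        return self.wavelength * 0.1

    def to_yaml(self, path) -> None:
        payload = {
            "wavelength_angstrom": float(self.wavelength),
            "sample_detector_distance_m": float(self.sample_detector_distance),
            "pixel_size_m": float(self.pixel_size),
            "beam_center_px": [float(self.beam_center[0]), float(self.beam_center[1])],
            "loading_axis_angle_deg": float(self.loading_axis_angle),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionGeometry":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            wavelength=d["wavelength_angstrom"],
            sample_detector_distance=d["sample_detector_distance_m"],
            pixel_size=d["pixel_size_m"],
            beam_center=tuple(d["beam_center_px"]),
            loading_axis_angle=d.get("loading_axis_angle_deg", 0.0),
        )


def q_of_radius(r_px: np.ndarray | float, geometry: AcquisitionGeometry):
    """q (nm^-1) of a pixel at radial distance ``r_px`` pixels from the beam.

    Uses the exact flat-detector relation
    ``q = (4 pi / lambda) * sin(arctan(r * p / L) / 2)``.
    """
    r_px = np.asarray(r_px, dtype=float)
    two_theta = np.arctan(
        r_px * geometry.pixel_size / geometry.sample_detector_distance
    )
    return (4.0 * np.pi / geometry.wavelength_nm) * np.sin(0.5 * two_theta)


def radius_of_q(q: np.ndarray | float, geometry: AcquisitionGeometry):
    """Inverse of :func:`q_of_radius`: radial pixel distance of a given q."""
    q = np.asarray(q, dtype=float)
    theta = np.arcsin(q * geometry.wavelength_nm / (4.0 * np.pi))
    return (
        np.tan(2.0 * theta)
        * geometry.sample_detector_distance
        / geometry.pixel_size
    )


def q_chi_map(
    geometry: AcquisitionGeometry, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (q, chi) grids for a detector of the given shape.

    ``chi`` is in degrees in [-180, 180), measured counter-clockwise from the
    loading axis (image convention: row index increases downward, so the
    geometric CCW sense is computed with the row axis negated).

    Returns
    -------
    q : ndarray
        Wavevector magnitude per pixel, nm^-1.
    chi : ndarray
        Azimuth per pixel, degrees in [-180, 180).
    """
    n_rows, n_cols = shape
    r0, c0 = geometry.beam_center
    if not (0 <= r0 < n_rows and 0 <= c0 < n_cols):
        warnings.warn("beam center lies outside the frame", stacklevel=2)
    rows = np.arange(n_rows, dtype=float)[:, None] - r0
    cols = np.arange(n_cols, dtype=float)[None, :] - c0
    r_px = np.hypot(rows, cols)
    q = q_of_radius(r_px, geometry)
    # CCW from loading axis; -rows because image row grows downward
    chi = np.degrees(np.arctan2(-rows, cols)) - geometry.loading_axis_angle
    chi = np.mod(chi + 180.0, 360.0) - 180.0
    return q, chi
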