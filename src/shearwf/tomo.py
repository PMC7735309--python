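"""Parallel-beam ray transform and the digitized canonical relation.

The ray transform of an image f on [-1, 1]^2 is

    R(f)(theta, p) = int f(p*omega(theta) + s*omega_perp(theta)) ds,

with omega(theta) = (cos theta, sin theta) and omega_perp = (-sin, cos),
sampled on an (angle, offset) grid: theta in [0, pi), p in [-sqrt(2),
sqrt(2)].  Line integrals are discretized by bilinear interpolation at a
step no larger than one pixel; the back-projection implemented here is the
exact adjoint of that discretization.

The canonical relation of the ray transform maps an image singularity at
x0 with normal direction theta0 to a sinogram singularity at (theta0,
p0 = x0.omega(theta0)) with covector direction s*(-q dtheta + dp), where
q = x0.omega_perp(theta0).  Its inverse recovers x0 = p0*omega + q*omega_perp
and the normal direction theta0.  Directions whose angle is not measured
(up to a snapping tolerance) are invisible: they produce no sinogram
element and cannot be recovered from data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, InvalidConfigError, ShapeError
from .phantoms import Phantom
from .wavefront import DigitalWavefrontSet

__all__ = [
    "SinogramGeometry",
    "Sinogram",
    "SinogramWFElement",
    "ray_transform",
    "back_projection",
    "canonical_forward",
    "canonical_inverse",
    "visible_wavefront",
    "sinogram_wavefront_truth",
    "sinogram_set_to_image_set",
    "embed_sinogram_periodic",
    "fold_extended_rows",
]


@dataclass(frozen=True)
class SinogramGeometry:
    """Parallel-beam sampling grid."""

    angles: np.ndarray  # radians, strictly increasing, in [0, pi)
    offsets: np.ndarray  # domain units, strictly increasing, covering [-sqrt2, sqrt2]
    image_size: int

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float)
        offsets = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "offsets", offsets)
        if angles.ndim != 1 or np.any(np.diff(angles) <= 0):
            raise InvalidConfigError("angles must be a strictly increasing 1-D grid")
        if np.any(angles < 0) or np.any(angles >= np.pi):
            raise InvalidConfigError("angles must lie in [0, pi)")
        if offsets.ndim != 1 or np.any(np.diff(offsets) <= 0):
            raise InvalidConfigError("offsets must be a strictly increasing 1-D grid")
        if offsets[0] > -1.0 or offsets[-1] < 1.0:
            raise InvalidConfigError("offsets must cover the unit square's shadow")

    @classmethod
    def parallel(cls, image_size: int, n_angles: int = 180, n_det: int | None = None,
                 angle_step_deg: float | None = None) -> "SinogramGeometry":
        """Uniform geometry; ``angle_step_deg`` (e.g. 6) overrides n_angles."""
        if angle_step_deg is not None:
            angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
        else:
            angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
        if n_det is None:
            n_det = image_size
        offsets = np.linspace(-math.sqrt(2), math.sqrt(2), n_det)
        return cls(angles=angles, offsets=offsets, image_size=image_size)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_det(self) -> int:
        return len(self.offsets)

    @property
    def angle_spacing(self) -> float:
        return float(np.min(np.diff(self.angles))) if self.n_angles > 1 else np.pi

    @property
    def offset_spacing(self) -> float:
        return float(self.offsets[1] - self.offsets[0])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"angles": self.angles.tolist(), "offsets": self.offsets.tolist(),
                       "image_size": self.image_size}, fh)

    @classmethod
    def from_json(cls, path) -> "SinogramGeometry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(angles=np.asarray(d["angles"]), offsets=np.asarray(d["offsets"]),
                   image_size=int(d["image_size"]))


@dataclass
class Sinogram:
    data: np.ndarray  # (n_angles, n_det)
    geometry: SinogramGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.geometry.n_angles, self.geometry.n_det):
            raise ShapeError("sinogram shape does not match geometry")
        if not np.all(np.isfinite(self.data)):
            raise InputError("sinogram contains non-finite values")


@dataclass(frozen=True)
class SinogramWFElement:
    """One sinogram wavefront element: grid indices plus the slope q.

    The covector direction is s*(-q dtheta + dp); the sign of s collapses
    under the mod-180-degree orientation convention.
    """

    angle_index: int
    offset_index: int
    slope: float


# ---------------------------------------------------------------------------
# Ray transform and its adjoint


def _sample_points(geometry: SinogramGeometry):
    M = geometry.image_size
    step = 2.0 / M  # one pixel width
    smax = math.sqrt(2)
    n_steps = int(np.ceil(2 * smax / step)) + 1
    s = np.linspace(-smax, smax, n_steps)
    theta = geometry.angles[:, None, None]
    p = geometry.offsets[None, :, None]
    x = p * np.cos(theta) - s[None, None, :] * np.sin(theta)
    y = p * np.sin(theta) + s[None, None, :] * np.cos(theta)
    ds = s[1] - s[0]
    col = (x + 1.0) * M / 2.0 - 0.5
    row = (y + 1.0) * M / 2.0 - 0.5
    return row, col, ds


def _bilinear_weights(row, col, M):
    r0 = np.floor(row).astype(int)
    c0 = np.floor(col).astype(int)
    fr, fc = row - r0, col - c0
    out = []
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        valid = (rr >= 0) & (rr < M) & (cc >= 0) & (cc < M)
        out.append((np.where(valid, rr, 0), np.where(valid, cc, 0), np.where(valid, w, 0.0)))
    return out


def ray_transform(image: np.ndarray, geometry: SinogramGeometry) -> Sinogram:
    """Parallel-beam line integrals of a square image (linear in the image)."""
    image = np.asarray(image, dtype=float)
    M = geometry.image_size
    if image.shape != (M, M):
        raise ShapeError(f"image shape {image.shape} does not match geometry size {M}")
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite pixels")
    row, col, ds = _sample_points(geometry)
    acc = np.zeros(row.shape)
    for rr, cc, w in _bilinear_weights(row, col, M):
        acc += w * image[rr, cc]
    return Sinogram(data=acc.sum(axis=-1) * ds, geometry=geometry)


def back_projection(sinogram: Sinogram, geometry: SinogramGeometry | None = None) -> np.ndarray:
    """Exact adjoint of :func:`ray_transform` (unfiltered back-projection)."""
    geometry = geometry or sinogram.geometry
    M = geometry.image_size
    row, col, ds = _sample_points(geometry)
    image = np.zeros((M, M))
    vals = sinogram.data[:, :, None] * ds
    for rr, cc, w in _bilinear_weights(row, col, M):
        np.add.at(image, (rr.ravel(), cc.ravel()), (w * vals).ravel())
    return image


# ---------------------------------------------------------------------------
# Canonical relation


def _bin_center_angle(bin_: int, n_orientations: int) -> float:
    """Center of an orientation bin, radians in [0, pi)."""
    return (bin_ + 0.5) * np.pi / n_orientations


def _angle_of_bin(theta: float, n_orientations: int) -> int:
    deg_width = np.pi / n_orientations
    return int(np.floor((theta % np.pi) / deg_width)) % n_orientations


def _snap_angle(theta: float, geometry: SinogramGeometry, tol: float | None):
    """Index of the measured angle matching theta mod pi, or None if invisible.

    Matching uses a half-open window [angle - tol, angle + tol) in the
    signed circular difference, with tol defaulting to half the angular
    spacing so that every direction is matched by a full angle grid.
    """
    if tol is None:
        tol = geometry.angle_spacing / 2.0
    diffs = (theta - geometry.angles + np.pi / 2) % np.pi - np.pi / 2
    eps = 1e-9  # guard the half-open window against float rounding
    admissible = (diffs >= -tol - eps) & (diffs < tol - eps)
    if not np.any(admissible):
        return None
    candidates = np.nonzero(admissible)[0]
    return int(candidates[np.argmin(np.abs(diffs[candidates]))])


def canonical_forward(
    pixel: tuple[int, int],
    bin_: int,
    geometry: SinogramGeometry,
    n_orientations: int,
    angle_tolerance: float | None = None,
) -> list[SinogramWFElement]:
    """Map an image wavefront element to sinogram wavefront elements.

    ``pixel`` is (row, col) in the M x M image; the normal direction is the
    bin's center angle.  Returns an empty list when the direction is not
    measured (invisible) or the offset falls outside the detector.
    """
    M = geometry.image_size
    theta0 = _bin_center_angle(bin_, n_orientations)
    idx = _snap_angle(theta0, geometry, angle_tolerance)
    if idx is None:
        return []
    theta = geometry.angles[idx]
    x0 = np.array([(2 * pixel[1] + 1) / M - 1.0, (2 * pixel[0] + 1) / M - 1.0])
    omega = np.array([math.cos(theta), math.sin(theta)])
    omega_perp = np.array([-math.sin(theta), math.cos(theta)])
    p0 = float(x0 @ omega)
    q = float(x0 @ omega_perp)
    j = int(round((p0 - geometry.offsets[0]) / geometry.offset_spacing))
    if not 0 <= j < geometry.n_det:
        return []
    return [SinogramWFElement(angle_index=idx, offset_index=j, slope=q)]


def canonical_inverse(
    element: SinogramWFElement,
    geometry: SinogramGeometry,
    n_orientations: int,
) -> tuple[tuple[int, int], int] | None:
    """Map a sinogram wavefront element back to an image pixel and bin.

    Returns ((row, col), orientation_bin), or None if the recovered point
    lies outside the image.
    """
    M = geometry.image_size
    theta = float(geometry.angles[element.angle_index])
    p0 = float(geometry.offsets[element.offset_index])
    omega = np.array([math.cos(theta), math.sin(theta)])
    omega_perp = np.array([-math.sin(theta), math.cos(theta)])
    x0 = p0 * omega + element.slope * omega_perp
    col = int(round((x0[0] + 1.0) * M / 2.0 - 0.5))
    row = int(round((x0[1] + 1.0) * M / 2.0 - 0.5))
    if not (0 <= row < M and 0 <= col < M):
        return None
    return (row, col), _angle_of_bin(theta, n_orientations)


def visible_wavefront(
    truth: DigitalWavefrontSet,
    geometry: SinogramGeometry,
    angle_tolerance: float | None = None,
) -> DigitalWavefrontSet:
    """Subset of elements whose normal direction is measured by the geometry."""
    out = DigitalWavefrontSet(truth.domain_shape, n_orientations=truth.n_orientations)
    for (r, c), bins in truth.elements.items():
        for b in bins:
            theta = _bin_center_angle(b, truth.n_orientations)
            if _snap_angle(theta, geometry, angle_tolerance) is not None:
                out.add(r, c, b)
    return out


# ---------------------------------------------------------------------------
# Sinogram-domain wavefront sets


def _sinogram_direction_bin(q: float, geometry: SinogramGeometry, n_orientations: int) -> int:
    """Orientation bin of the covector (-q dtheta + dp) on the index grid.

    The covector is expressed in (angle index, offset index) units: the
    dtheta component scales with the angular spacing and the dp component
    with the detector spacing (grid-aware aspect normalization).
    """
    c_row = -q * geometry.angle_spacing
    c_col = geometry.offset_spacing
    phi = math.atan2(c_row, c_col) % np.pi
    return int(np.floor(phi / (np.pi / n_orientations))) % n_orientations


def _sinogram_bin_slope(bin_: int, geometry: SinogramGeometry, n_orientations: int) -> float:
    """Inverse of the direction binning: representative slope q of a bin center."""
    phi = _bin_center_angle(bin_, n_orientations)
    return -math.tan(phi) * geometry.offset_spacing / geometry.angle_spacing


def sinogram_wavefront_truth(
    phantom: Phantom,
    geometry: SinogramGeometry,
    n_orientations: int | None = None,
    angle_tolerance: float | None = None,
) -> DigitalWavefrontSet:
    """Analytic image truth pushed through the canonical relation.

    The slope q of each mapped element is binned into sinogram-direction
    orientation bins; the result is a wavefront set on the (angle, offset)
    grid, directly comparable with classifier output on sinograms.
    """
    truth = phantom.truth
    n_out = n_orientations or truth.n_orientations
    out = DigitalWavefrontSet((geometry.n_angles, geometry.n_det), n_orientations=n_out)
    for (r, c), bins in truth.elements.items():
        for b in bins:
            for el in canonical_forward((r, c), b, geometry, truth.n_orientations,
                                        angle_tolerance):
                out.add(el.angle_index, el.offset_index,
                        _sinogram_direction_bin(el.slope, geometry, n_out))
    return out


def sinogram_set_to_image_set(
    wf_sino: DigitalWavefrontSet,
    geometry: SinogramGeometry,
    n_orientations_image: int,
) -> DigitalWavefrontSet:
    """Inverse canonical relation applied to a sinogram-domain wavefront set."""
    M = geometry.image_size
    out = DigitalWavefrontSet((M, M), n_orientations=n_orientations_image)
    for (i, j), bins in wf_sino.elements.items():
        for b in bins:
            q = _sinogram_bin_slope(b, geometry, wf_sino.n_orientations)
            el = SinogramWFElement(angle_index=i, offset_index=j, slope=q)
            mapped = canonical_inverse(el, geometry, n_orientations_image)
            if mapped is not None:
                (r, c), bin_img = mapped
                out.add(r, c, bin_img)
    return out


# ---------------------------------------------------------------------------
# Square embedding of sinograms (for the shearlet classifier)


def embed_sinogram_periodic(sinogram: Sinogram, size: int) -> np.ndarray:
    """Extend a sinogram to ``size`` angle rows using its pi-periodicity.

    g(theta + pi, p) = g(theta, -p), so rows repeat with the detector axis
    flipped; the resulting square image is continuous across the seam and
    compatible with the circular convolutions of the shearlet transform.
    """
    n = sinogram.geometry.n_angles
    if size < n:
        raise InvalidConfigError("embedding size must be >= number of angles")
    rows = []
    for r in range(size):
        base, flip = r % n, (r // n) % 2 == 1
        row = sinogram.data[base]
        rows.append(row[::-1] if flip else row)
    return np.asarray(rows)


def fold_extended_rows(
    wf_ext: DigitalWavefrontSet, geometry: SinogramGeometry
) -> DigitalWavefrontSet:
    """Fold predictions on a periodically extended sinogram back to the base grid.

    A detection in a flipped copy maps to (row mod n, n_det - 1 - col) with
    the orientation mirrored (the p-axis flip negates the dp component).
    """
    n, n_det = geometry.n_angles, geometry.n_det
    n_or = wf_ext.n_orientations
    out = DigitalWavefrontSet((n, n_det), n_orientations=n_or)
    for (r, c), bins in wf_ext.elements.items():
        base, flip = r % n, (r // n) % 2 == 1
        if c >= n_det:
            continue
        for b in bins:
            if flip:
                out.add(base, n_det - 1 - c, (n_or - 1 - b) % n_or)
            else:
                out.add(base, c, b)
    return out
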