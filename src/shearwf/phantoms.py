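"""Random-ellipse head phantoms with analytic digital wavefront truth.

Phantoms model the square [-1, 1]^2; a pixel (row, col) of an M x M image
has its center at x = (2*col + 1)/M - 1, y = (2*row + 1)/M - 1.  A phantom
consists of two large concentric "skull" ellipses (the outer one positive,
the inner one negative so they render as a ring) and a random number of
small interior ellipses with varying size, intensity, orientation and edge
regularity.  Intensities of overlapping ellipses add.

Because the geometry is analytic, the digital wavefront set is known
exactly: every pixel whose center lies within half a pixel of an ellipse
boundary carries the orientation bin of the outward normal there (mod
180 degrees), and the truth of a union of ellipses is the union of the
per-ellipse truths.  Smoothing an edge (edge_width > 0) changes the
rendered profile but not the wavefront truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import GenerationError, InvalidConfigError
from .wavefront import DigitalWavefrontSet

__all__ = [
    "Ellipse",
    "PhantomConfig",
    "Phantom",
    "rasterize",
    "analytic_wavefront_set",
    "sample_head_phantom",
]


@dataclass(frozen=True)
class Ellipse:
    """Ellipse in domain units with additive intensity and optional soft edge."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float  # radians, in [0, pi)
    intensity: float
    edge_width: float = 0.0  # 0 = sharp jump; >0 = smooth ramp width (domain units)

    def __post_init__(self):
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise InvalidConfigError("semi-axes must be positive")
        if self.edge_width < 0:
            raise InvalidConfigError("edge_width must be >= 0")

    def boundary_points(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """n boundary points and outward unit normals, both as (n, 2) (x, y)."""
        u = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        cos_p, sin_p = math.cos(self.rotation), math.sin(self.rotation)
        ex, ey = a * np.cos(u), b * np.sin(u)
        pts = np.stack(
            [self.center[0] + cos_p * ex - sin_p * ey,
             self.center[1] + sin_p * ex + cos_p * ey], axis=1)
        nx, ny = b * np.cos(u), a * np.sin(u)  # unnormalized outward normal
        normals = np.stack([cos_p * nx - sin_p * ny, sin_p * nx + cos_p * ny], axis=1)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return pts, normals


@dataclass(frozen=True)
class PhantomConfig:
    """Sampling distribution of the head-phantom generator."""

    image_size: int = 256
    n_small: tuple[int, int] = (5, 12)  # inclusive range of interior ellipses
    intensity_range: tuple[float, float] = (0.2, 1.0)  # |intensity|; sign is random
    semi_axis_range: tuple[float, float] = (0.05, 0.25)
    edge_width_range: tuple[float, float] = (0.005, 0.03)
    sharp_fraction: float = 0.5  # probability of a sharp (edge_width = 0) edge
    skull_outer: tuple[float, float] = (0.72, 0.9)
    skull_inner: tuple[float, float] = (0.62, 0.78)
    skull_intensities: tuple[float, float] = (1.0, -0.6)
    skull_jitter: float = 0.04  # relative jitter on skull axes and rotation
    supersample: int = 4
    n_orientations: int = 180
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 2 != 0 or self.image_size < 32:
            raise InvalidConfigError("image_size must be even and >= 32")
        if self.n_small[0] < 0 or self.n_small[1] < self.n_small[0]:
            raise InvalidConfigError("n_small range must be non-empty and non-negative")


@dataclass
class Phantom:
    """Rasterized image together with its ellipse list and wavefront truth."""

    image: np.ndarray
    ellipses: list[Ellipse]
    truth: DigitalWavefrontSet


def _pixel_grid(M: int, supersample: int) -> tuple[np.ndarray, np.ndarray]:
    n = M * supersample
    coords = (2.0 * np.arange(n) + 1.0) / n - 1.0
    return coords[None, :], coords[:, None]  # x varies over cols, y over rows


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x ** 4 * (35.0 - 84.0 * x + 70.0 * x ** 2 - 20.0 * x ** 3)


def rasterize(ellipses, M: int, supersample: int = 4) -> np.ndarray:
    """Additive anti-aliased rendering of a list of ellipses.

    Sharp ellipses contribute intensity times the (supersampled) fractional
    pixel coverage; soft ellipses replace the indicator by a polynomial
    ramp of width ``edge_width`` across the boundary, measured along the
    local normal to first order.
    """
    if M % 2 != 0:
        raise InvalidConfigError("M must be even")
    if supersample < 1:
        raise InvalidConfigError("supersample must be >= 1")
    x, y = _pixel_grid(M, supersample)
    n = M * supersample
    img = np.zeros((n, n))
    for e in ellipses:
        a, b = e.semi_axes
        cos_p, sin_p = math.cos(e.rotation), math.sin(e.rotation)
        dx, dy = x - e.center[0], y - e.center[1]
        u1 = (cos_p * dx + sin_p * dy) / a
        u2 = (-sin_p * dx + cos_p * dy) / b
        r2 = u1 ** 2 + u2 ** 2
        if e.edge_width == 0.0:
            img += e.intensity * (r2 <= 1.0)
        else:
            r = np.sqrt(r2)
            grad = np.sqrt((u1 / a) ** 2 + (u2 / b) ** 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                dist = np.where(grad > 0, (1.0 - r) * r / grad, 1.0)
            img += e.intensity * _smoothstep(dist / e.edge_width + 0.5)
    if supersample > 1:
        img = img.reshape(M, supersample, M, supersample).mean(axis=(1, 3))
    return img


def analytic_wavefront_set(ellipses, M: int, n_orientations: int = 180) -> DigitalWavefrontSet:
    """Exact digital wavefront set of a union of ellipses.

    The truth is the union of the co-normal bundles of the individual
    boundaries; cancellation along exactly coincident boundaries is
    ignored.  Ellipses with zero intensity contribute nothing.
    """
    if n_orientations < 2:
        raise InvalidConfigError("n_orientations must be >= 2")
    wf = DigitalWavefrontSet((M, M), n_orientations=n_orientations)
    half_pixel = 1.0 / M  # half of the pixel width 2/M
    bin_width = 180.0 / n_orientations
    centers = (2.0 * np.arange(M) + 1.0) / M - 1.0
    for e in ellipses:
        if e.intensity == 0.0:
            continue
        # sample the boundary densely enough that arc spacing << pixel size
        perimeter_px = np.pi * (3 * sum(e.semi_axes)) * M / 2.0  # generous bound
        n_samples = max(64, int(perimeter_px / 0.2))
        pts, normals = e.boundary_points(n_samples)
        tree = cKDTree(pts)
        # candidate pixels: a band around the curve's bounding box
        lo = pts.min(axis=0) - 3.0 / M
        hi = pts.max(axis=0) + 3.0 / M
        cols = np.nonzero((centers >= lo[0]) & (centers <= hi[0]))[0]
        rows = np.nonzero((centers >= lo[1]) & (centers <= hi[1]))[0]
        if len(cols) == 0 or len(rows) == 0:
            continue
        cc, rr = np.meshgrid(cols, rows)
        query = np.stack([centers[cc.ravel()], centers[rr.ravel()]], axis=1)
        dist, idx = tree.query(query)
        close = dist <= half_pixel
        angles = np.degrees(np.arctan2(normals[idx, 1], normals[idx, 0])) % 180.0
        bins = np.floor(angles / bin_width).astype(int) % n_orientations
        for r, c, b in zip(rr.ravel()[close], cc.ravel()[close], bins[close]):
            wf.add(r, c, b)
    return wf


def _max_extent(e: Ellipse) -> float:
    return max(e.semi_axes)


def _inside_ellipse(point, host: Ellipse, margin: float) -> bool:
    """Conservative check that a disk of radius margin around point fits in host."""
    cos_p, sin_p = math.cos(host.rotation), math.sin(host.rotation)
    dx, dy = point[0] - host.center[0], point[1] - host.center[1]
    u1 = cos_p * dx + sin_p * dy
    u2 = -sin_p * dx + cos_p * dy
    a_eff = max(host.semi_axes[0] - margin, 1e-6)
    b_eff = max(host.semi_axes[1] - margin, 1e-6)
    return (u1 / a_eff) ** 2 + (u2 / b_eff) ** 2 <= 1.0


def sample_head_phantom(config: PhantomConfig, rng_seed: int | None = None) -> Phantom:
    """Draw one head-like phantom; identical seeds give identical phantoms.

    The two skull ellipses are always present; every interior ellipse is
    placed fully inside the inner skull (bounded rejection sampling).
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    jit = config.skull_jitter
    rot = rng.uniform(-jit, jit) * np.pi
    outer = Ellipse(
        center=(0.0, 0.0),
        semi_axes=tuple(s * rng.uniform(1 - jit, 1 + jit) for s in config.skull_outer),
        rotation=rot % np.pi,
        intensity=config.skull_intensities[0],
    )
    inner = Ellipse(
        center=(0.0, 0.0),
        semi_axes=tuple(s * rng.uniform(1 - jit, 1 + jit) for s in config.skull_inner),
        rotation=rot % np.pi,
        intensity=config.skull_intensities[1],
    )
    ellipses = [outer, inner]
    n_small = int(rng.integers(config.n_small[0], config.n_small[1] + 1))
    for _ in range(n_small):
        for _attempt in range(200):
            a = rng.uniform(*config.semi_axis_range)
            b = rng.uniform(*config.semi_axis_range)
            phi = rng.uniform(0.0, np.pi)
            cand_center = tuple(rng.uniform(-0.6, 0.6, size=2))
            if _inside_ellipse(cand_center, inner, margin=max(a, b) + 0.02):
                break
        else:
            raise GenerationError("could not place an interior ellipse inside the skull")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        intensity = sign * rng.uniform(*config.intensity_range)
        if rng.random() < config.sharp_fraction:
            width = 0.0
        else:
            width = rng.uniform(*config.edge_width_range)
        ellipses.append(
            Ellipse(center=cand_center, semi_axes=(a, b), rotation=phi,
                    intensity=intensity, edge_width=width)
        )
    image = rasterize(ellipses, config.image_size, config.supersample)
    truth = analytic_wavefront_set(ellipses, config.image_size, config.n_orientations)
    return Phantom(image=image, ellipses=ellipses, truth=truth)


def save_ellipses_json(ellipses, path) -> None:
    payload = [
        {
            "center": list(e.center), "semi_axes": list(e.semi_axes),
            "rotation": e.rotation, "intensity": e.intensity, "edge_width": e.edge_width,
        }
        for e in ellipses
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_ellipses_json(path) -> list[Ellipse]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Ellipse(center=tuple(d["center"]), semi_axes=tuple(d["semi_axes"]),
                rotation=d["rotation"], intensity=d["intensity"],
                edge_width=d["edge_width"])
        for d in payload
    ]
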