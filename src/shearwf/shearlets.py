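"""Cone-adapted digital shearlet filter bank.

The system is built directly in the frequency domain from a Meyer-type
band-limited generator: a 1-D wavelet window satisfying the discrete
Calderon condition controls the radial (scale) localization along the cone
axis, and a 1-D bump window controls the angular (shear) localization in
the slope variable xi2/xi1.  Shearing acts as a frequency-variable
resampling of the slope, so the digital grid is left invariant.  The two
boundary shearlets |k| = k_j of each scale are glued across the seam
|xi1| = |xi2| and shared between the horizontal and vertical cones, which
is what makes the slice count

    L = 2 * sum_j (K_j - 1) + 1

(one low-pass slice, K_j = 2 k_j + 1 shears per scale and cone).  After
construction the stack is Parseval-normalized: the pointwise sum of
squared filter moduli is identically one, so the transform is an isometry
and the adjoint reproduces the input exactly.

Convolutions are circular (periodic boundary), matching the FFT
implementation.  Image sizes must be even; the unpaired Nyquist
frequencies are symmetrized so that every filter has a real, even impulse
response.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InputError, ShapeError

__all__ = [
    "ShearletConfig",
    "ShearletSystem",
    "CoefficientVolume",
    "SliceIndex",
    "default_shear_counts",
    "build_shearlet_system",
    "shearlet_transform",
    "adjoint_transform",
    "impulse_response",
    "save_system",
    "load_system",
]


def default_shear_counts(n_scales: int) -> list[int]:
    """Per-scale shear counts K_j = 2^(ceil(j/2)+1) + 1, j = 1..J.

    For J = 4 this gives (5, 5, 9, 9) and hence a 49-slice system.
    """
    return [2 ** (math.ceil(j / 2) + 1) + 1 for j in range(1, n_scales + 1)]


@dataclass(frozen=True)
class ShearletConfig:
    """Parameters of a digital shearlet system on an M x M pixel grid."""

    image_size: int
    n_scales: int = 4
    shear_counts: tuple[int, ...] | None = None
    generator: str = "classical_meyer"

    def __post_init__(self):
        M, J = self.image_size, self.n_scales
        if M < 32 or M % 2 != 0:
            raise InvalidConfigError(f"image_size must be even and >= 32, got {M}")
        if J < 1:
            raise InvalidConfigError(f"n_scales must be >= 1, got {J}")
        counts = self.shear_counts
        if counts is None:
            counts = tuple(default_shear_counts(J))
            object.__setattr__(self, "shear_counts", counts)
        else:
            counts = tuple(int(k) for k in counts)
            object.__setattr__(self, "shear_counts", counts)
        if len(counts) != J:
            raise InvalidConfigError("shear_counts must have one entry per scale")
        for K in counts:
            if K < 3 or K % 2 == 0:
                raise InvalidConfigError(f"every shear count must be odd and >= 3, got {K}")
        if self.generator != "classical_meyer":
            raise InvalidConfigError(f"unknown generator {self.generator!r}")

    @property
    def n_slices(self) -> int:
        return 2 * sum(K - 1 for K in self.shear_counts) + 1

    def to_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "n_scales": self.n_scales,
            "shear_counts": list(self.shear_counts),
            "generator": self.generator,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShearletConfig":
        return cls(
            image_size=int(d["image_size"]),
            n_scales=int(d["n_scales"]),
            shear_counts=tuple(d["shear_counts"]),
            generator=d.get("generator", "classical_meyer"),
        )


@dataclass(frozen=True)
class SliceIndex:
    """Index record of one filter slice.

    ``cone`` is +1 (horizontal, |xi2| <= |xi1|), -1 (vertical) or 0 for the
    low-pass slice.  Boundary shearlets |shear| = k_j are shared between
    both cones and carry the cone label of the horizontal cone by
    convention, with ``boundary`` set.
    """

    scale: int  # 1-based, 1 = coarsest
    shear: int
    cone: int
    boundary: bool = False


@dataclass
class ShearletSystem:
    """Frequency-domain filter stack with its (scale, shear, cone) table."""

    filters: np.ndarray  # (L, M, M), real, FFT layout (DC at [0, 0])
    index_table: list[SliceIndex]
    config: ShearletConfig

    @property
    def n_slices(self) -> int:
        return self.filters.shape[0]

    @property
    def image_size(self) -> int:
        return self.config.image_size

    @property
    def system_id(self) -> str:
        return json.dumps(self.config.to_dict(), sort_keys=True)


@dataclass
class CoefficientVolume:
    """Stack of shearlet coefficient images, one M x M slice per filter."""

    data: np.ndarray  # (L, M, M) real
    system_id: str


# ---------------------------------------------------------------------------
# Meyer-type windows


def _meyer_aux(x: np.ndarray) -> np.ndarray:
    """Polynomial Meyer auxiliary function: v(0)=0, v(1)=1, v(x)+v(1-x)=1."""
    x = np.clip(x, 0.0, 1.0)
    return x ** 4 * (35.0 - 84.0 * x + 70.0 * x ** 2 - 20.0 * x ** 3)


def _band_window(u: np.ndarray, final_scale: bool) -> np.ndarray:
    """Radial (cone-axis) window B with supp B in [1/4, 1].

    B^2 rises on [1/4, 1/2] and falls on [1/2, 1] so that
    B(u)^2 + B(u/2)^2 = 1 on the overlap (discrete Calderon pairing).  For
    the finest scale the fall is omitted (flat up to Nyquist) so the dyadic
    partition terminates cleanly at the grid's band limit.
    """
    u = np.abs(u)
    out = np.zeros_like(u)
    rise = (u >= 0.25) & (u < 0.5)
    out[rise] = np.sin(0.5 * np.pi * _meyer_aux(4.0 * u[rise] - 1.0))
    if final_scale:
        out[u >= 0.5] = 1.0
    else:
        fall = (u >= 0.5) & (u <= 1.0)
        out[fall] = np.cos(0.5 * np.pi * _meyer_aux(2.0 * u[fall] - 1.0))
    return out


def _bump_window(x: np.ndarray) -> np.ndarray:
    """Angular bump W with supp W = [-1, 1] and sum_k W(x - k)^2 = 1."""
    out = np.zeros_like(x)
    neg = (x >= -1.0) & (x < 0.0)
    pos = (x >= 0.0) & (x <= 1.0)
    out[neg] = np.sqrt(_meyer_aux(1.0 + x[neg]))
    out[pos] = np.sqrt(_meyer_aux(1.0 - x[pos]))
    return out


# ---------------------------------------------------------------------------
# System construction


def _nyquist_symmetrize(F: np.ndarray) -> np.ndarray:
    """Make the unpaired Nyquist row/column even so impulse responses are real.

    Replaces values on the xi = -M/2 row (column) by the root-mean-square of
    the value and its mirror in the other coordinate; this preserves the
    pointwise sum of squares across the stack.
    """
    M = F.shape[-1]
    h = M // 2
    neg = (-np.arange(M)) % M
    G = F.copy()
    G[h, :] = np.sqrt(0.5 * (F[h, :] ** 2 + F[h, neg] ** 2))
    G[:, h] = np.sqrt(0.5 * (G[:, h] ** 2 + G[neg, h] ** 2))
    return G


def build_shearlet_system(config: ShearletConfig) -> ShearletSystem:
    """Construct the cone-adapted digital shearlet filter bank.

    Deterministic for a fixed config.  The returned stack tiles the digital
    frequency plane into a horizontal and a vertical cone of sheared band
    filters plus one low-pass slice, and is Parseval-normalized so the sum
    of squared moduli is one at every frequency.
    """
    M, J = config.image_size, config.n_scales
    xi = np.fft.fftfreq(M, d=1.0 / M)  # integer frequencies, FFT layout
    xi1 = xi[:, None] / (M / 2.0)  # cone variable, rows = xi1
    xi2 = xi[None, :] / (M / 2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_h = np.where(xi1 != 0.0, xi2 / xi1, np.inf)  # slope in horizontal cone
        t_v = np.where(xi2 != 0.0, xi1 / xi2, np.inf)
    horiz = np.abs(xi2) <= np.abs(xi1)

    filters: list[np.ndarray] = []
    table: list[SliceIndex] = []
    for j in range(1, J + 1):
        K = config.shear_counts[j - 1]
        k_j = (K - 1) // 2
        scale_factor = 2.0 ** (J - j)
        band_h = _band_window(scale_factor * xi1, final_scale=(j == J))
        band_v = _band_window(scale_factor * xi2, final_scale=(j == J))
        for k in range(-k_j, k_j + 1):
            if abs(k) < k_j:
                # interior shear: bump support lies inside one cone
                for cone, band, t in ((1, band_h, t_h), (-1, band_v, t_v)):
                    F = band * _bump_window(np.where(np.isfinite(t), k_j * t - k, 2.0))
                    filters.append(_nyquist_symmetrize(F))
                    table.append(SliceIndex(scale=j, shear=k, cone=cone))
            else:
                # boundary shear: glued across the seam, shared by both cones
                Fh = band_h * _bump_window(np.where(np.isfinite(t_h), k_j * t_h - k, 2.0))
                Fv = band_v * _bump_window(np.where(np.isfinite(t_v), k_j * t_v - k, 2.0))
                F = np.where(horiz, Fh, Fv)
                filters.append(_nyquist_symmetrize(F))
                table.append(SliceIndex(scale=j, shear=k, cone=1, boundary=True))

    stack = np.asarray(filters)
    residual = 1.0 - np.sum(stack ** 2, axis=0)
    lowpass = np.sqrt(np.clip(residual, 0.0, None))
    stack = np.concatenate([stack, lowpass[None]], axis=0)
    table.append(SliceIndex(scale=0, shear=0, cone=0))

    # Parseval normalization: exact partition of unity over frequency
    total = np.sqrt(np.sum(stack ** 2, axis=0))
    stack = stack / total[None]

    expected = 2 * sum(K - 1 for K in config.shear_counts) + 1
    assert stack.shape[0] == expected, (stack.shape[0], expected)
    return ShearletSystem(filters=stack, index_table=table, config=config)


# ---------------------------------------------------------------------------
# Transforms


def _check_image(image: np.ndarray, system: ShearletSystem) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    M = system.image_size
    if image.shape != (M, M):
        raise ShapeError(f"image shape {image.shape} does not match system size {M}")
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite pixels")
    return image


def shearlet_transform(image: np.ndarray, system: ShearletSystem) -> CoefficientVolume:
    """Digital shearlet transform: circular cross-correlation with each filter."""
    image = _check_image(image, system)
    spectrum = np.fft.fft2(image)
    coeffs = np.fft.ifft2(spectrum[None] * np.conj(system.filters), axes=(-2, -1))
    return CoefficientVolume(data=coeffs.real, system_id=system.system_id)


def adjoint_transform(volume: CoefficientVolume, system: ShearletSystem) -> np.ndarray:
    """Adjoint of the transform; reconstructs the image for a Parseval system."""
    data = np.asarray(volume.data, dtype=float)
    M = system.image_size
    if data.shape != (system.n_slices, M, M):
        raise ShapeError(
            f"volume shape {data.shape} does not match system ({system.n_slices}, {M}, {M})"
        )
    spectra = np.fft.fft2(data, axes=(-2, -1))
    image = np.fft.ifft2(np.sum(spectra * system.filters, axis=0))
    return image.real


def impulse_response(system: ShearletSystem, slice_index: int) -> np.ndarray:
    """Centered spatial impulse response of one filter slice."""
    return np.fft.fftshift(np.fft.ifft2(system.filters[slice_index]).real)


# ---------------------------------------------------------------------------
# Serialization (single-file .npz container)


def save_system(system: ShearletSystem, path) -> None:
    meta = {
        "config": system.config.to_dict(),
        "index_table": [
            {"scale": s.scale, "shear": s.shear, "cone": s.cone, "boundary": s.boundary}
            for s in system.index_table
        ],
    }
    np.savez_compressed(path, filters=system.filters, meta=np.bytes_(json.dumps(meta)))


def load_system(path) -> ShearletSystem:
    with np.load(path) as npz:
        filters = npz["filters"]
        meta = json.loads(bytes(npz["meta"]).decode())
    config = ShearletConfig.from_dict(meta["config"])
    table = [
        SliceIndex(scale=d["scale"], shear=d["shear"], cone=d["cone"], boundary=d["boundary"])
        for d in meta["index_table"]
    ]
    return ShearletSystem(filters=filters, index_table=table, config=config)
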