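"""Photometric-stereo recovery of surface gradients and albedo.

A Lambertian surface imaged under a known directional light obeys

    I(x, y) = rho * <N, L>,        N = [-p, -q, 1] / sqrt(1 + p^2 + q^2)

where ``rho`` is the per-pixel albedo, ``p = -dz/dx`` and ``q = -dz/dy``
are the surface gradients of the height field ``z = f(x, y)`` (x = column
index increasing rightward, y = row index increasing downward, z toward the
camera), and ``L`` is the unit light vector.  With at least three lights
whose azimuths are not collinear, the scaled normal ``rho * N`` — and hence
``rho``, ``p`` and ``q`` — is determined per pixel by linear least squares.

Surface gradients are the working feature of the extraction pipeline; the
integrated depth map is provided for visualisation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "LightRig",
    "PSStack",
    "GradientField",
    "DepthMap",
    "subtract_ambient",
    "segment_foreground",
    "solve_normals",
    "integrate_depth",
]


def _as_float(a) -> np.ndarray:
    return np.asarray(a, dtype=np.float64)


@dataclass(frozen=True)
class LightRig:
    """A set of N >= 3 unit illumination vectors ``[a_x, a_y, a_z]``.

    The z-component of every vector must be positive (lights in front of the
    surface) and the azimuths must not all be collinear, otherwise the
    photometric-stereo design matrix is singular.
    """

    vectors: np.ndarray

    def __post_init__(self):
        v = _as_float(self.vectors)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("light vectors must be an (N, 3) array")
        if v.shape[0] < 3:
            raise ValueError(f"need at least 3 lights, got {v.shape[0]}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("light vectors must have unit norm (tol 1e-9)")
        if np.any(v[:, 2] <= 0):
            raise ValueError("all light z-components must be positive")
        if np.linalg.matrix_rank(v, tol=1e-9) < 3:
            raise ValueError(
                "light azimuths are collinear: design matrix is singular"
            )
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @classmethod
    def from_angles(cls, azimuths_deg: Sequence[float],
                    elevations_deg: Sequence[float]) -> "LightRig":
        """Build unit vectors from azimuth (from +x, CCW) and elevation."""
        az = np.deg2rad(_as_float(azimuths_deg))
        el = np.deg2rad(_as_float(elevations_deg))
        if az.shape != el.shape:
            raise ValueError("azimuths and elevations must have equal length")
        v = np.stack(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)],
            axis=1,
        )
        return cls(v)

    @classmethod
    def default_four(cls) -> "LightRig":
        """Four symmetric oblique lights at 45 deg elevation.

        Azimuths 45/135/225/315 deg, mimicking illuminators mounted on the
        corners of a square rig above the imaging plane.
        """
        return cls.from_angles([45.0, 135.0, 225.0, 315.0], [45.0] * 4)


@dataclass
class PSStack:
    """One photometric-stereo capture: N lit frames plus one ambient frame.

    ``frames`` has shape (N, H, W) with values in [0, 1]; ``ambient`` has
    shape (H, W).  ``lights`` carries the matching unit light vectors.
    """

    frames: np.ndarray
    ambient: np.ndarray | None
    lights: LightRig
    foreground: np.ndarray | None = None

    def __post_init__(self):
        self.frames = _as_float(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be an (N, H, W) array")
        if self.frames.shape[0] != len(self.lights):
            raise ValueError(
                f"{self.frames.shape[0]} frames but "
                f"{len(self.lights)} light vectors"
            )
        if self.ambient is not None:
            self.ambient = _as_float(self.ambient)
            if self.ambient.shape != self.frames.shape[1:]:
                raise ValueError(
                    "ambient frame shape differs from lit frames")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame values must lie in [0, 1]")

    @property
    def n_lights(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class GradientField:
    """Per-pixel surface gradients (p, q) and albedo with a validity mask.

    ``valid`` flags pixels where the least-squares solve is well
    conditioned; p and q are finite and albedo non-negative there.
    """

    p: np.ndarray
    q: np.ndarray
    albedo: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape

    def normals(self) -> np.ndarray:
        """Unit normals as an (H, W, 3) array, [-p, -q, 1] normalised."""
        n = np.stack([-self.p, -self.q, np.ones_like(self.p)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


@dataclass
class DepthMap:
    """Integrated height field, defined up to an additive constant."""

    z: np.ndarray


def subtract_ambient(stack: PSStack) -> PSStack:
    """Subtract the ambient frame from every lit frame, clamping at zero.

    Returns a new stack whose ambient frame is zeroed; pixels where the
    ambient exceeds the lit frame are clamped to 0 rather than going
    negative.
    """
    if stack.ambient is None:
        raise ValueError("stack has no ambient frame")
    if stack.ambient.shape != stack.frames.shape[1:]:
        raise ValueError("ambient frame shape differs from lit frames")
    corrected = np.clip(stack.frames - stack.ambient[None, :, :], 0.0, None)
    return PSStack(
        frames=corrected,
        ambient=np.zeros_like(stack.ambient),
        lights=stack.lights,
        foreground=stack.foreground,
    )


def segment_foreground(image: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Segment the leaf from a single greyscale image.

    Applies Otsu's global threshold and keeps the largest connected
    component as the leaf.  Raises on a constant image, for which no
    threshold exists.
    """
    if method != "otsu":
        raise ValueError(f"unknown segmentation method: {method!r}")
    img = _as_float(image)
    if np.ptp(img) == 0:
        raise ValueError("constant image: no Otsu threshold exists")
    t = threshold_otsu(img)
    mask = img > t
    if not mask.any():
        return mask
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def solve_normals(
    stack: PSStack,
    albedo_floor: float = 1e-4,
    nz_floor: float = 0.05,
) -> GradientField:
    """Recover per-pixel gradients (p, q) and albedo by least squares.

    Solves ``I_i = <m, L_i>`` for the scaled normal ``m = rho * N`` at every
    pixel over the N >= 3 lights, then ``rho = |m|`` and
    ``(p, q) = (-m_x / m_z, -m_y / m_z)`` from the ``N = [-p, -q, 1]``
    convention.  Pixels with albedo below ``albedo_floor`` or a normal
    z-component below ``nz_floor`` are flagged invalid (their p, q are
    zeroed).

    The result is invariant to the ordering of (frame, light) pairs and
    scales linearly in albedo with any global gain applied to the frames.
    """
    L = stack.lights.vectors  # validated: N >= 3, rank 3
    n, h, w = stack.frames.shape
    I = stack.frames.reshape(n, -1)  # noqa: E741
    # pinv(L) @ I solves all pixels at once; L has full column rank.
    m = (np.linalg.pinv(L) @ I).T  # (H*W, 3)
    albedo = np.linalg.norm(m, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nz = np.where(albedo > 0, m[:, 2] / albedo, 0.0)
        p = np.where(m[:, 2] != 0, -m[:, 0] / m[:, 2], 0.0)
        q = np.where(m[:, 2] != 0, -m[:, 1] / m[:, 2], 0.0)
    valid = (albedo >= albedo_floor) & (np.abs(nz) >= nz_floor)
    valid &= np.isfinite(p) & np.isfinite(q)
    p = np.where(valid, p, 0.0)
    q = np.where(valid, q, 0.0)
    return GradientField(
        p=p.reshape(h, w),
        q=q.reshape(h, w),
        albedo=albedo.reshape(h, w),
        valid=valid.reshape(h, w),
    )


def integrate_depth(field: GradientField) -> DepthMap:
    """Integrate gradients into a height field (visualisation only).

    Fourier-domain least-squares integrability projection
    (Frankot–Chellappa): the returned surface is the globally integrable
    field whose gradients best match ``(dz/dx, dz/dy) = (-p, -q)`` in the
    least-squares sense under periodic boundary conditions.  Output is
    mean-free.  Non-integrable input is projected rather than rejected.
    """
    zx = -field.p
    zy = -field.q
    h, w = zx.shape
    wx = 2.0 * np.pi * np.fft.fftfreq(w)[None, :]
    wy = 2.0 * np.pi * np.fft.fftfreq(h)[:, None]
    Zx = np.fft.fft2(zx)
    Zy = np.fft.fft2(zy)
    denom = wx**2 + wy**2
    denom[0, 0] = 1.0  # DC handled separately
    Z = (-1j * wx * Zx - 1j * wy * Zy) / denom
    Z[0, 0] = 0.0  # mean-free
    z = np.real(np.fft.ifft2(Z))
    return DepthMap(z=z - z.mean())
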