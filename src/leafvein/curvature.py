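"""Local shape measures: principal curvatures, shape index, curvedness.

The principal curvatures k1 >= k2 of the surface ``z = f(x, y)`` are the
eigenvalues of the shape operator built from the first and second
fundamental forms of the Monge patch.  First derivatives come from the
photometric-stereo gradients (``dz/dx = -p``, ``dz/dy = -q``); second
derivatives are Gaussian-derivative filters applied to them.  The sign
convention is that curvature is positive where the surface is convex toward
the camera, so a raised vein (ridge) carries positive curvature across its
crest and a recessed vein (rut) negative.

From (k1, k2) two decoupled local descriptors follow:

* the shape index ``s = (2/pi) * arctan((k1 + k2) / (k1 - k2))``, mapping
  every non-planar patch into [-1, +1] independent of its size — a
  canonical ridge sits at +0.5, a rut at -0.5, umbilic patches at the
  endpoints +-1;
* the curvedness ``c = sqrt((k1^2 + k2^2) / 2)``, a non-negative magnitude
  that is zero only on planar patches and scales linearly with surface
  height in the small-slope regime.

Shape-index values are banded into nine categories (spherical cup, trough,
rut, saddle rut, saddle, saddle ridge, ridge, dome, spherical cap), and a
Butterworth-style weight function turns the shape-index map into a smooth
per-pixel weight that peaks on the band matching a chosen vein polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .photometric import GradientField

__all__ = [
    "SHAPE_CATEGORIES",
    "CurvatureMaps",
    "ShapeWeightMap",
    "principal_curvatures",
    "shape_index",
    "classify_shape",
    "curvedness",
    "shape_weight_map",
]

#: Nine shape categories over s in [-1, 1]: end caps of width 0.125, seven
#: interior bands of width 0.25, each half-open on the right (the last band
#: includes +1).  The rut band is [-0.625, -0.375).
SHAPE_CATEGORIES = (
    "spherical cup",
    "trough",
    "rut",
    "saddle rut",
    "saddle",
    "saddle ridge",
    "ridge",
    "dome",
    "spherical cap",
)

_BAND_EDGES = np.array(
    [-0.875, -0.625, -0.375, -0.125, 0.125, 0.375, 0.625, 0.875]
)

PLANAR_LABEL = -1


@dataclass
class CurvatureMaps:
    """Per-pixel principal curvatures and derived shape measures.

    ``planar`` flags pixels where k1 and k2 are both (numerically) zero;
    the shape index is undefined there and set to NaN.
    """

    k1: np.ndarray
    k2: np.ndarray
    s: np.ndarray
    c: np.ndarray
    planar: np.ndarray

    @classmethod
    def from_gradients(
        cls, field: GradientField, sigma_px: float = 2.0,
        planar_rtol: float = 1e-6,
    ) -> "CurvatureMaps":
        k1, k2 = principal_curvatures(field, sigma_px)
        c = curvedness(k1, k2)
        planar = c < planar_rtol * c.max() if c.max() > 0 else np.ones_like(
            c, dtype=bool)
        s = shape_index(k1, k2)
        s = np.where(planar, np.nan, s)
        return cls(k1=k1, k2=k2, s=s, c=c, planar=planar)


@dataclass
class ShapeWeightMap:
    """Butterworth-style per-pixel weights for one vein polarity.

    ``weights`` lies in [0, 1] and equals 1 exactly at the band centre
    ``s_m`` (-0.5 for ruts, +0.5 for ridges).
    """

    weights: np.ndarray
    polarity: str  # "ridge" | "rut"
    sigma: float
    omega: float
    s_m: float


def principal_curvatures(
    field: GradientField, sigma_px: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Principal curvatures (k1 >= k2) from a gradient field.

    First derivatives ``(zx, zy) = (-p, -q)`` are Gaussian-smoothed at scale
    ``sigma_px``; second derivatives are Gaussian-derivative filters applied
    to them (the mixed derivative is averaged over its two estimates).  The
    curvatures are the eigenvalues ``H +- sqrt(H^2 - K)`` of the shape
    operator of the Monge patch, with the sign flipped so that convex toward
    the camera is positive.  Invalid pixels keep their (zeroed) gradients
    and therefore yield locally meaningless curvature; callers should mask
    with ``field.valid``.
    """
    if sigma_px <= 0:
        raise ValueError("smoothing scale sigma_px must be positive")
    zx = ndimage.gaussian_filter(-field.p, sigma_px)
    zy = ndimage.gaussian_filter(-field.q, sigma_px)
    zxx = ndimage.gaussian_filter(-field.p, sigma_px, order=(0, 1))
    zyy = ndimage.gaussian_filter(-field.q, sigma_px, order=(1, 0))
    zxy = 0.5 * (
        ndimage.gaussian_filter(-field.p, sigma_px, order=(1, 0))
        + ndimage.gaussian_filter(-field.q, sigma_px, order=(0, 1))
    )
    # fundamental forms of z = f(x, y) with the normal toward the camera
    E = 1.0 + zx**2
    F = zx * zy
    G = 1.0 + zy**2
    denom = np.sqrt(1.0 + zx**2 + zy**2)
    L = zxx / denom
    M = zxy / denom
    N = zyy / denom
    det_I = E * G - F**2
    K = (L * N - M**2) / det_I
    H = (E * N - 2.0 * F * M + G * L) / (2.0 * det_I)
    # eigenvalues H +- sqrt(H^2 - K); negate for convex-positive convention
    disc = np.sqrt(np.clip(H**2 - K, 0.0, None))
    k1 = -H + disc
    k2 = -H - disc
    return k1, k2


def shape_index(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Shape index ``s = (2/pi) arctan((k1 + k2) / (k1 - k2))`` in [-1, 1].

    Requires k1 >= k2.  Umbilic patches (k1 == k2 != 0) map exactly to the
    endpoints +-1; a canonical ridge (k1 > 0, k2 = 0) to +0.5 and a rut
    (k1 = 0, k2 < 0) to -0.5.  Planar pixels (k1 == k2 == 0) return 0 here;
    use :class:`CurvatureMaps` to mask them as undefined.
    """
    k1 = np.asarray(k1, dtype=np.float64)
    k2 = np.asarray(k2, dtype=np.float64)
    if np.any(k1 - k2 < -1e-12 * np.maximum(np.abs(k1), np.abs(k2))):
        raise ValueError("shape_index requires k1 >= k2 everywhere")
    return (2.0 / np.pi) * np.arctan2(k1 + k2, k1 - k2)


def classify_shape(s: np.ndarray, planar: np.ndarray | None = None
                   ) -> np.ndarray:
    """Map shape-index values to the nine category labels.

    Returns integer labels indexing :data:`SHAPE_CATEGORIES`; planar pixels
    get :data:`PLANAR_LABEL` (-1).  Bands are half-open on the right, e.g.
    the rut band is [-0.625, -0.375), so a value exactly on a boundary falls
    into the band to its right.
    """
    s = np.asarray(s, dtype=np.float64)
    labels = np.digitize(s, _BAND_EDGES, right=False).astype(np.int8)
    nanmask = ~np.isfinite(s)
    if planar is not None:
        nanmask |= np.asarray(planar, dtype=bool)
    labels[nanmask] = PLANAR_LABEL
    return labels


def curvedness(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Curvedness ``c = sqrt((k1^2 + k2^2) / 2)``, the size of local bending.

    Non-negative everywhere, zero exactly on planar patches, and linear in
    a uniform scaling of surface height while the shape index stays fixed.
    """
    return np.sqrt((np.asarray(k1) ** 2 + np.asarray(k2) ** 2) / 2.0)


def shape_weight_map(
    s: np.ndarray,
    polarity: str,
    sigma: float = 4.0,
    omega: float = 0.4,
    planar: np.ndarray | None = None,
) -> ShapeWeightMap:
    """Butterworth-style weight of the shape index for one vein polarity.

    For rut (negative) veins::

        s_w = 1 / (1 + ((s - s_m) / omega)^(2*sigma))   where s < 0
        s_w = 0                                          where s >= 0

    with band centre ``s_m = -0.5`` (the median shape index of a rut).  The
    ridge variant mirrors this with ``s_m = +0.5`` and zero weight on
    ``s <= 0``: weights vanish on the shapes of the opposite convexity.
    ``sigma`` is the filter order (controls pass-band flatness), ``omega``
    the cut-off half-width; the defaults (4, 0.4) give a flat pass band over
    the matching category band with rapid roll-off.  Planar pixels get
    weight 0.
    """
    if omega <= 0:
        raise ValueError("cut-off omega must be positive")
    if sigma < 1:
        raise ValueError("filter order sigma must be >= 1")
    if polarity not in ("ridge", "rut"):
        raise ValueError("polarity must be 'ridge' or 'rut'")
    s = np.asarray(s, dtype=np.float64)
    s_m = 0.5 if polarity == "ridge" else -0.5
    finite = np.isfinite(s)
    s_f = np.where(finite, s, 0.0)
    w = 1.0 / (1.0 + (np.abs(s_f - s_m) / omega) ** (2.0 * sigma))
    if polarity == "rut":
        w = np.where(s_f < 0, w, 0.0)
    else:
        w = np.where(s_f > 0, w, 0.0)
    w = np.where(finite, w, 0.0)
    if planar is not None:
        w = np.where(np.asarray(planar, dtype=bool), 0.0, w)
    return ShapeWeightMap(weights=w, polarity=polarity, sigma=sigma,
                          omega=omega, s_m=s_m)
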