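"""Synthetic Lambertian leaves with vein networks of known geometry.

This module stands in for a physical multi-light capture rig: it builds
parametric leaf surfaces — a gently undulating elliptical blade carrying a
vein network that is either raised (ridge-like, positive polarity) or
recessed (rut-like, negative polarity) — and renders photometric-stereo
image stacks from them under a configurable light rig, with per-pixel
albedo variation, ambient light and sensor noise.

Every output (skeleton, height field, gradients, rendered frames, ground
truth) is a deterministic function of the spec and its seed.

Vein cross-sections are Gaussian tubes ``amplitude * exp(-d^2 / (2 w^2))``
around the skeleton, where ``d`` is the Euclidean distance to the nearest
skeleton pixel and ``w`` the half-width.  The albedo pattern, when enabled,
is a smooth random field seeded independently of the vein geometry, so
surface colouring is spatially uncorrelated with the vein mask and cannot
explain any downstream detection.

Four venation architectures are supported:

* ``pinnate`` — a midrib with alternating secondary veins;
* ``palmate`` — several primary veins radiating from the petiole point;
* ``transverse`` — pinnate plus tertiaries connecting the secondaries;
* ``reticulate`` — a net-like polygonal mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .photometric import LightRig, PSStack

__all__ = [
    "ARCHITECTURES",
    "SyntheticLeafSpec",
    "SyntheticLeaf",
    "make_vein_skeleton",
    "build_surface",
    "render_ps_stack",
    "simulate_leaf",
    "evaluate_mask",
    "MaskMetrics",
]

ARCHITECTURES = ("palmate", "pinnate", "transverse", "reticulate")
POLARITIES = ("positive", "negative")


@dataclass(frozen=True)
class SyntheticLeafSpec:
    """Parameters of one synthetic leaf capture.

    Heights are in arbitrary "height units" on the same scale as pixel
    coordinates; a default blade of ~200 px extent with a vein amplitude of
    4 gives vein relief of roughly 2% of the blade extent, which is the
    regime of real leaf veins (sub-millimetre relief on centimetre blades).

    Attributes
    ----------
    height, width : int
        Raster size in pixels.
    architecture : str
        One of ``palmate``, ``pinnate``, ``transverse``, ``reticulate``.
    polarity : str
        ``positive`` for ridge-like (raised) veins, ``negative`` for
        rut-like (recessed) veins.
    vein_amplitude : float
        Peak height of the vein profile above/below the blade (> 0).
    vein_half_width : float
        Gaussian half-width of the vein cross-section in pixels (> 0).
    undulation_amplitude, undulation_scale : float
        Amplitude (height units) and spatial wavelength (pixels) of the
        gentle blade curvature.
    albedo_pattern : bool
        Whether to paint a smooth random colour pattern on the blade.
    albedo_contrast : float
        Relative contrast of the pattern, in (0, 1).
    noise_sd : float
        Sensor noise standard deviation as a fraction of full scale.
    ambient : float
        Ambient illumination level as a fraction of full scale.
    seed : int
        Seed for every random draw (geometry and rendering).
    albedo_seed : int or None
        Separate seed for the albedo pattern; derived from ``seed`` when
        None.  Changing it reshuffles the colouring without touching the
        geometry or the ground-truth masks.
    palmate_primaries : int
        Number of primary veins radiating from the petiole (palmate only).
    """

    height: int = 256
    width: int = 256
    architecture: str = "pinnate"
    polarity: str = "positive"
    vein_amplitude: float = 4.0
    vein_half_width: float = 2.5
    undulation_amplitude: float = 2.0
    undulation_scale: float = 80.0
    albedo_pattern: bool = True
    albedo_contrast: float = 0.5
    noise_sd: float = 0.005
    ambient: float = 0.05
    seed: int = 0
    albedo_seed: int | None = None
    palmate_primaries: int = 5

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"valid names: {', '.join(ARCHITECTURES)}"
            )
        if self.polarity not in POLARITIES:
            raise ValueError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )
        if self.vein_amplitude <= 0:
            raise ValueError("vein_amplitude must be strictly positive")
        if self.vein_half_width <= 0:
            raise ValueError("vein_half_width must be strictly positive")
        if not 0 <= self.albedo_contrast < 1:
            raise ValueError("albedo_contrast must lie in [0, 1)")
        if self.height < 32 or self.width < 32:
            raise ValueError("raster must be at least 32 x 32 pixels")


@dataclass
class SyntheticLeaf:
    """Ground truth for one synthetic leaf.

    ``p`` and ``q`` are the negated partial derivatives of the height
    field (central differences), matching the convention used by the
    photometric-stereo solver, so the rendered stack round-trips exactly.
    """

    height_field: np.ndarray
    p: np.ndarray
    q: np.ndarray
    albedo: np.ndarray
    foreground: np.ndarray
    vein_mask: np.ndarray
    polarity: str
    spec: SyntheticLeafSpec

    def normals(self) -> np.ndarray:
        n = np.stack([-self.p, -self.q, np.ones_like(self.p)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Blade geometry helpers
# ---------------------------------------------------------------------------

def _blade_geometry(spec: SyntheticLeafSpec):
    """Ellipse centre, semi-axes and petiole point (row, col)."""
    cy, cx = spec.height / 2.0, spec.width / 2.0
    a = 0.42 * spec.width   # semi-axis along x (columns)
    b = 0.34 * spec.height  # semi-axis along y (rows)
    petiole = (int(round(cy)), int(round(cx - a)) + 1)
    return (cy, cx), (a, b), petiole


def _blade_mask(spec: SyntheticLeafSpec) -> np.ndarray:
    (cy, cx), (a, b), _ = _blade_geometry(spec)
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _inside_frac(y, x, spec, frac=0.92) -> bool:
    (cy, cx), (a, b), _ = _blade_geometry(spec)
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= frac**2


def _clip_to_blade(y0, x0, y1, x1, spec, frac=0.92):
    """Shorten the segment (y0,x0)->(y1,x1) to stay inside the blade."""
    t_ok = 0.0
    for t in np.linspace(0.0, 1.0, 128):
        y = y0 + t * (y1 - y0)
        x = x0 + t * (x1 - x0)
        if _inside_frac(y, x, spec, frac):
            t_ok = t
    return y0 + t_ok * (y1 - y0), x0 + t_ok * (x1 - x0)


def _rasterize(polylines, shape) -> np.ndarray:
    skel = np.zeros(shape, dtype=bool)
    for poly in polylines:
        pts = np.asarray(poly)
        for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(int(round(y0)), int(round(x0)),
                               int(round(y1)), int(round(x1)))
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            skel[rr[keep], cc[keep]] = True
    return skel


def _pinnate_polylines(spec, rng):
    (cy, cx), (a, b), petiole = _blade_geometry(spec)
    tip = (cy, cx + 0.9 * a)
    polys = [[(float(petiole[0]), float(petiole[1])), tip]]
    # alternating secondaries branching off the midrib
    n_sec = 6
    xs = np.linspace(cx - 0.72 * a, cx + 0.6 * a, n_sec)
    for i, x in enumerate(xs):
        side = 1 if i % 2 == 0 else -1
        ang = math.radians(40.0 + rng.uniform(-6, 6))
        length = 1.4 * b
        y1 = cy + side * length * math.sin(ang)
        x1 = x + length * math.cos(ang)
        y1, x1 = _clip_to_blade(cy, x, y1, x1, spec)
        polys.append([(cy, x), (y1, x1)])
    return polys


def _palmate_polylines(spec, rng):
    (cy, cx), (a, b), petiole = _blade_geometry(spec)
    k = spec.palmate_primaries
    py, px = float(petiole[0]), float(petiole[1])
    spread = math.radians(100.0)
    angles = np.linspace(-spread / 2, spread / 2, k)
    polys = []
    for ang in angles:
        ang = ang + rng.uniform(-0.03, 0.03)
        y1 = py + 2.2 * a * math.sin(ang)
        x1 = px + 2.2 * a * math.cos(ang)
        y1, x1 = _clip_to_blade(py, px, y1, x1, spec)
        polys.append([(py, px), (y1, x1)])
    return polys


def _transverse_polylines(spec, rng):
    polys = _pinnate_polylines(spec, rng)
    # tertiaries connecting midpoints of consecutive same-side secondaries
    secondaries = polys[1:]
    for i in range(len(secondaries) - 2):
        (y0a, x0a), (y1a, x1a) = secondaries[i]
        (y0b, x0b), (y1b, x1b) = secondaries[i + 2]
        for t in (0.45, 0.85):
            ya = y0a + t * (y1a - y0a)
            xa = x0a + t * (x1a - x0a)
            yb = y0b + t * (y1b - y0b)
            xb = x0b + t * (x1b - x0b)
            polys.append([(ya, xa), (yb, xb)])
    return polys


def _reticulate_polylines(spec, rng):
    """Net-like mesh: Delaunay edges over random interior points."""
    from scipy.spatial import Delaunay

    (cy, cx), (a, b), petiole = _blade_geometry(spec)
    # dart-throwing with a minimum separation: mesh cells must be much
    # wider than the vein band itself, as in real net-like venation
    n_pts = 18
    min_sep = 0.30 * b
    pts = []
    attempts = 0
    while len(pts) < n_pts and attempts < 4000:
        attempts += 1
        y = rng.uniform(cy - b, cy + b)
        x = rng.uniform(cx - a, cx + a)
        if not _inside_frac(y, x, spec, frac=0.85):
            continue
        if all(math.hypot(y - yp, x - xp) >= min_sep for yp, xp in pts):
            pts.append((y, x))
    pts.append((float(petiole[0]), float(petiole[1])))
    pts = np.asarray(pts)
    tri = Delaunay(pts[:, ::-1])  # (x, y) order for Delaunay
    polys = []
    seen = set()
    for simplex in tri.simplices:
        for i in range(3):
            e = tuple(sorted((simplex[i], simplex[(i + 1) % 3])))
            if e in seen:
                continue
            seen.add(e)
            (ya, xa), (yb, xb) = pts[e[0]], pts[e[1]]
            # drop long sliver edges hugging the hull
            if math.hypot(ya - yb, xa - xb) < 0.8 * a:
                polys.append([(ya, xa), (yb, xb)])
    return polys


_ARCH_BUILDERS = {
    "pinnate": _pinnate_polylines,
    "palmate": _palmate_polylines,
    "transverse": _transverse_polylines,
    "reticulate": _reticulate_polylines,
}


def make_vein_skeleton(spec: SyntheticLeafSpec):
    """Generate the vein skeleton for a spec.

    Returns ``(skeleton, polylines)``: a one-pixel-wide boolean raster and
    the generating polylines as lists of (row, col) points.  The skeleton
    lies inside an elliptical blade outline.  Identical spec and seed give
    bit-identical rasters.
    """
    rng = np.random.default_rng(spec.seed)
    polys = _ARCH_BUILDERS[spec.architecture](spec, rng)
    skel = _rasterize(polys, (spec.height, spec.width))
    skel &= _blade_mask(spec)
    return skel, polys


# ---------------------------------------------------------------------------
# Surface construction and rendering
# ---------------------------------------------------------------------------

def _undulation(spec: SyntheticLeafSpec, rng) -> np.ndarray:
    """Gentle blade curvature: two random-phase sinusoid products."""
    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(np.float64)
    lam = spec.undulation_scale
    ph = rng.uniform(0, 2 * np.pi, size=4)
    z = (np.sin(2 * np.pi * xx / lam + ph[0])
         * np.sin(2 * np.pi * yy / lam + ph[1]))
    z += 0.6 * (np.sin(2 * np.pi * xx / (1.7 * lam) + ph[2])
                * np.sin(2 * np.pi * yy / (1.3 * lam) + ph[3]))
    peak = np.abs(z).max()
    if peak > 0:
        z *= spec.undulation_amplitude / peak
    return z


def _albedo_map(spec: SyntheticLeafSpec, foreground: np.ndarray) -> np.ndarray:
    """Blade albedo ~0.65 with an optional smooth random pattern.

    The pattern seed is independent of the geometry seed, so the colouring
    carries no information about vein locations.
    """
    base_blade, base_bg = 0.65, 0.06
    albedo = np.where(foreground, base_blade, base_bg)
    if spec.albedo_pattern and spec.albedo_contrast > 0:
        aseed = (spec.albedo_seed if spec.albedo_seed is not None
                 else (spec.seed * 7919 + 104729) % (2**31))
        arng = np.random.default_rng(aseed)
        noise = arng.standard_normal((spec.height, spec.width))
        pattern = ndimage.gaussian_filter(noise, sigma=12.0)
        peak = np.abs(pattern).max()
        if peak > 0:
            pattern /= peak
        albedo = albedo * (1.0 + spec.albedo_contrast * pattern * foreground)
    return np.clip(albedo, 0.01, 1.0)


def build_surface(spec: SyntheticLeafSpec, skeleton: np.ndarray) -> SyntheticLeaf:
    """Build the leaf surface and ground truth from a vein skeleton.

    The height field is a smooth blade undulation plus a signed
    Gaussian-profile tube along the skeleton (positive polarity raises the
    veins, negative recesses them).  Gradients follow ``p = -dz/dx``,
    ``q = -dz/dy`` via central differences.  The ground-truth vein mask is
    the set of foreground pixels within one half-width of the skeleton.
    """
    rng = np.random.default_rng(spec.seed + 1)
    z = _undulation(spec, rng)
    d = ndimage.distance_transform_edt(~skeleton)
    sign = 1.0 if spec.polarity == "positive" else -1.0
    w = spec.vein_half_width
    profile = spec.vein_amplitude * np.exp(-(d**2) / (2.0 * w**2))
    z = z + sign * profile
    gy, gx = np.gradient(z)
    p = -gx
    q = -gy
    foreground = _blade_mask(spec)
    vein_mask = (d <= w) & foreground
    albedo = _albedo_map(spec, foreground)
    return SyntheticLeaf(
        height_field=z, p=p, q=q, albedo=albedo,
        foreground=foreground, vein_mask=vein_mask,
        polarity=spec.polarity, spec=spec,
    )


def render_ps_stack(
    leaf: SyntheticLeaf,
    rig: LightRig | None = None,
    noise_sd: float | None = None,
    ambient: float | None = None,
    seed: int | None = None,
) -> PSStack:
    """Render a Lambertian photometric-stereo stack from a leaf surface.

    For each light ``L``, intensity is
    ``albedo * max(0, <N, L>) + ambient + noise`` clipped to [0, 1] —
    attached-shadow pixels (``<N, L> <= 0``) render at ambient level.  One
    additional ambient-only frame is appended.  Noise is i.i.d. Gaussian,
    added before clipping.
    """
    rig = rig if rig is not None else LightRig.default_four()
    spec = leaf.spec
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    ambient = spec.ambient if ambient is None else ambient
    seed = (spec.seed + 2) if seed is None else seed
    rng = np.random.default_rng(seed)

    normals = leaf.normals()  # (H, W, 3)
    frames = []
    for L in rig.vectors:
        shading = np.clip(normals @ L, 0.0, None)
        img = leaf.albedo * shading + ambient
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames.append(np.clip(img, 0.0, 1.0))
    amb = np.full(leaf.height_field.shape, ambient)
    if noise_sd > 0:
        amb = amb + rng.normal(0.0, noise_sd, size=amb.shape)
    amb = np.clip(amb, 0.0, 1.0)
    return PSStack(frames=np.stack(frames), ambient=amb, lights=rig)


def simulate_leaf(spec: SyntheticLeafSpec, rig: LightRig | None = None):
    """Convenience: skeleton -> surface -> rendered stack.

    Returns ``(leaf, stack)``.
    """
    skeleton, _ = make_vein_skeleton(spec)
    leaf = build_surface(spec, skeleton)
    stack = render_ps_stack(leaf, rig=rig)
    return leaf, stack


# ---------------------------------------------------------------------------
# Mask metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskMetrics:
    dice: float
    precision: float
    recall: float


def evaluate_mask(predicted: np.ndarray, truth: np.ndarray) -> MaskMetrics:
    """Dice, precision and recall between two binary masks.

    All three lie in [0, 1]; comparing two empty masks is defined as
    perfect agreement (1.0).
    """
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {true.shape}"
        )
    inter = np.count_nonzero(pred & true)
    np_, nt = np.count_nonzero(pred), np.count_nonzero(true)
    dice = 1.0 if (np_ + nt) == 0 else 2.0 * inter / (np_ + nt)
    precision = (1.0 if nt == 0 else 0.0) if np_ == 0 else inter / np_
    recall = (1.0 if np_ == 0 else 0.0) if nt == 0 else inter / nt
    return MaskMetrics(dice=dice, precision=precision, recall=recall)
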