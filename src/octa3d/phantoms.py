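"""Seeded synthetic phantoms with known ground truth.

Two generators:

* :func:`make_layered_volume` — layered skin-like structural volumes
  (background / epidermis / dermis separated by smooth curved boundary
  surfaces) with multiplicative speckle and additive Gaussian noise.
* :func:`make_vessel_volume` — angiographic volumes containing bright
  tubes plus the artifact families seen in decorrelation angiography:
  Gaussian noise, salt-and-pepper noise, motion-induced stripe lines
  along the fast axis, and axial tail artifacts above large vessels.

Ground-truth labels, masks and centerlines are rasterized *before* any
noise or artifact is applied, so they are exact regardless of the noise
configuration.  Identical spec + seed always yields bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised when phantom boundary surfaces overlap or invert."""


# --------------------------------------------------------------------------
# layered structural phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LayeredPhantomSpec:
    """Geometry and noise for a layered skin phantom.

    The three boundary surfaces (background-epidermis AB1, epidermis-dermis
    AB2, dermis-background AB3) are either given explicitly as (X, Y) height
    fields in ``boundaries``, or generated as sums of ``n_waves``
    low-frequency sinusoids of total amplitude ``boundary_amplitude`` around
    the mean depths ``depths``.

    ``speckle_shape`` is the shape parameter of a multiplicative
    unit-mean Gamma field (the standard coherent-imaging speckle
    surrogate); ``None`` or 0 disables speckle.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    depths: tuple[float, float, float] = (14.0, 28.0, 52.0)
    boundary_amplitude: float = 3.0
    n_waves: int = 3
    boundaries: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    layer_intensities: tuple[float, float, float] = (0.05, 0.55, 0.35)
    speckle_shape: float | None = 4.0
    additive_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if any(n < 4 for n in self.shape):
            raise ValueError(f"shape too small: {self.shape}")
        if any(i < 0 for i in self.layer_intensities):
            raise ValueError("layer intensities must be non-negative")


def _wave_field(rng, shape_xy, amplitude, n_waves):
    """Sum of low-frequency sinusoids over the lateral grid."""
    nx, ny = shape_xy
    x = np.arange(nx)[:, None] / nx
    y = np.arange(ny)[None, :] / ny
    f = np.zeros(shape_xy)
    if amplitude == 0 or n_waves == 0:
        return f
    for _ in range(n_waves):
        kx, ky = rng.integers(0, 3, size=2)
        if kx == 0 and ky == 0:
            kx = 1
        phase = rng.uniform(0, 2 * np.pi)
        f += np.sin(2 * np.pi * (kx * x + ky * y) + phase)
    return f * (amplitude / n_waves)


def _boundary_fields(spec: LayeredPhantomSpec):
    nz, nx, ny = spec.shape
    if spec.boundaries is not None:
        b1, b2, b3 = (np.asarray(b, float) for b in spec.boundaries)
        for b in (b1, b2, b3):
            if b.shape != (nx, ny):
                raise GeometryError(
                    f"boundary field shape {b.shape} != lateral grid {(nx, ny)}")
    else:
        rng = np.random.default_rng(spec.seed)
        d1, d2, d3 = spec.depths
        b1 = d1 + _wave_field(rng, (nx, ny), spec.boundary_amplitude, spec.n_waves)
        b2 = d2 + _wave_field(rng, (nx, ny), spec.boundary_amplitude, spec.n_waves)
        b3 = d3 + _wave_field(rng, (nx, ny), spec.boundary_amplitude, spec.n_waves)
    if not (np.all(b1 < b2) and np.all(b2 < b3)):
        raise GeometryError("boundary surfaces overlap or invert (need AB1 < AB2 < AB3)")
    if b1.min() < 0 or b3.max() >= nz:
        raise GeometryError("boundary surfaces leave the axial range [0, Z)")
    return b1, b2, b3


def make_layered_volume(spec: LayeredPhantomSpec):
    """Generate a layered structural phantom.

    Returns
    -------
    volume : (Z, X, Y) float32 ndarray
        Layer-mean reflectivity x multiplicative speckle + Gaussian noise.
    labels : (Z, X, Y) uint8 ndarray
        Exact noise-free class map: 0 background, 1 epidermis, 2 dermis.
    """
    nz, nx, ny = spec.shape
    b1, b2, b3 = _boundary_fields(spec)
    z = np.arange(nz)[:, None, None]
    labels = np.zeros(spec.shape, np.uint8)
    labels[(z >= b1[None]) & (z < b2[None])] = 1
    labels[(z >= b2[None]) & (z < b3[None])] = 2

    means = np.asarray(spec.layer_intensities, float)
    vol = means[labels]
    # geometry and noise use independent sub-streams of the same seed
    rng = np.random.default_rng([spec.seed, 1])
    if spec.speckle_shape:
        k = float(spec.speckle_shape)
        vol = vol * rng.gamma(k, 1.0 / k, size=spec.shape)
    if spec.additive_sigma:
        vol = vol + rng.normal(0.0, spec.additive_sigma, size=spec.shape)
    return vol.astype(np.float32), labels


# --------------------------------------------------------------------------
# vessel phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Tube:
    """A tube: polyline centerline (voxel coordinates, (z,x,y)), radius, intensity."""

    points: tuple  # ((z, x, y), ...) at least 2 points
    radius: float = 3.0
    intensity: float = 1.0

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("a tube needs at least 2 centerline points")
        if self.radius < 1:
            raise ValueError("tube radius must be >= 1 voxel")


def straight_tube(p0, p1, radius=3.0, intensity=1.0) -> Tube:
    return Tube(points=(tuple(p0), tuple(p1)), radius=radius, intensity=intensity)


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Tubes plus the angiography artifact families.

    ``stripe_axis`` is the image axis the stripe lines run along (1 = fast
    axis); stripes are placed at seeded random positions on the other two
    axes and add ``stripe_amplitude`` intensity along their full extent.
    ``tail_factor`` in [0, 1) scales the false-flow tail placed axially
    *above* each tube (toward smaller z when ``tail_direction`` is -1),
    decaying exponentially with length ``tail_decay`` voxels; tails are
    dimmer than the vessel itself by construction.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    tubes: tuple[Tube, ...] = ()
    gaussian_sigma: float = 0.05
    salt_pepper_fraction: float = 0.0
    stripe_count: int = 0
    stripe_axis: int = 1
    stripe_amplitude: float = 0.5
    tail_factor: float = 0.0
    tail_direction: int = -1
    tail_decay: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.tail_factor < 1):
            raise ValueError("tail intensity factor must lie in [0, 1)")
        if self.stripe_axis not in (0, 1, 2):
            raise ValueError("stripe_axis must be 0, 1 or 2")
        if self.tail_direction not in (-1, 1):
            raise ValueError("tail_direction must be -1 (above) or +1 (below)")


def _rasterize_tube(mask, intens, tube: Tube, shape):
    """Paint one tube into mask/intensity arrays (distance-to-polyline)."""
    pts = np.asarray(tube.points, float)
    r = float(tube.radius)
    clipped = bool(np.any(pts - r < 0) or np.any(pts + r > np.asarray(shape) - 1))
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.floor(np.minimum(a, b) - r).astype(int)
        hi = np.ceil(np.maximum(a, b) + r).astype(int) + 1
        lo = np.clip(lo, 0, shape)
        hi = np.clip(hi, 0, shape)
        if np.any(hi <= lo):
            continue
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                            indexing="ij")
        p = np.stack([g.astype(float) for g in grids], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            t = np.zeros(p.shape[:-1])
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = np.sum((p - closest) ** 2, axis=-1)
        inside = d2 <= r * r
        region = tuple(slice(l, h) for l, h in zip(lo, hi))
        mask[region] |= inside
        np.maximum(intens[region], np.where(inside, tube.intensity, 0.0),
                   out=intens[region])
    return clipped


def _centerline_voxels(tube: Tube, shape):
    pts = np.asarray(tube.points, float)
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) * 4)))
        t = np.linspace(0, 1, n)
        out.append(np.round(a + t[:, None] * (b - a)).astype(int))
    vox = np.unique(np.concatenate(out), axis=0)
    keep = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
    return vox[keep]


def make_vessel_volume(spec: VesselPhantomSpec):
    """Generate an angiographic tube phantom.

    Returns
    -------
    volume : (Z, X, Y) float32 ndarray
        Intensity volume with tails, stripes and noise applied.
    mask : (Z, X, Y) bool ndarray
        Exact union of the rasterized tubes (pre-noise ground truth).
    centerlines : (n, 3) int ndarray
        Voxel coordinates (z, x, y) of the tube centerlines.
    """
    shape = spec.shape
    mask = np.zeros(shape, bool)
    intens = np.zeros(shape, float)
    clipped = False
    for tube in spec.tubes:
        clipped |= _rasterize_tube(mask, intens, tube, shape)
    if clipped:
        warnings.warn("tube extends outside the volume; clipped", stacklevel=2)
    if spec.tubes:
        centerlines = np.concatenate(
            [_centerline_voxels(t, shape) for t in spec.tubes])
        centerlines = np.unique(centerlines, axis=0)
    else:
        centerlines = np.empty((0, 3), int)

    vol = intens.copy()
    rng = np.random.default_rng(spec.seed)

    # axial tail artifacts: dim false-flow columns extending from the tube
    # top (tail_direction=-1, the default "above" case) or bottom
    if spec.tail_factor > 0 and mask.any():
        nz = shape[0]
        zidx = np.arange(nz)[:, None, None]
        any_col = mask.any(axis=0)
        if spec.tail_direction == -1:
            edge = np.where(any_col, np.argmax(mask, axis=0), nz)
            dist = edge[None] - zidx          # >0 above the tube top
        else:
            rev = np.argmax(mask[::-1], axis=0)
            edge = np.where(any_col, nz - 1 - rev, -1)
            dist = zidx - edge[None]          # >0 below the tube bottom
        col_int = np.max(intens, axis=0)
        tail = (spec.tail_factor * col_int[None]
                * np.exp(-np.maximum(dist, 0) / spec.tail_decay))
        tail = np.where((dist > 0) & any_col[None], tail, 0.0)
        vol = np.maximum(vol, tail)

    # stripe artifacts: full-extent bright lines along stripe_axis
    if spec.stripe_count > 0:
        other = [ax for ax in range(3) if ax != spec.stripe_axis]
        for _ in range(spec.stripe_count):
            pos = [int(rng.integers(0, shape[ax])) for ax in other]
            idx = [slice(None)] * 3
            idx[other[0]], idx[other[1]] = pos
            vol[tuple(idx)] += spec.stripe_amplitude

    if spec.gaussian_sigma > 0:
        vol = vol + rng.normal(0.0, spec.gaussian_sigma, size=shape)

    if spec.salt_pepper_fraction > 0:
        n = vol.size
        k = int(round(spec.salt_pepper_fraction * n))
        flat = rng.choice(n, size=k, replace=False)
        peak = max(1.0, float(intens.max()))
        half = k // 2
        vol.flat[flat[:half]] = peak
        vol.flat[flat[half:]] = 0.0

    return vol.astype(np.float32), mask, centerlines


def psnr(reference, test, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB of ``test`` against ``reference``."""
    ref = np.asarray(reference, float)
    tst = np.asarray(test, float)
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0:
        return float("inf")
    if peak is None:
        peak = float(ref.max() - ref.min()) or 1.0
    return 10.0 * np.log10(peak * peak / mse)
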