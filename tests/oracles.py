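"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: explicit
loops, direct finite differences, discrete surface integrals.
"""

import numpy as np
from scipy import ndimage


def cylinder_voxels(shape, p0, p1, radius):
    """Per-voxel point-to-segment distance test, explicit loop."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    ab = p1 - p0
    denom = float(ab @ ab)
    out = np.zeros(shape, bool)
    for z in range(shape[0]):
        for x in range(shape[1]):
            for y in range(shape[2]):
                p = np.array([z, x, y], float)
                t = np.clip((p - p0) @ ab / denom, 0.0, 1.0)
                d = np.linalg.norm(p - (p0 + t * ab))
                out[z, x, y] = d <= radius
    return out


def flood_fill_components(mask):
    """26-connected component labelling by explicit BFS flood fill."""
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, int)
    nbrs = [(dz, dx, dy) for dz in (-1, 0, 1) for dx in (-1, 0, 1)
            for dy in (-1, 0, 1) if (dz, dx, dy) != (0, 0, 0)]
    current = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        current += 1
        stack = [seed]
        labels[seed] = current
        while stack:
            z, x, y = stack.pop()
            for dz, dx, dy in nbrs:
                q = (z + dz, x + dx, y + dy)
                if all(0 <= q[i] < mask.shape[i] for i in range(3)) \
                        and mask[q] and not labels[q]:
                    labels[q] = current
                    stack.append(q)
    return labels, current


def histogram_equalize(img):
    """Plain global histogram equalization via the empirical CDF."""
    flat = img.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order, float)
    ranks[order] = np.arange(1, flat.size + 1)
    return (ranks / flat.size).reshape(img.shape)


def _fibonacci_sphere(n):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(phi), np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta)], 1)


def _diff4(a, axis):
    return (-np.roll(a, -2, axis) + 8 * np.roll(a, -1, axis)
            - 8 * np.roll(a, 1, axis) + np.roll(a, 2, axis)) / 12.0


def oriented_flux_surface_integral(vol, r, point, sigma=1.0, npts=4000):
    """Q(x, r) by direct numerical flux integration over a discretized
    sphere: 4th-order finite-difference gradient, cubic interpolation."""
    vs = ndimage.gaussian_filter(np.asarray(vol, float), sigma, mode="mirror")
    grad = np.stack([_diff4(vs, i) for i in range(3)], axis=0)
    pts = _fibonacci_sphere(npts)
    dA = 4 * np.pi * r ** 2 / npts
    coords = (np.asarray(point, float)[None, :] + r * pts).T
    g = np.stack([ndimage.map_coordinates(grad[i], coords, order=3,
                                          mode="nearest") for i in range(3)], 0)
    Q = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Q[i, j] = np.sum(g[i] * pts[:, j]) * dA
    return Q
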