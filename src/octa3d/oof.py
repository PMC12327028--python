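"""Optimally-oriented-flux (OOF) vessel enhancement.

For each voxel x and sphere radius r, the oriented-flux matrix

    Q_ij(x; r) = ∮_{|h|=r} ∂_i(G_σ * f)(x + h) n_j(h) dA

measures the flux of the smoothed image gradient through a local sphere,
projected on the coordinate directions.  By the divergence theorem this
equals the Hessian of the smoothed image convolved with the solid-ball
indicator, which is evaluated here in the Fourier domain using the
analytic ball transform

    B_r(ξ) = 4πr³ (sin u − u cos u) / u³,   u = 2πr|ξ|.

Inside a bright tube the two cross-sectional eigenvalues of Q are
strongly negative while the axial one is near zero (λ1 ≤ λ2 ≤ λ3 ≈ 0);
the multi-radius response takes the best surface-normalized eigenvalue
combination over an integer radius grid:

    R(x) = max_{r} max(−λ̄(x, r) / r², 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["OOFParams", "oriented_flux_matrix", "eig_sym3", "oof_response"]


@dataclass(frozen=True)
class OOFParams:
    """Multi-radius response configuration.

    radii are sphere radii in voxels; ``eig_rule`` selects the eigenvalue
    combination λ̄: "mean12" uses (λ1+λ2)/2 (tubes with elliptical
    cross-sections), "lambda1" uses λ1 alone (plate-suppressing).
    ``smooth_sigma`` is the Gaussian pre-smoothing in voxels.
    """

    radii: tuple[int, ...] = (2, 3, 4, 5, 6)
    eig_rule: str = "mean12"
    smooth_sigma: float = 1.0

    def __post_init__(self):
        if not self.radii or any(r < 1 for r in self.radii):
            raise ValueError("radii must be a non-empty set of integers >= 1")
        if self.eig_rule not in ("mean12", "lambda1"):
            raise ValueError("eig_rule must be 'mean12' or 'lambda1'")


def _ball_ft(kk, r):
    """Fourier transform of the radius-r solid-ball indicator."""
    u = 2.0 * np.pi * r * kk
    out = np.empty_like(u)
    small = u < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 4.0 * np.pi * r ** 3 * (np.sin(u) - u * np.cos(u)) / u ** 3
    out[small] = 4.0 / 3.0 * np.pi * r ** 3
    return out


def oriented_flux_matrix(volume, r: int, smooth_sigma: float = 1.0) -> np.ndarray:
    """Per-voxel oriented-flux matrix Q(x, r), shape (Z, X, Y, 3, 3).

    The volume is mirror-padded by r + 2 voxels before the FFT so the
    circular convolution never wraps tube responses around the borders.
    """
    from .volume import as_array
    v = np.asarray(as_array(volume), float)
    if v.ndim != 3:
        raise ValueError("expected a 3D volume")
    if r < 1:
        raise ValueError("radius must be >= 1 voxel")
    if r > min(v.shape) // 2:
        raise ValueError(f"radius {r} too large for volume shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("volume contains non-finite voxels")
    if smooth_sigma > 0:
        v = ndimage.gaussian_filter(v, smooth_sigma, mode="mirror")
    pad = int(r) + 2
    vp = np.pad(v, pad, mode="reflect")
    freqs = np.meshgrid(*[np.fft.fftfreq(n) for n in vp.shape],
                        indexing="ij", sparse=True)
    kk = np.sqrt(sum(k ** 2 for k in freqs))
    ball = _ball_ft(kk, float(r))
    F = np.fft.fftn(vp)
    sl = tuple(slice(pad, pad + n) for n in v.shape)
    Q = np.empty(v.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            kern = -((2.0 * np.pi) ** 2) * freqs[i] * freqs[j] * ball
            qij = np.fft.ifftn(F * kern).real[sl]
            Q[..., i, j] = qij
            Q[..., j, i] = qij
    return Q


def eig_sym3(field: np.ndarray) -> np.ndarray:
    """Sorted eigenvalues (λ1 ≤ λ2 ≤ λ3) of a symmetric 3x3 matrix field."""
    Q = np.asarray(field)
    if Q.shape[-2:] != (3, 3):
        raise ValueError("expected trailing (3, 3) matrix axes")
    asym = np.abs(Q - np.swapaxes(Q, -1, -2)).max()
    if asym > 1e-8:
        raise ValueError(f"matrix field is not symmetric (max |Q - Qᵀ| = {asym:g})")
    return np.linalg.eigvalsh(Q)


def oof_response(volume, params: OOFParams | None = None,
                 return_per_radius: bool = False):
    """Multi-radius OOF response R(x) ≥ 0; optionally the per-radius stack."""
    params = params or OOFParams()
    from .volume import as_array
    v = np.asarray(as_array(volume), float)
    per_r = []
    resp = np.zeros(v.shape)
    for r in params.radii:
        Q = oriented_flux_matrix(v, int(r), params.smooth_sigma)
        lam = eig_sym3(Q)
        if params.eig_rule == "mean12":
            lam_bar = 0.5 * (lam[..., 0] + lam[..., 1])
        else:
            lam_bar = lam[..., 0]
        rr = np.maximum(-lam_bar / float(r) ** 2, 0.0)
        if return_per_radius:
            per_r.append(rr)
        np.maximum(resp, rr, out=resp)
    if return_per_radius:
        return resp, np.stack(per_r, axis=0)
    return resp
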