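import numpy as np
import pytest

from octa3d import (
    LayeredPhantomSpec,
    SegModelSpec,
    Tube,
    VesselPhantomSpec,
    make_layered_volume,
    make_vessel_volume,
    train_unet,
)


@pytest.fixture(scope="session")
def tube_phantom_clean():
    """Straight radius-3 tube along the slow axis, no noise."""
    tube = Tube(points=((24, 24, 4), (24, 24, 44)), radius=3.0, intensity=1.0)
    spec = VesselPhantomSpec(shape=(48, 48, 48), tubes=(tube,),
                             gaussian_sigma=0.0, seed=7)
    vol, mask, centers = make_vessel_volume(spec)
    return spec, vol, mask, centers


@pytest.fixture(scope="session")
def tube_phantom_noisy():
    """Same tube plus Gaussian noise and 5 stripes along the fast axis."""
    tube = Tube(points=((24, 24, 4), (24, 24, 44)), radius=3.0, intensity=1.0)
    spec = VesselPhantomSpec(shape=(48, 48, 48), tubes=(tube,),
                             gaussian_sigma=0.1, stripe_count=5,
                             stripe_axis=1, stripe_amplitude=0.8, seed=7)
    vol, mask, centers = make_vessel_volume(spec)
    return spec, vol, mask, centers


@pytest.fixture(scope="session")
def flat_layer_labels():
    """Noise-free flat-boundary phantom (layers at z = 8 / 16 / 26)."""
    nx = ny = 32
    b = tuple(np.full((nx, ny), d) for d in (8.0, 16.0, 26.0))
    spec = LayeredPhantomSpec(shape=(32, nx, ny), boundaries=b,
                              speckle_shape=None, additive_sigma=0.0, seed=0)
    return make_layered_volume(spec)


@pytest.fixture(scope="session")
def seg_model_tiny():
    """Small U-Net trained on 32x32 B-scans pooled from three phantom
    geometries (session-cached)."""
    variants = [
        dict(seed=11), dict(seed=12), dict(seed=13),
        dict(seed=14, speckle_shape=None, additive_sigma=0.0),
        dict(seed=15, speckle_shape=None, additive_sigma=0.0,
             boundary_amplitude=0.0),
    ]
    xs, ys = [], []
    for kw in variants:
        spec = LayeredPhantomSpec(shape=(32, 32, 24), depths=(6.0, 12.0, 26.0),
                                  boundary_amplitude=kw.pop("boundary_amplitude", 1.5),
                                  speckle_shape=kw.pop("speckle_shape", 4.0),
                                  additive_sigma=kw.pop("additive_sigma", 0.01),
                                  **kw)
        vol, labels = make_layered_volume(spec)
        xs.append(np.moveaxis(vol, 2, 0))
        ys.append(np.moveaxis(labels, 2, 0))
    mspec = SegModelSpec(depth=2, base_channels=8, epochs=15, folds=2, seed=0)
    return train_unet(np.concatenate(xs), np.concatenate(ys), mspec,
                      cross_validate=False)
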