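"""Generate the two phantom families every other stage is tested on.

A layered structural phantom mimics skin OCT: three classes (background,
epidermis, dermis) separated by smooth curved boundary surfaces, with
multiplicative speckle.  A vessel phantom mimics OCTA: bright tubes plus
Gaussian noise, stripe artifacts and axial tails.  Ground truth (labels,
mask, centerlines) is exact because it is rasterized before any noise.
"""

import numpy as np

from octa3d import (LayeredPhantomSpec, Tube, VesselPhantomSpec,
                    make_layered_volume, make_vessel_volume)

layered = LayeredPhantomSpec(shape=(64, 64, 64), seed=1)
vol, labels = make_layered_volume(layered)
frac = np.bincount(labels.ravel(), minlength=3) / labels.size
print(f"structural phantom {vol.shape}: "
      f"background {frac[0]:.0%}, epidermis {frac[1]:.0%}, dermis {frac[2]:.0%}")

vessels = VesselPhantomSpec(
    shape=(64, 64, 64),
    tubes=(Tube(points=((32, 20, 4), (32, 20, 60)), radius=3.0),
           Tube(points=((32, 44, 4), (32, 44, 60)), radius=2.0)),
    gaussian_sigma=0.05, stripe_count=3, tail_factor=0.4, seed=2)
avol, mask, centers = make_vessel_volume(vessels)
print(f"vessel phantom: {int(mask.sum())} vessel voxels "
      f"({mask.mean():.2%} of the volume), "
      f"{len(centers)} centerline voxels, "
      f"intensity range [{avol.min():.2f}, {avol.max():.2f}]")
# the mask voxel count is the ground-truth VA of this phantom; the
# centerline count is the ground-truth VS (vessel length proxy)
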