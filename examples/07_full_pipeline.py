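"""End-to-end run: segment -> denoise -> enhance -> vesselize -> metrics.

Three synthetic "days" with growing vasculature are pushed through the
whole workflow; vessel metrics are restricted to the predicted dermis
mask, and the 3D VA series increases with the simulated growth.
Takes ~1 min on one CPU (most of it training the tiny U-Net).
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from octa3d import (LayeredPhantomSpec, RunConfig, SegModelSpec, Tube,
                    VesselPhantomSpec, make_layered_volume,
                    make_vessel_volume, run_pipeline, train_unet,
                    write_volume)

tmp = Path(tempfile.mkdtemp(prefix="octa3d_demo_"))

# one structural phantom reused across days; train the tiny U-Net on it
struct_spec = LayeredPhantomSpec(shape=(32, 32, 24), depths=(6.0, 12.0, 26.0),
                                 boundary_amplitude=1.0, additive_sigma=0.01,
                                 seed=21)
svol, slabels = make_layered_volume(struct_spec)
model = train_unet(np.moveaxis(svol, 2, 0), np.moveaxis(slabels, 2, 0),
                   SegModelSpec(depth=2, base_channels=8, epochs=12, folds=2,
                                seed=0), cross_validate=False)

inputs = []
for day, n_tubes in enumerate((1, 2, 3)):
    xs = (16, 8, 24)
    tubes = tuple(Tube(points=((17, xs[k], 3), (17, xs[k], 20)), radius=2.0)
                  for k in range(n_tubes))
    avol, _, _ = make_vessel_volume(VesselPhantomSpec(
        shape=(32, 32, 24), tubes=tubes, gaussian_sigma=0.03,
        stripe_count=2, stripe_amplitude=0.3, seed=30 + day))
    spath, apath = tmp / f"s{day}.tif", tmp / f"a{day}.tif"
    write_volume(svol, spath)
    write_volume(avol, apath)
    inputs.append({"day": day, "structural": str(spath),
                   "angiographic": str(apath)})

config = RunConfig(inputs=inputs, output_dir=str(tmp / "out"), seed=0,
                   oof={"radii": [2, 3]}, vesselize={"min_volume": 10})
record = run_pipeline(config, model=model)

table = pd.read_csv(record.outputs["metrics"])
va = table[(table["parameter"] == "VA") & (table["dims"] == "3D")]
print(table[table["parameter"].isin(["VA", "VS", "VAD", "VSD"])]
      .to_string(index=False))
print(f"\n3D VA by day: {va.sort_values('day')['value'].tolist()} "
      "(strictly increasing with the simulated vessel growth)")
print(f"config hash {record.config_hash}; outputs under {tmp/'out'}")
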