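"""Skin-layer segmentation of structural volumes.

B-scans (axial Z x fast X cross-sections, sliced along the slow axis)
are contrast-enhanced with CLAHE and segmented into background /
epidermis / dermis by a small U-Net.  Per-slice predictions are
re-stacked into a 3D label volume, from which the three boundary
surfaces are extracted per A-line:

* AB1 — background-epidermal interface (first epidermis voxel),
* AB2 — epidermal-dermal junction (first dermis voxel),
* AB3 — dermal-background interface (one past the last dermis voxel).

Layer thickness maps are boundary differences scaled by the axial voxel
size.  Because background/tissue class frequencies are heavily
imbalanced, training uses weighted cross-entropy plus soft Dice, and
segmentation quality is judged by boundary position error rather than
raw pixel agreement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

from ._unet import UNet2D, ce_dice_loss, softmax
from .volume import as_array

__all__ = [
    "SegModelSpec", "SegModel", "BoundarySurfaces", "ThicknessMap",
    "clahe_enhance", "train_unet", "predict_labels",
    "extract_boundaries", "boundary_error", "thickness_stats",
]


# --------------------------------------------------------------------------
# CLAHE
# --------------------------------------------------------------------------

def clahe_enhance(bscan, clip_limit: float = 2.0,
                  tiles: tuple[int, int] = (8, 8), nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one B-scan.

    ``clip_limit`` is expressed as a multiple of the uniform histogram
    level (so 1.0 disables amplification limiting entirely only when
    very large; ~2-4 are typical).  Output is rescaled to [0, 1].
    Constant images are returned unchanged with a warning.
    """
    img = np.asarray(bscan, float)
    if img.ndim != 2:
        raise ValueError("B-scan must be 2D (Z x X)")
    if not np.all(np.isfinite(img)):
        raise ValueError("B-scan contains non-finite values")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant B-scan; CLAHE returns it unchanged", stacklevel=2)
        return np.clip(img, 0.0, 1.0)
    img01 = (img - lo) / (hi - lo)
    kernel = (max(1, img.shape[0] // tiles[0]), max(1, img.shape[1] // tiles[1]))
    # skimage clips at clip_limit * tile_pixels counts; the uniform level is
    # tile_pixels / nbins, so a uniform-level multiple k maps to k / nbins
    clip01 = min(1.0, float(clip_limit) / nbins)
    out = exposure.equalize_adapthist(img01, kernel_size=kernel,
                                      clip_limit=clip01, nbins=nbins)
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# model spec / training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegModelSpec:
    """U-Net training configuration.

    depth: number of 2x2 pooling stages; base_channels: channels at the
    top level; loss_weights: (cross-entropy, Dice) composite weights;
    folds: cross-validation folds (>= 2; partitions are disjoint and
    cover every sample once).
    """

    depth: int = 3
    base_channels: int = 16
    loss_weights: tuple[float, float] = (1.0, 1.0)
    epochs: int = 25
    folds: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class SegModel:
    """Trained segmentation model: network, input geometry, preprocessing.

    Prediction applies the same CLAHE + normalization used at training
    time, so raw B-scans/volumes can be fed directly.
    """

    net: UNet2D
    image_shape: tuple[int, int]
    norm: tuple[float, float]  # (offset, scale) applied as (x - offset) / scale
    clahe: bool = True
    clahe_params: tuple[float, int, int] = (2.0, 8, 8)
    spec: SegModelSpec | None = None
    history: dict = field(default_factory=dict)

    def preprocess(self, bscan) -> np.ndarray:
        img = np.asarray(bscan, float)
        if img.shape != self.image_shape:
            raise ValueError(
                f"B-scan shape {img.shape} != training geometry {self.image_shape}")
        if self.clahe:
            clip, tz, tx = self.clahe_params
            img = clahe_enhance(img, clip_limit=clip, tiles=(int(tz), int(tx)))
        return (img - self.norm[0]) / self.norm[1]

    def predict_bscan(self, bscan) -> np.ndarray:
        x = self.preprocess(bscan)[None, None]
        logits = self.net.forward(x)
        return np.argmax(logits[0], axis=0).astype(np.uint8)

    def save(self, path) -> None:
        cfg = {"net": self.net.config(), "image_shape": list(self.image_shape),
               "norm": list(self.norm), "clahe": self.clahe,
               "clahe_params": list(self.clahe_params)}
        arrs = {f"param/{k}": v for k, v in self.net.state_dict().items()}
        np.savez_compressed(path, __config__=json.dumps(cfg), **arrs)

    @classmethod
    def load(cls, path) -> "SegModel":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            net = UNet2D(**cfg["net"])
            net.load_state_dict(
                {k.split("/", 1)[1]: z[k] for k in z.files if k.startswith("param/")})
        return cls(net=net, image_shape=tuple(cfg["image_shape"]),
                   norm=tuple(cfg["norm"]), clahe=cfg.get("clahe", True),
                   clahe_params=tuple(cfg.get("clahe_params", (2.0, 8, 8))))


def _validate_training_data(bscans, labels):
    x = np.asarray(bscans, float)
    y = np.asarray(labels)
    if x.ndim != 3 or y.shape != x.shape:
        raise ValueError("bscans and labels must be matching (N, Z, X) stacks")
    if not np.all(np.isin(np.unique(y), (0, 1, 2))):
        raise ValueError("labels must take values in {0, 1, 2}")
    return x, y.astype(np.int64)


def _fit(net, x, y, spec, rng, val=None):
    """One training run; returns per-epoch loss/accuracy curves."""
    n = x.shape[0]
    w_ce, w_dice = spec.loss_weights
    curves = {"loss": [], "accuracy": [], "val_accuracy": []}
    cw = None
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct, ep_pix = 0.0, 0, 0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, yb = x[idx], y[idx]
            logits, cache = net.forward(xb, cache={})
            loss, dlogits, cw = ce_dice_loss(logits, yb, class_weights=cw,
                                             w_ce=w_ce, w_dice=w_dice)
            grads = net.backward(dlogits, cache)
            net.adam_step(grads, lr=spec.learning_rate)
            ep_loss += loss * len(idx)
            pred = logits.argmax(axis=1)
            ep_correct += int((pred == yb).sum())
            ep_pix += yb.size
        curves["loss"].append(ep_loss / n)
        curves["accuracy"].append(ep_correct / ep_pix)
        if val is not None:
            xv, yv = val
            pv = net.forward(xv).argmax(axis=1)
            curves["val_accuracy"].append(float((pv == yv).mean()))
    return curves


def train_unet(bscans, labels, spec: SegModelSpec | None = None,
               cross_validate: bool = True, clahe: bool = True,
               clahe_params: tuple[float, int, int] = (2.0, 8, 8)) -> SegModel:
    """Train the layer-segmentation U-Net on labelled B-scans.

    Raw B-scans are CLAHE-enhanced (unless ``clahe=False``) and
    normalized; the returned model stores the preprocessing so it can be
    fed raw data at inference.  Runs ``spec.folds``-fold cross-validation
    (disjoint partitions covering every sample once), recording
    loss/accuracy curves per fold, then fits the returned model on all
    samples.  Deterministic for a fixed ``spec.seed``.
    """
    spec = spec or SegModelSpec()
    x, y = _validate_training_data(bscans, labels)
    n = x.shape[0]
    if n < spec.folds:
        raise ValueError(f"need at least folds={spec.folds} labelled B-scans")
    if any(s % 2 ** spec.depth for s in x.shape[1:]):
        raise ValueError(
            f"B-scan dims {x.shape[1:]} must be divisible by 2**depth")

    if clahe:
        clip, tz, tx = clahe_params
        x = np.stack([clahe_enhance(b, clip_limit=clip, tiles=(int(tz), int(tx)))
                      for b in x])
    offset, scale = float(x.mean()), float(x.std() or 1.0)
    xn = ((x - offset) / scale)[:, None]  # (N,1,H,W)

    history: dict = {"folds": []}
    rng = np.random.default_rng(spec.seed)
    if cross_validate:
        perm = rng.permutation(n)
        parts = np.array_split(perm, spec.folds)
        for k, hold in enumerate(parts):
            tr = np.setdiff1d(perm, hold)
            net = UNet2D(depth=spec.depth, base=spec.base_channels,
                         seed=spec.seed + 100 + k)
            curves = _fit(net, xn[tr], y[tr], spec,
                          np.random.default_rng([spec.seed, k]),
                          val=(xn[hold], y[hold]))
            curves["val_indices"] = hold.tolist()
            history["folds"].append(curves)

    net = UNet2D(depth=spec.depth, base=spec.base_channels, seed=spec.seed)
    history["final"] = _fit(net, xn, y, spec,
                            np.random.default_rng([spec.seed, 999]))
    return SegModel(net=net, image_shape=x.shape[1:], norm=(offset, scale),
                    clahe=clahe, clahe_params=clahe_params,
                    spec=spec, history=history)


def predict_labels(model: SegModel, volume) -> np.ndarray:
    """Slice the volume along the slow axis, predict per B-scan, restack.

    Returns a (Z, X, Y) uint8 label volume (0 background, 1 epidermis,
    2 dermis).  Inference is deterministic for a fixed model.
    """
    v = np.asarray(as_array(volume), float)
    if v.ndim != 3:
        raise ValueError("expected a 3D volume")
    if v.shape[:2] != model.image_shape:
        raise ValueError(
            f"volume B-scan shape {v.shape[:2]} != training geometry "
            f"{model.image_shape}")
    xn = np.stack([model.preprocess(v[:, :, iy]) for iy in range(v.shape[2])])
    xn = xn[:, None]
    out = np.empty((v.shape[2],) + model.image_shape, np.uint8)
    for start in range(0, xn.shape[0], 16):
        logits = model.net.forward(xn[start:start + 16])
        out[start:start + 16] = logits.argmax(axis=1)
    return np.moveaxis(out, 0, 2)


def predict_proba_bscan(model: SegModel, bscan) -> np.ndarray:
    """Per-class softmax probabilities for one B-scan (K, Z, X)."""
    img = np.asarray(bscan, float)
    x = ((img - model.norm[0]) / model.norm[1])[None, None]
    return softmax(model.net.forward(x))[0]


# --------------------------------------------------------------------------
# boundaries and thickness
# --------------------------------------------------------------------------

@dataclass
class BoundarySurfaces:
    """Per-A-line axial boundary positions (NaN where undefined)."""

    ab1: np.ndarray
    ab2: np.ndarray
    ab3: np.ndarray
    qc_flags: dict = field(default_factory=dict)

    def defined(self) -> np.ndarray:
        return ~(np.isnan(self.ab1) | np.isnan(self.ab2) | np.isnan(self.ab3))


def _runs(col: np.ndarray, cls: int):
    """(start, stop) half-open runs of value cls in a 1D array."""
    m = np.concatenate([[0], (col == cls).astype(np.int8), [0]])
    d = np.diff(m)
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def extract_boundaries(labels) -> BoundarySurfaces:
    """Extract AB1/AB2/AB3 height fields from a label volume.

    Per A-line: AB1 = first epidermis voxel, AB2 = first dermis voxel,
    AB3 = one past the last dermis voxel.  A-lines with several runs of
    a class keep the longest run and are QC-flagged; A-lines missing a
    class are NaN, never interpolated.  Ordering AB1 <= AB2 <= AB3 is
    enforced on every defined column.
    """
    lab = np.asarray(as_array(labels))
    if lab.ndim != 3:
        raise ValueError("expected a 3D label volume")
    nz, nx, ny = lab.shape
    ab1 = np.full((nx, ny), np.nan)
    ab2 = np.full((nx, ny), np.nan)
    ab3 = np.full((nx, ny), np.nan)
    multi = np.zeros((nx, ny), bool)
    for ix in range(nx):
        for iy in range(ny):
            col = lab[:, ix, iy]
            runs1 = _runs(col, 1)
            runs2 = _runs(col, 2)
            if len(runs1) > 1 or len(runs2) > 1:
                multi[ix, iy] = True
            if runs1:
                s, e = max(runs1, key=lambda r: r[1] - r[0])
                ab1[ix, iy] = s
            if runs2:
                s, e = max(runs2, key=lambda r: r[1] - r[0])
                ab2[ix, iy] = s
                ab3[ix, iy] = e
    # enforce monotone ordering where defined
    both12 = ~np.isnan(ab1) & ~np.isnan(ab2)
    ab2[both12] = np.maximum(ab1[both12], ab2[both12])
    both23 = ~np.isnan(ab2) & ~np.isnan(ab3)
    ab3[both23] = np.maximum(ab2[both23], ab3[both23])
    qc = {"multi_run_columns": int(multi.sum()),
          "undefined_columns": int((np.isnan(ab1) | np.isnan(ab2)
                                    | np.isnan(ab3)).sum())}
    return BoundarySurfaces(ab1, ab2, ab3, qc)


def boundary_error(pred: BoundarySurfaces, truth: BoundarySurfaces) -> dict:
    """Mean absolute axial deviation (voxels) per boundary.

    Computed over the columns where both surfaces are defined; raises if
    a boundary has no commonly defined columns.
    """
    if pred.ab1.shape != truth.ab1.shape:
        raise ValueError("boundary surfaces are on different lateral grids")
    out = {}
    for name in ("ab1", "ab2", "ab3"):
        p, t = getattr(pred, name), getattr(truth, name)
        ok = ~np.isnan(p) & ~np.isnan(t)
        if not ok.any():
            raise ValueError(f"no commonly defined columns for {name}")
        out[name] = float(np.mean(np.abs(p[ok] - t[ok])))
    return out


@dataclass
class ThicknessMap:
    """Lateral thickness field of one layer, in micrometres."""

    layer: str
    values_um: np.ndarray
    mean: float
    variance: float

    @property
    def empty(self) -> bool:
        return not np.isfinite(self.mean)


def thickness_stats(labels, voxel_size_um: float = 5.0,
                    boundaries: BoundarySurfaces | None = None) -> dict:
    """Thickness maps and summaries for epidermis and dermis.

    thickness(x, y) = boundary difference (voxels) x axial voxel size.
    Undefined columns are NaN in the maps and excluded from the mean and
    variance; a layer with no defined column gets NaN summaries.
    """
    b = boundaries if boundaries is not None else extract_boundaries(labels)
    out = {}
    for layer, hi, lo in (("epidermis", b.ab2, b.ab1),
                          ("dermis", b.ab3, b.ab2)):
        vals = (hi - lo) * float(voxel_size_um)
        ok = ~np.isnan(vals)
        if ok.any():
            mean = float(vals[ok].mean())
            var = float(vals[ok].var())
        else:
            mean = var = float("nan")
        out[layer] = ThicknessMap(layer, vals, mean, var)
    return out
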