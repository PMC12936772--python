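"""Deep-learning autoencoder (DLA) features for lesion patches.

An unsupervised autoencoder is trained to reconstruct fixed-size 2-D
lesion patches through a low-dimensional bottleneck; the bottleneck
activations ("dla_00" .. "dla_31" at the default latent_dim = 32) are
used as imaging features, and decoding a traversal along one latent
coordinate visualises what that coordinate encodes (size, morphology).

The model is a fully-connected autoencoder implemented directly on
numpy: ReLU hidden layers, a linear bottleneck, a sigmoid output layer,
mean-squared reconstruction error minimised with Adam.  Training is
bit-deterministic given the seed (fixed initialisation and minibatch
order).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LesionVolume

DEFAULT_PATCH_SHAPE = (64, 64)
DEFAULT_HU_WINDOW = (-1000.0, 400.0)


@dataclass
class LesionPatch:
    """Fixed-size 2-D patch, intensities scaled to [0, 1]."""

    intensities: np.ndarray
    patient_id: str = "anon"
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("patch must be 2-D")
        lo, hi = self.intensities.min(), self.intensities.max()
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"patch values must lie in [0, 1], got [{lo}, {hi}]")


def extract_patch(
    volume: LesionVolume,
    patch_mm: float = 48.0,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
    patch_shape: tuple[int, int] = DEFAULT_PATCH_SHAPE,
    patient_id: str = "anon",
) -> LesionPatch:
    """Patch centred on the ROI centroid of the largest-ROI axial slice.

    A ``patch_mm`` x ``patch_mm`` window is resampled (bilinear) to
    ``patch_shape``; intensities are clipped to ``hu_window`` and then
    min-max scaled to [0, 1] (an all-constant patch maps to 0).  Regions
    outside the volume are zero-padded at the window floor, with a
    warning.
    """
    if not volume.mask.any():
        raise ValueError("mask is empty")
    idx = volume.largest_roi_slice()
    plane = volume.image[:, :, idx]
    sx, sy = volume.spacing[:2]
    cx, cy = ndimage.center_of_mass(volume.mask[:, :, idx])

    nx, ny = patch_shape
    xs = cx + (np.arange(nx) - (nx - 1) / 2) * (patch_mm / nx) / sx
    ys = cy + (np.arange(ny) - (ny - 1) / 2) * (patch_mm / ny) / sy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    if (gx.min() < 0 or gy.min() < 0
            or gx.max() > plane.shape[0] - 1 or gy.max() > plane.shape[1] - 1):
        warnings.warn(
            f"patch for {patient_id} extends outside the volume; zero-padding",
            stacklevel=2,
        )
    lo, hi = hu_window
    # clip before resampling so out-of-window values cannot bleed through
    # the bilinear interpolation at lesion boundaries
    patch = ndimage.map_coordinates(
        np.clip(plane, lo, hi), np.stack([gx, gy]), order=1, mode="constant", cval=lo
    )
    ptp = patch.max() - patch.min()
    patch = np.zeros_like(patch) if ptp == 0 else (patch - patch.min()) / ptp
    return LesionPatch(patch, patient_id=patient_id, slice_index=idx)


# ---------------------------------------------------------------------------
# the autoencoder


def _as_matrix(patches) -> np.ndarray:
    arrs = [p.intensities if isinstance(p, LesionPatch) else np.asarray(p) for p in patches]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"patches must share one shape, got {sorted(shapes)}")
    return np.stack([a.ravel() for a in arrs]).astype(np.float64)


@dataclass
class Autoencoder:
    """Fully-connected autoencoder state (weights, config, training curve)."""

    sizes: list[int]              # full layer widths, input .. latent .. output
    latent_index: int             # position of the bottleneck in `sizes`
    patch_shape: tuple[int, int]
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)

    @property
    def latent_dim(self) -> int:
        return self.sizes[self.latent_index]

    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Return pre-activations and activations per layer."""
        zs, acts = [], [x]
        a = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            zs.append(z)
            if i == last:
                a = 1.0 / (1.0 + np.exp(-z))       # sigmoid output
            elif i == self.latent_index - 1:
                a = z                               # linear bottleneck
            else:
                a = np.maximum(z, 0.0)              # ReLU hidden
            acts.append(a)
        return zs, acts

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(x))[1][-1]

    def mse(self, x: np.ndarray) -> float:
        xhat = self.reconstruct(x)
        return float(np.mean((xhat - np.atleast_2d(x)) ** 2))


def _init_model(
    n_in: int, latent_dim: int, hidden: tuple[int, ...], patch_shape, rng
) -> Autoencoder:
    sizes = [n_in, *hidden, latent_dim, *reversed(hidden), n_in]
    model = Autoencoder(sizes=sizes, latent_index=1 + len(hidden), patch_shape=patch_shape)
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)
        model.weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
        model.biases.append(np.zeros(fan_out))
    return model


def train_autoencoder(
    patches,
    latent_dim: int = 32,
    epochs: int = 30,
    seed: int = 0,
    hidden: tuple[int, ...] = (256,),
    lr: float = 1e-3,
    batch_size: int = 32,
) -> Autoencoder:
    """Train the autoencoder on a patch corpus (MSE, Adam).

    The per-epoch mean reconstruction MSE is recorded on
    ``model.loss_history``; element 0 is the untrained-model loss.
    """
    x = _as_matrix(patches)
    n, d = x.shape
    if n < 16:
        raise ValueError(f"need >= 16 patches to train, got {n}")
    if latent_dim >= d:
        raise ValueError(f"latent_dim={latent_dim} must be < flattened patch size {d}")
    patch_shape = (
        patches[0].intensities.shape
        if isinstance(patches[0], LesionPatch)
        else np.asarray(patches[0]).shape
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    model = _init_model(d, latent_dim, tuple(hidden), tuple(patch_shape), rng)
    model.loss_history.append(model.mse(x))

    # Adam state
    mw = [np.zeros_like(w) for w in model.weights]
    vw = [np.zeros_like(w) for w in model.weights]
    mb = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    last = len(model.weights) - 1

    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = x[order[start:start + batch_size]]
            zs, acts = model._forward(xb)
            # d(mean squared error)/d(output)
            delta = 2.0 * (acts[-1] - xb) / xb.size
            grads_w, grads_b = [None] * len(model.weights), [None] * len(model.biases)
            for i in range(last, -1, -1):
                if i == last:
                    s = acts[i + 1]
                    dz = delta * s * (1.0 - s)
                elif i == model.latent_index - 1:
                    dz = delta
                else:
                    dz = delta * (zs[i] > 0)
                grads_w[i] = acts[i].T @ dz
                grads_b[i] = dz.sum(axis=0)
                if i > 0:
                    delta = dz @ model.weights[i].T
            t += 1
            corr = np.sqrt(1 - b2**t) / (1 - b1**t)
            for i in range(len(model.weights)):
                mw[i] = b1 * mw[i] + (1 - b1) * grads_w[i]
                vw[i] = b2 * vw[i] + (1 - b2) * grads_w[i] ** 2
                model.weights[i] -= lr * corr * mw[i] / (np.sqrt(vw[i]) + eps)
                mb[i] = b1 * mb[i] + (1 - b1) * grads_b[i]
                vb[i] = b2 * vb[i] + (1 - b2) * grads_b[i] ** 2
                model.biases[i] -= lr * corr * mb[i] / (np.sqrt(vb[i]) + eps)
        model.loss_history.append(model.mse(x))
    return model


def _check_patch(model: Autoencoder, patch) -> np.ndarray:
    arr = patch.intensities if isinstance(patch, LesionPatch) else np.asarray(patch)
    if arr.shape != model.patch_shape:
        raise ValueError(f"patch shape {arr.shape} != model patch shape {model.patch_shape}")
    return arr.ravel()[None, :]


def encode(model: Autoencoder, patch) -> pd.Series:
    """Latent code of one patch, named dla_00 .. dla_<latent_dim-1>."""
    x = _check_patch(model, patch)
    _, acts = model._forward(x)
    z = acts[model.latent_index][0]
    return pd.Series(z, index=[f"dla_{i:02d}" for i in range(model.latent_dim)])


def encode_batch(model: Autoencoder, patches) -> pd.DataFrame:
    """Order-preserving latent codes for a patch list (rows = patient ids)."""
    x = _as_matrix(patches)
    if x.shape[1] != model.sizes[0]:
        raise ValueError("patch size does not match the trained model")
    _, acts = model._forward(x)
    z = acts[model.latent_index]
    ids = [
        p.patient_id if isinstance(p, LesionPatch) else str(i)
        for i, p in enumerate(patches)
    ]
    df = pd.DataFrame(z, index=ids, columns=[f"dla_{i:02d}" for i in range(model.latent_dim)])
    df.index.name = "patient_id"
    df.attrs["modality"] = "dla"
    return df


def decode(model: Autoencoder, z: np.ndarray) -> np.ndarray:
    """Decode a latent vector to a patch-shaped image in [0, 1]."""
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.size != model.latent_dim:
        raise ValueError(f"latent vector length {z.size} != latent_dim {model.latent_dim}")
    a = z[None, :]
    last = len(model.weights) - 1
    for i in range(model.latent_index, len(model.weights)):
        zi = a @ model.weights[i] + model.biases[i]
        a = 1.0 / (1.0 + np.exp(-zi)) if i == last else np.maximum(zi, 0.0)
    return a[0].reshape(model.patch_shape)


def latent_traversal(model: Autoencoder, patch, dim_index: int, values) -> list[np.ndarray]:
    """Decode the patch's code with one latent coordinate swept over `values`."""
    if not 0 <= dim_index < model.latent_dim:
        raise ValueError(f"dim_index {dim_index} out of range [0, {model.latent_dim})")
    z0 = encode(model, patch).to_numpy()
    images = []
    for v in values:
        z = z0.copy()
        z[dim_index] = v
        images.append(decode(model, z))
    return images


def save_model(model: Autoencoder, path: str | Path) -> None:
    """Single-file weight archive plus a JSON config sidecar."""
    path = Path(path)
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    np.savez(path, **arrays)
    cfg = {
        "sizes": model.sizes,
        "latent_index": model.latent_index,
        "patch_shape": list(model.patch_shape),
        "loss_history": model.loss_history,
    }
    path.with_suffix(".json").write_text(json.dumps(cfg))


def load_model(path: str | Path) -> Autoencoder:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    n_layers = len(cfg["sizes"]) - 1
    return Autoencoder(
        sizes=cfg["sizes"],
        latent_index=cfg["latent_index"],
        patch_shape=tuple(cfg["patch_shape"]),
        weights=[data[f"w{i}"] for i in range(n_layers)],
        biases=[data[f"b{i}"] for i in range(n_layers)],
        loss_history=list(cfg["loss_history"]),
    )
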