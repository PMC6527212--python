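"""Patch-based training of one orientation model.

Patches are sampled slice-wise along the model's orientation: a square
label window is drawn at a random in-slice position (half of the draws
centered inside the liver bounding box for class balance, half uniform),
and the network input is the label window grown by (RF − 1)/2 pixels per
side, reflect-padded wherever it reaches beyond the slice. Augmentation
applies in-plane rotations drawn from Normal(0, 10 deg) and global
intensity shifts from Normal(0, 0.1). The objective is the batch-
aggregated soft Dice loss under Adam; model quality is monitored as the
mean full-volume Jaccard over held-out validation cases every
``val_interval`` iterations, with early stopping after ``patience``
validations without improvement and the best-Jaccard checkpoint retained.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .imaging_io import ImageVolume, MaskVolume
from .model import ModelConfig, UNet2D, build_model, orientation_axis

logger = logging.getLogger(__name__)

EPS = 1e-5


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``patch_size`` is the label-window side before padding; the actual
    input side is ``patch_size + RF − 1`` (reflective padding of
    (RF − 1)/2 ≈ 46 pixels per side for the default model).
    """

    patch_size: int = 228
    batch_size: int = 16
    learning_rate: float = 1e-4
    val_interval: int = 500
    patience: int = 20
    rot_sigma_deg: float = 10.0
    intensity_shift_sigma: float = 0.1
    val_fraction: float = 0.2
    max_iterations: int | None = None
    liver_centered_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("patch_size, batch_size and learning_rate must be positive")
        if self.val_interval < 1 or self.patience < 1:
            raise ValueError("val_interval and patience must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.rot_sigma_deg < 0 or self.intensity_shift_sigma < 0:
            raise ValueError("augmentation scales must be >= 0")


@dataclass
class PatchBatch:
    inputs: np.ndarray   # (N, 1, H_in, W_in) padded image patches
    labels: np.ndarray   # (N, H_lab, W_lab) binary, aligned to the valid output
    orientation: str = "axial"


@dataclass
class TrainingHistory:
    iterations: list[int] = field(default_factory=list)
    val_jaccard: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)

    @property
    def best_jaccard(self) -> float:
        return max(self.val_jaccard) if self.val_jaccard else float("nan")

    def to_dict(self) -> dict:
        return {"iterations": self.iterations, "val_jaccard": self.val_jaccard}


def _slice2d(arr: np.ndarray, index: int, axis: int) -> np.ndarray:
    return np.take(arr, index, axis=axis)


def _window(slice2d: np.ndarray, top: int, left: int, size: int) -> np.ndarray:
    """Square window with reflective padding where it leaves the slice."""
    h, w = slice2d.shape
    pt, pl = max(0, -top), max(0, -left)
    pb, pr = max(0, top + size - h), max(0, left + size - w)
    arr = slice2d
    off_t, off_l = top, left
    while pt or pl or pb or pr:
        ph, pw = arr.shape
        t, b = min(pt, ph - 1), min(pb, ph - 1)
        l, r = min(pl, pw - 1), min(pr, pw - 1)
        arr = np.pad(arr, ((t, b), (l, r)), mode="reflect")
        off_t += t
        off_l += l
        pt -= t; pb -= b; pl -= l; pr -= r
    return arr[off_t:off_t + size, off_l:off_l + size]


def sample_patch_batch(cases: list[tuple[ImageVolume, MaskVolume]], orientation: str,
                       config: TrainConfig, model: UNet2D,
                       rng: np.random.Generator) -> PatchBatch:
    """Draw one mini-batch of aligned (input, label) patch pairs.

    Cases must already be preprocessed (isotropic, normalized). The input
    window side is derived from the built model so that the network's
    valid output window coincides exactly with the label window.
    """
    if not cases:
        raise ValueError("no training cases given")
    config.validate()
    label_size = model.next_valid_input(config.patch_size + model.receptive_field - 1) \
        - (model.receptive_field - 1)
    input_size = label_size + model.receptive_field - 1
    pad = (model.receptive_field - 1) // 2
    axis = orientation_axis(orientation, cases[0][0].geometry)

    inputs = np.empty((config.batch_size, 1, input_size, input_size))
    labels = np.empty((config.batch_size, label_size, label_size), dtype=np.uint8)
    for k in range(config.batch_size):
        image, mask = cases[rng.integers(len(cases))]
        n_slices = image.voxels.shape[axis]
        liver_centered = rng.random() < config.liver_centered_fraction
        fg = np.argwhere(mask.voxels)
        if liver_centered and len(fg):
            lo, hi = fg.min(axis=0), fg.max(axis=0)
            idx = int(rng.integers(lo[axis], hi[axis] + 1))
            img2d = _slice2d(image.voxels, idx, axis)
            in_plane = [a for a in range(3) if a != axis]
            center = [int(rng.integers(lo[a], hi[a] + 1)) for a in in_plane]
            top = center[0] - label_size // 2
            left = center[1] - label_size // 2
        else:
            idx = int(rng.integers(n_slices))
            img2d = _slice2d(image.voxels, idx, axis)
            top = int(rng.integers(-label_size // 2, img2d.shape[0] - label_size // 2))
            left = int(rng.integers(-label_size // 2, img2d.shape[1] - label_size // 2))
        msk2d = _slice2d(mask.voxels, idx, axis)
        inputs[k, 0] = _window(img2d, top - pad, left - pad, input_size)
        labels[k] = _window(msk2d, top, left, label_size)
    return PatchBatch(inputs=inputs, labels=labels, orientation=orientation)


def draw_augmentation_params(config: TrainConfig, rng: np.random.Generator,
                             n: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotation angles (deg) ~ N(0, rot_sigma) and intensity shifts
    ~ N(0, intensity_shift_sigma) for ``n`` samples."""
    angles = rng.normal(0.0, config.rot_sigma_deg, n)
    shifts = rng.normal(0.0, config.intensity_shift_sigma, n)
    return angles, shifts


def augment(batch: PatchBatch, config: TrainConfig, rng: np.random.Generator) -> PatchBatch:
    """In-plane rotation (image linear, label nearest) and uniform
    intensity shift; intensities are not re-clipped, labels stay binary."""
    n = batch.inputs.shape[0]
    angles, shifts = draw_augmentation_params(config, rng, n)
    inputs = batch.inputs.copy()
    labels = batch.labels.copy()
    for k in range(n):
        if angles[k] != 0.0:
            inputs[k, 0] = ndimage.rotate(inputs[k, 0], angles[k], reshape=False,
                                          order=1, mode="reflect")
            labels[k] = ndimage.rotate(labels[k], angles[k], reshape=False,
                                       order=0, mode="reflect")
        inputs[k] += shifts[k]
    return PatchBatch(inputs=inputs, labels=labels, orientation=batch.orientation)


def soft_dice_loss(pred, labels):
    """Batch-aggregated soft Dice loss 1 − (2·Σpg + ε)/(Σp + Σg + ε).

    ``pred`` may be an autodiff tensor (training) or a plain array;
    ``labels`` is binary. The ε = 1e-5 smoothing makes the empty-empty
    case a perfect (zero-loss) prediction.
    """
    g = np.asarray(labels, dtype=np.float64)
    if isinstance(pred, nn.Tensor):
        if pred.data.shape != g.shape:
            raise ValueError(f"shape mismatch: pred {pred.data.shape}, labels {g.shape}")
        inter = (pred * g).sum()
        return 1.0 - (inter * 2.0 + EPS) / (pred.sum() + g.sum() + EPS)
    pred = np.asarray(pred, dtype=np.float64)
    if pred.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, labels {g.shape}")
    return float(1.0 - (2.0 * (pred * g).sum() + EPS) / (pred.sum() + g.sum() + EPS))


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B| for binary arrays; both empty gives 1."""
    a = np.asarray(getattr(a, "voxels", a)).astype(bool)
    b = np.asarray(getattr(b, "voxels", b)).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def split_cases(cases, val_fraction: float, rng: np.random.Generator):
    """Seeded case-level train/validation split (at least one case each)."""
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 cases (1 train + 1 validation)")
    order = rng.permutation(n)
    n_val = min(max(1, int(round(n * val_fraction))), n - 1)
    val_idx = set(order[:n_val].tolist())
    train = [cases[i] for i in range(n) if i not in val_idx]
    val = [cases[i] for i in range(n) if i in val_idx]
    return train, val


def train_orientation_model(cases: list[tuple[ImageVolume, MaskVolume]],
                            orientation: str,
                            model_config: ModelConfig | None = None,
                            train_config: TrainConfig | None = None,
                            ) -> tuple[UNet2D, TrainingHistory]:
    """Train one orientation model with soft-Dice/Adam and Jaccard-based
    early stopping; returns the best-validation-Jaccard checkpoint."""
    from .inference import predict_orientation  # cycle-free at call time

    train_config = train_config or TrainConfig()
    train_config.validate()
    rng = np.random.Generator(np.random.PCG64(train_config.seed))
    model = build_model(model_config, seed=int(rng.integers(2 ** 31)))
    train_cases, val_cases = split_cases(cases, train_config.val_fraction, rng)

    optimizer = nn.Adam(model.params(), lr=train_config.learning_rate)
    history = TrainingHistory()
    best_state, best_j, since_best = None, -np.inf, 0
    iteration = 0
    while True:
        iteration += 1
        model.train(True)
        batch = sample_patch_batch(train_cases, orientation, train_config, model, rng)
        batch = augment(batch, train_config, rng)
        probs = model.forward(batch.inputs)
        loss = soft_dice_loss(_fg(probs), batch.labels)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss {loss.data} at iteration {iteration}; aborting")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        history.loss.append(float(loss.data))

        stop = (train_config.max_iterations is not None
                and iteration >= train_config.max_iterations)
        if iteration % train_config.val_interval == 0 or stop:
            model.eval()
            js = [jaccard(predict_orientation(model, img, orientation).voxels, msk.voxels)
                  for img, msk in val_cases]
            j = float(np.mean(js))
            history.iterations.append(iteration)
            history.val_jaccard.append(j)
            logger.info("iter %d: validation Jaccard %.4f (best %.4f)", iteration, j,
                        max(best_j, j))
            if j > best_j:
                best_j, since_best = j, 0
                best_state = copy.deepcopy(model.state_arrays())
            else:
                since_best += 1
            if since_best >= train_config.patience or stop:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history


def _fg(probs: nn.Tensor) -> nn.Tensor:
    """Foreground-channel slice of (N, 2, h, w) class probabilities."""
    data = probs.data[:, 1]

    def bw(g):
        full = np.zeros_like(probs.data)
        full[:, 1] = g
        return (full,)

    return nn.Tensor(data, (probs,), bw)
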