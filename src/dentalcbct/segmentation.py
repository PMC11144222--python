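"""3-D U-Net tooth segmentation: model, training protocol and DSC evaluation.

The network follows a U-Net encoder-decoder: each encoder level applies a
3x3x3 convolution (batch norm + ReLU) followed by a 3x3x3 stride-2
downsampling convolution (batch norm + LeakyReLU); the decoder restores
resolution with 2x2x2 nearest-neighbour upsampling, concatenates the skip
connection and convolves again; a final 1x1x1 convolution with a sigmoid
emits a single-channel probability map, thresholded at 0.5 (ties to
foreground) for the binary mask.

Training follows a resampled-rounds protocol: each round draws a fixed
number of samples from the corpus, splits them into train/validation,
optimizes a soft-Dice loss with Adam for a fixed number of epochs, and
keeps the best-validation-Dice model before the next round redraws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .dataset_factory import ToothSample


@dataclasses.dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters; input must be divisible by 2**levels."""

    input_size: int = 128
    levels: int = 4
    base_channels: int = 16
    leaky_slope: float = 0.01
    init_seed: int = 0

    def __post_init__(self):
        if self.levels < 1 or self.base_channels < 1:
            raise ValueError("levels and base_channels must be >= 1")
        if self.input_size % (2**self.levels) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^{self.levels}"
            )


class UNet3D:
    """U-Net over [N, 1, S, S, S] volumes producing per-voxel probabilities."""

    def __init__(self, spec: UNetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        base, levels = spec.base_channels, spec.levels
        ch = lambda l: base * 2**l  # noqa: E731
        self.enc = [
            nn.Sequential(
                nn.Conv3d(1 if l == 0 else ch(l), ch(l), 3, 1, rng),
                nn.BatchNorm3d(ch(l)),
                nn.ReLU(),
            )
            for l in range(levels)
        ]
        self.down = [
            nn.Sequential(
                nn.Conv3d(ch(l), ch(l + 1), 3, 2, rng),
                nn.BatchNorm3d(ch(l + 1)),
                nn.LeakyReLU(spec.leaky_slope),
            )
            for l in range(levels)
        ]
        self.bottleneck = nn.Sequential(
            nn.Conv3d(ch(levels), ch(levels), 3, 1, rng),
            nn.BatchNorm3d(ch(levels)),
            nn.ReLU(),
        )
        self.up = [nn.NearestUpsample3d() for _ in range(levels)]
        self.dec = [
            nn.Sequential(
                nn.Conv3d(ch(l) + ch(l + 1), ch(l), 3, 1, rng),
                nn.BatchNorm3d(ch(l)),
                nn.ReLU(),
            )
            for l in range(levels)
        ]
        self.head = nn.Sequential(nn.Conv3d(base, 1, 1, 1, rng), nn.Sigmoid())

    def _all_layers(self) -> list[nn.Layer]:
        return [*self.enc, *self.down, self.bottleneck, *self.up, *self.dec, self.head]

    def parameters(self) -> list[nn.Parameter]:
        return [p for layer in self._all_layers() for p in layer.parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        levels = self.spec.levels
        if x.ndim != 5 or x.shape[1] != 1 or len(set(x.shape[2:])) != 1:
            raise ValueError(f"expected [N, 1, S, S, S] input, got {x.shape}")
        if x.shape[2] % (2**levels) != 0:
            raise ValueError(
                f"input size {x.shape[2]} not divisible by 2^{levels}"
            )
        x = np.asarray(x, dtype=np.float32)
        skips = []
        for l in range(levels):
            x = self.enc[l].forward(x, train)
            skips.append(x)
            x = self.down[l].forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for l in reversed(range(levels)):
            x = self.up[l].forward(x, train)
            x = np.concatenate([skips[l], x], axis=1)
            x = self.dec[l].forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        levels = self.spec.levels
        grad = self.head.backward(grad)
        skip_grads: list[np.ndarray | None] = [None] * levels
        for l in range(levels):
            grad = self.dec[l].backward(grad)
            sc = self._skip_channels[l]
            skip_grads[l] = grad[:, :sc]
            grad = self.up[l].backward(grad[:, sc:])
        grad = self.bottleneck.backward(grad)
        for l in reversed(range(levels)):
            grad = self.down[l].backward(grad)
            grad = grad + skip_grads[l]
            grad = self.enc[l].backward(grad)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        state = nn.get_state(self._all_layers())
        np.savez_compressed(path, **{f"s{i}": a for i, a in enumerate(state)})
        path.with_suffix(".json").write_text(json.dumps(dataclasses.asdict(self.spec)))

    @classmethod
    def load(cls, path) -> "UNet3D":
        path = Path(path)
        spec = UNetSpec(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(spec)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
            state = [data[f"s{i}"] for i in range(len(data.files))]
        nn.set_state(model._all_layers(), state)
        return model


def build_unet(spec: UNetSpec) -> UNet3D:
    """Construct the U-Net; raises if the input size is not divisible by
    2**levels."""
    return UNet3D(spec)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-sample min-max normalization to [0, 1] (condition-robust input)."""
    image = np.asarray(image, dtype=np.float32)
    lo, hi = float(image.min()), float(image.max())
    return (image - lo) / (hi - lo + 1e-6)


def _to_pair(sample) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sample, ToothSample):
        return normalize_image(sample.image), sample.mask.astype(np.float32)
    image, mask = sample
    return normalize_image(image), np.asarray(mask, dtype=np.float32)


def load_corpus(corpus_dir, holdout_teeth: Sequence[int] = (), invert: bool = False):
    """Load ToothSamples from a generated corpus directory.

    ``holdout_teeth`` filters those tooth IDs out (train split); with
    ``invert=True`` only the held-out teeth are returned (test split).
    """
    import h5py

    corpus_dir = Path(corpus_dir)
    manifest = pd.read_csv(corpus_dir / "manifest.csv")
    manifest = manifest[manifest["status"] == "ok"]
    if holdout_teeth:
        held = manifest["tooth_id"].isin(list(holdout_teeth))
        manifest = manifest[held] if invert else manifest[~held]
    samples = []
    for file_name, sub in manifest.groupby("file"):
        with h5py.File(corpus_dir / file_name, "r") as fh:
            for rec in sub.to_dict("records"):
                i = int(rec["index_in_shard"])
                samples.append(
                    ToothSample(
                        image=fh["image"][i],
                        mask=fh["mask"][i].astype(bool),
                        meta={
                            "tooth_id": int(rec["tooth_id"]),
                            "sample_id": rec["sample_id"],
                            "condition_index": int(rec["condition_index"]),
                        },
                    )
                )
    return samples


@dataclasses.dataclass(frozen=True)
class TrainProtocol:
    """Resampled-rounds training protocol.

    Defaults mirror the full-scale recipe (rounds of 500 samples, 80% train,
    ~50 epochs per round, ~2000 total); scaled-down values are what the
    tests and desk runs use.
    """

    round_size: int = 500
    train_fraction: float = 0.8
    epochs_per_round: int = 50
    total_epochs: int = 2000
    batch_size: int = 2
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.total_epochs < self.epochs_per_round:
            raise ValueError("total_epochs must be >= epochs_per_round")
        if self.round_size < 1 or self.batch_size < 1:
            raise ValueError("round_size and batch_size must be >= 1")


def train(
    model: UNet3D,
    samples: Sequence,
    protocol: TrainProtocol,
    progress: bool = False,
) -> dict:
    """Train in resampled rounds; keeps the best-validation-Dice state.

    ``samples`` is a sequence of :class:`ToothSample` or (image, mask)
    pairs.  Returns a history dict with per-epoch training losses and
    validation Dice scores.
    """
    if len(samples) == 0:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(protocol.seed)
    optimizer = nn.Adam(model.parameters(), lr=protocol.learning_rate)
    n_rounds = math.ceil(protocol.total_epochs / protocol.epochs_per_round)
    history = {"train_loss": [], "val_dice": [], "round": []}
    layers = model._all_layers()
    best_state = nn.get_state(layers)
    epoch_iter = range(n_rounds)
    if progress:
        from tqdm import tqdm

        epoch_iter = tqdm(epoch_iter, desc="rounds")
    for rnd in epoch_iter:
        draw_size = min(protocol.round_size, len(samples))
        draw = rng.choice(len(samples), size=draw_size, replace=False)
        n_train = max(1, int(round(protocol.train_fraction * draw_size)))
        if n_train == draw_size and draw_size > 1:
            n_train -= 1
        train_idx, val_idx = draw[:n_train], draw[n_train:]
        train_set = [_to_pair(samples[i]) for i in train_idx]
        val_set = [_to_pair(samples[i]) for i in val_idx]
        best_val = -1.0
        epochs = min(protocol.epochs_per_round, protocol.total_epochs - rnd * protocol.epochs_per_round)
        for _epoch in range(epochs):
            order = rng.permutation(len(train_set))
            losses = []
            for start in range(0, len(order), protocol.batch_size):
                batch = [train_set[i] for i in order[start : start + protocol.batch_size]]
                x = np.stack([b[0] for b in batch])[:, None]
                y = np.stack([b[1] for b in batch])[:, None]
                probs = model.forward(x, train=True)
                loss, dprobs = nn.soft_dice_loss(probs, y)
                optimizer.zero_grad()
                model.backward(dprobs)
                optimizer.step()
                losses.append(float(loss))
            history["train_loss"].append(float(np.mean(losses)))
            history["round"].append(rnd)
            if val_set:
                scores = [
                    dice(predict_mask(model, img), msk > 0.5) for img, msk in val_set
                ]
                val = float(np.mean(scores))
            else:
                val = 1.0 - history["train_loss"][-1]
            history["val_dice"].append(val)
            if val >= best_val:
                best_val = val
                best_state = nn.get_state(layers)
        nn.set_state(layers, best_state)
    return history


def predict_mask(model: UNet3D, image: np.ndarray) -> np.ndarray:
    """Probability map thresholded at 0.5 (0.5 itself is foreground)."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a 3-D image, got shape {image.shape}")
    probs = model.forward(normalize_image(image)[None, None], train=False)
    return probs[0, 0] >= 0.5


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|); 1.0 when both empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    total = int(pred.sum()) + int(truth.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / total


@dataclasses.dataclass
class DiceReport:
    """Per-sample DSC scores with mean +- population standard deviation."""

    scores: list[float]
    model_label: str
    input_label: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def std(self) -> float:
        return float(np.std(self.scores))  # population std

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": range(len(self.scores)),
                "model": self.model_label,
                "input": self.input_label,
                "dsc": self.scores,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate(
    model: UNet3D,
    samples: Sequence,
    model_label: str = "virtual",
    input_label: str = "virtual",
) -> DiceReport:
    """Per-sample DSC via predict_mask on each test sample."""
    if len(samples) == 0:
        raise ValueError("need at least one test sample")
    scores = []
    for sample in samples:
        image, mask = _to_pair(sample)
        scores.append(dice(predict_mask(model, image), mask > 0.5))
    return DiceReport(scores=scores, model_label=model_label, input_label=input_label)
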