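"""2.5D multi-decoder segmentation network and Dice metrics.

Three independent 2D networks — one per orthogonal slice orientation —
share a common topology: a single convolutional encoder and nine parallel
decoders, one output per tissue class plus background.  Counting
convolution, pooling, transposed-convolution and output layers, an
encoder-decoder path has 23 layers of which 6 are 2x2 max-pooling steps;
the first convolution encodes 8 feature maps and the width doubles after
every pooling.  Decoder widths start from a cap of ``base_features * 2^(P-2)``
and halve per upsampling level (floor at ``base_features``), with three
width-preserving 3x3 refinement convolutions; this reconciles the stated
topology with a total of ~5 million trainable parameters per 2D network
(4,774,353 at the defaults; the closed-form count is asserted in tests).

Volumes are segmented by summing the three orientations' probability maps
and taking the per-voxel argmax; voxels on which no decoder fired at all
receive the modal label of their 26-neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    MaxPool2D,
    ReLU,
    Sequential,
    Sigmoid,
)
from .volumes import (
    ORIENTATION_AXIS,
    ImageVolume,
    LabelVolume,
    TISSUE_NAMES,
    check_same_geometry,
)

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "SliceBatch",
    "ForkNet",
    "build_network",
    "slice_volumes",
    "dice",
    "dice_loss",
    "train",
    "predict_volume",
    "fuse_2p5d",
    "evaluate_segmentation",
    "leave_one_out_folds",
    "ORIENTATIONS",
]

log = logging.getLogger(__name__)

ORIENTATIONS = ("transverse", "coronal", "sagittal")
N_CLASSES = 9


@dataclass
class NetworkSpec:
    """Topology of one 2D network (fully convolutional).

    ``skip_connections`` adds encoder-to-decoder additive skips through 1x1
    projections at the refinement levels.  The default (off) is the plain
    multi-decoder topology; the scaled-down study enables skips to recover
    fine structure within its much smaller optimization budget.
    """

    base_features: int = 8
    pooling_steps: int = 6
    decoders: int = 9
    refine_convs: int = 3
    skip_connections: bool = False
    bn_momentum: float = 0.9
    bn_eps: float = 1e-3

    @property
    def encoder_widths(self) -> list[int]:
        return [self.base_features * 2**d for d in range(self.pooling_steps + 1)]

    @property
    def decoder_widths(self) -> list[int]:
        cap = self.base_features * 2 ** max(self.pooling_steps - 2, 0)
        return [max(cap >> i, self.base_features) for i in range(self.pooling_steps)]

    @property
    def n_refine(self) -> int:
        # refinement convs sit after the 2nd..4th deconvs where they exist
        return min(self.refine_convs, max(self.pooling_steps - 1, 0))

    @property
    def total_layers(self) -> int:
        """Layers along one encoder-decoder path (convs, pools, deconvs,
        output conv; normalization/activations not counted)."""
        encoder = 1 + 2 * self.pooling_steps
        decoder = self.pooling_steps + self.n_refine + 1
        return encoder + decoder

    @property
    def divisor(self) -> int:
        return 2**self.pooling_steps

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    batch_size: int = 10
    epochs: int = 40
    train_fraction: float = 0.9
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine" (decay to ~0 over the run)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


class _DecoderBlock:
    """One decoder upsampling level: deconv + BN + ReLU, an optional
    additive encoder skip through a 1x1 projection, and an optional 3x3
    refinement conv stack."""

    def __init__(self, c_in, w, enc_width, refine, skip, spec, rng):
        self.up = Sequential(
            [
                ConvTranspose2D(c_in, w, rng),
                BatchNorm2D(w, spec.bn_momentum, spec.bn_eps),
                ReLU(),
            ]
        )
        self.proj = Conv2D(enc_width, w, 1, rng) if skip else None
        self.refine = (
            Sequential(
                [
                    Conv2D(w, w, 3, rng),
                    BatchNorm2D(w, spec.bn_momentum, spec.bn_eps),
                    ReLU(),
                ]
            )
            if refine
            else None
        )

    def params(self):
        out = self.up.params()
        if self.proj is not None:
            out.extend(self.proj.params())
        if self.refine is not None:
            out.extend(self.refine.params())
        return out

    def forward(self, x, enc_feat, training):
        x = self.up.forward(x, training)
        if self.proj is not None:
            x = x + self.proj.forward(enc_feat, training)
        if self.refine is not None:
            x = self.refine.forward(x, training)
        return x

    def backward(self, dy):
        """Returns (dx, d_enc_feat or None)."""
        if self.refine is not None:
            dy = self.refine.backward(dy)
        d_enc = self.proj.backward(dy) if self.proj is not None else None
        return self.up.backward(dy), d_enc


class ForkNet:
    """One common encoder feeding ``spec.decoders`` parallel decoders."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.encoder_widths
        self.enc_stages = [
            Sequential(
                [
                    Conv2D(1, f[0], 3, rng),
                    BatchNorm2D(f[0], spec.bn_momentum, spec.bn_eps),
                    ReLU(),
                ]
            )
        ]
        for d in range(1, spec.pooling_steps + 1):
            self.enc_stages.append(
                Sequential(
                    [
                        MaxPool2D(),
                        Conv2D(f[d - 1], f[d], 3, rng),
                        BatchNorm2D(f[d], spec.bn_momentum, spec.bn_eps),
                        ReLU(),
                    ]
                )
            )

        widths = spec.decoder_widths
        refine_at = set(range(1, 1 + spec.n_refine))  # after 2nd..4th deconv
        self.decoders = []
        self.out_heads = []
        for _ in range(spec.decoders):
            blocks = []
            c_in = f[-1]
            for i, w in enumerate(widths):
                # encoder feature at the resolution this block produces
                enc_width = f[spec.pooling_steps - 1 - i]
                blocks.append(
                    _DecoderBlock(
                        c_in,
                        w,
                        enc_width,
                        refine=i in refine_at,
                        skip=spec.skip_connections and i in refine_at,
                        spec=spec,
                        rng=rng,
                    )
                )
                c_in = w
            out_conv = Conv2D(c_in, 1, 1, rng)
            # start each decoder quiet: with sigmoid outputs near 0 the
            # soft-Dice gradients of small classes are not swamped early on
            out_conv.b[...] = -2.0
            self.decoders.append(blocks)
            self.out_heads.append(Sequential([out_conv, Sigmoid()]))
        self._feats = None

    def params(self):
        out = []
        for stage in self.enc_stages:
            out.extend(stage.params())
        for blocks, head in zip(self.decoders, self.out_heads):
            for b in blocks:
                out.extend(b.params())
            out.extend(head.params())
        return out

    def count_params(self) -> int:
        """Total number of trainable parameters (weights, biases and
        batch-normalization scale/shift)."""
        return int(sum(p.size for p, _ in self.params()))

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        d = self.spec.divisor
        if h % d or w % d:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{self.spec.pooling_steps}"
            )
        feats = []
        for stage in self.enc_stages:
            x = stage.forward(x, training)
            feats.append(x)
        self._feats = feats
        P = self.spec.pooling_steps
        outs = []
        for blocks, head in zip(self.decoders, self.out_heads):
            z = feats[-1]
            for i, block in enumerate(blocks):
                z = block.forward(z, feats[P - 1 - i], training)
            outs.append(head.forward(z, training))
        return np.concatenate(outs, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        P = self.spec.pooling_steps
        d_feats = [None] * (P + 1)

        def inject(level, g):
            if d_feats[level] is None:
                d_feats[level] = g.copy()
            else:
                d_feats[level] += g

        for di, (blocks, head) in enumerate(zip(self.decoders, self.out_heads)):
            g = head.backward(dy[:, di : di + 1])
            for i in reversed(range(len(blocks))):
                g, d_enc = blocks[i].backward(g)
                if d_enc is not None:
                    inject(P - 1 - i, d_enc)
            inject(P, g)
        g = d_feats[P]
        for level in reversed(range(len(self.enc_stages))):
            if level < P and d_feats[level] is not None:
                g = g + d_feats[level]
            g = self.enc_stages[level].backward(g)
        return g


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> ForkNet:
    """Instantiate a trainable multi-decoder network from its spec."""
    return ForkNet(spec or NetworkSpec(), seed)


# ---------------------------------------------------------------------------
# data handling


@dataclass
class SliceBatch:
    """2D slices of a set of volumes along one orientation.

    ``labels`` are stored as integer maps; one-hot targets (which partition
    each slice into the 9 classes) are materialized per mini-batch by
    :meth:`one_hot`.
    """

    images: np.ndarray  # (S, h, w) float32
    labels: np.ndarray  # (S, h, w) int16
    orientation: str

    def __len__(self) -> int:
        return self.images.shape[0]

    def one_hot(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (images (b,1,h,w), targets (b,9,h,w)) for the given slice
        indices."""
        x = self.images[idx][:, None].astype(np.float32)
        lab = self.labels[idx]
        t = np.zeros((len(idx), N_CLASSES) + lab.shape[1:], dtype=np.float32)
        for c in range(N_CLASSES):
            t[:, c] = lab == c
        return x, t


def _normalize_volume(grid: np.ndarray) -> np.ndarray:
    """Per-volume scaling by the 99th-percentile intensity."""
    p99 = np.percentile(grid, 99)
    return (grid / p99 if p99 > 0 else grid).astype(np.float32)


def slice_volumes(
    volumes: list[tuple[ImageVolume, LabelVolume]],
    orientation: str,
    seed: int | None = None,
) -> SliceBatch:
    """Cut volumes into 2D slices along one orientation.

    The slice count is ``len(volumes) * axis_length``; slices are paired
    with their label maps and the order is randomized when a seed is given.
    """
    if orientation not in ORIENTATION_AXIS:
        raise ValueError(f"unknown orientation {orientation!r}")
    axis = ORIENTATION_AXIS[orientation]
    shape = volumes[0][0].shape
    imgs, labs = [], []
    for img, lab in volumes:
        if img.shape != shape or lab.shape != shape:
            raise ValueError(
                f"volume shape mismatch: {img.shape}/{lab.shape} vs {shape}"
            )
        imgs.append(np.moveaxis(_normalize_volume(img.grid), axis, 0))
        labs.append(np.moveaxis(lab.grid, axis, 0))
    images = np.concatenate(imgs, axis=0)
    labels = np.concatenate(labs, axis=0).astype(np.int16)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(images.shape[0])
        images, labels = images[order], labels[order]
    return SliceBatch(images, labels, orientation)


# ---------------------------------------------------------------------------
# metrics and loss


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|a&b| / (|a|+|b|)``; 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def dice_loss(
    pred: np.ndarray, target: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """Soft-Dice loss over the decoder outputs, with its gradient.

    ``1 - mean_c (2*sum(p*t)+s) / (sum(p)+sum(t)+s)`` aggregated over the
    batch per class; returns ``(loss, dloss/dpred)``.
    """
    if pred.shape != target.shape:
        raise ValueError("pred/target shape mismatch")
    c = pred.shape[1]
    axes = (0, 2, 3)
    inter = (pred * target).sum(axis=axes)
    num = 2.0 * inter + smooth
    den = pred.sum(axis=axes) + target.sum(axis=axes) + smooth
    loss = 1.0 - float(np.mean(num / den))
    grad = -(2.0 * target * den[None, :, None, None] - num[None, :, None, None]) / (
        c * den[None, :, None, None] ** 2
    )
    return loss, grad.astype(pred.dtype)


# ---------------------------------------------------------------------------
# training and inference


def _eval_loss(net: ForkNet, batch: SliceBatch, idx: np.ndarray, bs: int) -> float:
    losses = []
    for s in range(0, len(idx), bs):
        x, t = batch.one_hot(idx[s : s + bs])
        p = net.forward(x, training=False)
        losses.append(dice_loss(p, t)[0])
    return float(np.mean(losses)) if losses else float("nan")


def train(
    volumes: list[tuple[ImageVolume, LabelVolume]],
    config: TrainConfig,
    spec: NetworkSpec | None = None,
    orientations: tuple[str, ...] = ORIENTATIONS,
) -> tuple[dict[str, ForkNet], dict[str, dict]]:
    """Train one 2D network per slice orientation.

    The caller is responsible for excluding the test subject from
    ``volumes`` (leave-one-out contract).  Slices are shuffled by the
    config seed, split into train/validation by ``train_fraction``, and
    optimized with Adam on the soft-Dice loss in mini-batches.  Fully
    deterministic for a fixed seed.
    """
    if not volumes:
        raise ValueError("empty training set")
    spec = spec or NetworkSpec()
    nets: dict[str, ForkNet] = {}
    history: dict[str, dict] = {}
    for oi, orientation in enumerate(orientations):
        batch = slice_volumes(volumes, orientation, seed=config.seed + 101 * oi)
        n_train = int(round(config.train_fraction * len(batch)))
        n_train = min(max(n_train, 1), len(batch) - 1) if len(batch) > 1 else len(batch)
        train_idx = np.arange(n_train)
        val_idx = np.arange(n_train, len(batch))
        net = build_network(spec, seed=config.seed + 1000 + oi)
        opt = Adam(net.params(), lr=config.learning_rate)
        rng = np.random.default_rng(config.seed + 2000 + oi)
        hist = {"train_loss": [], "val_loss": []}
        for _epoch in range(config.epochs):
            if config.lr_schedule == "cosine":
                opt.lr = config.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * _epoch / config.epochs)
                )
            order = rng.permutation(train_idx)
            ep_losses = []
            for s in range(0, len(order), config.batch_size):
                x, t = batch.one_hot(order[s : s + config.batch_size])
                p = net.forward(x, training=True)
                loss, g = dice_loss(p, t)
                net.backward(g)
                opt.step()
                ep_losses.append(loss)
            hist["train_loss"].append(float(np.mean(ep_losses)))
            hist["val_loss"].append(_eval_loss(net, batch, val_idx, config.batch_size))
        nets[orientation] = net
        history[orientation] = hist
        log.info(
            "trained %s network: train loss %.4f -> %.4f",
            orientation,
            hist["train_loss"][0],
            hist["train_loss"][-1],
        )
    return nets, history


def predict_volume(
    nets: dict[str, ForkNet], image: ImageVolume, batch_size: int = 8
) -> dict[str, np.ndarray]:
    """Per-orientation probability maps ``(9, nx, ny, nz)`` for a volume."""
    grid = _normalize_volume(image.grid)
    out: dict[str, np.ndarray] = {}
    for orientation, net in nets.items():
        axis = ORIENTATION_AXIS[orientation]
        slices = np.moveaxis(grid, axis, 0)
        probs = np.empty((slices.shape[0], N_CLASSES) + slices.shape[1:], dtype=np.float32)
        for s in range(0, slices.shape[0], batch_size):
            x = slices[s : s + batch_size][:, None]
            probs[s : s + batch_size] = net.forward(x, training=False)
        # (S, 9, h, w) -> (9, S, h, w) -> (9, nx, ny, nz)
        out[orientation] = np.moveaxis(np.moveaxis(probs, 1, 0), 1, axis + 1)
    return out


def fuse_2p5d(
    out_t: np.ndarray,
    out_c: np.ndarray,
    out_s: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
) -> LabelVolume:
    """Fuse the three orientations' probability maps into a label volume.

    Labels are assigned by the argmax over the summed output channels
    (ties to the lowest channel index).  Voxels where every summed channel
    is exactly zero — unassigned by all decoders — take the modal label of
    their 26-neighborhood, with background excluded from the vote whenever
    any tissue neighbor exists, so no voxel is left unclassified.
    """
    if not (out_t.shape == out_c.shape == out_s.shape):
        raise ValueError("probability map geometry mismatch")
    summed = out_t.astype(np.float64) + out_c + out_s
    labels = np.argmax(summed, axis=0).astype(np.int16)
    void = ~np.any(summed != 0.0, axis=0)
    if np.any(void):
        labels[void] = -1
        padded = np.pad(labels, 1, constant_values=-1)
        for i, j, k in np.argwhere(void):
            neigh = padded[i : i + 3, j : j + 3, k : k + 3].ravel().copy()
            neigh[13] = -1  # drop the centre voxel itself
            neigh = neigh[neigh >= 0]
            if neigh.size == 0:
                labels[i, j, k] = 0
                continue
            counts = np.bincount(neigh, minlength=N_CLASSES)
            if counts[1:].sum() > 0:
                counts[0] = 0  # background excluded when a tissue neighbor exists
            labels[i, j, k] = int(np.argmax(counts))
    return LabelVolume(labels, voxel_size)


def evaluate_segmentation(pred: LabelVolume, truth: LabelVolume) -> dict:
    """Per-tissue Dice table plus mean and SD across the 8 tissue classes."""
    check_same_geometry(pred, truth, "pred/truth")
    per_class = {}
    for code in range(1, N_CLASSES):
        per_class[TISSUE_NAMES[code]] = dice(pred.grid == code, truth.grid == code)
    vals = np.array(list(per_class.values()))
    return {
        "per_class": per_class,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=0)),
    }


def leave_one_out_folds(n: int):
    """Yield ``(test_index, train_indices)`` for leave-one-out over n subjects."""
    for i in range(n):
        yield i, [j for j in range(n) if j != i]
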