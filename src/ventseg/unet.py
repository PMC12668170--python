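"""Dual-head attention-gated 1-D U-Net for breath-onset detection.

The network maps a normalized (batch, 352, 2) pressure/flow window to two
(batch, 176, 1) probability traces — inspiratory and expiratory onset — over
the central output span.  Architecture:

* encoder: ``depth`` blocks of ``convs_per_block`` x (conv + LeakyReLU) with
  filter counts doubling from ``base_filters``, each followed by stride-2 max
  pooling;
* bottleneck: dilated convolutions (rates 1, 2, 4 by default) + LeakyReLU +
  dropout;
* decoder: stride-2 transposed-convolution upsampling, concatenation with the
  attention-gated encoder skip, then conv + LeakyReLU pairs;
* the shared trunk output is center-cropped to the output span and feeds two
  task-specific heads: conv -> layer norm -> dropout -> position-wise dense
  with GELU -> 1x1 conv -> sigmoid.

Training minimizes an uncertainty-weighted composite of focal and dice
losses,

    L_total = L_focal / (2 sigma1^2) + L_dice / (2 sigma2^2)
              + log sigma1 + log sigma2,

with sigma1, sigma2 learned (parameterized as log sigma^2, initialized at 0)
so the two terms are balanced dynamically; the log terms keep the sigmas from
diverging.  Optimization uses AdamW (lr 5e-4, batch 32) with He-initialized
weights and early stopping on validation loss (patience 10, min delta 1e-4),
restoring the weights of the best validation epoch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .core import (
    ConfigurationError,
    OnsetAnnotation,
    WaveformRecord,
    WindowBatch,
    check_disjoint_provenance,
    make_windows,
)
from .nn.layers import AttentionGate1d, Conv1d, ConvTranspose1d, Dropout, LayerNorm, Module
from .nn.optim import AdamW
from .nn.tensor import Tensor, concat, maxpool1d

__all__ = [
    "ModelConfig",
    "LossConfig",
    "TrainConfig",
    "Prediction",
    "UNet1d",
    "build_model",
    "focal_loss",
    "dice_loss",
    "total_loss",
    "train",
    "predict_record",
    "postprocess_events",
    "UNetSegmenter",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# configs


@dataclass
class ModelConfig:
    depth: int = 4
    base_filters: int = 32
    kernel_size: int = 7
    convs_per_block: int = 2
    bottleneck_dilations: tuple = (1, 2, 4)
    dropout_bottleneck: float = 0.3
    dropout_head: float = 0.2
    leaky_slope: float = 0.01
    input_len: int = 352
    output_len: int = 176
    channels_in: int = 2

    def __post_init__(self):
        if self.input_len % (2 ** self.depth):
            raise ConfigurationError(
                f"input_len {self.input_len} not divisible by 2^depth = {2 ** self.depth}"
            )
        if self.output_len > self.input_len:
            raise ConfigurationError("output_len must not exceed input_len")


@dataclass
class LossConfig:
    alpha: float = 0.25  # focal balancing factor
    gamma: float = 2.0  # focal focusing strength
    epsilon: float = 1e-6  # dice stability constant
    sigma1: float = 1.0  # uncertainty weight of the focal term (learned)
    sigma2: float = 1.0  # uncertainty weight of the dice term (learned)
    per_head_sigma: bool = False  # alternative reading: one sigma per task head

    def __post_init__(self):
        if self.gamma < 0 or self.epsilon <= 0:
            raise ConfigurationError("need gamma >= 0 and epsilon > 0")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ConfigurationError("sigma parameters must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 1e-2
    batch_size: int = 32
    patience: int = 10
    min_delta: float = 1e-4
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.weight_decay, self.batch_size, self.min_delta) <= 0:
            raise ConfigurationError("training scalars must be positive")
        if self.patience < 1 or self.max_epochs < 1:
            raise ConfigurationError("patience and max_epochs must be >= 1")


@dataclass
class Prediction:
    """Stitched per-sample onset probabilities plus post-processed events."""

    p_insp: np.ndarray
    p_exp: np.ndarray
    events: OnsetAnnotation
    sample_rate: float = 50.0


# ---------------------------------------------------------------------------
# model


class UNet1d(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        k = c.kernel_size

        self.enc_blocks: list[list[Conv1d]] = []
        ch = c.channels_in
        for level in range(c.depth):
            out_ch = c.base_filters * 2 ** level
            block = []
            for _ in range(c.convs_per_block):
                block.append(Conv1d(ch, out_ch, k, rng))
                ch = out_ch
            self.enc_blocks.append(block)

        bottleneck_ch = c.base_filters * 2 ** c.depth
        self.bottleneck: list[Conv1d] = []
        for dilation in c.bottleneck_dilations:
            self.bottleneck.append(Conv1d(ch, bottleneck_ch, k, rng, dilation=dilation))
            ch = bottleneck_ch
        self.bottleneck_dropout = Dropout(c.dropout_bottleneck)

        self.up_convs: list[ConvTranspose1d] = []
        self.gates: list[AttentionGate1d] = []
        self.dec_blocks: list[list[Conv1d]] = []
        for level in reversed(range(c.depth)):
            skip_ch = c.base_filters * 2 ** level
            self.up_convs.append(ConvTranspose1d(ch, skip_ch, rng))
            self.gates.append(AttentionGate1d(skip_ch, skip_ch, rng))
            block = []
            ch = 2 * skip_ch
            for _ in range(c.convs_per_block):
                block.append(Conv1d(ch, skip_ch, k, rng))
                ch = skip_ch
            self.dec_blocks.append(block)

        self.heads: list[dict] = []
        for _ in range(2):
            head = {
                "conv": Conv1d(ch, c.base_filters, k, rng),
                "norm": LayerNorm(c.base_filters),
                "dropout": Dropout(c.dropout_head),
                "dense": Conv1d(c.base_filters, c.base_filters, 1, rng),
                "out": Conv1d(c.base_filters, 1, 1, rng),
            }
            self.heads.append(head)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for block in self.enc_blocks + self.dec_blocks:
            for layer in block:
                params.extend(layer.parameters())
        for layer in self.bottleneck + self.up_convs + self.gates:
            params.extend(layer.parameters())
        for head in self.heads:
            for layer in head.values():
                if isinstance(layer, Module):
                    params.extend(layer.parameters())
        return params

    def forward(
        self,
        x: np.ndarray | Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_internals: bool = False,
    ):
        """Run the network.

        Returns ``(p_insp, p_exp)`` of shape (N, output_len, 1), or a dict
        with probabilities, pre-sigmoid logits and the pre-crop trunk feature
        map when ``return_internals`` is set (used by Grad-CAM).
        """
        c = self.config
        slope = c.leaky_slope
        h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if h.ndim != 3 or h.shape[1] != c.input_len or h.shape[2] != c.channels_in:
            raise ConfigurationError(
                f"expected input (N, {c.input_len}, {c.channels_in}), got {h.shape}"
            )

        skips = []
        for block in self.enc_blocks:
            for conv in block:
                h = conv(h).leaky_relu(slope)
            skips.append(h)
            h = maxpool1d(h, 2)

        for conv in self.bottleneck:
            h = conv(h).leaky_relu(slope)
        h = self.bottleneck_dropout(h, rng, training)

        for up, gate, block, skip in zip(
            self.up_convs, self.gates, self.dec_blocks, reversed(skips)
        ):
            h = up(h)
            h = concat([h, gate(skip, h)], axis=-1)
            for conv in block:
                h = conv(h).leaky_relu(slope)

        trunk = h  # last shared convolutional feature map, full input length
        lo = (c.input_len - c.output_len) // 2
        cropped = trunk[:, lo : lo + c.output_len, :]

        logits = []
        for head in self.heads:
            z = head["conv"](cropped).leaky_relu(slope)
            z = head["norm"](z)
            z = head["dropout"](z, rng, training)
            z = head["dense"](z).gelu()
            logits.append(head["out"](z))
        probs = [z.sigmoid() for z in logits]
        if return_internals:
            return {
                "p_insp": probs[0],
                "p_exp": probs[1],
                "logit_insp": logits[0],
                "logit_exp": logits[1],
                "trunk": trunk,
            }
        return probs[0], probs[1]

    __call__ = forward


def build_model(config: ModelConfig | None = None, seed: int = 0) -> UNet1d:
    """He-initialized dual-head attention-gated 1-D U-Net."""
    return UNet1d(config or ModelConfig(), np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# losses

_CLIP = 1e-7


def _as_tensor_pair(p, g):
    pt = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    gt = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=np.float64))
    if pt.shape != gt.shape:
        raise ValueError(f"shape mismatch: predictions {pt.shape}, targets {gt.shape}")
    return pt, gt


def focal_loss(p, g, alpha: float = 0.25, gamma: float = 2.0):
    """Mean of ``-alpha * (1 - p_t)^gamma * log(p_t)``.

    ``p_t`` is the predicted probability of the true class (``p`` where the
    target is 1, ``1 - p`` where it is 0).  At ``gamma=0, alpha=1`` this is
    plain binary cross-entropy.  Accepts arrays (returns a float) or graph
    tensors (returns a Tensor for backprop).
    """
    pt_, gt = _as_tensor_pair(p, g)
    pc = pt_.clip(_CLIP, 1.0 - _CLIP)
    p_true = pc * gt + (1.0 - pc) * (1.0 - gt)
    loss = ((1.0 - p_true) ** gamma * p_true.log() * (-alpha)).mean()
    return loss if isinstance(p, Tensor) else float(loss.data)


def dice_loss(p, g, epsilon: float = 1e-6):
    """``1 - (2 sum(p*g) + eps) / (sum(p) + sum(g) + eps)`` (soft dice)."""
    pt_, gt = _as_tensor_pair(p, g)
    num = (pt_ * gt).sum() * 2.0 + epsilon
    den = pt_.sum() + gt.sum() + epsilon
    loss = 1.0 - num / den
    return loss if isinstance(p, Tensor) else float(loss.data)


def total_loss(loss_focal, loss_dice, loss_config: LossConfig | None = None):
    """Uncertainty-weighted combination of the two component losses.

    ``L/(2 sigma1^2) + L/(2 sigma2^2) + log sigma1 + log sigma2`` with the
    sigma values taken from ``loss_config`` (both default to 1, reducing to
    the plain average of the halves).
    """
    cfg = loss_config or LossConfig()
    s1, s2 = cfg.sigma1, cfg.sigma2
    lf = float(loss_focal.data) if isinstance(loss_focal, Tensor) else float(loss_focal)
    ld = float(loss_dice.data) if isinstance(loss_dice, Tensor) else float(loss_dice)
    return lf / (2 * s1 ** 2) + ld / (2 * s2 ** 2) + np.log(s1) + np.log(s2)


def _total_loss_graph(lf: Tensor, ld: Tensor, log_var1: Tensor, log_var2: Tensor) -> Tensor:
    """Graph version with learned log sigma^2: 0.5*(exp(-s)*L + s) per term."""
    return (
        ((-1.0 * log_var1).exp() * lf + log_var1) * 0.5
        + ((-1.0 * log_var2).exp() * ld + log_var2) * 0.5
    )


# ---------------------------------------------------------------------------
# training


def _composite_loss(model, xb, yb, loss_cfg, log_vars, training, rng):
    p_insp, p_exp = model.forward(xb, training=training, rng=rng)
    gi = Tensor(yb[:, :, 0:1].astype(np.float32))
    ge = Tensor(yb[:, :, 1:2].astype(np.float32))
    if loss_cfg.per_head_sigma:
        # alternative reading: one sigma per task head over (focal + dice)
        li = focal_loss(p_insp, gi, loss_cfg.alpha, loss_cfg.gamma) + dice_loss(
            p_insp, gi, loss_cfg.epsilon
        )
        le = focal_loss(p_exp, ge, loss_cfg.alpha, loss_cfg.gamma) + dice_loss(
            p_exp, ge, loss_cfg.epsilon
        )
        return _total_loss_graph(li, le, log_vars[0], log_vars[1])
    p_all = concat([p_insp, p_exp], axis=-1)
    g_all = concat([gi, ge], axis=-1)
    lf = focal_loss(p_all, g_all, loss_cfg.alpha, loss_cfg.gamma)
    ld = dice_loss(p_all, g_all, loss_cfg.epsilon)
    return _total_loss_graph(lf, ld, log_vars[0], log_vars[1])


def train(
    train_batch: WindowBatch,
    val_batch: WindowBatch,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
    verbose: bool = False,
):
    """Train the U-Net; returns ``(model, history)``.

    ``history`` holds per-epoch train/validation losses, the learned sigmas
    and the index of the best validation epoch (whose weights are restored).
    Raises :class:`LeakageError` if the two batches share a record.
    """
    model_config = model_config or ModelConfig()
    loss_cfg = loss_config or LossConfig()
    cfg = train_config or TrainConfig()
    if not len(train_batch) or not len(val_batch):
        raise ConfigurationError("train and validation batches must be non-empty")
    if train_batch.targets is None or val_batch.targets is None:
        raise ConfigurationError("training requires annotated (target-bearing) batches")
    check_disjoint_provenance(train_batch, val_batch)

    rng = np.random.default_rng(cfg.seed)
    model = UNet1d(model_config, rng)
    log_vars = [
        Tensor(np.zeros(()), requires_grad=True),  # log sigma1^2, init 0
        Tensor(np.zeros(()), requires_grad=True),
    ]
    weights, aux = [], []
    for p in model.parameters():
        (weights if p.ndim > 1 else aux).append(p)
    optimizer = AdamW(
        weights,
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        no_decay_params=aux + log_vars,
    )

    x_train = train_batch.inputs.astype(np.float32)
    y_train = train_batch.targets
    n = len(x_train)
    history = {"train_loss": [], "val_loss": [], "sigma1": [], "sigma2": []}
    best_val, best_state, best_epoch, wait = np.inf, None, -1, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss = _composite_loss(
                model, x_train[sel], y_train[sel], loss_cfg, log_vars, True, rng
            )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))

        val_loss = _evaluate_loss(model, val_batch, loss_cfg, log_vars, cfg.batch_size)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["sigma1"].append(float(np.exp(0.5 * log_vars[0].data)))
        history["sigma2"].append(float(np.exp(0.5 * log_vars[1].data)))
        if verbose:
            print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} val {val_loss:.4f}")

        if val_loss < best_val - cfg.min_delta:
            best_val, best_epoch, wait = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            wait += 1
            if wait >= cfg.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["n_epochs"] = len(history["val_loss"])
    history["sigma1_final"] = float(np.exp(0.5 * log_vars[0].data))
    history["sigma2_final"] = float(np.exp(0.5 * log_vars[1].data))
    return model, history


def _evaluate_loss(model, batch: WindowBatch, loss_cfg, log_vars, batch_size: int) -> float:
    losses, sizes = [], []
    for start in range(0, len(batch), batch_size):
        xb = batch.inputs[start : start + batch_size].astype(np.float32)
        yb = batch.targets[start : start + batch_size]
        loss = _composite_loss(model, xb, yb, loss_cfg, log_vars, False, None)
        losses.append(float(loss.data))
        sizes.append(len(xb))
    return float(np.average(losses, weights=sizes))


# ---------------------------------------------------------------------------
# inference + post-processing


def postprocess_events(
    p_insp: np.ndarray,
    p_exp: np.ndarray,
    threshold: float = 0.5,
    debounce: int = 5,
    sample_rate: float = 50.0,
) -> OnsetAnnotation:
    """Turn probability traces into a plausible onset annotation.

    Candidates are local maxima strictly above ``threshold``; candidates of
    the same type closer than ``debounce`` samples are merged keeping the
    highest-probability one; between consecutive inspiratory onsets only the
    single highest-probability expiratory candidate survives (candidates in
    the open segments before the first / after the last inspiratory onset are
    kept only if unique there).
    """
    p_insp = np.asarray(p_insp, dtype=np.float64)
    p_exp = np.asarray(p_exp, dtype=np.float64)
    if p_insp.shape != p_exp.shape:
        raise ValueError("probability traces must have the same length")

    def candidates(trace):
        peaks, _ = find_peaks(trace)
        peaks = peaks[trace[peaks] > threshold]
        if not peaks.size or debounce <= 0:
            return peaks
        keep = []
        for idx in peaks[np.argsort(trace[peaks])[::-1]]:  # highest first
            if all(abs(idx - k) >= debounce for k in keep):
                keep.append(int(idx))
        return np.array(sorted(keep), dtype=np.int64)

    insp = candidates(p_insp)
    exp_cand = candidates(p_exp)

    if insp.size == 0:
        exp = exp_cand if exp_cand.size <= 1 else np.array([], dtype=np.int64)
        return OnsetAnnotation(insp, exp)

    exp_keep = []
    segments = (
        [(-np.inf, insp[0], True)]
        + [(a, b, False) for a, b in zip(insp[:-1], insp[1:])]
        + [(insp[-1], np.inf, True)]
    )
    for lo, hi, open_ended in segments:
        inside = exp_cand[(exp_cand > lo) & (exp_cand < hi)]
        if not inside.size:
            continue
        if open_ended:
            if inside.size == 1:
                exp_keep.append(int(inside[0]))
        else:
            exp_keep.append(int(inside[np.argmax(p_exp[inside])]))
    return OnsetAnnotation(insp, np.array(sorted(exp_keep), dtype=np.int64))


def predict_record(
    model: UNet1d,
    record: WaveformRecord,
    threshold: float = 0.5,
    debounce: int = 5,
    batch_size: int = 64,
) -> Prediction:
    """Sliding-window inference over a full record.

    The record is tiled with non-overlapping output spans (step = output
    length), each window is normalized and passed through the network, and
    the per-span probabilities are stitched into full-length traces before
    event post-processing.
    """
    c = model.config
    batch = make_windows(record.with_annotation(None), c.input_len, c.output_len, c.output_len)
    n_windows = len(batch)
    stitched_len = int(batch.window_starts[-1] + c.output_len)
    p_insp = np.zeros(stitched_len)
    p_exp = np.zeros(stitched_len)
    for start in range(0, n_windows, batch_size):
        xs = batch.inputs[start : start + batch_size]
        pi, pe = model.forward(xs, training=False)
        for j, s in enumerate(batch.window_starts[start : start + batch_size]):
            p_insp[s : s + c.output_len] = pi.data[j, :, 0]
            p_exp[s : s + c.output_len] = pe.data[j, :, 0]
    p_insp = p_insp[: len(record)]
    p_exp = p_exp[: len(record)]
    events = postprocess_events(p_insp, p_exp, threshold, debounce, record.sample_rate)
    return Prediction(p_insp=p_insp, p_exp=p_exp, events=events, sample_rate=record.sample_rate)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: UNet1d, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.state_dict())
    cfg = asdict(model.config)
    cfg["bottleneck_dilations"] = list(model.config.bottleneck_dilations)
    (directory / "model_config.json").write_text(json.dumps(cfg, indent=2))


def load_model(directory) -> UNet1d:
    directory = Path(directory)
    cfg = json.loads((directory / "model_config.json").read_text())
    cfg["bottleneck_dilations"] = tuple(cfg["bottleneck_dilations"])
    model = build_model(ModelConfig(**cfg), seed=0)
    with np.load(directory / "weights.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


# ---------------------------------------------------------------------------
# estimator


class UNetSegmenter(BaseEstimator):
    """scikit-learn style wrapper around the U-Net segmentation pipeline.

    ``fit`` takes lists of annotated :class:`WaveformRecord` (training and,
    optionally, validation; without an explicit validation set a by-patient
    split is made).  ``predict`` returns the post-processed
    :class:`OnsetAnnotation` for one record; ``predict_proba`` returns the
    full :class:`Prediction` with stitched probability traces.
    """

    def __init__(
        self,
        depth: int = 4,
        base_filters: int = 32,
        kernel_size: int = 7,
        convs_per_block: int = 2,
        bottleneck_dilations: tuple = (1, 2, 4),
        dropout_bottleneck: float = 0.3,
        dropout_head: float = 0.2,
        leaky_slope: float = 0.01,
        input_len: int = 352,
        output_len: int = 176,
        alpha: float = 0.25,
        gamma: float = 2.0,
        epsilon: float = 1e-6,
        per_head_sigma: bool = False,
        learning_rate: float = 5e-4,
        weight_decay: float = 1e-2,
        batch_size: int = 32,
        patience: int = 10,
        min_delta: float = 1e-4,
        max_epochs: int = 100,
        threshold: float = 0.5,
        debounce: int = 5,
        val_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.depth = depth
        self.base_filters = base_filters
        self.kernel_size = kernel_size
        self.convs_per_block = convs_per_block
        self.bottleneck_dilations = bottleneck_dilations
        self.dropout_bottleneck = dropout_bottleneck
        self.dropout_head = dropout_head
        self.leaky_slope = leaky_slope
        self.input_len = input_len
        self.output_len = output_len
        self.alpha = alpha
        self.gamma = gamma
        self.epsilon = epsilon
        self.per_head_sigma = per_head_sigma
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.patience = patience
        self.min_delta = min_delta
        self.max_epochs = max_epochs
        self.threshold = threshold
        self.debounce = debounce
        self.val_fraction = val_fraction
        self.seed = seed

    # -- config assembly ---------------------------------------------------

    def _configs(self):
        model_cfg = ModelConfig(
            depth=self.depth,
            base_filters=self.base_filters,
            kernel_size=self.kernel_size,
            convs_per_block=self.convs_per_block,
            bottleneck_dilations=tuple(self.bottleneck_dilations),
            dropout_bottleneck=self.dropout_bottleneck,
            dropout_head=self.dropout_head,
            leaky_slope=self.leaky_slope,
            input_len=self.input_len,
            output_len=self.output_len,
        )
        loss_cfg = LossConfig(
            alpha=self.alpha,
            gamma=self.gamma,
            epsilon=self.epsilon,
            per_head_sigma=self.per_head_sigma,
        )
        train_cfg = TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            patience=self.patience,
            min_delta=self.min_delta,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )
        return model_cfg, loss_cfg, train_cfg

    def _batch(self, records) -> WindowBatch:
        return WindowBatch.concatenate(
            [make_windows(r, self.input_len, self.output_len, self.output_len) for r in records]
        )

    def fit(self, records, val_records=None, verbose: bool = False):
        records = list(records)
        if val_records is None:
            ids = sorted({r.patient_id for r in records})
            if len(ids) < 2:
                raise ConfigurationError(
                    "need >= 2 patients (or an explicit val_records) for a by-patient split"
                )
            rng = np.random.default_rng(self.seed)
            ids = list(rng.permutation(ids))
            n_val = max(1, int(round(self.val_fraction * len(ids))))
            val_ids = set(ids[:n_val])
            val_records = [r for r in records if r.patient_id in val_ids]
            records = [r for r in records if r.patient_id not in val_ids]
        model_cfg, loss_cfg, train_cfg = self._configs()
        self.model_, self.history_ = train(
            self._batch(records), self._batch(list(val_records)),
            model_cfg, loss_cfg, train_cfg, verbose=verbose,
        )
        self.n_epochs_ = self.history_["n_epochs"]
        return self

    def predict_proba(self, record: WaveformRecord) -> Prediction:
        if not hasattr(self, "model_"):
            raise RuntimeError("UNetSegmenter is not fitted")
        return predict_record(self.model_, record, self.threshold, self.debounce)

    def predict(self, record: WaveformRecord) -> OnsetAnnotation:
        return self.predict_proba(record).events
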