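"""The sleep-stage classifier: four conv units, a peephole LSTM, softmax.

Architecture (input: one 2-D feature stream, treated as a 1-channel
image of stacked cepstral rows by context frames):

    conv 6x6 + LReLU(0.1) + maxpool 2x2
    conv 5x5 + LReLU(0.1) + maxpool 2x2
    conv 5x5 + LReLU(0.1) + maxpool 2x2
    conv 2x2 + LReLU(0.1)
    width axis -> sequence, (channels x height) -> step features
    peephole LSTM (128 units), last hidden state
    fully connected -> softmax over the five stages

Training minimizes unweighted categorical cross-entropy with Adam,
keeps the parameters of the best validation-accuracy epoch and stops
early when validation accuracy has not improved for ``patience``
epochs.  All randomness (initialization, shuffling) derives from the
single config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from melstage import nn
from melstage.staging import STAGES, STAGE_TO_CODE, CODE_TO_STAGE
from melstage.streams import FeatureStream


class ModelShapeError(ValueError):
    """Input too small for the configured kernel/pooling stack."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization knobs.

    Kernel sizes and the LReLU slope follow the reference architecture;
    per-conv filter counts and pooling are open choices exposed here.
    The defaults (8/16/16/32 filters) keep single-CPU training of the
    synthetic study tractable while leaving the capacity well above
    what the five-class problem needs.
    """

    conv_kernels: tuple[tuple[int, int], ...] = ((6, 6), (5, 5), (5, 5), (2, 2))
    conv_filters: tuple[int, ...] = (6, 12, 12, 24)
    pool_after: tuple[bool, ...] = (True, True, True, False)
    pool_size: int = 2
    lrelu_slope: float = 0.1
    lstm_units: int = 128
    n_classes: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 10
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_kernels) != 4:
            raise ValueError("the architecture uses exactly four convolutional units")
        if len(self.conv_filters) != len(self.conv_kernels) or len(self.pool_after) != len(self.conv_kernels):
            raise ValueError("conv_filters and pool_after must match conv_kernels in length")
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be >= 1")
        if self.n_classes != 5:
            raise ValueError("the classifier targets the five AASM stages")


@dataclass
class Prediction:
    """Class probabilities on the 5-simplex plus the argmax stage."""

    probs: np.ndarray
    stage: str

    @property
    def code(self) -> int:
        return STAGE_TO_CODE[self.stage]


class SleepStageNet:
    """A built network bound to one input shape."""

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int]):
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(cfg.seed)
        layers: list[nn.Layer] = []
        shape = (1, *self.input_shape)  # (C,H,W)
        for li, (kernel, filters, pool) in enumerate(
            zip(cfg.conv_kernels, cfg.conv_filters, cfg.pool_after), start=1
        ):
            conv = nn.Conv2d(shape[0], filters, kernel, rng, name=f"conv{li}")
            if li == 1:
                conv.compute_input_grad = False  # no layer below needs it
            layers.append(conv)
            shape = conv.out_shape(shape)
            layers.append(nn.LeakyReLU(cfg.lrelu_slope))
            if pool:
                pool_layer = nn.MaxPool2d(cfg.pool_size)
                try:
                    shape = pool_layer.out_shape(shape)
                except ValueError as e:
                    raise ModelShapeError(f"after conv{li}: {e}") from e
                layers.append(pool_layer)
            if shape[1] < 1 or shape[2] < 1:
                raise ModelShapeError(
                    f"conv{li} leaves an empty {shape[1]}x{shape[2]} map for input "
                    f"{self.input_shape}"
                )
        bridge = nn.ConvToSequence()
        seq_shape = bridge.out_shape(shape)
        layers.append(bridge)
        lstm = nn.PeepholeLSTM(seq_shape[1], cfg.lstm_units, rng)
        layers.append(lstm)
        layers.append(nn.Dense(cfg.lstm_units, cfg.n_classes, rng))
        self.net = nn.Sequential(layers)

    @property
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.net.params())

    def forward_logits(self, batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ModelShapeError(
                f"model was built for {self.input_shape} streams, got {x.shape[1:]}"
            )
        return self.net.forward(x[:, None, :, :])

    def predict_proba(self, batch: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        out = [nn.softmax(self.forward_logits(x[i : i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def get_state(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.net.params()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.net.params():
            p.value[...] = state[p.name]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        cfg = asdict(self.cfg)
        np.savez(
            path,
            __config__=json.dumps(cfg),
            __input_shape__=np.array(self.input_shape),
            **self.get_state(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SleepStageNet":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            for k in ("conv_kernels", "conv_filters", "pool_after"):
                cfg_dict[k] = tuple(tuple(v) if isinstance(v, list) else v for v in cfg_dict[k])
            cfg = ModelConfig(**cfg_dict)
            model = cls(cfg, tuple(int(v) for v in data["__input_shape__"]))
            model.set_state({k: data[k] for k in data.files if not k.startswith("__")})
        return model


def build_model(cfg: ModelConfig, input_shape: tuple[int, int]) -> SleepStageNet:
    """Instantiate the network for streams of shape (height, width)."""
    return SleepStageNet(cfg, input_shape)


def _to_arrays(streams: Sequence[FeatureStream]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([st.tensor for st in streams]).astype(np.float32)
    y = np.array([STAGE_TO_CODE[st.label] for st in streams], dtype=np.int64)
    return x, y


def _accuracy(model: SleepStageNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    pred = model.predict_proba(x, batch_size=batch).argmax(axis=1)
    return float((pred == y).mean())


def train(
    model: SleepStageNet,
    train_streams: Sequence[FeatureStream],
    val_streams: Sequence[FeatureStream],
    cfg: Optional[ModelConfig] = None,
    verbose: bool = False,
) -> dict[str, list[float]]:
    """Fit the network; returns the per-epoch history.

    The parameters achieving the best validation accuracy are restored
    at the end.  Refuses a single-class training set (nothing to
    discriminate; the loss would only calibrate the prior).
    """
    cfg = cfg or model.cfg
    if not train_streams or not val_streams:
        raise ValueError("training and validation partitions must be non-empty")
    xtr, ytr = _to_arrays(train_streams)
    xva, yva = _to_arrays(val_streams)
    if len(np.unique(ytr)) < 2:
        raise ValueError(
            f"training set contains a single class ({CODE_TO_STAGE[int(ytr[0])]}); "
            "at least two stages are required"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "train_acc": [], "val_acc": []}
    best_state = model.get_state()
    best_val = -1.0
    stale = 0
    n = len(xtr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        hits = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            model.net.zero_grad()
            logits = model.forward_logits(xb)
            loss, dlogits = nn.cross_entropy(logits, yb)
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == yb).sum())
        val_acc = _accuracy(model, xva, yva, cfg.batch_size)
        history["loss"].append(sum(losses) / n)
        history["train_acc"].append(hits / n)
        history["val_acc"].append(val_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  loss {history['loss'][-1]:.4f}  "
                f"train {history['train_acc'][-1]:.3f}  val {val_acc:.3f}"
            )
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.set_state(best_state)
    return history


def predict(model: SleepStageNet, streams: Sequence[FeatureStream]) -> list[Prediction]:
    """Deterministic batched inference, one Prediction per stream in order."""
    if not streams:
        return []
    x = np.stack([st.tensor for st in streams]).astype(np.float32)
    probs = model.predict_proba(x)
    return [
        Prediction(probs=p, stage=STAGES[int(p.argmax())]) for p in probs
    ]
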