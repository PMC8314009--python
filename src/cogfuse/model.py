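"""Two-tower late-fusion sentence classifiers.

The text tower embeds tokens and encodes them with a masked bidirectional
LSTM followed by two ReLU dense layers with dropout between them. The
cognitive tower decodes the per-word feature sequence with either an
analogous recurrent component or an inception-style convolutional component
(parallel 1-D convolutions with kernel sizes 1, 4 and 7, ELU activations,
pooling, then flatten and the same dense block). Tower outputs are merged
(concatenation by default; addition, subtraction and elementwise maximum are
available) and a final dense layer produces class scores: softmax for
single-label tasks, independent sigmoids with a tuned decision threshold for
multi-label relation detection.

Band-augmented models can attach one cognitive tower per frequency band
(a five-component model for text + theta/alpha/beta/gamma) or concatenate
the bands into a single wide input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .embeddings import EmbeddingSpec
from .records import N_EEG_CHANNELS

CNN_KERNELS = (1, 4, 7)

#: Admissible hyper-parameter values for the search grid.
GRID_RANGES = {
    "lstm_dim": (64, 128, 256, 512),
    "lstm_layers": (1, 2, 3, 4),
    "cnn_filters": (14, 16, 18),
    "cnn_pool": (3, 5, 7),
    "dense_dim": (8, 16, 32, 64, 128, 256, 512),
    "dropout": (0.1, 0.3, 0.5),
    "batch": (20, 40, 60),
    "lr": (1e-1, 1e-2, 1e-3, 1e-4, 1e-5),
    "threshold": (0.3, 0.5, 0.7),
}

COGNITIVE_INPUTS = ("none", "eeg", "gaze", "noise")
FUSIONS = ("concat", "add", "subtract", "max")


@dataclass(frozen=True)
class HyperPoint:
    """One point of the hyper-parameter grid; every field is checked against its range."""

    lstm_dim: int = 64
    lstm_layers: int = 1
    cnn_filters: int = 16
    cnn_pool: int = 5
    dense_dim: int = 16
    dropout: float = 0.1
    batch: int = 60
    lr: float = 1e-3
    threshold: float = 0.5

    def __post_init__(self):
        for name, allowed in GRID_RANGES.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name}={getattr(self, name)} not in grid range {allowed}")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice: embedding, cognitive modality, decoder, fusion, head."""

    embedding: EmbeddingSpec
    n_classes: int
    cognitive_input: str = "none"
    eeg_bands: tuple[str, ...] = ("theta",)
    eeg_component: str = "recurrent"
    band_fusion: str = "towers"  # "towers": one component per band; "concat": one wide input
    fusion: str = "concat"
    head: str = "softmax"
    pool_op: str = "max"
    hyper: HyperPoint = field(default_factory=HyperPoint)

    def __post_init__(self):
        if self.cognitive_input not in COGNITIVE_INPUTS:
            raise ValueError(f"unknown cognitive input {self.cognitive_input!r}")
        if self.fusion not in FUSIONS:
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.head not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.eeg_component not in ("recurrent", "convolutional"):
            raise ValueError(f"unknown EEG component {self.eeg_component!r}")

    @property
    def cognitive_dim(self) -> int:
        if self.cognitive_input == "gaze":
            return 5
        if self.cognitive_input in ("eeg", "noise"):
            return N_EEG_CHANNELS
        return 0

    @property
    def cognitive_streams(self) -> list[tuple[str, int]]:
        """(input name, width) per cognitive tower."""
        if self.cognitive_input == "none":
            return []
        if self.cognitive_input == "eeg":
            if self.band_fusion == "concat":
                return [("+".join(self.eeg_bands), N_EEG_CHANNELS * len(self.eeg_bands))]
            return [(b, N_EEG_CHANNELS) for b in self.eeg_bands]
        return [(self.cognitive_input, self.cognitive_dim)]


def predict_multilabel(scores: np.ndarray, threshold: float) -> set[int]:
    """Label set {i : score_i > threshold}; the empty set means "no relation"."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be inside (0, 1)")
    scores = np.asarray(scores)
    return {int(i) for i in np.flatnonzero(scores > threshold)}


class _DenseBlock(nn.Module):
    """dense -> ReLU -> dropout -> dense -> ReLU."""

    def __init__(self, d_in: int, d_hidden: int, dropout: float, rng: np.random.Generator):
        self.fc1 = nn.Dense(d_in, d_hidden, rng)
        self.fc2 = nn.Dense(d_hidden, d_hidden, rng)
        self.drop = nn.Dropout(dropout)

    def __call__(self, x, rng, training):
        h = self.drop(self.fc1(x).relu(), rng, training)
        return self.fc2(h).relu()


class RecurrentTower(nn.Module):
    """Masked BiLSTM encoder + dense block; used for text and for EEG/gaze."""

    def __init__(self, d_in: int, hyper: HyperPoint, rng: np.random.Generator):
        self.lstm = nn.BiLSTM(d_in, hyper.lstm_dim, hyper.lstm_layers, rng)
        self.block = _DenseBlock(self.lstm.d_out, hyper.dense_dim, hyper.dropout, rng)

    def __call__(self, x: nn.Tensor, mask: np.ndarray, rng, training) -> nn.Tensor:
        length = x.shape[1]
        steps = [x[:, t, :] for t in range(length)]
        masks = [mask[:, t] for t in range(length)]
        _, final = self.lstm(steps, masks)
        return self.block(final, rng, training)


class ConvolutionalTower(nn.Module):
    """Inception-style decoder: parallel convolutions, pooling, flatten, dense block.

    Operates on the fixed padded length; pad positions enter the convolutions
    as zeros (no masking).
    """

    def __init__(self, d_in: int, pad_len: int, hyper: HyperPoint, rng: np.random.Generator,
                 pool_op: str = "max"):
        self.convs = [
            (nn.Tensor(rng.uniform(-s, s, size=(k, d_in, hyper.cnn_filters)), requires_grad=True),
             nn.Tensor(np.zeros(hyper.cnn_filters), requires_grad=True))
            for k in CNN_KERNELS
            for s in (1.0 / np.sqrt(k * d_in),)
        ]
        self.pool = hyper.cnn_pool
        self.pool_op = pool_op
        n_win = pad_len // hyper.cnn_pool
        flat = n_win * len(CNN_KERNELS) * hyper.cnn_filters
        self.block = _DenseBlock(flat, hyper.dense_dim, hyper.dropout, rng)

    def parameters(self):
        params = [t for pair in self.convs for t in pair]
        return params + self.block.parameters()

    def __call__(self, x: nn.Tensor, mask: np.ndarray, rng, training) -> nn.Tensor:
        branches = [nn.conv1d(x, w, b).elu() for w, b in self.convs]
        h = nn.concat(branches, axis=2)
        if self.pool_op == "max":
            h = nn.maxpool1d(h, self.pool)
        else:  # average pooling
            bsz, length, c = h.shape
            n_win = length // self.pool
            h = h[:, : n_win * self.pool, :].reshape(bsz, n_win, self.pool, c).mean(axis=2)
        bsz, n_win, c = h.shape
        return self.block(h.reshape(bsz, n_win * c), rng, training)


class FusionClassifier(nn.Module):
    """Late-fusion multi-tower classifier producing class logits."""

    def __init__(self, spec: ModelSpec, vocab_size: int, pad_len: int, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.pad_len = pad_len
        hyper = spec.hyper
        self.embed = (
            nn.Embedding(vocab_size, spec.embedding.d, rng)
            if spec.embedding.kind == "random"
            else None
        )
        self.text_tower = RecurrentTower(spec.embedding.d, hyper, rng)
        self.cog_towers: list[tuple[str, nn.Module]] = []
        for name, width in spec.cognitive_streams:
            if spec.eeg_component == "convolutional" and spec.cognitive_input in ("eeg", "noise"):
                tower = ConvolutionalTower(width, pad_len, hyper, rng, spec.pool_op)
            else:
                tower = RecurrentTower(width, hyper, rng)
            self.cog_towers.append((name, tower))
        n_towers = 1 + len(self.cog_towers)
        head_in = hyper.dense_dim * (n_towers if spec.fusion == "concat" else 1)
        self.head = nn.Dense(head_in, spec.n_classes, rng)

    def parameters(self):
        params = [] if self.embed is None else self.embed.parameters()
        params += self.text_tower.parameters()
        for _, tower in self.cog_towers:
            params += tower.parameters()
        return params + self.head.parameters()

    def _fuse(self, hidden: list[nn.Tensor]) -> nn.Tensor:
        if self.spec.fusion == "concat" or len(hidden) == 1:
            return nn.concat(hidden, axis=1) if len(hidden) > 1 else hidden[0]
        out = hidden[0]
        for h in hidden[1:]:
            if self.spec.fusion == "add":
                out = out + h
            elif self.spec.fusion == "subtract":
                out = out - h
            else:
                out = nn.maximum(out, h)
        return out

    def forward(self, batch: dict, rng: np.random.Generator | None = None,
                training: bool = False) -> nn.Tensor:
        mask = batch["mask"]
        if self.embed is not None:
            x = self.embed(batch["token_ids"])
        else:
            x = nn.Tensor(batch["text_feats"])
        hidden = [self.text_tower(x, mask, rng, training)]
        for name, tower in self.cog_towers:
            hidden.append(tower(nn.Tensor(batch["cog"][name]), mask, rng, training))
        return self.head(self._fuse(hidden))

    def predict_proba(self, batch: dict) -> np.ndarray:
        logits = self.forward(batch, rng=None, training=False).data
        if self.spec.head == "softmax":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return 0.5 * (1.0 + np.tanh(0.5 * logits))

    def predict(self, batch: dict) -> list:
        probs = self.predict_proba(batch)
        if self.spec.head == "softmax":
            return [int(i) for i in probs.argmax(axis=1)]
        return [frozenset(predict_multilabel(p, self.spec.hyper.threshold)) for p in probs]

    def loss(self, batch: dict, rng: np.random.Generator, training: bool = True) -> nn.Tensor:
        logits = self.forward(batch, rng=rng, training=training)
        if self.spec.head == "softmax":
            return nn.softmax_cross_entropy(logits, batch["labels"])
        return nn.sigmoid_binary_cross_entropy(logits, batch["label_matrix"])


def assemble(spec: ModelSpec, vocab_size: int, pad_len: int, seed: int) -> FusionClassifier:
    """Build the classifier for `spec` with seeded initialization."""
    return FusionClassifier(spec, vocab_size, pad_len, seed)


def with_hyper(spec: ModelSpec, hyper: HyperPoint) -> ModelSpec:
    return replace(spec, hyper=hyper)
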