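"""Training protocol: splits, early stopping, seeds, grid search.

Per random seed, sentences are split into 80% train / 20% test; 10% of the
train set is held out for validation, which drives both early stopping
(patience in epochs, minimum improvement in validation accuracy) and
hyper-parameter selection. Five such resampled splits ("folds") per seed
reproduce the full protocol; desk-scale studies use one split per seed.
Every run is bitwise reproducible from its seed: initialization, shuffling
and dropout draw from seeded generators only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .embeddings import HashContextualEncoder, Vocab, build_vocab, synthetic_static_table
from .evaluation import macro_prf
from .model import FusionClassifier, HyperPoint, ModelSpec, assemble
from .records import SentenceRecord

DEFAULT_SEEDS = (13, 22, 42, 66, 78)


@dataclass
class TrainConfig:
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    n_folds: int = 5
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.1
    patience: int = 80
    min_delta: float = 1e-7
    max_epochs: int = 500
    grid: tuple[HyperPoint, ...] = (HyperPoint(),)
    split_mode: str = "resample"  # "resample": fresh 80/20 per fold; "cv": folds inside one split

    def __post_init__(self):
        if not (0 < self.test_fraction < 1 and 0 < self.val_fraction_of_train < 1):
            raise ValueError("fractions must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class Split:
    train: np.ndarray  # fit + val
    val: np.ndarray
    fit: np.ndarray
    test: np.ndarray


def _fold_rng(seed: int, fold: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[seed, fold]))


def make_splits(n: int, config: TrainConfig, seed: int) -> list[Split]:
    """Reproducible (train, val, test) index partitions for each fold."""
    if n < 10:
        raise ValueError(f"dataset of {n} sentences is too small to split")
    n_test = int(n * config.test_fraction)
    splits = []
    if config.split_mode == "cv":
        perm = _fold_rng(seed, 0).permutation(n)
        test = perm[:n_test]
        train = perm[n_test:]
        parts = np.array_split(train, config.n_folds)
        for f in range(config.n_folds):
            val = parts[f]
            fit = np.concatenate([p for i, p in enumerate(parts) if i != f])
            splits.append(Split(train=train, val=val, fit=fit, test=test))
        return splits
    for f in range(config.n_folds):
        perm = _fold_rng(seed, f).permutation(n)
        test = perm[:n_test]
        train = perm[n_test:]
        n_val = int(len(train) * config.val_fraction_of_train)
        val = train[:n_val]
        fit = train[n_val:]
        splits.append(Split(train=train, val=val, fit=fit, test=test))
    return splits


# ---------------------------------------------------------------------------
# Dataset encoding


@dataclass
class EncodedDataset:
    """Dense model-ready arrays for one corpus under one embedding choice."""

    vocab: Vocab
    pad_len: int
    token_ids: np.ndarray  # (N, pad_len) int
    mask: np.ndarray  # (N, pad_len) float
    text_feats: np.ndarray | None  # (N, pad_len, d) for static/contextual
    cog: dict[str, np.ndarray]  # stream name -> (N, pad_len, width)
    labels: np.ndarray | None  # (N,) int for single-label
    label_matrix: np.ndarray | None  # (N, k) for multi-label
    n_classes: int

    def __len__(self) -> int:
        return self.token_ids.shape[0]

    def take(self, idx: np.ndarray, spec: ModelSpec) -> dict:
        batch = {
            "token_ids": self.token_ids[idx],
            "mask": self.mask[idx],
            "cog": {name: self.cog[name][idx] for name, _ in spec.cognitive_streams
                    if name in self.cog},
        }
        if self.text_feats is not None:
            batch["text_feats"] = self.text_feats[idx]
        if self.labels is not None:
            batch["labels"] = self.labels[idx]
        if self.label_matrix is not None:
            batch["label_matrix"] = self.label_matrix[idx]
        return batch

    def truths(self, idx: np.ndarray) -> list:
        if self.labels is not None:
            return [int(c) for c in self.labels[idx]]
        return [frozenset(np.flatnonzero(row)) for row in self.label_matrix[idx]]


def encode_dataset(
    records: list[SentenceRecord],
    spec: ModelSpec,
    *,
    vocab: Vocab | None = None,
    pad_len: int | None = None,
    static_table: np.ndarray | None = None,
    contextual_encoder=None,
    n_classes: int | None = None,
) -> EncodedDataset:
    """Pad and vectorize records for `spec`'s embedding and cognitive streams.

    Sentences longer than `pad_len` are truncated with a warning. For the
    static kind a vocab-aligned table is required (a deterministic synthetic
    one is generated when none is given); contextual matrices come from the
    bundled hash encoder unless a real encoder is supplied.
    """
    vocab = vocab or build_vocab(records)
    max_len = max(len(r) for r in records)
    if pad_len is None:
        pad_len = max_len
    elif max_len > pad_len:
        warnings.warn(f"truncating sentences longer than pad length {pad_len}")
    n = len(records)
    token_ids = np.zeros((n, pad_len), dtype=np.int64)
    mask = np.zeros((n, pad_len))
    for i, rec in enumerate(records):
        ids = vocab.encode(rec.tokens)[:pad_len]
        token_ids[i, : len(ids)] = ids
        mask[i, : len(ids)] = 1.0

    text_feats = None
    kind = spec.embedding.kind
    if kind == "static_pretrained":
        table = static_table if static_table is not None else synthetic_static_table(vocab)
        text_feats = table[token_ids] * mask[:, :, None]
    elif kind == "contextual":
        encoder = contextual_encoder or HashContextualEncoder(d=spec.embedding.d)
        text_feats = np.zeros((n, pad_len, spec.embedding.d))
        for i, rec in enumerate(records):
            m = encoder(rec.tokens[:pad_len])
            text_feats[i, : m.shape[0]] = m

    cog: dict[str, np.ndarray] = {}
    for name, width in spec.cognitive_streams:
        arr = np.zeros((n, pad_len, width))
        if spec.cognitive_input == "eeg":
            parts = name.split("+")
            for i, rec in enumerate(records):
                m = np.concatenate([rec.features[b] for b in parts], axis=1)[:pad_len]
                arr[i, : m.shape[0]] = m
        elif spec.cognitive_input == "gaze":
            for i, rec in enumerate(records):
                m = rec.features["gaze"][:pad_len]
                arr[i, : m.shape[0]] = m
        # "noise" stays zero here; the trainer redraws it uniformly each epoch
        cog[name] = arr

    labels = label_matrix = None
    if records[0].labels is not None:
        k = n_classes or (max(max(r.labels, default=-1) for r in records) + 1)
        label_matrix = np.zeros((n, k))
        for i, rec in enumerate(records):
            for c in rec.labels:
                label_matrix[i, c] = 1.0
        n_cls = k
    else:
        labels = np.array([r.label for r in records], dtype=np.int64)
        n_cls = n_classes or int(labels.max()) + 1

    return EncodedDataset(
        vocab=vocab,
        pad_len=pad_len,
        token_ids=token_ids,
        mask=mask,
        text_feats=text_feats,
        cog=cog,
        labels=labels,
        label_matrix=label_matrix,
        n_classes=n_cls,
    )


# ---------------------------------------------------------------------------
# Single training run


@dataclass
class RunEntry:
    """One (seed, fold) training run: selection metadata plus test predictions."""

    seed: int
    fold: int
    hyper: HyperPoint
    epochs_trained: int
    val_accuracy: float
    test_idx: np.ndarray
    test_pred: list
    test_true: list
    macro_p: float
    macro_r: float
    macro_f1: float
    failed: bool = False


def _accuracy(pred: list, true: list) -> float:
    """Plain accuracy; exact-set match for multi-label predictions."""
    return float(np.mean([p == t for p, t in zip(pred, true)]))


def _noise_batch(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.random(shape)


def train_one(
    spec: ModelSpec,
    data: EncodedDataset,
    split: Split,
    config: TrainConfig,
    seed: int,
    fold: int = 0,
) -> RunEntry:
    """Train one model on one fold; early-stops on validation accuracy and
    restores the best-validation weights before scoring the test split."""
    model_seed = int((seed * 1_000_003 + fold * 7919) % 2**31)
    model = assemble(spec, len(data.vocab), data.pad_len, model_seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, fold, 101]))
    opt = nn.Adam(model.parameters(), lr=spec.hyper.lr)
    noisy = spec.cognitive_input == "noise"
    noise_name = spec.cognitive_streams[0][0] if noisy else None
    if noisy:
        eval_rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, fold, 202]))
        eval_noise = _noise_batch(eval_rng, data.cog[noise_name].shape)

    def eval_batch(idx):
        batch = data.take(idx, spec)
        if noisy:
            batch["cog"][noise_name] = eval_noise[idx]
        return batch

    best_val, best_state, wait, epochs = -np.inf, None, 0, 0
    failed = False
    fit = split.fit.copy()
    for epoch in range(1, config.max_epochs + 1):
        epochs = epoch
        rng.shuffle(fit)
        epoch_noise = _noise_batch(rng, data.cog[noise_name].shape) if noisy else None
        diverged = False
        for start in range(0, len(fit), spec.hyper.batch):
            idx = fit[start : start + spec.hyper.batch]
            batch = data.take(idx, spec)
            if noisy:
                batch["cog"][noise_name] = epoch_noise[idx]
            loss = model.loss(batch, rng, training=True)
            if not np.isfinite(loss.data):
                diverged = True
                break
            opt.zero_grad()
            loss.backward()
            opt.step()
            if model.embed is not None:
                model.embed.reset_pad_row()
        if diverged:
            failed = True
            break
        val_acc = _accuracy(model.predict(eval_batch(split.val)), data.truths(split.val))
        if val_acc > best_val + config.min_delta:
            best_val, best_state, wait = val_acc, model.state(), 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    if best_state is not None:
        model.load_state(best_state)
    if failed and best_state is None:
        return RunEntry(seed, fold, spec.hyper, epochs, -np.inf, split.test, [], [], 0.0, 0.0, 0.0,
                        failed=True)
    pred = model.predict(eval_batch(split.test))
    true = data.truths(split.test)
    classes = list(range(data.n_classes))
    p, r, f1 = macro_prf(pred, true, classes)
    return RunEntry(seed, fold, spec.hyper, epochs, best_val, split.test, pred, true, p, r, f1,
                    failed=failed)


# ---------------------------------------------------------------------------
# Grid search and the full protocol


def _model_size(h: HyperPoint) -> tuple:
    return (h.dense_dim, h.lstm_dim, h.lstm_layers, h.cnn_filters)


def grid_search(
    spec: ModelSpec,
    data: EncodedDataset,
    config: TrainConfig,
    tuning_seed: int | None = None,
) -> tuple[HyperPoint, list[RunEntry]]:
    """Select the grid point with the best mean validation accuracy over folds.

    Diverged runs are excluded; ties go to the smaller model, then the lower
    learning rate. Tuning uses one seed (the first by default); test metrics
    are never consulted.
    """
    if not config.grid:
        raise ValueError("empty hyper-parameter grid")
    seed = config.seeds[0] if tuning_seed is None else tuning_seed
    splits = make_splits(len(data), config, seed)
    scored: list[tuple[float, tuple, float, HyperPoint, list[RunEntry]]] = []
    from .model import with_hyper

    for point in config.grid:
        entries = [
            train_one(with_hyper(spec, point), data, split, config, seed, fold)
            for fold, split in enumerate(splits)
        ]
        ok = [e for e in entries if not e.failed]
        if not ok:
            continue
        mean_val = float(np.mean([e.val_accuracy for e in ok]))
        scored.append((mean_val, _model_size(point), point.lr, point, entries))
    if not scored:
        raise RuntimeError("every grid point diverged")
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    best = scored[0]
    return best[3], best[4]


def run_protocol(
    spec: ModelSpec,
    data: EncodedDataset,
    config: TrainConfig,
    fit_subsample: float | None = None,
) -> list[RunEntry]:
    """The full study protocol for one model spec.

    Grid search picks the hyper-point (skipped for singleton grids), then one
    run per (seed, fold) with the chosen point. `fit_subsample` implements the
    data ablation: the train-set target size is floor(frac * n_train), the
    validation set stays fixed, and the fit subset shrinks to the remainder.
    """
    best = config.grid[0]
    if len(config.grid) > 1:
        best, _ = grid_search(spec, data, config)
    from .model import with_hyper

    spec = with_hyper(spec, best)
    entries = []
    for seed in config.seeds:
        splits = make_splits(len(data), config, seed)
        for fold, split in enumerate(splits):
            if fit_subsample is not None:
                split = _ablate_split(split, fit_subsample, seed, fold)
            entries.append(train_one(spec, data, split, config, seed, fold))
    return entries


def ablated_train_size(n_train: int, fraction: float) -> int:
    """Train-set size at an ablation fraction (floor arithmetic)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return int(n_train * fraction)


def _ablate_split(split: Split, fraction: float, seed: int, fold: int) -> Split:
    n_target = ablated_train_size(len(split.train), fraction)
    n_fit = n_target - len(split.val)
    if n_fit < 1:
        raise ValueError(f"ablation fraction {fraction} leaves no training sentences")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, fold, 303]))
    fit = rng.permutation(split.fit)[:n_fit]
    return Split(train=np.concatenate([split.val, fit]), val=split.val, fit=fit, test=split.test)


def summarize(entries: list[RunEntry]) -> dict:
    """Mean/std of macro metrics over runs (failed runs excluded)."""
    ok = [e for e in entries if not e.failed]
    if not ok:
        return {"p": np.nan, "r": np.nan, "f1": np.nan, "f1_std": np.nan, "n_runs": 0}
    return {
        "p": float(np.mean([e.macro_p for e in ok])),
        "r": float(np.mean([e.macro_r for e in ok])),
        "f1": float(np.mean([e.macro_f1 for e in ok])),
        "f1_std": float(np.std([e.macro_f1 for e in ok])),
        "n_runs": len(ok),
    }
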