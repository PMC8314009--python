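"""Synthetic corpora shaped like co-registered reading data.

Generates labelled sentences with per-word 105-channel band features, 5-dim
gaze features, and raw word-epoch fixtures, with *planted*, controllable
label-correlated structure:

* EEG: per-token channel noise is Gaussian; a fixed random subset of
  "carrier" channels receives a class-dependent mean shift of
  ``eeg_effect_size`` standard deviations (mimicking a topographically
  localized effect).
* Text: tokens are drawn from a closed vocabulary. With probability
  ``text_effect_size`` a sentence is *informative*: half of its tokens (in
  expectation) come from a small class-specific signal vocabulary, the rest
  from a shared Zipf-weighted background. The remaining sentences are pure
  background, so ``text_effect_size`` interpolates the text channel's
  attainable accuracy linearly from chance (0.0) to perfect (1.0).
* Gaze: log-normal fixation durations whose location shifts weakly with the
  class.

The planted truth (class, carrier channels, signal-token flags) is recorded
for diagnostics only and is never visible to models or evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (
    CANONICAL_BANDS,
    GAZE_FEATURES,
    N_EEG_CHANNELS,
    SAMPLING_RATE,
    SentenceRecord,
    WordEpoch,
)

TASKS = ("binary_sentiment", "ternary_sentiment", "relation_detection")

N_RELATIONS = 11

#: Default per-relation marginals: two dominant relations, a long tail, and
#: most sentences carrying 0-2 relations in expectation.
DEFAULT_RELATION_MARGINALS = (
    0.25, 0.20, 0.08, 0.08, 0.06, 0.05, 0.05, 0.04, 0.04, 0.03, 0.03,
)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_sentences: int = 400
    sentence_length_range: tuple[int, int] = (4, 12)
    task: str = "binary_sentiment"
    n_channels: int = N_EEG_CHANNELS
    bands: tuple[str, ...] = tuple(CANONICAL_BANDS)
    eeg_effect_size: float = 2.0
    text_effect_size: float = 0.3
    gaze_effect_size: float = 0.5
    noise_sd: float = 1.0
    label_distribution: tuple[float, ...] | None = None
    n_signal_channels: int = 16
    vocab_size: int = 2000
    skip_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.eeg_effect_size < 0 or self.text_effect_size < 0 or self.gaze_effect_size < 0:
            raise ValueError("effect sizes must be non-negative")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        lo, hi = self.sentence_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid sentence_length_range")
        if not 0.0 <= self.text_effect_size <= 1.0:
            raise ValueError("text_effect_size must be in [0, 1]")
        if self.label_distribution is None:
            self.label_distribution = (
                DEFAULT_RELATION_MARGINALS
                if self.task == "relation_detection"
                else tuple([1.0 / self.n_classes] * self.n_classes)
            )
        p = np.asarray(self.label_distribution, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.task == "relation_detection":
            if len(p) != N_RELATIONS:
                raise ValueError(f"relation task needs {N_RELATIONS} marginals")
        else:
            if len(p) != self.n_classes or not np.isclose(p.sum(), 1.0):
                raise ValueError("class probabilities must sum to 1")

    @property
    def n_classes(self) -> int:
        return {"binary_sentiment": 2, "ternary_sentiment": 3, "relation_detection": N_RELATIONS}[
            self.task
        ]

    @property
    def multilabel(self) -> bool:
        return self.task == "relation_detection"


@dataclass
class SynthDataset:
    """Generated records plus the planted truth (diagnostics only)."""

    records: list[SentenceRecord]
    task: str
    n_channels: int
    bands: tuple[str, ...]
    config: SynthConfig
    generator_truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def _class_delta(label: int, n_classes: int) -> float:
    """Centered class direction in [-1, 1] (binary: ±1)."""
    if n_classes == 1:
        return 0.0
    return 2.0 * label / (n_classes - 1) - 1.0


def _background_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)  # Zipf-like
    return w / w.sum()


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Draw one dataset under `config`; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_cls = config.n_classes
    carriers = rng.choice(
        config.n_channels, size=min(config.n_signal_channels, config.n_channels), replace=False
    )
    carriers.sort()

    # Closed vocabulary: per-class signal types plus shared background.
    vocab = [f"w{i:05d}" for i in range(config.vocab_size)]
    n_sig = 30
    signal_sets = [vocab[c * n_sig : (c + 1) * n_sig] for c in range(n_cls)]
    background = vocab[n_cls * n_sig :]
    bg_weights = _background_weights(len(background))

    # Per-relation carrier sign patterns (multi-label only).
    rel_signs = rng.choice([-1.0, 1.0], size=(n_cls, carriers.size)) if config.multilabel else None

    records: list[SentenceRecord] = []
    truth_classes: list = []
    for s in range(config.n_sentences):
        if config.multilabel:
            active = np.flatnonzero(rng.random(n_cls) < np.asarray(config.label_distribution))
            labels = frozenset(int(r) for r in active)
            label = None
            shift = np.zeros(carriers.size)
            for r in active:
                shift += rel_signs[r]
            shift *= 0.5 * config.eeg_effect_size * config.noise_sd
            signal_pool = [w for r in active for w in signal_sets[r]]
            truth_classes.append(sorted(labels))
        else:
            label = int(rng.choice(n_cls, p=np.asarray(config.label_distribution)))
            labels = None
            delta = _class_delta(label, n_cls)
            shift = np.full(carriers.size, 0.5 * config.eeg_effect_size * config.noise_sd * delta)
            signal_pool = signal_sets[label]
            truth_classes.append(label)

        length = int(rng.integers(config.sentence_length_range[0], config.sentence_length_range[1] + 1))
        informative = rng.random() < config.text_effect_size and len(signal_pool) > 0
        use_signal = (rng.random(length) < 0.5) & informative
        tokens = [
            signal_pool[rng.integers(len(signal_pool))]
            if use_signal[t]
            else background[rng.choice(len(background), p=bg_weights)]
            for t in range(length)
        ]

        skipped = rng.random(length) < config.skip_prob
        features: dict[str, np.ndarray] = {}
        valid: dict[str, np.ndarray] = {}
        for band in config.bands:
            mat = rng.normal(0.0, config.noise_sd, size=(length, config.n_channels))
            mat[:, carriers] += shift
            mat[skipped] = 0.0
            features[band] = mat
            valid[band] = ~skipped
        features["gaze"], valid["gaze"] = _gaze_matrix(
            rng, length, config, label if label is not None else 0, skipped
        )

        records.append(
            SentenceRecord(
                sent_id=f"s{s:05d}",
                tokens=tokens,
                label=label,
                labels=labels,
                features=features,
                feature_valid=valid,
            )
        )

    truth = {
        "classes": truth_classes,
        "carrier_channels": carriers.tolist(),
        "signal_vocab": [list(s) for s in signal_sets],
    }
    return SynthDataset(
        records=records,
        task=config.task,
        n_channels=config.n_channels,
        bands=tuple(config.bands),
        config=config,
        generator_truth=truth,
    )


def _gaze_matrix(
    rng: np.random.Generator,
    length: int,
    config: SynthConfig,
    label: int,
    skipped: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-normal reading durations with a weak class-correlated location shift."""
    delta = _class_delta(label, config.n_classes)
    mu = np.log(200.0) + 0.2 * config.gaze_effect_size * delta
    ffd = rng.lognormal(mu, 0.25, size=length)
    refix = rng.random(length) < 0.3
    gd = ffd + refix * rng.exponential(60.0, size=length)
    trt = gd + (rng.random(length) < 0.25) * rng.exponential(90.0, size=length)
    gpt = gd + (rng.random(length) < 0.2) * rng.exponential(70.0, size=length)
    n_fix = 1.0 + refix + (trt > gd)
    mat = np.column_stack([gd, trt, ffd, gpt, n_fix])
    assert mat.shape[1] == len(GAZE_FEATURES)
    mat[skipped] = 0.0
    return mat, ~skipped


def generate_word_epochs(
    n_subjects: int,
    carrier_freq: float,
    amplitude: float,
    fixation_layout: list[tuple[int, int]],
    seed: int,
    *,
    n_channels: int = N_EEG_CHANNELS,
    n_time: int = 500,
    noise_sd: float = 0.0,
    sampling_rate: float = SAMPLING_RATE,
) -> list[WordEpoch]:
    """Raw-signal fixtures: per subject, carrier sinusoid + white noise.

    Each epoch is channels x time (µV) with the given fixation intervals in
    samples; amplitude is the sinusoid's peak in µV.
    """
    if not 0.5 <= carrier_freq <= 50.0:
        raise ValueError("carrier frequency must be within 0.5-50 Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(n_time) / sampling_rate
    carrier = amplitude * np.sin(2 * np.pi * carrier_freq * t)
    epochs = []
    for s in range(n_subjects):
        samples = carrier + rng.normal(0.0, noise_sd, size=(n_channels, n_time))
        epochs.append(
            WordEpoch(
                samples=samples,
                sampling_rate=sampling_rate,
                fixations=list(fixation_layout),
                subject_id=f"sub{s:02d}",
            )
        )
    return epochs
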