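"""Core domain types shared across the package.

The unit of modelling is the sentence: tokens, one cognitive feature matrix
per spectral band (105 EEG channels per word) or per gaze variant (5 reading
measures per word), and a task label. Words that were never fixated, or whose
EEG trial was rejected, carry an all-zero feature row flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical spectral bands (Hz). Broadband is the full preprocessed signal.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "broadband": (0.5, 50.0),
    "theta": (4.0, 8.0),
    "alpha": (8.5, 13.0),
    "beta": (13.5, 30.0),
    "gamma": (30.5, 49.5),
}

#: Gaze measure order inside the 5-dim gaze feature vector.
GAZE_FEATURES = ("GD", "TRT", "FFD", "GPT", "nFix")

#: EEG channels retained after montage clean-up (see `n_retained_channels`).
N_EEG_CHANNELS = 105

#: EEG amplifier sampling rate (Hz).
SAMPLING_RATE = 500.0


def n_retained_channels(total: int = 128, outer_ring: int = 13, eog: int = 10) -> int:
    """EEG channels kept for analysis.

    Of a 128-electrode montage, the outermost ring (chin/neck, mostly muscle
    activity) and the EOG electrodes used for ocular-artifact detection are
    dropped, leaving 105 scalp channels.
    """
    return total - outer_ring - eog


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with [low, high] edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")

    @classmethod
    def canonical(cls, name: str) -> "BandSpec":
        try:
            low, high = CANONICAL_BANDS[name]
        except KeyError:
            raise ValueError(f"unknown band {name!r}; expected one of {sorted(CANONICAL_BANDS)}")
        return cls(name, low, high)


@dataclass
class WordEpoch:
    """One word's multi-channel EEG segment for one subject.

    `samples` is channels x time in microvolts; `fixations` are half-open
    [start, end) sample intervals within the epoch.
    """

    samples: np.ndarray
    sampling_rate: float
    fixations: list[tuple[int, int]]
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        n_time = self.samples.shape[1]
        for start, end in self.fixations:
            if not (0 <= start < end <= n_time):
                raise ValueError(f"fixation [{start}, {end}) outside epoch of {n_time} samples")


@dataclass(frozen=True)
class FixationRecord:
    """One fixation event in a sentence reading, in milliseconds."""

    word_index: int
    start: float
    end: float
    order: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("fixation end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FeatureVector:
    """Per-word cognitive feature: 105 EEG channel values or 5 gaze measures.

    Invalid vectors (rejected trial, skipped word) are all-zero with
    ``valid=False`` so sequence lengths stay aligned with tokens.
    """

    values: np.ndarray
    band: str
    valid: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.valid:
            self.values = np.zeros_like(self.values)

    @classmethod
    def invalid(cls, length: int, band: str) -> "FeatureVector":
        return cls(np.zeros(length), band, valid=False)


@dataclass
class SentenceRecord:
    """Tokens plus per-token feature matrices and the task label(s).

    ``features[band]`` is tokens x e (e=105 for EEG bands, 5 for "gaze");
    ``feature_valid[band]`` marks rows that carry real measurements.
    ``label`` holds the class index for single-label tasks; ``labels`` the
    zero-or-more relation indices for multi-label relation detection.
    """

    sent_id: str
    tokens: list[str]
    label: int | None = None
    labels: frozenset[int] | None = None
    features: dict[str, np.ndarray] = field(default_factory=dict)
    feature_valid: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tokens)
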