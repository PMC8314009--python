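"""Word-level cognitive feature extraction.

EEG path: band-pass each word epoch (zero-phase Butterworth), take the
Hilbert envelope (instantaneous amplitude), average it per channel over the
union of the word's fixation intervals, then average the per-subject vectors.
A trial is rejected outright when any raw sample in any channel exceeds
±90 µV. Gaze path: the five standard reading measures (GD, TRT, FFD, GPT,
nFix) from an ordered fixation stream, after dropping fixations shorter than
100 ms, which are unlikely to reflect language processing.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .records import GAZE_FEATURES, BandSpec, FeatureVector, FixationRecord, WordEpoch

#: Raw-amplitude screen (µV): any sample beyond this rejects the whole trial.
ARTIFACT_THRESHOLD_UV = 90.0

#: Fixations shorter than this (ms) are excluded from all gaze measures.
MIN_FIXATION_MS = 100.0

_FILTER_ORDER = 4

#: Cap on filtfilt's odd-extension length (samples); the extension absorbs
#: the narrowband filter transient so it decays before the epoch interior.
_MAX_PADLEN = 1000


def bandpass(signal: np.ndarray, band: BandSpec, sampling_rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the time axis.

    Applied forward-backward (no group delay) with a generous odd-symmetric
    edge extension, since narrow bands ring far longer than filtfilt's
    default padding assumes.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if sampling_rate <= 2.0 * band.high:
        raise ValueError(
            f"band {band.name} (high={band.high} Hz) exceeds Nyquist for fs={sampling_rate} Hz"
        )
    sos = butter(_FILTER_ORDER, (band.low, band.high), btype="bandpass", fs=sampling_rate, output="sos")
    padlen = min(signal.shape[-1] - 1, _MAX_PADLEN)
    return sosfiltfilt(sos, signal, axis=-1, padlen=padlen)


def hilbert_envelope(signal: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude via the analytic signal; non-negative, same shape.

    Computed on the unpadded epoch: artificial extensions distort the
    analytic signal more than the intrinsic spectral edge ripple they try to
    suppress, and that ripple decays within ~100 samples of the epoch edges,
    outside typical fixation windows.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite samples in input")
    return np.abs(hilbert(signal, axis=-1))


def word_feature(
    epoch: WordEpoch,
    band: BandSpec,
    *,
    window: str = "fixations",
) -> FeatureVector:
    """Per-channel mean band envelope over the word's fixation windows.

    ``window="epoch"`` averages over the whole epoch instead of the fixation
    union, for sensitivity analyses. The ±90 µV screen is applied to the raw
    (unfiltered) samples and invalidates the entire trial.
    """
    n_channels = epoch.samples.shape[0]
    if np.any(np.abs(epoch.samples) > ARTIFACT_THRESHOLD_UV):
        return FeatureVector.invalid(n_channels, band.name)
    if window == "fixations" and not epoch.fixations:
        return FeatureVector.invalid(n_channels, band.name)

    env = hilbert_envelope(bandpass(epoch.samples, band, epoch.sampling_rate))
    if window == "epoch":
        sel = np.ones(epoch.samples.shape[1], dtype=bool)
    elif window == "fixations":
        sel = np.zeros(epoch.samples.shape[1], dtype=bool)
        for start, end in epoch.fixations:  # union, not concatenation
            sel[start:end] = True
    else:
        raise ValueError(f"unknown averaging window {window!r}")
    return FeatureVector(env[:, sel].mean(axis=1), band.name)


def average_over_subjects(vectors: list[FeatureVector]) -> FeatureVector:
    """Element-wise mean over valid per-subject vectors.

    Rejected trials are excluded; if no subject contributed a valid trial the
    result is an invalid all-zero vector.
    """
    if not vectors:
        raise ValueError("empty vector list")
    bands = {v.band for v in vectors}
    lengths = {v.values.shape[0] for v in vectors}
    if len(bands) > 1 or len(lengths) > 1:
        raise ValueError("vectors must share band and length")
    valid = [v.values for v in vectors if v.valid]
    if not valid:
        return FeatureVector.invalid(lengths.pop(), bands.pop())
    return FeatureVector(np.mean(valid, axis=0), bands.pop())


def gaze_features(fixations: list[FixationRecord], word_index: int) -> FeatureVector:
    """The five reading measures for one word, in ms (nFix is a count).

    GD: first-pass time, summing consecutive fixations on the word from first
    entry until the gaze leaves it in either direction. TRT: all fixations on
    the word, including re-reading. FFD: the first fixation's duration. GPT:
    everything from first entering the word until first moving past it to the
    right, including regressions launched from it. nFix: fixation count.
    """
    if any(b.order <= a.order for a, b in zip(fixations, fixations[1:])):
        raise ValueError("fixations must be ordered by `order`")
    fixations = [f for f in fixations if f.duration >= MIN_FIXATION_MS]
    on_word = [i for i, f in enumerate(fixations) if f.word_index == word_index]
    if not on_word:
        return FeatureVector.invalid(len(GAZE_FEATURES), "gaze")

    first = on_word[0]
    ffd = fixations[first].duration
    trt = sum(fixations[i].duration for i in on_word)
    n_fix = len(on_word)

    gd = 0.0
    for f in fixations[first:]:
        if f.word_index != word_index:
            break
        gd += f.duration

    gpt = 0.0
    for f in fixations[first:]:
        if f.word_index > word_index:
            break
        gpt += f.duration

    return FeatureVector(np.array([gd, trt, ffd, gpt, float(n_fix)]), "gaze")
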