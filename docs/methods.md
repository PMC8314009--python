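# Methods

## Problem and model

`cogfuse` studies whether word-level brain-activity features recorded during
natural reading carry information that complements the text itself for
sentence-level NLP tasks (binary/ternary sentiment, multi-label relation
detection). The classifier is a *late-fusion* multi-tower network:

* **Text tower.** Token embeddings (one of three kinds, below) feed a masked
  bidirectional LSTM; the concatenated final states of both directions pass
  through two dense layers (ReLU) with dropout between them.
* **Cognitive tower(s).** The per-word feature sequence (105 EEG channel
  values per band, or 5 gaze measures, or 105-dim uniform noise for the
  control) is decoded either by an analogous recurrent component or by an
  inception-style convolutional component: three parallel 1-D convolutions
  with kernel sizes 1, 4 and 7 (`cnn_filters` each, ELU activations), their
  channel-concatenated output max-pooled (pool size from the grid), then
  flattened into the same two-dense-layer block. When several frequency
  bands are attached, each band gets its own tower by default (a
  five-component model for text + θ/α/β/γ); a single wide 420-dim tower is
  available behind `band_fusion="concat"`.
* **Fusion and head.** Tower outputs are concatenated (addition, subtraction
  and elementwise maximum are implemented as alternatives; non-concat
  fusions require equal tower widths, which holds by construction since all
  towers end in `dense_dim`). A final dense layer yields softmax class
  scores for single-label tasks or independent sigmoid scores for the
  11-way multi-label relation task, where a sentence receives every label
  whose score exceeds a tuned threshold (the empty set means "no relation").

Optimization is Adam with the grid learning rate; losses are cross-entropy
(softmax head) and per-class binary cross-entropy (sigmoid head). The paper
family this architecture belongs to leaves optimizer and loss to the
implementer; these are the family defaults.

### Why a local NumPy network library

The towers, autograd engine and Adam implementation live in `cogfuse.nn` —
a compact reverse-mode autodiff over float64 NumPy arrays sized exactly to
these models. Operating on plain arrays keeps every training run bitwise
reproducible from its integer seed (initialization, shuffling and dropout
all draw from explicit `numpy` generators), which the test suite treats as
a contract. Gradients of every operation, including the LSTM recurrence and
the convolution/pooling path, are checked against central finite
differences.

## Word-level EEG features

Epochs are channels × time segments (µV) at 500 Hz aligned to one word, with
the word's fixation intervals in samples. The pipeline per band:

1. **Band-pass** with a 4th-order Butterworth applied forward–backward
   (zero phase). Bands: broadband 0.5–50 Hz, θ 4–8, α 8.5–13, β 13.5–30,
   γ 30.5–49.5.
2. **Hilbert envelope** — the instantaneous amplitude of the analytic
   signal.
3. **Fixation averaging** — per channel, the mean envelope over the union
   of the word's fixation intervals (a whole-epoch window is available via
   `window="epoch"` for sensitivity analysis).
4. **Subject averaging** — element-wise mean over subjects' valid vectors.

A trial is rejected outright (all channels, `valid=False`, zero vector)
when any raw sample in any channel exceeds ±90 µV; the screen is applied to
the unfiltered signal. Words never fixated also yield invalid zero vectors,
which keeps feature sequences aligned with token sequences; models consume
the zeros.

**Edge handling.** Narrow bands ring for hundreds of samples, so the
band-pass uses filtfilt's odd-symmetric extension with a generous length
(up to 1000 samples) instead of the default. The Hilbert transform runs on
the *unpadded* epoch: measured on pure-tone fixtures, even-symmetric
reflection padding reverses the oscillation's phase at the boundary and
injects several percent of envelope ripple into the epoch interior, whereas
the intrinsic spectral edge ripple of the unpadded transform decays within
~100 samples — outside typical fixation windows. With this scheme a
noiseless 10 µV tone is recovered to within 0.1% in its own band and
cross-band leakage stays below 2%.

## Gaze features

Five standard reading measures per word, computed from the ordered fixation
stream after dropping fixations shorter than 100 ms (too short to reflect
language processing): gaze duration (first-pass time on the word), total
reading time, first fixation duration, go-past time (everything from first
entering the word until first moving past it to the right, including
regressions launched from it), and number of fixations. Invariants enforced
by construction and tested: FFD ≤ GD ≤ TRT and GD ≤ GPT.

## Word representations

* `random`: trainable vocabulary-sized table, d = 32, pad row pinned to 0.
* `static_pretrained`: d = 300 vectors loaded from GloVe-format text files
  and frozen; out-of-vocabulary tokens get the zero vector. For synthetic
  corpora with no real vector file, a deterministic hash-based table stands
  in (clearly labelled synthetic; frozen like the real thing).
* `contextual`: d = 768. The bundled encoder is a deterministic stub —
  seeded hash embeddings mixed with a fixed-weight average of the left
  context, so identical tokens differ across contexts — and any callable
  returning a tokens × 768 matrix (e.g., a real transformer with sub-word
  vectors mean-pooled per word) plugs into the same interface. The stub
  exists so the full pipeline is exercisable without pretrained downloads;
  results obtained with it say nothing about real contextual embeddings.

## Training protocol

Per run: an 80/20 train/test split, with 10% of the train set held out for
validation; validation accuracy (exact-set match for multi-label) drives
both early stopping (patience in epochs, minimum improvement 1e-7) and
hyper-parameter selection; the best-validation weights are restored before
test scoring. The full-scale protocol uses five random seeds
(13, 22, 42, 66, 78) × five resampled splits, patience 80, up to 500
epochs. Grid values are restricted to the admissible ranges (LSTM width
64–512, 1–4 layers, 14–18 CNN filters, kernel ensemble [1,4,7], pool 3–7,
dense 8–512, dropout 0.1/0.3/0.5, batch 20/40/60, learning rate 1e-1…1e-5,
multi-label threshold 0.3/0.5/0.7). Grid selection maximizes mean
validation accuracy over folds; diverged runs (non-finite loss) are
excluded; ties go to the smaller model, then the lower learning rate. Test
indices are never visible to training or selection.

**Desk-scale protocol.** Synthetic studies run with the same five seeds but
two resampled splits per seed (10 runs), max 25 epochs, patience 6, and a
reduced four-point grid (LSTM 64; dense 16/32/64; dropout 0.1/0.3; lr
1e-2/1e-3; batch 20). These sizes were fixed once for single-CPU runtimes;
the synthetic corpora converge within a handful of epochs, so the shortened
patience changes nothing qualitatively.

**Data ablation.** At fraction f the train-set target size is
⌊f · n_train⌋; the validation set is kept fixed and the fit subset shrinks
to the remainder, so early stopping sees a constant-size validation set and
only the training-size effect varies. Test splits are untouched. (A 263-
sentence corpus at f = 0.5 gives 105 training sentences.) At f = 1 the run
is identical to the unablated protocol.

**Noise control.** The uniform-[0,1) noise matrices are redrawn every
epoch during training (and fixed, seeded, for evaluation), making the
channel uninformative by construction rather than memorizable.

## Evaluation and statistics

Macro-averaged precision, recall and F1 from per-class confusion counts;
0/0 ratios are defined as 0, penalizing never-predicted classes under label
imbalance. Multi-label counts are computed per label over binary indicator
vectors. The implementation is verified exactly against an independent
brute-force per-class loop and against scikit-learn.

Model comparisons use a paired bootstrap over test sentences: both systems
predict the same test sets (shared splits); each of n_boot resamples
redraws sentences with replacement per run and recomputes the run-averaged
macro-F1 difference; the one-sided p-value is the add-one-smoothed fraction
of resamples with difference ≤ 0. Five scalar per-run scores cannot support
a resampling test, so the sentence level is the default unit; a run-level
mode is deliberately not offered. Family-wise error uses Bonferroni:
reject iff p < α/N, with N computed from the executed plan (embeddings ×
EEG feature sets; the full 3 × 6 grid gives N = 18 and a corrected level of
0.003 at α = 0.05).

## Synthetic data generator

The generator emulates the *shape* of co-registered reading corpora:
tokenized sentences (default 400 sentences of 4–12 tokens over a closed
2000-type vocabulary), per-word 105-channel features in five spectral
variants, five gaze features per word, and either sentiment labels (2 or 3
classes) or 11 relation-type multi-labels drawn from skewed independent
marginals (two dominant relations; most sentences carry 0–2).

Planted structure, all seeded:

* **EEG**: i.i.d. Gaussian channel noise (σ = `noise_sd`); a fixed random
  subset of 16 carrier channels receives a class-dependent mean shift so
  that adjacent extreme classes differ by `eeg_effect_size` standard
  deviations (a topographically localized effect a decoder must find).
  Relations get seeded ±1 carrier patterns that add when co-occurring.
* **Text**: with probability `text_effect_size` a sentence is informative —
  about half its tokens come from a small class-exclusive signal
  vocabulary — otherwise all tokens are Zipf-weighted background. The
  parameter therefore interpolates the text channel's attainable accuracy
  linearly from chance (0) to perfect (1); 0.3 yields the weak-text regime
  in which a useful second modality should show a clear gain.
* **Gaze**: log-normal durations with a weak class-dependent location
  shift, respecting the reading-measure inequalities.
* About 10% of words are "skipped" (invalid zero rows), mimicking skipped
  words in reading.

What the generator does *not* emulate: real EEG spectra and channel
covariance, ocular artifacts, fixation-sequence autocorrelation, natural
language statistics, or inter-subject variability. Passing recovery tests
therefore demonstrates that the pipeline extracts planted localized signal
under realistic dimensionality and sample sizes — not that real EEG carries
such signal.

Raw-signal fixtures (`generate_word_epochs`) are carrier sinusoids plus
white noise per channel at 500 Hz with known fixation layouts, used to test
the feature path end to end against closed-form expectations.

## Reference study and degenerate inputs

`experiments.planted_signal_study` is the package's standing recovery
experiment: 400 planted sentences (EEG effect 2.0, text effect 0.3),
random embeddings, text-only baseline vs theta-augmented vs uniform-noise
control under the desk-scale protocol, with the paired bootstrap evaluated
at the full-study corrected level (α/18). All three models share one fixed
grid point (LSTM 64, dense 16, dropout 0.1, lr 1e-2, batch 20): at this
corpus size, independent per-cell grid selection adds more between-model
variance than the baseline-vs-noise neutrality comparison can absorb, so
selection is deliberately held fixed in this study (per-cell tuning remains
the default elsewhere). Expected behavior, asserted by
the acceptance tests: the EEG model's mean macro-F1 exceeds the baseline by
at least 0.10 with a corrected rejection, while the noise control stays
within ±0.05 of the baseline with no corrected rejection in at least 80% of
per-run tests.

Degenerate inputs have defined behavior throughout: empty fixation lists
and all-rejected trials yield invalid zero vectors; an all-invalid subject
set averages to an invalid vector; all-pad sentences encode to the
deterministic empty-sequence state; datasets smaller than 10 sentences,
ablation fractions leaving no training sentences, empty grids, thresholds
outside (0,1) and bands beyond Nyquist raise errors.

## Known limitations

* CPU-scale only; the NumPy towers are not meant for large corpora.
* The contextual stub is a plumbing device, not a language model.
* The reduced protocol trades the full 5 × 5 seed × fold design for
  runtime; reported standard deviations are accordingly coarser.
* ZuCo's MAT containers are not parsed; real-data use requires an adapter
  producing `WordEpoch`/`SentenceRecord` objects or the HDF5 container.
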