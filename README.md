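# cogfuse

Multi-modal sentence classification from text and word-level brain-activity
features recorded during natural reading.

When people read, co-registered EEG and eye tracking yield a fixation-aligned
record of language processing: for every word, the multi-channel EEG during
its fixations and the standard reading-time measures. `cogfuse` implements a
complete, tested pipeline for asking whether those signals carry information
that *complements* the text for sentence-level NLP tasks (binary/ternary
sentiment, 11-way multi-label relation detection):

* **Feature extraction** — per word and frequency band (broadband 0.5–50 Hz,
  θ 4–8, α 8.5–13, β 13.5–30, γ 30.5–49.5), the Hilbert envelope of the
  zero-phase band-passed signal averaged over the word's fixations and over
  subjects, yielding one value per retained channel (105 of a 128-electrode
  montage, after dropping the outer ring and EOG electrodes); trials with any
  raw sample beyond ±90 µV are rejected. Plus the five gaze measures
  (GD, TRT, FFD, GPT, nFix) with sub-100 ms fixations excluded.
* **Models** — a late-fusion two-tower classifier: a BiLSTM text tower over
  random (d=32), static pretrained (d=300, GloVe format) or contextual
  (d=768) word embeddings, fused with a recurrent or inception-style
  convolutional EEG decoder (parallel 1-D convolutions, kernels 1/4/7);
  softmax head for sentiment, thresholded sigmoid head for multi-label
  relations. Gaze- and uniform-noise-augmented variants serve as controls.
* **Protocol** — seeded 80/20 splits with a 10% validation carve-out, early
  stopping, hyper-parameter grids over the admissible ranges, five canonical
  random seeds; every run is bitwise reproducible from its seed.
* **Statistics** — macro precision/recall/F1; paired sentence-level
  bootstrap against the text baseline; Bonferroni correction over the
  embeddings × EEG-feature-set family (α/N; the full 3 × 6 family gives the
  corrected level 0.05/18 ≈ 0.003).
* **Synthetic data** — a generator that emulates the corpus shape (tokens,
  105-channel band features, gaze, labels) with planted, seeded
  label-correlated structure, so every stage is testable without any
  external downloads.

The neural components run on a compact NumPy autodiff engine bundled in
`cogfuse.nn` (gradient-checked against finite differences), which keeps the
whole pipeline dependency-light and deterministic.

## Worked example

```python
from cogfuse.synthetic import SynthConfig, generate_dataset
from cogfuse.embeddings import EmbeddingSpec
from cogfuse.model import HyperPoint, ModelSpec
from cogfuse.training import TrainConfig, encode_dataset, run_protocol, summarize

dataset = generate_dataset(SynthConfig(n_sentences=400, bands=("theta",), seed=17))
hyper = HyperPoint(lstm_dim=64, dense_dim=16, dropout=0.1, lr=1e-2, batch=20)
config = TrainConfig(n_folds=1, max_epochs=20, patience=5, grid=(hyper,))

for cognitive in ("none", "eeg"):
    spec = ModelSpec(embedding=EmbeddingSpec.of("random"), n_classes=2,
                     cognitive_input=cognitive, eeg_bands=("theta",), hyper=hyper)
    data = encode_dataset(dataset.records, spec, n_classes=2)
    stats = summarize(run_protocol(spec, data, config))
    print(f"{cognitive:>5}: F1 {stats['f1']:.3f} ({stats['f1_std']:.2f})")
```

prints

```
 none: F1 0.591 (0.13)
  eeg: F1 1.000 (0.00)
```

— on this synthetic corpus the text channel alone supports only weak
classification (about a third of sentences carry no text signal at all, by
construction), while the theta-band features carry a planted 2-SD localized
effect that the EEG tower recovers essentially perfectly. The gap between
the rows is the quantity the bootstrap test then assesses against the text
baseline.

The same studies are scriptable from the shell:

```bash
cogfuse simulate sim.yaml --seed 3 --out data/ds
cogfuse run-grid data/ds --embedding random --modality baseline --modality theta
cogfuse reduce-relation data/rel --label 0 --out data/rel-binary
```

## Layout

| Module | Contents |
|---|---|
| `cogfuse.synthetic` | corpus and raw-epoch generators with planted structure |
| `cogfuse.features` | band-pass, Hilbert envelopes, word/gaze features |
| `cogfuse.embeddings` | vocabulary, GloVe-format reader, contextual interface |
| `cogfuse.model` | towers, fusion, heads, hyper-parameter grid |
| `cogfuse.training` | splits, early stopping, grid search, determinism |
| `cogfuse.evaluation` | macro metrics, paired bootstrap, Bonferroni |
| `cogfuse.experiments` | study orchestration, ablations, tables |
| `cogfuse.datasets_io` | HDF5 + JSON-lines dataset container |
| `cogfuse.nn` | NumPy autograd, layers, Adam |

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.
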