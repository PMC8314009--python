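"""On-disk dataset container: JSON-lines metadata + HDF5 arrays + manifest.

A dataset directory holds:

* ``metadata.jsonl`` — one object per sentence (id, tokens, labels);
* ``arrays.h5`` — one group per band with ``features`` (sentences x
  max_tokens x channels) and ``valid`` masks, plus per-sentence token counts;
* ``manifest.json`` — format version, channel count, band table, generator
  config and seed, and SHA-256 content checksums.

Writes are atomic (temp directory + rename); loads verify the checksums and
the format version. Token indexing is 0-based and fixation intervals are
half-open [start, end) throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import shutil
import tempfile
from pathlib import Path

import h5py
import numpy as np

from .records import CANONICAL_BANDS, SentenceRecord
from .synthetic import SynthConfig, SynthDataset

FORMAT_VERSION = 1


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: SynthDataset, path: str | os.PathLike) -> None:
    """Serialize `dataset` to a container directory (atomic)."""
    path = Path(path)
    records = dataset.records
    max_len = max(len(r) for r in records)
    bands = list(records[0].features)
    for rec in records:
        for band in bands:
            if rec.features[band].shape[0] != len(rec.tokens):
                raise ValueError(f"{rec.sent_id}: feature/token length mismatch in {band!r}")
            if rec.feature_valid[band].shape[0] != len(rec.tokens):
                raise ValueError(f"{rec.sent_id}: mask/array mismatch in {band!r}")

    tmp = Path(tempfile.mkdtemp(prefix=path.name + ".", dir=path.parent or "."))
    try:
        with open(tmp / "metadata.jsonl", "w", encoding="utf-8") as fh:
            for rec in records:
                obj = {"id": rec.sent_id, "tokens": rec.tokens}
                if rec.label is not None:
                    obj["label"] = rec.label
                if rec.labels is not None:
                    obj["labels"] = sorted(rec.labels)
                fh.write(json.dumps(obj) + "\n")

        with h5py.File(tmp / "arrays.h5", "w") as h5:
            h5.create_dataset("n_tokens", data=np.array([len(r) for r in records], dtype=np.int64))
            for band in bands:
                width = records[0].features[band].shape[1]
                feats = np.zeros((len(records), max_len, width))
                valid = np.zeros((len(records), max_len), dtype=bool)
                for i, rec in enumerate(records):
                    feats[i, : len(rec)] = rec.features[band]
                    valid[i, : len(rec)] = rec.feature_valid[band]
                grp = h5.create_group(f"bands/{band}")
                grp.create_dataset("features", data=feats)
                grp.create_dataset("valid", data=valid)

        with open(tmp / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(dataset.generator_truth, fh)

        manifest = {
            "format_version": FORMAT_VERSION,
            "task": dataset.task,
            "n_channels": dataset.n_channels,
            "bands": list(dataset.bands),
            "band_table": {b: CANONICAL_BANDS[b] for b in dataset.bands if b in CANONICAL_BANDS},
            "config": dataclasses.asdict(dataset.config),
            "indexing": {"tokens": "0-based", "fixations": "half-open [start, end) samples"},
            "checksums": {
                name: _sha256(tmp / name) for name in ("metadata.jsonl", "arrays.h5", "truth.json")
            },
        }
        with open(tmp / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

        if path.exists():
            shutil.rmtree(path)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            shutil.rmtree(tmp, ignore_errors=True)


def read_dataset(path: str | os.PathLike, bands: list[str] | None = None) -> SynthDataset:
    """Load a container; verifies checksums and the format version.

    `bands` restricts which feature groups are materialized; requesting a
    band that was never extracted raises a KeyError.
    """
    path = Path(path)
    with open(path / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported container version {manifest['format_version']}")
    for name, expected in manifest["checksums"].items():
        actual = _sha256(path / name)
        if actual != expected:
            raise ValueError(f"checksum mismatch for {name}: container corrupted")

    stored_bands = list(manifest["bands"]) + ["gaze"]
    want = stored_bands if bands is None else list(bands)
    for band in want:
        if band not in stored_bands:
            raise KeyError(f"band {band!r} not extracted in this container")

    with open(path / "metadata.jsonl", encoding="utf-8") as fh:
        meta = [json.loads(line) for line in fh]
    with open(path / "truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)

    records: list[SentenceRecord] = []
    with h5py.File(path / "arrays.h5", "r") as h5:
        n_tokens = h5["n_tokens"][:]
        if len(n_tokens) != len(meta):
            raise ValueError("metadata/array sentence count mismatch")
        band_data = {
            band: (h5[f"bands/{band}/features"][:], h5[f"bands/{band}/valid"][:]) for band in want
        }
    for i, obj in enumerate(meta):
        n = int(n_tokens[i])
        features = {b: band_data[b][0][i, :n] for b in want}
        valid = {b: band_data[b][1][i, :n] for b in want}
        records.append(
            SentenceRecord(
                sent_id=obj["id"],
                tokens=obj["tokens"],
                label=obj.get("label"),
                labels=frozenset(obj["labels"]) if "labels" in obj else None,
                features=features,
                feature_valid=valid,
            )
        )

    cfg = manifest["config"]
    for key in ("sentence_length_range", "bands", "label_distribution"):
        if isinstance(cfg.get(key), list):
            cfg[key] = tuple(cfg[key])
    config = SynthConfig(**cfg)
    return SynthDataset(
        records=records,
        task=manifest["task"],
        n_channels=manifest["n_channels"],
        bands=tuple(manifest["bands"]),
        config=config,
        generator_truth=truth,
    )
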