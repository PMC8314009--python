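"""Layers built on the autograd engine: dense, dropout, embeddings, BiLSTM."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, embedding_lookup

__all__ = ["Module", "Dense", "Dropout", "Embedding", "BiLSTM"]


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []

        def collect(v):
            if isinstance(v, Tensor):
                if v.requires_grad:
                    out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item)

        for v in vars(self).values():
            collect(v)
        return out

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data[...] = s


def _uniform(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_in)
        self.w = _uniform(rng, (d_in, d_out), scale)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Dropout(Module):
    """Inverted dropout; identity when `training` is False."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None, training: bool) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Embedding(Module):
    """Trainable token-embedding table; row 0 (pad) is pinned to zero."""

    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator):
        table = rng.uniform(-0.05, 0.05, size=(n_vocab, d))
        table[0] = 0.0
        self.table = Tensor(table, requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding_lookup(self.table, indices)

    def reset_pad_row(self) -> None:
        self.table.data[0] = 0.0


class _LSTMCellParams(Module):
    """One direction of one LSTM layer; gate order (i, f, g, o)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_hidden)
        self.wx = _uniform(rng, (d_in, 4 * d_hidden), scale)
        self.wh = _uniform(rng, (d_hidden, 4 * d_hidden), scale)
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.d_hidden = d_hidden


class BiLSTM(Module):
    """Stacked bidirectional LSTM with per-timestep masking.

    Pad positions (mask 0) leave the hidden and cell states untouched, so
    appending padding to a batch never changes any real sentence's encoding.
    """

    def __init__(self, d_in: int, d_hidden: int, n_layers: int, rng: np.random.Generator):
        self.layers: list[tuple[_LSTMCellParams, _LSTMCellParams]] = []
        d = d_in
        for _ in range(n_layers):
            fwd = _LSTMCellParams(d, d_hidden, rng)
            bwd = _LSTMCellParams(d, d_hidden, rng)
            self.layers.append((fwd, bwd))
            d = 2 * d_hidden
        self.d_out = d

    @staticmethod
    def _run_direction(
        cell: _LSTMCellParams,
        steps: list[Tensor],
        masks: list[np.ndarray],
        reverse: bool,
    ) -> tuple[list[Tensor], Tensor]:
        h_dim = cell.d_hidden
        batch = steps[0].shape[0]
        h = Tensor(np.zeros((batch, h_dim)))
        c = Tensor(np.zeros((batch, h_dim)))
        order = range(len(steps) - 1, -1, -1) if reverse else range(len(steps))
        outputs: list[Tensor | None] = [None] * len(steps)
        for t in order:
            gates = steps[t] @ cell.wx + h @ cell.wh + cell.b
            i = gates[:, 0 * h_dim : 1 * h_dim].sigmoid()
            f = gates[:, 1 * h_dim : 2 * h_dim].sigmoid()
            g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
            o = gates[:, 3 * h_dim : 4 * h_dim].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = Tensor(masks[t][:, None])
            one_minus = Tensor(1.0 - masks[t][:, None])
            c = m * c_new + one_minus * c
            h = m * h_new + one_minus * h
            outputs[t] = h
        return outputs, h  # h is the final state over real tokens

    def __call__(self, steps: list[Tensor], masks: list[np.ndarray]) -> tuple[list[Tensor], Tensor]:
        """Returns per-timestep outputs and the concatenated final states."""
        final_parts: list[Tensor] = []
        for fwd, bwd in self.layers:
            out_f, h_f = self._run_direction(fwd, steps, masks, reverse=False)
            out_b, h_b = self._run_direction(bwd, steps, masks, reverse=True)
            steps = [concat([a, b], axis=1) for a, b in zip(out_f, out_b)]
            final_parts = [h_f, h_b]
        return steps, concat(final_parts, axis=1)
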