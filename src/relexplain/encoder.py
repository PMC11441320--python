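"""Small trainable transformer encoder with a two-way softmax decision head.

The encoder is deliberately tiny (identifier strings like ``"tiny-2l-32d"``)
so the full pipeline — training, prediction, and layer-level attribution —
runs on a single CPU in seconds.  Architecture follows the standard post-LN
encoder: token + learned position embeddings, L blocks of multi-head
self-attention and a GELU feed-forward, then a tanh pooler over the
snippet-start token feeding a two-class linear decision layer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import AdamW, Parameter, Tensor, cross_entropy_logits, embedding, no_grad

_NEG_INF = -1e9


@dataclass
class EncoderConfig:
    vocab_size: int
    n_layers: int = 2
    d_model: int = 32
    n_heads: int = 2
    d_ff: int = 64
    max_len: int = 128
    pad_id: int = 0
    n_classes: int = 2
    rel_window: int = 8  # clipped relative-position bias range per head

    @classmethod
    def from_identifier(cls, identifier: str, vocab_size: int,
                        max_len: int = 128, pad_id: int = 0) -> "EncoderConfig":
        """Parse identifiers of the form ``tiny-<L>l-<D>d[-<H>h]``."""
        m = re.fullmatch(r"tiny-(\d+)l-(\d+)d(?:-(\d+)h)?", identifier)
        if m is None:
            raise ValueError(
                f"unknown encoder identifier {identifier!r}; expected 'tiny-<L>l-<D>d[-<H>h]'"
            )
        n_layers, d_model = int(m.group(1)), int(m.group(2))
        n_heads = int(m.group(3)) if m.group(3) else max(1, d_model // 16)
        return cls(vocab_size=vocab_size, n_layers=n_layers, d_model=d_model,
                   n_heads=n_heads, d_ff=4 * d_model, max_len=max_len, pad_id=pad_id)


class TransformerClassifier:
    def __init__(self, config: EncoderConfig, seed: int = 0):
        if config.d_model % config.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        s = 0.02
        p: dict[str, Parameter] = {}

        def init(name: str, *shape: int, zero: bool = False, one: bool = False):
            if zero:
                data = np.zeros(shape)
            elif one:
                data = np.ones(shape)
            else:
                data = rng.normal(0.0, s, size=shape)
            p[name] = Parameter(data)

        init("tok_emb", c.vocab_size, c.d_model)
        init("pos_emb", c.max_len, c.d_model)
        init("emb_ln_g", c.d_model, one=True)
        init("emb_ln_b", c.d_model, zero=True)
        for i in range(c.n_layers):
            init(f"l{i}.wq", c.d_model, c.d_model)
            init(f"l{i}.bq", c.d_model, zero=True)
            init(f"l{i}.wk", c.d_model, c.d_model)
            init(f"l{i}.bk", c.d_model, zero=True)
            init(f"l{i}.wv", c.d_model, c.d_model)
            init(f"l{i}.bv", c.d_model, zero=True)
            init(f"l{i}.wo", c.d_model, c.d_model)
            init(f"l{i}.bo", c.d_model, zero=True)
            init(f"l{i}.ln1_g", c.d_model, one=True)
            init(f"l{i}.ln1_b", c.d_model, zero=True)
            init(f"l{i}.w1", c.d_model, c.d_ff)
            init(f"l{i}.b1", c.d_ff, zero=True)
            init(f"l{i}.w2", c.d_ff, c.d_model)
            init(f"l{i}.b2", c.d_model, zero=True)
            init(f"l{i}.ln2_g", c.d_model, one=True)
            init(f"l{i}.ln2_b", c.d_model, zero=True)
            # learned relative-position attention bias, clipped to ±rel_window
            init(f"l{i}.rel", c.n_heads, 2 * c.rel_window + 1, zero=True)
        init("pool_w", c.d_model, c.d_model)
        init("pool_wa", c.d_model, c.d_model)
        init("pool_wb", c.d_model, c.d_model)
        init("pool_b", c.d_model, zero=True)
        init("cls_w", c.d_model, c.n_classes)
        init("cls_b", c.n_classes, zero=True)
        self.params = p

    # -- forward pieces ------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def _mask_bias(self, ids: np.ndarray) -> np.ndarray:
        """(B, 1, 1, T) additive attention bias hiding padding keys."""
        pad = ids == self.config.pad_id
        return np.where(pad, _NEG_INF, 0.0)[:, None, None, :]

    def _block(self, x: Tensor, bias: np.ndarray, i: int) -> Tensor:
        p = self.params
        c = self.config
        B, T, D = x.shape
        H = c.n_heads
        dh = D // H

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

        q = heads(x @ p[f"l{i}.wq"] + p[f"l{i}.bq"])
        k = heads(x @ p[f"l{i}.wk"] + p[f"l{i}.bk"])
        v = heads(x @ p[f"l{i}.wv"] + p[f"l{i}.bv"])
        w = c.rel_window
        dist = np.clip(np.arange(T)[None, :] - np.arange(T)[:, None], -w, w) + w
        rel = p[f"l{i}.rel"].take(dist, axis=1)  # (H, T, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)) + rel + bias
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        x = (x + (ctx @ p[f"l{i}.wo"] + p[f"l{i}.bo"])).layer_norm(
            p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"]
        )
        ff = ((x @ p[f"l{i}.w1"] + p[f"l{i}.b1"]).gelu() @ p[f"l{i}.w2"]) + p[f"l{i}.b2"]
        return (x + ff).layer_norm(p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])

    def embed(self, ids: np.ndarray) -> Tensor:
        """Layer-0 activations: token + position embeddings, normalized."""
        p = self.params
        B, T = ids.shape
        if T > self.config.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.config.max_len}")
        x = embedding(p["tok_emb"], ids) + embedding(p["pos_emb"], np.arange(T))
        return x.layer_norm(p["emb_ln_g"], p["emb_ln_b"])

    def head(self, x: Tensor, anchors: np.ndarray | None = None) -> Tensor:
        """Decision logits from final-layer activations (B, T, D) -> (B, C).

        The decision layer sees the snippet-start token plus the encoder
        outputs at the two entity anchor positions (first marker/placeholder
        token of each focus mention); *anchors* is (B, 2) token indices and
        defaults to the snippet-start position.
        """
        p = self.params
        B, T, D = x.shape
        if anchors is None:
            anchors = np.zeros((B, 2), dtype=np.int64)
        flat = x.reshape(B * T, D)
        offsets = np.arange(B) * T
        first = flat.take(offsets, axis=0)
        at_a = flat.take(offsets + anchors[:, 0], axis=0)
        at_b = flat.take(offsets + anchors[:, 1], axis=0)
        pooled = (
            first @ p["pool_w"] + at_a @ p["pool_wa"] + at_b @ p["pool_wb"] + p["pool_b"]
        ).tanh()
        return pooled @ p["cls_w"] + p["cls_b"]

    def forward(self, ids: np.ndarray, anchors: np.ndarray | None = None,
                collect_layers: bool = False, mask_ids: np.ndarray | None = None):
        """Logits for a (B, T) id batch; optionally all layer activations.

        With ``collect_layers`` the second return value is a list of L+1
        tensors: index 0 is the embedding output, index i the output of
        block i.  ``mask_ids`` substitutes the ids used to build the
        attention mask (attribution baselines keep the original mask).
        """
        ids = np.asarray(ids)
        bias = self._mask_bias(ids if mask_ids is None else np.asarray(mask_ids))
        x = self.embed(ids)
        acts = [x]
        for i in range(self.config.n_layers):
            x = self._block(x, bias, i)
            acts.append(x)
        logits = self.head(x, anchors)
        if collect_layers:
            return logits, acts
        return logits

    def forward_from_layer(self, layer: int, acts: Tensor, ids: np.ndarray,
                           anchors: np.ndarray | None = None) -> Tensor:
        """Resume the forward pass with *acts* substituted as layer output."""
        if not (0 <= layer <= self.config.n_layers):
            raise ValueError(f"layer {layer} out of range [0, {self.config.n_layers}]")
        bias = self._mask_bias(np.asarray(ids))
        x = acts
        for i in range(layer, self.config.n_layers):
            x = self._block(x, bias, i)
        return self.head(x, anchors)

    # -- inference / training helpers ---------------------------------------

    def predict_proba(self, ids: np.ndarray, anchors: np.ndarray | None = None) -> np.ndarray:
        with no_grad():
            logits = self.forward(np.asarray(ids), anchors)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def loss(self, ids: np.ndarray, labels: np.ndarray,
             anchors: np.ndarray | None = None) -> Tensor:
        return cross_entropy_logits(self.forward(ids, anchors), labels)

    def make_optimizer(self, lr: float, total_steps: int | None = None,
                       weight_decay: float = 0.01, warmup_frac: float = 0.1) -> AdamW:
        return AdamW(self.params, lr=lr, weight_decay=weight_decay,
                     total_steps=total_steps, warmup_frac=warmup_frac)

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=np.float64)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "encoder_config.json").write_text(json.dumps(asdict(self.config)))
        np.savez(directory / "weights.npz", **self.state_dict())

    @classmethod
    def load(cls, directory: str | Path) -> "TransformerClassifier":
        directory = Path(directory)
        config = EncoderConfig(**json.loads((directory / "encoder_config.json").read_text()))
        model = cls(config, seed=0)
        with np.load(directory / "weights.npz") as state:
            model.load_state_dict({k: state[k] for k in state.files})
        return model
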