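"""The label-embedding transformer.

A standard encoder-decoder transformer in which the encoder reads the
residue feature matrix (with sinusoidal positional encodings) and the
decoder reads one learnable token per function class. Three attention roles
fall out of this layout:

* residue-residue attention (encoder self-attention),
* function-function attention (decoder self-attention — each class updates
  its representation from the other classes), and
* function-residue attention (decoder cross-attention into the sequence).

The decoder input carries no positional encoding: function tokens are an
unordered set, so the decoder is permutation-equivariant over classes.
The decoder output ``Z`` (one d_model vector per function) feeds either a
single shared linear+sigmoid head or C independent function-specific heads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .autodiff import Parameter, Tensor, concatenate, no_grad
from .encoding import FunctionVocabulary

_NEG_INF = -1e9
_LN_EPS = 1e-5


@dataclass
class ModelConfig:
    d_model: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    d_ff: int = 128
    dropout: float = 0.0
    L: int = 50
    C: int = 15
    d_input: int = 40
    pe_base: float = 1000.0     # base constant printed in the model's encoding
    d_model_pe: int | None = None  # defaults to d_model
    mask_padding: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by n_heads={self.n_heads}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class AttentionRecord:
    """Per-layer (batch, heads, query, key) attention weights."""

    residue_residue: list[np.ndarray] = field(default_factory=list)
    function_function: list[np.ndarray] = field(default_factory=list)
    function_residue: list[np.ndarray] = field(default_factory=list)


def positional_encoding(L: int, d: int, base: float = 1000.0,
                        d_prime: int | None = None) -> np.ndarray:
    """Sinusoidal positional encodings, positions 0..L-1.

    PE(pos, 2i) = sin(pos / base^(2i/d')), PE(pos, 2i+1) = cos(...), where
    the exponent width d' defaults to ``d`` but may be set independently.
    Odd ``d`` is handled by computing full sin/cos pairs and truncating.
    """
    dp = d_prime if d_prime is not None else d
    pos = np.arange(L)[:, None]
    i = np.arange((d + 1) // 2)[None, :]
    angle = pos / base ** (2 * i / dp)
    pe = np.zeros((L, 2 * ((d + 1) // 2)))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe[:, :d]


def _attention(q: Tensor, k: Tensor, v: Tensor, scale: float,
               bias: Tensor | np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(scale))
    if bias is not None:
        logits = logits + bias
    weights = logits.softmax(axis=-1)
    return weights @ v, weights


def scaled_attention(Q, K, V, scale: float, mask_bias=None):
    """Scaled dot-product attention on plain arrays.

    Returns ``(output, weights)`` with ``weights = softmax(QK^T / sqrt(scale))``
    row-wise. ``scale`` is the model width under the square root.
    """
    Q, K, V = (np.asarray(x, dtype=float) for x in (Q, K, V))
    for name, x in (("Q", Q), ("K", K), ("V", V)):
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite values in {name}")
    with no_grad():
        out, w = _attention(Tensor(Q), Tensor(K), Tensor(V), scale, mask_bias)
    return out.data, w.data


def _split_heads(x: Tensor, h: int) -> Tensor:
    b, n, d = x.shape
    return x.reshape(b, n, h, d // h).swapaxes(1, 2)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, dk = x.shape
    return x.swapaxes(1, 2).reshape(b, n, h * dk)


def _mha(x_q: Tensor, x_kv: Tensor, p: dict, h: int, scale: float,
         bias=None) -> tuple[Tensor, Tensor]:
    q = _split_heads(x_q @ p["Wq"] + p["bq"], h)
    k = _split_heads(x_kv @ p["Wk"] + p["bk"], h)
    v = _split_heads(x_kv @ p["Wv"] + p["bv"], h)
    out, w = _attention(q, k, v, scale, bias)
    return _merge_heads(out) @ p["Wo"] + p["bo"], w


def multi_head_attention(X_query, X_keyvalue, params: dict, n_heads: int,
                         scale: float | None = None, mask_bias=None):
    """Multi-head attention on plain arrays (batched or single-instance).

    ``params`` maps Wq/bq/Wk/bk/Wv/bv/Wo/bo to arrays; heads are split from
    d_model, attended independently, concatenated and output-projected.
    Returns ``(output, per-head weights)``.
    """
    Xq = np.asarray(X_query, dtype=float)
    Xkv = np.asarray(X_keyvalue, dtype=float)
    single = Xq.ndim == 2
    if single:
        Xq, Xkv = Xq[None], Xkv[None]
    d = params["Wq"].shape[0]
    if d % n_heads != 0:
        raise ValueError(f"d_model={d} not divisible by n_heads={n_heads}")
    with no_grad():
        out, w = _mha(Tensor(Xq), Tensor(Xkv),
                      {k: Tensor(v) for k, v in params.items()},
                      n_heads, scale if scale is not None else d, mask_bias)
    if single:
        return out.data[0], w.data[0]
    return out.data, w.data


def _layer_norm(x: Tensor, gamma: Parameter, beta: Parameter) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + _LN_EPS) ** -0.5) * gamma + beta


class LabelEmbeddingTransformer:
    """Encoder-decoder model mapping an encoded peptide to per-function
    representation vectors ``Z`` (C x d_model) plus classifier heads."""

    def __init__(self, config: ModelConfig,
                 vocab: FunctionVocabulary | None = None, seed: int = 0):
        self.config = config
        self.vocab = vocab if vocab is not None else FunctionVocabulary()
        if len(self.vocab) != config.C:
            raise ValueError("vocabulary size does not match config.C")
        self.params: dict[str, Parameter] = {}
        self._rng = np.random.default_rng(seed)
        self._build()
        self.pe = positional_encoding(config.L, config.d_model, config.pe_base,
                                      d_prime=config.d_model_pe)

    # -- construction ---------------------------------------------------
    def _linear(self, name: str, d_in: int, d_out: int) -> None:
        bound = 1.0 / np.sqrt(d_in)
        self.params[f"{name}.W"] = Parameter(
            self._rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.params[f"{name}.b"] = Parameter(
            self._rng.uniform(-bound, bound, size=(d_out,)))

    def _ln(self, name: str, d: int) -> None:
        self.params[f"{name}.gamma"] = Parameter(np.ones(d))
        self.params[f"{name}.beta"] = Parameter(np.zeros(d))

    def _attn_block(self, name: str, d: int) -> None:
        for part in ("Wq", "Wk", "Wv", "Wo"):
            self._linear(f"{name}.{part}", d, d)

    def _build(self) -> None:
        cfg = self.config
        d = cfg.d_model
        self._linear("f_enc", cfg.d_input, d)
        for l in range(cfg.n_encoder_layers):
            self._attn_block(f"enc{l}.self", d)
            self._ln(f"enc{l}.ln1", d)
            self._linear(f"enc{l}.ff1", d, cfg.d_ff)
            self._linear(f"enc{l}.ff2", cfg.d_ff, d)
            self._ln(f"enc{l}.ln2", d)
        self._linear("f_dec", cfg.C, d)
        for l in range(cfg.n_decoder_layers):
            self._attn_block(f"dec{l}.self", d)
            self._ln(f"dec{l}.ln1", d)
            self._attn_block(f"dec{l}.cross", d)
            self._ln(f"dec{l}.ln2", d)
            self._linear(f"dec{l}.ff1", d, cfg.d_ff)
            self._linear(f"dec{l}.ff2", cfg.d_ff, d)
            self._ln(f"dec{l}.ln3", d)
        self._linear("single", d, 1)
        for c in range(cfg.C):
            self._linear(f"specific{c}", d, 1)

    def _group(self, prefixes: tuple[str, ...]) -> list[Parameter]:
        return [p for name, p in self.params.items()
                if name.startswith(prefixes)]

    def parameter_groups(self) -> dict[str, list[Parameter]]:
        """Partition of all trainable parameters into the four modules."""
        groups = {
            "E_seq": self._group(("f_enc", "enc")),
            "E_func": self._group(("f_dec", "dec")),
            "F_single": self._group(("single",)),
            "F_specific": self._group(("specific",)),
        }
        assert sum(len(v) for v in groups.values()) == len(self.params)
        return groups

    def _mha_params(self, name: str) -> dict[str, Parameter]:
        return {"Wq": self.params[f"{name}.Wq.W"], "bq": self.params[f"{name}.Wq.b"],
                "Wk": self.params[f"{name}.Wk.W"], "bk": self.params[f"{name}.Wk.b"],
                "Wv": self.params[f"{name}.Wv.W"], "bv": self.params[f"{name}.Wv.b"],
                "Wo": self.params[f"{name}.Wo.W"], "bo": self.params[f"{name}.Wo.b"]}

    # -- forward --------------------------------------------------------
    def forward(self, Xs: np.ndarray, mask: np.ndarray,
                record_attention: bool = False,
                function_permutation: np.ndarray | None = None,
                dropout_rng: np.random.Generator | None = None
                ) -> tuple[Tensor, AttentionRecord | None]:
        """Run the network on a batch.

        Parameters
        ----------
        Xs : (B, L, 40) residue features; mask : (B, L) bool.
        function_permutation : optional ordering of the decoder's function
            tokens (identity order by default). Z rows are returned in that
            same order, so permuting the tokens permutes Z identically.
        """
        cfg = self.config
        Xs = np.asarray(Xs, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if Xs.ndim == 2:
            Xs, mask = Xs[None], mask[None]
        B = Xs.shape[0]
        if Xs.shape[1:] != (cfg.L, cfg.d_input):
            raise ValueError(f"expected Xs of shape (B, {cfg.L}, {cfg.d_input}), "
                             f"got {Xs.shape}")
        record = AttentionRecord() if record_attention else None
        scale = cfg.d_model

        key_bias = None
        if cfg.mask_padding:
            key_bias = np.where(mask, 0.0, _NEG_INF)[:, None, None, :]

        drop = self._make_dropout(dropout_rng)

        h = Tensor(Xs) @ self.params["f_enc.W"] + self.params["f_enc.b"]
        h = h + Tensor(self.pe[None])
        for l in range(cfg.n_encoder_layers):
            attn_out, w = _mha(h, h, self._mha_params(f"enc{l}.self"),
                               cfg.n_heads, scale, key_bias)
            if record is not None:
                record.residue_residue.append(
                    np.broadcast_to(w.data, (B,) + w.data.shape[1:]).copy())
            h = _layer_norm(h + drop(attn_out), self.params[f"enc{l}.ln1.gamma"],
                            self.params[f"enc{l}.ln1.beta"])
            ff = (h @ self.params[f"enc{l}.ff1.W"] + self.params[f"enc{l}.ff1.b"]
                  ).relu() @ self.params[f"enc{l}.ff2.W"] + self.params[f"enc{l}.ff2.b"]
            h = _layer_norm(h + drop(ff), self.params[f"enc{l}.ln2.gamma"],
                            self.params[f"enc{l}.ln2.beta"])

        Xt = np.eye(cfg.C)
        if function_permutation is not None:
            Xt = Xt[np.asarray(function_permutation)]
        z = Tensor(Xt[None]) @ self.params["f_dec.W"] + self.params["f_dec.b"]
        for l in range(cfg.n_decoder_layers):
            attn_out, w = _mha(z, z, self._mha_params(f"dec{l}.self"),
                               cfg.n_heads, scale, None)
            if record is not None:
                record.function_function.append(
                    np.broadcast_to(w.data, (B,) + w.data.shape[1:]).copy())
            z = _layer_norm(z + drop(attn_out), self.params[f"dec{l}.ln1.gamma"],
                            self.params[f"dec{l}.ln1.beta"])
            cross_out, w = _mha(z, h, self._mha_params(f"dec{l}.cross"),
                                cfg.n_heads, scale, key_bias)
            if record is not None:
                record.function_residue.append(
                    np.broadcast_to(w.data, (B,) + w.data.shape[1:]).copy())
            z = _layer_norm(z + drop(cross_out), self.params[f"dec{l}.ln2.gamma"],
                            self.params[f"dec{l}.ln2.beta"])
            ff = (z @ self.params[f"dec{l}.ff1.W"] + self.params[f"dec{l}.ff1.b"]
                  ).relu() @ self.params[f"dec{l}.ff2.W"] + self.params[f"dec{l}.ff2.b"]
            z = _layer_norm(z + drop(ff), self.params[f"dec{l}.ln3.gamma"],
                            self.params[f"dec{l}.ln3.beta"])
        return z, record

    def _make_dropout(self, rng: np.random.Generator | None):
        p = self.config.dropout
        if p <= 0.0 or rng is None:
            return lambda t: t

        def drop(t: Tensor) -> Tensor:
            keep = rng.random(t.shape) >= p
            return t * Tensor(keep / (1.0 - p))

        return drop

    # -- heads ----------------------------------------------------------
    def classify_single(self, Z: Tensor) -> Tensor:
        """Shared head: sigmoid(Z w_single + b_single), one probability per
        function, identical decision boundary for every class."""
        return (Z @ self.params["single.W"] + self.params["single.b"]) \
            .reshape(Z.shape[0], self.config.C).sigmoid()

    def classify_specific(self, Z: Tensor,
                          functions: list[int] | None = None) -> Tensor:
        """Function-specific heads: class i uses only (w_i, b_i) and row z_i."""
        idx = functions if functions is not None else range(self.config.C)
        cols = []
        for c in idx:
            zc = Z[:, c, :]
            cols.append((zc @ self.params[f"specific{c}.W"]
                         + self.params[f"specific{c}.b"]).sigmoid())
        return concatenate(cols, axis=-1)

    def predict_proba(self, Xs: np.ndarray, mask: np.ndarray,
                      head: str = "specific", batch_size: int = 256) -> np.ndarray:
        """Per-function probabilities for a batch, without building a graph."""
        Xs = np.asarray(Xs, dtype=float)
        if Xs.ndim == 2:
            Xs, mask = Xs[None], np.asarray(mask)[None]
        out = []
        with no_grad():
            for lo in range(0, len(Xs), batch_size):
                Z, _ = self.forward(Xs[lo:lo + batch_size], mask[lo:lo + batch_size])
                probs = (self.classify_specific(Z) if head == "specific"
                         else self.classify_single(Z))
                out.append(probs.data)
        return np.concatenate(out, axis=0)


def predict_labels(probs: np.ndarray, vocab: FunctionVocabulary,
                   threshold: float = 0.5) -> list[set[str]] | set[str]:
    """Threshold probabilities into label sets (strictly greater than 0.5
    by default; a tie at exactly the threshold is excluded)."""
    probs = np.asarray(probs)
    single = probs.ndim == 1
    if single:
        probs = probs[None]
    names = list(vocab)
    out = [{names[j] for j in range(len(names)) if row[j] > threshold}
           for row in probs]
    return out[0] if single else out


# -- checkpointing ------------------------------------------------------

def save_checkpoint(model: LabelEmbeddingTransformer, path: str | Path) -> None:
    """Single-archive checkpoint: config + vocabulary + named tensors."""
    meta = json.dumps({"config": asdict(model.config),
                       "vocab": list(model.vocab)})
    arrays = {f"param/{k}": p.data for k, p in model.params.items()}
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path: str | Path) -> LabelEmbeddingTransformer:
    with np.load(path) as npz:
        meta = json.loads(str(npz["__meta__"]))
        model = LabelEmbeddingTransformer(
            ModelConfig(**meta["config"]),
            FunctionVocabulary(tuple(meta["vocab"])))
        for key in npz.files:
            if key.startswith("param/"):
                model.params[key[len("param/"):]].data[...] = npz[key]
    return model
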