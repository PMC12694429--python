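"""Time-conditioned self-attention denoiser.

The network maps (CDR prefix + noised V region, step t) to per-position
vocabulary logits predicting x_0. Input layout is

    [CDR prefix][CLS][V region, 149 columns][SEP]

with learned absolute position embeddings over the whole concatenation, a
two-valued segment embedding (0 on the CDR prefix, 1 on the V-region side
including [CLS]/[SEP]), and a sinusoidal embedding of the diffusion step t,
projected and added to the input of every transformer block. Blocks are
pre-norm multi-head self-attention + GELU feed-forward (width 4x hidden);
dropout sits after the attention-head concatenation and after the
feed-forward, active only in training mode.

The reference configuration is 12 layers, 16 heads, hidden 1024; tests and
toy pipelines run 2-layer, 32-hidden models of the same shape.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .numbering_io import ALIGNED_LENGTH, VOCAB

VOCAB_SIZE = len(VOCAB)


@dataclass(frozen=True)
class DenoiserConfig:
    n_layers: int = 12
    n_heads: int = 16
    hidden_size: int = 1024
    vocab_size: int = VOCAB_SIZE
    max_len: int = 218  # 67-column light prefix + [CLS] + 149 + [SEP]
    T: int = 512
    dropout: float = 0.1
    ffn_mult: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.vocab_size != VOCAB_SIZE:
            raise ValueError(f"vocab_size must be {VOCAB_SIZE}")


def count_parameters(config: DenoiserConfig) -> int:
    """Parameter count from the layer formulas, without allocating anything."""
    d, f = config.hidden_size, config.ffn_mult * config.hidden_size
    emb = (config.vocab_size + config.max_len + 2) * d  # token + position + segment
    time_proj = d * d + d
    per_layer = (
        2 * (2 * d)            # two layer norms (gain + bias)
        + 4 * (d * d + d)      # Wq, Wk, Wv, Wo with biases
        + (d * f + f)          # FFN in
        + (f * d + d)          # FFN out
    )
    head = 2 * d + d * config.vocab_size + config.vocab_size  # final norm + output
    return emb + time_proj + config.n_layers * per_layer + head


@dataclass
class ModelInput:
    """Token/position/segment layout for one (possibly batched) forward pass."""

    tokens: np.ndarray    # (B, L) int64
    segment: np.ndarray   # (B, L) int64: 0 = CDR prefix, 1 = V-region side
    v_slice: slice        # the 149 V-region positions within L
    t: int | np.ndarray   # scalar step, or one step per batch row

    @classmethod
    def build(
        cls, v_tokens: np.ndarray, cdr_prefix: np.ndarray, t: int | np.ndarray
    ) -> "ModelInput":
        """Assemble [prefix][CLS][V][SEP] from V-region and prefix token ids."""
        v_tokens = np.atleast_2d(np.asarray(v_tokens, dtype=np.int64))
        cdr_prefix = np.atleast_2d(np.asarray(cdr_prefix, dtype=np.int64))
        if cdr_prefix.shape[0] == 1 and v_tokens.shape[0] > 1:
            cdr_prefix = np.repeat(cdr_prefix, v_tokens.shape[0], axis=0)
        b, lc = cdr_prefix.shape
        if v_tokens.shape != (b, ALIGNED_LENGTH):
            raise ValueError(f"V-region tokens must be (B, {ALIGNED_LENGTH})")
        cls_col = np.full((b, 1), VOCAB.index("[CLS]"), dtype=np.int64)
        sep_col = np.full((b, 1), VOCAB.index("[SEP]"), dtype=np.int64)
        tokens = np.concatenate([cdr_prefix, cls_col, v_tokens, sep_col], axis=1)
        segment = np.concatenate(
            [np.zeros((b, lc), dtype=np.int64), np.ones((b, ALIGNED_LENGTH + 2), dtype=np.int64)],
            axis=1,
        )
        return cls(tokens=tokens, segment=segment,
                   v_slice=slice(lc + 1, lc + 1 + ALIGNED_LENGTH), t=t)


def sinusoidal_time_embedding(t: int, dim: int, T: int) -> np.ndarray:
    """Standard sin/cos embedding of the diffusion step."""
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    angles = t * freqs
    emb = np.concatenate([np.sin(angles), np.cos(angles)])
    if emb.shape[0] < dim:
        emb = np.concatenate([emb, np.zeros(dim - emb.shape[0])])
    return emb


class Denoiser:
    """Transformer denoiser; see module docstring for the layout."""

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, v, f = config.hidden_size, config.vocab_size, config.ffn_mult * config.hidden_size
        s = 0.02

        def p(*shape):
            return Tensor(rng.normal(0.0, s, size=shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        self.tok_emb = p(v, d)
        self.pos_emb = p(config.max_len, d)
        self.seg_emb = p(2, d)
        self.time_w = p(d, d)
        self.time_b = zeros(d)
        self.layers = []
        for _ in range(config.n_layers):
            self.layers.append(
                {
                    "ln1_g": ones(d), "ln1_b": zeros(d),
                    "wq": p(d, d), "bq": zeros(d),
                    "wk": p(d, d), "bk": zeros(d),
                    "wv": p(d, d), "bv": zeros(d),
                    "wo": p(d, d), "bo": zeros(d),
                    "ln2_g": ones(d), "ln2_b": zeros(d),
                    "w1": p(d, f), "b1": zeros(f),
                    "w2": p(f, d), "b2": zeros(d),
                }
            )
        self.ln_f_g = ones(d)
        self.ln_f_b = zeros(d)
        self.out_w = p(d, v)
        self.out_b = zeros(v)

    def parameters(self) -> list[Tensor]:
        params = [
            self.tok_emb, self.pos_emb, self.seg_emb, self.time_w, self.time_b,
        ]
        for layer in self.layers:
            params.extend(layer.values())
        params.extend([self.ln_f_g, self.ln_f_b, self.out_w, self.out_b])
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward --------------------------------------------------------------
    def forward(
        self, inp: ModelInput, train_rng: np.random.Generator | None = None
    ) -> Tensor:
        """Return logits over the full layout, shape (B, L, vocab)."""
        cfg = self.config
        b, L = inp.tokens.shape
        t_arr = np.atleast_1d(np.asarray(inp.t, dtype=np.int64))
        if t_arr.size == 1:
            t_arr = np.repeat(t_arr, b)
        if t_arr.shape != (b,):
            raise ValueError("t must be a scalar or one step per batch row")
        if np.any(t_arr < 1) or np.any(t_arr > cfg.T):
            raise ValueError(f"t outside [1, {cfg.T}]")
        if L > cfg.max_len:
            raise ValueError(f"layout length {L} exceeds max_len {cfg.max_len}")
        d = cfg.hidden_size
        nh, hd = cfg.n_heads, d // cfg.n_heads

        x = (
            ad.embedding(self.tok_emb, inp.tokens)
            + ad.embedding(self.pos_emb, np.broadcast_to(np.arange(L), (b, L)))
            + ad.embedding(self.seg_emb, inp.segment)
        )
        t_emb = np.stack(
            [sinusoidal_time_embedding(int(tt), d, cfg.T) for tt in t_arr]
        )[:, None, :]  # (B, 1, d)
        t_add = Tensor(t_emb) @ self.time_w + self.time_b

        for layer in self.layers:
            x = x + t_add  # time conditioning at the input of every block
            h = ad.layer_norm(x, layer["ln1_g"], layer["ln1_b"])
            q = (h @ layer["wq"] + layer["bq"]).reshape(b, L, nh, hd)
            k = (h @ layer["wk"] + layer["bk"]).reshape(b, L, nh, hd)
            v = (h @ layer["wv"] + layer["bv"]).reshape(b, L, nh, hd)
            q = q.swapaxes(1, 2)  # (B, H, L, hd)
            k = k.swapaxes(1, 2)
            v = v.swapaxes(1, 2)
            att = ad.softmax(q @ k.transpose_last() * (1.0 / np.sqrt(hd)), axis=-1)
            ctx = (att @ v).swapaxes(1, 2).reshape(b, L, d)
            ctx = ad.dropout(ctx, cfg.dropout, train_rng)  # after head concat
            x = x + (ctx @ layer["wo"] + layer["bo"])
            h2 = ad.layer_norm(x, layer["ln2_g"], layer["ln2_b"])
            ff = ad.gelu(h2 @ layer["w1"] + layer["b1"]) @ layer["w2"] + layer["b2"]
            x = x + ad.dropout(ff, cfg.dropout, train_rng)

        x = ad.layer_norm(x, self.ln_f_g, self.ln_f_b)
        return x @ self.out_w + self.out_b


def build_denoiser(config: DenoiserConfig) -> Denoiser:
    """Construct a denoiser with seed-deterministic initialization."""
    return Denoiser(config)


def predict_x0_logits(
    model: Denoiser, inp: ModelInput, train_rng: np.random.Generator | None = None
) -> Tensor:
    """Logits for the 149 V-region slots only, shape (B, 149, 26)."""
    full = model.forward(inp, train_rng=train_rng)
    return full[:, inp.v_slice, :]


def x0_probs(
    model: Denoiser,
    inp: ModelInput,
    temperature: float = 1.0,
    mask_structural: bool = True,
) -> np.ndarray:
    """Row-stochastic (B, 149, 26) x_0 predictions.

    ``mask_structural`` removes [CLS]/[PAD]/[SEP]/[MASK]/[UNK] from the
    generation support (the gap symbol stays: aligned sequences contain
    gaps). Temperature divides the logits before the softmax.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    logits = predict_x0_logits(model, inp).data / temperature
    if mask_structural:
        logits = logits.copy()
        logits[..., list(VOCAB.structural_indices)] = -np.inf
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


class OracleDenoiser:
    """A denoiser fixed on one target V region, for calibration and testing.

    Ignores its input tokens and always predicts the target with a large
    logit margin; ancestral sampling through the posterior must then
    reconstruct the target exactly. Implements the same ``forward`` surface
    as :class:`Denoiser`.
    """

    def __init__(self, target_tokens: np.ndarray, margin: float = 50.0):
        self.target = np.asarray(target_tokens, dtype=np.int64)
        if self.target.shape != (ALIGNED_LENGTH,):
            raise ValueError(f"target must have length {ALIGNED_LENGTH}")
        self.margin = margin

    def forward(self, inp: ModelInput, train_rng=None) -> Tensor:
        b, L = inp.tokens.shape
        logits = np.zeros((b, L, VOCAB_SIZE))
        v_positions = np.arange(inp.v_slice.start, inp.v_slice.stop)
        logits[:, v_positions, self.target] = self.margin
        return Tensor(logits)

    def as_denoise_fn(self):
        """Adapter to the (NoisedState, t) -> (149, 26) contract."""
        def fn(state, t):
            inp = ModelInput.build(state.tokens, state.cdr_prefix, t)
            return x0_probs(self, inp)[0]
        return fn


def denoise_fn_from_model(model, cdr_prefix: np.ndarray, temperature: float = 1.0):
    """Wrap a denoiser as the (NoisedState, t) -> (149, 26) probability map."""
    def fn(state, t):
        inp = ModelInput.build(state.tokens, state.cdr_prefix, t)
        return x0_probs(model, inp, temperature=temperature)[0]
    return fn


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(model: Denoiser, path: str | Path, metadata: dict | None = None) -> None:
    """Write weights (pickle of ndarrays) plus a JSON config sidecar."""
    path = Path(path)
    weights = [p.data for p in model.parameters()]
    with open(path, "wb") as fh:
        pickle.dump({"weights": weights}, fh)
    sidecar = {"config": asdict(model.config), "metadata": metadata or {}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> Denoiser:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    model = Denoiser(DenoiserConfig(**sidecar["config"]))
    with open(path, "rb") as fh:
        weights = pickle.load(fh)["weights"]
    params = model.parameters()
    if len(weights) != len(params):
        raise ValueError("checkpoint does not match config")
    for p, w in zip(params, weights):
        if p.data.shape != w.shape:
            raise ValueError("checkpoint does not match config")
        p.data = np.asarray(w, dtype=np.float64)
    return model
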