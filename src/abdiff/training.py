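"""Diffusion training loop.

Each training example draws a uniform step t in {1..T}, masks the V region
by the forward process at that step, and asks the denoiser to predict the
clean tokens. The default objective ("ce-masked") is the x0-parameterized
cross-entropy on the masked positions; the "hybrid" objective adds the
variational KL term, which for an absorbing chain has the closed form

    KL_j = a log(a / (a p_j(x0_j))) + (1 - a) log((1 - a) / (1 - a + a p_j(M)))

per masked position j, with a = (alpha_bar_{t-1} - alpha_bar_t)/(1 - alpha_bar_t)
the reveal weight and p_j the model x0 distribution. Noise is re-seeded per
example (not per batch position), so the epoch loss is invariant to batch
order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import AdamW, Tensor
from .denoiser import Denoiser, ModelInput
from .diffusion_core import MASK_INDEX, DiffusionSchedule, NoisedState, forward_sample
from .numbering_io import VOCAB, AlignedChain, extract_cdr_prefix


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 3e-5
    weight_decay: float = 0.01
    epochs: int = 10
    loss_kind: str = "ce-masked"  # or "hybrid"
    hybrid_lambda: float = 1.0
    grad_clip: float = 1.0
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss_kind not in ("ce-masked", "hybrid"):
            raise ValueError(f"unknown loss_kind {self.loss_kind!r}")


def diffusion_loss(
    x0_tokens: np.ndarray,
    xt_tokens: np.ndarray,
    t: np.ndarray,
    logits: Tensor,
    schedule: DiffusionSchedule,
    loss_kind: str = "ce-masked",
    hybrid_lambda: float = 1.0,
) -> Tensor:
    """Scalar training loss (autodiff node).

    ``x0_tokens``/``xt_tokens`` are (B, 149) int arrays, ``t`` the per-example
    steps, ``logits`` the (B, 149, 26) denoiser output. Raises if no position
    is masked (degenerate draw; callers resample t).
    """
    x0_tokens = np.asarray(x0_tokens, dtype=np.int64)
    xt_tokens = np.asarray(xt_tokens, dtype=np.int64)
    masked = xt_tokens == MASK_INDEX
    n_masked = int(masked.sum())
    if n_masked == 0:
        raise ValueError("no masked positions at the sampled t; resample")
    logp = ad.log_softmax(logits, axis=-1)
    nll_all = -ad.gather_last(logp, x0_tokens)  # (B, 149)
    mask_f = Tensor(masked.astype(np.float64))
    ce = (nll_all * mask_f).sum() * (1.0 / n_masked)
    if loss_kind == "ce-masked":
        return ce
    if loss_kind != "hybrid":
        raise ValueError(f"unknown loss_kind {loss_kind!r}")

    # closed-form per-position KL of the absorbing-chain posteriors
    t = np.atleast_1d(np.asarray(t, dtype=np.int64))
    ab_prev = np.array([schedule.alpha_bar(int(tt) - 1) for tt in t])
    ab_t = np.array([schedule.alpha_bar(int(tt)) for tt in t])
    a = (ab_prev - ab_t) / (1.0 - ab_t)  # (B,)
    probs = ad.softmax(logits, axis=-1)
    p_x0 = ad.gather_last(probs, x0_tokens)
    p_mask = ad.gather_last(
        probs, np.full_like(x0_tokens, MASK_INDEX)
    )
    eps = 1e-12
    a_t = Tensor(np.broadcast_to(a[:, None], x0_tokens.shape).copy())
    one_minus_a = Tensor(np.broadcast_to((1.0 - a)[:, None], x0_tokens.shape).copy())
    term1 = a_t * ((a_t + eps).log() - (a_t * p_x0 + eps).log())
    term2 = one_minus_a * (
        (one_minus_a + eps).log() - (one_minus_a + a_t * p_mask + eps).log()
    )
    kl = ((term1 + term2) * Tensor(masked.astype(np.float64))).sum() * (1.0 / n_masked)
    return ce + hybrid_lambda * kl


def _example_rng(seed: int, epoch: int, index: int) -> np.random.Generator:
    """Noise rng tied to (run seed, epoch, example identity)."""
    mixed = (seed * 1_000_003 + epoch * 9_176 + index * 31 + 7) % (2**31)
    return np.random.default_rng(mixed)


def noise_example(
    x0_tokens: np.ndarray,
    cdr_prefix: np.ndarray,
    schedule: DiffusionSchedule,
    seed: int,
    epoch: int,
    index: int,
) -> tuple[np.ndarray, int]:
    """Draw (x_t, t) for one example, resampling t until a mask exists."""
    rng = _example_rng(seed, epoch, index)
    state = NoisedState(tokens=x0_tokens, t=0, cdr_prefix=cdr_prefix)
    while True:
        t = int(rng.integers(1, schedule.T + 1))
        xt = forward_sample(state, t, schedule, seed=rng)
        if np.any(xt.tokens == MASK_INDEX):
            return xt.tokens, t


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    wall_time_s: float = 0.0


def train(
    model: Denoiser,
    repertoire: Sequence[AlignedChain],
    train_cfg: TrainConfig,
    schedule: DiffusionSchedule,
    verbose: bool = False,
) -> tuple[Denoiser, TrainHistory]:
    """Fit the denoiser on an aligned repertoire (single chain type)."""
    if not repertoire:
        raise ValueError("repertoire is empty")
    chain_type = repertoire[0].chain_type
    if any(c.chain_type != chain_type for c in repertoire):
        raise ValueError("repertoire must contain a single chain type")

    x0_all = np.stack([VOCAB.encode(c.sequence) for c in repertoire])
    prefixes = np.stack(
        [VOCAB.encode(extract_cdr_prefix(c)) for c in repertoire]
    )
    n = x0_all.shape[0]
    optimizer = AdamW(
        model.parameters(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
    )
    order_rng = np.random.default_rng(train_cfg.seed % (2**31))
    dropout_rng = np.random.default_rng((train_cfg.seed + 17) % (2**31))
    history = TrainHistory()
    start = time.time()

    for epoch in range(train_cfg.epochs):
        order = order_rng.permutation(n)
        losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo : lo + train_cfg.batch_size]
            xt_batch, t_batch = [], []
            for i in idx:
                xt, t = noise_example(
                    x0_all[i], prefixes[i], schedule, train_cfg.seed, epoch, int(i)
                )
                xt_batch.append(xt)
                t_batch.append(t)
            xt_arr = np.stack(xt_batch)
            t_arr = np.array(t_batch)
            inp = ModelInput.build(xt_arr, prefixes[idx], t_arr)
            logits = model.forward(inp, train_rng=dropout_rng)[:, inp.v_slice, :]
            loss = diffusion_loss(
                x0_all[idx], xt_arr, t_arr, logits, schedule,
                loss_kind=train_cfg.loss_kind,
                hybrid_lambda=train_cfg.hybrid_lambda,
            )
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}: aborting "
                    "(check learning rate / gradient clipping)"
                )
            optimizer.zero_grad()
            loss.backward()
            ad.clip_grad_norm(model.parameters(), train_cfg.grad_clip)
            optimizer.step()
            losses.append(value)
        history.epoch_loss.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{train_cfg.epochs} loss {history.epoch_loss[-1]:.4f}")
    history.wall_time_s = time.time() - start
    return model, history
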