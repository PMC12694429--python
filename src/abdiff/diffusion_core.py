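"""Absorbing-state discrete diffusion over the 26-token alignment vocabulary.

Forward process: at step t each V-region token independently transitions to
the [MASK] token with probability beta_t and otherwise stays itself; [MASK]
is absorbing. The cumulative keep probability
``alpha_bar_t = prod_{s<=t} (1 - beta_s)`` fully determines the marginal
``q(x_t | x_0)``: keep ``x_0`` with probability alpha_bar_t, else [MASK].
With the default "linear-marginal" schedule ``beta_t = 1/(T - t + 1)`` the
masked fraction grows exactly linearly, ``alpha_bar_t = (T - t)/T``, and at
t = T the whole V region is masked (pure noise).

The reverse posterior ``q(x_{t-1} | x_t, x_0)`` of an absorbing chain has a
two-case closed form: an observed (non-mask) token is carried backwards as a
point mass, while a masked token reveals ``x_0`` with probability
``(alpha_bar_{t-1} - alpha_bar_t) / (1 - alpha_bar_t)`` and stays masked
otherwise. During sampling the one-hot ``x_0`` is replaced by the denoiser's
predicted distribution over x_0.

The CDR prefix conditions the denoiser but is never noised: it is held
bitwise fixed through every forward and reverse step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .numbering_io import VOCAB

MASK_INDEX = VOCAB.mask_index
VOCAB_SIZE = len(VOCAB)

DEFAULT_T = 512

SCHEDULE_KINDS = ("linear-marginal", "cosine", "spindle")


@dataclass(frozen=True)
class DiffusionSchedule:
    """Per-step mask probabilities beta_t and their cumulative keep products.

    ``beta[t-1]`` is the step-t mask probability (1-based steps, stored
    0-based); ``alpha_bar(t)`` returns the cumulative keep probability with
    ``alpha_bar(0) = 1`` and ``alpha_bar(T) = 0``.
    """

    T: int
    kind: str
    beta: np.ndarray = field(repr=False)
    cumulative_keep: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        assert self.beta.shape == (self.T,)
        assert self.cumulative_keep.shape == (self.T,)

    def alpha_bar(self, t: int) -> float:
        """Cumulative keep probability after t steps; alpha_bar(0) = 1."""
        if t == 0:
            return 1.0
        return float(self.cumulative_keep[t - 1])

    def to_json(self) -> dict:
        return {"T": self.T, "kind": self.kind, "beta": self.beta.tolist()}


def make_schedule(T: int = DEFAULT_T, kind: str = "linear-marginal") -> DiffusionSchedule:
    """Build a noise schedule with alpha_bar(T) = 0 (full masking at t = T).

    kinds
    -----
    - ``linear-marginal`` (default): beta_t = 1/(T-t+1), so alpha_bar(t) = (T-t)/T.
    - ``cosine``: alpha_bar(t) = cos^2(pi t / 2T), squashed to end at 0.
    - ``spindle``: mask probability concentrated mid-trajectory,
      alpha_bar(t) = 1 - t/T + sin(2 pi t / T) / (2 pi) * (t < T).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t = np.arange(1, T + 1, dtype=np.float64)
    if kind == "linear-marginal":
        keep = (T - t) / T
    elif kind == "cosine":
        keep = np.cos(np.pi * t / (2 * T)) ** 2
        keep[-1] = 0.0
    elif kind == "spindle":
        keep = 1.0 - t / T + np.sin(2.0 * np.pi * t / T) / (2.0 * np.pi)
        keep[-1] = 0.0
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    prev = np.concatenate(([1.0], keep[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(prev > 0, 1.0 - keep / np.where(prev > 0, prev, 1.0), 1.0)
    beta = np.clip(beta, 0.0, 1.0)
    return DiffusionSchedule(T=T, kind=kind, beta=beta, cumulative_keep=keep)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 26x26 single-step or cumulative transition matrix."""

    Q: np.ndarray = field(repr=False)
    t: int

    def __post_init__(self) -> None:
        assert self.Q.shape == (VOCAB_SIZE, VOCAB_SIZE)


def _absorbing_matrix(keep: float) -> np.ndarray:
    Q = np.eye(VOCAB_SIZE) * keep
    Q[:, MASK_INDEX] += 1.0 - keep
    Q[MASK_INDEX] = 0.0
    Q[MASK_INDEX, MASK_INDEX] = 1.0
    return Q


def transition_matrix(schedule: DiffusionSchedule, t: int) -> TransitionMatrix:
    """Single-step Q_t: keep prob 1 - beta_t on the diagonal, rest to [MASK]."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    return TransitionMatrix(Q=_absorbing_matrix(1.0 - float(schedule.beta[t - 1])), t=t)


def cumulative_transition(schedule: DiffusionSchedule, t: int) -> TransitionMatrix:
    """Closed-form Q_bar_t = Q_1 Q_2 ... Q_t (keep prob = alpha_bar(t)).

    For an absorbing chain the product of per-step matrices is itself an
    absorbing matrix whose keep probability telescopes to the cumulative
    keep product, so no repeated multiplication is needed.
    """
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    return TransitionMatrix(Q=_absorbing_matrix(schedule.alpha_bar(t)), t=t)


@dataclass
class NoisedState:
    """V-region tokens at diffusion step t plus the (never-noised) CDR prefix."""

    tokens: np.ndarray  # (149,) int64
    t: int
    cdr_prefix: np.ndarray  # (64|67,) int64

    def copy(self) -> "NoisedState":
        return NoisedState(self.tokens.copy(), self.t, self.cdr_prefix)


def forward_sample(
    x0: NoisedState,
    t: int,
    schedule: DiffusionSchedule,
    seed: int | np.random.Generator = 0,
    freeze_columns: np.ndarray | None = None,
) -> NoisedState:
    """Sample x_t ~ q(x_t | x_0): keep each position w.p. alpha_bar(t), else [MASK].

    ``freeze_columns`` (boolean, length 149) optionally exempts columns — the
    alternative reading in which the V-region copies of the CDR columns are
    themselves never noised. The CDR prefix is carried through unchanged.
    """
    if x0.t != 0:
        raise ValueError("forward_sample expects a state at t=0")
    if np.any(x0.tokens == MASK_INDEX):
        raise ValueError("x0 must contain no [MASK] tokens")
    if not 0 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [0, {schedule.T}]")
    if t == 0:
        return x0.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.random(x0.tokens.shape) < schedule.alpha_bar(t)
    if freeze_columns is not None:
        keep = keep | np.asarray(freeze_columns, dtype=bool)
    tokens = np.where(keep, x0.tokens, MASK_INDEX)
    return NoisedState(tokens=tokens, t=t, cdr_prefix=x0.cdr_prefix)


def posterior_params(
    xt: NoisedState,
    x0_probs: np.ndarray,
    schedule: DiffusionSchedule,
) -> np.ndarray:
    """Per-position categorical parameters of q(x_{t-1} | x_t, x_0-dist).

    Positions where x_t is not [MASK] return a point mass on the observed
    token (absorbing-chain property). Masked positions return the mixture
    with weight ``(alpha_bar_{t-1} - alpha_bar_t)/(1 - alpha_bar_t)`` on the
    x_0 distribution and the complement on [MASK]. ``x0_probs`` may be the
    one-hot ground truth (training) or the denoiser output (sampling).
    """
    t = xt.t
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    x0_probs = np.asarray(x0_probs, dtype=np.float64)
    if x0_probs.shape != (xt.tokens.shape[0], VOCAB_SIZE):
        raise ValueError(f"x0_probs shape {x0_probs.shape} mismatch")
    if not np.allclose(x0_probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("x0_probs rows must sum to 1")
    if np.any(x0_probs < -1e-12):
        raise ValueError("x0_probs must be non-negative")

    ab_prev = schedule.alpha_bar(t - 1)
    ab_t = schedule.alpha_bar(t)
    # reveal weight: P(x_{t-1} = x_0 | x_t = MASK, x_0)
    reveal = (ab_prev - ab_t) / (1.0 - ab_t)

    n = xt.tokens.shape[0]
    out = np.zeros((n, VOCAB_SIZE))
    masked = xt.tokens == MASK_INDEX
    # unmasked: point mass on the observed token
    out[np.arange(n), xt.tokens] = 1.0
    if masked.any():
        p = x0_probs[masked]
        mix = reveal * p
        # any x0 mass on [MASK] itself stays masked with certainty
        mix[:, MASK_INDEX] = 0.0
        row = np.zeros_like(p)
        row[:, :] = mix
        row[:, MASK_INDEX] = 1.0 - mix.sum(axis=1)
        out[masked] = row
    return out


DenoiseFn = Callable[[NoisedState, int], np.ndarray]


def _categorical_kl(q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row-wise KL(q || p) with 0 log 0 := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * (np.log(np.where(q > 0, q, 1.0)) - np.log(p)), 0.0)
    return terms.sum(axis=-1)


def elbo(
    x0_tokens: np.ndarray,
    denoise_fn: DenoiseFn,
    schedule: DiffusionSchedule,
    cdr_prefix: np.ndarray,
    n_samples: int = 64,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the diffusion evidence lower bound (nats, <= 0).

    ELBO = E_q[log p(x_0|x_1)] - sum_{t=2}^T E_q KL(q(x_{t-1}|x_t,x_0) ||
    p_theta(x_{t-1}|x_t)); the prior term vanishes because q(x_T|x_0) is the
    deterministic all-mask state. Each draw samples t uniformly from {1..T}
    and x_t ~ q(x_t|x_0); the per-draw term is scaled by T to keep the
    estimator unbiased. Larger values mean the sequence is more probable
    under the model; a denoiser that always returns the one-hot truth gives
    exactly 0.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    x0_tokens = np.asarray(x0_tokens, dtype=np.int64)
    n = x0_tokens.shape[0]
    rng = np.random.default_rng(seed)
    x0_state = NoisedState(tokens=x0_tokens, t=0, cdr_prefix=cdr_prefix)
    total = 0.0
    for _ in range(n_samples):
        t = int(rng.integers(1, schedule.T + 1))
        xt = forward_sample(x0_state, t, schedule, seed=rng)
        probs = np.asarray(denoise_fn(xt, t), dtype=np.float64)
        if probs.shape != (n, VOCAB_SIZE) or not np.allclose(
            probs.sum(axis=1), 1.0, atol=1e-6
        ):
            raise ValueError("denoise_fn output is not row-stochastic")
        masked = xt.tokens == MASK_INDEX
        if t == 1:
            # reconstruction: q(x_0 | x_1, x_0-dist) has zero residual mask
            # weight, so masked positions contribute log p_hat(x_0).
            post = posterior_params(xt, probs, schedule)
            logp = np.log(np.maximum(post[np.arange(n), x0_tokens], 1e-300))
            term = float(logp[masked].sum())
        else:
            onehot = np.zeros((n, VOCAB_SIZE))
            onehot[np.arange(n), x0_tokens] = 1.0
            q_post = posterior_params(xt, onehot, schedule)
            p_post = posterior_params(xt, probs, schedule)
            kl = _categorical_kl(q_post, np.maximum(p_post, 1e-300))
            term = -float(kl[masked].sum())
        total += schedule.T * term
    return total / n_samples
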