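"""Variant ranking and humanness scoring.

Ranking: a variant's log-likelihood under a sequence scorer is the sum of
per-position log-probabilities, LL = sum_j log P_j(s_j | M). External
protein language models (the ESM family in the reference workflow) are
adapters behind the same Scorer contract; the library ships toy scorers
(uniform, point-mass, profile) and a pseudo-log-likelihood scorer built
from a trained denoiser. With several scorers, variants are ordered by the
unweighted mean LL, ties broken by variant id, and the top-k kept.

Humanness / immunogenicity proxy: the diffusion ELBO of a chain, min-max
normalized against a reference cohort to [0, 1]; paired (VH, VL) scores are
stratified by the minimum of the two against a threshold (0.9 in the
reference analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .denoiser import Denoiser, ModelInput
from .diffusion_core import MASK_INDEX, DiffusionSchedule
from .numbering_io import AMINO_ACIDS, VOCAB, AlignedChain, strip_gaps
from . import denoiser as _denoiser_mod


@dataclass(frozen=True)
class VariantRecord:
    """A generated variant plus its scores."""

    chain: AlignedChain
    ll: float | None = None
    elbo: float | None = None
    norm_elbo: float | None = None
    norm_elbo_degenerate: bool = False
    rank: int | None = None


class Scorer:
    """Contract: per-position log-probabilities for an ungapped sequence.

    Subclasses implement :meth:`log_probs`; entries must be <= 0 and the
    output length must equal the sequence length.
    """

    name = "scorer"

    def log_probs(self, sequence: str) -> np.ndarray:
        raise NotImplementedError

    def log_likelihood_of_chain(self, chain: AlignedChain) -> float:
        """Total LL of a chain; default scores the ungapped sequence."""
        return log_likelihood(strip_gaps(chain.sequence), self)


class UniformScorer(Scorer):
    """log(1/20) everywhere; the maximum-entropy baseline."""

    name = "uniform"

    def log_probs(self, sequence: str) -> np.ndarray:
        return np.full(len(sequence), -np.log(len(AMINO_ACIDS)))


class PointMassScorer(Scorer):
    """Probability 1 on one target sequence's residues, ``floor`` elsewhere."""

    name = "pointmass"

    def __init__(self, target: str, floor: float = 1e-6):
        self.target = target
        self.floor = floor

    def log_probs(self, sequence: str) -> np.ndarray:
        if len(sequence) != len(self.target):
            raise ValueError("sequence length does not match target")
        hit = np.array([s == t for s, t in zip(sequence, self.target)])
        return np.where(hit, 0.0, np.log(self.floor))


class ProfileScorer(Scorer):
    """Scores against per-position residue probabilities (rows sum to 1)."""

    name = "profile"

    def __init__(self, probs: np.ndarray, alphabet: str = AMINO_ACIDS):
        self.probs = np.asarray(probs, dtype=np.float64)
        self.index = {a: i for i, a in enumerate(alphabet)}

    def log_probs(self, sequence: str) -> np.ndarray:
        if len(sequence) != self.probs.shape[0]:
            raise ValueError("sequence length does not match profile")
        p = np.array(
            [self.probs[j, self.index[s]] for j, s in enumerate(sequence)]
        )
        return np.log(np.maximum(p, 1e-300))


class ModelPseudoLikelihoodScorer(Scorer):
    """Pseudo-LL from a trained denoiser at t=1 single-position masking.

    Each aligned position is masked alone at the last reverse step and the
    model's probability of the true token there is read off; the chain LL is
    the sum over non-gap positions. Scores aligned chains directly (it needs
    the alignment frame and the CDR prefix), so ``log_probs`` on a bare
    string is unsupported.
    """

    name = "model-pll"

    def __init__(self, model: Denoiser, schedule: DiffusionSchedule):
        self.model = model
        self.schedule = schedule

    def log_probs(self, sequence: str) -> np.ndarray:
        raise NotImplementedError(
            "model scorer operates on AlignedChain via log_likelihood_of_chain"
        )

    def log_likelihood_of_chain(self, chain: AlignedChain) -> float:
        from .numbering_io import extract_cdr_prefix

        tokens = VOCAB.encode(chain.sequence)
        prefix = VOCAB.encode(extract_cdr_prefix(chain))
        non_gap = np.where(tokens != VOCAB.gap_index)[0]
        batch = np.repeat(tokens[None, :], len(non_gap), axis=0)
        batch[np.arange(len(non_gap)), non_gap] = MASK_INDEX
        inp = ModelInput.build(batch, prefix, 1)
        probs = _denoiser_mod.x0_probs(self.model, inp)
        p_true = probs[np.arange(len(non_gap)), non_gap, tokens[non_gap]]
        return float(np.log(np.maximum(p_true, 1e-300)).sum())


def log_likelihood(sequence: str, scorer: Scorer) -> float:
    """LL = sum_j log P_j(s_j | M) over the (nonempty, ungapped) sequence."""
    if not sequence:
        raise ValueError("sequence is empty")
    lp = np.asarray(scorer.log_probs(sequence), dtype=np.float64)
    if lp.shape != (len(sequence),):
        raise ValueError(
            f"scorer returned {lp.shape}, expected ({len(sequence)},)"
        )
    return float(lp.sum())


def rank_variants(
    records: Sequence[VariantRecord],
    scorers: Sequence[Scorer],
    top_k: int | None = None,
) -> list[VariantRecord]:
    """Top-k variants by mean LL across scorers (descending, id tie-break)."""
    if not records:
        raise ValueError("no variants to rank")
    if not scorers:
        raise ValueError("no scorers given")
    if top_k is None:
        top_k = len(records)
    if top_k > len(records):
        raise ValueError("top_k exceeds the number of records")
    scored = []
    for rec in records:
        lls = [s.log_likelihood_of_chain(rec.chain) for s in scorers]
        scored.append(replace(rec, ll=float(np.mean(lls))))
    scored.sort(key=lambda r: (-r.ll, r.chain.id))
    return [replace(r, rank=i + 1) for i, r in enumerate(scored[:top_k])]


def normalized_elbo(
    records: Sequence[VariantRecord], reference: Sequence[float]
) -> list[VariantRecord]:
    """Min-max normalize each record's ELBO against a reference cohort.

    norm = (elbo - min(ref)) / (max(ref) - min(ref)), clipped to [0, 1].
    A degenerate reference (all values equal) yields 0 with a warning flag.
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    ref = np.asarray(reference, dtype=np.float64)
    lo, hi = float(ref.min()), float(ref.max())
    degenerate = hi == lo
    out = []
    for rec in records:
        if rec.elbo is None:
            raise ValueError(f"{rec.chain.id}: elbo not set")
        if degenerate:
            out.append(replace(rec, norm_elbo=0.0, norm_elbo_degenerate=True))
        else:
            val = float(np.clip((rec.elbo - lo) / (hi - lo), 0.0, 1.0))
            out.append(replace(rec, norm_elbo=val))
    return out


def stratify(
    scored_pairs: Sequence[tuple[float, float]], threshold: float = 0.9
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Split (VH, VL) score pairs by min(vh, vl) >= threshold.

    Returns (group_high, group_low); the minimum of the two chains is used
    because the weaker chain is expected to set the immunogenicity level.
    """
    group_high, group_low = [], []
    for vh, vl in scored_pairs:
        if not (0.0 <= vh <= 1.0 and 0.0 <= vl <= 1.0):
            raise ValueError("scores must lie in [0, 1]")
        (group_high if min(vh, vl) >= threshold else group_low).append((vh, vl))
    return group_high, group_low
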