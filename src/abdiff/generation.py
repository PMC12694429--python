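"""Reverse-process sampling: CDRs in, humanized aligned V regions out.

Generation starts at t = T from a fully masked 149-column V region with the
aligned CDR prefix as conditioning, and ancestrally samples x_{t-1} from the
absorbing-chain posterior at every step down to t = 1 (all T steps are
visited; no skip-step sampling). Temperature divides the denoiser logits
before the softmax; the posterior mixture weights themselves are schedule-
fixed and untouched. Default temperatures follow the reference settings:
0.7 for heavy chains, 0.65 for light chains.

Generated CDR columns are *not* overwritten by default — the conditioning is
supposed to reproduce them without an explicit constraint — but
:func:`enforce_cdrs` can check or graft them post hoc, and the check is
always reported by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .denoiser import Denoiser, ModelInput, x0_probs
from .diffusion_core import (
    MASK_INDEX,
    VOCAB_SIZE,
    DiffusionSchedule,
    NoisedState,
    posterior_params,
)
from .numbering_io import (
    ALIGNED_LENGTH,
    VOCAB,
    AlignedChain,
    cdr_mask,
    cdr_prefix_length,
    strip_gaps,
    write_aligned,
)

DEFAULT_TEMPERATURE = {"H": 0.7, "K": 0.65, "L": 0.65}


def generate(
    model: Denoiser,
    cdr_prefix: str,
    chain_type: str,
    schedule: DiffusionSchedule,
    n_variants: int = 100,
    temperature: float | None = None,
    seed: int = 0,
    greedy: bool = False,
    freeze_cdr_columns: bool = False,
    id_prefix: str = "variant",
) -> list[AlignedChain]:
    """Sample ``n_variants`` aligned V regions conditioned on a CDR prefix.

    ``greedy`` replaces the categorical token draw by the argmax (the
    temperature -> 0 limit) while keeping the schedule-driven reveal times;
    ``freeze_cdr_columns`` starts the CDR columns of the V region unmasked at
    their prefix values instead of letting the model generate them.
    """
    expected = cdr_prefix_length(chain_type)
    if len(cdr_prefix) != expected:
        raise ValueError(
            f"CDR prefix length {len(cdr_prefix)} does not match chain "
            f"{chain_type} (expected {expected})"
        )
    if temperature is None:
        temperature = DEFAULT_TEMPERATURE[chain_type]
    if temperature <= 0:
        raise ValueError("temperature must be > 0")

    prefix_tokens = VOCAB.encode(cdr_prefix)
    rng = np.random.default_rng(seed)
    b = n_variants
    tokens = np.full((b, ALIGNED_LENGTH), MASK_INDEX, dtype=np.int64)
    frozen = None
    if freeze_cdr_columns:
        mask = cdr_mask(chain_type)
        frame = np.zeros(ALIGNED_LENGTH, dtype=np.int64)
        it = iter(prefix_tokens)
        for start, stop in mask.segments:
            for col in range(start, stop):
                frame[col] = next(it)
        frozen = mask.columns
        tokens[:, frozen] = frame[frozen]

    for t in range(schedule.T, 0, -1):
        inp = ModelInput.build(tokens, prefix_tokens, t)
        probs = x0_probs(model, inp, temperature=temperature)  # (B, 149, 26)
        flat_state = NoisedState(
            tokens=tokens.reshape(-1), t=t, cdr_prefix=prefix_tokens
        )
        post = posterior_params(
            flat_state, probs.reshape(-1, VOCAB_SIZE), schedule
        ).reshape(b, ALIGNED_LENGTH, VOCAB_SIZE)

        masked = tokens == MASK_INDEX
        reveal_prob = 1.0 - post[:, :, MASK_INDEX]
        u_reveal = rng.random((b, ALIGNED_LENGTH))
        u_token = rng.random((b, ALIGNED_LENGTH))
        reveal = masked & (u_reveal < reveal_prob)
        if reveal.any():
            token_dist = post.copy()
            token_dist[:, :, MASK_INDEX] = 0.0
            denom = np.maximum(token_dist.sum(axis=2, keepdims=True), 1e-300)
            token_dist /= denom
            if greedy:
                choice = token_dist.argmax(axis=2)
            else:
                cdf = np.cumsum(token_dist, axis=2)
                choice = (u_token[:, :, None] > cdf).sum(axis=2)
                choice = np.minimum(choice, VOCAB_SIZE - 1)
            tokens = np.where(reveal, choice, tokens)

    if np.any(tokens == MASK_INDEX):
        raise RuntimeError("internal error: residual [MASK] at t=0")
    return [
        AlignedChain(
            id=f"{id_prefix}_{i}",
            sequence=VOCAB.decode(tokens[i]),
            chain_type=chain_type,
        )
        for i in range(b)
    ]


@dataclass(frozen=True)
class CdrFidelityReport:
    """Per-segment identity between generated CDR columns and the input prefix."""

    segment_identity: tuple[float, ...]  # CDR1, CDR2, CDR3
    overall_identity: float


def enforce_cdrs(
    variant: AlignedChain, cdr_prefix: str, mode: str = "check"
) -> tuple[AlignedChain, CdrFidelityReport]:
    """Check or graft the input CDRs onto a generated variant.

    mode "check" leaves the variant untouched and reports identities; mode
    "graft" overwrites the CDR columns with the prefix.
    """
    mask = cdr_mask(variant.chain_type)
    if len(cdr_prefix) != mask.n_cdr_columns:
        raise ValueError("prefix length does not match chain type")
    seq = list(variant.sequence)
    identities = []
    offset = 0
    n_match_total = 0
    for start, stop in mask.segments:
        width = stop - start
        seg_prefix = cdr_prefix[offset : offset + width]
        matches = sum(
            1 for i, col in enumerate(range(start, stop)) if seq[col] == seg_prefix[i]
        )
        identities.append(matches / width)
        n_match_total += matches
        offset += width
    report = CdrFidelityReport(
        segment_identity=tuple(identities),
        overall_identity=n_match_total / mask.n_cdr_columns,
    )
    if mode == "check":
        return variant, report
    if mode == "graft":
        it = iter(cdr_prefix)
        for start, stop in mask.segments:
            for col in range(start, stop):
                seq[col] = next(it)
        grafted = AlignedChain(
            id=variant.id, sequence="".join(seq), chain_type=variant.chain_type
        )
        return grafted, report
    raise ValueError(f"unknown mode {mode!r}")


SCORE_COLUMNS = ("ll", "elbo", "norm_elbo", "cdr_fidelity")


def export_variants(
    variants: Sequence[AlignedChain],
    scores: Mapping[str, Mapping[str, float]] | None,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write gapped FASTA plus a TSV of per-variant scores.

    ``scores`` maps variant id to any subset of ``ll``, ``elbo``,
    ``norm_elbo``, ``cdr_fidelity``; missing values are left empty. Returns
    the (fasta_path, tsv_path) pair.
    """
    out_prefix = Path(out_prefix)
    fasta_path = out_prefix.with_suffix(".fasta")
    tsv_path = out_prefix.with_suffix(".tsv")
    write_aligned(variants, fasta_path)
    rows = []
    for v in variants:
        row: dict[str, object] = {
            "id": v.id,
            "sequence": strip_gaps(v.sequence),
        }
        entry = (scores or {}).get(v.id, {})
        for col in SCORE_COLUMNS:
            row[col] = entry.get(col, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", "sequence", *SCORE_COLUMNS])
    df.to_csv(tsv_path, sep="\t", index=False)
    return fasta_path, tsv_path
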