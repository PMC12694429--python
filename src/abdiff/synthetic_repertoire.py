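"""Synthetic AHo-aligned repertoires with known statistical structure.

Real human repertoires (e.g. OAS extracts) have near-conserved framework
columns, hypervariable CDR columns and a chain-type-specific indel
architecture that the AHo frame expresses as gap-dominant columns. This
module emulates exactly those three features with a column-independent
position profile so that every downstream distributional test has a
closed-form expectation. Column independence is deliberate: testability
beats realism here, and the features it drops (clonal structure, hotspot
correlation) are not what the diffusion machinery is exercised on.

All sampling is a pure function of (arguments, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .numbering_io import (
    ALIGNED_LENGTH,
    ALIGNMENT_SYMBOLS,
    AMINO_ACIDS,
    GAP,
    AlignedChain,
    cdr_mask,
)

N_SYMBOLS = len(ALIGNMENT_SYMBOLS)  # 20 residues + gap
_GAP_COL = N_SYMBOLS - 1

#: Fixed gap-dominant columns per chain type, mimicking the AHo indel
#: architecture (insertions sit mid-CDR, so unfilled frames leave gap runs
#: there; light chains carry one extra FR1 gap column).
GAP_DOMINANT_COLUMNS: dict[str, tuple[int, ...]] = {
    "H": tuple(range(32, 38)) + tuple(range(63, 68)) + tuple(range(115, 127)),
    "K": (7,) + tuple(range(30, 38)) + tuple(range(63, 68)) + tuple(range(113, 125)),
    "L": (7,) + tuple(range(30, 38)) + tuple(range(63, 68)) + tuple(range(113, 125)),
}

DEFAULT_FR_CONSERVATION = 0.85
DEFAULT_GAP_DOMINANCE = 0.90


@dataclass(frozen=True)
class PositionProfile:
    """Row-stochastic 149x21 per-column distribution over residues and gap."""

    chain_type: str
    probs: np.ndarray = field(repr=False)
    fr_conservation: float
    seed: int

    def __post_init__(self) -> None:
        assert self.probs.shape == (ALIGNED_LENGTH, N_SYMBOLS)
        np.testing.assert_allclose(self.probs.sum(axis=1), 1.0, atol=1e-9)

    @property
    def conservation(self) -> np.ndarray:
        """Per-column max probability (a conservation score in [0, 1])."""
        return self.probs.max(axis=1)


def build_profile(
    chain_type: str,
    fr_conservation: float = DEFAULT_FR_CONSERVATION,
    seed: int = 0,
    gap_dominance: float = DEFAULT_GAP_DOMINANCE,
) -> PositionProfile:
    """Construct a deterministic position profile for one chain type.

    Non-gap FR columns put ``fr_conservation`` on one dominant residue (drawn
    from the seed) and spread the remainder uniformly over the other 19; CDR
    columns are uniform over the 20 residues; the fixed gap-dominant columns
    put ``gap_dominance`` on the gap symbol.
    """
    if not 0.0 < fr_conservation <= 1.0:
        raise ValueError(f"fr_conservation must be in (0, 1], got {fr_conservation}")
    if not 0.0 < gap_dominance <= 1.0:
        raise ValueError(f"gap_dominance must be in (0, 1], got {gap_dominance}")
    rng = np.random.default_rng(seed)
    is_cdr = cdr_mask(chain_type).columns
    gap_cols = set(GAP_DOMINANT_COLUMNS[chain_type])

    probs = np.zeros((ALIGNED_LENGTH, N_SYMBOLS))
    dominant = rng.integers(0, len(AMINO_ACIDS), size=ALIGNED_LENGTH)
    for col in range(ALIGNED_LENGTH):
        if col in gap_cols:
            probs[col, :_GAP_COL] = (1.0 - gap_dominance) / len(AMINO_ACIDS)
            probs[col, _GAP_COL] = gap_dominance
        elif is_cdr[col]:
            probs[col, :_GAP_COL] = 1.0 / len(AMINO_ACIDS)
        else:
            rest = (1.0 - fr_conservation) / (len(AMINO_ACIDS) - 1)
            probs[col, :_GAP_COL] = rest
            probs[col, dominant[col]] = fr_conservation
    probs /= probs.sum(axis=1, keepdims=True)
    probs.setflags(write=False)
    return PositionProfile(
        chain_type=chain_type,
        probs=probs,
        fr_conservation=fr_conservation,
        seed=seed,
    )


def sample_repertoire(
    profile: PositionProfile, n: int, seed: int = 0, id_prefix: str = "syn"
) -> list[AlignedChain]:
    """Draw ``n`` i.i.d. aligned chains, column-independent, seeded."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    symbols = np.array(list(ALIGNMENT_SYMBOLS))
    # inverse-CDF per column, vectorized over sequences
    cum = np.cumsum(profile.probs, axis=1)
    u = rng.random((n, ALIGNED_LENGTH))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    return [
        AlignedChain(
            id=f"{id_prefix}_{profile.chain_type}_{i}",
            sequence="".join(symbols[idx[i]]),
            chain_type=profile.chain_type,
        )
        for i in range(n)
    ]


DEFAULT_FR_MUTATION_RATE = 0.30


def make_precursor(
    chain: AlignedChain,
    fr_mutation_rate: float = DEFAULT_FR_MUTATION_RATE,
    seed: int = 0,
) -> AlignedChain:
    """Emulate an animal-derived precursor of a human chain.

    Each non-gap FR residue is substituted with probability
    ``fr_mutation_rate`` by a uniformly random *different* residue; CDR
    columns and gap structure are untouched. The default rate of 0.30
    reflects the typical framework divergence between murine and human
    variable domains.
    """
    if not 0.0 <= fr_mutation_rate <= 1.0:
        raise ValueError(f"fr_mutation_rate must be in [0, 1], got {fr_mutation_rate}")
    rng = np.random.default_rng(seed)
    is_cdr = cdr_mask(chain.chain_type).columns
    seq = list(chain.sequence)
    for col in range(ALIGNED_LENGTH):
        if is_cdr[col] or seq[col] == GAP:
            continue
        if rng.random() < fr_mutation_rate:
            alternatives = [a for a in AMINO_ACIDS if a != seq[col]]
            seq[col] = alternatives[rng.integers(0, len(alternatives))]
    return AlignedChain(
        id=f"{chain.id}_precursor",
        sequence="".join(seq),
        chain_type=chain.chain_type,
    )


def write_sidecar(profile: PositionProfile, n: int, sample_seed: int, path: str | Path) -> None:
    """JSON sidecar recording how a written repertoire was produced."""
    meta = {
        "chain_type": profile.chain_type,
        "fr_conservation": profile.fr_conservation,
        "profile_seed": profile.seed,
        "sample_seed": sample_seed,
        "n": n,
        "aligned_length": ALIGNED_LENGTH,
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
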