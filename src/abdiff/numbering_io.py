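"""AHo-aligned antibody V-region data model and I/O.

Antibody variable domains (heavy VH, kappa VK, lambda VL) are represented on the
fixed 149-column AHo alignment frame, so every chain of a given type is a string
of exactly 149 symbols over the 20 amino acids plus the gap character ``-``.
CDR loops are marked column-wise with a North-style definition mapped onto the
AHo frame; the three CDR segments concatenate to 64 columns on heavy chains and
67 on light chains, and everything else is framework (FR1..FR4).

Coordinates are 0-based half-open throughout the library; 1-based numbers only
appear in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALIGNED_LENGTH = 149

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALIGNMENT_SYMBOLS = AMINO_ACIDS + GAP
_ALIGNMENT_SET = frozenset(ALIGNMENT_SYMBOLS)

CHAIN_TYPES = ("H", "K", "L")

#: North CDR segments on the 149-column AHo frame, 0-based half-open.
#: Version 1 of this table. The boundaries place CDR1/CDR2/CDR3 inside the
#: hypervariable stretches of the AHo frame and are fixed so that the three
#: segments concatenate to 64 columns for heavy chains and 67 for light
#: chains (kappa and lambda share one light-chain table).
NORTH_CDR_SEGMENTS: dict[str, tuple[tuple[int, int], ...]] = {
    "H": ((26, 42), (56, 76), (107, 135)),   # 16 + 20 + 28 = 64
    "K": ((23, 42), (56, 76), (106, 134)),   # 19 + 20 + 28 = 67
    "L": ((23, 42), (56, 76), (106, 134)),
}
CDR_TABLE_VERSION = 1


class RecordError(ValueError):
    """A sequence record violates the alignment contract."""


@dataclass(frozen=True)
class AlignedChain:
    """One AHo-aligned V-region sequence.

    Parameters
    ----------
    id : record identifier (FASTA header / TSV first column).
    sequence : exactly 149 characters over the 20 amino acids and ``-``.
    chain_type : ``"H"`` (heavy), ``"K"`` (kappa) or ``"L"`` (lambda).
    """

    id: str
    sequence: str
    chain_type: str

    def __post_init__(self) -> None:
        if self.chain_type not in CHAIN_TYPES:
            raise RecordError(f"{self.id}: unknown chain_type {self.chain_type!r}")
        if len(self.sequence) != ALIGNED_LENGTH:
            raise RecordError(
                f"{self.id}: aligned length is {len(self.sequence)}, expected {ALIGNED_LENGTH}"
            )
        if not set(self.sequence) <= _ALIGNMENT_SET:  # fast path
            for pos, sym in enumerate(self.sequence):
                if sym not in _ALIGNMENT_SET:
                    raise RecordError(
                        f"{self.id}: illegal symbol {sym!r} at column {pos}"
                    )

    def __len__(self) -> int:
        return ALIGNED_LENGTH


@dataclass(frozen=True)
class CdrColumnMask:
    """Boolean CDR column mask for one chain type plus its three segments."""

    chain_type: str
    columns: np.ndarray = field(repr=False)
    segments: tuple[tuple[int, int], ...]

    @property
    def n_cdr_columns(self) -> int:
        return int(self.columns.sum())

    def fr_segments(self) -> tuple[tuple[int, int], ...]:
        """The four framework segments FR1..FR4 (complement of the CDRs)."""
        bounds = [0]
        for start, stop in self.segments:
            bounds.extend((start, stop))
        bounds.append(ALIGNED_LENGTH)
        return tuple((bounds[i], bounds[i + 1]) for i in range(0, 8, 2))


def cdr_mask(chain_type: str) -> CdrColumnMask:
    """Return the fixed North-on-AHo CDR column mask for a chain type.

    Heavy masks cover 64 columns, light (kappa/lambda) masks 67. Pure
    function: repeated calls return equal masks.
    """
    if chain_type not in NORTH_CDR_SEGMENTS:
        raise ValueError(f"unknown chain_type {chain_type!r}")
    segments = NORTH_CDR_SEGMENTS[chain_type]
    columns = np.zeros(ALIGNED_LENGTH, dtype=bool)
    for start, stop in segments:
        columns[start:stop] = True
    columns.setflags(write=False)
    return CdrColumnMask(chain_type=chain_type, columns=columns, segments=segments)


def cdr_prefix_length(chain_type: str) -> int:
    """Concatenated CDR length: 64 for heavy, 67 for light chains."""
    return cdr_mask(chain_type).n_cdr_columns


def extract_cdr_prefix(chain: AlignedChain) -> str:
    """Concatenate the three CDR column substrings, gaps preserved."""
    seq = chain.sequence
    return "".join(
        seq[start:stop] for start, stop in cdr_mask(chain.chain_type).segments
    )


def insert_cdr_prefix(prefix: str, chain_type: str, template: str | None = None) -> str:
    """Write a concatenated CDR prefix back into the CDR columns of a frame.

    ``template`` supplies the FR columns (all-gap frame by default). Inverse of
    :func:`extract_cdr_prefix` on the CDR columns.
    """
    mask = cdr_mask(chain_type)
    if len(prefix) != mask.n_cdr_columns:
        raise ValueError(
            f"prefix length {len(prefix)} does not match chain {chain_type} "
            f"({mask.n_cdr_columns} CDR columns)"
        )
    frame = list(template if template is not None else GAP * ALIGNED_LENGTH)
    it = iter(prefix)
    for start, stop in mask.segments:
        for col in range(start, stop):
            frame[col] = next(it)
    return "".join(frame)


def strip_gaps(aligned: str) -> str:
    """Drop ``-`` characters; residue order is preserved."""
    for sym in aligned:
        if sym not in ALIGNMENT_SYMBOLS:
            raise ValueError(f"non-alignment symbol {sym!r}")
    return aligned.replace(GAP, "")


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

CLS, PAD, SEP, MASK, UNK = "[CLS]", "[PAD]", "[SEP]", "[MASK]", "[UNK]"


@dataclass(frozen=True)
class Vocabulary:
    """26-token alphabet: 20 amino acids, gap, and five structural tokens."""

    tokens: tuple[str, ...] = tuple(AMINO_ACIDS) + (GAP, CLS, PAD, SEP, MASK, UNK)

    def __post_init__(self) -> None:
        assert len(self.tokens) == 26
        object.__setattr__(
            self, "_index", {tok: i for i, tok in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self._index[token]

    @property
    def mask_index(self) -> int:
        return self._index[MASK]

    @property
    def gap_index(self) -> int:
        return self._index[GAP]

    @property
    def structural_indices(self) -> tuple[int, ...]:
        """Indices never emitted in a generated alignment (incl. [MASK])."""
        return tuple(self._index[t] for t in (CLS, PAD, SEP, MASK, UNK))

    def encode(self, sequence: str) -> np.ndarray:
        """Aligned sequence -> int64 index vector (single characters only)."""
        return np.array([self._index[s] for s in sequence], dtype=np.int64)

    def decode(self, indices: Sequence[int]) -> str:
        out = []
        for i in indices:
            tok = self.tokens[int(i)]
            if len(tok) != 1:
                raise ValueError(f"structural token {tok} in decoded sequence")
            out.append(tok)
        return "".join(out)


VOCAB = Vocabulary()


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_records(path: Path) -> Iterable[tuple[str, str]]:
    text = path.read_text()
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        for line_no, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise RecordError(f"{path}:{line_no}: expected 'id<TAB>sequence'")
            yield parts[0], parts[1]


def load_aligned(path: str | Path, chain_type: str) -> list[AlignedChain]:
    """Load AHo-aligned chains from FASTA or two-column TSV.

    Every record must be exactly 149 columns over the alignment alphabet;
    violations raise :class:`RecordError` naming the offending record.
    """
    if chain_type not in CHAIN_TYPES:
        raise ValueError(f"unknown chain_type {chain_type!r}")
    return [
        AlignedChain(id=rid, sequence=seq.upper(), chain_type=chain_type)
        for rid, seq in _parse_records(Path(path))
    ]


def write_aligned(chains: Sequence[AlignedChain], path: str | Path) -> None:
    """Write chains as gapped FASTA (``.fa``/``.fasta``) or TSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta"}:
        records = [
            SeqRecord(Seq(c.sequence), id=c.id, description="") for c in chains
        ]
        SeqIO.write(records, str(path), "fasta")
    else:
        with open(path, "w") as fh:
            for c in chains:
                fh.write(f"{c.id}\t{c.sequence}\n")
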