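"""Generation-quality metrics: Template Overlap Ratio and FR diversity.

Template Overlap Ratio (TOR) asks whether generated framework regions are
human-template-like without being verbatim copies: the CDR columns of a
query are masked with ``X``, the best-matching template in an aligned human
database is found by framework identity, and the ratio of identical FR
residues to the query's non-gap FR residues is reported. A verbatim copy
scores exactly 1; nonhomologous frameworks score near the background
identity. The database scan is exhaustive column-wise identity — exact at
the scales this library targets; a local-alignment search tool is only an
accelerator for large databases, with this scan as the correctness oracle.

Diversity: framework segments are clustered by single-linkage agglomeration
on pairwise column identity across a range of identity thresholds; the
cluster count per threshold summarizes repertoire diversity (counts are
non-decreasing in the threshold).

Identity between two aligned segments counts residue=residue matches only;
gap-gap columns are excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .numbering_io import ALIGNED_LENGTH, GAP, AlignedChain, cdr_mask

FR_REGIONS = ("FR1", "FR2", "FR3", "FR4", "all-FR")


@dataclass(frozen=True)
class TemplateDB:
    """Aligned human chains of one chain type, searchable by FR identity."""

    entries: tuple[AlignedChain, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("template database is empty")
        types = {e.chain_type for e in self.entries}
        if len(types) != 1:
            raise ValueError(f"mixed chain types in database: {sorted(types)}")
        object.__setattr__(
            self, "_by_id", {e.id: e for e in self.entries}
        )

    @property
    def chain_type(self) -> str:
        return self.entries[0].chain_type

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, entry_id: str) -> AlignedChain:
        return self._by_id[entry_id]


def mask_cdrs_x(chain: AlignedChain) -> str:
    """Replace CDR columns with ``X``; FR columns are untouched."""
    seq = list(chain.sequence)
    for col in np.where(cdr_mask(chain.chain_type).columns)[0]:
        seq[col] = "X"
    return "".join(seq)


def template_overlap_ratio(query: AlignedChain, template: AlignedChain) -> float:
    """Identical non-gap FR residues / non-gap FR residues of the query."""
    if query.chain_type != template.chain_type:
        raise ValueError("query and template chain types differ")
    fr_cols = ~cdr_mask(query.chain_type).columns
    q = np.array(list(query.sequence))[fr_cols]
    t = np.array(list(template.sequence))[fr_cols]
    non_gap = q != GAP
    denom = int(non_gap.sum())
    if denom == 0:
        raise ValueError(f"{query.id}: no non-gap FR residues")
    matches = int(((q == t) & non_gap).sum())
    return matches / denom


def find_template(
    query: AlignedChain, db: TemplateDB
) -> tuple[str, float]:
    """Best template by FR identity with the CDR-masked query.

    Exhaustive scan of the database; ties broken by lowest template id.
    Returns (template_id, fr_identity).
    """
    if query.chain_type != db.chain_type:
        raise ValueError("query chain type does not match database")
    best_id, best_score = None, -1.0
    for entry in sorted(db.entries, key=lambda e: e.id):
        score = template_overlap_ratio(query, entry)
        if score > best_score:
            best_id, best_score = entry.id, score
    return best_id, best_score


def _fr_columns(chain_type: str, region: str) -> np.ndarray:
    mask = cdr_mask(chain_type)
    if region == "all-FR":
        return ~mask.columns
    try:
        idx = ("FR1", "FR2", "FR3", "FR4").index(region)
    except ValueError:
        raise ValueError(f"unknown region {region!r}; choose from {FR_REGIONS}")
    start, stop = mask.fr_segments()[idx]
    cols = np.zeros(ALIGNED_LENGTH, dtype=bool)
    cols[start:stop] = True
    return cols


def segment_identity(a: str, b: str) -> float:
    """Column identity of two aligned segments, gap-gap columns excluded."""
    aa = np.array(list(a))
    bb = np.array(list(b))
    informative = ~((aa == GAP) & (bb == GAP))
    denom = int(informative.sum())
    if denom == 0:
        return 1.0  # two all-gap segments are identical
    matches = int(((aa == bb) & (aa != GAP) & informative).sum())
    return matches / denom


def pairwise_identity(segments: Sequence[str]) -> np.ndarray:
    n = len(segments)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = segment_identity(segments[i], segments[j])
    return out


def cluster_frs(
    chains: Sequence[AlignedChain],
    region: str = "all-FR",
    thresholds: Sequence[float] = (0.6, 0.7, 0.8, 0.9),
) -> dict[float, int]:
    """Cluster FR segments by single-linkage identity; count per threshold.

    At threshold h, two segments end up in one cluster iff a chain of
    pairwise identities >= h connects them (single linkage cut at distance
    1 - h). Counts are non-decreasing in h.
    """
    if not chains:
        raise ValueError("no chains to cluster")
    for h in thresholds:
        if not 0.0 < h <= 1.0:
            raise ValueError(f"threshold {h} outside (0, 1]")
    types = {c.chain_type for c in chains}
    if len(types) != 1:
        raise ValueError("chains must share one chain type")
    cols = _fr_columns(chains[0].chain_type, region)
    segments = ["".join(np.array(list(c.sequence))[cols]) for c in chains]
    if len(segments) == 1:
        return {float(h): 1 for h in thresholds}
    dist = 1.0 - pairwise_identity(segments)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="single")
    counts = {}
    for h in thresholds:
        labels = fcluster(Z, t=(1.0 - h) + 1e-12, criterion="distance")
        counts[float(h)] = int(labels.max())
    return counts
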