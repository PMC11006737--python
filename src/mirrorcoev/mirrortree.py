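"""The core mirror-tree statistic: correlation of two distance matrices.

Two families sharing N species give two N-by-N distance matrices; their
strict upper triangles are vectorized in the same (sorted-species, row-major)
order into vectors of length n = (N^2 - N)/2 and correlated by the Pearson
product-moment coefficient r_AB. High r_AB indicates that rate variation
along the two families' phylogenies is shared — the signature of coevolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mirrorcoev import corrstats
from mirrorcoev.distance import DEFAULT_MIN_SITES, DistanceMatrix, distance_matrix
from mirrorcoev.errors import DomainError, UndefinedCorrelationError
from mirrorcoev.sequence_io import Alignment, common_species


def pairing_count(N: int) -> int:
    """Number of unordered species pairs, n = (N^2 - N)/2.

    This is the length of the vectorized strict upper triangle of an N-by-N
    distance matrix, i.e. the number of points in a mirror-tree correlation.
    """
    if N < 2:
        raise DomainError(f"need at least 2 organisms, got {N}")
    return (N * N - N) // 2


def vectorize(m: DistanceMatrix, species: Sequence[str]) -> np.ndarray:
    """Strict upper triangle of the matrix restricted to ``species``.

    Species are sorted and the triangle is read row-major, so the output is a
    deterministic function of the species *set* regardless of matrix or list
    order.
    """
    sub = m.submatrix(species)
    iu = np.triu_indices(len(sub), k=1)
    return sub.d[iu]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Computed by the direct sum formula in float64. Raises
    :class:`UndefinedCorrelationError` for vectors shorter than 3 or with zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need at least 3 points, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx * dx).sum()))
    sy = float(np.sqrt((dy * dy).sum()))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("constant vector has undefined correlation")
    r = float((dx * dy).sum() / (sx * sy))
    return min(1.0, max(-1.0, r))


@dataclass(frozen=True)
class MirrorTreeResult:
    """Mirror-tree correlation between two families over their common species."""

    r_AB: float
    N: int
    n: int
    p_single: float
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n != pairing_count(self.N):
            raise ValueError(f"n={self.n} inconsistent with N={self.N}")
        if not -1.0 <= self.r_AB <= 1.0:
            raise ValueError(f"r_AB={self.r_AB} outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "r_AB": self.r_AB,
            "N": self.N,
            "n": self.n,
            "p_single": self.p_single,
            "species": list(self.species),
        }


def mirror_tree(
    a: Alignment,
    b: Alignment,
    min_overlap: int = 5,
    min_sites: int = DEFAULT_MIN_SITES,
    gap_policy: str = "pairwise",
) -> MirrorTreeResult:
    """Full mirror-tree analysis of two aligned families.

    Filters both alignments to their common species, builds the two p-distance
    matrices over that subset, vectorizes them in the shared sorted-species
    order, and returns r_AB with N, n and the two-tailed significance of r_AB
    against the null of no correlation.

    Distances are computed on the common-species rows of each family's full
    alignment; columns are not re-aligned after filtering.
    """
    shared = common_species(a, b, min_overlap=min_overlap)
    ma = distance_matrix(a, shared, min_sites=min_sites, gap_policy=gap_policy)
    mb = distance_matrix(b, shared, min_sites=min_sites, gap_policy=gap_policy)
    va = vectorize(ma, shared)
    vb = vectorize(mb, shared)
    r = pearson(va, vb)
    N = len(shared)
    n = pairing_count(N)
    p = corrstats.single_corr_p(r, n) if abs(r) < 1.0 else 0.0
    return MirrorTreeResult(r_AB=r, N=N, n=n, p_single=p, species=tuple(shared))
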