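"""Uncorrected p-distances and species-labelled distance matrices.

The distance between two aligned protein sequences is the proportion of
differing residues among the sites compared: substitutions divided by the
number of amino acids considered. Gap and ambiguity handling follows
pairwise deletion — a site enters the comparison only when both sequences
carry a canonical residue there — so species with partial sequences are
retained. No multiple-hit correction is applied: the statistic downstream is
a correlation between matrices, which is monotone-invariant enough that the
uncorrected distance is the conventional choice for mirror-tree analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from mirrorcoev.errors import MatrixFormatError, UndefinedDistanceError
from mirrorcoev.sequence_io import CANONICAL, Alignment

#: default minimum number of both-canonical sites for a defined distance;
#: roughly 10% of a short P-type-ATPase domain. Pass 1 to disable the guard.
DEFAULT_MIN_SITES = 50

_CODE = {c: i for i, c in enumerate(CANONICAL)}


def _encode(residues: str) -> np.ndarray:
    """Map residues to integer codes; gap/X become -1 (non-canonical)."""
    return np.array([_CODE.get(c, -1) for c in residues], dtype=np.int16)


def p_distance(
    x: str,
    y: str,
    min_sites: int = DEFAULT_MIN_SITES,
    gap_policy: str = "pairwise",
) -> tuple[float, int]:
    """Proportion of differing residues between two aligned sequences.

    Returns ``(distance, usable_sites)``. Under ``gap_policy="pairwise"``
    (default) a usable site has a canonical residue in both sequences;
    ``"complete"`` additionally requires *no* gap/X in either sequence at any
    site it uses — for a two-sequence call the policies coincide, the
    distinction matters at the matrix level.

    Raises :class:`UndefinedDistanceError` when usable sites fall below
    ``min_sites`` (or zero).
    """
    if len(x) != len(y):
        raise ValueError(f"aligned lengths differ: {len(x)} vs {len(y)}")
    cx, cy = _encode(x), _encode(y)
    usable = (cx >= 0) & (cy >= 0)
    n = int(usable.sum())
    if n == 0 or n < min_sites:
        raise UndefinedDistanceError(
            f"{n} usable sites (minimum {max(min_sites, 1)})"
        )
    mismatches = int((cx[usable] != cy[usable]).sum())
    return mismatches / n, n


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric species-by-species matrix of substitutions per site."""

    species: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.species)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} species")
        if len(set(self.species)) != n:
            raise ValueError("duplicate species labels")
        if list(self.species) != sorted(self.species):
            raise ValueError("species labels must be sorted")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("diagonal not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("entries outside [0, 1]")
        object.__setattr__(self, "d", d)

    def submatrix(self, species: Sequence[str]) -> "DistanceMatrix":
        """Restrict to a subset of species (re-sorted)."""
        wanted = sorted(species)
        index = {s: i for i, s in enumerate(self.species)}
        try:
            idx = [index[s] for s in wanted]
        except KeyError as e:
            raise KeyError(f"species {e.args[0]!r} not in matrix") from None
        return DistanceMatrix(tuple(wanted), self.d[np.ix_(idx, idx)])

    def __len__(self) -> int:
        return len(self.species)


def distance_matrix(
    a: Alignment,
    species_subset: Sequence[str] | None = None,
    min_sites: int = DEFAULT_MIN_SITES,
    gap_policy: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise p-distance matrix over (a subset of) the alignment's species.

    Species are sorted lexicographically so the output is invariant to record
    order. Under ``gap_policy="complete"`` only columns canonical in every
    included sequence are compared, for all pairs alike.
    """
    if gap_policy not in ("pairwise", "complete"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    species = sorted(species_subset) if species_subset is not None else sorted(a.species)
    rows = np.stack([_encode(a.record_for(s).residues) for s in species])
    canonical = rows >= 0
    if gap_policy == "complete":
        keep = canonical.all(axis=0)
        rows = rows[:, keep]
        canonical = canonical[:, keep]
    n = len(species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = canonical[i] & canonical[j]
            sites = int(usable.sum())
            if sites == 0 or sites < min_sites:
                raise UndefinedDistanceError(
                    f"pair ({species[i]}, {species[j]}): {sites} usable sites "
                    f"(minimum {max(min_sites, 1)})"
                )
            d[i, j] = d[j, i] = (rows[i, usable] != rows[j, usable]).sum() / sites
    return DistanceMatrix(tuple(species), d)


def write_matrix(m: DistanceMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write a distance matrix: labelled TSV (default) or square PHYLIP."""
    path = Path(path)
    with path.open("w") as fh:
        if fmt == "tsv":
            fh.write("\t" + "\t".join(m.species) + "\n")
            for s, row in zip(m.species, m.d):
                fh.write(s + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        elif fmt == "phylip":
            fh.write(f"{len(m)}\n")
            for s, row in zip(m.species, m.d):
                fh.write(s + "  " + "  ".join(repr(float(v)) for v in row) + "\n")
        else:
            raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path) -> DistanceMatrix:
    """Read a labelled TSV or square PHYLIP distance matrix.

    Validates squareness and symmetry (tolerance 1e-9); raises
    :class:`MatrixFormatError` otherwise.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty matrix file")
    first = lines[0].split()
    try:
        labels, rows = _parse_phylip(lines) if len(first) == 1 and first[0].isdigit() else _parse_tsv(lines)
    except (ValueError, IndexError) as e:
        raise MatrixFormatError(f"{path}: {e}") from None
    n = len(labels)
    d = np.array(rows, dtype=float)
    if d.shape != (n, n):
        raise MatrixFormatError(f"{path}: non-square matrix {d.shape}")
    if not np.allclose(d, d.T, atol=1e-9):
        i, j = np.unravel_index(np.argmax(np.abs(d - d.T)), d.shape)
        raise MatrixFormatError(
            f"{path}: asymmetric at ({labels[i]}, {labels[j]}): {d[i, j]} vs {d[j, i]}"
        )
    order = np.argsort(labels)
    labels_sorted = tuple(labels[i] for i in order)
    return DistanceMatrix(labels_sorted, d[np.ix_(order, order)])


def _parse_phylip(lines: list[str]) -> tuple[list[str], list[list[float]]]:
    n = int(lines[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if len(labels) != n:
        raise ValueError(f"expected {n} rows, found {len(labels)}")
    return labels, rows


def _parse_tsv(lines: list[str]) -> tuple[list[str], list[list[float]]]:
    header = lines[0].split("\t")
    col_labels = [h for h in header if h]
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if labels != col_labels:
        raise ValueError("row labels do not match column labels")
    return labels, rows
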