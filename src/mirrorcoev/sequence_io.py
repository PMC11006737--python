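"""FASTA reading/writing, species-label normalization, and alignment validation.

Species labels are the join key of the whole analysis: two families are
compared over the species present in both, so every header is parsed down to
a normalized binomial (``genus_species``). Two header dialects are supported —
UniProt ``OS=Genus species`` fields and NCBI-style bracketed organisms
``[Genus species]`` — with a fallback that takes the last two whitespace
tokens of the description.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirrorcoev.errors import (
    AlphabetError,
    FastaParseError,
    InsufficientOverlapError,
    RaggedAlignmentError,
)

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted verbatim: 20 canonical amino acids, X (ambiguous), - (gap)
ALPHABET = frozenset(CANONICAL + "X-")
#: non-canonical codes silently folded into X (with a warning)
AMBIGUOUS_MAP = str.maketrans({c: "X" for c in "BZJUO"})

_OS_RE = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")
_BRACKET_RE = re.compile(r"\[([^\]]+)\]")


def normalize_species(raw: str) -> str:
    """Normalize a free-text organism name to a ``genus_species`` label.

    Lowercases, keeps the first two whitespace tokens (dropping subspecies,
    strain and author tokens), and joins them with an underscore. Single-token
    names pass through lowercased with a warning.
    """
    tokens = raw.strip().lower().split()
    if not tokens:
        raise ValueError("empty species name")
    if len(tokens) == 1:
        warnings.warn(f"single-token species name {tokens[0]!r} passed through", stacklevel=2)
        return tokens[0]
    return "_".join(tokens[:2])


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned (or plain) protein sequence with its species label."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residue string")
        if not self.species:
            raise ValueError(f"record {self.id!r}: empty species label")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)!r}"
            )

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count("-")


def _clean_residues(seq: str, rec_id: str) -> str:
    seq = seq.upper().replace(".", "-").replace("*", "")
    cleaned = seq.translate(AMBIGUOUS_MAP)
    if cleaned != seq:
        warnings.warn(
            f"record {rec_id!r}: non-canonical residues (B/Z/J/U/O) mapped to X",
            stacklevel=3,
        )
    return cleaned


def _parse_species(header_id: str, description: str, species_from: str) -> str:
    """Extract the organism name from a FASTA header.

    ``species_from`` is one of ``os`` (UniProt OS= field), ``bracket``
    (NCBI ``[Genus species]``) or ``auto`` (try both, then fall back to the
    last two whitespace tokens of the description).
    """
    if species_from not in ("os", "bracket", "auto"):
        raise ValueError(f"unknown species_from mode {species_from!r}")
    if species_from in ("os", "auto"):
        m = _OS_RE.search(description)
        if m:
            return normalize_species(m.group(1))
        if species_from == "os":
            raise FastaParseError(f"header {header_id!r}: no OS= field")
    if species_from in ("bracket", "auto"):
        m = _BRACKET_RE.search(description)
        if m:
            return normalize_species(m.group(1))
        if species_from == "bracket":
            raise FastaParseError(f"header {header_id!r}: no bracketed organism")
    # fallback: last two tokens of the description, or the bare id
    tokens = description.split()
    if len(tokens) >= 3:
        return normalize_species(" ".join(tokens[-2:]))
    return normalize_species(header_id)


def read_fasta(path: str | Path, species_from: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and non-canonical codes folded to X. Raises
    :class:`FastaParseError` on empty or non-FASTA input.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaParseError(f"{path}: empty file")
    if not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: not FASTA (first record lacks '>')")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = _parse_species(rec.id, rec.description, species_from)
        records.append(
            SequenceRecord(
                id=rec.id,
                species=species,
                residues=_clean_residues(str(rec.seq), rec.id),
            )
        )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with ``id [Genus species]`` headers."""
    seqs = []
    for r in records:
        genus_species = r.species.replace("_", " ").capitalize()
        seqs.append(
            SeqRecord(Seq(r.residues), id=r.id, description=f"[{genus_species}]")
        )
    SeqIO.write(seqs, str(path), "fasta")


@dataclass(frozen=True)
class Alignment:
    """Equal-length residue strings keyed by unique species labels."""

    records: tuple[SequenceRecord, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment with no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise RaggedAlignmentError(f"mixed sequence lengths {sorted(lengths)}")
        species = [r.species for r in self.records]
        if len(set(species)) != len(species):
            raise ValueError("duplicate species labels in alignment")
        object.__setattr__(self, "length", len(self.records[0].residues))

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def record_for(self, species: str) -> SequenceRecord:
        for r in self.records:
            if r.species == species:
                return r
        raise KeyError(species)

    def __len__(self) -> int:
        return len(self.records)


def validate_alignment(records: Sequence[SequenceRecord]) -> Alignment:
    """Check equal lengths, collapse duplicate species, return an Alignment.

    Duplicate species keep the record with the most non-gap residues; ties
    break on lexicographically smallest id (deterministic, favours complete
    entries). Ragged input raises naming the offending record.
    """
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 records")
    ref_len = len(records[0].residues)
    for r in records:
        if len(r.residues) != ref_len:
            raise RaggedAlignmentError(
                f"record {r.id!r} has length {len(r.residues)}, expected {ref_len}"
            )
    best: dict[str, SequenceRecord] = {}
    for r in records:
        cur = best.get(r.species)
        if cur is None:
            best[r.species] = r
        elif (r.ungapped_length, _neg_id(r.id)) > (cur.ungapped_length, _neg_id(cur.id)):
            best[r.species] = r
    # preserve first-seen order of surviving species
    seen: list[str] = []
    for r in records:
        if r.species not in seen:
            seen.append(r.species)
    return Alignment(records=tuple(best[s] for s in seen))


class _neg_id(str):
    """Inverts string comparison so 'larger' means lexicographically smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def common_species(a: Alignment, b: Alignment, min_overlap: int = 5) -> list[str]:
    """Sorted intersection of the two alignments' species labels.

    Raises :class:`InsufficientOverlapError` when fewer than ``min_overlap``
    species are shared — below that, a distance-matrix correlation is
    statistically vacuous.
    """
    shared = sorted(set(a.species) & set(b.species))
    if len(shared) < min_overlap:
        raise InsufficientOverlapError(
            f"only {len(shared)} common species (minimum {min_overlap})"
        )
    return shared
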