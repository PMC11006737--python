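"""Per-column conservation profiling and kinase-consensus context scanning.

Built for N-terminal regulatory-tail questions of the kind raised by the
gastric H+,K+-ATPase alpha subunit: which candidate phosphorylation sites
(Tyr/Ser/Thr) are conserved across vertebrate classes, and does their local
sequence context look like a Src-family tyrosine-kinase substrate (acidic
residues near the tyrosine) or a PKC serine/threonine substrate (basic
residues flanking the site)?

Positions are reported in the coordinates of a chosen reference species
(conventionally the human sequence); alignment columns where the reference
has a gap carry no reference number. Species may be grouped into classes
(placental mammals, marsupials, reptiles, amphibians, bony fish,
cartilaginous fish, ...) via an explicit species-to-class map — no taxonomy
lookup is attempted, keeping runs offline and deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from mirrorcoev.errors import LookupFailure
from mirrorcoev.sequence_io import Alignment

ACIDIC = frozenset("DE")
BASIC = frozenset("KR")


def map_reference_positions(a: Alignment, reference_species: str) -> dict[int, int]:
    """Map alignment columns (0-based) to reference positions (1-based).

    Only columns where the reference species has a non-gap residue receive a
    position; reference-gap columns are absent from the map.
    """
    try:
        ref = a.record_for(reference_species)
    except KeyError:
        raise LookupFailure(f"reference species {reference_species!r} not in alignment")
    mapping: dict[int, int] = {}
    pos = 0
    for col, residue in enumerate(ref.residues):
        if residue != "-":
            pos += 1
            mapping[col] = pos
    if not mapping:
        raise LookupFailure(f"reference {reference_species!r} is all gaps")
    return mapping


@dataclass(frozen=True)
class PositionSummary:
    """Conservation of one reference position across species and classes."""

    position: int          # 1-based reference coordinate
    column: int            # 0-based alignment column
    reference_residue: str
    counts: dict[str, int]             # residue -> species count (non-gap only)
    modal_residue: str
    fraction: float                    # modal frequency among non-gap species
    n_gapped: int                      # species with a gap at this column
    group_fractions: dict[str, tuple[str, float]]  # class -> (modal, fraction)


@dataclass(frozen=True)
class ConservationProfile:
    reference_species: str
    positions: tuple[PositionSummary, ...]
    groups: dict[str, str] = field(default_factory=dict)

    def at(self, position: int) -> PositionSummary:
        for p in self.positions:
            if p.position == position:
                return p
        raise LookupFailure(f"reference position {position} not in profile")


def conservation_profile(
    a: Alignment,
    reference_species: str,
    groups: Mapping[str, str] | None = None,
) -> ConservationProfile:
    """Per-reference-position residue counts, modal fractions and class breakdown.

    Gap-bearing species at a column are excluded from that column's
    denominator (their count is reported separately); species without a class
    assignment fall into ``"ungrouped"``.
    """
    ref_map = map_reference_positions(a, reference_species)
    groups = dict(groups or {})
    group_of = {s: groups.get(s, "ungrouped") for s in a.species}
    ref = a.record_for(reference_species)
    summaries = []
    for col in sorted(ref_map):
        residues = {r.species: r.residues[col] for r in a.records}
        non_gap = {s: c for s, c in residues.items() if c != "-"}
        counts = Counter(non_gap.values())
        modal, modal_count = counts.most_common(1)[0]
        by_group: dict[str, Counter] = {}
        for s, c in non_gap.items():
            by_group.setdefault(group_of[s], Counter())[c] += 1
        group_fractions = {
            g: (cnt.most_common(1)[0][0], cnt.most_common(1)[0][1] / sum(cnt.values()))
            for g, cnt in sorted(by_group.items())
        }
        summaries.append(
            PositionSummary(
                position=ref_map[col],
                column=col,
                reference_residue=ref.residues[col],
                counts=dict(counts),
                modal_residue=modal,
                fraction=modal_count / len(non_gap),
                n_gapped=len(residues) - len(non_gap),
                group_fractions=group_fractions,
            )
        )
    return ConservationProfile(
        reference_species=reference_species,
        positions=tuple(summaries),
        groups=dict(groups),
    )


def find_conserved(p: ConservationProfile, threshold: float = 1.0) -> list[int]:
    """Reference positions whose modal non-gap residue fraction is >= threshold.

    ``threshold=1.0`` (default) reproduces the strict "conserved across all
    species" criterion.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return [s.position for s in p.positions if s.fraction >= threshold]


@dataclass(frozen=True)
class KinaseContextReport:
    """Local sequence context of one candidate phosphosite in one species."""

    species: str
    position: int
    residue: str
    window: str            # ungapped flanking residues, site included, '.' padding
    acidic: int            # D/E within the window (site excluded)
    basic: int             # K/R within the window (site excluded)
    basic_before: int
    basic_after: int
    truncated: bool        # window clipped by a sequence end
    verdict: str           # "src-context" | "pkc-context" | "none"


def _verdict(residue: str, acidic: int, basic_before: int, basic_after: int) -> str:
    # Src-family kinases prefer acidic residues near the target tyrosine;
    # PKC prefers basic residues flanking the target serine/threonine.
    if residue == "Y" and acidic >= 1:
        return "src-context"
    if residue in ("S", "T") and (
        (basic_before >= 1 and basic_after >= 1) or basic_before + basic_after >= 2
    ):
        return "pkc-context"
    return "none"


def kinase_context(
    a: Alignment,
    position: int,
    reference_species: str,
    window_size: int | None = None,
) -> tuple[list[KinaseContextReport], dict[str, float]]:
    """Scan the +/-window neighbourhood of a reference position in every species.

    For each species the residue aligned to the reference position is located
    in that species' own (ungapped) coordinates and its flanking residues
    extracted — so insertions and deletions elsewhere in the alignment do not
    distort the window. The default window is 3 residues either side for
    tyrosines and 5 for serines/threonines, reflecting the span over which
    Src-family acid preference and PKC basic-flank preference are described.

    Returns the per-species reports and a summary mapping each verdict to the
    fraction of scored species carrying it (species gapped at the site are
    excluded from the denominator).
    """
    ref_map = map_reference_positions(a, reference_species)
    col_of = {pos: col for col, pos in ref_map.items()}
    if position not in col_of:
        raise LookupFailure(f"reference position {position} is not mapped")
    col = col_of[position]
    if window_size is not None and window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    reports = []
    for rec in a.records:
        site = rec.residues[col]
        if site == "-":
            continue
        w = window_size
        if w is None:
            w = 3 if site == "Y" else 5
        ungapped = rec.residues.replace("-", "")
        idx = len(rec.residues[: col + 1].replace("-", "")) - 1
        lo = max(0, idx - w)
        hi = min(len(ungapped), idx + w + 1)
        before = ungapped[lo:idx]
        after = ungapped[idx + 1 : hi]
        acidic = sum(c in ACIDIC for c in before + after)
        basic_before = sum(c in BASIC for c in before)
        basic_after = sum(c in BASIC for c in after)
        reports.append(
            KinaseContextReport(
                species=rec.species,
                position=position,
                residue=site,
                window=before + site + after,
                acidic=acidic,
                basic=basic_before + basic_after,
                basic_before=basic_before,
                basic_after=basic_after,
                truncated=(idx - lo < w) or (hi - idx - 1 < w),
                verdict=_verdict(site, acidic, basic_before, basic_after),
            )
        )
    summary: dict[str, float] = {}
    if reports:
        counts = Counter(r.verdict for r in reports)
        summary = {v: c / len(reports) for v, c in sorted(counts.items())}
    return reports, summary
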