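"""Panel orchestration: one query family against candidate partners, with controls.

A run takes a query alignment (e.g. the H+,K+-ATPase alpha subunit), a panel
of candidate partner families (e.g. the PKC isoforms or the Src-family
kinases), and optional labelled control pairs — a positive control of two
proteins known to coevolve (such as the pump's own alpha and beta subunits)
and negative controls of proteins with no reason to coevolve. Every pair gets
a mirror-tree correlation; the panel is ranked with top-versus-rest Fisher-z
comparisons; and the controls set an empirical candidacy band: a panel member
is only called a coevolution candidate when its r_AB exceeds every negative
control's, because a shared underlying species phylogeny alone already
produces large correlations between unrelated families.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from mirrorcoev.corrstats import rank_partners
from mirrorcoev.distance import DEFAULT_MIN_SITES
from mirrorcoev.errors import ConfigError, MirrorCoevError
from mirrorcoev.mirrortree import MirrorTreeResult, mirror_tree
from mirrorcoev.sequence_io import read_fasta, validate_alignment

logger = logging.getLogger(__name__)

#: empirical fallback candidacy threshold used when no negative controls are
#: supplied: the level above the strongest published negative control.
DEFAULT_CANDIDATE_THRESHOLD = 0.92


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative description of one panel run (normally loaded from YAML)."""

    query: str
    panel: dict[str, str]
    positive_controls: dict[str, tuple[str, str]] = field(default_factory=dict)
    negative_controls: dict[str, tuple[str, str]] = field(default_factory=dict)
    gap_policy: str = "pairwise"
    sample_size: str = "pairings"
    min_overlap: int = 5
    min_sites: int = DEFAULT_MIN_SITES
    species_from: str = "auto"
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel:
            raise ConfigError("panel must not be empty")
        if self.gap_policy not in ("pairwise", "complete"):
            raise ConfigError(f"unknown gap policy {self.gap_policy!r}")
        if self.sample_size not in ("pairings", "organisms"):
            raise ConfigError(f"unknown sample-size convention {self.sample_size!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        panel = raw.get("panel") or {}
        if len(panel) != len(set(panel)):
            raise ConfigError("duplicate panel labels")
        controls = raw.get("controls") or {}

        def _pairs(kind: str) -> dict[str, tuple[str, str]]:
            out = {}
            for label, pair in (controls.get(kind) or {}).items():
                if not isinstance(pair, (list, tuple)) or len(pair) != 2:
                    raise ConfigError(f"control {label!r}: expected a 2-item path pair")
                out[label] = (str(pair[0]), str(pair[1]))
            return out

        return cls(
            query=str(raw["query"]),
            panel={str(k): str(v) for k, v in panel.items()},
            positive_controls=_pairs("positive"),
            negative_controls=_pairs("negative"),
            gap_policy=raw.get("gap_policy", "pairwise"),
            sample_size=raw.get("sample_size", "pairings"),
            min_overlap=int(raw.get("min_overlap", 5)),
            min_sites=int(raw.get("min_sites", DEFAULT_MIN_SITES)),
            species_from=raw.get("species_from", "auto"),
            out_dir=str(raw.get("out_dir", ".")),
            seed=int(raw.get("seed", 0)),
        )


def control_banding(
    positive_r: float | None,
    negative_rs: Sequence[float],
    fallback: float = DEFAULT_CANDIDATE_THRESHOLD,
) -> dict:
    """Candidacy band from control correlations.

    The threshold is the maximum negative-control r_AB: members strictly above
    it are flagged ``candidate``, members at or below are not distinguishable
    from a non-coevolving pair. Without negative controls the published-level
    fallback (0.92) is used, with a warning. A negative control exceeding the
    positive one degenerates the band and is warned about.
    """
    if negative_rs:
        threshold = max(negative_rs)
        source = "max negative control"
    else:
        threshold = fallback
        source = "fallback"
        logger.warning("no negative controls; using fallback threshold %.2f", fallback)
    degenerate = positive_r is not None and negative_rs and threshold >= positive_r
    if degenerate:
        logger.warning(
            "negative control r (%.4f) >= positive control r (%.4f): band degenerate",
            threshold,
            positive_r,
        )
    return {
        "threshold": threshold,
        "source": source,
        "positive_r": positive_r,
        "degenerate": bool(degenerate),
    }


@dataclass(frozen=True)
class PanelReport:
    results: dict[str, MirrorTreeResult]
    skipped: dict[str, str]
    ranking: "object"  # pandas DataFrame from rank_partners
    controls: dict[str, dict]
    banding: dict
    candidates: dict[str, bool]

    def to_json(self) -> str:
        """Deterministic JSON: fixed key order, floats at full repr precision."""
        payload = {
            "results": {k: self.results[k].to_dict() for k in sorted(self.results)},
            "skipped": dict(sorted(self.skipped.items())),
            "ranking": self.ranking.to_dict(orient="records"),
            "controls": {k: self.controls[k] for k in sorted(self.controls)},
            "banding": self.banding,
            "candidates": dict(sorted(self.candidates.items())),
        }
        return json.dumps(payload, indent=2, sort_keys=False)


def _load(path: str, species_from: str):
    return validate_alignment(read_fasta(path, species_from=species_from))


def run_panel(config: AnalysisConfig) -> PanelReport:
    """Run the full panel analysis described by ``config``.

    Panel members that fail (insufficient overlap, undefined distances) are
    recorded as skipped with the reason and the run continues; if every member
    fails the run errors. Outputs ``ranking.tsv`` and ``report.json`` under
    the configured output directory.
    """
    paths = [config.query, *config.panel.values()]
    if len(paths) != len(set(paths)):
        raise ConfigError("query/panel paths must be distinct")
    query = _load(config.query, config.species_from)
    kwargs = dict(
        min_overlap=config.min_overlap,
        min_sites=config.min_sites,
        gap_policy=config.gap_policy,
    )
    results: dict[str, MirrorTreeResult] = {}
    skipped: dict[str, str] = {}
    for label, path in config.panel.items():
        try:
            res = mirror_tree(query, _load(path, config.species_from), **kwargs)
        except MirrorCoevError as e:
            logger.warning("panel member %s skipped: %s", label, e)
            skipped[label] = str(e)
            continue
        logger.info(
            "panel %s: N=%d n=%d r_AB=%.4f p=%.3g",
            label, res.N, res.n, res.r_AB, res.p_single,
        )
        results[label] = res
    if not results:
        raise MirrorCoevError("every panel member failed; nothing to rank")

    controls: dict[str, dict] = {}
    positive_r = None
    negative_rs = []
    for kind, pairs in (
        ("positive", config.positive_controls),
        ("negative", config.negative_controls),
    ):
        for label, (pa, pb) in pairs.items():
            res = mirror_tree(
                _load(pa, config.species_from), _load(pb, config.species_from), **kwargs
            )
            controls[label] = {"kind": kind, **res.to_dict()}
            logger.info("control %s (%s): r_AB=%.4f", label, kind, res.r_AB)
            if kind == "positive":
                positive_r = res.r_AB if positive_r is None else max(positive_r, res.r_AB)
            else:
                negative_rs.append(res.r_AB)

    # the Fisher-z tests take the pairing count n by default; the organism
    # count N is available as an alternative convention
    entries = [
        (label, (res.r_AB, res.n if config.sample_size == "pairings" else res.N))
        for label, res in sorted(results.items())
    ]
    if len(entries) >= 2:
        ranking = rank_partners(entries)
    else:
        import pandas as pd

        (label, (r, size)), = entries
        ranking = pd.DataFrame(
            [{"label": label, "r_AB": r, "n": size,
              "p_single": results[label].p_single, "p_vs_top": float("nan"),
              "tie_with_top": False}]
        )
    banding = control_banding(positive_r, negative_rs) if (positive_r is not None or negative_rs) else {}
    threshold = banding.get("threshold")
    candidates = {
        label: bool(threshold is not None and res.r_AB > threshold)
        for label, res in results.items()
    }
    report = PanelReport(
        results=results,
        skipped=skipped,
        ranking=ranking,
        controls=controls,
        banding=banding,
        candidates=candidates,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ranking_out = ranking.copy()
    ranking_out.to_csv(out / "ranking.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "report.json").write_text(report.to_json() + "\n")
    return report
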