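"""Fisher r-to-z machinery for testing and comparing correlation coefficients.

Two tests drive the partner ranking:

* significance of a single correlation — the t statistic
  ``t = r * sqrt((n - 2) / (1 - r^2))`` referred to Student's t with ``n - 2``
  degrees of freedom, two-tailed;
* significance of the difference between two correlations — both r values are
  mapped through Fisher's transformation ``z = atanh(r)``, whose sampling
  distribution is approximately normal with variance ``1/(n - 3)``, and the
  standardized difference ``(z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))`` is
  referred to the standard normal, two-tailed.

Sample size convention: in a mirror-tree analysis each correlation is over
the n = (N^2 - N)/2 vectorized matrix entries, and that pairing count is the
n used in both tests by default. The matrix entries are not independent
observations (each species contributes to N - 1 of them), so these p-values
are anti-conservative in absolute terms; they are used comparatively, to
rank candidate partners. Pass ``sample_size="organisms"`` helpers the N
convention instead where a caller wants it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from mirrorcoev.errors import DomainError


def fisher_z(r: float) -> float:
    """Fisher's r-to-z transformation, z = atanh(r) = 0.5*ln((1+r)/(1-r))."""
    if not -1.0 < r < 1.0:
        raise DomainError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def single_corr_p(r: float, n: int) -> float:
    """Two-tailed p for the null of zero correlation, via Student's t.

    ``n`` is the number of paired observations (the pairing count in a
    mirror-tree context); requires ``n >= 4`` and ``|r| < 1``.
    """
    if n < 4:
        raise DomainError(f"need n >= 4, got {n}")
    if not -1.0 < r < 1.0:
        raise DomainError(f"|r| must be < 1, got {r}")
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(stats.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher-z comparison of two correlation coefficients."""

    r1: float
    r2: float
    n1: int
    n2: int
    z1: float
    z2: float
    z_stat: float
    p_two_tailed: float


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Two-tailed test that two correlations differ.

    Both correlations are Fisher-transformed and their standardized difference
    is referred to the standard normal (no continuity correction, matching the
    classic Vassarstats calculator).
    """
    if n1 < 4 or n2 < 4:
        raise DomainError(f"need n >= 4, got n1={n1}, n2={n2}")
    z1 = fisher_z(r1)
    z2 = fisher_z(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (z1 - z2) / se
    p = 2.0 * float(stats.norm.sf(abs(z_stat)))
    return CorrelationComparison(
        r1=r1, r2=r2, n1=n1, n2=n2, z1=z1, z2=z2, z_stat=z_stat, p_two_tailed=min(p, 1.0)
    )


def _as_rn(entry) -> tuple[float, int]:
    """Accept a MirrorTreeResult-like object or a plain (r, n) pair."""
    if hasattr(entry, "r_AB"):
        return float(entry.r_AB), int(entry.n)
    r, n = entry
    return float(r), int(n)


def rank_partners(
    results: Sequence[tuple[str, object]],
    tie_alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank candidate partners by r_AB and test the leader against the rest.

    ``results`` is a sequence of ``(label, MirrorTreeResult)`` or
    ``(label, (r, n))`` entries. Returns a DataFrame sorted descending by
    r_AB with, for every non-top entry, the Fisher-z comparison against the
    top entry (``p_vs_top``) and a ``tie_with_top`` flag where that p exceeds
    ``tie_alpha`` — i.e. where the data cannot distinguish the candidate from
    the leader.
    """
    if len(results) < 2:
        raise DomainError(f"need at least 2 results to rank, got {len(results)}")
    rows = []
    for label, entry in results:
        r, n = _as_rn(entry)
        p_single = single_corr_p(r, n) if abs(r) < 1.0 else 0.0
        rows.append({"label": label, "r_AB": r, "n": n, "p_single": p_single})
    df = pd.DataFrame(rows).sort_values(
        ["r_AB", "label"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = df.iloc[0]
    p_vs_top = [float("nan")]
    ties = [False]
    for _, row in df.iloc[1:].iterrows():
        cmp = compare_correlations(top["r_AB"], int(top["n"]), row["r_AB"], int(row["n"]))
        p_vs_top.append(cmp.p_two_tailed)
        ties.append(cmp.p_two_tailed > tie_alpha)
    df["p_vs_top"] = p_vs_top
    df["tie_with_top"] = ties
    return df
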