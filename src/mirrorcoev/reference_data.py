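"""Published mirror-tree statistics for the gastric H+,K+-ATPase alpha1 subunit.

These are the reported Pearson correlations of the pump's distance matrix
against each PKC isoform and each Src-family kinase, with the number of
common organisms N and pairing count n for each analysis, plus the control
correlations (alpha1/beta1 subunits as the positive control; alpha1 vs
hexokinase and PKC-alpha vs EGFR as negatives). They are inputs for the
Fisher-z ranking machinery — the underlying sequence sets are database
retrievals that are not redistributed here.
"""

from __future__ import annotations

from typing import NamedTuple


class PanelRow(NamedTuple):
    label: str
    r_AB: float
    N: int
    n: int


#: mirror-tree correlations of H+,K+-ATPase alpha1 vs PKC isoforms
PKC_PANEL: tuple[PanelRow, ...] = (
    PanelRow("alpha", 0.9240, 41, 820),
    PanelRow("beta", 0.1284, 46, 1035),
    PanelRow("gamma", 0.9132, 53, 1378),
    PanelRow("delta", 0.7580, 67, 2211),
    PanelRow("epsilon", 0.8421, 45, 990),
    PanelRow("eta", 0.9274, 55, 1485),
    PanelRow("theta", 0.9427, 48, 1128),
    PanelRow("zeta", 0.9053, 36, 630),
    PanelRow("lambda", 0.6799, 51, 1275),
)

#: mirror-tree correlations of H+,K+-ATPase alpha1 vs Src-family kinases.
#: NOTE: the Lyn row's published n (4075) does not satisfy n = (N^2-N)/2
#: for N=91 (which gives 4095) — an inconsistency in the published table,
#: reproduced here verbatim.
SRC_PANEL: tuple[PanelRow, ...] = (
    PanelRow("Src", 0.8070, 83, 3403),
    PanelRow("Yes", 0.9468, 85, 3570),
    PanelRow("Lyn", 0.9384, 91, 4075),
    PanelRow("Lck", 0.9512, 94, 4371),
    PanelRow("Fyn", 0.9384, 97, 4656),
    PanelRow("Fgr", 0.3143, 89, 3916),
    PanelRow("Hck", 0.9358, 61, 1830),
    PanelRow("Blk", 0.9187, 87, 3741),
)

#: control correlations: alpha1/beta1 subunits coevolve (positive); the
#: alpha1/hexokinase and PKC-alpha/EGFR pairs should not (negatives).
POSITIVE_CONTROL_R = 0.9639
NEGATIVE_CONTROL_RS = (0.9172, 0.7915)
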