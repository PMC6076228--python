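"""Canonical deleteriousness predictors and their category mappings.

The ensemble consumes raw scores from 17 published deleteriousness-scoring
methods: 8 functional prediction scores (Polyphen2_HDIV, Polyphen2_HVAR,
MutationTaster, SIFT, LRT, FATHMM, MutationAssessor, M-CAP), 7 newer scores
(PROVEAN, VEST3, MetaSVM, MetaLR, fathmm-MKL, CADD, DANN) and 2 cross-species
conservation scores (GERP++, phyloP100way).

Raw scores are mapped onto a five-level categorical scale
(damaging / possibly_damaging / unclassified / possibly_benign / benign)
using per-tool thresholds.  Each tool carries a "damaging" cut-off and a
"benign" cut-off taken from its authors' recommended operating points; scores
between the two cuts are split at the midpoint into the two "possibly"
categories.  All thresholds are configurable: pass your own mapping of
:class:`ToolThresholds` wherever a ``thresholds`` argument is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

# Categorical scale and its point values on the -10..+10 score axis.
DAMAGING = "damaging"
POSSIBLY_DAMAGING = "possibly_damaging"
UNCLASSIFIED = "unclassified"
POSSIBLY_BENIGN = "possibly_benign"
BENIGN = "benign"

CATEGORIES = (DAMAGING, POSSIBLY_DAMAGING, UNCLASSIFIED, POSSIBLY_BENIGN, BENIGN)

_CATEGORY_POINTS = {
    DAMAGING: 10,
    POSSIBLY_DAMAGING: 5,
    UNCLASSIFIED: 0,
    POSSIBLY_BENIGN: -5,
    BENIGN: -10,
}

#: The 17 canonical tool names, in the order they are usually tabulated.
TOOLS = (
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "MutationTaster",
    "SIFT",
    "LRT",
    "FATHMM",
    "MutationAssessor",
    "M-CAP",
    "PROVEAN",
    "VEST3",
    "MetaSVM",
    "MetaLR",
    "fathmm-MKL",
    "CADD",
    "DANN",
    "GERP++",
    "phyloP100way",
)

#: Conservation scores: excluded from candidate trios by default and used for
#: the +1 conserved-position bonus instead (they carry a double role in the
#: 17-tool list; we resolve it this way, with a switch to put them back).
CONSERVATION_TOOLS = ("GERP++", "phyloP100way")

#: The 15 functional predictors eligible for trio selection by default.
FUNCTIONAL_TOOLS = tuple(t for t in TOOLS if t not in CONSERVATION_TOOLS)


@dataclass(frozen=True)
class ToolThresholds:
    """Category cut-offs for one tool.

    ``damaging``/``benign`` are the outer cut-offs; scores on the damaging
    side of ``damaging`` map to the damaging category (direction given by
    ``lower_is_damaging``).  ``lo``/``hi`` bound the plausible raw-score range
    and are used only to place synthetic scores inside a category band.
    """

    damaging: float
    benign: float
    lower_is_damaging: bool = False
    lo: float = 0.0
    hi: float = 1.0

    @property
    def midpoint(self) -> float:
        return (self.damaging + self.benign) / 2.0


#: Default per-tool operating points (authors' published cut-offs where they
#: exist; all overridable).
DEFAULT_THRESHOLDS: Mapping[str, ToolThresholds] = {
    "Polyphen2_HDIV": ToolThresholds(0.957, 0.452),
    "Polyphen2_HVAR": ToolThresholds(0.909, 0.446),
    "MutationTaster": ToolThresholds(0.9, 0.1),
    "SIFT": ToolThresholds(0.05, 0.95, lower_is_damaging=True),
    "LRT": ToolThresholds(0.001, 0.5, lower_is_damaging=True),
    "FATHMM": ToolThresholds(-1.5, 1.5, lower_is_damaging=True, lo=-10.0, hi=10.0),
    "MutationAssessor": ToolThresholds(3.5, 1.935, lo=-6.0, hi=6.0),
    "M-CAP": ToolThresholds(0.025, 0.005),
    "PROVEAN": ToolThresholds(-2.5, -1.0, lower_is_damaging=True, lo=-14.0, hi=14.0),
    "VEST3": ToolThresholds(0.8, 0.3),
    "MetaSVM": ToolThresholds(0.5, -0.5, lo=-2.0, hi=2.0),
    "MetaLR": ToolThresholds(0.75, 0.25),
    "fathmm-MKL": ToolThresholds(0.9, 0.1),
    "CADD": ToolThresholds(20.0, 10.0, lo=0.0, hi=60.0),
    "DANN": ToolThresholds(0.96, 0.5),
    "GERP++": ToolThresholds(4.0, 2.0, lo=-12.3, hi=6.17),
    "phyloP100way": ToolThresholds(2.0, 0.0, lo=-20.0, hi=10.0),
}


def map_raw_to_category(
    tool: str,
    raw: Optional[float],
    thresholds: Optional[Mapping[str, ToolThresholds]] = None,
) -> str:
    """Map a raw tool score to the five-level categorical scale.

    An absent score always maps to ``unclassified``.  Unknown tool names are
    an error.
    """
    th = (thresholds or DEFAULT_THRESHOLDS).get(tool)
    if th is None:
        raise ValueError(f"unknown prediction tool: {tool!r}")
    if raw is None:
        return UNCLASSIFIED
    raw = float(raw)
    mid = th.midpoint
    if th.lower_is_damaging:
        if raw <= th.damaging:
            return DAMAGING
        if raw >= th.benign:
            return BENIGN
        return POSSIBLY_DAMAGING if raw < mid else POSSIBLY_BENIGN
    if raw >= th.damaging:
        return DAMAGING
    if raw <= th.benign:
        return BENIGN
    return POSSIBLY_DAMAGING if raw > mid else POSSIBLY_BENIGN


def category_points(category: str) -> int:
    """Point value of a category: damaging 10, possibly damaging 5,
    unclassified 0, possibly benign -5, benign -10."""
    try:
        return _CATEGORY_POINTS[category]
    except KeyError:
        raise ValueError(f"unknown category: {category!r}") from None


def category_band_midpoint(
    tool: str,
    category: str,
    thresholds: Optional[Mapping[str, ToolThresholds]] = None,
) -> float:
    """Raw score at the centre of a tool's category band.

    Used by the simulator so that generated raw scores invert exactly under
    :func:`map_raw_to_category`.
    """
    th = (thresholds or DEFAULT_THRESHOLDS).get(tool)
    if th is None:
        raise ValueError(f"unknown prediction tool: {tool!r}")
    if category == UNCLASSIFIED:
        raise ValueError("unclassified has no raw-score band")
    mid = th.midpoint
    if th.lower_is_damaging:
        bands = {
            DAMAGING: (th.lo + th.damaging) / 2.0,
            POSSIBLY_DAMAGING: (th.damaging + mid) / 2.0,
            POSSIBLY_BENIGN: (mid + th.benign) / 2.0,
            BENIGN: (th.benign + th.hi) / 2.0,
        }
    else:
        bands = {
            DAMAGING: (th.damaging + th.hi) / 2.0,
            POSSIBLY_DAMAGING: (mid + th.damaging) / 2.0,
            POSSIBLY_BENIGN: (th.benign + mid) / 2.0,
            BENIGN: (th.lo + th.benign) / 2.0,
        }
    if category not in bands:
        raise ValueError(f"unknown category: {category!r}")
    return bands[category]
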