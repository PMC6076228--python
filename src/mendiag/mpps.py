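"""Ensemble pathogenicity classification for nonsynonymous SNVs (MPPS).

The classifier combines 17 published deleteriousness-scoring methods.  Its
accuracy rests on an empirical observation: the reliability of individual
predictors varies across the genome.  The method therefore

1. fits, from a labeled truth set, per-region per-tool *weights* — the
   fraction of correct predictions a tool achieves in that region, separately
   for pathogenic ("damaging"-side) and neutral ("benign"-side) truth;
2. selects, for the region containing a query variant, the 3 tools with the
   highest damaging-side weight and the 3 with the highest benign-side weight;
3. scores the variant on each side as the weight-normalized sum of the tools'
   category points (damaging 10, possibly damaging 5, unclassified 0,
   possibly benign -5, benign -10), adds +1 when the position is conserved
   (GERP++ and phyloP100way both above threshold), and classifies by sign.

If the two trios disagree, the next-best rank triple of tools is tried, up to
five rounds over the 15 functional predictors.  A variant on which no round
agrees is flagged ``mis_classified`` but still receives a fallback
classification (the sign of the mean round-1 score), so every input variant
gets an output and prediction coverage is 100% by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._util import MendiagError, atomic_write_text, norm_chrom
from .predictors import (
    BENIGN,
    CONSERVATION_TOOLS,
    DAMAGING,
    DEFAULT_THRESHOLDS,
    FUNCTIONAL_TOOLS,
    POSSIBLY_BENIGN,
    POSSIBLY_DAMAGING,
    TOOLS,
    UNCLASSIFIED,
    ToolThresholds,
    category_points,
    map_raw_to_category,
)
from .variants import VariantRecord

GENOME_WIDE = "genome"

_DAMAGING_SIDE = (DAMAGING, POSSIBLY_DAMAGING)
_BENIGN_SIDE = (BENIGN, POSSIBLY_BENIGN)

TruthSet = Dict[Tuple[str, int, str, str], str]  # label: "pathogenic" | "neutral"


@dataclass
class WeightRow:
    w_dmg: float
    w_ben: float
    n_dmg: int
    n_ben: int


class RegionWeightTable:
    """Per-region, per-tool correct-prediction fractions with a genome-wide
    fallback row.

    Regions are fixed-size genomic bins keyed ``"{chrom}:{pos // bin_size}"``.
    A (region, tool) pair with no dedicated row falls back to the genome-wide
    row; a tool absent even there gets the uninformative prior 0.5.
    """

    def __init__(self, bin_size: int = 10_000_000):
        if bin_size < 1:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.rows: Dict[Tuple[str, str], WeightRow] = {}

    def region_of(self, chrom: str, pos: int) -> str:
        return f"{norm_chrom(chrom)}:{pos // self.bin_size}"

    def set(self, region: str, tool: str, row: WeightRow) -> None:
        if not (0.0 <= row.w_dmg <= 1.0 and 0.0 <= row.w_ben <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        self.rows[(region, tool)] = row

    def row(self, region: str, tool: str) -> WeightRow:
        r = self.rows.get((region, tool))
        if r is None:
            r = self.rows.get((GENOME_WIDE, tool))
        if r is None:
            r = WeightRow(0.5, 0.5, 0, 0)
        return r

    def weight(self, region: str, tool: str, side: str) -> float:
        r = self.row(region, tool)
        if side == "dmg":
            return r.w_dmg
        if side == "ben":
            return r.w_ben
        raise ValueError(f"side must be 'dmg' or 'ben', got {side!r}")

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str) -> None:
        lines = [f"#bin_size={self.bin_size}", "region\ttool\tw_dmg\tw_ben\tn_dmg\tn_ben"]
        for (region, tool), r in sorted(self.rows.items()):
            lines.append(
                f"{region}\t{tool}\t{r.w_dmg:.6f}\t{r.w_ben:.6f}\t{r.n_dmg}\t{r.n_ben}"
            )
        atomic_write_text(path, "\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "RegionWeightTable":
        with open(path) as fh:
            first = fh.readline().strip()
        if not first.startswith("#bin_size="):
            raise MendiagError(f"{path}: not a weight table (missing #bin_size header)")
        table = cls(bin_size=int(first.split("=", 1)[1]))
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"region": str})
        for _, row in df.iterrows():
            table.set(
                str(row["region"]),
                str(row["tool"]),
                WeightRow(float(row["w_dmg"]), float(row["w_ben"]), int(row["n_dmg"]), int(row["n_ben"])),
            )
        return table


def fit_region_weights(
    truth: TruthSet,
    records: Sequence[VariantRecord],
    bin_size: int = 10_000_000,
    min_n: int = 50,
    seed: Optional[int] = None,
    subsample: float = 1.0,
    thresholds: Optional[Mapping[str, ToolThresholds]] = None,
    tools: Sequence[str] = TOOLS,
) -> RegionWeightTable:
    """Fit per-region per-tool weights from a labeled truth set.

    The weight of a tool in a region is the fraction of correct predictions it
    makes there, computed separately over truth-pathogenic variants
    (damaging-side weight) and truth-neutral variants (benign-side weight).
    Only variants on which the tool emits a prediction enter the denominator.
    Bins with fewer than ``min_n`` predicted truth variants of either class
    inherit the genome-wide fallback row.  ``subsample`` < 1 fits on a random
    subset of the truth keys (seeded), mirroring the original sampling scheme.
    """
    if not truth:
        raise ValueError("truth set is empty")
    labels = set(truth.values())
    by_key = {r.key: r for r in records}
    missing = [k for k in truth if k not in by_key]
    if missing:
        raise ValueError(f"{len(missing)} truth keys have no prediction profile, e.g. {missing[0]}")
    keys = sorted(truth)
    if subsample < 1.0:
        rng = np.random.default_rng(seed)
        n_keep = max(1, int(round(subsample * len(keys))))
        keys = [keys[i] for i in sorted(rng.choice(len(keys), size=n_keep, replace=False))]

    table = RegionWeightTable(bin_size=bin_size)
    # counts[(region, tool)] = [n_dmg, correct_dmg, n_ben, correct_ben]
    counts: Dict[Tuple[str, str], List[int]] = {}
    for key in keys:
        rec = by_key[key]
        label = truth[key]
        region = table.region_of(rec.chrom, rec.pos)
        for tool in tools:
            cat = map_raw_to_category(tool, rec.tool_scores.get(tool), thresholds)
            if cat == UNCLASSIFIED:
                continue
            for reg in (region, GENOME_WIDE):
                c = counts.setdefault((reg, tool), [0, 0, 0, 0])
                if label == "pathogenic":
                    c[0] += 1
                    c[1] += cat in _DAMAGING_SIDE
                else:
                    c[2] += 1
                    c[3] += cat in _BENIGN_SIDE

    one_class = {"pathogenic", "neutral"} - labels
    if one_class:
        warnings.warn(
            f"truth set has no {one_class.pop()} variants; missing-class weights "
            "fall back to the uninformative prior 0.5",
            stacklevel=2,
        )

    def _row(c: List[int]) -> WeightRow:
        w_dmg = c[1] / c[0] if c[0] else 0.5
        w_ben = c[3] / c[2] if c[2] else 0.5
        return WeightRow(w_dmg, w_ben, c[0], c[2])

    # genome-wide fallback row always present for every tool
    for tool in tools:
        table.set(GENOME_WIDE, tool, _row(counts.get((GENOME_WIDE, tool), [0, 0, 0, 0])))
    for (region, tool), c in counts.items():
        if region == GENOME_WIDE:
            continue
        if c[0] >= min_n and c[2] >= min_n:
            table.set(region, tool, _row(c))
    return table


@dataclass(frozen=True)
class TrioSelection:
    """The rank triple of tools chosen on each side for one round."""

    round: int
    dmg_tools: Tuple[str, str, str]
    ben_tools: Tuple[str, str, str]


def select_trios(
    weights: RegionWeightTable,
    region: str,
    round: int = 1,
    candidates: Sequence[str] = FUNCTIONAL_TOOLS,
) -> TrioSelection:
    """Pick round-``round``'s trio on each side for a region.

    Tools are ranked by the side's weight, descending, ties broken by tool
    name; round *r* takes ranks ``3(r-1)+1 .. 3r``.  Rounds are exhausted when
    ``3 * round`` exceeds the candidate pool (round > 5 for the default 15
    functional predictors).
    """
    if round < 1:
        raise ValueError("round must be >= 1")
    if 3 * round > len(candidates):
        raise ValueError(
            f"round {round} exhausts the ranked list of {len(candidates)} candidate tools"
        )
    lo, hi = 3 * (round - 1), 3 * round
    ranked_dmg = sorted(candidates, key=lambda t: (-weights.weight(region, t, "dmg"), t))
    ranked_ben = sorted(candidates, key=lambda t: (-weights.weight(region, t, "ben"), t))
    return TrioSelection(round, tuple(ranked_dmg[lo:hi]), tuple(ranked_ben[lo:hi]))


def weighted_trio_score(points: Sequence[float], trio_weights: Sequence[float]) -> float:
    """Weight-normalized sum: sum(w_i * p_i) / sum(w_i); 0 when all weights
    vanish.  Normalizing keeps the result inside [-10, 10] for any weights."""
    sw = float(sum(trio_weights))
    if sw == 0.0:
        return 0.0
    return float(sum(w * p for w, p in zip(trio_weights, points)) / sw)


def trio_score(
    profile: Union[VariantRecord, Mapping[str, float]],
    trio: Sequence[str],
    weights: RegionWeightTable,
    region: str,
    side: str,
    thresholds: Optional[Mapping[str, ToolThresholds]] = None,
) -> float:
    """Score one side's trio for a variant; absent predictions contribute 0
    points but their weight still enters the normalization."""
    scores = profile.tool_scores if isinstance(profile, VariantRecord) else profile
    pts = [category_points(map_raw_to_category(t, scores.get(t), thresholds)) for t in trio]
    ws = [weights.weight(region, t, side) for t in trio]
    return weighted_trio_score(pts, ws)


def conservation_bonus(
    score: float,
    gerp: Optional[float],
    phylop: Optional[float],
    gerp_threshold: float = 2.0,
    phylop_threshold: float = 1.6,
) -> float:
    """Add +1 to a trio score at conserved positions, clamped at +10.

    A position counts as conserved only when both conservation scores are
    present and at or above their thresholds.
    """
    if gerp is not None and phylop is not None:
        if gerp >= gerp_threshold and phylop >= phylop_threshold:
            return min(score + 1.0, 10.0)
    return score


@dataclass
class MppsResult:
    """Outcome of the iterative trio-agreement protocol for one variant."""

    score_dmg: float
    score_ben: float
    classification: str  # "damaging" | "benign"
    mis_classified: bool
    round_used: int
    trio_dmg: Tuple[str, str, str]
    trio_ben: Tuple[str, str, str]
    conserved: bool


def _side_label(score: float, margin: float) -> Optional[str]:
    if score >= margin:
        return DAMAGING
    if score <= -margin:
        return BENIGN
    return None


def classify_variant(
    record: Union[VariantRecord, Mapping[str, float]],
    weights: RegionWeightTable,
    region: Optional[str] = None,
    thresholds: Optional[Mapping[str, ToolThresholds]] = None,
    gerp_threshold: float = 2.0,
    phylop_threshold: float = 1.6,
    agreement_margin: float = 1.0,
    max_rounds: int = 5,
    include_conservation_in_trios: bool = False,
    bonus_both_sides: bool = True,
) -> MppsResult:
    """Run the full iterative agreement protocol on one variant.

    Each round selects the next-best trio on each side, scores both, applies
    the conservation bonus, and classifies each side by sign (``>= +margin``
    damaging, ``<= -margin`` benign, otherwise indeterminate).  Agreement
    terminates the loop.  If no round agrees the variant is flagged
    mis-classified and classified by the sign of the mean round-1 score (ties
    resolve to damaging, the review-conservative side), so a classification is
    always emitted.
    """
    if isinstance(record, VariantRecord):
        scores = record.tool_scores
        if region is None:
            region = weights.region_of(record.chrom, record.pos)
    else:
        scores = record
        if region is None:
            region = GENOME_WIDE
    candidates = TOOLS if include_conservation_in_trios else FUNCTIONAL_TOOLS
    gerp = scores.get("GERP++")
    phylop = scores.get("phyloP100way")
    conserved = (
        gerp is not None
        and phylop is not None
        and gerp >= gerp_threshold
        and phylop >= phylop_threshold
    )
    max_rounds = min(max_rounds, len(candidates) // 3)
    first: Optional[Tuple[float, float, TrioSelection]] = None
    for rnd in range(1, max_rounds + 1):
        sel = select_trios(weights, region, rnd, candidates)
        s_dmg = trio_score(scores, sel.dmg_tools, weights, region, "dmg", thresholds)
        s_ben = trio_score(scores, sel.ben_tools, weights, region, "ben", thresholds)
        if bonus_both_sides:
            s_dmg = conservation_bonus(s_dmg, gerp, phylop, gerp_threshold, phylop_threshold)
            s_ben = conservation_bonus(s_ben, gerp, phylop, gerp_threshold, phylop_threshold)
        else:
            s_dmg = conservation_bonus(s_dmg, gerp, phylop, gerp_threshold, phylop_threshold)
        if first is None:
            first = (s_dmg, s_ben, sel)
        lab_d = _side_label(s_dmg, agreement_margin)
        lab_b = _side_label(s_ben, agreement_margin)
        if lab_d is not None and lab_d == lab_b:
            return MppsResult(
                s_dmg, s_ben, lab_d, False, rnd, sel.dmg_tools, sel.ben_tools, conserved
            )
    assert first is not None
    s_dmg1, s_ben1, sel1 = first
    mean = (s_dmg1 + s_ben1) / 2.0
    fallback = DAMAGING if mean >= 0 else BENIGN
    return MppsResult(
        s_dmg1, s_ben1, fallback, True, max_rounds, sel1.dmg_tools, sel1.ben_tools, conserved
    )


def predict_batch(
    records: Sequence[VariantRecord],
    weights: RegionWeightTable,
    **kwargs,
) -> List[MppsResult]:
    """Classify every variant in a batch; exactly one result per input, in
    order, so the batch's prediction coverage is 100% by construction."""
    return [classify_variant(r, weights, **kwargs) for r in records]


def results_to_dataframe(
    records: Sequence[VariantRecord], results: Sequence[MppsResult]
) -> pd.DataFrame:
    if len(records) != len(results):
        raise ValueError("records and results must be parallel")
    rows = []
    for r, m in zip(records, results):
        rows.append(
            {
                "chrom": norm_chrom(r.chrom),
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "score_dmg": round(m.score_dmg, 6),
                "score_ben": round(m.score_ben, 6),
                "classification": m.classification,
                "mis_classified": m.mis_classified,
                "round_used": m.round_used,
                "conserved": m.conserved,
            }
        )
    cols = [
        "chrom", "pos", "ref", "alt", "score_dmg", "score_ben",
        "classification", "mis_classified", "round_used", "conserved",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_results_tsv(
    records: Sequence[VariantRecord], results: Sequence[MppsResult], path: str
) -> None:
    df = results_to_dataframe(records, results)
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


class MppsClassifier:
    """Thin fit/predict wrapper around the functional interface.

    >>> clf = MppsClassifier(bin_size=10_000_000, min_n=50)
    >>> clf.fit(truth, annotated_records)       # doctest: +SKIP
    >>> results = clf.predict(new_records)      # doctest: +SKIP
    """

    def __init__(self, bin_size: int = 10_000_000, min_n: int = 50, seed: Optional[int] = None, **predict_kwargs):
        self.bin_size = bin_size
        self.min_n = min_n
        self.seed = seed
        self.predict_kwargs = predict_kwargs
        self.weights_: Optional[RegionWeightTable] = None

    def fit(self, truth: TruthSet, records: Sequence[VariantRecord]) -> "MppsClassifier":
        self.weights_ = fit_region_weights(
            truth, records, bin_size=self.bin_size, min_n=self.min_n, seed=self.seed
        )
        return self

    def predict(self, records: Sequence[VariantRecord]) -> List[MppsResult]:
        if self.weights_ is None:
            raise RuntimeError("classifier is not fitted")
        return predict_batch(records, self.weights_, **self.predict_kwargs)
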