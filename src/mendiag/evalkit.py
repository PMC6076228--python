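"""Benchmark statistics: per-tool accuracy, prediction coverage, genotype
concordance.

Prediction Coverage of a method is the number of variants it predicts
(correctly or incorrectly) divided by the total number of variants evaluated.
Accuracy denominators are, by default, the variants for which the method did
emit a prediction — coverage and accuracy are reported as separate axes — with
a flag to switch to all-variants denominators.  All percentages are rounded
half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._util import MendiagError, atomic_write_text, ratio_pct
from .predictors import (
    BENIGN,
    DAMAGING,
    POSSIBLY_BENIGN,
    POSSIBLY_DAMAGING,
    TOOLS,
    UNCLASSIFIED,
    map_raw_to_category,
)
from .mpps import TruthSet, fit_region_weights, predict_batch
from .variants import VariantRecord

_PATHOGENIC_CALLS = (DAMAGING, POSSIBLY_DAMAGING)
_NEUTRAL_CALLS = (BENIGN, POSSIBLY_BENIGN)


def tool_accuracy(
    categories: Mapping[Tuple, str],
    truth: TruthSet,
    all_variant_denominator: bool = False,
) -> Dict[str, object]:
    """Accuracy and coverage of one method against a labeled truth set.

    ``categories`` maps variant keys to the method's five-level category;
    damaging-side calls count as pathogenic predictions, benign-side calls as
    neutral predictions, ``unclassified`` as no prediction.  A truth class
    with no variants (or, under prediction denominators, no predictions)
    yields ``None`` for that percentage rather than 0.
    """
    if not truth:
        raise ValueError("truth set is empty")
    n_total = len(truth)
    n_pred = 0
    n = {"pathogenic": 0, "neutral": 0}          # truth-class totals
    n_called = {"pathogenic": 0, "neutral": 0}   # with a prediction
    n_correct = {"pathogenic": 0, "neutral": 0}
    for key, label in truth.items():
        n[label] += 1
        cat = categories.get(key, UNCLASSIFIED)
        if cat == UNCLASSIFIED:
            continue
        n_pred += 1
        n_called[label] += 1
        if label == "pathogenic":
            n_correct[label] += cat in _PATHOGENIC_CALLS
        else:
            n_correct[label] += cat in _NEUTRAL_CALLS

    def _pct(label: str) -> Optional[float]:
        denom = n[label] if all_variant_denominator else n_called[label]
        if denom == 0:
            return None
        return ratio_pct(n_correct[label], denom)

    return {
        "pct_correct_pathogenic": _pct("pathogenic"),
        "pct_correct_neutral": _pct("neutral"),
        "prediction_coverage": ratio_pct(n_pred, n_total),
        "n_pathogenic": n["pathogenic"],
        "n_neutral": n["neutral"],
        "n_predicted_pathogenic": n_called["pathogenic"],
        "n_predicted_neutral": n_called["neutral"],
        "n_correct_pathogenic": n_correct["pathogenic"],
        "n_correct_neutral": n_correct["neutral"],
        "n_predicted": n_pred,
        "n_total": n_total,
    }


def split_truth(
    truth: TruthSet, seed: int, eval_frac: float = 0.5
) -> Tuple[TruthSet, TruthSet]:
    """Seeded fit/eval split of a truth set (stratification-free shuffle)."""
    keys = sorted(truth)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_eval = int(round(eval_frac * len(keys)))
    eval_keys = set(keys[:n_eval])
    fit = {k: v for k, v in truth.items() if k not in eval_keys}
    ev = {k: v for k, v in truth.items() if k in eval_keys}
    return fit, ev


def benchmark_all(
    records: Sequence[VariantRecord],
    truth: TruthSet,
    seed: int = 0,
    eval_frac: float = 0.5,
    allow_resubstitution: bool = False,
    fit_truth: Optional[TruthSet] = None,
    eval_truth: Optional[TruthSet] = None,
    bin_size: int = 10_000_000,
    min_n: int = 50,
    thresholds=None,
    all_variant_denominator: bool = False,
    **predict_kwargs,
) -> pd.DataFrame:
    """Accuracy/coverage table over the 17 tools plus the MPPS ensemble.

    Ensemble weights are fitted on a truth split disjoint from the evaluation
    split (seeded 50/50 by default; pass explicit splits to control it).
    Overlapping explicit splits are an error unless ``allow_resubstitution``;
    with ``allow_resubstitution`` and no explicit splits, the full truth set is
    used for both fitting and evaluation.
    """
    if fit_truth is None and eval_truth is None:
        if allow_resubstitution:
            fit_truth, eval_truth = truth, truth
        else:
            fit_truth, eval_truth = split_truth(truth, seed=seed, eval_frac=eval_frac)
    elif fit_truth is None or eval_truth is None:
        raise ValueError("provide both fit_truth and eval_truth, or neither")
    overlap = set(fit_truth) & set(eval_truth)
    if overlap and not allow_resubstitution:
        raise MendiagError(
            f"fit and eval truth splits overlap on {len(overlap)} variants; "
            "pass allow_resubstitution=True to evaluate in-sample"
        )

    by_key = {r.key: r for r in records}
    weights = fit_region_weights(
        fit_truth,
        [by_key[k] for k in fit_truth],
        bin_size=bin_size,
        min_n=min_n,
        seed=seed,
    )
    eval_keys = sorted(eval_truth)
    eval_records = [by_key[k] for k in eval_keys]

    rows = []
    for tool in TOOLS:
        cats = {
            k: map_raw_to_category(tool, by_key[k].tool_scores.get(tool), thresholds)
            for k in eval_keys
        }
        row = tool_accuracy(cats, eval_truth, all_variant_denominator)
        row["method"] = tool
        rows.append(row)

    results = predict_batch(eval_records, weights, thresholds=thresholds, **predict_kwargs)
    mpps_cats = {k: m.classification for k, m in zip(eval_keys, results)}
    row = tool_accuracy(mpps_cats, eval_truth, all_variant_denominator)
    row["method"] = "MPPS"
    rows.append(row)

    cols = ["method"] + [c for c in rows[0] if c != "method"]
    return pd.DataFrame(rows, columns=cols)


def write_benchmark_tsv(table: pd.DataFrame, path: str) -> None:
    atomic_write_text(path, table.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# Genotype concordance


@dataclass(frozen=True)
class ConcordanceResult:
    """Genotype agreement between two call sets over their shared loci."""

    n_compared: int
    n_concordant: int
    pct: float


def _norm_genotype(gt) -> Tuple[str, ...]:
    if isinstance(gt, str):
        alleles = gt.replace("|", "/").split("/")
    else:
        alleles = list(gt)
    return tuple(sorted(str(a) for a in alleles))


def genotype_concordance(
    calls_a: Mapping[Hashable, object], calls_b: Mapping[Hashable, object]
) -> ConcordanceResult:
    """Fraction of shared loci at which two call sets report the same
    genotype (compared as unordered allele pairs; phase is ignored).

    Percentage rounded half-up to two decimals.  No shared loci is an error.
    """
    shared = set(calls_a) & set(calls_b)
    if not shared:
        raise MendiagError("no shared loci between the two call sets")
    n_conc = sum(
        1 for k in shared if _norm_genotype(calls_a[k]) == _norm_genotype(calls_b[k])
    )
    return ConcordanceResult(len(shared), n_conc, ratio_pct(n_conc, len(shared)))


def read_genotype_map(path: str) -> Dict[Tuple[str, int], str]:
    """Headered TSV with columns chrom, pos, genotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {(str(r["chrom"]), int(r["pos"])): str(r["genotype"]) for _, r in df.iterrows()}
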