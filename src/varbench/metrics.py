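"""Aggregate match annotations into the headline benchmark numbers.

Two true-positive counts are kept, because the same truth variant can be
predicted several times by one callset (e.g. as part of several complex
replacements): ``tp_query`` counts query-side TP annotations (duplicates
counted each time) and ``tp_truth`` counts matched truth variants once, with
``tp_query >= tp_truth`` always.  Metrics follow the established definitions

    precision = TP_query / (TP_query + FP)
    recall    = TP_truth / (TP_truth + FN)
    F*        = TP_query / (TP_query + FP + FN)

F* is a monotone transformation of the F-measure with a direct reading: the
probability that a random variant drawn from the union of prediction and
truth is predicted correctly (1.0 for a perfect callset).  The fraction of
wrongly predicted genotypes is counted over allele-matched (calling-mode)
query TPs.  Undefined metrics (zero denominator) are reported as "." —
never as 0 — so empty strata are visibly empty rather than spuriously
perfect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .match import MODES, MatchAnnotation

#: serialization of undefined metric values
UNDEFINED = "."

METRICS_COLUMNS = ["callset", "stratum", "mode", "tp_query", "tp_truth",
                   "fp", "fn", "gt_mismatch", "precision", "recall",
                   "f_star", "gt_mismatch_fraction"]


@dataclass(frozen=True)
class OutcomeCounts:
    """TP/FP/FN tallies for one callset x stratum x mode.

    ``tp_query >= tp_truth`` whenever query and truth share the same atomic
    decomposition (the normal case after normalization): a truth atom can
    only be matched by query atoms, each counted at least once.  The one
    exception is a superlocus where a *smaller* query atom set matches a
    larger, representationally different truth set through haplotype
    equivalence; the honest counts are reported rather than clamped.
    """

    tp_query: int = 0
    tp_truth: int = 0
    fp: int = 0
    fn: int = 0
    gt_mismatch: int = 0

    def __post_init__(self) -> None:
        for name in ("tp_query", "tp_truth", "fp", "fn", "gt_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gt_mismatch > self.tp_query:
            raise ValueError("gt_mismatch cannot exceed tp_query")

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(self.tp_query + other.tp_query,
                             self.tp_truth + other.tp_truth,
                             self.fp + other.fp, self.fn + other.fn,
                             self.gt_mismatch + other.gt_mismatch)


def count_outcomes(annotations: Iterable[MatchAnnotation]) -> OutcomeCounts:
    """Tally one set of annotations (pre-filtered to a stratum/mode)."""
    tp_query = tp_truth = fp = fn = gt_mismatch = 0
    for ann in annotations:
        if ann.side == "query":
            if ann.status == "TP":
                tp_query += 1
                if ann.genotype_concordant is False:
                    gt_mismatch += 1
            elif ann.status == "FP":
                fp += 1
        else:
            if ann.status == "TP":
                tp_truth += 1
            elif ann.status == "FN":
                fn += 1
    return OutcomeCounts(tp_query, tp_truth, fp, fn, gt_mismatch)


def precision(c: OutcomeCounts) -> Optional[float]:
    """TP_query / (TP_query + FP); None when the callset is empty here."""
    denom = c.tp_query + c.fp
    return c.tp_query / denom if denom else None


def recall(c: OutcomeCounts) -> Optional[float]:
    """TP_truth / (TP_truth + FN); None when the truth is empty here."""
    denom = c.tp_truth + c.fn
    return c.tp_truth / denom if denom else None


def f_star(c: OutcomeCounts) -> Optional[float]:
    """TP_query / (TP_query + FP + FN); None when all three are zero."""
    denom = c.tp_query + c.fp + c.fn
    return c.tp_query / denom if denom else None


def gt_mismatch_fraction(c: OutcomeCounts) -> Optional[float]:
    """Wrongly genotyped fraction of allele-matched query TPs."""
    return c.gt_mismatch / c.tp_query if c.tp_query else None


def metrics_table(match_results: Dict[str, Dict[str, List[MatchAnnotation]]],
                  stratum_names: Sequence[str]) -> pd.DataFrame:
    """One row per callset x stratum x mode.

    ``match_results`` maps callset id -> mode -> annotations (as produced by
    :func:`varbench.match.match_callset`).  The genotype-mismatch count and
    fraction are taken from calling-mode allele matches for both rows of a
    stratum, so the same quantity is never re-derived differently per mode.
    """
    rows = []
    for callset_id in sorted(match_results):
        per_mode = match_results[callset_id]
        for stratum in stratum_names:
            calling = count_outcomes(
                a for a in per_mode["calling"] if a.stratum == stratum)
            for mode in MODES:
                c = count_outcomes(
                    a for a in per_mode[mode] if a.stratum == stratum)
                rows.append({
                    "callset": callset_id,
                    "stratum": stratum,
                    "mode": mode,
                    "tp_query": c.tp_query,
                    "tp_truth": c.tp_truth,
                    "fp": c.fp,
                    "fn": c.fn,
                    "gt_mismatch": calling.gt_mismatch,
                    "precision": precision(c),
                    "recall": recall(c),
                    "f_star": f_star(c),
                    "gt_mismatch_fraction": gt_mismatch_fraction(calling),
                })
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_tsv(table: pd.DataFrame, path) -> None:
    """Serialize the metrics table; undefined values become ".". """
    out = table.copy()
    for col in ("precision", "recall", "f_star", "gt_mismatch_fraction"):
        out[col] = out[col].map(
            lambda v: UNDEFINED if v is None or pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
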