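"""Label association of shared false-positive / false-negative patterns.

Each evaluated callset carries categorical labels (caller, mapper, kit,
...).  For every variant that is an FP (or FN) in at least one callset, a
Pearson chi-square test asks whether the error's presence/absence pattern
across callsets is associated with a label: the contingency table has two
rows (error present / absent) and one column per label value, counts are
numbers of callsets, and the statistic is referred to a chi-square
distribution with (L - 1) degrees of freedom, without continuity correction.

Because nearby variants can be strongly positively or negatively correlated
(same or different haplotype), the p-values within each (label, error-kind)
family are corrected with the Benjamini-Yekutieli procedure, which controls
the false discovery rate under arbitrary dependence.  Small expected counts
are the norm at typical callset numbers; tables with expected counts < 5
are flagged rather than suppressed, and the exact p-value remains
well-defined.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .match import MatchAnnotation

DEFAULT_ALPHA = 0.05

ASSOC_COLUMNS = ["kind", "contig", "pos", "ref", "alt", "label",
                 "p_value", "q_value", "significant", "low_expected"]


def error_variants(annotations: Iterable[MatchAnnotation],
                   kind: str) -> set:
    """Allele keys of this callset's FPs (query side) or FNs (truth side)."""
    if kind == "FP":
        return {a.variant.allele_key for a in annotations
                if a.side == "query" and a.status == "FP"}
    if kind == "FN":
        return {a.variant.allele_key for a in annotations
                if a.side == "truth" and a.status == "FN"}
    raise ValueError(f"unknown error kind {kind!r}")


def build_pattern_matrix(errors_by_callset: Mapping[str, set],
                         kind: str = "FP") -> pd.DataFrame:
    """Boolean variant x callset matrix of one error kind.

    Rows are the distinct erroneous variants across all callsets (keyed by
    contig, pos, ref, alt); a variant absent from a callset's errors gives
    False.  Requires at least two callsets.
    """
    if len(errors_by_callset) < 2:
        raise ConfigError("pattern matrix needs at least 2 callsets")
    callsets = sorted(errors_by_callset)
    variants = sorted(set().union(*errors_by_callset.values()))
    data = {cs: [v in errors_by_callset[cs] for v in variants]
            for cs in callsets}
    index = pd.MultiIndex.from_tuples(variants,
                                      names=["contig", "pos", "ref", "alt"]) \
        if variants else pd.MultiIndex.from_arrays(
            [[], [], [], []], names=["contig", "pos", "ref", "alt"])
    matrix = pd.DataFrame(data, index=index, columns=callsets, dtype=bool)
    matrix.attrs["kind"] = kind
    return matrix


def chi2_label_test(row: Sequence[bool],
                    labels: Sequence[str]) -> Tuple[Optional[float], bool]:
    """Pearson chi-square of one error pattern against one label.

    Returns ``(p_value, low_expected)``; the p-value is None (test skipped)
    when the label has a single value.  A constant pattern (error in all or
    no callsets) carries no information: statistic 0, p = 1.
    """
    values = sorted(set(labels))
    if len(values) < 2:
        return None, False
    row = list(row)
    if all(row) or not any(row):
        return 1.0, False
    table = np.zeros((2, len(values)), dtype=int)
    for present, value in zip(row, labels):
        table[0 if present else 1, values.index(value)] += 1
    stat, p, _, expected = chi2_contingency(table, correction=False)
    return float(p), bool((expected < 5).any())


def by_fdr(p_values: Sequence[float],
           alpha: float = DEFAULT_ALPHA) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up adjustment.

    q_i = min over j >= i (sorted order) of m * c(m) * p_(j) / j with
    c(m) = sum_{k<=m} 1/k, capped at 1; significant where q <= alpha.
    Valid under arbitrary dependence among the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return q, q <= alpha


def associate(matrices: Mapping[str, pd.DataFrame],
              labels: Mapping[str, Mapping[str, str]],
              alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Chi-square tests of every variant x label, FDR-corrected per family.

    ``matrices`` maps error kind ("FP"/"FN") to a pattern matrix;
    ``labels`` maps callset id to its label dict.  The FDR family is one
    (label name, error kind) pair — the most conservative scoping that still
    yields one result view per label.  Rows are deterministically ordered.
    """
    label_names = sorted({name for lab in labels.values() for name in lab})
    rows: List[dict] = []
    for kind in sorted(matrices):
        matrix = matrices[kind]
        callsets = list(matrix.columns)
        for label_name in label_names:
            values = [labels[cs].get(label_name, "") for cs in callsets]
            family: List[dict] = []
            for variant, pattern in matrix.iterrows():
                p, low_exp = chi2_label_test(list(pattern), values)
                if p is None:
                    continue
                contig, pos, ref, alt = variant
                family.append({"kind": kind, "contig": contig, "pos": pos,
                               "ref": ref, "alt": alt, "label": label_name,
                               "p_value": p, "low_expected": low_exp})
            if family:
                q, sig = by_fdr([r["p_value"] for r in family], alpha)
                for r, qi, si in zip(family, q, sig):
                    r["q_value"] = float(qi)
                    r["significant"] = bool(si)
                rows.extend(family)
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    if not df.empty:
        df = df.sort_values(["kind", "label", "contig", "pos", "ref", "alt"],
                            kind="mergesort").reset_index(drop=True)
    return df


def write_pattern_tsv(matrix: pd.DataFrame,
                      labels: Mapping[str, Mapping[str, str]], path) -> None:
    """Pattern matrix as TSV with label header rows above the callset columns."""
    callsets = list(matrix.columns)
    label_names = sorted({name for lab in labels.values() for name in lab})
    with open(path, "w") as fh:
        for name in label_names:
            values = "\t".join(labels[cs].get(name, ".") for cs in callsets)
            fh.write(f"#label:{name}\t\t\t\t{values}\n")
        fh.write("contig\tpos\tref\talt\t" + "\t".join(callsets) + "\n")
        for variant, pattern in matrix.iterrows():
            contig, pos, ref, alt = variant
            cells = "\t".join("1" if v else "0" for v in pattern)
            fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\t{cells}\n")
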