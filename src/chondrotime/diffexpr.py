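"""Fold changes vs baseline, thresholded gene lists and reference contrasts.

Fold changes are computed on the log2 scale from replicate means and
exponentiated, so they are invariant to per-probe additive offsets.  The
conventional >= 3.29-fold threshold splits probes into up- and
down-regulated lists per time point.  A two-matrix contrast (e.g.
undifferentiated cells vs reference tissue) runs a per-gene pooled-variance
two-sample t-test with Bonferroni control across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TimeCourseDesign
from .preprocess import timepoint_means

__all__ = [
    "FoldChangeTable",
    "fold_change",
    "threshold_fold_change",
    "compare_to_reference",
    "export_network_list",
]


@dataclass(frozen=True)
class FoldChangeTable:
    """Linear-scale fold changes vs a baseline time point.

    ``fold_change`` and ``log2_ratio`` are probes x time points; the
    baseline column is exactly 1 (respectively 0).
    """

    fold_change: pd.DataFrame
    log2_ratio: pd.DataFrame
    baseline: int


def fold_change(
    em: pd.DataFrame,
    design: TimeCourseDesign,
    baseline: int | None = None,
    scale: str = "log2",
) -> FoldChangeTable:
    """Per-probe fold change of each time point vs the baseline.

    ``FC(g, t) = 2^(mean_t(g) - mean_baseline(g))`` on log2 input; with
    ``scale='linear'`` the matrix is log2-transformed first (values must be
    positive).
    """
    if scale not in ("log2", "linear"):
        raise ValueError("scale must be 'log2' or 'linear'")
    if scale == "linear":
        if (em.to_numpy(dtype=float) <= 0).any():
            raise ValueError("linear-scale intensities must be positive")
        em = np.log2(em)
    mpm = timepoint_means(em, design)
    if baseline is None:
        baseline = int(design.timepoints[0])
    if baseline not in mpm.columns:
        raise ValueError(
            f"baseline time point {baseline} absent from design "
            f"(have {list(mpm.columns)})"
        )
    log2fc = mpm.sub(mpm[baseline], axis=0)
    return FoldChangeTable(
        fold_change=2.0 ** log2fc, log2_ratio=log2fc, baseline=baseline
    )


def threshold_fold_change(
    fct: FoldChangeTable,
    cutoff: float = 3.29,
    timepoint: int | None = None,
) -> tuple[list[str], list[str]]:
    """Probes >= cutoff-fold up (FC >= cutoff) or down (FC <= 1/cutoff).

    Both comparisons are inclusive; the lists are disjoint for any
    cutoff > 1.  Defaults to the last time point of the course.
    """
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    if timepoint is None:
        timepoint = int(fct.fold_change.columns[-1])
    if timepoint not in fct.fold_change.columns:
        raise ValueError(f"time point {timepoint} absent from fold-change table")
    # compare on the log2 scale: numerically stable at the exact boundary
    log_cut = np.log2(cutoff)
    ratio = fct.log2_ratio[timepoint]
    up = fct.log2_ratio.index[ratio >= log_cut].tolist()
    down = fct.log2_ratio.index[ratio <= -log_cut].tolist()
    return up, down


def compare_to_reference(
    em_a: pd.DataFrame, em_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene two-sample t-test between two log2 matrices.

    Rows must cover the same genes; each matrix needs >= 2 replicate
    columns.  Uses the pooled-variance t statistic and Bonferroni
    adjustment across all genes; the result is sorted by adjusted p, then
    by absolute mean difference (descending).
    """
    if em_a.shape[1] < 2 or em_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicate columns")
    missing = em_a.index.symmetric_difference(em_b.index)
    if len(missing):
        raise ValueError(
            f"matrices do not share probe IDs; first offenders: "
            f"{missing.tolist()[:10]}"
        )
    em_b = em_b.loc[em_a.index]
    a = em_a.to_numpy(dtype=float)
    b = em_b.to_numpy(dtype=float)
    tstat, pvals = stats.ttest_ind(a, b, axis=1, equal_var=True)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    m = em_a.shape[0]
    adjusted = np.minimum(1.0, pvals * m)
    result = pd.DataFrame(
        {
            "mean_difference": a.mean(axis=1) - b.mean(axis=1),
            "t_statistic": tstat,
            "p_value": pvals,
            "p_adjusted": adjusted,
            "significant": adjusted < alpha,
        },
        index=em_a.index,
    )
    result["_abs"] = result["mean_difference"].abs()
    result = result.sort_values(
        ["p_adjusted", "_abs"], ascending=[True, False], kind="mergesort"
    ).drop(columns="_abs")
    return result


def export_network_list(genes, path) -> list[str]:
    """Write a deduplicated one-symbol-per-line file for network services.

    Symbols are whitespace-trimmed; order of first appearance is kept.  An
    empty list produces an empty file with a warning.  Returns the written
    symbols.
    """
    cleaned: list[str] = []
    seen: set[str] = set()
    for g in genes:
        g = str(g).strip()
        if g and g not in seen:
            seen.add(g)
            cleaned.append(g)
    if not cleaned:
        warnings.warn("empty gene list; writing an empty file", stacklevel=2)
    with open(path, "w") as handle:
        for g in cleaned:
            handle.write(g + "\n")
    return cleaned
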