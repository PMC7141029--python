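"""Differential promoter coverage between case and control groups.

Per promoter window: two-sided Wilcoxon rank-sum p-value, Benjamini–
Hochberg FDR, and log2 fold change of group-mean RPKM.  A promoter is
selected when FDR <= fdr_max and |log2FC| >= lfc_min (defaults 0.1 and 1).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageMatrix

logger = logging.getLogger("promoterfoot")

__all__ = [
    "wilcoxon_rank_sum_p",
    "bh_adjust",
    "log2_fold_change",
    "select_differential",
    "zscore_matrix",
    "DEFAULT_PSEUDOCOUNT",
]

#: pseudocount (RPKM) added to both group means before the log2 ratio
DEFAULT_PSEUDOCOUNT = 0.01

#: largest total sample count for which the exact rank-sum null is enumerated
_EXACT_MAX_N = 20


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum_p(
    case_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration of the rank-sum null when n_case + n_control <= 20
    and the pooled values are tie-free; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    exact = case.size + control.size <= _EXACT_MAX_N and not _has_ties(
        np.concatenate([case, control])
    )
    res = stats.mannwhitneyu(
        case,
        control,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def _wilcoxon_matrix_p(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Columnwise two-sided rank-sum p-values (same method rules as above)."""
    n_total = case.shape[0] + control.shape[0]
    p = stats.mannwhitneyu(
        case, control, alternative="two-sided", method="asymptotic",
        use_continuity=True, axis=0,
    ).pvalue
    if n_total <= _EXACT_MAX_N:
        pooled = np.vstack([case, control])
        tie_free = np.array(
            [not _has_ties(pooled[:, j]) for j in range(pooled.shape[1])]
        )
        if tie_free.any():
            p_exact = stats.mannwhitneyu(
                case[:, tie_free], control[:, tie_free],
                alternative="two-sided", method="exact", axis=0,
            ).pvalue
            p = np.asarray(p, dtype=float)
            p[tie_free] = p_exact
    return np.minimum(np.asarray(p, dtype=float), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR: q_(i) = min_{j>=i} p_(j)·m/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(
    mean_case: float, mean_control: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((mean_case + pseudocount) / (mean_control + pseudocount))."""
    if mean_case < 0 or mean_control < 0:
        raise ValueError("group means must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    num = mean_case + pseudocount
    den = mean_control + pseudocount
    if num == 0 or den == 0:
        raise ValueError("zero mean with zero pseudocount; supply a pseudocount")
    return float(np.log2(num / den))


def select_differential(
    matrix: CoverageMatrix,
    labels: Sequence[str] | None = None,
    fdr_max: float = 0.1,
    lfc_min: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-window differential table, sorted by p then |log2FC| descending.

    ``labels`` defaults to the matrix metadata's ``label`` column and must
    contain the values "case" and "control".  Columns of the result:
    window, gene, mean_case, mean_control, log2fc, pvalue, fdr, selected.
    """
    if labels is None:
        labels = matrix.meta["label"]
    labels = np.asarray(labels)
    case_mask = labels == "case"
    control_mask = labels == "control"
    if case_mask.sum() < 2 or control_mask.sum() < 2:
        raise ValueError("need >= 2 samples per group (case and control)")
    values = matrix.values.to_numpy(dtype=float)
    case = values[case_mask]
    control = values[control_mask]
    mean_case = case.mean(axis=0)
    mean_control = control.mean(axis=0)
    lfc = np.log2((mean_case + pseudocount) / (mean_control + pseudocount))
    pvals = _wilcoxon_matrix_p(case, control)
    fdr = bh_adjust(pvals)
    selected = (fdr <= fdr_max) & (np.abs(lfc) >= lfc_min)
    table = pd.DataFrame(
        {
            "window": matrix.window_ids,
            "gene": [matrix.window_genes.get(w, w) for w in matrix.window_ids],
            "mean_case": mean_case,
            "mean_control": mean_control,
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "selected": selected,
        }
    )
    table = (
        table.assign(abs_lfc=np.abs(lfc))
        .sort_values(["pvalue", "abs_lfc"], ascending=[True, False], kind="mergesort")
        .drop(columns="abs_lfc")
    )
    return table.reset_index(drop=True)


def zscore_matrix(matrix: CoverageMatrix, windows: Sequence[str] | None = None) -> pd.DataFrame:
    """Columnwise z-scores (mean 0, sd 1 with ddof=1) of the RPKM matrix.

    Zero-variance columns are emitted as all zeros with a logged warning
    (they carry no contrast for a heatmap).
    """
    values = matrix.values if windows is None else matrix.values[list(windows)]
    if len(values) < 2:
        raise ValueError("need >= 2 samples to standardize")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "zscore_matrix: %d zero-variance window(s) emitted as zeros",
            int(zero_var.sum()),
        )
    sd_safe = np.where(zero_var, 1.0, sd)
    z = (arr - mean) / sd_safe
    z[:, zero_var] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)
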