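"""Pairwise group contrasts: means, log2 fold changes, significance.

Fold changes are ratios of arithmetic group means of raw FPKM, reported
as log2(mean_B / mean_A) for a contrast (A, B) — e.g. contrast
("C", "A20") reports A20/C.  Significance comes from Welch's
unequal-variance two-sample t-test on log2(FPKM + pseudocount) with
Benjamini-Hochberg adjustment across genes; the test engine is pluggable
(``test_fn``) since FPKM-level pipelines differ in this choice.
Contrasts are corrected separately, never jointly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DesignError, ExpressionMatrix, PlsrankError

logger = logging.getLogger(__name__)


@dataclass
class DEGTable:
    """Per-gene records for one contrast.

    ``table`` columns: group means, ``log2fc`` (B vs A), ``p_value``,
    ``q_value`` (BH), ``significant`` (q <= alpha), ``direction``
    (up/down/flat in B relative to A), ``fc_pseudocount_used``.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    alpha: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean of raw FPKM per gene and group."""
    out = {}
    for g in matrix.groups:
        cols = matrix.samples_in(g)
        if not cols:
            raise DesignError(f"group {g!r} has no samples")
        out[g] = matrix.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def log2_fold_change(mean_num: float, mean_den: float, pseudocount: float | None = None) -> float:
    """log2 of a ratio of group means; antisymmetric under argument swap.

    Non-positive means are only accepted with a ``pseudocount``, which is
    then added to both means.
    """
    if mean_num <= 0 or mean_den <= 0:
        if pseudocount is None:
            raise PlsrankError(
                "non-positive group mean; supply a pseudocount to compute a fold change"
            )
        mean_num, mean_den = mean_num + pseudocount, mean_den + pseudocount
        if mean_num <= 0 or mean_den <= 0:
            raise PlsrankError("group means non-positive even after pseudocount")
    return math.log2(mean_num / mean_den)


def welch_test(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values for two sample blocks (genes x samples)."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values across one family of tests."""
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    test_fn=welch_test,
) -> DEGTable:
    """Test every gene for the contrast (A, B); fold change is B vs A.

    Genes with zero within-group variance in both groups get p = 1 (no
    evidence either way at the test's resolution) with a logged note.
    """
    ga, gb = contrast
    cols_a, cols_b = matrix.samples_in(ga), matrix.samples_in(gb)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError(f"contrast {contrast} needs >= 2 samples per group")
    if not 0 < alpha < 1:
        raise PlsrankError("alpha must be in (0, 1)")

    raw_a = matrix.values[cols_a].to_numpy(float)
    raw_b = matrix.values[cols_b].to_numpy(float)
    log_a = np.log2(raw_a + pseudocount)
    log_b = np.log2(raw_b + pseudocount)

    degenerate = (log_a.std(axis=1) == 0) & (log_b.std(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant genes
        p = test_fn(log_a, log_b)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    if degenerate.any():
        logger.info(
            "%d gene(s) with zero variance in both groups; p set to 1", degenerate.sum()
        )
    q = benjamini_hochberg(p)

    mean_a, mean_b = raw_a.mean(axis=1), raw_b.mean(axis=1)
    needs_pc = (mean_a <= 0) | (mean_b <= 0)
    lfc = np.empty(len(mean_a))
    lfc[~needs_pc] = np.log2(mean_b[~needs_pc] / mean_a[~needs_pc])
    lfc[needs_pc] = np.log2(
        (mean_b[needs_pc] + pseudocount) / (mean_a[needs_pc] + pseudocount)
    )

    table = pd.DataFrame(
        {
            f"mean_{ga}": mean_a,
            f"mean_{gb}": mean_b,
            "log2fc": lfc,
            "p_value": p,
            "q_value": q,
            "significant": q <= alpha,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat")),
            "fc_pseudocount_used": needs_pc,
        },
        index=matrix.values.index,
    )
    return DEGTable(table=table, contrast=(ga, gb), alpha=alpha)
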