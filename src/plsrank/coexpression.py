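"""Coexpression screening against an analytic critical correlation.

Under the null of no association, the Pearson correlation of two
bivariate-normal variables over n samples relates to Student's t with
df = n - 2 via r = t / sqrt(t^2 + df).  Inverting the two-tailed t
quantile at level alpha gives the smallest |r| significant at that
level; with n = 12 samples (two groups of six) and alpha = 0.001 the
critical value is r = 0.823.  Partners of a key gene are all genes in a
supplied list whose log2 expression across the relevant samples passes
that threshold; their behavior terms are then propagated as hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PlsrankError

#: Threshold comparison is inclusive: a correlation printed at exactly the
#: critical value counts as passing.


def critical_r(df: int, alpha: float) -> float:
    """Two-tailed critical Pearson r for the given degrees of freedom.

    Strictly decreasing in df, strictly increasing as alpha decreases,
    always in (0, 1).
    """
    if df < 1:
        raise PlsrankError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise PlsrankError("alpha must be in (0, 1)")
    t = stats.t.isf(alpha / 2.0, df)  # isf keeps far-tail precision
    return float(t / np.hypot(t, np.sqrt(df)))


@dataclass
class CoexpressionResult:
    """Partner correlations of one key gene, ranked by |r|."""

    key_gene: str
    table: pd.DataFrame  # columns: r, abs_r, passes, rank
    threshold: float
    n_samples: int

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["passes"]])


def coexpressed_partners(
    key_gene: str,
    deg_genes: list[str],
    matrix: ExpressionMatrix,
    groups: tuple[str, str] = ("C", "AD"),
    alpha: float = 0.001,
    threshold: float | None = None,
    top_k: int | None = None,
    pseudocount: float = 1.0,
) -> CoexpressionResult:
    """Correlate a key gene with a gene list across two groups' samples.

    Expression is taken as log2(FPKM + pseudocount) over the samples of
    the two groups (n = 12 for a 6 + 6 design, hence df = 10).  The
    threshold defaults to ``critical_r(n - 2, alpha)``.  Partners are
    ranked by |r| (ties alphabetical); ``top_k`` truncates the returned
    table but never the flag computation.  The key gene is excluded from
    its own partner list.
    """
    if key_gene not in matrix.values.index:
        raise PlsrankError(f"key gene {key_gene!r} absent from the matrix")
    partners = [g for g in dict.fromkeys(deg_genes) if g != key_gene]
    missing = [g for g in partners if g not in matrix.values.index]
    if missing:
        raise PlsrankError(f"partner gene(s) absent: {', '.join(missing[:5])}")
    samples = matrix.samples_in(*groups)
    n = len(samples)
    if n < 3:
        raise PlsrankError("need at least 3 samples for a correlation")
    thr = critical_r(n - 2, alpha) if threshold is None else threshold

    logx = np.log2(matrix.values.loc[partners, samples].to_numpy(float) + pseudocount)
    key = np.log2(matrix.values.loc[key_gene, samples].to_numpy(float) + pseudocount)
    kc = key - key.mean()
    xc = logx - logx.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ kc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(kc))
    r = np.clip(np.where(np.isfinite(r), r, np.nan), -1.0, 1.0)

    table = pd.DataFrame(
        {"r": r, "abs_r": np.abs(r), "passes": np.abs(r) >= thr},
        index=pd.Index(partners, name="gene_id"),
    )
    order = np.lexsort(
        (np.asarray(table.index, dtype=object), -np.nan_to_num(table["abs_r"], nan=-1.0))
    )
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    if top_k is not None:
        table = table.iloc[:top_k]
    return CoexpressionResult(key_gene=key_gene, table=table, threshold=thr, n_samples=n)


def propagate_terms(
    results: list[CoexpressionResult],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Behavior-term hypotheses for flagged partners.

    Every partner passing the threshold of at least one key gene gets a
    row per term: terms the partner already carries in the annotation
    are marked ``known``; terms inherited from the key gene(s) it passes
    with (and not already known) are marked ``hypothesis``.  A partner
    correlated with a single key gene inherits only that gene's terms.
    """
    from .io import annotate

    keys = [res.key_gene for res in results]
    key_ann = annotate(keys, annotation)
    flagged: dict[str, set[str]] = {}
    for res in results:
        for g in res.flagged:
            flagged.setdefault(g, set()).add(res.key_gene)

    rows = []
    for partner in sorted(flagged):
        own = set()
        if partner in annotation.index:
            own = set(annotation.loc[partner, "behavior_terms"])
        inherited: set[str] = set()
        for k in flagged[partner]:
            inherited |= set(key_ann.loc[k, "behavior_terms"])
        for term in sorted(own | inherited):
            rows.append(
                {
                    "gene_id": partner,
                    "term": term,
                    "status": "known" if term in own else "hypothesis",
                    "source_key_genes": ",".join(
                        sorted(
                            k
                            for k in flagged[partner]
                            if term in set(key_ann.loc[k, "behavior_terms"])
                        )
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "term", "status", "source_key_genes"])
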