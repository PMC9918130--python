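"""Two-block PLS-DA and per-gene Axis-1 correlation ranking.

The discriminant analysis relates two blocks measured on the same
samples: the processed (log2, z-scored) expression block X and a
column-centered dummy block Y coding membership in the two contrasted
groups.  Axis 1 is the direction in gene space whose sample scores have
maximal covariance with the dummy block — the first singular triple of
the centered cross-covariance X_c' Y_c (one NIPALS component); further
axes come from the deflated X block, so successive score vectors are
orthogonal.

Genes are then ranked by the Pearson correlation of their processed
expression with the Axis-1 sample scores.  The orientation convention
(control-group mean score positive) makes genes DOWN in the
experimental group correlate positively — so a strong up-regulated gene
carries a large negative r, and candidate selection operates on |r|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DesignError, PlsrankError
from .preprocess import ProcessedMatrix

logger = logging.getLogger(__name__)

#: |r| bin edges, width 0.1; bins are lower-closed, the top bin closed
#: on both ends so |r| = 1 (and a printed 0.90) lands in "1.00-0.90".
BIN_LABELS = (
    "1.00-0.90", "0.89-0.80", "0.79-0.70", "0.69-0.60", "0.59-0.50",
    "0.49-0.40", "0.39-0.30", "0.29-0.20", "0.19-0.10", "0.09-0.00",
)


@dataclass
class DummyBlock:
    """Column-centered group-membership indicators for two groups."""

    values: pd.DataFrame  # samples x 2, centered
    groups: tuple[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PLSDAModel:
    """Fitted two-block PLS-DA.

    ``weights``: genes x axes, each column unit-norm.  ``scores``:
    samples x axes.  ``covariance_explained``: per-axis share of the
    squared cross-covariance.  ``axis_stable`` flags axes whose singular
    value is numerically above zero — with no group effect there is no
    stable discriminant direction.
    """

    weights: pd.DataFrame
    scores: pd.DataFrame
    groups: tuple[str, str]
    singular_values: np.ndarray
    covariance_explained: np.ndarray
    axis_stable: list[bool]


@dataclass
class CorrelationRanking:
    """Per-gene Pearson r with the Axis-1 scores, |r| bins, candidacy."""

    table: pd.DataFrame  # columns: r, abs_r, bin, candidate
    r_threshold: float


def make_dummy(design: pd.Series, groups: tuple[str, str]) -> DummyBlock:
    """Indicator block for exactly two groups, column-centered.

    Before centering each sample row sums to 1; after centering each
    column sums to 0.  Samples are restricted to the two groups, in
    design order.
    """
    if len(groups) != 2 or groups[0] == groups[1]:
        raise DesignError("exactly two distinct groups are required")
    present = set(design)
    for g in groups:
        if g not in present:
            raise DesignError(f"group {g!r} not present in design")
    samples = [s for s in design.index if design[s] in groups]
    raw = np.column_stack(
        [(design.loc[samples] == g).to_numpy(float) for g in groups]
    )
    centered = raw - raw.mean(axis=0)
    return DummyBlock(
        values=pd.DataFrame(centered, index=pd.Index(samples, name="sample_id"),
                            columns=list(groups)),
        groups=tuple(groups),
    )


def fit_plsda(
    X: ProcessedMatrix | pd.DataFrame,
    Y: DummyBlock,
    n_axes: int = 2,
) -> PLSDAModel:
    """Fit the two-block PLS-DA on the samples of the dummy block.

    X is genes x samples (processed scale) and must contain every sample
    of Y; it is restricted to Y's samples and column-centered (per gene,
    across those samples) before the cross-covariance is formed.
    """
    values = X.values if isinstance(X, ProcessedMatrix) else X
    missing = [s for s in Y.sample_ids if s not in values.columns]
    if missing:
        raise DesignError(f"samples missing from X: {', '.join(missing)}")
    samples = Y.sample_ids
    genes = list(values.index)
    Xs = values[samples].to_numpy(float).T  # samples x genes
    Yc = Y.values.to_numpy(float)
    n_axes = int(n_axes)
    if n_axes < 1:
        raise PlsrankError("n_axes must be >= 1")

    scale = max(np.linalg.norm(Xs) * np.linalg.norm(Yc), 1.0)
    Xd = Xs - Xs.mean(axis=0)
    weights, scores, svals, stable = [], [], [], []
    for _ in range(n_axes):
        c = Xd.T @ Yc  # genes x 2 cross-covariance
        u, s, _vt = np.linalg.svd(c, full_matrices=False)
        w = u[:, 0]
        sigma = s[0]
        t = Xd @ w
        stable.append(bool(sigma > 1e-10 * scale))
        weights.append(w)
        scores.append(t)
        svals.append(sigma)
        denom = t @ t
        if denom > 0:
            Xd = Xd - np.outer(t, (t @ Xd) / denom)  # deflate X

    weights = np.column_stack(weights)
    scores = np.column_stack(scores)
    svals = np.asarray(svals)

    # orientation: control group (first of the pair) has positive mean score
    if Y.groups[0] in Y.values.columns:
        control_mask = (Y.values[Y.groups[0]] > 0).to_numpy()
    elif Y.groups[1] in Y.values.columns:
        control_mask = (Y.values[Y.groups[1]] < 0).to_numpy()
    else:
        raise DesignError("dummy block carries no recognizable group column")
    for k in range(n_axes):
        mean_control = scores[control_mask, k].mean()
        if mean_control < 0:
            scores[:, k] *= -1.0
            weights[:, k] *= -1.0

    total = (svals**2).sum()
    explained = svals**2 / total if total > 0 else np.zeros(n_axes)
    explained[~np.asarray(stable)] = 0.0  # no stable axis, nothing explained
    axes = [f"Axis{i + 1}" for i in range(n_axes)]
    return PLSDAModel(
        weights=pd.DataFrame(weights, index=pd.Index(genes, name="gene_id"), columns=axes),
        scores=pd.DataFrame(scores, index=pd.Index(samples, name="sample_id"), columns=axes),
        groups=Y.groups,
        singular_values=svals,
        covariance_explained=explained,
        axis_stable=stable,
    )


def axis1_correlations(
    X: ProcessedMatrix | pd.DataFrame,
    model: PLSDAModel,
    r_threshold: float = 0.90,
) -> CorrelationRanking:
    """Pearson r of every gene with the Axis-1 sample scores.

    Correlations are computed across the model's samples.  A gene with
    zero variance across those samples (possible for a subset of an
    already-standardized matrix) gets r = NaN with a logged note.
    """
    values = X.values if isinstance(X, ProcessedMatrix) else X
    samples = list(model.scores.index)
    t = model.scores["Axis1"].to_numpy(float)
    xs = values[samples].to_numpy(float)
    xc = xs - xs.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    xnorm = np.linalg.norm(xc, axis=1)
    tnorm = np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc) / (xnorm * tnorm)
    bad = ~np.isfinite(r)
    if bad.any():
        logger.info("%d gene(s) with undefined Axis-1 correlation", bad.sum())
        r = np.where(bad, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    abs_r = np.abs(r)
    table = pd.DataFrame(
        {
            "r": r,
            "abs_r": abs_r,
            "bin": [_bin_label(a) for a in abs_r],
            "candidate": abs_r >= r_threshold,
        },
        index=values.index,
    )
    return CorrelationRanking(table=table, r_threshold=r_threshold)


def _bin_label(abs_r: float) -> str:
    if np.isnan(abs_r):
        return "undefined"
    if abs_r >= 0.9:
        return BIN_LABELS[0]
    return BIN_LABELS[9 - int(abs_r * 10)]


def bin_abs_correlations(
    ranking: CorrelationRanking,
    annotation: pd.DataFrame | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Counts of genes per |r| bin, optionally cross-tabulated.

    ``genes`` restricts the tabulation (e.g. to DEGs intersected with a
    neurogenesis list).  With an annotation table, adds a transcription-
    factor column and one column per behavior term.
    """
    table = ranking.table
    if genes is not None:
        table = table.loc[[g for g in genes if g in table.index]]
    out = pd.DataFrame(index=pd.Index(BIN_LABELS, name="bin"))
    counts = table["bin"].value_counts()
    out["n_genes"] = [int(counts.get(b, 0)) for b in BIN_LABELS]
    if annotation is not None:
        ann = annotation.reindex(table.index)
        out["n_tf"] = [
            int(ann["is_tf"].fillna(False)[table["bin"] == b].sum()) for b in BIN_LABELS
        ]
        from .io import BEHAVIOR_TERMS

        for term in BEHAVIOR_TERMS:
            has = ann["behavior_terms"].apply(
                lambda s: isinstance(s, frozenset) and term in s
            )
            out[term] = [int(has[table["bin"] == b].sum()) for b in BIN_LABELS]
    return out


def select_candidates(
    ranking: CorrelationRanking,
    annotation: pd.DataFrame | None = None,
    r_threshold: float | None = None,
    require_neurogenesis: bool = False,
    require_tf: bool = False,
    require_terms: bool = False,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Candidate table: genes with |r| >= threshold, annotated, sorted.

    Sorting is by |r| descending with alphabetical tie-break.  The
    threshold comparison is inclusive: at print precision a gene at
    exactly the threshold counts as a candidate.  ``require_terms``
    keeps only genes carrying at least one behavior term.
    """
    thr = ranking.r_threshold if r_threshold is None else r_threshold
    table = ranking.table
    if genes is not None:
        table = table.loc[[g for g in genes if g in table.index]]
    sel = table[table["abs_r"] >= thr].copy()
    if annotation is not None:
        from .io import annotate

        ann = annotate(sel.index, annotation)
        sel = sel.join(ann)
        if require_neurogenesis:
            sel = sel[sel["is_neurogenesis"]]
        if require_tf:
            sel = sel[sel["is_tf"]]
        if require_terms:
            sel = sel[sel["behavior_terms"].apply(len) > 0]
    # |r| descending, alphabetical tie-break
    sel = sel.iloc[
        np.lexsort((np.asarray(sel.index, dtype=object), -sel["abs_r"].to_numpy()))
    ]
    return sel
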