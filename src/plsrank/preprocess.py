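"""Expression preprocessing and sample ordination.

The analysis scale is log2(FPKM + pseudocount), per-gene centered and
scaled to unit variance ("z-scored rows").  Sample ordination is
classical principal coordinate analysis (PCoA, metric MDS) of the
Euclidean distances between samples on that scale; on a Euclidean
distance matrix PCoA coincides with PCA of the samples up to axis sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix, PlsrankError

logger = logging.getLogger(__name__)


@dataclass
class ProcessedMatrix:
    """Genes x samples values on the log2, centered, unit-variance scale.

    Zero-variance genes are dropped before standardization and listed in
    ``dropped_genes``.  Row SD uses the sample convention (n - 1).
    """

    values: pd.DataFrame
    pseudocount: float
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class OrdinationResult:
    """PCoA sample coordinates with eigenvalues per axis.

    ``coordinates`` holds the requested leading axes; ``eigenvalues`` and
    ``proportion_explained`` cover every axis with positive eigenvalue,
    in non-increasing order.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def standardize_rows(values: pd.DataFrame, tol: float = 1e-12):
    """Center each row and scale to unit sample variance.

    Returns the standardized frame and the list of dropped zero-variance
    row labels.
    """
    sd = values.std(axis=1, ddof=1)
    dropped = list(values.index[(sd <= tol) | sd.isna()])
    kept = values.drop(index=dropped)
    if dropped:
        logger.info(
            "dropped %d zero-variance gene(s): %s",
            len(dropped),
            ", ".join(map(str, dropped[:10])) + ("..." if len(dropped) > 10 else ""),
        )
    out = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[kept.index], axis=0)
    return out, dropped


def preprocess(
    matrix: ExpressionMatrix | pd.DataFrame,
    pseudocount: float = 1.0,
    log_transform: bool = True,
) -> ProcessedMatrix:
    """log2-transform (with pseudocount), then z-score every gene row.

    ``log_transform=False`` skips the log step (for data already on a
    log-like scale); z-scoring itself is idempotent.
    """
    if pseudocount <= 0:
        raise PlsrankError("pseudocount must be positive")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if log_transform:
        values = np.log2(values + pseudocount)
    out, dropped = standardize_rows(values)
    if out.empty:
        raise PlsrankError("all genes have zero variance; nothing to analyze")
    return ProcessedMatrix(out, pseudocount, dropped)


def pcoa(processed: ProcessedMatrix | pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Classical PCoA of Euclidean sample distances.

    Gower double-centering of the squared distance matrix followed by an
    eigendecomposition; coordinates are eigenvectors scaled by the square
    root of their (positive) eigenvalues, so pairwise Euclidean distances
    between full coordinate rows reproduce the input distances.  Each
    axis is oriented so the first sample's coordinate is non-negative.
    """
    values = processed.values if isinstance(processed, ProcessedMatrix) else processed
    samples = list(values.columns)
    n = len(samples)
    if n < 2:
        raise PlsrankError("PCoA needs at least 2 samples")
    d2 = squareform(pdist(values.to_numpy().T, metric="euclidean")) ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # numerically-negative eigenvalues of a Euclidean configuration
    pos = eigval > max(1e-10 * abs(eigval[0]), 1e-12)
    eigval_pos = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(eigval_pos)
    # deterministic axis orientation
    flip = np.where(coords[0] < 0, -1.0, 1.0)
    coords = coords * flip
    k = min(n_axes, coords.shape[1])
    coordinates = pd.DataFrame(
        coords[:, :k],
        index=pd.Index(samples, name="sample_id"),
        columns=[f"Axis{i + 1}" for i in range(k)],
    )
    return OrdinationResult(
        coordinates=coordinates,
        eigenvalues=eigval_pos,
        proportion_explained=eigval_pos / eigval_pos.sum(),
        )


def full_coordinates(processed: ProcessedMatrix | pd.DataFrame) -> pd.DataFrame:
    """All positive-eigenvalue PCoA axes (for distance-preservation checks)."""
    values = processed.values if isinstance(processed, ProcessedMatrix) else processed
    return pcoa(processed, n_axes=values.shape[1]).coordinates
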