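"""Synthetic three-group FPKM experiments with planted ground truth.

Generates the statistical structure the downstream analysis assumes: a
log-normal FPKM baseline (normal on the log2 scale), three groups of
samples (control C, 20-day winners A20, winners after fighting
deprivation AD), planted per-gene effects following named trajectory
classes across the C -> A20 -> AD timeline, a latent-factor coexpression
block, and gene annotations (neurogenesis membership, transcription-
factor status, behavior terms).  The generator emits the ground truth
needed to test every downstream stage.

The expression model is log-normal rather than count-based on purpose:
the whole analysis operates on FPKM and its log2 transform, so count-
level simulation would add machinery without exercising anything the
pipeline computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BEHAVIOR_TERMS, ConfigurationError, ExpressionMatrix

#: Trajectory classes over the C -> A20 -> AD timeline, in decision-table order.
TRAJECTORY_CLASSES = (
    "persistent",
    "partial_normalization",
    "deprivation_emergent",
    "gradual_emergent",
    "restored",
)

#: Marker used for genes with no planted effect.
NULL_CLASS = "none"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic three-group experiment.

    Baseline log2-FPKM means are drawn per gene from
    ``Normal(baseline_log2_mean, baseline_log2_sd)``; within-group
    variation is ``Normal(0, noise_sd)`` on the log2 scale.  Defaults put
    typical FPKM in the 3-80 range seen for hippocampal genes and use a
    within-group spread consistent with effects of |log2FC| ~ 0.2-0.4
    being confidently detectable at n = 6 per group.
    """

    n_genes: int = 2000
    n_per_group: int = 6
    group_labels: tuple[str, str, str] = ("C", "A20", "AD")
    baseline_log2_mean: float = 4.5
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.1
    deg_fraction: float = 0.1
    effect_size_range: tuple[float, float] = (0.2, 0.6)
    trajectory_mix: tuple[float, ...] = (0.4, 0.2, 0.1, 0.1, 0.2)
    neurogenesis_fraction: float = 0.04
    tf_fraction: float = 0.1
    behavior_term_prob: float = 0.15
    coexpr_block_size: int = 30
    coexpr_loading: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ConfigurationError("n_genes and n_per_group must be positive")
        if len(self.group_labels) != 3 or len(set(self.group_labels)) != 3:
            raise ConfigurationError("group_labels must be three distinct labels")
        if self.baseline_log2_sd <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("baseline_log2_sd and noise_sd must be positive")
        for name in ("deg_fraction", "neurogenesis_fraction", "tf_fraction",
                     "behavior_term_prob", "coexpr_loading"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.effect_size_range
        if not 0 <= lo <= hi:
            raise ConfigurationError("effect_size_range must be 0 <= lo <= hi")
        if len(self.trajectory_mix) != len(TRAJECTORY_CLASSES):
            raise ConfigurationError(
                f"trajectory_mix needs {len(TRAJECTORY_CLASSES)} proportions"
            )
        if any(p < 0 for p in self.trajectory_mix) or not np.isclose(
            sum(self.trajectory_mix), 1.0
        ):
            raise ConfigurationError("trajectory_mix must be non-negative and sum to 1")
        if self.coexpr_block_size < 0:
            raise ConfigurationError("coexpr_block_size must be non-negative")
        if self.coexpr_block_size > self.n_genes:
            raise ConfigurationError("coexpr_block_size exceeds n_genes")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic matrix.

    ``table`` has one row per gene: ``planted_class`` (a trajectory class
    or ``"none"``), true log2 fold changes for the three contrasts,
    coexpression-block membership, and the annotation flags as generated.
    """

    table: pd.DataFrame

    @property
    def planted(self) -> pd.DataFrame:
        return self.table[self.table["planted_class"] != NULL_CLASS]


def _class_shifts(cls: str, delta: float, noise_sd: float) -> tuple[float, float]:
    """Log2-mean shifts of (A20, AD) relative to control for one gene.

    ``delta`` is the signed planted effect.  The gradual class is planted
    as two equal sub-threshold steps scaled to the noise level (1.5 sigma
    each): by definition its per-step changes are individually
    undetectable while the cumulative change is detectable, so its
    magnitude is tied to ``noise_sd`` rather than to ``delta``.
    """
    if cls == "persistent":
        return delta, delta
    if cls == "partial_normalization":
        return delta, delta / 2.0
    if cls == "deprivation_emergent":
        return 0.0, delta
    if cls == "gradual_emergent":
        step = 1.5 * noise_sd * np.sign(delta)
        return step, 2.0 * step
    if cls == "restored":
        return delta, 0.0
    raise ConfigurationError(f"unknown trajectory class {cls!r}")


def generate_experiment(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic experiment.

    Returns the FPKM matrix (strictly positive, ``n_genes`` x
    ``3 * n_per_group``) and its ground truth.  Identical configs (the
    seed is part of the config) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_per_group
    genes = [f"G{i:05d}" for i in range(n)]
    samples = [f"{g}_{j + 1}" for g in config.group_labels for j in range(m)]
    design = pd.Series(
        [g for g in config.group_labels for _ in range(m)],
        index=pd.Index(samples, name="sample_id"),
        name="group",
    )

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    log2x = baseline[:, None] + rng.normal(0.0, config.noise_sd, (n, 3 * m))

    # planted trajectory effects
    n_planted = int(round(config.deg_fraction * n))
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    classes = np.full(n, NULL_CLASS, dtype=object)
    lfc = np.zeros((n, 3))  # columns: C_A20, C_AD, A20_AD
    if n_planted:
        drawn = rng.choice(
            len(TRAJECTORY_CLASSES), size=n_planted, p=list(config.trajectory_mix)
        )
        lo, hi = config.effect_size_range
        deltas = rng.uniform(lo, hi, n_planted) * rng.choice([-1.0, 1.0], n_planted)
        for i, ci, d in zip(planted_idx, drawn, deltas):
            cls = TRAJECTORY_CLASSES[ci]
            s20, sad = _class_shifts(cls, d, config.noise_sd)
            classes[i] = cls
            lfc[i] = (s20, sad, sad - s20)
            log2x[i, m : 2 * m] += s20
            log2x[i, 2 * m :] += sad

    # latent-factor coexpression block: correlated residuals, no mean shift.
    # The first drawn gene is the hub (loading 1 on the factor); the rest
    # load at coexpr_loading, so hub-spoke correlation = loading and
    # spoke-spoke correlation = loading^2.
    in_block = np.zeros(n, dtype=bool)
    is_hub = np.zeros(n, dtype=bool)
    if config.coexpr_block_size:
        block = rng.choice(n, size=config.coexpr_block_size, replace=False)
        in_block[block] = True
        is_hub[block[0]] = True
        lam = config.coexpr_loading
        factor = rng.normal(0.0, 1.0, 3 * m)
        loadings = np.full(config.coexpr_block_size, lam)
        loadings[0] = 1.0
        own = rng.normal(0.0, 1.0, (config.coexpr_block_size, 3 * m))
        log2x[block] = baseline[block, None] + config.noise_sd * (
            loadings[:, None] * factor[None, :]
            + np.sqrt(1.0 - loadings[:, None] ** 2) * own
        )
        # restore any planted mean shifts on block genes
        for i in block:
            log2x[i, m : 2 * m] += lfc[i, 0]
            log2x[i, 2 * m :] += lfc[i, 1]

    # annotations as generated
    is_neuro = rng.random(n) < config.neurogenesis_fraction
    is_tf = rng.random(n) < config.tf_fraction
    terms = [
        frozenset(
            t for t in BEHAVIOR_TERMS if neuro and rng.random() < config.behavior_term_prob
        )
        for neuro in is_neuro
    ]

    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.exp2(log2x), index=pd.Index(genes, name="gene_id"), columns=samples
        ),
        design,
    )
    truth = GroundTruth(
        pd.DataFrame(
            {
                "planted_class": classes,
                "true_lfc_C_A20": lfc[:, 0],
                "true_lfc_C_AD": lfc[:, 1],
                "true_lfc_A20_AD": lfc[:, 2],
                "in_coexpr_block": in_block,
                "coexpr_hub": is_hub,
                "is_neurogenesis": is_neuro,
                "is_tf": is_tf,
                "behavior_terms": terms,
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )
    return matrix, truth


def annotation_from_truth(truth: GroundTruth) -> pd.DataFrame:
    """Annotation table (io.annotate-compatible) from generated truth."""
    return truth.table[["is_neurogenesis", "is_tf", "behavior_terms"]].copy()


def write_truth(truth: GroundTruth, path) -> None:
    """Write ground truth as TSV; round-trips losslessly via read_truth."""
    df = truth.table.copy()
    df["behavior_terms"] = ["|".join(sorted(t)) for t in df["behavior_terms"]]
    for col in ("in_coexpr_block", "coexpr_hub", "is_neurogenesis", "is_tf"):
        df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_filter=False, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df["behavior_terms"] = [
        frozenset(t for t in str(s).split("|") if t) for s in df["behavior_terms"]
    ]
    for col in ("in_coexpr_block", "coexpr_hub", "is_neurogenesis", "is_tf"):
        df[col] = df[col].astype(int).astype(bool)
    for col in ("true_lfc_C_A20", "true_lfc_C_AD", "true_lfc_A20_AD"):
        df[col] = df[col].astype(float)
    df["planted_class"] = df["planted_class"].astype(object)
    return GroundTruth(df)
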