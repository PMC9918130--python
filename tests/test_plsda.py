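"""Two-block PLS-DA, Axis-1 correlation ranking, bins, candidates."""

import numpy as np
import pandas as pd
import pytest

import plsrank as pr
from plsrank.plsda import BIN_LABELS, _bin_label


def _design(groups):
    samples = [f"s{j}" for j in range(len(groups))]
    return pd.Series(list(groups), index=samples)


def _processed(values, samples=None):
    genes = [f"g{i}" for i in range(len(values))]
    samples = samples or [f"s{j}" for j in range(len(values[0]))]
    return pd.DataFrame(values, index=genes, columns=samples, dtype=float)


def brute_force_axis1(x, y, n_coarse=2000, n_fine=4001, width=0.01):
    """Exhaustive unit-direction search maximizing |cov(Xw, y)|, 2 genes.

    Grid over the half-circle, then a fine local grid; independent of the
    SVD route used by the fitted model.
    """
    xc = x - x.mean(axis=0)  # samples x 2
    yc = y - y.mean(axis=0)

    def score(theta):
        w = np.stack([np.cos(theta), np.sin(theta)])
        t = xc @ w
        return np.linalg.norm(t.T @ yc, axis=1)

    thetas = np.linspace(0, np.pi, n_coarse, endpoint=False)
    best = thetas[np.argmax(score(thetas))]
    local = np.linspace(best - width, best + width, n_fine)
    best = local[np.argmax(score(local))]
    return np.array([np.cos(best), np.sin(best)])


def angle_between(u, v):
    c = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1, 1)))


class TestDummyBlock:
    def test_two_plus_two(self):
        dummy = pr.make_dummy(_design("AABB"), ("A", "B"))
        assert dummy.values.shape == (4, 2)
        np.testing.assert_allclose(dummy.values.sum(axis=0), 0, atol=1e-12)

    def test_six_plus_six_from_three_groups(self):
        design = _design("C" * 6 + "X" * 6 + "Y" * 6)
        dummy = pr.make_dummy(design, ("C", "Y"))
        assert dummy.values.shape == (12, 2)
        assert all(design[s] in ("C", "Y") for s in dummy.sample_ids)

    def test_rows_sum_to_one_before_centering(self):
        dummy = pr.make_dummy(_design("AABB"), ("A", "B"))
        raw = dummy.values.to_numpy() + 0.5  # undo the centering (2+2 design)
        np.testing.assert_allclose(raw.sum(axis=1), 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(pr.DesignError):
            pr.make_dummy(_design("AABB"), ("A", "A"))

    def test_absent_group_rejected(self):
        with pytest.raises(pr.DesignError, match="Z"):
            pr.make_dummy(_design("AABB"), ("A", "Z"))


class TestFitPlsda:
    def test_separating_gene_dominates_axis1(self):
        # gene g0 separates the groups; g1 is noise
        x = _processed([[1.0, 1.2, 3.0, 3.1], [0.5, 0.4, 0.45, 0.5]])
        dummy = pr.make_dummy(_design("AABB"), ("A", "B"))
        model = pr.fit_plsda(x, dummy, n_axes=1)
        w = model.weights["Axis1"]
        assert abs(w["g0"]) > 0.99
        assert np.linalg.norm(w) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_axis1_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (6, 2))
        x[3:] += rng.normal(0.5, 0.5, 2)
        dummy = pr.make_dummy(_design("AAABBB"), ("A", "B"))
        model = pr.fit_plsda(_processed(x.T), dummy, n_axes=1)
        oracle = brute_force_axis1(x, dummy.values.to_numpy())
        got = model.weights["Axis1"].to_numpy()
        assert angle_between(got, oracle) < 1e-3

    def test_matches_sklearn_first_component(self, default_experiment):
        PLSCanonical = pytest.importorskip("sklearn.cross_decomposition").PLSCanonical
        matrix, _ = default_experiment
        processed = pr.preprocess(matrix)
        dummy = pr.make_dummy(matrix.design, ("C", "A20"))
        model = pr.fit_plsda(processed, dummy, n_axes=1)
        xs = processed.values[dummy.sample_ids].to_numpy().T
        pls = PLSCanonical(n_components=1, scale=False).fit(
            xs, dummy.values.to_numpy()
        )
        ref = pls.x_weights_[:, 0]
        got = model.weights["Axis1"].to_numpy()
        assert angle_between(got, ref) < 1e-6

    def test_orientation_control_mean_positive(self, default_experiment):
        matrix, _ = default_experiment
        processed = pr.preprocess(matrix)
        dummy = pr.make_dummy(matrix.design, ("C", "A20"))
        model = pr.fit_plsda(processed, dummy)
        scores = model.scores["Axis1"]
        control = [s for s in dummy.sample_ids if matrix.design[s] == "C"]
        assert scores[control].mean() > 0

    def test_score_vectors_orthogonal(self, default_experiment):
        matrix, _ = default_experiment
        model = pr.fit_plsda(
            pr.preprocess(matrix), pr.make_dummy(matrix.design, ("C", "A20")), n_axes=2
        )
        t = model.scores.to_numpy()
        assert abs(t[:, 0] @ t[:, 1]) < 1e-8

    def test_null_case_flagged_unstable(self):
        # the two groups contain identical sample values -> zero cross-cov
        base = np.random.default_rng(3).normal(0, 1, (5, 3))
        x = _processed(np.hstack([base, base]))
        dummy = pr.make_dummy(_design("AAABBB"), ("A", "B"))
        model = pr.fit_plsda(x, dummy, n_axes=1)
        assert model.axis_stable == [False]
        assert model.covariance_explained[0] == 0.0

    def test_sample_permutation_invariance(self, default_experiment):
        matrix, _ = default_experiment
        processed = pr.preprocess(matrix)
        dummy = pr.make_dummy(matrix.design, ("C", "A20"))
        model = pr.fit_plsda(processed, dummy)
        # same permutation of X columns and Y rows
        perm = np.random.default_rng(0).permutation(dummy.sample_ids)
        dummy2 = pr.DummyBlock(dummy.values.loc[perm], dummy.groups)
        model2 = pr.fit_plsda(processed, dummy2)
        np.testing.assert_allclose(
            model.weights.to_numpy(), model2.weights.to_numpy(), atol=1e-9
        )
        np.testing.assert_allclose(
            model.scores.loc[perm].to_numpy(), model2.scores.to_numpy(), atol=1e-9
        )

    def test_missing_sample_rejected(self):
        x = _processed([[1.0, 2.0, 3.0]], samples=["s0", "s1", "s2"])
        dummy = pr.make_dummy(_design("AABB"), ("A", "B"))
        with pytest.raises(pr.DesignError, match="s3"):
            pr.fit_plsda(x, dummy)

    def test_single_dummy_column_gives_same_scores(self, default_experiment):
        """Two-group degeneracy: either dummy column carries the same axis."""
        matrix, _ = default_experiment
        processed = pr.preprocess(matrix)
        dummy = pr.make_dummy(matrix.design, ("C", "A20"))
        one_col = pr.DummyBlock(dummy.values.iloc[:, [0]], dummy.groups)
        other_col = pr.DummyBlock(dummy.values.iloc[:, [1]], dummy.groups)
        t_full = pr.fit_plsda(processed, dummy, n_axes=1).scores["Axis1"]
        t_one = pr.fit_plsda(processed, one_col, n_axes=1).scores["Axis1"]
        t_other = pr.fit_plsda(processed, other_col, n_axes=1).scores["Axis1"]
        np.testing.assert_allclose(t_one, t_full, atol=1e-9)
        np.testing.assert_allclose(t_other, t_full, atol=1e-9)


class TestAxis1Correlations:
    def _model_with_scores(self, scores, samples):
        return pr.PLSDAModel(
            weights=pd.DataFrame({"Axis1": [1.0]}, index=["w"]),
            scores=pd.DataFrame({"Axis1": scores}, index=samples),
            groups=("A", "B"),
            singular_values=np.array([1.0]),
            covariance_explained=np.array([1.0]),
            axis_stable=[True],
        )

    def test_gene_equal_to_scores_has_r_one(self):
        samples = [f"s{j}" for j in range(6)]
        scores = np.array([1.0, 2.0, 0.5, -1.0, -2.0, -0.5])
        x = _processed([scores, -scores], samples=samples)
        ranking = pr.axis1_correlations(x, self._model_with_scores(scores, samples))
        assert ranking.table.loc["g0", "r"] == pytest.approx(1.0)
        assert ranking.table.loc["g1", "r"] == pytest.approx(-1.0)

    def test_upregulated_gene_correlates_negatively(self):
        """Orientation: a gene UP in the experimental group gets r < 0."""
        cfg = pr.SyntheticConfig(
            n_genes=300, deg_fraction=0.2, effect_size_range=(0.5, 0.6),
            trajectory_mix=(1.0, 0.0, 0.0, 0.0, 0.0), seed=13,
        )
        matrix, truth = pr.generate_experiment(cfg)
        processed = pr.preprocess(matrix)
        model = pr.fit_plsda(processed, pr.make_dummy(matrix.design, ("C", "A20")))
        ranking = pr.axis1_correlations(processed, model)
        planted = truth.planted
        up = planted.index[planted["true_lfc_C_A20"] > 0]
        down = planted.index[planted["true_lfc_C_A20"] < 0]
        assert (ranking.table.loc[up, "r"] < 0).mean() > 0.95
        assert (ranking.table.loc[down, "r"] > 0).mean() > 0.95

    def test_all_r_in_range(self, default_experiment):
        matrix, _ = default_experiment
        processed = pr.preprocess(matrix)
        model = pr.fit_plsda(processed, pr.make_dummy(matrix.design, ("C", "AD")))
        ranking = pr.axis1_correlations(processed, model)
        r = ranking.table["r"]
        assert r.between(-1, 1).all()


class TestBinning:
    def test_bin_examples(self):
        samples = [f"s{j}" for j in range(8)]
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 8)
        ranking = pr.CorrelationRanking(
            table=pd.DataFrame(
                {
                    "r": [0.95, -0.91, 0.05],
                    "abs_r": [0.95, 0.91, 0.05],
                    "bin": [_bin_label(a) for a in (0.95, 0.91, 0.05)],
                    "candidate": [True, True, False],
                },
                index=["a", "b", "c"],
            ),
            r_threshold=0.90,
        )
        bins = pr.bin_abs_correlations(ranking)
        assert bins.loc["1.00-0.90", "n_genes"] == 2
        assert bins.loc["0.09-0.00", "n_genes"] == 1
        assert bins["n_genes"].sum() == 3

    def test_boundary_rule_lower_closed(self):
        assert _bin_label(0.5) == "0.59-0.50"
        assert _bin_label(0.9) == "1.00-0.90"   # printed threshold lands in top bin
        assert _bin_label(1.0) == "1.00-0.90"
        assert _bin_label(0.0) == "0.09-0.00"
        assert _bin_label(0.8999999) == "0.89-0.80"

    def test_cross_tab_row_sums(self):
        """Restricted to a 72-gene neurogenesis DEG set, counts conserve."""
        cfg = pr.SyntheticConfig(n_genes=500, deg_fraction=0.3, seed=8)
        matrix, truth = pr.generate_experiment(cfg)
        processed = pr.preprocess(matrix)
        model = pr.fit_plsda(processed, pr.make_dummy(matrix.design, ("C", "A20")))
        ranking = pr.axis1_correlations(processed, model)
        ann = pr.annotation_from_truth(truth)
        subset = list(truth.table.index[:72])
        bins = pr.bin_abs_correlations(ranking, annotation=ann, genes=subset)
        assert bins["n_genes"].sum() == 72
        assert (bins["n_tf"] <= bins["n_genes"]).all()
        assert list(bins.index) == list(BIN_LABELS)


class TestSelectCandidates:
    @pytest.fixture
    def ranking(self, default_experiment):
        matrix, _ = default_experiment
        processed = pr.preprocess(matrix)
        model = pr.fit_plsda(processed, pr.make_dummy(matrix.design, ("C", "A20")))
        return pr.axis1_correlations(processed, model)

    def test_impossible_threshold_empty(self, ranking):
        # nothing correlates perfectly with the latent axis on noisy data
        assert (ranking.table["abs_r"] < 1).all()
        assert len(pr.select_candidates(ranking, r_threshold=1.0)) == 0

    def test_zero_threshold_keeps_all(self, ranking):
        assert len(pr.select_candidates(ranking, r_threshold=0.0)) == len(ranking.table)

    def test_sorted_by_abs_r_then_name(self, ranking):
        out = pr.select_candidates(ranking, r_threshold=0.0)
        abs_r = out["abs_r"].to_numpy()
        assert (np.diff(abs_r) <= 1e-15).all()

    def test_annotation_filters(self, default_experiment, ranking):
        _, truth = default_experiment
        ann = pr.annotation_from_truth(truth)
        all_c = pr.select_candidates(ranking, annotation=ann, r_threshold=0.5)
        neuro = pr.select_candidates(
            ranking, annotation=ann, r_threshold=0.5, require_neurogenesis=True
        )
        assert set(neuro.index) <= set(all_c.index)
        assert neuro["is_neurogenesis"].all()


def test_scale_invariance_end_to_end(default_experiment):
    """Multiplying a gene's FPKM by a constant leaves its rank untouched."""
    matrix, _ = default_experiment
    scaled = matrix.values.copy()
    scaled.iloc[5] *= 137.0
    m2 = pr.ExpressionMatrix(scaled, matrix.design)

    def ranking_of(m):
        p = pr.preprocess(m, pseudocount=1e-9)  # tiny offset: pure log2 scaling
        model = pr.fit_plsda(p, pr.make_dummy(m.design, ("C", "A20")))
        return pr.axis1_correlations(p, model).table["r"]

    r1, r2 = ranking_of(matrix), ranking_of(m2)
    np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-7)
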