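"""Factor extraction, varimax rotation, clustering and factor alignment."""

import numpy as np
import pytest
from scipy import stats

from neurosem.factors import (
    FactorSolution,
    align_two,
    assign_voxels_to_factors,
    correlate_scores_with_ratings,
    extract_clusters,
    factor_scores,
    group_level_fa,
    individual_level_fa,
    principal_factor_analysis,
    residual_columns,
    secondary_fa,
    squared_multiple_correlations,
    varimax_criterion,
    varimax_rotate,
    voxel_factor_loadings,
)
from neurosem.preprocess import voxel_stability
from neurosem.synth import simulate_participant


def random_corr(rng, n_obs, n_var):
    X = rng.standard_normal((n_obs, n_var))
    return np.corrcoef(X, rowvar=False), X


class TestSmc:
    def test_two_variable_closed_form(self):
        """For a 2x2 correlation matrix, SMC of each variable is r^2."""
        for r in (0.0, 0.3, -0.8):
            corr = np.array([[1.0, r], [r, 1.0]])
            assert np.allclose(squared_multiple_correlations(corr), r**2)

    def test_matches_regression_r2_oracle(self):
        """SMC of variable j equals the R^2 of regressing j on the rest."""
        rng = np.random.default_rng(0)
        corr, X = random_corr(rng, 200, 5)
        smc = squared_multiple_correlations(corr)
        for j in range(5):
            others = np.delete(X, j, axis=1)
            A = np.column_stack([others, np.ones(len(X))])
            coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
            pred = A @ coef
            r2 = np.corrcoef(pred, X[:, j])[0, 1] ** 2
            assert smc[j] == pytest.approx(r2, abs=1e-10)

    def test_singular_matrix_falls_back_to_pinv_in_range(self):
        rng = np.random.default_rng(1)
        corr, _ = random_corr(rng, 4, 10)  # rank-deficient
        smc = squared_multiple_correlations(corr)
        assert np.isfinite(smc).all()
        assert ((smc >= 0) & (smc <= 1)).all()


class TestPrincipalFactorAnalysis:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        corr, _ = random_corr(rng, 100, 6)
        sol = principal_factor_analysis(corr, 2)
        reduced = corr.copy()
        np.fill_diagonal(reduced, squared_multiple_correlations(corr))
        w, V = np.linalg.eigh(reduced)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        oracle = V[:, :2] * np.sqrt(w[:2])
        # compare up to per-column sign
        for j in range(2):
            assert np.allclose(sol.loadings[:, j], oracle[:, j], atol=1e-10) or np.allclose(
                sol.loadings[:, j], -oracle[:, j], atol=1e-10
            )
        assert np.allclose(sol.communalities, (oracle**2).sum(axis=1), atol=1e-10)
        assert np.allclose(sol.variance_explained, (oracle**2).sum(axis=0), atol=1e-10)

    def test_one_common_factor_recovered(self):
        """Classic single-factor model: R = LL' + Psi with known loadings."""
        lam = np.array([0.9, 0.8, 0.7, 0.6])
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        sol = principal_factor_analysis(corr, 1)
        # SMC priors underestimate communalities slightly; structure survives
        assert np.allclose(sol.loadings[:, 0] / sol.loadings[0, 0], lam / lam[0], atol=0.05)

    def test_identity_matrix_warns_zero_solution(self):
        with pytest.warns(UserWarning, match="no positive eigenvalues"):
            sol = principal_factor_analysis(np.eye(4), 2)
        assert np.allclose(sol.loadings, 0)

    def test_fewer_positive_eigenvalues_reduces_count(self):
        rng = np.random.default_rng(3)
        corr, _ = random_corr(rng, 3, 6)  # rank 2 at most
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            sol = principal_factor_analysis(corr, 5)
        assert sol.n_factors < 5

    def test_validation(self):
        with pytest.raises(ValueError, match="square"):
            principal_factor_analysis(np.zeros((2, 3)), 1)
        with pytest.raises(ValueError, match="symmetric"):
            principal_factor_analysis(np.array([[1.0, 0.5], [0.1, 1.0]]), 1)
        with pytest.raises(ValueError, match="diagonal"):
            principal_factor_analysis(np.array([[2.0, 0.0], [0.0, 2.0]]), 1)
        with pytest.raises(ValueError, match="n_factors"):
            principal_factor_analysis(np.eye(3), 0)


class TestVarimax:
    def test_angle_grid_search_oracle_two_factors(self):
        """For 2 factors the planar rotation angle can be searched by brute
        force; varimax must reach the same criterion value."""
        rng = np.random.default_rng(4)
        L = rng.standard_normal((12, 2))
        rotated = varimax_rotate(L, normalize=False)
        crits = []
        for theta in np.linspace(0, np.pi / 2, 20001, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            crits.append(varimax_criterion(L @ np.array([[c, -s], [s, c]])))
        assert varimax_criterion(rotated) == pytest.approx(max(crits), abs=1e-7)

    def test_recovers_planted_simple_structure(self):
        """Scramble a perfect simple structure with a random rotation;
        varimax must un-scramble it up to column order and sign."""
        rng = np.random.default_rng(5)
        L0 = np.zeros((9, 3))
        for j in range(3):
            L0[3 * j : 3 * j + 3, j] = [0.9, 0.8, 0.7]
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        recovered = varimax_rotate(L0 @ Q)
        match = np.abs(L0.T @ recovered) / (
            np.linalg.norm(L0, axis=0)[:, None] * np.linalg.norm(recovered, axis=0)
        )
        # each planted column has a near-identical recovered partner
        assert np.allclose(match.max(axis=1), 1.0, atol=1e-6)

    def test_preserves_communalities_and_criterion_not_decreased(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            L = rng.standard_normal((10, 3))
            # rotation preserves row norms regardless of normalization mode
            R = varimax_rotate(L)
            assert np.allclose((R**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8)
            # the raw criterion is what the un-normalized variant maximizes
            R_raw = varimax_rotate(L, normalize=False)
            assert varimax_criterion(R_raw) >= varimax_criterion(L) - 1e-10

    def test_single_factor_unchanged(self):
        L = np.arange(5.0)[:, None]
        assert np.array_equal(varimax_rotate(L), L)

    def test_column_sign_convention(self):
        rng = np.random.default_rng(7)
        R = varimax_rotate(rng.standard_normal((8, 2)))
        for j in range(2):
            assert R[np.argmax(np.abs(R[:, j])), j] > 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            varimax_rotate(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestFactorScores:
    def test_matches_manual_regression_estimator(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 4))
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        corr = np.corrcoef(Z, rowvar=False)
        sol = principal_factor_analysis(corr, 2)
        got = factor_scores(Z, sol, corr)
        manual = Z @ np.linalg.inv(corr) @ sol.loadings
        manual = (manual - manual.mean(axis=0)) / manual.std(axis=0)
        assert np.allclose(got, manual, atol=1e-10)
        assert np.allclose(got.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(got.std(axis=0), 1, atol=1e-12)


class TestGroupLevel:
    def _individual(self, rng, scores_true, n_factors=2, noise=0.05):
        """Fabricate an individual solution whose score columns are noisy
        copies of the true dimension scores."""
        C = scores_true.shape[0]
        S = np.column_stack(
            [scores_true[:, j % scores_true.shape[1]] + noise * rng.standard_normal(C)
             for j in range(n_factors)]
        )
        S = (S - S.mean(axis=0)) / S.std(axis=0)
        return FactorSolution(
            loadings=np.zeros((5, n_factors)),
            communalities=np.zeros(5),
            variance_explained=np.ones(n_factors),
            scores=S,
            column_info=list(range(5)),
        )

    def test_recovers_shared_dimensions_across_participants(self):
        rng = np.random.default_rng(9)
        # orthogonalized planted dimensions (varimax factors are orthogonal,
        # so correlated dimensions could not both be matched exactly)
        true, _ = np.linalg.qr(rng.standard_normal((30, 2)))
        sols = {
            f"P{i}": {"frontal": self._individual(rng, true)} for i in range(3)
        }
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            group = group_level_fa(sols, variance_threshold=0.1)
        assert group.n_factors == 2
        for d in range(2):
            rs = np.abs(voxel_factor_loadings(true[:, [d]], group.scores))
            assert rs.max() > 0.98

    def test_column_info_traces_participant_lobe_factor(self):
        rng = np.random.default_rng(10)
        true = rng.standard_normal((20, 1))
        sols = {"A": {"occipital": self._individual(rng, true, n_factors=2)}}
        group = group_level_fa(sols, variance_threshold=0.1)
        assert group.column_info == [("A", "occipital", 0), ("A", "occipital", 1)]

    def test_pure_noise_columns_yield_no_factor_above_noise_ceiling(self):
        """At 45 observations and M columns, a pure-noise correlation matrix
        has top eigenvalue near the Marchenko-Pastur edge (1 + sqrt(M/45))^2.
        A retention threshold above that edge (as a fraction of M) must
        reject everything when the input is white noise."""
        rng = np.random.default_rng(11)
        C, M = 45, 30
        edge_fraction = (1 + np.sqrt(M / C)) ** 2 / M  # ~0.11
        X = rng.standard_normal((C, M))
        with pytest.warns(UserWarning, match="variance threshold"):
            sol = secondary_fa(X, variance_threshold=2 * edge_fraction)
        assert sol.n_factors == 0
        assert sol.scores.shape == (C, 0)

    def test_planted_coherent_signal_survives_same_threshold(self):
        rng = np.random.default_rng(12)
        C, M = 45, 30
        edge_fraction = (1 + np.sqrt(M / C)) ** 2 / M
        signal = rng.standard_normal(C)
        X = 0.25 * rng.standard_normal((C, M))
        X[:, :12] += signal[:, None]
        sol = secondary_fa(X, variance_threshold=2 * edge_fraction)
        assert sol.n_factors >= 1
        r = np.abs(voxel_factor_loadings(signal[:, None], sol.scores))
        assert r.max() > 0.99

    def test_secondary_fa_empty_and_single_column(self):
        empty = secondary_fa(np.zeros((10, 0)))
        assert empty.n_factors == 0
        rng = np.random.default_rng(13)
        col = rng.standard_normal(10)
        one = secondary_fa(col, column_info=["x"])
        assert one.n_factors == 1
        assert np.allclose(one.scores[:, 0], (col - col.mean()) / col.std())

    def test_residual_columns(self):
        sol = FactorSolution(
            loadings=np.array([[0.9, 0.0], [0.1, 0.2], [0.0, -0.8]]),
            communalities=np.zeros(3),
            variance_explained=np.zeros(2),
        )
        assert residual_columns(sol, threshold=0.4).tolist() == [1]
        nothing = FactorSolution(
            loadings=np.zeros((3, 0)),
            communalities=np.zeros(3),
            variance_explained=np.zeros(0),
        )
        assert residual_columns(nothing).tolist() == [0, 1, 2]

    def test_missing_scores_and_mismatched_concepts_rejected(self):
        bare = FactorSolution(
            loadings=np.zeros((2, 1)),
            communalities=np.zeros(2),
            variance_explained=np.zeros(1),
        )
        with pytest.raises(ValueError, match="scores"):
            group_level_fa({"A": {"frontal": bare}})
        rng = np.random.default_rng(14)
        a = self._individual(rng, rng.standard_normal((10, 1)))
        b = self._individual(rng, rng.standard_normal((12, 1)))
        with pytest.raises(ValueError, match="concept"):
            group_level_fa({"A": {"frontal": a}, "B": {"frontal": b}})


class TestVoxelAssignment:
    def test_loadings_match_pearsonr_oracle(self):
        rng = np.random.default_rng(15)
        profiles = rng.standard_normal((25, 6))
        scores = rng.standard_normal((25, 3))
        L = voxel_factor_loadings(profiles, scores)
        for v in range(6):
            for f in range(3):
                r = stats.pearsonr(profiles[:, v], scores[:, f]).statistic
                assert L[v, f] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_voxel_loads_zero(self):
        profiles = np.ones((10, 2))
        profiles[:, 1] = np.arange(10.0)
        scores = np.arange(10.0)[:, None]
        L = voxel_factor_loadings(profiles, scores)
        assert L[0, 0] == 0.0
        assert L[1, 0] == pytest.approx(1.0)

    def test_assignment_threshold_is_strict(self):
        L = np.array([[0.4, 0.1], [0.41, 0.1], [-0.9, 0.85], [0.1, 0.2]])
        assert assign_voxels_to_factors(L, 0.4).tolist() == [-1, 0, 0, -1]

    def test_no_factors_gives_all_unassigned(self):
        out = assign_voxels_to_factors(np.zeros((4, 0)))
        assert out.tolist() == [-1] * 4

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_voxels_to_factors(np.array([[np.inf]]))


class TestExtractClusters:
    def test_hand_built_components(self, tiny_geom):
        assignment = np.full(64, -1)
        # factor 0: a face-connected pair along z, plus an isolated voxel
        a = tiny_geom.grid_to_index(np.array([[0, 0, 0], [0, 0, 1], [3, 3, 3]]))
        assignment[a] = 0
        # factor 1: an L-triple
        b = tiny_geom.grid_to_index(np.array([[2, 0, 0], [2, 1, 0], [3, 1, 0]]))
        assignment[b] = 1
        cmap = extract_clusters(assignment, tiny_geom, min_size=2)
        assert len(cmap) == 2
        c0, c1 = cmap.for_factor(0)[0], cmap.for_factor(1)[0]
        assert c0.voxels == tuple(sorted(int(v) for v in a[:2]))
        assert c1.voxels == tuple(sorted(int(v) for v in b))
        assert cmap.unassigned == (int(a[2]),)
        # centroid is the mean of the member mm coordinates
        assert np.allclose(c0.centroid_mm, tiny_geom.voxel_mm(a[:2]).mean(axis=0))

    def test_min_size_filter(self, tiny_geom):
        assignment = np.full(64, -1)
        pair = tiny_geom.grid_to_index(np.array([[0, 0, 0], [0, 0, 1]]))
        assignment[pair] = 0
        assert len(extract_clusters(assignment, tiny_geom, min_size=3)) == 0
        assert len(extract_clusters(assignment, tiny_geom, min_size=2)) == 1

    def test_diagonal_pair_joined_only_at_26_connectivity(self, tiny_geom):
        assignment = np.full(64, -1)
        diag = tiny_geom.grid_to_index(np.array([[0, 0, 0], [1, 1, 1]]))
        assignment[diag] = 0
        assert len(extract_clusters(assignment, tiny_geom, connectivity=6)) == 0
        cmap = extract_clusters(assignment, tiny_geom, connectivity=26)
        assert len(cmap) == 1 and cmap.clusters[0].size == 2
        with pytest.raises(ValueError, match="connectivity"):
            extract_clusters(assignment, tiny_geom, connectivity=18)

    def test_two_factor_components_do_not_merge(self, tiny_geom):
        assignment = np.full(64, -1)
        left = tiny_geom.grid_to_index(np.array([[0, 0, 0], [0, 0, 1]]))
        right = tiny_geom.grid_to_index(np.array([[0, 0, 2], [0, 0, 3]]))
        assignment[left] = 0
        assignment[right] = 1  # adjacent in space but different factors
        cmap = extract_clusters(assignment, tiny_geom)
        assert sorted(c.factor for c in cmap.clusters) == [0, 1]


class TestAlignment:
    def test_greedy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            A = rng.standard_normal((15, 3))
            B = rng.standard_normal((15, 3))
            greedy = align_two(A, B)
            exhaustive = align_two(A, B, exhaustive=True)
            g = sum(abs(r) for *_, r in greedy)
            e = sum(abs(r) for *_, r in exhaustive)
            assert g <= e + 1e-12  # greedy never beats the oracle ...
            # ... and on permuted copies of the same solution it ties it
        perm = [2, 0, 1]
        A = rng.standard_normal((15, 3))
        B = A[:, perm]
        got = {a: b for a, b, _ in align_two(A, B)}
        assert got == {0: perm.index(0), 1: perm.index(1), 2: perm.index(2)}

    def test_sign_flips_reported_with_signed_r(self):
        rng = np.random.default_rng(17)
        A = rng.standard_normal((20, 2))
        B = np.column_stack([-A[:, 0], A[:, 1]])
        pairs = align_two(A, B)
        assert pairs[0][2] == pytest.approx(-1.0)
        assert pairs[1][2] == pytest.approx(1.0)

    def test_empty_inputs(self):
        assert align_two(np.zeros((5, 0)), np.zeros((5, 2))) == []


class TestRatingsValidation:
    def test_perfect_scores_give_unit_correlation(self):
        rng = np.random.default_rng(18)
        S = rng.standard_normal((30, 3))
        out = correlate_scores_with_ratings(S[:, [1, 2]], S)
        by_dim = {rec["dimension"]: rec["factor"] for rec in out}
        # scores column 0 is ratings dimension 1, column 1 is dimension 2
        assert by_dim["dimension_1"] == 0
        assert by_dim["dimension_2"] == 1
        for rec in out:
            assert abs(rec["r"]) == pytest.approx(1.0)
            assert rec["p"] < 1e-10
            assert rec["n"] == 30

    def test_extremes_subset_size_and_improved_r(self):
        rng = np.random.default_rng(19)
        true = rng.standard_normal(40)
        ratings = (true + 0.8 * rng.standard_normal(40))[:, None]
        scores = true[:, None]
        full = correlate_scores_with_ratings(scores, ratings, subset="all")[0]
        ext = correlate_scores_with_ratings(scores, ratings, subset=("extremes", 10))[0]
        assert ext["n"] == 10
        # spreading out the predictor raises |r| for a noisy linear relation
        assert abs(ext["r"]) > abs(full["r"])

    def test_constant_rating_dimension_raises_with_name(self):
        rng = np.random.default_rng(20)
        S = rng.standard_normal((10, 1))
        R = np.ones((10, 1))
        with pytest.raises(ValueError, match="dimension_0"):
            correlate_scores_with_ratings(S, R)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="same concepts"):
            correlate_scores_with_ratings(np.zeros((5, 1)), np.ones((6, 1)))


class TestIndividualLevelFa:
    def test_zero_noise_lobe_factors_track_planted_dimensions(self, zero_noise_gt):
        """With no noise, each lobe hosting planted clusters must yield a
        factor whose scores reproduce the planted dimension scores."""
        ds = simulate_participant(zero_noise_gt, 0, n_presentations=4)
        stab = voxel_stability(ds.psc)
        # out-of-cluster voxels are exactly constant at zero noise, so only
        # the planted voxels are scoreable and the selection warns
        with pytest.warns(UserWarning, match="scoreable"):
            sols = individual_level_fa(ds, stab, n_per_lobe=20, n_factors=3)
        assert set(sols) == set(zero_noise_gt.geometry.lobe_names)
        planted_by_lobe: dict[str, set] = {}
        voxels_by_lobe: dict[str, set] = {}
        for c in zero_noise_gt.cluster_specs["faculty"]:
            planted_by_lobe.setdefault(c.lobe, set()).add(c.dimension)
            voxels_by_lobe.setdefault(c.lobe, set()).update(c.voxels)
        for lobe, dims in planted_by_lobe.items():
            sol = sols[lobe]
            assert set(sol.column_info) == voxels_by_lobe[lobe]
            for dim in dims:
                true = zero_noise_gt.scores_for(dim)[:, None]
                r = np.abs(voxel_factor_loadings(true, sol.scores))
                # sampled dimensions are mildly correlated with each other,
                # while varimax factors are orthogonal; 0.9 is the design bar
                assert r.max() > 0.9, (lobe, dim)
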