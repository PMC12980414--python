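"""Projection and chi^2-band + density ensemble selection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import sbmsaxs as sx
from sbmsaxs import synthetic as syn
from sbmsaxs.ensemble import EnsembleError


# -- features ----------------------------------------------------------

def test_features_invariant_under_rigid_motion():
    rng = np.random.default_rng(0)
    frame = rng.normal(0, 3, (12, 3))
    theta = 1.1
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = frame @ R.T + np.array([4.0, 5.0, -6.0])
    feats = sx.internal_distance_features(
        np.stack([frame, moved]), pair_sample=30, seed=1)
    np.testing.assert_allclose(feats[0], feats[1], atol=1e-9)


def test_three_atom_frame_gives_three_pairs():
    frames = np.zeros((2, 3, 3))
    frames[1, 2, 0] = 1.0
    feats = sx.internal_distance_features(frames, pair_sample=10**6, seed=0)
    assert feats.shape == (2, 3)


def test_pair_subsample_deterministic_for_seed():
    rng = np.random.default_rng(1)
    frames = rng.normal(0, 1, (3, 20, 3))
    a = sx.internal_distance_features(frames, pair_sample=40, seed=7)
    b = sx.internal_distance_features(frames, pair_sample=40, seed=7)
    np.testing.assert_array_equal(a, b)


def test_inconsistent_atom_count_rejected():
    with pytest.raises(EnsembleError):
        sx.internal_distance_features(np.zeros((1, 5, 3)))


# -- dissimilarity -----------------------------------------------------

def test_identical_frames_zero_dissimilarity():
    feats = np.ones((3, 10))
    d = sx.dissimilarity(feats)
    np.testing.assert_allclose(d.condensed, 0.0)


def test_dissimilarity_matches_double_loop_oracle():
    rng = np.random.default_rng(2)
    feats = rng.normal(0, 1, (10, 17))
    d = sx.dissimilarity(feats).full()
    for i in range(10):
        for j in range(10):
            expect = np.sqrt(np.sum((feats[i] - feats[j]) ** 2) / 17)
            assert d[i, j] == pytest.approx(expect, abs=1e-12)


def test_frame_permutation_permutes_matrix():
    rng = np.random.default_rng(3)
    feats = rng.normal(0, 1, (8, 9))
    perm = rng.permutation(8)
    d1 = sx.dissimilarity(feats).full()
    d2 = sx.dissimilarity(feats[perm]).full()
    np.testing.assert_allclose(d2, d1[np.ix_(perm, perm)], atol=1e-12)


# -- projection --------------------------------------------------------

def test_equilateral_dissimilarities_embed_as_equilateral_triangle():
    D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
    proj = sx.project_2d(sx.DissimilarityMatrix(3, squareform(D)), seed=0,
                         max_iter=2000, tol=1e-15)
    d = pdist(proj.coords)
    assert np.ptp(d) / np.mean(d) < 0.01


def test_planted_planar_geometry_recovered():
    rng = np.random.default_rng(4)
    pts = rng.normal(0, 1, (40, 2))
    target = pdist(pts)
    proj = sx.project_2d(sx.DissimilarityMatrix(40, target), seed=1,
                         max_iter=3000, tol=1e-15)
    assert proj.stress < 1e-3
    np.testing.assert_allclose(pdist(proj.coords), target,
                               rtol=0.01, atol=1e-4)


def test_duplicate_frames_become_coincident_points():
    rng = np.random.default_rng(5)
    pts = rng.normal(0, 1, (10, 2))
    pts[7] = pts[2]
    proj = sx.project_2d(sx.DissimilarityMatrix(10, pdist(pts)), seed=0,
                         max_iter=5000, tol=1e-16)
    assert np.linalg.norm(proj.coords[7] - proj.coords[2]) < 1e-4


def test_stress_monotone_and_reproducible():
    rng = np.random.default_rng(6)
    D = squareform(pdist(rng.normal(0, 1, (25, 5))))
    p1 = sx.project_2d(sx.DissimilarityMatrix(25, squareform(D)), seed=3)
    p2 = sx.project_2d(sx.DissimilarityMatrix(25, squareform(D)), seed=3)
    np.testing.assert_array_equal(p1.coords, p2.coords)
    assert np.all(np.diff(p1.stress_history) <= 1e-12)


def test_final_stress_comparable_to_sklearn_smacof():
    """Independent cross-check against sklearn's SMACOF on one instance."""
    from sklearn.manifold import smacof
    rng = np.random.default_rng(7)
    D = squareform(pdist(rng.normal(0, 1, (30, 2))))
    ours = sx.StressProjection(seed=0, max_iter=2000, tol=1e-15).fit(D)
    _, their_raw = smacof(D, n_components=2, n_init=4, random_state=0,
                          normalized_stress=False)
    our_raw = ours.stress_history_[-1]
    assert our_raw <= their_raw + 1e-6


def test_too_few_frames_rejected():
    with pytest.raises(EnsembleError):
        sx.project_2d(sx.DissimilarityMatrix(2, np.array([1.0])))


# -- chi^2 annotation --------------------------------------------------

def test_identical_frames_to_generator_give_zero_chi2(two_domain, q_grid):
    s = two_domain[0]
    th = sx.debye_profile(s, q_grid)
    exp = sx.ScatteringCurve(q_grid, th.I, 0.02 * th.I)
    frames = np.stack([s.coord] * 4)
    chi2 = sx.annotate_chi2(frames, s.element, exp)
    np.testing.assert_allclose(chi2, 0.0, atol=1e-18)


def test_two_cluster_trajectory_orders_by_chi2(two_domain, q_grid):
    """Near-native frames score strictly better than swollen decoys."""
    s = two_domain[0]
    ens = syn.planted_ensemble(s, n_frames=60, mixture_weights=(0.5, 0.5),
                               seed=8)
    exp = syn.synth_saxs(s, q_grid, seed=9)
    chi2 = sx.annotate_chi2(ens.frames, ens.elements, exp, method="binned")
    assert np.median(chi2[ens.labels == 0]) < np.median(chi2[ens.labels == 1])


def test_annotation_preserves_frame_order(two_domain, q_grid):
    s = two_domain[0]
    ens = syn.planted_ensemble(s, n_frames=12, seed=10)
    exp = syn.synth_saxs(s, q_grid, seed=11)
    all_chi2 = sx.annotate_chi2(ens.frames, ens.elements, exp)
    one = sx.annotate_chi2(ens.frames[5:6], ens.elements, exp)
    assert all_chi2[5] == pytest.approx(one[0], rel=1e-12)


# -- selection ---------------------------------------------------------

def test_single_tight_cluster_selects_all_with_central_peak():
    rng = np.random.default_rng(12)
    xy = rng.normal(0, 0.3, (50, 2))
    chi2 = np.full(50, 1.0)
    sel = sx.EnsembleSelector(k=5).fit(xy, chi2).selection_
    assert len(sel.member_frames) == 50
    np.testing.assert_allclose(sel.density_peak, xy.mean(axis=0), atol=0.3)
    assert len(sel.representatives) == 5


def test_planted_majority_cluster_wins():
    """80/20 split of in-band frames: all representatives from the
    dominant cluster."""
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = rng.normal((-2, 0), 0.3, (80, 2))
        b = rng.normal((2, 0), 0.3, (20, 2))
        xy = np.vstack([a, b])
        chi2 = np.full(100, 1.0)
        sel = sx.EnsembleSelector(k=5).fit(xy, chi2).selection_
        if np.all(sel.representatives < 80):
            wins += 1
    assert wins >= 19


def test_out_of_band_frames_never_selected():
    rng = np.random.default_rng(13)
    xy = rng.normal(0, 1.0, (60, 2))
    chi2 = np.where(np.arange(60) < 30, 1.0, 5.0)
    sel = sx.select_ensemble(
        sx.Projection2D(xy, 0.0, 0, 1, True, np.zeros(1)), chi2)
    assert np.all(chi2[sel.member_frames] <= 1.1)
    assert set(sel.representatives) <= set(sel.member_frames)


def test_band_endpoints_inclusive():
    xy = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
    chi2 = np.array([0.9, 1.1, 0.8999, 1.1001])
    sel = sx.EnsembleSelector(k=2).fit(xy, chi2).selection_
    assert set(sel.member_frames) == {0, 1}


def test_k_larger_than_cluster_returns_whole_cluster_with_warning():
    xy = np.array([[0.0, 0], [0.1, 0], [0, 0.1]])
    chi2 = np.ones(3)
    with pytest.warns(RuntimeWarning, match="k=9"):
        sel = sx.EnsembleSelector(k=9).fit(xy, chi2).selection_
    assert len(sel.representatives) == 3
    assert sel.warning


def test_empty_band_raises_actionable_error():
    xy = np.zeros((5, 2))
    chi2 = np.full(5, 10.0)
    with pytest.raises(EnsembleError, match="widen"):
        sx.EnsembleSelector().fit(xy, chi2)


def test_band_filter_commutes_with_frame_permutation():
    rng = np.random.default_rng(14)
    xy = rng.normal(0, 1, (40, 2))
    chi2 = rng.uniform(0.5, 1.5, 40)
    sel = sx.EnsembleSelector(k=3).fit(xy, chi2).selection_
    perm = rng.permutation(40)
    sel_p = sx.EnsembleSelector(k=3).fit(xy[perm], chi2[perm]).selection_
    members_orig = set(sel.member_frames)
    members_perm = {perm[i] for i in sel_p.member_frames}
    assert members_orig == members_perm


def test_end_to_end_selection_recovers_generating_mode(two_domain, q_grid):
    """Planted two-mode trajectory + curve from the native mode: the
    selected representatives sit nearer the native than the decoy."""
    s = two_domain[0]
    ens = syn.planted_ensemble(s, n_frames=300, seed=20)
    exp = syn.synth_saxs(s, q_grid, seed=21)
    chi2 = sx.annotate_chi2(ens.frames, ens.elements, exp, method="binned")
    feats = sx.internal_distance_features(ens.frames, pair_sample=150,
                                          seed=22)
    proj = sx.project_2d(sx.dissimilarity(feats), seed=23, max_iter=60)
    sel = sx.select_ensemble(proj, chi2)
    r_native = np.mean([syn.rmsd(ens.frames[i], ens.modes[0])
                        for i in sel.representatives])
    r_decoy = np.mean([syn.rmsd(ens.frames[i], ens.modes[1])
                       for i in sel.representatives])
    assert r_native < r_decoy
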