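"""Star-coordinate projection, separation scoring, layout search."""

import itertools

import numpy as np
import pytest

from radargate import (
    ConfigurationError,
    EventMatrix,
    InputError,
    RadarLayout,
    default_layouts,
    optimize_layout,
    project_radar,
    separation_score,
)

from conftest import small_event_matrix


def scaled_matrix(values, markers):
    values = np.asarray(values, dtype=float)
    channels = tuple(f"c{i}" for i in range(values.shape[1]))
    return EventMatrix(values=values, channels=channels,
                       markers=dict(zip(channels, markers)))


class TestProjectRadar:
    def test_zero_event_maps_to_origin(self):
        em = scaled_matrix([[0.0, 0.0, 0.0]], ["A", "B", "C"])
        layout = RadarLayout(0, ("A", "B", "C"))
        np.testing.assert_allclose(project_radar(em, layout), [[0.0, 0.0]])

    def test_single_axis_contribution(self):
        em = scaled_matrix([[1.0, 0.0, 0.0, 0.0]], ["A", "B", "C", "D"])
        layout = RadarLayout(0, ("A", "B", "C", "D"))
        np.testing.assert_allclose(project_radar(em, layout), [[0.25, 0.0]],
                                   atol=1e-15)

    def test_symmetric_event_cancels_for_k3(self):
        em = scaled_matrix([[1.0, 1.0, 1.0]], ["A", "B", "C"])
        layout = RadarLayout(0, ("A", "B", "C"))
        np.testing.assert_allclose(project_radar(em, layout), [[0.0, 0.0]],
                                   atol=1e-15)

    def test_projection_linear_in_event_vector(self):
        rng = np.random.default_rng(0)
        x = rng.random((20, 5))
        y = rng.random((20, 5))
        layout = RadarLayout(0, tuple("ABCDE"))
        markers = list("ABCDE")
        p = lambda v: project_radar(scaled_matrix(v, markers), layout)
        np.testing.assert_allclose(p(0.5 * x + 0.5 * y),
                                   0.5 * p(x) + 0.5 * p(y), atol=1e-12)

    def test_cyclic_shift_rotates_projection(self):
        rng = np.random.default_rng(1)
        x = rng.random((100, 6))
        markers = list("ABCDEF")
        base = project_radar(scaled_matrix(x, markers), RadarLayout(0, tuple(markers)))
        shifted_layout = RadarLayout(0, tuple(markers[1:] + markers[:1]))
        shifted = project_radar(scaled_matrix(x, markers), shifted_layout)
        theta = -2 * np.pi / 6  # axis i moves to angle of axis i-1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        np.testing.assert_allclose(shifted, base @ rot.T, atol=1e-9)

    def test_points_stay_in_unit_disc(self):
        rng = np.random.default_rng(2)
        x = rng.random((1000, 7))
        layout = RadarLayout(0, tuple("ABCDEFG"))
        pts = project_radar(scaled_matrix(x, list("ABCDEFG")), layout)
        assert np.all(np.linalg.norm(pts, axis=1) <= 1.0 + 1e-12)

    def test_unscaled_input_rejected(self):
        em = scaled_matrix([[2.0, 0.0, 0.0]], ["A", "B", "C"])
        with pytest.raises(InputError, match="scaled"):
            project_radar(em, RadarLayout(0, ("A", "B", "C")))

    def test_missing_layout_channel_rejected(self):
        em = scaled_matrix([[0.5, 0.5]], ["A", "B"])
        with pytest.raises(ConfigurationError):
            project_radar(em, RadarLayout(0, ("A", "B", "Z")))


class TestSeparationScore:
    def test_identical_clouds_score_zero(self):
        pts = np.random.default_rng(0).normal(size=(100, 2))
        pts = np.vstack([pts, pts])
        labels = ["a"] * 100 + ["b"] * 100
        assert separation_score(pts, labels).aggregate == pytest.approx(0.0)

    def test_unit_variance_clouds_at_2root2_score_2(self):
        rng = np.random.default_rng(4)
        n = 200_000  # large n so empirical sigma^2 ~ 1
        a = rng.normal(size=(n, 2)) / np.sqrt(2)  # total variance 1
        b = a + np.array([2.0, 2.0])  # centroid distance 2*sqrt(2)
        score = separation_score(np.vstack([a, b]), ["a"] * n + ["b"] * n)
        assert score.aggregate == pytest.approx(2.0, rel=0.01)

    def test_aggregate_is_min_of_pairwise(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(loc, 0.3, size=(50, 2))
                         for loc in ([0, 0], [3, 0], [0, 5])])
        labels = np.repeat(["a", "b", "c"], 50)
        score = separation_score(pts, labels)
        pair_vals = []
        for g1, g2 in itertools.combinations("abc", 2):
            m = np.isin(labels, [g1, g2])
            pair_vals.append(separation_score(pts[m], labels[m]).aggregate)
        assert score.aggregate == pytest.approx(min(pair_vals))

    def test_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(300, 2))
        labels = np.repeat(["a", "b", "c"], 100)
        pts[100:200] += [4, 0]
        pts[200:] += [0, 6]
        base = separation_score(pts, labels).aggregate
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [10.0, -3.0]
        assert separation_score(moved, labels).aggregate == pytest.approx(base)

    def test_tiny_population_rejected(self):
        with pytest.raises(InputError):
            separation_score(np.zeros((3, 2)), ["a", "a", "b"])


def _gaussian_populations(rng, means, n=300):
    """Labelled event matrix with per-population channel means in [0,1]."""
    blocks, labels = [], []
    for name, mu in means.items():
        x = np.clip(rng.normal(mu, 0.05, size=(n, len(mu))), 0, 1)
        blocks.append(x)
        labels += [name] * n
    markers = [f"M{i}" for i in range(len(next(iter(means.values()))))]
    return scaled_matrix(np.vstack(blocks), markers), np.array(labels), markers


def _oracle_best(em, labels, markers):
    """Independent exhaustive search over circular orderings via projection."""
    from radargate.radar import circular_orderings

    best_score, best = -np.inf, None
    for order in circular_orderings(len(markers)):
        chans = tuple(markers[i] for i in order)
        pts = project_radar(em, RadarLayout(0, chans))
        s = separation_score(pts, labels).aggregate
        if s > best_score:
            best_score, best = s, chans
    return best_score, best


class TestOptimizeLayout:
    def test_k3_forced_single_ordering(self):
        rng = np.random.default_rng(7)
        em, labels, markers = _gaussian_populations(
            rng, {"a": [0.1, 0.5, 0.9], "b": [0.9, 0.1, 0.5]}
        )
        layout = optimize_layout(em, labels, channels=markers)
        assert set(layout.channels) == set(markers)
        assert layout.k == 3

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_matches_exhaustive_oracle(self, k):
        rng = np.random.default_rng(k)
        means = {
            "a": rng.random(k), "b": rng.random(k), "c": rng.random(k),
        }
        em, labels, markers = _gaussian_populations(rng, means, n=200)
        layout = optimize_layout(em, labels, channels=markers)
        oracle_score, _ = _oracle_best(em, labels, markers)
        pts = project_radar(em, layout)
        achieved = separation_score(pts, labels).aggregate
        assert achieved == pytest.approx(oracle_score, rel=1e-9)

    def test_beats_random_orderings(self):
        rng = np.random.default_rng(12)
        k = 6
        means = {"a": rng.random(k), "b": rng.random(k)}
        em, labels, markers = _gaussian_populations(rng, means, n=200)
        layout = optimize_layout(em, labels, channels=markers)
        best = separation_score(project_radar(em, layout), labels).aggregate
        for _ in range(1000):
            perm = tuple(np.array(markers)[rng.permutation(k)])
            s = separation_score(
                project_radar(em, RadarLayout(0, perm)), labels
            ).aggregate
            assert s <= best + 1e-9

    def test_noise_channel_excluded_by_subset_selection(self):
        rng = np.random.default_rng(21)
        # populations differ on M0..M3; M4 is pure noise around 0.5
        means = {
            "a": [0.1, 0.2, 0.8, 0.9, 0.5],
            "b": [0.9, 0.8, 0.2, 0.1, 0.5],
            "c": [0.1, 0.9, 0.1, 0.9, 0.5],
        }
        em, labels, markers = _gaussian_populations(rng, means, n=200)
        layout = optimize_layout(em, labels, channels=markers, k=4,
                                 select_subset=True)
        assert "M4" not in layout.channels
        # oracle over all 4-subsets and orderings
        best_score = -np.inf
        best_subset = None
        for combo in itertools.combinations(markers, 4):
            s, _ = _oracle_best(em, labels, list(combo))
            if s > best_score:
                best_score, best_subset = s, set(combo)
        assert set(layout.channels) == best_subset

    def test_single_population_rejected(self):
        rng = np.random.default_rng(1)
        em, labels, markers = _gaussian_populations(rng, {"a": [0.5, 0.5, 0.5]})
        with pytest.raises(InputError):
            optimize_layout(em, np.array(["a"] * em.n_events), channels=markers)


def test_default_layouts_follow_published_tube_lists():
    layouts = default_layouts()
    assert layouts[1].channels == ("SSC", "CD4", "CD64", "CD11b", "CD13",
                                   "HLA-DR", "CD14", "CD300e", "CD45")
    assert layouts[2].channels == ("CD15", "CD123", "SSC", "CD34", "CD13",
                                   "HLA-DR", "CD45")
    assert layouts[3].channels == ("CD34", "CD117", "CD56", "CD45", "CD33", "SSC")
    assert layouts[4].channels == ("cyFXIII-A", "cyMPO", "HLA-DR", "SSC",
                                   "CD117", "CD45")
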