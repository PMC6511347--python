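"""Star-coordinate (radar) projection and layout optimization.

Each of the K selected channels is assigned an axis at angle
2*pi*(i-1)/K on the unit circle (axis 1 at angle 0, counter-clockwise).
An event with scaled channel values x_1..x_K in [0, 1] projects to

    p = (1/K) * sum_i x_i * (cos theta_i, sin theta_i),

so every event lies in the unit disc.  The layout (which channels, in which
circular order) is what makes the morphology groups visually separate; it
can be optimized so that the worst-separated pair of labelled reference
populations is as far apart as possible, measured by the standardized
centroid distance

    s_ab = ||c_a - c_b|| / sqrt(sigma_a^2 + sigma_b^2),

with sigma^2 the mean squared distance of a population's projected points
to its own centroid.

The shipped default layouts are the published per-tube parameter orders:
tube 1: SSC, CD4, CD64, CD11b, CD13, HLA-DR, CD14, CD300e, CD45;
tube 2: CD15, CD123, SSC, CD34, CD13, HLA-DR, CD45;
tube 3: CD34, CD117, CD56, CD45, CD33, SSC;
tube 4: cyFXIII-A, cyMPO, HLA-DR, SSC, CD117, CD45.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .events import EventMatrix
from .panel import normalize_marker

_PROJECTION_TOL = 1e-9
MOMENT_SUBSAMPLE = 20_000


DEFAULT_LAYOUT_CHANNELS: dict[int, tuple[str, ...]] = {
    1: ("SSC", "CD4", "CD64", "CD11b", "CD13", "HLA-DR", "CD14", "CD300e", "CD45"),
    2: ("CD15", "CD123", "SSC", "CD34", "CD13", "HLA-DR", "CD45"),
    3: ("CD34", "CD117", "CD56", "CD45", "CD33", "SSC"),
    4: ("cyFXIII-A", "cyMPO", "HLA-DR", "SSC", "CD117", "CD45"),
}


@dataclass(frozen=True)
class RadarLayout:
    """An ordered set of channels on equally spaced radar axes."""

    tube_id: int
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.channels)
        if not (3 <= k <= 10):
            raise InputError(f"radar layout needs 3..10 channels, got {k}")
        keys = [normalize_marker(c) for c in self.channels]
        if len(set(keys)) != len(keys):
            raise InputError("radar layout channels must be unique")

    @property
    def k(self) -> int:
        return len(self.channels)

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.k) / self.k

    def unit_vectors(self) -> np.ndarray:
        """(K, 2) array of axis direction vectors."""
        a = self.angles
        return np.column_stack([np.cos(a), np.sin(a)])


def default_layouts() -> dict[int, RadarLayout]:
    return {t: RadarLayout(tube_id=t, channels=chs)
            for t, chs in DEFAULT_LAYOUT_CHANNELS.items()}


def project_radar(scaled: EventMatrix, layout: RadarLayout) -> np.ndarray:
    """Project scaled events to 2-D star coordinates; returns (n, 2)."""
    cols = []
    for ch in layout.channels:
        try:
            cols.append(scaled.marker_values(ch))
        except ConfigurationError as exc:
            raise ConfigurationError(f"layout channel missing: {exc}") from exc
    x = np.column_stack(cols)
    if x.size and (x.min() < -_PROJECTION_TOL or x.max() > 1.0 + _PROJECTION_TOL):
        raise InputError(
            "radar projection expects channels scaled to [0, 1]; "
            f"got range [{x.min():.3g}, {x.max():.3g}]"
        )
    return x @ layout.unit_vectors() / layout.k


# ---------------------------------------------------------------------------
# separation scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeparationScore:
    """Pairwise standardized centroid distances and their minimum."""

    pairwise: dict[tuple[str, str], float]
    aggregate: float

    def pair(self, a, b) -> float:
        key = (str(a), str(b)) if (str(a), str(b)) in self.pairwise else (str(b), str(a))
        return self.pairwise[key]


def _population_moments(points: np.ndarray, labels: np.ndarray):
    groups = {}
    for lab in np.unique(labels):
        pts = points[labels == lab]
        if pts.shape[0] < 2:
            raise InputError(f"population '{lab}' has fewer than 2 points")
        centroid = pts.mean(axis=0)
        var = float(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
        groups[str(lab)] = (centroid, var)
    return groups


def separation_score(points: np.ndarray, labels) -> SeparationScore:
    """Score how well labelled populations separate in the 2-D projection."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[1] != 2:
        raise InputError("points must be (n, 2)")
    groups = _population_moments(points, labels)
    if len(groups) < 2:
        raise InputError("separation score needs at least 2 populations")
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        (ca, va), (cb, vb) = groups[a], groups[b]
        denom = np.sqrt(va + vb)
        s = float(np.linalg.norm(ca - cb) / denom) if denom > 0 else np.inf
        if not np.isfinite(s):
            s = 0.0 if np.allclose(ca, cb) else np.inf
        pairwise[(a, b)] = s
    return SeparationScore(pairwise=pairwise, aggregate=min(pairwise.values()))


# ---------------------------------------------------------------------------
# layout optimization
# ---------------------------------------------------------------------------

def _axis_matrix(k: int) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(k) / k
    return np.column_stack([np.cos(angles), np.sin(angles)]) / k  # (K, 2)


def _score_ordering(order: tuple[int, ...], means, covs) -> float:
    """Separation aggregate from per-population channel moments.

    The projection is linear, so the projected centroid is the projection of
    the channel means and the projected total variance is trace(A Sigma A^T).
    This reproduces separation_score on the same event set exactly.
    """
    a = _axis_matrix(len(order))  # (K, 2)
    idx = list(order)
    cents = {g: mu[idx] @ a for g, mu in means.items()}
    variances = {g: float(np.trace(a.T @ cov[np.ix_(idx, idx)] @ a)) for g, cov in covs.items()}
    best = np.inf
    for g1, g2 in itertools.combinations(sorted(cents), 2):
        denom = np.sqrt(variances[g1] + variances[g2])
        s = float(np.linalg.norm(cents[g1] - cents[g2]) / denom) if denom > 0 else np.inf
        best = min(best, s)
    return best


def _canonical(order: tuple[int, ...], names: list[str]) -> tuple[str, ...]:
    """Normalize a circular ordering under rotation and reflection."""
    seqs = []
    n = len(order)
    for seq in (order, tuple(reversed(order))):
        for r in range(n):
            rot = seq[r:] + seq[:r]
            seqs.append(tuple(names[i] for i in rot))
    return min(seqs)


def circular_orderings(n_items: int):
    """Distinct circular orderings of range(n_items) up to rotation/reflection.

    The first item is fixed and reflections are removed by requiring the
    second element to be smaller than the last, giving (n-1)!/2 orderings
    (all of them for n = 3, where there is a single distinct ordering).
    """
    rest = list(range(1, n_items))
    for perm in itertools.permutations(rest):
        if perm[0] > perm[-1]:  # drop mirror images
            continue
        yield (0,) + perm


def optimize_layout(
    scaled: EventMatrix,
    labels,
    channels: list[str] | None = None,
    k: int | None = None,
    tube_id: int = 0,
    select_subset: bool = False,
    subsample: int = MOMENT_SUBSAMPLE,
    seed: int = 0,
) -> RadarLayout:
    """Find the circular channel ordering that best separates populations.

    Searches every distinct circular ordering (up to rotation/reflection)
    for K <= 9 and falls back to greedy insertion beyond.  With
    ``select_subset=True`` the best K-subset of the candidate channels is
    chosen by the same criterion.  Moments are computed on a seeded
    subsample of at most ``subsample`` events per population; ties are
    broken by the lexicographically smallest canonical channel sequence.
    """
    labels = np.asarray(labels)
    if channels is None:
        channels = [events_ch for events_ch in scaled.channels]
    names = list(channels)
    if k is None:
        k = len(names)
    if k > len(names):
        raise InputError(f"cannot place {k} axes with {len(names)} candidate channels")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise InputError("layout optimization needs at least 2 labelled populations")

    # per-population channel means / covariances on a seeded subsample
    data = np.column_stack([scaled.marker_values(ch) for ch in names])
    rng = np.random.default_rng(seed)
    means: dict[str, np.ndarray] = {}
    covs: dict[str, np.ndarray] = {}
    for lab in uniq:
        block = data[labels == lab]
        if block.shape[0] < 2:
            raise InputError(f"population '{lab}' has fewer than 2 points")
        if block.shape[0] > subsample:
            sel = rng.choice(block.shape[0], size=subsample, replace=False)
            block = block[np.sort(sel)]
        means[str(lab)] = block.mean(axis=0)
        covs[str(lab)] = np.cov(block, rowvar=False, bias=True)

    def search_orderings(subset_idx: list[int]):
        sub_names = [names[i] for i in subset_idx]
        sub_means = {g: mu[subset_idx] for g, mu in means.items()}
        sub_covs = {g: c[np.ix_(subset_idx, subset_idx)] for g, c in covs.items()}
        best_score, best_seq = -np.inf, None
        if k <= 9:
            candidates = circular_orderings(k)
        else:
            candidates = [_greedy_ordering(k, sub_means, sub_covs)]
        for order in candidates:
            s = _score_ordering(order, sub_means, sub_covs)
            seq = _canonical(order, sub_names)
            if s > best_score or (s == best_score and (best_seq is None or seq < best_seq)):
                best_score, best_seq = s, seq
        return best_score, best_seq

    if k < len(names):
        select_subset = True  # fewer axes than candidates forces a subset choice
    if select_subset and k < len(names):
        best = (-np.inf, None)
        for combo in itertools.combinations(range(len(names)), k):
            score, seq = search_orderings(list(combo))
            if score > best[0] or (score == best[0] and (best[1] is None or seq < best[1])):
                best = (score, seq)
        seq = best[1]
    else:
        _, seq = search_orderings(list(range(len(names))))
    return RadarLayout(tube_id=tube_id, channels=tuple(seq))


def _greedy_ordering(k: int, means, covs) -> tuple[int, ...]:
    """Greedy insertion heuristic for K beyond exhaustive reach."""
    order = [0, 1, 2]
    for nxt in range(3, k):
        best_pos, best_score = 0, -np.inf
        for pos in range(len(order) + 1):
            trial = tuple(order[:pos] + [nxt] + order[pos:])
            s = _score_ordering(trial, means, covs)
            if s > best_score:
                best_pos, best_score = pos, s
        order.insert(best_pos, nxt)
    return tuple(order)
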