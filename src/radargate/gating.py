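"""Blast gating on the CD45/SSC plot and marker-positivity calls.

Blasts are the CD45-dim population with variable side scatter.  The default
blast gate is a rectangle in scaled display coordinates (CD45 in
[0.15, 0.55], any SSC); the vertices are configurable per case.  Marker
positivity follows the conventional population-level thresholds: a blast
population is called positive for a marker when strictly more than 20% of
blasts (10% for cytoplasmic MPO) exceed the event-level intensity cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .errors import ConfigurationError, GeometryError, InputError
from .events import EventMatrix
from .panel import normalize_marker

DEFAULT_EVENT_CUTOFF = 0.25  # scaled display units
DEFAULT_THRESHOLD = 0.20
MPO_THRESHOLD = 0.10


@dataclass(frozen=True)
class PolygonGate:
    """A closed simple polygon on a 2-D (x marker, y marker) plot."""

    name: str
    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError(f"gate '{self.name}' needs at least 3 vertices")

    def polygon(self) -> shapely.Polygon:
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid or poly.area == 0.0:
            raise GeometryError(f"gate '{self.name}' polygon is not simple")
        return poly

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "x_channel": self.x_channel,
            "y_channel": self.y_channel,
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolygonGate":
        return cls(
            name=d["name"],
            x_channel=d["x_channel"],
            y_channel=d["y_channel"],
            vertices=tuple((float(x), float(y)) for x, y in d["vertices"]),
        )


def default_blast_gate(cd45_low: float = 0.15, cd45_high: float = 0.55) -> PolygonGate:
    """CD45-dim / SSC-variable rectangle in scaled coordinates."""
    return PolygonGate(
        name="blasts",
        x_channel="CD45",
        y_channel="SSC",
        vertices=(
            (cd45_low, 0.0),
            (cd45_high, 0.0),
            (cd45_high, 1.0),
            (cd45_low, 1.0),
        ),
    )


def points_in_polygon(points: np.ndarray, polygon: shapely.Polygon) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test; boundary counts as inside."""
    pts = shapely.points(np.asarray(points, dtype=float))
    return shapely.covers(polygon, pts)


def apply_polygon_gate(events: EventMatrix, gate: PolygonGate) -> np.ndarray:
    """Boolean membership mask for *events* against *gate*.

    Raises a configuration error when either gate channel is missing and a
    geometry error for self-intersecting polygons.
    """
    try:
        x = events.marker_values(gate.x_channel)
        y = events.marker_values(gate.y_channel)
    except ConfigurationError as exc:
        raise ConfigurationError(f"gate '{gate.name}': {exc}") from exc
    return points_in_polygon(np.column_stack([x, y]), gate.polygon())


@dataclass
class BlastPopulation:
    """Result of blast gating: the subset, its share of the tube, flags."""

    events: EventMatrix | None
    fraction: float
    zero_blast: bool

    @property
    def n_blasts(self) -> int:
        return 0 if self.events is None else self.events.n_events


def gate_blasts(events: EventMatrix, gate: PolygonGate | None = None) -> BlastPopulation:
    """Select the blast population on the CD45/SSC bivariate plot."""
    gate = gate or default_blast_gate()
    mask = apply_polygon_gate(events, gate)
    fraction = float(np.mean(mask)) if events.n_events else 0.0
    if not mask.any():
        warnings.warn("blast gate selected zero events; case not classifiable",
                      stacklevel=2)
        return BlastPopulation(events=None, fraction=0.0, zero_blast=True)
    subset = events.subset(mask).with_label("population", "blast")
    return BlastPopulation(events=subset, fraction=fraction, zero_blast=False)


@dataclass(frozen=True)
class PositivityRule:
    """Event cutoff plus population threshold for one marker.

    ``threshold`` is the population-level fraction that must be *strictly*
    exceeded for a positive call: 0.10 for cyMPO, 0.20 for everything else.
    ``cutoff`` is the event-level intensity (in scaled display units) above
    which a single event counts as positive.
    """

    marker: str
    cutoff: float = DEFAULT_EVENT_CUTOFF
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise InputError("population threshold must be in (0, 1)")
        if not np.isfinite(self.cutoff):
            raise InputError("event cutoff must be finite")


def default_positivity_rule(marker: str, cutoff: float = DEFAULT_EVENT_CUTOFF) -> PositivityRule:
    threshold = MPO_THRESHOLD if normalize_marker(marker) == "CYMPO" else DEFAULT_THRESHOLD
    return PositivityRule(marker=marker, cutoff=cutoff, threshold=threshold)


@dataclass(frozen=True)
class PositivityResult:
    marker: str
    fraction: float
    positive: bool


def marker_positivity(blasts: EventMatrix, rule: PositivityRule) -> PositivityResult:
    """Fraction of blasts above the event cutoff and the population call."""
    if blasts is None or blasts.n_events == 0:
        raise InputError("marker positivity needs a nonempty blast population")
    intensities = blasts.marker_values(rule.marker)
    fraction = float(np.mean(intensities > rule.cutoff))
    return PositivityResult(
        marker=rule.marker, fraction=fraction, positive=bool(fraction > rule.threshold)
    )
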