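"""Screening-template construction: 95%-containment gates in radar space.

The template is the trained screening instrument.  For each tube it stores
the radar layout, the frozen channel scaling, the CD45/SSC blast gate, and
two gate regions — hypergranular and microgranular — each built from the
merged, projected blasts of the reference APL cases of that type.

A gate region is the polygonized outer contour of the smallest
highest-density region (Gaussian KDE, Scott bandwidth) that holds at least
the requested fraction (default 95%) of the merged reference blasts.  The
achieved containment is verified by an exact point-in-polygon recount and
the polygon is dilated about its centroid when the recount falls short.  On
top of the merged-reference criterion, template building dilates each gate
until every individual reference case has at least the cutoff fraction of
its own blasts inside — the property the protocol is defined by (each
reference case must sit inside its group's gate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure

from .errors import InputError, TemplateError
from .events import EventMatrix
from .gating import PolygonGate, default_blast_gate, gate_blasts, points_in_polygon
from .panel import PanelConfig, default_panel
from .preprocess import ScalingRef, fit_scaling, scale_to_unit
from .radar import RadarLayout, default_layouts, optimize_layout, project_radar

DENSITY_GRID_SIZE = 64
KDE_GRID_SIZE = 256
GATE_VERTICES = 128
MIN_GATE_POINTS = 500


# ---------------------------------------------------------------------------
# gate regions
# ---------------------------------------------------------------------------

@dataclass
class GateRegion:
    """A closed polygon in radar space plus the reference density pattern."""

    gate_type: str
    tube_id: int
    vertices: np.ndarray  # (m, 2)
    density_grid: np.ndarray  # (64, 64), sums to 1
    grid_bbox: tuple[float, float, float, float]  # x0, x1, y0, y1
    containment: float
    flags: dict = field(default_factory=dict)

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def area(self) -> float:
        return float(self.polygon().area)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return points_in_polygon(points, self.polygon())

    def dilate(self, factor: float) -> "GateRegion":
        """Scale the polygon outward about its centroid."""
        c = self.vertices.mean(axis=0)
        return GateRegion(
            gate_type=self.gate_type,
            tube_id=self.tube_id,
            vertices=c + factor * (self.vertices - c),
            density_grid=self.density_grid,
            grid_bbox=self.grid_bbox,
            containment=self.containment,
            flags=dict(self.flags),
        )

    def to_dict(self) -> dict:
        return {
            "gate_type": self.gate_type,
            "tube_id": int(self.tube_id),
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
            "density_grid": [float(v) for v in self.density_grid.ravel()],
            "grid_shape": list(self.density_grid.shape),
            "grid_bbox": [float(v) for v in self.grid_bbox],
            "containment": float(self.containment),
            "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateRegion":
        shape = tuple(d.get("grid_shape", (DENSITY_GRID_SIZE, DENSITY_GRID_SIZE)))
        grid = np.asarray(d["density_grid"], dtype=float).reshape(shape)
        return cls(
            gate_type=d["gate_type"],
            tube_id=int(d["tube_id"]),
            vertices=np.asarray(d["vertices"], dtype=float),
            density_grid=grid,
            grid_bbox=tuple(float(v) for v in d["grid_bbox"]),
            containment=float(d["containment"]),
            flags=dict(d.get("flags", {})),
        )


def _resample_closed(loop: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n vertices at equal arc length."""
    if not np.allclose(loop[0], loop[-1]):
        loop = np.vstack([loop, loop[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return loop[:-1][:n]
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, loop[:, 0])
    y = np.interp(targets, s, loop[:, 1])
    return np.column_stack([x, y])


def _pattern_grid(points: np.ndarray, bbox, size: int = DENSITY_GRID_SIZE) -> np.ndarray:
    x0, x1, y0, y1 = bbox
    hist, _, _ = np.histogram2d(
        points[:, 0], points[:, 1], bins=size, range=[[x0, x1], [y0, y1]]
    )
    total = hist.sum()
    if total == 0:
        return np.full((size, size), 1.0 / size**2)
    return hist / total


def build_gate(
    points: np.ndarray,
    containment: float = 0.95,
    gate_type: str = "",
    tube_id: int = 0,
    kde_grid: int = KDE_GRID_SIZE,
    n_vertices: int = GATE_VERTICES,
) -> GateRegion:
    """Build the smallest 2-D highest-density-region gate around *points*.

    Density is estimated with a Gaussian kernel (Scott's rule bandwidth) on
    a binned grid; the gate polygon is the outer contour at the density
    level that keeps at least ``containment`` of the points.  A disconnected
    region falls back to the convex hull of its contours (flagged).  The
    achieved containment is recomputed by exact point-in-polygon count and
    the polygon is minimally dilated when the recount falls short.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise InputError("points must be (n, 2)")
    n = points.shape[0]
    if n < MIN_GATE_POINTS:
        raise InputError(f"gate construction needs >= {MIN_GATE_POINTS} points, got {n}")
    if not (0.5 < containment < 1.0):
        raise InputError("containment must lie in (0.5, 1)")

    span = points.max(axis=0) - points.min(axis=0)
    if np.all(span < 1e-12):  # degenerate: all points identical
        c = points[0]
        eps = 1e-6
        vertices = np.array(
            [[c[0] - eps, c[1] - eps], [c[0] + eps, c[1] - eps],
             [c[0] + eps, c[1] + eps], [c[0] - eps, c[1] + eps]]
        )
        bbox = (c[0] - eps, c[0] + eps, c[1] - eps, c[1] + eps)
        return GateRegion(
            gate_type=gate_type, tube_id=tube_id, vertices=vertices,
            density_grid=_pattern_grid(points, bbox), grid_bbox=bbox,
            containment=1.0, flags={"degenerate": True, "n_reference": n},
        )

    # Scott's rule per dimension, floored to avoid zero bandwidth
    std = points.std(axis=0, ddof=1)
    bw = np.maximum(std, 1e-9 * max(span.max(), 1e-12)) * n ** (-1.0 / 6.0)

    pad = 4.0 * bw
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    hist, xedges, yedges = np.histogram2d(
        points[:, 0], points[:, 1], bins=kde_grid, range=[[lo[0], hi[0]], [lo[1], hi[1]]]
    )
    cell = (hi - lo) / kde_grid
    density = ndimage.gaussian_filter(hist, sigma=bw / cell, mode="constant")

    # density at each point (bilinear on bin centers)
    centers_x = (xedges[:-1] + xedges[1:]) / 2.0
    centers_y = (yedges[:-1] + yedges[1:]) / 2.0
    fx = np.clip((points[:, 0] - centers_x[0]) / cell[0], 0, kde_grid - 1)
    fy = np.clip((points[:, 1] - centers_y[0]) / cell[1], 0, kde_grid - 1)
    dens_at_points = ndimage.map_coordinates(density, [fx, fy], order=1, mode="nearest")

    level = float(np.quantile(dens_at_points, 1.0 - containment))
    level = min(level, float(density.max()) * (1 - 1e-12))

    contours = measure.find_contours(density, level)
    contours = [c for c in contours if len(c) >= 4]
    flags: dict = {"n_reference": int(n)}
    if not contours:
        # level above grid maximum (pathological); fall back to convex hull
        hull = shapely.MultiPoint(points).convex_hull
        loop = np.asarray(hull.exterior.coords)
        flags["hull_fallback"] = True
    elif len(contours) == 1:
        loop = _grid_to_data(contours[0], centers_x, centers_y, cell)
    else:
        pts = np.vstack([_grid_to_data(c, centers_x, centers_y, cell) for c in contours])
        hull = shapely.MultiPoint(pts).convex_hull
        loop = np.asarray(hull.exterior.coords)
        flags["disconnected_hdr"] = True

    vertices = _resample_closed(np.asarray(loop, dtype=float), n_vertices)
    poly = shapely.Polygon(vertices)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        vertices = _resample_closed(np.asarray(poly.exterior.coords), n_vertices)

    # exact recount; dilate outward minimally if short of target
    achieved = float(np.mean(points_in_polygon(points, shapely.Polygon(vertices))))
    factor = 1.0
    centroid = vertices.mean(axis=0)
    while achieved < containment and factor < 5.0:
        factor *= 1.02
        trial = centroid + factor * (vertices - centroid)
        achieved = float(np.mean(points_in_polygon(points, shapely.Polygon(trial))))
    if factor > 1.0:
        vertices = centroid + factor * (vertices - centroid)
        flags["dilated_factor"] = round(factor, 6)

    bbox = (
        float(vertices[:, 0].min()), float(vertices[:, 0].max()),
        float(vertices[:, 1].min()), float(vertices[:, 1].max()),
    )
    return GateRegion(
        gate_type=gate_type, tube_id=tube_id, vertices=vertices,
        density_grid=_pattern_grid(points, bbox), grid_bbox=bbox,
        containment=achieved, flags=flags,
    )


def _grid_to_data(contour: np.ndarray, cx: np.ndarray, cy: np.ndarray, cell) -> np.ndarray:
    return np.column_stack([cx[0] + contour[:, 0] * cell[0], cy[0] + contour[:, 1] * cell[1]])


# ---------------------------------------------------------------------------
# the cohort template
# ---------------------------------------------------------------------------

@dataclass
class TubeTemplate:
    layout: RadarLayout
    scaling: ScalingRef
    gates: dict[str, GateRegion]  # keys: hypergranular, microgranular


@dataclass
class CohortTemplate:
    """Per-tube layouts, frozen scaling and APL gates; the trained screen."""

    panel: PanelConfig
    tubes: dict[int, TubeTemplate]
    blast_gate: PolygonGate
    cutoff: float = 95.0  # percent
    provenance: dict = field(default_factory=dict)
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 100.0):
            raise TemplateError(f"cutoff must lie in (0, 100), got {self.cutoff}")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "cutoff": float(self.cutoff),
            "panel": self.panel.to_dict(),
            "blast_gate": self.blast_gate.to_dict(),
            "tubes": {
                str(t): {
                    "layout": list(tt.layout.channels),
                    "scaling": tt.scaling.to_dict(),
                    "gates": {k: g.to_dict() for k, g in tt.gates.items()},
                }
                for t, tt in sorted(self.tubes.items())
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortTemplate":
        try:
            panel = PanelConfig.from_dict(d["panel"])
            tubes = {}
            for t_str, td in d["tubes"].items():
                t = int(t_str)
                tubes[t] = TubeTemplate(
                    layout=RadarLayout(tube_id=t, channels=tuple(td["layout"])),
                    scaling=ScalingRef.from_dict(td["scaling"]),
                    gates={k: GateRegion.from_dict(g) for k, g in td["gates"].items()},
                )
            template = cls(
                panel=panel,
                tubes=tubes,
                blast_gate=PolygonGate.from_dict(d["blast_gate"]),
                cutoff=float(d["cutoff"]),
                provenance=dict(d.get("provenance", {})),
                schema_version=int(d.get("schema_version", 1)),
            )
        except TemplateError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise TemplateError(f"template schema violation at {exc!r}") from exc
        template.validate()
        return template

    def validate(self) -> None:
        if not self.tubes:
            raise TemplateError("template has no tubes")
        for t, tt in self.tubes.items():
            for key, gate in tt.gates.items():
                total = float(gate.density_grid.sum())
                if abs(total - 1.0) > 1e-9:
                    raise TemplateError(
                        f"tubes.{t}.gates.{key}.density_grid sums to {total}, not 1"
                    )
                if gate.vertices.shape[0] < 3:
                    raise TemplateError(f"tubes.{t}.gates.{key}.vertices: fewer than 3")


def save_template(template: CohortTemplate, path) -> None:
    with open(path, "w") as fh:
        json.dump(template.to_dict(), fh, sort_keys=True, separators=(",", ":"))


def load_template(path) -> CohortTemplate:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise TemplateError(f"cannot load template {path}: {exc}") from exc
    return CohortTemplate.from_dict(d)


# ---------------------------------------------------------------------------
# template building
# ---------------------------------------------------------------------------

def _case_id_of(tubes: Mapping[int, EventMatrix], fallback: str) -> str:
    for em in tubes.values():
        if "case_id" in em.labels and em.n_events:
            return str(np.asarray(em.labels["case_id"])[0])
    return fallback


def build_template(
    hypergranular: Sequence[Mapping[int, EventMatrix]],
    microgranular: Sequence[Mapping[int, EventMatrix]],
    panel: PanelConfig | None = None,
    layouts: Mapping[int, RadarLayout] | str | None = None,
    containment: float = 0.95,
    blast_gate: PolygonGate | None = None,
    per_case_containment: bool = True,
    provenance: dict | None = None,
) -> CohortTemplate:
    """Train the screening template from reference APL cases.

    Each reference case is a mapping tube_id -> EventMatrix of that tube's
    full acquisition.  Per tube, the channel scaling is fit on the merged
    reference events and frozen; blasts are selected per case with the
    CD45/SSC blast gate; hypergranular and microgranular blasts are merged
    separately, projected with the tube layout, and enclosed in 95%-HDR
    gates.  With ``per_case_containment`` (default) each gate is further
    dilated until every individual reference case of its type reaches the
    containment level — the defining property of the protocol.

    ``layouts`` may be a mapping of prebuilt layouts, the string
    ``"optimize"`` (search the ordering that separates hypergranular,
    microgranular and non-blast events best), or None for the published
    per-tube defaults.
    """
    panel = panel or default_panel()
    if len(hypergranular) < 1:
        raise InputError("need at least one hypergranular reference case")
    if len(microgranular) < 1:
        raise InputError("need at least one microgranular reference case")
    blast_gate = blast_gate or default_blast_gate()

    groups = [("hypergranular", hypergranular), ("microgranular", microgranular)]
    for gname, cases in groups:
        for i, case in enumerate(cases):
            for t in panel.tube_ids:
                if t not in case:
                    cid = _case_id_of(case, f"{gname}[{i}]")
                    raise InputError(f"reference case {cid} is missing tube {t}")

    if layouts is None:
        layout_map = {t: l for t, l in default_layouts().items() if t in panel.tube_ids}
    elif layouts == "optimize":
        layout_map = None  # filled per tube below
    else:
        layout_map = dict(layouts)

    tube_data: dict[int, tuple] = {}
    gate_provenance: dict[str, dict] = {}
    for t in panel.tube_ids:
        merged_all = np.vstack(
            [case[t].values for _, cases in groups for case in cases]
        )
        ref_events = EventMatrix(
            values=merged_all,
            channels=groups[0][1][0][t].channels,
            markers=dict(groups[0][1][0][t].markers),
        )
        scaling = fit_scaling(ref_events)

        projected: dict[str, list[np.ndarray]] = {"hypergranular": [], "microgranular": []}
        if layout_map is not None:
            layout = layout_map[t]
        else:
            layout = _optimized_layout(t, groups, scaling, blast_gate)

        per_case_points: dict[str, list[np.ndarray]] = {"hypergranular": [], "microgranular": []}
        for gname, cases in groups:
            for case in cases:
                scaled = scale_to_unit(case[t], scaling)
                blasts = gate_blasts(scaled, blast_gate)
                if blasts.zero_blast:
                    cid = _case_id_of(case, gname)
                    raise InputError(f"reference case {cid}, tube {t}: no blasts in gate")
                pts = project_radar(blasts.events, layout)
                projected[gname].append(pts)
                per_case_points[gname].append(pts)

        base_gates: dict[str, GateRegion] = {}
        for gname, _ in groups:
            base_gates[gname] = build_gate(
                np.vstack(per_case_points[gname]), containment=containment,
                gate_type=gname, tube_id=t,
            )
            gate_provenance[f"tube{t}.{gname}"] = {
                "n_cases": len(per_case_points[gname]),
                "n_blasts": int(np.vstack(projected[gname]).shape[0]),
            }
        tube_data[t] = (layout, scaling, per_case_points, base_gates)

    # predictive calibration: leave-one-out dilation samples pooled over all
    # tubes and both gate types, one uniform factor for the whole template
    loo_samples: list[float] = []
    if per_case_containment:
        for t, (_, _, per_case_points, _) in tube_data.items():
            for gname, _ in groups:
                loo_samples += _loo_factors(per_case_points[gname],
                                            containment, gname, t)
    factor = predictive_dilation_factor(loo_samples)

    tubes: dict[int, TubeTemplate] = {}
    for t, (layout, scaling, per_case_points, base_gates) in tube_data.items():
        gates: dict[str, GateRegion] = {}
        for gname, gate in base_gates.items():
            case_points = per_case_points[gname]
            if per_case_containment:
                gate = _calibrate_gate(gate, case_points,
                                       np.vstack(case_points), containment,
                                       factor)
            gates[gname] = gate
        tubes[t] = TubeTemplate(layout=layout, scaling=scaling, gates=gates)

    prov = {
        "hypergranular_cases": [
            _case_id_of(c, f"hyper[{i}]") for i, c in enumerate(hypergranular)
        ],
        "microgranular_cases": [
            _case_id_of(c, f"micro[{i}]") for i, c in enumerate(microgranular)
        ],
        "gates": gate_provenance,
        "calibration_factor": round(factor, 6),
        "n_loo_samples": len(loo_samples),
    }
    prov.update(provenance or {})
    return CohortTemplate(
        panel=panel,
        tubes=tubes,
        blast_gate=blast_gate,
        cutoff=containment * 100.0,
        provenance=prov,
    )


def _dilation_for(gate: GateRegion, points: np.ndarray, containment: float,
                  step: float = 1.02, cap: float = 5.0) -> float:
    """Smallest centroid dilation factor giving *points* the containment."""
    factor = 1.0
    while float(np.mean(gate.dilate(factor).contains(points))) < containment:
        factor *= step
        if factor >= cap:
            return cap
    return factor


#: design level for the predictive calibration: the gate aims to cover the
#: (1 - alpha) quantile of future same-type cases.  The screening claim is
#: that *every* APL case clears the cutoff in *every* tube, so the per-tube
#: failure budget must be well below one in a practical cohort's worth of
#: tube measurements.
PREDICTIVE_ALPHA = 0.001


def _loo_factors(case_points: list[np.ndarray], containment: float,
                 gate_type: str, tube_id: int) -> list[float]:
    """Leave-one-out samples of the dilation a new same-type case needs.

    For each reference case a gate is rebuilt from the remaining cases and
    the centroid-dilation factor needed for the left-out case to reach the
    containment level is recorded (empty when fewer than two cases exist).
    """
    n = len(case_points)
    if n < 2:
        return []
    factors = []
    for i in range(n):
        rest = np.vstack([p for j, p in enumerate(case_points) if j != i])
        loo_gate = build_gate(rest, containment=containment,
                              gate_type=gate_type, tube_id=tube_id)
        factors.append(_dilation_for(loo_gate, case_points[i], containment))
    return factors


def predictive_dilation_factor(loo_samples: list[float],
                               alpha: float = PREDICTIVE_ALPHA) -> float:
    """The uniform gate dilation that covers the (1 - alpha) future case.

    The gate must predict where the blasts of a future case of its type
    fall.  With a handful of reference cases, the raw highest-density region
    of the merged reference hugs the training points, so an exchangeable new
    case lands at the containment level only on average.  Calibration uses
    no non-reference data:

    * ``loo_samples`` are leave-one-out dilation factors pooled across all
      tubes and both APL types (see :func:`_loo_factors`).  A dilation
      factor is dimensionless and the case-to-case variation it measures —
      staining efficiency, instrument day effects, biological intensity
      spread — is a property of cases, common to tubes and groups, so
      pooling is the standard small-sample move and protects a tube in
      which the few reference cases happen to agree;
    * extreme-value allowance: the max of n pooled samples estimates only
      the ~n/(n+1) quantile of the dilation a future case needs, so the
      log of the maximum is inflated by sqrt(log(1/alpha) / log(n + 1)),
      targeting roughly the (1 - alpha) quantile instead.  The allowance
      shrinks toward 1 as reference cases accumulate.

    Screening specificity tolerates the generous margin because the
    conjunctive all-tubes rule only fails when a non-APL case mimics the
    reference phenotype in every tube at once.
    """
    samples = [f for f in loo_samples if f > 0]
    if not samples or max(samples) <= 1.0:
        return 1.0
    n = len(samples)
    allowance = np.sqrt(np.log(1.0 / alpha) / np.log(n + 1.0))
    return float(np.exp(allowance * np.log(max(samples))))


def _calibrate_gate(
    gate: GateRegion,
    case_points: list[np.ndarray],
    merged_pts: np.ndarray,
    containment: float,
    factor: float,
) -> GateRegion:
    """Apply the predictive dilation and enforce in-sample containment."""
    calibrated = gate.dilate(factor) if factor > 1.0 else gate
    # in-sample guarantee: every reference case at or above the level
    worst_needed = max(
        _dilation_for(calibrated, pts, containment) for pts in case_points
    )
    if worst_needed > 1.0:
        calibrated = calibrated.dilate(worst_needed)
        factor *= worst_needed
    calibrated.containment = float(np.mean(calibrated.contains(merged_pts)))
    calibrated.flags["calibration_factor"] = round(factor, 6)
    calibrated.flags["worst_case_containment"] = round(
        min(float(np.mean(calibrated.contains(p))) for p in case_points), 6
    )
    return calibrated


def _optimized_layout(tube_id, groups, scaling, blast_gate) -> RadarLayout:
    """Layout search: separate hyper- from microgranular reference blasts."""
    blocks, labels = [], []
    for gname, cases in groups:
        for case in cases:
            scaled = scale_to_unit(case[tube_id], scaling)
            blasts = gate_blasts(scaled, blast_gate)
            if blasts.zero_blast:
                continue
            blocks.append(blasts.events.values)
            labels.append(np.full(blasts.events.n_events, gname, dtype=object))
    first = None
    for _, cases in groups:
        for case in cases:
            first = case[tube_id]
            break
        break
    merged = EventMatrix(
        values=np.vstack(blocks), channels=first.channels, markers=dict(first.markers)
    )
    candidates = [first.markers[ch] for ch in first.channels
                  if first.markers.get(ch, "") != "FSC"]
    k = min(len(candidates), 9)
    return optimize_layout(
        merged, np.concatenate(labels), channels=candidates, k=k, tube_id=tube_id
    )
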