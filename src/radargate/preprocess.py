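"""Spillover compensation and channel scaling to the unit interval.

Radar projections need all channels on a common bounded scale.  Fluorescence
channels are transformed with the inverse hyperbolic sine (cofactor 150, the
usual choice for digital cytometers); scatter channels stay linear.  Each
channel is then mapped affinely to [0, 1] using low/high quantile anchors of
a reference event set, and clipped.  The anchors are fit once on the
template-building cohort and frozen into the screening template so that test
cases land on exactly the same display scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError, NumericalError
from .events import EventMatrix

DEFAULT_COFACTOR = 150.0
DEFAULT_Q_LOW = 0.001
DEFAULT_Q_HIGH = 0.999

_SCATTER_MARKERS = {"FSC", "SSC"}


def is_scatter_channel(channel: str, marker: str | None = None) -> bool:
    name = (marker or channel).upper()
    return name.startswith("FSC") or name.startswith("SSC")


def asinh_transform(x: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


# ---------------------------------------------------------------------------
# compensation
# ---------------------------------------------------------------------------

def compensate(events: EventMatrix, spillover: np.ndarray,
               channels: list[str] | None = None) -> EventMatrix:
    """Remove fluorescence spillover by solving the linear mixing model.

    The convention used throughout the package: ``spillover[i, j]`` is the
    fraction of true signal from channel *j* read by detector *i*, so the
    observed event row satisfies ``observed = true @ spillover.T`` and the
    corrected values solve that system.  With
    ``S = [[1, 0.1], [0, 1]]`` an observed event ``(110, 100)`` corrects to
    ``(100, 100)``.  Scatter channels are untouched.
    """
    S = np.asarray(spillover, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ConfigurationError(f"spillover matrix must be square, got shape {S.shape}")
    if channels is None:
        channels = [ch for ch in events.channels
                    if not is_scatter_channel(ch, events.markers.get(ch))]
    if S.shape[0] != len(channels):
        raise ConfigurationError(
            f"spillover is {S.shape[0]}x{S.shape[0]} but there are "
            f"{len(channels)} fluorescence channels"
        )
    idx = [events.channel_index(ch) for ch in channels]
    raw = events.values[:, idx]
    try:
        corrected = np.linalg.solve(S, raw.T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular spillover matrix: {exc}") from exc
    out = events.values.copy()
    out[:, idx] = corrected
    return events.with_values(out)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingRef:
    """Frozen per-channel transform + unit-interval anchors.

    ``kinds[ch]`` is ``"asinh"`` or ``"linear"``; ``low``/``high`` are the
    anchors in *transformed* units.  Channels whose reference values were
    constant are widened by an epsilon margin and listed in ``degenerate``.
    """

    channels: tuple[str, ...]
    kinds: dict[str, str]
    low: dict[str, float]
    high: dict[str, float]
    cofactor: float = DEFAULT_COFACTOR
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    def transform(self, channel: str, x: np.ndarray) -> np.ndarray:
        if self.kinds[channel] == "asinh":
            return asinh_transform(x, self.cofactor)
        return np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "kinds": {c: self.kinds[c] for c in self.channels},
            "low": {c: float(self.low[c]) for c in self.channels},
            "high": {c: float(self.high[c]) for c in self.channels},
            "cofactor": float(self.cofactor),
            "degenerate": list(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingRef":
        return cls(
            channels=tuple(d["channels"]),
            kinds=dict(d["kinds"]),
            low={k: float(v) for k, v in d["low"].items()},
            high={k: float(v) for k, v in d["high"].items()},
            cofactor=float(d["cofactor"]),
            degenerate=tuple(d.get("degenerate", ())),
        )


def fit_scaling(
    reference: EventMatrix,
    q_low: float = DEFAULT_Q_LOW,
    q_high: float = DEFAULT_Q_HIGH,
    cofactor: float = DEFAULT_COFACTOR,
) -> ScalingRef:
    """Fit per-channel unit-interval anchors on a reference event set.

    Anchors are the empirical (q_low, q_high) quantiles of the transformed
    reference values.  Constant channels are flagged degenerate and their
    anchors widened by a machine-epsilon-scaled margin so the affine map
    stays well defined.
    """
    if reference.n_events == 0:
        raise InputError("cannot fit scaling on an empty reference")
    if not (0.0 <= q_low < q_high <= 1.0):
        raise InputError(f"require 0 <= q_low < q_high <= 1, got ({q_low}, {q_high})")

    kinds: dict[str, str] = {}
    low: dict[str, float] = {}
    high: dict[str, float] = {}
    degenerate: list[str] = []
    for ch in reference.channels:
        kind = "linear" if is_scatter_channel(ch, reference.markers.get(ch)) else "asinh"
        kinds[ch] = kind
        t = asinh_transform(reference.channel_values(ch), cofactor) if kind == "asinh" \
            else reference.channel_values(ch).astype(float)
        lo, hi = float(np.quantile(t, q_low)), float(np.quantile(t, q_high))
        if hi <= lo:
            margin = max(abs(lo), 1.0) * np.finfo(float).eps * 1e3
            lo, hi = lo - margin, lo + margin
            degenerate.append(ch)
        low[ch], high[ch] = lo, hi
    return ScalingRef(
        channels=tuple(reference.channels),
        kinds=kinds,
        low=low,
        high=high,
        cofactor=cofactor,
        degenerate=tuple(degenerate),
    )


def scale_to_unit(events: EventMatrix, ref: ScalingRef) -> EventMatrix:
    """Map every channel to [0, 1] via the frozen transform and anchors.

    Values below the low anchor clip to 0 and above the high anchor to 1;
    the map is monotone on every channel.
    """
    missing = [ch for ch in events.channels if ch not in ref.kinds]
    if missing:
        raise ConfigurationError(f"scaling reference lacks channels {missing}")
    out = np.empty_like(events.values)
    for j, ch in enumerate(events.channels):
        t = ref.transform(ch, events.values[:, j])
        out[:, j] = np.clip((t - ref.low[ch]) / (ref.high[ch] - ref.low[ch]), 0.0, 1.0)
    scaled = events.with_values(out)
    scaled.metadata["scaled"] = True
    return scaled
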