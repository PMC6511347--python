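"""The in-memory list-mode container: events x channels with marker mapping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, MergeError
from .panel import normalize_marker


@dataclass
class EventMatrix:
    """A rectangular events-by-channels block of cytometry measurements.

    Parameters
    ----------
    values
        ``(n_events, n_channels)`` float array of fluorescence/scatter
        intensities (arbitrary units; raw or transformed).
    channels
        Unique channel (detector) names, one per column.
    markers
        Mapping channel name -> marker name (``"FSC"``/``"SSC"`` for the
        scatter channels).
    labels
        Optional per-event tags, each an array of length ``n_events``
        (conventionally ``case_id`` and ``population``).
    metadata
        Free-form acquisition keywords (e.g. the parsed FCS TEXT segment,
        a spillover matrix).
    """

    values: np.ndarray
    channels: tuple[str, ...]
    markers: dict[str, str] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D events x channels array")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.values.shape[1]:
            raise InputError(
                f"{len(self.channels)} channel names for {self.values.shape[1]} columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise InputError("channel names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise InputError("event values must be finite")
        for key, arr in self.labels.items():
            if len(arr) != self.values.shape[0]:
                raise InputError(f"label '{key}' length does not match event count")

    # -- basic accessors -----------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise ConfigurationError(f"channel '{channel}' not present") from None

    def marker_channel(self, marker: str) -> str:
        """Channel carrying *marker* (normalized match; scatter by name too)."""
        key = normalize_marker(marker)
        for ch, m in self.markers.items():
            if normalize_marker(m) == key:
                return ch
        for ch in self.channels:  # allow direct channel-name addressing
            if normalize_marker(ch) == key:
                return ch
        raise ConfigurationError(f"marker '{marker}' not present in event matrix")

    def marker_values(self, marker: str) -> np.ndarray:
        return self.values[:, self.channel_index(self.marker_channel(marker))]

    def channel_values(self, channel: str) -> np.ndarray:
        return self.values[:, self.channel_index(channel)]

    # -- derived views -------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "EventMatrix":
        mask = np.asarray(mask)
        return EventMatrix(
            values=self.values[mask],
            channels=self.channels,
            markers=dict(self.markers),
            labels={k: np.asarray(v)[mask] for k, v in self.labels.items()},
            metadata=dict(self.metadata),
        )

    def with_values(self, values: np.ndarray) -> "EventMatrix":
        return EventMatrix(
            values=values,
            channels=self.channels,
            markers=dict(self.markers),
            labels=dict(self.labels),
            metadata=dict(self.metadata),
        )

    def with_label(self, key: str, value) -> "EventMatrix":
        labels = dict(self.labels)
        if np.isscalar(value) or isinstance(value, str):
            value = np.full(self.n_events, value, dtype=object)
        labels[key] = np.asarray(value)
        return EventMatrix(self.values, self.channels, dict(self.markers), labels, dict(self.metadata))

    def to_dataframe(self) -> pd.DataFrame:
        cols = [self.markers.get(ch, ch) for ch in self.channels]
        df = pd.DataFrame(self.values, columns=cols)
        for key, arr in self.labels.items():
            df[key] = arr
        return df

    def normalized_marker_map(self) -> dict[str, str]:
        return {ch: normalize_marker(m) for ch, m in self.markers.items()}


def merge_cases(cases: list[EventMatrix]) -> EventMatrix:
    """Concatenate same-tube event matrices from several cases.

    Every input must share the channel list and (normalized) marker map and
    carry a uniform, distinct ``case_id`` label.  Event order within each
    case is preserved; cases are stacked in input order.
    """
    if not cases:
        raise InputError("merge_cases needs at least one case")
    first = cases[0]
    ref_map = first.normalized_marker_map()
    case_ids = []
    for c in cases:
        if c.channels != first.channels:
            raise MergeError("channel lists differ between cases")
        cmap = c.normalized_marker_map()
        for pos, ch in enumerate(c.channels):
            if cmap.get(ch) != ref_map.get(ch):
                raise MergeError(
                    f"marker conflict at channel position {pos} ('{ch}'): "
                    f"{cmap.get(ch)} vs {ref_map.get(ch)}"
                )
        if "case_id" not in c.labels:
            raise MergeError("every case must carry a case_id label")
        ids = set(np.asarray(c.labels["case_id"]).tolist())
        if len(ids) != 1:
            raise MergeError("case_id label must be uniform within a case")
        case_ids.append(ids.pop())
    if len(set(case_ids)) != len(case_ids):
        raise MergeError(f"case ids not distinct: {case_ids}")

    label_keys = set(first.labels)
    for c in cases[1:]:
        label_keys &= set(c.labels)
    merged_labels = {
        k: np.concatenate([np.asarray(c.labels[k]) for c in cases]) for k in label_keys
    }
    return EventMatrix(
        values=np.vstack([c.values for c in cases]),
        channels=first.channels,
        markers=dict(first.markers),
        labels=merged_labels,
        metadata={"merged_from": case_ids},
    )
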