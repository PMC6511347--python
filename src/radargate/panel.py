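"""Panel configuration for the four-tube 8-color AML screening panel.

A panel maps instrument detectors (fluorochrome positions) to antibody
markers, tube by tube.  The shipped default is the standard four-tube AML
combination used for APL screening:

    tube 1: CD14 / CD11b / HLA-DR / CD13 / CD300e / CD64 / CD4    / CD45
    tube 2: CD15 / CD123 / CD34   / CD13 / CD10   / CD16 / HLA-DR / CD45
    tube 3: CD71 / CD117 / CD33   / CD56 / CD34   / CD38 / CD7    / CD45
    tube 4: cyFXIII-A / cyMPO / CD33 / CD2 / CD34 / CD117 / HLA-DR / CD45

(fluorochrome order FITC, PE, PerCP-Cy5.5, PC7, APC, APC-AF750, PB, PO),
plus forward and side scatter in every tube.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .errors import ConfigurationError

#: Detector (channel) names for the 8 fluorescence positions, in panel order.
DEFAULT_DETECTORS: tuple[str, ...] = (
    "FITC-A",
    "PE-A",
    "PerCP-Cy5.5-A",
    "PC7-A",
    "APC-A",
    "APC-AF750-A",
    "PB-A",
    "PO-A",
)

FSC_CHANNEL = "FSC-A"
SSC_CHANNEL = "SSC-A"

_DEFAULT_TUBE_MARKERS: dict[int, tuple[str, ...]] = {
    1: ("CD14", "CD11b", "HLA-DR", "CD13", "CD300e", "CD64", "CD4", "CD45"),
    2: ("CD15", "CD123", "CD34", "CD13", "CD10", "CD16", "HLA-DR", "CD45"),
    3: ("CD71", "CD117", "CD33", "CD56", "CD34", "CD38", "CD7", "CD45"),
    4: ("cyFXIII-A", "cyMPO", "CD33", "CD2", "CD34", "CD117", "HLA-DR", "CD45"),
}


def normalize_marker(name: str) -> str:
    """Canonical marker key: case-insensitive, hyphens/spaces/underscores ignored.

    Vendors disagree on conventions ("HLA-DR" vs "HLADR", "cyMPO" vs "CyMPO");
    all comparisons in the package go through this function.
    """
    return re.sub(r"[\s\-_]", "", name).upper()


@dataclass(frozen=True)
class TubeSpec:
    """One tube of the panel: ordered markers per fluorescence detector."""

    tube_id: int
    markers: tuple[str, ...]
    detectors: tuple[str, ...] = DEFAULT_DETECTORS
    fsc_channel: str = FSC_CHANNEL
    ssc_channel: str = SSC_CHANNEL

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.detectors):
            raise ConfigurationError(
                f"tube {self.tube_id}: {len(self.markers)} markers for "
                f"{len(self.detectors)} detectors"
            )
        keys = [normalize_marker(m) for m in self.markers]
        if len(set(keys)) != len(keys):
            raise ConfigurationError(f"tube {self.tube_id}: duplicate marker names")
        if "CD45" not in keys:
            raise ConfigurationError(f"tube {self.tube_id}: CD45 missing from panel")

    @property
    def channels(self) -> tuple[str, ...]:
        """All channel names, scatter first then fluorescence."""
        return (self.fsc_channel, self.ssc_channel) + self.detectors

    @property
    def marker_map(self) -> dict[str, str]:
        """channel name -> marker name ('FSC'/'SSC' for scatter)."""
        mapping = {self.fsc_channel: "FSC", self.ssc_channel: "SSC"}
        mapping.update(dict(zip(self.detectors, self.markers)))
        return mapping

    @property
    def n_channels(self) -> int:
        return 2 + len(self.detectors)


@dataclass(frozen=True)
class PanelConfig:
    """The full multi-tube panel."""

    tubes: tuple[TubeSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.tubes:
            raise ConfigurationError("panel must define at least one tube")
        ids = [t.tube_id for t in self.tubes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate tube ids in panel")

    @property
    def tube_ids(self) -> tuple[int, ...]:
        return tuple(t.tube_id for t in self.tubes)

    def tube(self, tube_id: int) -> TubeSpec:
        for t in self.tubes:
            if t.tube_id == tube_id:
                return t
        raise ConfigurationError(f"panel has no tube {tube_id}")

    def all_markers(self) -> tuple[str, ...]:
        """Union of fluorescence markers over all tubes (first-seen order)."""
        seen: dict[str, str] = {}
        for t in self.tubes:
            for m in t.markers:
                seen.setdefault(normalize_marker(m), m)
        return tuple(seen.values())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tubes": [
                {
                    "tube_id": t.tube_id,
                    "markers": list(t.markers),
                    "detectors": list(t.detectors),
                    "fsc_channel": t.fsc_channel,
                    "ssc_channel": t.ssc_channel,
                }
                for t in self.tubes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        try:
            tubes = tuple(
                TubeSpec(
                    tube_id=int(t["tube_id"]),
                    markers=tuple(t["markers"]),
                    detectors=tuple(t.get("detectors", DEFAULT_DETECTORS)),
                    fsc_channel=t.get("fsc_channel", FSC_CHANNEL),
                    ssc_channel=t.get("ssc_channel", SSC_CHANNEL),
                )
                for t in d["tubes"]
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed panel config: {exc}") from exc
        return cls(tubes=tubes)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PanelConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_panel() -> PanelConfig:
    """The shipped four-tube AML panel."""
    return PanelConfig(
        tubes=tuple(TubeSpec(tube_id=i, markers=_DEFAULT_TUBE_MARKERS[i]) for i in (1, 2, 3, 4))
    )
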