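"""Reading and writing FCS 3.0/3.1 list-mode files.

A deliberately small, strict implementation of the parts of the FCS
standard that digital cytometers actually emit for list-mode data:

* HEADER with ASCII segment offsets (``$BEGINDATA``/``$ENDDATA`` used when
  the offsets overflow the header fields),
* a single delimited TEXT segment,
* DATA in list mode (``$MODE L``) as float (``F``), double (``D``) or
  unsigned integer (``I`` with uniform ``$PnB``) values, either byte order.

Files are written as FCS 3.1, float storage, little-endian.  The
``$SPILLOVER`` keyword, when present, is parsed into a square matrix and
attached to the returned metadata.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, FormatError
from .events import EventMatrix
from .panel import PanelConfig, normalize_marker

_HEADER_LEN = 58  # 6-byte version + 4 spaces + six 8-byte offsets
_DELIM = "/"


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_fcs_file(
    path,
    values: np.ndarray,
    channels: Sequence[str],
    markers: dict[str, str] | None = None,
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write *values* (events x channels) as an FCS 3.1 float file.

    ``$PnN`` holds the channel (detector) name and ``$PnS`` the marker name
    taken from *markers*.  Values are stored as little-endian float32.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ConfigurationError("values must be 2-D")
    n, p = values.shape
    if p != len(channels):
        raise ConfigurationError("channel list does not match value columns")
    markers = markers or {}

    data = values.astype("<f4").tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width placeholders so the TEXT length is offset-independent
        "$BEGINDATA": "%012d" % 0,
        "$ENDDATA": "%012d" % 0,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n),
        "$PAR": str(p),
    }
    for i, ch in enumerate(channels, start=1):
        rng = float(np.max(values[:, i - 1])) if n else 0.0
        keywords[f"$P{i}N"] = str(ch)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, np.ceil(rng + 1))))
        if ch in markers:
            keywords[f"$P{i}S"] = str(markers[ch])
    for k, v in (extra_keywords or {}).items():
        keywords[str(k)] = str(v)

    def render(kw: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in kw.items():
            if _DELIM in k or _DELIM in str(v):
                raise ConfigurationError(f"keyword {k!r} contains the delimiter")
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    text = render(keywords)
    data_begin = _HEADER_LEN + len(text)
    data_end = data_begin + len(data) - 1
    keywords["$BEGINDATA"] = "%012d" % data_begin
    keywords["$ENDDATA"] = "%012d" % data_end
    text = render(keywords)  # same length: placeholders were fixed width

    text_begin = _HEADER_LEN
    text_end = _HEADER_LEN + len(text) - 1

    def off(v: int) -> bytes:
        s = str(v) if v <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        off(v) for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = chr(raw[0])
    body = raw.decode("latin-1")
    fields = body.split(delim)[1:]  # leading delimiter
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FormatError("TEXT segment has an odd number of fields")
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs_file(path) -> tuple[np.ndarray, list[str], dict[str, str], dict[str, str]]:
    """Low-level read: returns (values, channel names, marker map, keywords)."""
    try:
        with open(path, "rb") as fh:
            blob = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(blob) < _HEADER_LEN:
        raise FormatError(f"{path}: truncated header")
    version = blob[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def field(i: int) -> int:
        s = blob[10 + 8 * i : 18 + 8 * i].decode("ascii", "replace").strip()
        try:
            return int(s) if s else 0
        except ValueError:
            raise FormatError(f"{path}: malformed header offset {s!r}") from None

    text_begin, text_end = field(0), field(1)
    data_begin, data_end = field(2), field(3)
    if text_end <= text_begin or text_end >= len(blob):
        raise FormatError(f"{path}: TEXT segment offsets out of range")
    kw = _parse_text(blob[text_begin : text_end + 1])

    if data_begin == 0 or data_end == 0:
        try:
            data_begin = int(kw["$BEGINDATA"])
            data_end = int(kw["$ENDDATA"])
        except (KeyError, ValueError):
            raise FormatError(f"{path}: DATA segment offsets missing") from None

    try:
        n = int(kw["$TOT"])
        p = int(kw["$PAR"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
        mode = kw.get("$MODE", "L").strip().upper()
    except KeyError as exc:
        raise FormatError(f"{path}: required keyword {exc} missing") from exc
    if mode != "L":
        raise FormatError(f"{path}: only list mode ($MODE L) is supported")
    endian = "<" if byteord.startswith("1") else ">"

    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {kw.get(f"$P{i}B", "").strip() for i in range(1, p + 1)}
        if len(bits) != 1 or bits.pop() not in ("8", "16", "32", "64"):
            raise FormatError(f"{path}: integer data requires a uniform $PnB of 8/16/32/64")
        nbytes = int(kw["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{nbytes}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n * p * dtype.itemsize
    raw = blob[data_begin : data_end + 1]
    if len(raw) < expected:
        raise FormatError(
            f"{path}: truncated DATA segment ({len(raw)} bytes, expected {expected})"
        )
    values = np.frombuffer(raw[:expected], dtype=dtype).reshape(n, p).astype(np.float64)

    channels = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, p + 1)]
    marker_map = {
        channels[i - 1]: kw[f"$P{i}S"] for i in range(1, p + 1) if f"$P{i}S" in kw
    }
    return values, channels, marker_map, kw


def parse_spillover(keywords: dict[str, str]) -> tuple[np.ndarray, list[str]] | None:
    """Parse ``$SPILLOVER``/``SPILL``/``$COMP`` into (matrix, channel names).

    The FCS convention stores rows as fluorochromes (observed = true @ S);
    the matrix is transposed here to the package convention where
    ``S[i, j]`` is the fraction of true signal *j* read by detector *i*.
    """
    for key in ("$SPILLOVER", "SPILL", "$COMP"):
        if key in keywords:
            parts = [p.strip() for p in keywords[key].split(",")]
            break
    else:
        return None
    try:
        k = int(parts[0])
        names = parts[1 : 1 + k]
        vals = np.array([float(x) for x in parts[1 + k :]], dtype=float)
        matrix = vals.reshape(k, k)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed spillover keyword: {exc}") from exc
    return matrix.T.copy(), names


def read_fcs(path, panel: PanelConfig, tube_id: int) -> EventMatrix:
    """Read one tube's FCS file and map its detectors to panel markers.

    The declared parameter count must match the panel tube (scatter + 8
    fluorescence channels); marker names in ``$PnS``, when present, must
    agree with the panel (case/hyphen-insensitive).  Event order is
    preserved and events are never subsampled.
    """
    tube = panel.tube(tube_id)
    values, channels, file_markers, kw = read_fcs_file(path)
    if len(channels) != tube.n_channels:
        raise ConfigurationError(
            f"{path}: file declares {len(channels)} parameters but tube "
            f"{tube_id} expects {tube.n_channels}"
        )

    # scatter channels: match by name prefix, fall back to position 0/1
    marker_map: dict[str, str] = {}
    panel_map = tube.marker_map
    panel_channels = tube.channels
    for pos, ch in enumerate(channels):
        expected_ch = panel_channels[pos]
        expected_marker = panel_map[expected_ch]
        declared = file_markers.get(ch)
        if declared is not None and normalize_marker(declared) not in (
            normalize_marker(expected_marker),
            normalize_marker(expected_ch),
        ):
            raise ConfigurationError(
                f"{path}: channel '{ch}' (position {pos + 1}) is labelled "
                f"'{declared}' but the panel expects '{expected_marker}'"
            )
        marker_map[ch] = expected_marker

    metadata: dict = {"keywords": kw, "path": str(path), "tube_id": tube_id}
    spill = parse_spillover(kw)
    if spill is not None:
        metadata["spillover"], metadata["spillover_channels"] = spill

    case_id = kw.get("CASE_ID") or os.path.splitext(os.path.basename(str(path)))[0]
    n = values.shape[0]
    return EventMatrix(
        values=values,
        channels=tuple(channels),
        markers=marker_map,
        labels={"case_id": np.full(n, case_id, dtype=object)},
        metadata=metadata,
    )
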