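"""Event-level cytometry I/O: the :class:`EventTable` container, FCS 3.0/3.1
and CSV readers/writers, and marker-name resolution.

FCS support is deliberately minimal and modern: list-mode, floating-point
data only (``$DATATYPE`` ``F`` or ``D``), as written by digital instruments.
Legacy integer/log-amplified encodings are rejected with a clear message.
Files are written as FCS 3.1, single dataset, little-endian float32.

The CSV dialect is one header row of ``channel_id|marker`` cells, one event
per row, optionally preceded by ``# key=value`` metadata lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from ._errors import ConfigurationError, FormatError, MarkerLookupError
from .panels import Channel, canonical_marker

__all__ = ["EventTable", "read_events", "write_events", "resolve_marker"]

#: transform_state values an EventTable can be in.
TRANSFORM_STATES = ("raw", "compensated", "transformed")

#: Metadata keys persisted to/from event files.
_META_KEYS = ("tube_id", "stained_volume_ul", "beads_per_tube", "transform_state")


@dataclass
class EventTable:
    """An events x channels intensity matrix with channel metadata.

    Parameters
    ----------
    data : ndarray, shape (n_events, n_channels)
        Intensities.  Raw-scale values are in arbitrary fluorescence units.
    channels : list of Channel
        Ordered channel descriptions; length must equal ``data.shape[1]``.
    meta : dict
        Acquisition metadata.  Recognised keys: ``tube_id``,
        ``stained_volume_ul`` (> 0 when present), ``beads_per_tube``
        (counting tube only) and ``transform_state``
        (``raw`` | ``compensated`` | ``transformed``).
    event_labels : ndarray of str, optional
        Generator ground-truth label per event (synthetic data only); never
        written to event files.
    """

    data: np.ndarray
    channels: list[Channel]
    meta: dict = field(default_factory=dict)
    event_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigurationError("event data must be a 2-D matrix")
        if self.data.shape[1] != len(self.channels):
            raise ConfigurationError(
                f"{self.data.shape[1]} data columns but {len(self.channels)} channels"
            )
        vol = self.meta.get("stained_volume_ul")
        if vol is not None and not vol > 0:
            raise ConfigurationError("stained_volume_ul must be > 0")
        self.meta.setdefault("transform_state", "raw")
        if self.meta["transform_state"] not in TRANSFORM_STATES:
            raise ConfigurationError(
                f"unknown transform_state {self.meta['transform_state']!r}"
            )
        if self.event_labels is not None and len(self.event_labels) != len(self.data):
            raise ConfigurationError("event_labels length mismatch")

    # -- convenience -----------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    @property
    def fluor_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.marker not in ("FSC", "SSC")]

    @property
    def transform_state(self) -> str:
        return self.meta["transform_state"]

    def marker_index(self, marker: str) -> int:
        return resolve_marker(self, marker)

    def column(self, marker: str) -> np.ndarray:
        """Intensity column for ``marker`` (alias-aware)."""
        return self.data[:, resolve_marker(self, marker)]

    def with_data(self, data: np.ndarray, **meta_updates) -> "EventTable":
        """Copy of this table with new intensities and updated metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EventTable(np.asarray(data), list(self.channels), meta,
                          self.event_labels)


def resolve_marker(table: EventTable, marker: str) -> int:
    """Index of the channel carrying ``marker``.

    Matching is case-insensitive over both canonical marker names and the
    alias table (CCR7 = CD197, PD1 = CD279, CD16/CD56 composite).

    Raises
    ------
    MarkerLookupError
        If the marker is absent from the tube, or matches more than one
        channel.
    """
    target = canonical_marker(marker).casefold()
    hits = [i for i, c in enumerate(table.channels)
            if canonical_marker(c.marker).casefold() == target]
    if not hits:
        tube = table.meta.get("tube_id", "?")
        raise MarkerLookupError(
            f"marker {marker!r} not present in tube {tube!r} "
            f"(channels: {', '.join(table.markers)})"
        )
    if len(hits) > 1:
        raise MarkerLookupError(f"marker {marker!r} is ambiguous in this tube")
    return hits[0]


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_events(path, format: str | None = None) -> EventTable:
    """Read an event table from an FCS 3.0/3.1 or CSV file.

    ``format`` may be ``"fcs"``, ``"csv"`` or ``None`` (infer from suffix).
    """
    fmt = _infer_format(path, format)
    if fmt == "fcs":
        return _read_fcs(path)
    return _read_csv(path)


def write_events(table: EventTable, path, format: str | None = None) -> None:
    """Write ``table`` to ``path`` as FCS 3.1 (float32) or CSV."""
    fmt = _infer_format(path, format)
    if fmt == "fcs":
        _write_fcs(table, path)
    else:
        _write_csv(table, path)


def _infer_format(path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("fcs", "csv"):
            raise ConfigurationError(f"unknown event-file format {format!r}")
        return fmt
    suffix = str(path).rsplit(".", 1)[-1].lower()
    if suffix in ("fcs", "csv"):
        return suffix
    raise ConfigurationError(f"cannot infer format from path {path!r}")


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------

_DELIM = "/"


def _write_fcs(table: EventTable, path) -> None:
    n, p = table.data.shape
    data = np.ascontiguousarray(table.data, dtype="<f4")
    payload = data.tobytes()

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(p),
        "$TOT": str(n),
    }
    for i, ch in enumerate(table.channels, start=1):
        kw[f"$P{i}N"] = ch.name
        kw[f"$P{i}S"] = ch.marker
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = float(np.max(np.abs(data[:, i - 1]))) if n else 1.0
        kw[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)
    for key in _META_KEYS:
        if table.meta.get(key) is not None:
            kw[key.upper()] = str(table.meta[key])

    # 10-digit zero-padded offsets keep the TEXT length independent of the
    # eventual values, so the segment can be laid out in one pass.
    kw["$BEGINDATA"] = "0" * 10
    kw["$ENDDATA"] = "0" * 10

    def render(d: dict[str, str]) -> bytes:
        # A delimiter inside a key or value is escaped by doubling it.
        out = _DELIM
        for k, v in d.items():
            v = v if v != "" else " "
            out += (k.replace(_DELIM, _DELIM * 2) + _DELIM
                    + v.replace(_DELIM, _DELIM * 2) + _DELIM)
        return out.encode("ascii")

    text_start = 256
    text = render(kw)
    data_start = text_start + len(text)
    kw["$BEGINDATA"] = f"{data_start:010d}"
    kw["$ENDDATA"] = f"{data_start + len(payload) - 1 if payload else 0:010d}"
    text = render(kw)
    text_end = text_start + len(text) - 1

    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode() + f"{text_end:8d}".encode()
        + f"{data_start if data_start <= 99_999_999 else 0:8d}".encode()
        + f"{(data_start + len(payload) - 1) if payload and data_start + len(payload) - 1 <= 99_999_999 else 0:8d}".encode()
        + f"{0:8d}".encode() + f"{0:8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - len(header)))
        fh.write(text)
        fh.write(payload)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty FCS TEXT segment")
    delim = chr(raw[0])
    body = raw.decode("latin-1")
    if not body.endswith(delim):
        body = body + delim
    # Split on the delimiter; an escaped (doubled) delimiter shows up as an
    # empty token, which we fold back into the preceding one.
    parts = body[1:-1].split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            tok += delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2:
        tokens = tokens[:-1]
    return {tokens[j].strip(): tokens[j + 1] for j in range(0, len(tokens), 2)}


def _read_fcs(path) -> EventTable:
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FormatError(f"{path}: file too short to be FCS")
    version = blob[:6].decode("latin-1", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def offset(a: int, b: int) -> int:
        try:
            return int(blob[a:b].decode("ascii").strip() or "0")
        except ValueError as exc:
            raise FormatError(f"{path}: malformed FCS header") from exc

    text_start, text_end = offset(10, 18), offset(18, 26)
    data_start, data_end = offset(26, 34), offset(34, 42)
    if not (0 < text_start < text_end < len(blob)):
        raise FormatError(f"{path}: invalid TEXT segment offsets")
    kw = _parse_text_segment(blob[text_start:text_end + 1])

    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) FCS is supported")
    dtype_code = kw.get("$DATATYPE", "").upper()
    if dtype_code == "F":
        itemsize, fmt_char = 4, "f"
    elif dtype_code == "D":
        itemsize, fmt_char = 8, "d"
    elif dtype_code == "I":
        raise FormatError(
            f"{path}: integer ($DATATYPE I) FCS encodings are not supported; "
            "re-export as floating point"
        )
    else:
        raise FormatError(f"{path}: missing or unknown $DATATYPE {dtype_code!r}")

    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith(("4", "8", "2")):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing $PAR/$TOT keywords") from exc

    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    nbytes = n_tot * n_par * itemsize
    if nbytes:
        if data_start <= 0 or data_start + nbytes > len(blob):
            raise FormatError(f"{path}: DATA segment out of bounds")
        arr = np.frombuffer(blob, dtype=f"{endian}{fmt_char}", count=n_tot * n_par,
                            offset=data_start)
        data = arr.reshape(n_tot, n_par).astype(np.float64)
    else:
        data = np.empty((0, n_par))

    channels = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N", f"P{i}")
        marker = kw.get(f"$P{i}S", "").strip() or name
        fluor = name[:-2] if name.endswith(("-A", "-H", "-W")) else ""
        if marker in ("FSC", "SSC") or name.upper().startswith(("FSC", "SSC")):
            fluor = ""
        channels.append(Channel(name, fluor, marker))

    meta: dict = {}
    for key in _META_KEYS:
        val = kw.get(key.upper())
        if val is not None:
            meta[key] = _coerce_meta(key, val)
    meta.setdefault("transform_state", "raw")
    if "$SPILLOVER" in kw or "SPILL" in kw:
        meta["spillover_keyword"] = kw.get("$SPILLOVER", kw.get("SPILL"))
    return EventTable(data, channels, meta)


def _coerce_meta(key: str, val: str):
    if key == "stained_volume_ul":
        return float(val)
    if key == "beads_per_tube":
        return int(float(val))
    return val


def parse_spillover_keyword(value: str) -> tuple[list[str], np.ndarray]:
    """Parse an FCS ``$SPILLOVER`` keyword into (channel names, matrix)."""
    parts = [p.strip() for p in value.split(",")]
    try:
        n = int(parts[0])
        names = parts[1:1 + n]
        vals = np.array([float(x) for x in parts[1 + n:1 + n + n * n]])
        return names, vals.reshape(n, n)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed $SPILLOVER keyword: {value!r}") from exc


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _write_csv(table: EventTable, path) -> None:
    buf = io.StringIO()
    for key in _META_KEYS:
        if table.meta.get(key) is not None:
            buf.write(f"# {key}={table.meta[key]}\n")
    buf.write(",".join(f"{c.name}|{c.marker}" for c in table.channels) + "\n")
    # %.9g round-trips float32 exactly.
    data32 = table.data.astype(np.float32)
    for row in data32:
        buf.write(",".join(f"{v:.9g}" for v in row) + "\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def _read_csv(path) -> EventTable:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if "=" in body:
            key, val = body.split("=", 1)
            key = key.strip()
            if key in _META_KEYS:
                meta[key] = _coerce_meta(key, val.strip())
        i += 1
    if i >= len(lines) or not lines[i].strip():
        raise FormatError(f"{path}: missing CSV header row")
    header = lines[i].split(",")
    channels = []
    for cell in header:
        if "|" in cell:
            name, marker = cell.split("|", 1)
        else:
            name = marker = cell
        fluor = name[:-2] if name.endswith("-A") and not name.startswith(("FSC", "SSC")) else ""
        channels.append(Channel(name.strip(), fluor, marker.strip()))
    rows = [ln for ln in lines[i + 1:] if ln.strip()]
    if rows:
        try:
            data = np.array([[float(x) for x in ln.split(",")] for ln in rows])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in CSV event table") from exc
        if data.shape[1] != len(channels):
            raise FormatError(f"{path}: ragged CSV (columns != header)")
    else:
        data = np.empty((0, len(channels)))
    return EventTable(data, channels, meta)
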