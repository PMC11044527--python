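"""Reading and writing FCS list-mode files and resolving the marker panel.

Supports FCS 3.0 / 3.1 list-mode files with float (``$DATATYPE F``/``D``) or
linear-scaled unsigned integer (``$DATATYPE I``, ``$PnE 0,0``) data.  Files
are written as FCS 3.1, 32-bit float, list mode, little-endian — a modern,
unambiguous dialect that every mainstream cytometry package parses.
Intensities are taken as already compensated; no spillover handling.

The marker panel of the assay is FSC, SSC, CD45, CD34, CD38, CD26 and CD3
(the CD3+ lymphocytes serve as the internal control for the CD26 cutoff).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FCSFormatError, FCSIntegrityError, PanelError

__all__ = [
    "REQUIRED_MARKERS",
    "ChannelMeta",
    "EventMatrix",
    "PanelConfig",
    "read_fcs",
    "write_fcs",
    "resolve_panel",
]

#: Markers every acquisition must carry for the CD26+ LSC workflow.
REQUIRED_MARKERS = ("FSC", "SSC", "CD45", "CD34", "CD38", "CD26", "CD3")

_SCATTER_ALIASES = {"FSC": ("FSC", "FS"), "SSC": ("SSC", "SS")}


@dataclass
class ChannelMeta:
    """Metadata for one acquisition channel ($PnN/$PnS/$PnR keywords)."""

    index: int  # 1-based channel position
    short_name: str  # instrument channel label ($PnN)
    marker: str = ""  # stain / antigen label ($PnS), may be empty
    range: float = 262144.0  # $PnR


@dataclass
class EventMatrix:
    """One acquisition: events x channels intensity table plus channel metadata.

    Intensities are in arbitrary (instrument, compensated) units; negative
    values are permitted because compensated fluorescence straddles zero.
    """

    data: np.ndarray
    channels: list[ChannelMeta]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("event data must be a 2-D events x channels array")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} data columns but "
                f"{len(self.channels)} channel metadata entries"
            )
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("event intensities must all be finite")
        idx = [c.index for c in self.channels]
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique")
        markers = [c.marker for c in self.channels if c.marker]
        if len(set(m.upper() for m in markers)) != len(markers):
            raise ValueError("non-empty marker labels must be unique")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.data[:, i]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [c.marker or c.short_name for c in self.channels]
        return pd.DataFrame(self.data, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        """Export the event table as CSV (header = marker names)."""
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class PanelConfig:
    """Explicit marker -> 0-based column mapping overriding file labels."""

    marker_to_channel: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        missing = [m for m in REQUIRED_MARKERS if m not in self.marker_to_channel]
        if missing:
            raise PanelError(f"panel config missing markers: {', '.join(missing)}")
        cols = list(self.marker_to_channel[m] for m in REQUIRED_MARKERS)
        if len(set(cols)) != len(cols):
            raise PanelError("panel config maps two markers to the same channel")


# ---------------------------------------------------------------------------
# FCS writing
# ---------------------------------------------------------------------------

_DELIM = "/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for k, v in keywords.items():
        v = str(v) if str(v) != "" else " "
        if _DELIM in k or _DELIM in str(v):
            raise ValueError("keyword text may not contain the delimiter")
        parts.append(f"{k}{_DELIM}{v}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(em: EventMatrix, path: str | Path) -> None:
    """Write an :class:`EventMatrix` as an FCS 3.1 float list-mode file."""
    data = np.ascontiguousarray(em.data, dtype="<f4")
    n, p = data.shape
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "%9d",
        "$ENDDATA": "%9d",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n),
        "$PAR": str(p),
    }
    for j, ch in enumerate(em.channels, start=1):
        keywords[f"$P{j}B"] = "32"
        keywords[f"$P{j}E"] = "0,0"
        keywords[f"$P{j}N"] = ch.short_name or f"P{j}"
        if ch.marker:
            keywords[f"$P{j}S"] = ch.marker
        rng = max(float(ch.range), float(np.max(np.abs(data[:, j - 1]))) + 1 if n else 1)
        keywords[f"$P{j}R"] = str(int(np.ceil(rng)))

    text_start = 64  # header is 58 bytes; pad to a round offset
    # Resolve data offsets with fixed-width (9-digit) values so the TEXT
    # length does not change when the real offsets are substituted.
    nbytes = data.nbytes
    kw = dict(keywords)
    kw["$BEGINDATA"] = "0" * 9
    kw["$ENDDATA"] = "0" * 9
    text = _text_segment(kw)
    text_end = text_start + len(text) - 1
    if nbytes:
        data_start = text_end + 1
        data_end = data_start + nbytes - 1
        kw["$BEGINDATA"] = f"{data_start:09d}"
        kw["$ENDDATA"] = f"{data_end:09d}"
    else:
        data_start = data_end = 0
    text = _text_segment(kw)
    assert text_start + len(text) - 1 == text_end

    header = b"FCS3.1    " + (
        f"{text_start:8d}{text_end:8d}"
        f"{data_start if data_start <= 99_999_999 else 0:8d}"
        f"{data_end if data_end <= 99_999_999 else 0:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - len(header)))
        fh.write(text)
        if nbytes:
            fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    parts = body.split(delim)[1:]  # leading delimiter
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    out: dict[str, str] = {}
    for i in range(0, len(parts), 2):
        out[parts[i].strip().upper()] = parts[i + 1].strip()
    return out


def read_fcs(path: str | Path) -> EventMatrix:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventMatrix`.

    Raises
    ------
    FCSFormatError
        Unsupported version, mode, data type or scaling.
    FCSIntegrityError
        Declared event count / offsets inconsistent with the file contents.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FCSFormatError(f"{path}: too short to be an FCS file")
    version = blob[:6].decode("latin-1")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

    def _off(a: int, b: int) -> int:
        s = blob[a:b].decode("latin-1").strip() or "0"
        try:
            return int(s)
        except ValueError as exc:
            raise FCSFormatError(f"{path}: malformed header offset {s!r}") from exc

    text_start, text_end = _off(10, 18), _off(18, 26)
    data_start, data_end = _off(26, 34), _off(34, 42)
    if text_end <= text_start or text_end >= len(blob):
        raise FCSIntegrityError(f"{path}: TEXT segment offsets out of range")
    kw = _parse_text(blob[text_start : text_end + 1])

    try:
        tot = int(kw["$TOT"])
        par = int(kw["$PAR"])
        datatype = kw["$DATATYPE"].upper()
        mode = kw.get("$MODE", "L").upper()
        byteord = kw.get("$BYTEORD", "1,2,3,4")
    except KeyError as exc:
        raise FCSFormatError(f"{path}: missing required keyword {exc}") from exc
    if mode != "L":
        raise FCSFormatError(f"{path}: only list mode supported, got $MODE {mode}")
    order = "<" if byteord.startswith("1") else ">"

    if not data_start:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))

    bits = {int(kw.get(f"$P{j}B", "32")) for j in range(1, par + 1)}
    if len(bits) > 1:
        raise FCSFormatError(f"{path}: mixed $PnB widths not supported")
    nbits = bits.pop() if bits else 32
    if datatype == "F":
        dtype = np.dtype(f"{order}f4")
        if nbits != 32:
            raise FCSFormatError(f"{path}: $DATATYPE F requires $PnB 32")
    elif datatype == "D":
        dtype = np.dtype(f"{order}f8")
    elif datatype == "I":
        if nbits not in (8, 16, 32, 64):
            raise FCSFormatError(f"{path}: unsupported integer width {nbits}")
        for j in range(1, par + 1):
            amp = kw.get(f"$P{j}E", "0,0").replace(" ", "")
            if amp not in ("0,0", "0.0,0.0", "0,0.0", "0.0,0"):
                raise FCSFormatError(
                    f"{path}: log-amplified integer data ($P{j}E {amp}) not supported"
                )
        dtype = np.dtype(f"{order}u{nbits // 8}")
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = tot * par * dtype.itemsize
    if expected:
        if data_start <= 0 or data_start >= len(blob):
            raise FCSIntegrityError(f"{path}: DATA segment offset missing")
        avail = len(blob) - data_start
        if data_end >= data_start:
            avail = min(avail, data_end - data_start + 1)
        if avail < expected:
            raise FCSIntegrityError(
                f"{path}: DATA segment has {avail} bytes, "
                f"{expected} required for $TOT {tot} x $PAR {par}"
            )
        raw = np.frombuffer(blob, dtype=dtype, count=tot * par, offset=data_start)
        data = raw.reshape(tot, par).astype(np.float64)
    else:
        data = np.empty((tot, par), dtype=np.float64)

    channels = []
    for j in range(1, par + 1):
        channels.append(
            ChannelMeta(
                index=j,
                short_name=kw.get(f"$P{j}N", f"P{j}"),
                marker=kw.get(f"$P{j}S", ""),
                range=float(kw.get(f"$P{j}R", "262144") or 262144),
            )
        )
    return EventMatrix(data=data, channels=channels, sample_id=path.stem)


# ---------------------------------------------------------------------------
# Panel resolution
# ---------------------------------------------------------------------------


def _token_match(marker: str, label: str) -> bool:
    # word-boundary match so CD3 does not match CD34/CD38
    pat = rf"(?<![A-Za-z0-9]){re.escape(marker)}(?![0-9])"
    return re.search(pat, label, flags=re.IGNORECASE) is not None


def resolve_panel(em: EventMatrix, cfg: PanelConfig | None = None) -> dict[str, int]:
    """Resolve the required markers to 0-based column indices.

    Without an explicit config, markers are matched case-insensitively as
    whole tokens against the stain label ($PnS), falling back to the channel
    short name ($PnN); ``CD3`` deliberately does not match ``CD34``.
    Deterministic and independent of channel order (lowest channel index wins
    on multiple matches).
    """
    if cfg is not None and cfg.marker_to_channel:
        cfg.validate()
        for m, col in cfg.marker_to_channel.items():
            if not 0 <= col < em.n_channels:
                raise PanelError(f"panel config column {col} for {m} out of range")
        return {m: cfg.marker_to_channel[m] for m in REQUIRED_MARKERS}

    order = sorted(range(em.n_channels), key=lambda i: em.channels[i].index)
    mapping: dict[str, int] = {}
    missing: list[str] = []
    for marker in REQUIRED_MARKERS:
        aliases = _SCATTER_ALIASES.get(marker, (marker,))
        hit = None
        for i in order:
            ch = em.channels[i]
            for alias in aliases:
                if _token_match(alias, ch.marker) or _token_match(alias, ch.short_name):
                    hit = i
                    break
            if hit is not None:
                break
        if hit is None:
            missing.append(marker)
        else:
            mapping[marker] = hit
    if missing:
        raise PanelError(f"required markers not found in file: {', '.join(missing)}")
    if len(set(mapping.values())) != len(mapping):
        raise PanelError("two required markers resolved to the same channel")
    return mapping
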