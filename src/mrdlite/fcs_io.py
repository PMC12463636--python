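"""FCS event-data I/O and panel validation.

Defines the in-memory event-data contract (:class:`Sample`) used by every
other stage, plus a self-contained FCS 3.0/3.1 reader and a deterministic
FCS 3.1 writer (list mode, single dataset, 32-bit float).

Events are stored on the *linear* scale; any log transform is applied only
inside gating. Channel names are normalized to canonical panel labels
("FSC", "SSC", "CD19", ...) through a configurable alias map, so files
exported with fluorochrome-qualified names ("CD19 FITC") still validate.

The reader supports the common core of the standard: list-mode data of
type F (float32), D (float64) or I (unsigned integers of uniform bit
width, with per-channel log-amplifier decoding via $PnE). Escaped TEXT
delimiters (doubled delimiter characters inside values) are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import load_panel_config

__all__ = [
    "TUBE1_SURFACE",
    "TUBE2_SYTO",
    "ChannelInfo",
    "Sample",
    "FcsParseError",
    "PanelValidationError",
    "read_fcs",
    "write_fcs",
    "validate_panel",
]

TUBE1_SURFACE = "TUBE1_SURFACE"
TUBE2_SYTO = "TUBE2_SYTO"

#: hard acquisition cap (events per tube)
MAX_EVENTS = 500_000

_HEADER_LEN = 58  # 6-byte version + 4 spaces + six 8-byte offset fields


class FcsParseError(ValueError):
    """Malformed FCS file; the message names the offending byte offset."""


class PanelValidationError(ValueError):
    """Required panel channels missing; carries the missing labels."""

    def __init__(self, tube: str, missing: list[str]):
        self.tube = tube
        self.missing = list(missing)
        super().__init__(
            f"sample does not conform to the {tube} panel: "
            f"missing channel(s) {', '.join(self.missing)}"
        )


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one detector channel."""

    name: str
    detector_range: float = 100_000.0
    transform_hint: str = "log10"  # {"linear", "log10"}

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("channel name must be non-empty")
        if not self.detector_range > 0:
            raise ValueError(f"detector_range must be > 0, got {self.detector_range}")
        if self.transform_hint not in ("linear", "log10"):
            raise ValueError(f"unknown transform_hint {self.transform_hint!r}")


@dataclass
class Sample:
    """One acquired tube: an events x channels matrix plus acquisition info."""

    sample_id: str
    tube_id: str
    events: np.ndarray
    channels: list[ChannelInfo]
    acquired_events: int = 0
    volume_ul: float = 100.0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix")
        n, c = self.events.shape
        if n < 1:
            raise ValueError("a Sample must contain at least one event")
        if n > MAX_EVENTS:
            raise ValueError(f"n_events {n} exceeds the acquisition cap {MAX_EVENTS}")
        if c != len(self.channels):
            raise ValueError(
                f"events has {c} columns but {len(self.channels)} channels declared"
            )
        names = [ch.name for ch in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")
        if not np.all(np.isfinite(self.events)):
            raise ValueError("event matrix contains non-finite values")
        if np.any(self.events < 0):
            raise ValueError("event values must be non-negative")
        if self.acquired_events == 0:
            self.acquired_events = n

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])

    @property
    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def channel(self, name: str) -> np.ndarray:
        """Column of the event matrix for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in sample") from None
        return self.events[:, idx]


# --------------------------------------------------------------------------
# writing

def _text_segment(sample: Sample, data_begin: int, data_end: int) -> bytes:
    """Fixed-order TEXT segment; fixed ordering makes writes deterministic."""
    n, par = sample.events.shape
    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", f"{data_begin:012d}"),
        ("$ENDDATA", f"{data_end:012d}"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(par)),
        ("$TOT", str(n)),
        ("MRDLITE_SAMPLEID", sample.sample_id or "-"),
        ("MRDLITE_TUBEID", sample.tube_id),
        ("MRDLITE_ACQEVENTS", str(sample.acquired_events)),
        ("MRDLITE_VOLUME_UL", repr(float(sample.volume_ul))),
    ]
    for i, ch in enumerate(sample.channels, start=1):
        kw.append((f"$P{i}N", ch.name))
        kw.append((f"$P{i}B", "32"))
        kw.append((f"$P{i}E", "0,0"))
        kw.append((f"$P{i}R", repr(float(ch.detector_range))))
        kw.append((f"MRDLITE_P{i}T", ch.transform_hint))
    parts = ["/"]
    for key, val in kw:
        if "/" in key or "/" in val:
            raise ValueError(f"keyword {key}={val!r} contains the TEXT delimiter")
        parts.append(f"{key}/{val}/")
    return "".join(parts).encode("ascii")


def write_fcs(sample: Sample, path: str | Path) -> None:
    """Write ``sample`` as a single-dataset FCS 3.1 file (float list mode).

    Identical samples produce byte-identical files: keyword order is fixed
    and no timestamps are emitted.
    """
    data = np.ascontiguousarray(sample.events, dtype="<f4").tobytes()
    # TEXT length does not depend on the offsets because they are written
    # zero-padded to a fixed 12-character width.
    probe = _text_segment(sample, 0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(probe) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text = _text_segment(sample, data_begin, data_end)
    assert len(text) == len(probe)

    def hdr(x: int) -> bytes:
        # header offset fields hold 8 ASCII chars; larger offsets are set to
        # 0 there and carried by $BEGINDATA/$ENDDATA (FCS 3.1 rule)
        return b"%8d" % x if x <= 99_999_999 else b"%8d" % 0

    header = b"FCS3.1    " + hdr(text_begin) + hdr(text_end) + hdr(data_begin) + hdr(data_end) + hdr(0) + hdr(0)
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


# --------------------------------------------------------------------------
# reading

def _parse_text(buf: bytes, begin: int, end: int) -> dict[str, str]:
    if begin >= len(buf) or end >= len(buf) or end <= begin:
        raise FcsParseError(
            f"TEXT segment offsets [{begin}, {end}] fall outside the file "
            f"(byte offset {begin})"
        )
    delim = buf[begin:begin + 1].decode("latin-1")
    raw = buf[begin + 1:end + 1].decode("latin-1")
    parts = raw.split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FcsParseError(
            f"TEXT segment at byte offset {begin} has an odd number of "
            f"delimited tokens ({len(parts)})"
        )
    out: dict[str, str] = {}
    for i in range(0, len(parts), 2):
        out[parts[i].strip().upper()] = parts[i + 1]
    return out


def _require(text: dict[str, str], key: str, begin: int) -> str:
    if key not in text:
        raise FcsParseError(
            f"required keyword {key} missing from TEXT segment at byte offset {begin}"
        )
    return text[key]


def _decode_data(buf: bytes, text: dict[str, str], begin: int, end: int,
                 par: int, tot: int) -> np.ndarray:
    if begin <= 0 or end >= len(buf) or end < begin:
        raise FcsParseError(f"DATA segment offsets [{begin}, {end}] fall outside the file (byte offset {begin})")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    order = "<" if byteord.startswith("1") else ">"
    dtype_code = text.get("$DATATYPE", "F").upper()
    raw = buf[begin:end + 1]
    if dtype_code == "F":
        itemsize = 4
        arr = np.frombuffer(raw[: par * tot * itemsize], dtype=f"{order}f4")
    elif dtype_code == "D":
        itemsize = 8
        arr = np.frombuffer(raw[: par * tot * itemsize], dtype=f"{order}f8")
    elif dtype_code == "I":
        bits = {int(text.get(f"$P{i}B", "16")) for i in range(1, par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise FcsParseError(
                f"integer data with mixed or unsupported $PnB widths at byte offset {begin}"
            )
        nbits = int(text.get("$P1B", "16"))
        itemsize = nbits // 8
        arr = np.frombuffer(raw[: par * tot * itemsize], dtype=f"{order}u{itemsize}")
    else:
        raise FcsParseError(f"unsupported $DATATYPE {dtype_code!r} (byte offset {begin})")
    expected = par * tot * itemsize
    if len(raw) < expected:
        raise FcsParseError(
            f"DATA segment holds {len(raw)} bytes, expected {expected} (byte offset {begin})"
        )
    events = arr.astype(np.float64).reshape(tot, par)
    if dtype_code == "I":
        # decode log-amplified integer channels to linear scale: $PnE f1,f2
        for i in range(1, par + 1):
            pne = text.get(f"$P{i}E", "0,0").split(",")
            f1 = float(pne[0])
            f2 = float(pne[1]) if len(pne) > 1 else 0.0
            if f1 > 0:
                rng = float(text.get(f"$P{i}R", "1024"))
                scale = f2 if f2 > 0 else 1.0
                events[:, i - 1] = scale * 10.0 ** (f1 * events[:, i - 1] / rng)
    return events


def _normalize_name(raw: str, aliases: dict[str, str]) -> str:
    key = raw.strip()
    up = key.upper()
    for cand in (key, up):
        if cand in aliases:
            return str(aliases[cand])
    upper_aliases = {str(k).upper(): str(v) for k, v in aliases.items()}
    return upper_aliases.get(up, up)


def read_fcs(path: str | Path, panel: dict | None = None,
             tube: str | None = None) -> Sample:
    """Read an FCS 3.0/3.1 file into a :class:`Sample` on the linear scale.

    Channel names are normalized through the panel alias map. If ``tube``
    is given, the sample is additionally validated against that tube's
    required panel. Never silently drops events: the returned matrix has
    exactly ``$TOT`` rows.
    """
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) < _HEADER_LEN:
        raise FcsParseError(f"file too short for an FCS header (byte offset 0, {len(buf)} bytes)")
    version = buf[0:6]
    if version not in (b"FCS3.0", b"FCS3.1"):
        raise FcsParseError(f"unsupported FCS version {version!r} (byte offset 0)")

    def offset(slot: int) -> int:
        start = 10 + 8 * slot
        fieldtxt = buf[start:start + 8].decode("latin-1").strip()
        try:
            return int(fieldtxt) if fieldtxt else 0
        except ValueError:
            raise FcsParseError(
                f"non-numeric header offset field {fieldtxt!r} (byte offset {start})"
            ) from None

    text_begin, text_end = offset(0), offset(1)
    data_begin, data_end = offset(2), offset(3)
    text = _parse_text(buf, text_begin, text_end)

    par = int(_require(text, "$PAR", text_begin))
    tot = int(_require(text, "$TOT", text_begin))
    mode = _require(text, "$MODE", text_begin).upper()
    if mode != "L":
        raise FcsParseError(f"only list-mode ($MODE L) data is supported, got {mode!r}")
    # FCS 3.1: header offsets may be 0 with the truth in $BEGINDATA/$ENDDATA
    if data_begin == 0:
        data_begin = int(_require(text, "$BEGINDATA", text_begin))
        data_end = int(_require(text, "$ENDDATA", text_begin))
    events = _decode_data(buf, text, data_begin, data_end, par, tot)

    panel = panel if panel is not None else load_panel_config()
    aliases = {str(k): str(v) for k, v in panel.get("aliases", {}).items()}
    channels: list[ChannelInfo] = []
    for i in range(1, par + 1):
        raw_name = _require(text, f"$P{i}N", text_begin)
        name = _normalize_name(raw_name, aliases)
        rng = float(text.get(f"$P{i}R", "100000"))
        hint = text.get(f"MRDLITE_P{i}T")
        if hint not in ("linear", "log10"):
            hint = "linear" if name in ("FSC", "SSC") else "log10"
        channels.append(ChannelInfo(name=name, detector_range=rng, transform_hint=hint))

    sample = Sample(
        sample_id=text.get("MRDLITE_SAMPLEID", path.stem),
        tube_id=text.get("MRDLITE_TUBEID", tube or "UNKNOWN"),
        events=np.clip(events, 0.0, None),
        channels=channels,
        acquired_events=int(text.get("MRDLITE_ACQEVENTS", str(tot))),
        volume_ul=float(text.get("MRDLITE_VOLUME_UL", "100")),
    )
    if tube is not None:
        sample = replace(sample, tube_id=tube)
        validate_panel(sample, tube, panel=panel)
    return sample


def validate_panel(sample: Sample, tube: str, panel: dict | None = None) -> Sample:
    """Check that all channels required for ``tube`` are present.

    Extra channels are permitted and retained. Returns the sample unchanged
    on success; raises :class:`PanelValidationError` listing every missing
    label otherwise.
    """
    panel = panel if panel is not None else load_panel_config()
    try:
        required = panel["required"][tube]
    except KeyError:
        raise ValueError(f"unknown tube identifier {tube!r}") from None
    present = set(sample.channel_names)
    missing = [ch for ch in required if ch not in present]
    if missing:
        raise PanelValidationError(tube, missing)
    return sample
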