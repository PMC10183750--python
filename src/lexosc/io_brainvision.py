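"""BrainVision (.vhdr/.vmrk/.eeg) reading, plus a fixture writer.

Reading delegates to MNE's BrainVision reader after explicit validation of
the sidecar triplet, so that the common failure modes (missing files,
channel-count mismatch, unsupported binary layout) surface as distinct,
informative errors.  The writer emits the minimal multiplexed dialect
(IEEE float32, or int16 with a per-channel resolution) and exists so that
tests and examples can build real on-disk recordings on the fly.
"""

from __future__ import annotations

import configparser
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ContinuousRecording", "read_brainvision", "write_brainvision"]


class BrainVisionError(IOError):
    pass


@dataclass
class ContinuousRecording:
    """Continuous multichannel signal in microvolts with event markers."""

    data: np.ndarray          # channels x samples, uV
    sfreq: float
    channels: list[str]
    events: list[tuple[int, str]]  # (sample index, marker type/description)


def _parse_vhdr(header_path: Path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser(strict=False)
    text = header_path.read_text(encoding="utf-8", errors="replace")
    # Strip the signature line; the rest is INI-formatted.
    body = re.sub(r"^Brain ?Vision Data Exchange Header File.*?$", "",
                  text, count=1, flags=re.M)
    parser.read_string(body)
    return parser


def read_brainvision(header_path) -> ContinuousRecording:
    """Read a BrainVision triplet; returns signal in uV and marker events."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise BrainVisionError(f"header file not found: {header_path}")
    ini = _parse_vhdr(header_path)
    try:
        common = ini["Common Infos"]
    except KeyError:
        raise BrainVisionError(f"not a BrainVision header: {header_path}") from None

    for key, kind in (("DataFile", "data (.eeg)"), ("MarkerFile", "marker (.vmrk)")):
        sidecar = header_path.parent / common.get(key, "")
        if not common.get(key) or not sidecar.exists():
            raise BrainVisionError(f"missing {kind} sidecar for {header_path}")

    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise BrainVisionError(f"unsupported data orientation {orientation!r}")
    fmt = ini.get("Binary Infos", "BinaryFormat", fallback="IEEE_FLOAT_32").upper()
    if fmt not in ("IEEE_FLOAT_32", "INT_16"):
        raise BrainVisionError(f"unsupported binary format {fmt!r}")

    n_channels = int(common["NumberOfChannels"])
    n_listed = sum(1 for k in ini["Channel Infos"] if k.lower().startswith("ch"))
    if n_listed != n_channels:
        raise BrainVisionError(
            f"channel-count mismatch: header declares {n_channels}, "
            f"lists {n_listed}")

    data_file = header_path.parent / common["DataFile"]
    itemsize = 4 if fmt == "IEEE_FLOAT_32" else 2
    n_bytes = data_file.stat().st_size
    if n_bytes % (itemsize * n_channels) != 0:
        raise BrainVisionError(
            f"truncated data file: {n_bytes} bytes is not a whole number of "
            f"{n_channels}-channel frames")

    import mne

    raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    events = []
    for annot in raw.annotations:
        sample = int(round(annot["onset"] * raw.info["sfreq"]))
        desc = annot["description"]
        if desc.startswith("New Segment"):
            continue
        if "/" in desc:  # mne renders "Stimulus/S 1"; keep the description
            desc = desc.split("/", 1)[1]
        events.append((sample, desc))
    return ContinuousRecording(
        data=data_uv, sfreq=float(raw.info["sfreq"]),
        channels=list(raw.ch_names), events=events)


def write_brainvision(
    data_uv: np.ndarray,
    sfreq: float,
    channels: list[str],
    events: list[tuple[int, str]],
    header_path,
    binary_format: str = "IEEE_FLOAT_32",
    resolution_uv: float = 0.1,
) -> Path:
    """Write a minimal BrainVision triplet (fixture writer).

    ``binary_format`` is ``IEEE_FLOAT_32`` or ``INT_16``; for int16 the
    stored value is ``round(uV / resolution_uv)``.
    """
    header_path = Path(header_path)
    data_uv = np.asarray(data_uv, dtype=float)
    n_channels, _ = data_uv.shape
    if len(channels) != n_channels:
        raise BrainVisionError("channel list does not match data shape")
    stem = header_path.stem
    eeg_path = header_path.with_suffix(".eeg")
    vmrk_path = header_path.with_suffix(".vmrk")

    if binary_format == "IEEE_FLOAT_32":
        frames = data_uv.T.astype("<f4")
        fmt_line, resolutions = "IEEE_FLOAT_32", np.ones(n_channels)
    elif binary_format == "INT_16":
        frames = np.round(data_uv.T / resolution_uv).astype("<i2")
        fmt_line, resolutions = "INT_16", np.full(n_channels, resolution_uv)
    else:
        raise BrainVisionError(f"unsupported binary format {binary_format!r}")
    eeg_path.write_bytes(np.ascontiguousarray(frames).tobytes())

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_channels}",
        f"SamplingInterval={1e6 / sfreq:.6f}",
        "[Binary Infos]",
        f"BinaryFormat={fmt_line}",
        "[Channel Infos]",
    ]
    for i, (name, res) in enumerate(zip(channels, resolutions), start=1):
        lines.append(f"Ch{i}={name},,{res:g},µV")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (sample, desc) in enumerate(events, start=2):
        # BrainVision marker positions are 1-based sample indices
        mlines.append(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0")
    vmrk_path.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return header_path
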