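"""File formats: the internal self-describing container, EDF and
BrainVision recordings, epoch containers, feature tables, and CT stacks.

The internal container for a recording is a trio of files sharing a base
path: ``<base>.json`` (fs, channel labels, dtype, shape), ``<base>.npy``
(the channel-by-sample matrix in µV), and ``<base>.events.tsv`` (columns
sample_index, event_id, is_target).  Epoch sets use ``<base>.epochs.npy``
plus a JSON header and a label sidecar.

EDF export is a minimal writer for the classic 16-bit EDF layout (one data
record per second); events go in the same TSV sidecar since plain EDF has
no annotation channel.  EDF and BrainVision *reading* go through mne.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, Epoch, Event
from .errors import DataError, ValidationError

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "write_edf",
    "read_edf",
    "read_brainvision",
    "write_features_csv",
    "read_features_csv",
    "save_ct_stack",
    "load_ct_stack",
]

_CONTAINER_VERSION = 1


def _events_frame(events: list[Event]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_index": [e.sample for e in events],
            "event_id": [e.identity for e in events],
            "is_target": [int(e.is_target) for e in events],
        }
    )


def _events_from_frame(df: pd.DataFrame) -> list[Event]:
    return [
        Event(sample=int(r.sample_index), identity=int(r.event_id),
              is_target=bool(r.is_target))
        for r in df.itertuples()
    ]


def save_recording(base: str | Path, rec: EEGRecording) -> None:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "version": _CONTAINER_VERSION,
        "kind": "recording",
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "units": "uV",
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=2))
    np.save(base.with_suffix(".npy"), rec.data)
    _events_frame(rec.events).to_csv(
        base.with_suffix(".events.tsv"), sep="\t", index=False
    )


def load_recording(base: str | Path) -> EEGRecording:
    base = Path(base)
    header = json.loads(base.with_suffix(".json").read_text())
    if header.get("kind") != "recording":
        raise DataError(f"{base}: not a recording container")
    data = np.load(base.with_suffix(".npy"))
    events_path = base.with_suffix(".events.tsv")
    events = (
        _events_from_frame(pd.read_csv(events_path, sep="\t"))
        if events_path.exists()
        else []
    )
    return EEGRecording(
        data=data, fs=float(header["fs"]),
        channel_labels=list(header["channel_labels"]), events=events,
    )


def save_epochs(base: str | Path, epochs: list[Epoch]) -> None:
    if not epochs:
        raise ValidationError("no epochs to save")
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    arr = np.stack([ep.data for ep in epochs])
    header = {
        "version": _CONTAINER_VERSION,
        "kind": "epochs",
        "fs": epochs[0].fs,
        "t0_offset_ms": epochs[0].t0_offset_ms,
        "shape": list(arr.shape),
        "units": "uV",
    }
    Path(str(base) + ".epochs.json").write_text(json.dumps(header, indent=2))
    np.save(str(base) + ".epochs.npy", arr)
    pd.DataFrame(
        {
            "identity": [ep.identity for ep in epochs],
            "is_target": [int(ep.is_target) for ep in epochs],
        }
    ).to_csv(str(base) + ".labels.tsv", sep="\t", index=False)


def load_epochs(base: str | Path) -> list[Epoch]:
    base = Path(base)
    header = json.loads(Path(str(base) + ".epochs.json").read_text())
    if header.get("kind") != "epochs":
        raise DataError(f"{base}: not an epochs container")
    arr = np.load(str(base) + ".epochs.npy")
    labels = pd.read_csv(str(base) + ".labels.tsv", sep="\t")
    if len(labels) != arr.shape[0]:
        raise DataError("label sidecar length mismatch")
    return [
        Epoch(data=arr[i], fs=float(header["fs"]),
              is_target=bool(labels.is_target[i]),
              identity=int(labels.identity[i]),
              t0_offset_ms=float(header["t0_offset_ms"]))
        for i in range(arr.shape[0])
    ]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad_ascii(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Minimal classic-EDF writer (16-bit, one data record per second).

    The sampling rate must be a positive integer.  The recording is padded
    with zeros to a whole number of one-second records; per-channel physical
    min/max are taken from the data so the 16-bit quantisation error is
    small.  Events go in a ``.events.tsv`` sidecar.
    """
    path = Path(path)
    fs = rec.fs
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF export needs an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_records * spr))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    header = bytearray()
    header += _pad_ascii("0", 8)
    header += _pad_ascii("X X X X", 80)          # patient id
    header += _pad_ascii("Startdate X X X X", 80)
    header += _pad_ascii("01.01.00", 8)
    header += _pad_ascii("00.00.00", 8)
    header += _pad_ascii(str(256 + 256 * n_ch), 8)
    header += _pad_ascii("", 44)
    header += _pad_ascii(str(n_records), 8)
    header += _pad_ascii("1", 8)                  # record duration, s
    header += _pad_ascii(str(n_ch), 4)
    for lab in rec.channel_labels:
        header += _pad_ascii(lab, 16)
    header += b"".join(_pad_ascii("EEG", 80) for _ in range(n_ch))
    header += b"".join(_pad_ascii("uV", 8) for _ in range(n_ch))
    for v in pmin:
        header += _pad_ascii(f"{v:.8g}"[:8], 8)
    for v in pmax:
        header += _pad_ascii(f"{v:.8g}"[:8], 8)
    header += b"".join(_pad_ascii(str(dmin), 8) for _ in range(n_ch))
    header += b"".join(_pad_ascii(str(dmax), 8) for _ in range(n_ch))
    header += b"".join(_pad_ascii("", 80) for _ in range(n_ch))
    header += b"".join(_pad_ascii(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_pad_ascii("", 32) for _ in range(n_ch))

    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            chunk = data[:, r * spr: (r + 1) * spr]
            digital = np.round(
                (chunk - pmin[:, None]) * scale[:, None] + dmin
            ).astype("<i2")
            fh.write(digital.tobytes())

    _events_frame(rec.events).to_csv(
        path.with_suffix(".events.tsv"), sep="\t", index=False
    )


def read_edf(path: str | Path, events_path: str | Path | None = None) -> EEGRecording:
    """Read an EDF recording via mne; events from the TSV sidecar if present."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    if events_path is None:
        events_path = path.with_suffix(".events.tsv")
    events = []
    if Path(events_path).exists():
        events = _events_from_frame(pd.read_csv(events_path, sep="\t"))
    return EEGRecording(
        data=data, fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names), events=events,
    )


def read_brainvision(
    vhdr_path: str | Path,
    target_descriptions: set[str] | None = None,
) -> EEGRecording:
    """Read a BrainVision triplet via mne.

    Stimulus annotations become events; an annotation whose description is
    in ``target_descriptions`` is marked as a target.  The numeric suffix of
    'Stimulus/S <n>'-style descriptions becomes the event identity.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])
    target_descriptions = target_descriptions or set()
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if not desc.startswith("Stimulus"):
            continue
        digits = "".join(ch for ch in desc if ch.isdigit())
        ident = int(digits) if digits else 0
        events.append(
            Event(sample=int(round(ann["onset"] * fs)), identity=ident,
                  is_target=desc in target_descriptions)
        )
    return EEGRecording(
        data=data, fs=fs, channel_labels=list(raw.ch_names), events=events
    )


# ---------------------------------------------------------------------------
# Feature tables and CT stacks
# ---------------------------------------------------------------------------

def write_features_csv(
    path: str | Path,
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    sidecar: dict | None = None,
) -> None:
    """Feature matrix as CSV with a header row from the layout names.

    A JSON sidecar records the configuration that produced the layout.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "is_target", np.asarray(y).astype(int))
    df.to_csv(path, index=False)
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_features_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if "is_target" not in df.columns:
        raise DataError("feature table lacks an is_target column")
    y = df.pop("is_target").to_numpy().astype(int)
    return df.to_numpy(dtype=float), y, list(df.columns)


def save_ct_stack(directory: str | Path, stack: np.ndarray,
                  mask: np.ndarray | None = None) -> list[Path]:
    """Write a 16-bit CT stack as per-slice PNGs (plus optional mask PNGs)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stack.ndim == 2:
        stack = stack[None]
    paths = []
    for i, sl in enumerate(stack):
        p = directory / f"slice_{i:04d}.png"
        iio.imwrite(p, sl.astype(np.uint16))
        paths.append(p)
    if mask is not None:
        mask = mask[None] if mask.ndim == 2 else mask
        for i, sl in enumerate(mask):
            iio.imwrite(directory / f"mask_{i:04d}.png",
                        (sl.astype(np.uint8) * 255))
    return paths


def load_ct_stack(directory: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(directory.glob("slice_*.png"))
    if not paths:
        raise DataError(f"no slice_*.png files in {directory}")
    return np.stack([iio.imread(p) for p in paths])
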