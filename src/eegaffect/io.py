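"""Readers and writers for every on-disk format the pipeline touches.

Formats:

* delimited recordings — comment metadata lines, a header row of channel
  names, then one comma-separated row of samples per channel;
* EDF — a minimal self-contained European Data Format reader/writer
  (16-bit, one 1 s data record per second);
* hierarchical array container (HDF5) — bit-exact round-trips for
  recordings, DE tensors, feature images and model checkpoints;
* manifests, questionnaire/score tables and session reports as CSV/JSON;
* an adapter for SEED-style per-session ``.mat`` files (never required by
  the test suite).

Every serialized object embeds a format-version string; readers reject
unknown versions rather than guessing.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

from .core import EMOTION_LABELS, N_CHANNELS, RawRecording
from .features import CANONICAL_BANDS, DETensor, FeatureImage

__all__ = [
    "FORMAT_VERSION",
    "canonical_channel_names",
    "read_recording", "write_recording",
    "read_delimited", "write_delimited",
    "read_edf", "write_edf",
    "save_recording_h5", "load_recording_h5",
    "save_tensor", "load_tensor",
    "save_image", "load_image",
    "save_checkpoint", "load_checkpoint",
    "ManifestEntry", "Manifest", "build_manifest",
    "read_manifest", "write_manifest",
    "read_seed_session",
    "read_score_table", "write_score_table",
    "write_session_report",
]

FORMAT_VERSION = "1"

logger = logging.getLogger("eegaffect")


def canonical_channel_names() -> list[str]:
    """The packaged 62-channel 10-20-system layout, in canonical order."""
    text = resources.files("eegaffect.data").joinpath("channels_62_10_20.txt").read_text()
    names = [line.strip() for line in text.splitlines() if line.strip()]
    assert len(names) == N_CHANNELS
    return names


# ---------------------------------------------------------------------------
# delimited recordings
# ---------------------------------------------------------------------------

def write_delimited(rec: RawRecording, path: str | Path) -> None:
    path = Path(path)
    names = rec.channel_names or [f"ch{i}" for i in range(rec.n_channels)]
    with path.open("w", newline="") as fh:
        fh.write(f"# eegaffect-recording v{FORMAT_VERSION}\n")
        fh.write(f"# sample_rate={rec.sample_rate!r}\n")
        if rec.label is not None:
            fh.write(f"# label={rec.label}\n")
        fh.write(",".join(names) + "\n")
        for row in rec.data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_delimited(path: str | Path) -> RawRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    names: list[str] | None = None
    rows: list[np.ndarray] = []
    version_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("eegaffect-recording"):
                    version = body.split("v")[-1]
                    if version != FORMAT_VERSION:
                        raise ValueError(
                            f"{path}: unknown recording format version {version!r}"
                        )
                    version_seen = True
                elif "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            if names is None:
                names = [c.strip() for c in line.split(",")]
                continue
            cells = line.split(",")
            try:
                rows.append(np.array([float(c) for c in cells]))
            except ValueError:
                for col, cell in enumerate(cells, start=1):
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                            f"column {col}"
                        ) from None
                raise
    if not version_seen:
        raise ValueError(f"{path}: malformed header, missing format-version line")
    if names is None or not rows:
        raise ValueError(f"{path}: no channel header or data rows found")
    if len(rows) != len(names):
        raise ValueError(
            f"{path}: {len(rows)} data rows for {len(names)} header channels"
        )
    if "sample_rate" not in meta:
        raise ValueError(f"{path}: malformed header, missing sample_rate")
    label = int(meta["label"]) if "label" in meta else None
    return RawRecording(data=np.vstack(rows), sample_rate=float(meta["sample_rate"]),
                        channel_names=names, label=label)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a 16-bit EDF file with one 1 s data record per second.

    The sampling rate must be a positive integer and the recording is
    truncated to whole seconds. The emotion label, when present, is stored
    in the recording-identification header field.
    """
    rate = rec.sample_rate
    if abs(rate - round(rate)) > 1e-9 or rate <= 0:
        raise ValueError(f"EDF export requires an integer sampling rate, got {rate}")
    spr = int(round(rate))
    ns = rec.n_channels
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * spr]
    absmax = np.abs(data).max(axis=1)
    absmax[absmax == 0] = 1.0
    dig = np.round(data / absmax[:, None] * 32767.0).astype("<i2")
    names = rec.channel_names or [f"ch{i}" for i in range(ns)]
    rec_id = f"label={rec.label}" if rec.label is not None else "unlabeled"

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field(rec_id, 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (ns + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(n, 16) for n in names),
        b"".join(_edf_field("", 80) for _ in names),
        b"".join(_edf_field("uV", 8) for _ in names),
        b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in absmax),
        b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in absmax),
        b"".join(_edf_field("-32767", 8) for _ in names),
        b"".join(_edf_field("32767", 8) for _ in names),
        b"".join(_edf_field("", 80) for _ in names),
        b"".join(_edf_field(str(spr), 8) for _ in names),
        b"".join(_edf_field("", 32) for _ in names),
    ])
    with Path(path).open("wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = dig[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF file written by :func:`write_edf` (or any 16-bit EDF
    whose signals share one sampling rate)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def f(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", errors="replace").strip()

    rec_id = f(88, 80)
    n_records = int(f(236, 8))
    record_duration = float(f(244, 8))
    ns = int(f(252, 4))
    base = 256
    labels = [f(base + 16 * i, 16) for i in range(ns)]
    off = base + ns * (16 + 80 + 8)
    phys_min = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    phys_max = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_min = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_max = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8 + ns * 80
    spr = [int(f(off + 8 * i, 8)) for i in range(ns)]
    if len(set(spr)) != 1:
        raise ValueError(f"{path}: mixed per-signal sampling rates are not supported")
    spr0 = spr[0]
    header_bytes = 256 * (ns + 1)
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * ns * spr0
    if body.size < expected:
        raise ValueError(f"{path}: EDF body shorter than declared record count")
    body = body[:expected].reshape(n_records, ns, spr0)
    dig = body.transpose(1, 0, 2).reshape(ns, n_records * spr0).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (dig - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    label: Optional[int] = None
    if "label=" in rec_id:
        try:
            label = int(rec_id.split("label=")[1].split()[0])
        except ValueError:
            label = None
    rate = spr0 / record_duration
    return RawRecording(data=data, sample_rate=rate, channel_names=labels, label=label)


# ---------------------------------------------------------------------------
# hierarchical array container (HDF5)
# ---------------------------------------------------------------------------

def _check_version(obj, path) -> None:
    version = obj.attrs.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: unknown container format version {version!r}")


def save_recording_h5(rec: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["kind"] = "recording"
        fh.attrs["sample_rate"] = rec.sample_rate
        if rec.label is not None:
            fh.attrs["label"] = rec.label
        fh.create_dataset("data", data=rec.data)
        if rec.channel_names:
            fh.create_dataset("channel_names",
                              data=np.array(rec.channel_names, dtype="S"))


def load_recording_h5(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        names = [n.decode() for n in fh["channel_names"][()]] if "channel_names" in fh else []
        label = int(fh.attrs["label"]) if "label" in fh.attrs else None
        return RawRecording(data=fh["data"][()], sample_rate=float(fh.attrs["sample_rate"]),
                            channel_names=names, label=label)


def save_tensor(tensor: DETensor, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["kind"] = "de_tensor"
        fh.attrs["window_length"] = tensor.window_length
        fh.attrs["band_names"] = json.dumps([b.name for b in tensor.bands])
        fh.create_dataset("values", data=tensor.values)


def load_tensor(path: str | Path) -> DETensor:
    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        names = json.loads(fh.attrs["band_names"])
        bands = tuple(b for b in CANONICAL_BANDS if b.name in names)
        return DETensor(values=fh["values"][()],
                        window_length=float(fh.attrs["window_length"]), bands=bands)


def save_image(image: FeatureImage, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["kind"] = "feature_image"
        fh.attrs["scale_min"] = image.scale_min
        fh.attrs["scale_max"] = image.scale_max
        fh.create_dataset("values", data=image.values)


def load_image(path: str | Path) -> FeatureImage:
    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        return FeatureImage(values=fh["values"][()],
                            scale_min=float(fh.attrs["scale_min"]),
                            scale_max=float(fh.attrs["scale_max"]))


def save_checkpoint(classifier, path: str | Path, seed: Optional[int] = None,
                    extra: Optional[dict] = None) -> None:
    """Persist a classifier's parameters together with its config and seed."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["kind"] = "checkpoint"
        fh.attrs["config"] = json.dumps(dataclasses.asdict(classifier.config))
        if seed is not None:
            fh.attrs["seed"] = seed
        if extra:
            fh.attrs["extra"] = json.dumps(extra)
        grp = fh.create_group("params")
        for name, arr in classifier.state_dict().items():
            grp.create_dataset(name, data=arr)


def load_checkpoint(path: str | Path):
    """Rebuild a classifier from a checkpoint written by :func:`save_checkpoint`."""
    from .model.network import NetworkConfig, build_network

    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        cfg_dict = json.loads(fh.attrs["config"])
        for key in ("stage_block_counts", "input_shape"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg_dict["stage_widths"] = tuple(tuple(w) for w in cfg_dict["stage_widths"])
        config = NetworkConfig(**cfg_dict)
        classifier = build_network(config, seed=int(fh.attrs.get("seed", 0)))
        state = {name: ds[()] for name, ds in fh["params"].items()}
        classifier.load_state_dict(state)
        return classifier


# ---------------------------------------------------------------------------
# convenience dispatch
# ---------------------------------------------------------------------------

_FORMATS = {"edf": (read_edf, write_edf),
            "delimited": (read_delimited, write_delimited),
            "array-container": (load_recording_h5, save_recording_h5)}

_SUFFIX_FORMAT = {".edf": "edf", ".csv": "delimited", ".txt": "delimited",
                  ".h5": "array-container", ".hdf5": "array-container"}


def _resolve_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ValueError(f"unknown recording format {format!r}")
        return format
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer recording format from suffix {path.suffix!r}")


def read_recording(path: str | Path, format: Optional[str] = None) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _FORMATS[_resolve_format(path, format)][0](path)


def write_recording(rec: RawRecording, path: str | Path,
                    format: Optional[str] = None) -> None:
    path = Path(path)
    _FORMATS[_resolve_format(path, format)][1](rec, path)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject: int
    session: int
    trial: int
    label: int

    def __post_init__(self) -> None:
        if self.label not in EMOTION_LABELS:
            raise ValueError(f"label must be in {EMOTION_LABELS}, got {self.label}")


@dataclass
class Manifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        keys = [(e.subject, e.session, e.trial) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, session, trial) in manifest")

    def __len__(self) -> int:
        return len(self.entries)

    def label_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for e in self.entries:
            hist[e.label] = hist.get(e.label, 0) + 1
        return hist


def build_manifest(n_subjects: int = 15, n_sessions: int = 3, n_trials: int = 15,
                   label_cycle: Sequence[int] = (-1, 0, 1),
                   path_template: str = "subject{subject:02d}/session{session}/trial{trial:02d}.csv",
                   ) -> Manifest:
    """Enumerate subjects x sessions x trials into manifest rows.

    Trial labels cycle through ``label_cycle`` within each session (a
    synthetic stand-in for per-trial stimulus labels).
    """
    entries = []
    for subject in range(1, n_subjects + 1):
        for session in range(1, n_sessions + 1):
            for trial in range(1, n_trials + 1):
                entries.append(ManifestEntry(
                    path=path_template.format(subject=subject, session=session, trial=trial),
                    subject=subject, session=session, trial=trial,
                    label=label_cycle[(trial - 1) % len(label_cycle)],
                ))
    return Manifest(entries=entries)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "subject", "session", "trial", "label"])
        for e in manifest.entries:
            writer.writerow([e.path, e.subject, e.session, e.trial, e.label])


def read_manifest(path: str | Path) -> Manifest:
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        entries = [ManifestEntry(path=row["path"], subject=int(row["subject"]),
                                 session=int(row["session"]), trial=int(row["trial"]),
                                 label=int(row["label"]))
                   for row in reader]
    return Manifest(entries=entries)


# ---------------------------------------------------------------------------
# SEED-style .mat adapter
# ---------------------------------------------------------------------------

def read_seed_session(path: str | Path, sample_rate: float = 200.0,
                      strict: bool = True) -> list[tuple[RawRecording, int]]:
    """Read one SEED-style session file: trial arrays plus a label vector.

    ``strict`` enforces the 15-trial session layout; relax it only for
    generated test fixtures. Array names vary across dataset versions, so
    trials are identified by shape (channels x time) and ordered by the
    trailing integer in their names.
    """
    from scipy.io import loadmat

    raw = loadmat(str(path))
    arrays = {k: v for k, v in raw.items() if not k.startswith("__")}
    label_keys = [k for k in arrays if "label" in k.lower()]
    if not label_keys:
        raise ValueError(f"{path}: no label vector found in session file")
    labels = np.asarray(arrays.pop(label_keys[0])).ravel().astype(int)

    def trial_index(name: str) -> int:
        digits = "".join(ch for ch in name if ch.isdigit())
        return int(digits) if digits else 0

    trial_keys = sorted((k for k in arrays if np.ndim(arrays[k]) == 2),
                        key=trial_index)
    if strict and len(trial_keys) != 15:
        raise ValueError(
            f"{path}: expected 15 trial arrays in a SEED session, found {len(trial_keys)}"
        )
    if len(trial_keys) != len(labels):
        raise ValueError(
            f"{path}: {len(trial_keys)} trial arrays but {len(labels)} labels"
        )
    bad = [int(l) for l in labels if int(l) not in EMOTION_LABELS]
    if bad:
        raise ValueError(f"{path}: labels outside {EMOTION_LABELS}: {bad}")
    names = canonical_channel_names()
    out = []
    for key, label in zip(trial_keys, labels):
        data = np.asarray(arrays[key], dtype=float)
        ch_names = names if data.shape[0] == N_CHANNELS else [f"ch{i}" for i in range(data.shape[0])]
        out.append((RawRecording(data=data, sample_rate=sample_rate,
                                 channel_names=ch_names, label=int(label)), int(label)))
    return out


# ---------------------------------------------------------------------------
# score tables and session reports
# ---------------------------------------------------------------------------

def write_score_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write (subject, artwork, score) rows as CSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["subject", "artwork", "score"])
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in ("subject", "artwork", "score")})


def read_score_table(path: str | Path) -> list[dict]:
    with Path(path).open(newline="") as fh:
        return [{"subject": row["subject"], "artwork": row["artwork"],
                 "score": float(row["score"])}
                for row in csv.DictReader(fh)]


def write_session_report(result, path: str | Path) -> None:
    """Machine-readable session record (JSON)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "context": result.context,
        "pleasure_score": result.pleasure_score,
        "probabilities": {
            "negative": float(result.probabilities[0]),
            "neutral": float(result.probabilities[1]),
            "positive": float(result.probabilities[2]),
        },
        "timestamp": result.timestamp,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
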