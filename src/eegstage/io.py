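"""Recording and manifest I/O.

Two on-disk dialects are supported for a recording:

``matrix``
    A plain whitespace-delimited text grid, one row per time sample and one
    column per electrode in canonical montage order, amplitudes in µV, plus
    a JSON sidecar (``<file>.json``) holding subject id, class label,
    sampling rate and channel names. Round-trips are exact to 1e-6 µV.

``edf``
    European Data Format. Reading goes through :mod:`mne`; writing uses a
    minimal single-record-per-second EDF encoder defined here (16-bit
    quantization over the per-channel amplitude range, so round-trips are
    exact only to the quantization step). Subject id and label travel in
    the same JSON sidecar, since classic EDF has no reliable field for a
    diagnostic label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CANONICAL_CHANNELS, INGEST_RATES, LABELS, N_CHANNELS

__all__ = [
    "Recording",
    "ManifestEntry",
    "DatasetManifest",
    "ChannelMismatchError",
    "FormatError",
    "read_recording",
    "write_recording",
    "load_manifest",
    "save_manifest",
]


class ChannelMismatchError(ValueError):
    """Raised when a file's electrodes do not match the 19-channel montage."""


class FormatError(ValueError):
    """Raised for unreadable/ill-formed recording files or manifests."""


@dataclass
class Recording:
    """One subject's multi-channel EEG, time-major, amplitudes in µV.

    ``data`` has shape ``(n_samples, 19)`` with columns in canonical montage
    order. ``fs`` is 256 or 1024 Hz on ingest and always 256 Hz after
    preprocessing.
    """

    subject_id: str
    label: str
    fs: int
    data: np.ndarray
    channels: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if int(self.fs) not in INGEST_RATES:
            raise ValueError(f"unsupported sampling rate {self.fs} Hz (expected 256 or 1024)")
        self.fs = int(self.fs)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise ChannelMismatchError(
                f"data must be (n_samples, {N_CHANNELS}); got {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if tuple(self.channels) != CANONICAL_CHANNELS:
            raise ChannelMismatchError("channels must be in canonical montage order")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite amplitudes")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: int | None = None) -> "Recording":
        return replace(self, data=data, fs=self.fs if fs is None else fs)


def _canonical_permutation(names: list[str]) -> np.ndarray:
    """Column permutation mapping ``names`` onto the canonical order.

    Raises :class:`ChannelMismatchError` naming missing/extra electrodes.
    """
    cleaned = [n.strip() for n in names]
    lowered = [n.lower() for n in cleaned]
    want = [c.lower() for c in CANONICAL_CHANNELS]
    missing = [CANONICAL_CHANNELS[i] for i, w in enumerate(want) if w not in lowered]
    extra = [cleaned[i] for i, n in enumerate(lowered) if n not in want]
    if missing or extra or len(names) != N_CHANNELS:
        raise ChannelMismatchError(
            f"channel set mismatch: missing={missing}, unexpected={extra}"
        )
    return np.array([lowered.index(w) for w in want], dtype=int)


# ---------------------------------------------------------------------------
# matrix dialect


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_matrix(rec: Recording, path: Path) -> None:
    np.savetxt(path, rec.data, fmt="%.6f", delimiter="\t")
    meta = {
        "subject_id": rec.subject_id,
        "label": rec.label,
        "fs": rec.fs,
        "channels": list(rec.channels),
        "unit": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_matrix(path: Path, subject_id, label) -> Recording:
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    try:
        data = np.loadtxt(path, ndmin=2)
    except Exception as exc:  # pragma: no cover - loadtxt error text varies
        raise FormatError(f"cannot parse matrix file {path}: {exc}") from exc
    if "fs" not in meta:
        raise FormatError(f"matrix dialect needs an fs entry in the sidecar {sidecar}")
    names = meta.get("channels", list(CANONICAL_CHANNELS))
    perm = _canonical_permutation(list(names))
    return Recording(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        label=label or meta.get("label", ""),
        fs=int(meta["fs"]),
        data=data[:, perm],
    )


# ---------------------------------------------------------------------------
# EDF dialect

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF encoder: one 1-second data record per second of signal."""
    if rec.n_samples % rec.fs != 0:
        raise FormatError(
            "EDF dialect stores whole seconds; pad/trim the recording or use "
            f"the matrix dialect (n_samples={rec.n_samples}, fs={rec.fs})"
        )
    n_records = rec.n_samples // rec.fs
    ns = N_CHANNELS
    # floor/ceil to the 2-decimal header precision so the stored physical
    # range always encloses the data (plain rounding can clip extremes)
    phys_min = np.floor(rec.data.min(axis=0) * 100.0) / 100.0
    phys_max = np.ceil(rec.data.max(axis=0) * 100.0) / 100.0
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header = b"".join(
        [
            _edf_field(0, 8),
            _edf_field(rec.subject_id, 80),
            _edf_field(f"Startdate 01-JAN-2000 {rec.label}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )

    def sig(vals, width):
        return b"".join(_edf_field(v, width) for v in vals)

    header += sig(rec.channels, 16)
    header += sig([""] * ns, 80)
    header += sig(["uV"] * ns, 8)
    header += sig([f"{v:.2f}" for v in phys_min], 8)
    header += sig([f"{v:.2f}" for v in phys_max], 8)
    header += sig([_EDF_DIG_MIN] * ns, 8)
    header += sig([_EDF_DIG_MAX] * ns, 8)
    header += sig([""] * ns, 80)
    header += sig([rec.fs] * ns, 8)
    header += sig([""] * ns, 32)

    # re-read the rounded physical limits so the stored gain matches exactly
    pmin = np.array([float(f"{v:.2f}") for v in phys_min])
    pmax = np.array([float(f"{v:.2f}") for v in phys_max])
    gain = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.rint((rec.data - pmin) / gain + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        per_rec = digital.reshape(n_records, rec.fs, ns)
        for r in range(n_records):
            # EDF stores each record channel-by-channel
            fh.write(per_rec[r].T.tobytes())
    meta = {"subject_id": rec.subject_id, "label": rec.label}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_edf(path: Path, subject_id, label) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    if not fs.is_integer() or int(fs) not in INGEST_RATES:
        raise FormatError(f"EDF sampling rate {fs} Hz is not one of {sorted(INGEST_RATES)}")
    perm = _canonical_permutation(list(raw.ch_names))
    data_uv = raw.get_data().T * 1e6  # mne returns Volts, time-major after .T
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Recording(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        label=label or meta.get("label", ""),
        fs=int(fs),
        data=data_uv[:, perm],
    )


# ---------------------------------------------------------------------------
# public recording API


def _infer_dialect(path: Path) -> str:
    return "edf" if path.suffix.lower() == ".edf" else "matrix"


def read_recording(
    path: str | Path,
    dialect: str | None = None,
    *,
    subject_id: str | None = None,
    label: str | None = None,
) -> Recording:
    """Read a recording, permuting channels into canonical montage order.

    ``subject_id``/``label`` override whatever the sidecar carries (used when
    the authoritative metadata lives in a manifest).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "matrix":
        return _read_matrix(path, subject_id, label)
    if dialect == "edf":
        return _read_edf(path, subject_id, label)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_recording(rec: Recording, path: str | Path, dialect: str | None = None) -> Path:
    """Write a recording (plus its JSON sidecar); returns the file path."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "matrix":
        _write_matrix(rec, path)
    elif dialect == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# manifest

_MANIFEST_COLUMNS = ["subject_id", "label", "age", "sex", "path", "fs"]


@dataclass
class ManifestEntry:
    subject_id: str
    label: str
    age: float
    sex: str
    path: str
    fs: int


@dataclass
class DatasetManifest:
    """Table of subjects: id, class label, demographics and file location."""

    entries: list[ManifestEntry] = field(default_factory=list)
    root: Path | None = None  #: directory paths are resolved against

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, entry: ManifestEntry) -> Path:
        p = Path(entry.path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p

    def validate(self, check_paths: bool = True) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate subject_id(s) in manifest: {dupes}")
        for e in self.entries:
            if e.label not in LABELS:
                raise FormatError(f"unknown label {e.label!r} for subject {e.subject_id}")
            if int(e.fs) not in INGEST_RATES:
                raise FormatError(f"unsupported fs {e.fs} for subject {e.subject_id}")
            if e.sex not in ("M", "F"):
                raise FormatError(f"sex must be M or F for subject {e.subject_id}")
            if check_paths and not self.resolve(e).exists():
                raise FormatError(f"missing recording file for subject {e.subject_id}: {e.path}")

    def load_recording(self, entry: ManifestEntry) -> Recording:
        return read_recording(
            self.resolve(entry), subject_id=entry.subject_id, label=entry.label
        )

    def iter_recordings(self):
        for entry in self.entries:
            yield self.load_recording(entry)


def load_manifest(path: str | Path, check_paths: bool = True) -> DatasetManifest:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "sex": str, "label": str})
    except Exception as exc:
        raise FormatError(f"cannot parse manifest {path}: {exc}") from exc
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} lacks required column(s) {missing}")
    entries = [
        ManifestEntry(
            subject_id=str(r.subject_id),
            label=str(r.label),
            age=float(r.age),
            sex=str(r.sex),
            path=str(r.path),
            fs=int(r.fs),
        )
        for r in df.itertuples()
    ]
    manifest = DatasetManifest(entries=entries, root=path.parent)
    manifest.validate(check_paths=check_paths)
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([vars(e) for e in manifest.entries], columns=_MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return path
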