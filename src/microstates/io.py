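"""EEG containers and readers/writers.

The package's in-memory EEG container is :class:`EEGRecording`, a plain
channels x samples matrix in microvolts tied to a :class:`~.montage.Montage`
plus subject / condition / side labels. Two on-disk formats are supported:

* **matrix** -- a plain TSV numeric matrix (channels as rows) with a YAML
  sidecar (``<file>.yaml``) carrying sampling rate, channel labels and the
  subject metadata. Chosen so test fixtures stay plain text.
* **EDF** -- European Data Format, read through :mod:`mne`. A minimal
  16-bit EDF writer is provided for exporting synthetic recordings.

All analysis in this package operates on average-referenced data; the
readers re-reference on load by default so downstream identities
(GFP / global dissimilarity) hold exactly.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as _signal

from .montage import Montage, get_montage, standard_1020_19

CONDITIONS = ("pre", "post")
SIDES = ("r-TLE", "l-TLE")


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray = field(repr=False)
    fs: float
    montage: Montage
    subject_id: str = ""
    condition: str | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            ch, sm = bad[0]
            raise ValueError(
                f"non-finite sample at channel {self.montage.names[ch]!r}, "
                f"sample index {sm} ({len(bad)} non-finite values total)"
            )
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy())


def apply_average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average (idempotent).

    After this, every per-sample channel mean is 0, making GFP and global
    dissimilarity reference-free quantities.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def bandpass_filter(
    rec: EEGRecording, l_freq: float = 1.0, h_freq: float = 40.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, the package's default preprocessing.

    The 1-40 Hz band is a convention for resting-state microstate work;
    artifact rejection is the caller's responsibility.
    """
    nyq = rec.fs / 2.0
    if not 0 < l_freq < h_freq < nyq:
        raise ValueError("require 0 < l_freq < h_freq < Nyquist")
    sos = _signal.butter(order, [l_freq, h_freq], btype="bandpass", fs=rec.fs, output="sos")
    data = _signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


# ---------------------------------------------------------------------------
# matrix (TSV + YAML sidecar) format
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".yaml")


def write_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write the recording as a TSV matrix plus a YAML sidecar header."""
    path = Path(path)
    np.savetxt(path, rec.data, fmt="%.8g", delimiter="\t")
    meta = {
        "fs": float(rec.fs),
        "channels": list(rec.montage.names),
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "side": rec.side,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def _read_matrix(path: Path, montage: Montage) -> EEGRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise OSError(f"missing sidecar header {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    labels = [str(c) for c in meta["channels"]]
    if data.shape[0] != len(labels):
        raise OSError(
            f"matrix has {data.shape[0]} rows but sidecar lists "
            f"{len(labels)} channels"
        )
    data = _reorder(data, labels, montage)
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        montage=montage,
        subject_id=str(meta.get("subject_id") or ""),
        condition=meta.get("condition"),
        side=meta.get("side"),
    )


def _normalize_label(label: str) -> str:
    lab = label.strip()
    for prefix in ("EEG ", "eeg "):
        if lab.startswith(prefix):
            lab = lab[len(prefix):]
    return lab.split("-")[0].strip().lower()


def _reorder(data: np.ndarray, labels: list[str], montage: Montage) -> np.ndarray:
    """Reorder data rows to montage channel order, erroring on missing channels."""
    normalized = {_normalize_label(lab): i for i, lab in enumerate(labels)}
    rows = []
    for name in montage.names:
        key = name.lower()
        if key not in normalized:
            raise ValueError(f"channel {name!r} required by montage not found in file")
        rows.append(normalized[key])
    return data[rows]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path, montage: Montage) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    rec = EEGRecording(
        data=_reorder(data, list(raw.ch_names), montage),
        fs=float(raw.info["sfreq"]),
        montage=montage,
    )
    return rec


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Minimal 16-bit EDF export (one data record spanning the recording).

    Sufficient for round-tripping synthetic data and test fixtures; not a
    full-featured clinical EDF writer (no annotations, single record).
    """
    path = Path(path)
    n_ch, n_samp = rec.data.shape
    record_dur = n_samp / rec.fs

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # avoid zero dynamic range
    flat = phys_max - phys_min < 1e-9
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad(value: str, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.subject_id or 'X'}", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + 256 * n_ch), 8),
        pad("", 44),
        pad("1", 8),                       # number of data records
        pad(f"{record_dur:.6g}", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        b"".join(pad(name, 16) for name in rec.montage.names),
        b"".join(pad("", 80) for _ in range(n_ch)),           # transducer
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{phys_min[i]:.6g}", 8) for i in range(n_ch)),
        b"".join(pad(f"{phys_max[i]:.6g}", 8) for i in range(n_ch)),
        b"".join(pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),           # prefiltering
        b"".join(pad(str(n_samp), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),           # reserved
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for i in range(n_ch):
            scale = (dig_max - dig_min) / (phys_max[i] - phys_min[i])
            dig = np.round((rec.data[i] - phys_min[i]) * scale + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(struct.pack(f"<{n_samp}h", *dig.tolist()))


# ---------------------------------------------------------------------------
# public reader
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    format: str | None = None,
    montage: Montage | None = None,
    average_reference: bool = True,
) -> EEGRecording:
    """Load an EEG recording, reordering channels to montage order.

    Parameters
    ----------
    path
        Input file. Format inferred from the extension (``.edf`` vs
        anything else = matrix) unless ``format`` is given.
    format
        ``"edf"`` or ``"matrix"``.
    montage
        Target montage; defaults to the builtin 19-channel 10/20 set.
    average_reference
        Re-reference to the common average on load (default). All analysis
        functions assume average-referenced input.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    montage = montage or standard_1020_19()
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        rec = _read_edf(path, montage)
    elif format == "matrix":
        rec = _read_matrix(path, montage)
    else:
        raise ValueError(f"unknown format {format!r}")
    if average_reference:
        rec = apply_average_reference(rec)
    return rec


__all__ = [
    "EEGRecording",
    "apply_average_reference",
    "bandpass_filter",
    "read_recording",
    "write_matrix",
    "write_edf",
    "get_montage",
    "standard_1020_19",
    "Montage",
]
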