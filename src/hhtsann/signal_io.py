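"""EEG input/output: EDF and plain-matrix loading, channel selection, epoching.

Recordings are held as channels x samples float arrays in microvolts together
with sampling rate, 10-20 channel labels and a per-subject class label
(``MDD`` is the positive class, ``HC`` the negative one). Fixed-length epochs
cut by a sliding window are the unit of training and evaluation downstream.

Sample coordinates are 0-based and half-open throughout: epoch ``k`` covers
samples ``[k*step, k*step + window)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .exceptions import (
    ChannelLookupError,
    ConfigurationError,
    EmptyInputError,
    FormatError,
    UnsupportedDialectError,
)

#: 19 scalp electrodes of the 10-20 montage used for resting-state EEG; the
#: accompanying ECG lead is recorded but excluded from model input by default.
SCALP_19 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "T3", "T5", "C3", "C4", "Fz",
    "Cz", "Pz", "F8", "T4", "T6", "P3", "P4", "O1", "O2",
)

LABEL_CODES = {"HC": 0, "MDD": 1}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}
UNKNOWN_LABEL_CODE = -1

_ANNOTATION_LABELS = {"edf annotations", "bdf annotations"}


def label_code(label: str) -> int:
    """Map a class label to its integer code (MDD=1 positive, HC=0, unknown=-1)."""
    return LABEL_CODES.get(label, UNKNOWN_LABEL_CODE)


@dataclass
class EEGRecording:
    """One subject/condition's multichannel EEG trace.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered electrode labels (10-20 system).
    subject_id : str
        Opaque subject key; epochs inherit it.
    label : str
        ``"MDD"``, ``"HC"`` or ``"unknown"``.
    condition : str
        ``"eyes_open"``, ``"eyes_closed"`` or ``"unspecified"``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = "unknown"
    label: str = "unknown"
    condition: str = "unspecified"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError("data must be a 2-D channels x samples matrix")
        if self.data.shape[1] < 1:
            raise EmptyInputError("recording has no samples")
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise FormatError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Stacked fixed-length windows with per-epoch subject ids and labels."""

    epochs: np.ndarray  # (n_epochs, n_channels, window_samples)
    subject_ids: np.ndarray  # (n_epochs,) str
    labels: np.ndarray  # (n_epochs,) int codes, MDD=1 / HC=0 / unknown=-1
    fs: float
    window_samples: int
    step_samples: int
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise FormatError("epochs must be (n_epochs, n_channels, window)")
        if self.epochs.shape[2] != self.window_samples:
            raise FormatError("epoch length does not match window_samples")
        if not (len(self.subject_ids) == len(self.labels) == self.n_epochs):
            raise FormatError("subject_ids/labels length mismatch")
        for sid in np.unique(self.subject_ids):
            if len(np.unique(self.labels[self.subject_ids == sid])) > 1:
                raise FormatError(f"subject {sid!r} carries more than one label")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        _, first = np.unique(self.subject_ids, return_index=True)
        return [str(self.subject_ids[i]) for i in np.sort(first)]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self,
            epochs=self.epochs[mask],
            subject_ids=self.subject_ids[mask],
            labels=self.labels[mask],
        )

    def concat(self, other: "EpochSet") -> "EpochSet":
        if other.window_samples != self.window_samples or other.fs != self.fs:
            raise FormatError("cannot concatenate epoch sets with different geometry")
        return replace(
            self,
            epochs=np.concatenate([self.epochs, other.epochs]),
            subject_ids=np.concatenate([self.subject_ids, other.subject_ids]),
            labels=np.concatenate([self.labels, other.labels]),
        )


# ---------------------------------------------------------------------------
# EDF reading (header validation here; sample decoding delegated to MNE)
# ---------------------------------------------------------------------------

def _ascii_field(raw: bytes, start: int, width: int, name: str) -> str:
    chunk = raw[start:start + width]
    if len(chunk) < width:
        raise FormatError(f"EDF header truncated inside field {name!r}")
    try:
        return chunk.decode("ascii").strip()
    except UnicodeDecodeError as exc:
        raise FormatError(f"EDF header field {name!r} is not ASCII") from exc


def _int_field(raw: bytes, start: int, width: int, name: str) -> int:
    text = _ascii_field(raw, start, width, name)
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"EDF header field {name!r} is not an integer: {text!r}") from exc


def validate_edf_header(path: str | Path) -> dict:
    """Parse and sanity-check the fixed-offset ASCII EDF header.

    Returns the parsed fields. Raises :class:`FormatError` naming the first
    offending header field, or :class:`UnsupportedDialectError` when data
    channels use different per-record sample counts (mixed sampling rates).
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 256:
        raise FormatError("file shorter than the 256-byte EDF header ('version' block)")
    n_records = _int_field(blob, 236, 8, "number of data records")
    record_dur = float(_ascii_field(blob, 244, 8, "duration of a data record") or "0")
    ns = _int_field(blob, 252, 4, "number of signals")
    if ns < 1:
        raise FormatError("EDF header field 'number of signals' must be >= 1")
    header_bytes = _int_field(blob, 184, 8, "number of bytes in header")
    expect_header = 256 * (ns + 1)
    if header_bytes != expect_header:
        raise FormatError(
            f"EDF 'number of bytes in header' is {header_bytes}, expected {expect_header}"
        )
    if len(blob) < expect_header:
        raise FormatError("file truncated inside the per-signal EDF header")
    labels = [_ascii_field(blob, 256 + 16 * i, 16, f"label[{i}]") for i in range(ns)]
    spr_off = 256 + ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [
        _int_field(blob, spr_off + 8 * i, 8, f"samples per record[{i}]")
        for i in range(ns)
    ]
    data_spr = {
        s for s, lab in zip(spr, labels) if lab.lower() not in _ANNOTATION_LABELS
    }
    if len(data_spr) > 1:
        raise UnsupportedDialectError(
            "mixed per-channel sampling rates are not supported "
            f"(samples per record: {sorted(data_spr)})"
        )
    record_bytes = 2 * sum(spr)
    if n_records >= 0 and len(blob) < expect_header + n_records * record_bytes:
        raise FormatError(
            "file truncated inside the data records "
            f"(header promises {n_records} records of {record_bytes} bytes)"
        )
    return {
        "n_signals": ns,
        "n_records": n_records,
        "record_duration_s": record_dur,
        "labels": labels,
        "samples_per_record": spr,
    }


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    Channels keep file order; annotation channels are dropped. The header is
    validated first so corrupt or mixed-rate files fail with a precise error.
    """
    import mne

    validate_edf_header(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne wraps many error types
        raise FormatError(f"MNE could not read {path}: {exc}") from exc
    try:
        data = raw.get_data(units="uV")
    except Exception:
        data = raw.get_data() * 1e6  # channels without a dim-aware type
    names = list(raw.ch_names)
    keep = [i for i, n in enumerate(names) if n.lower() not in _ANNOTATION_LABELS]
    rec = EEGRecording(
        data=data[keep],
        fs=float(raw.info["sfreq"]),
        channel_names=[names[i] for i in keep],
        subject_id=Path(path).stem,
    )
    return rec


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write a recording as a plain EDF file (16-bit samples, 1-s records).

    Minimal writer used for simulated output and round-trip tests; requires an
    integer sampling rate. Amplitudes are quantised to the 16-bit range of each
    channel, so round-trips are exact to ~1/65535 of the channel's span.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((rec.n_channels, n_records * spr))
    padded[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    dig_max, dig_min = 32767, -32768
    scaled = np.clip(padded / phys_max[:, None] * dig_max, dig_min, dig_max)
    digital = np.round(scaled).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    head = b"".join([
        pad("0", 8),
        pad(f"{rec.subject_id} X X X", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (rec.n_channels + 1)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(rec.n_channels), 4),
    ])
    cols: list[bytes] = []
    for width, values in [
        (16, rec.channel_names),
        (80, [""] * rec.n_channels),
        (8, ["uV"] * rec.n_channels),
        (8, [f"{-m:.6g}"[:8] for m in phys_max]),
        (8, [f"{m:.6g}"[:8] for m in phys_max]),
        (8, [str(dig_min)] * rec.n_channels),
        (8, [str(dig_max)] * rec.n_channels),
        (80, [""] * rec.n_channels),
        (8, [str(spr)] * rec.n_channels),
        (32, [""] * rec.n_channels),
    ]:
        cols.append(b"".join(pad(str(v), width) for v in values))
    with open(path, "wb") as fh:
        fh.write(head)
        fh.writelines(cols)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Plain-matrix loading with a YAML sidecar
# ---------------------------------------------------------------------------

def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".meta.yaml")


def save_matrix(path: str | Path, rec: EEGRecording) -> None:
    """Save a recording as CSV (samples x channels, header row) + YAML sidecar."""
    path = Path(path)
    header = ",".join(rec.channel_names)
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="")
    meta = {
        "fs": float(rec.fs),
        "channel_names": list(rec.channel_names),
        "subject_id": rec.subject_id,
        "label": rec.label,
        "condition": rec.condition,
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_matrix(path: str | Path) -> EEGRecording:
    """Load a CSV/NPY matrix with its ``<stem>.meta.yaml`` sidecar.

    The sidecar is a key-value file with keys ``fs`` (Hz, required),
    ``channel_names``, ``subject_id``, ``label`` and ``condition``.
    CSV files are samples x channels with a header row; NPY files are
    channels x samples.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar metadata file {side}")
    meta = yaml.safe_load(side.read_text()) or {}
    if "fs" not in meta:
        raise FormatError(f"sidecar {side} lacks required key 'fs'")
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter=",", skiprows=1).T
        if data.ndim == 1:
            data = data[None, :]
    names = meta.get("channel_names") or [f"Ch{i + 1}" for i in range(data.shape[0])]
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=names,
        subject_id=str(meta.get("subject_id", path.stem)),
        label=str(meta.get("label", "unknown")),
        condition=str(meta.get("condition", "unspecified")),
    )


# ---------------------------------------------------------------------------
# Channel selection and epoching
# ---------------------------------------------------------------------------

def select_channels(rec: EEGRecording, keep: list[str]) -> EEGRecording:
    """Keep the named channels (case-insensitive), preserving source order."""
    lookup = {name.lower() for name in keep}
    missing = lookup - {n.lower() for n in rec.channel_names}
    if missing:
        raise ChannelLookupError(
            f"unknown channel(s) {sorted(missing)}; available: {rec.channel_names}"
        )
    idx = [i for i, n in enumerate(rec.channel_names) if n.lower() in lookup]
    return replace(
        rec,
        data=rec.data[idx],
        channel_names=[rec.channel_names[i] for i in idx],
    )


def drop_ecg(rec: EEGRecording) -> EEGRecording:
    """Drop ECG/EKG leads, the default policy before scalp-EEG modelling."""
    keep = [n for n in rec.channel_names if n.lower() not in ("ecg", "ekg")]
    return select_channels(rec, keep)


def extract_epochs(
    rec: EEGRecording, window_samples: int, step_samples: int | None = None
) -> EpochSet:
    """Cut a recording into fixed windows of ``window_samples``.

    Default step equals the window (no overlap). Epoch ``k`` covers samples
    ``[k*step, k*step + window)``; the count is
    ``floor((n_samples - window)/step) + 1``.
    """
    if step_samples is None:
        step_samples = window_samples
    if window_samples < 1 or step_samples < 1:
        raise ConfigurationError("window_samples and step_samples must be >= 1")
    if window_samples > rec.n_samples:
        raise EmptyInputError(
            f"window of {window_samples} samples exceeds recording length {rec.n_samples}"
        )
    n = (rec.n_samples - window_samples) // step_samples + 1
    starts = np.arange(n) * step_samples
    epochs = np.stack([rec.data[:, s:s + window_samples] for s in starts])
    return EpochSet(
        epochs=epochs,
        subject_ids=np.array([rec.subject_id] * n),
        labels=np.full(n, label_code(rec.label)),
        fs=rec.fs,
        window_samples=window_samples,
        step_samples=step_samples,
        channel_names=list(rec.channel_names),
    )


def build_epoch_set(
    recordings: list[EEGRecording], window_samples: int, step_samples: int | None = None
) -> EpochSet:
    """Epoch several recordings and stack them into one :class:`EpochSet`."""
    if not recordings:
        raise EmptyInputError("no recordings supplied")
    sets = [extract_epochs(r, window_samples, step_samples) for r in recordings]
    out = sets[0]
    for es in sets[1:]:
        out = out.concat(es)
    return out


def normalize_epochs(es: EpochSet, method: str = "zscore_per_channel") -> EpochSet:
    """Normalise each epoch-channel trace; ``none`` is the identity.

    ``zscore_per_channel`` removes the per-trace mean and divides by the
    standard deviation clamped below at 1e-12, so constant traces map to zero.
    """
    if method == "none":
        return es
    if method != "zscore_per_channel":
        raise ConfigurationError(f"unknown normalisation method {method!r}")
    mean = es.epochs.mean(axis=2, keepdims=True)
    std = np.maximum(es.epochs.std(axis=2, keepdims=True), 1e-12)
    return replace(es, epochs=(es.epochs - mean) / std)


def save_epoch_set(path: str | Path, es: EpochSet) -> None:
    """Persist an epoch set as a single .npz archive."""
    np.savez(
        path,
        epochs=es.epochs,
        subject_ids=es.subject_ids.astype(str),
        labels=es.labels,
        fs=es.fs,
        window_samples=es.window_samples,
        step_samples=es.step_samples,
        channel_names=np.array(es.channel_names, dtype=str),
    )


def load_epoch_set(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        return EpochSet(
            epochs=z["epochs"],
            subject_ids=z["subject_ids"],
            labels=z["labels"],
            fs=float(z["fs"]),
            window_samples=int(z["window_samples"]),
            step_samples=int(z["step_samples"]),
            channel_names=[str(c) for c in z["channel_names"]],
        )
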