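"""Reading, writing, resampling and windowing of multi-lead ECG.

All model I/O in this package operates on fixed 12 x 1024 windows at the
canonical sampling rate of 500 Hz.  This module converts between on-disk
recordings of arbitrary length (WFDB, CSV, or raw ``.npy`` arrays) and those
windows, and stitches reconstructed windows back to the original length.

Amplitudes are millivolts everywhere; no filtering or scaling is applied on
read, so samples pass through the pipeline untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

#: Canonical 12-lead order used by every module; leads are indexed 0-11 in
#: this order (6 limb leads followed by the 6 precordial leads).
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: Map lead name -> 0-based canonical index (case-insensitive lookup helper).
LEAD_INDEX = {name: i for i, name in enumerate(LEAD_NAMES)}

#: Canonical sampling rate (Hz) of all model I/O.
CANONICAL_FS = 500.0

#: Fixed model window length in samples.
WINDOW_LEN = 1024


def lead_index(name: str) -> int:
    """Return the 0-based canonical index for a lead name such as ``"aVL"``."""
    key = name.strip()
    norm = {n.upper(): i for n, i in LEAD_INDEX.items()}
    try:
        return norm[key.upper()]
    except KeyError:
        raise KeyError(f"unknown lead name {name!r}; expected one of {LEAD_NAMES}")


@dataclass
class EcgRecord:
    """A multi-lead ECG recording.

    Attributes
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Amplitudes in mV.
    fs : float
        Sampling rate in Hz.
    lead_names : tuple of str
        One name per row of ``samples``.
    meta : dict
        Free-form metadata (record id, labels, ...).
    """

    samples: np.ndarray
    fs: float
    lead_names: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [leads x samples] array")
        if len(self.lead_names) != self.samples.shape[0]:
            raise ValueError("lead_names length must equal number of rows")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.lead_names = tuple(self.lead_names)

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EcgWindow:
    """One 12 x 1024 segment of a record, the unit of all model I/O.

    ``pad_len`` counts trailing samples that are zero padding rather than
    signal; metric computations exclude them.
    """

    samples: np.ndarray
    source_record: str = ""
    window_index: int = 0
    pad_len: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (12, WINDOW_LEN):
            raise ValueError(f"window must be 12 x {WINDOW_LEN}, got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")
        if not (0 <= self.pad_len < WINDOW_LEN):
            raise ValueError("pad_len must be in [0, 1023]")
        if self.window_index < 0:
            raise ValueError("window_index must be >= 0")


def _canonical_order(samples: np.ndarray, lead_names) -> tuple:
    """Reorder rows into canonical order when all 12 canonical leads appear."""
    upper = [n.strip().upper() for n in lead_names]
    canon = [n.upper() for n in LEAD_NAMES]
    if sorted(upper) == sorted(canon):
        perm = [upper.index(c) for c in canon]
        return samples[perm], LEAD_NAMES
    return samples, tuple(lead_names)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path, fs: float) -> EcgRecord:
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise ValueError(f"cannot parse CSV {path}: {exc}") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric cell in column {col!r} at data row {row}")
    if df.isna().any().any():
        raise ValueError(f"missing values in CSV {path}")
    samples = df.to_numpy(dtype=np.float64).T
    names = list(df.columns)
    known = {n.upper() for n in LEAD_NAMES}
    unmatched = [n for n in names if n.strip().upper() not in known]
    if unmatched:
        raise ValueError(f"unknown lead names in {path}: {unmatched}")
    samples, names = _canonical_order(samples, names)
    meta = _read_sidecar(path)
    fs = float(meta.get("fs", fs))
    return EcgRecord(samples, fs, names, meta)


def _write_csv(record: EcgRecord, path: Path) -> None:
    df = pd.DataFrame(record.samples.T, columns=list(record.lead_names))
    df.to_csv(path, index=False, float_format="%.6f")
    _write_sidecar(record, path)


# ---------------------------------------------------------------------------
# Raw arrays (.npy with JSON sidecar)
# ---------------------------------------------------------------------------

def _read_npy(path: Path, fs: float) -> EcgRecord:
    samples = np.load(path)
    meta = _read_sidecar(path)
    names = meta.get("lead_names", list(LEAD_NAMES[: samples.shape[0]]))
    fs = float(meta.get("fs", fs))
    samples, names = _canonical_order(np.asarray(samples, float), names)
    return EcgRecord(samples, fs, names, meta)


def _write_npy(record: EcgRecord, path: Path) -> None:
    np.save(path, record.samples)
    _write_sidecar(record, path)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar(path: Path) -> dict:
    sp = _sidecar_path(path)
    if sp.exists():
        return json.loads(sp.read_text())
    return {}


def _write_sidecar(record: EcgRecord, path: Path) -> None:
    meta = dict(record.meta)
    meta.update({
        "fs": record.fs,
        "lead_names": list(record.lead_names),
        "record_id": record.meta.get("record_id", path.stem),
    })
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=str))


# ---------------------------------------------------------------------------
# WFDB (minimal: header + format-16 signal file)
# ---------------------------------------------------------------------------
# Only the subset of the header grammar needed for 12-lead rhythm records is
# supported: one .dat file shared by all signals, format 16 (little-endian
# int16, interleaved), per-signal gain(baseline)/units.

_WFDB_GAIN = 1000.0  # ADC units per mV on write: 1 LSB = 1 uV


def _read_wfdb(path: Path) -> EcgRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    gains, baselines, units, names, fmts = [], [], [], [], []
    dat_name = None
    for spec_line in lines[1:1 + n_sig]:
        parts = spec_line.split()
        dat_name = parts[0]
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        fmts.append(fmt)
        gain_field = parts[2] if len(parts) > 2 else "200"
        unit = "mV"
        if "/" in gain_field:
            gain_field, unit = gain_field.split("/", 1)
        baseline = 0
        if "(" in gain_field:
            gain_field, rest = gain_field.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gains.append(float(gain_field) or 200.0)
        baselines.append(baseline)
        units.append(unit)
        names.append(parts[-1] if len(parts) > 8 else f"sig{len(names)}")
    if any(f != "16" for f in fmts):
        raise ValueError(f"unsupported WFDB signal format(s) {fmts}; only 16 is supported")
    dat = hea.parent / dat_name
    raw = np.fromfile(dat, dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_sig]
    data = raw.reshape(-1, n_sig).T.astype(np.float64)
    for i in range(n_sig):
        data[i] = (data[i] - baselines[i]) / gains[i]
        if units[i].lower() in ("uv", "microvolt", "microvolts"):
            data[i] /= 1000.0
    samples, names = _canonical_order(data, names)
    return EcgRecord(samples, fs, names, {"record_id": name})


def _write_wfdb(record: EcgRecord, path: Path) -> None:
    base = path.with_suffix("")
    name = base.name
    n_sig, n_samples = record.samples.shape
    adc = np.round(record.samples * _WFDB_GAIN)
    if np.abs(adc).max() > 32767:
        raise ValueError("amplitude exceeds WFDB format-16 range at gain 1000/mV")
    adc = adc.astype("<i2")
    lines = [f"{name} {n_sig} {record.fs:g} {n_samples}"]
    for lead in record.lead_names:
        lines.append(f"{name}.dat 16 {int(_WFDB_GAIN)}(0)/mV 16 0 0 0 0 {lead}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.T.reshape(-1).tofile(base.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# Public read/write
# ---------------------------------------------------------------------------

_FORMATS = ("wfdb", "csv", "npy")


def read_record(path, format: str | None = None, fs: float = CANONICAL_FS) -> EcgRecord:
    """Read an ECG record from disk.

    Parameters
    ----------
    path : path-like
        File to read (for WFDB, either the ``.hea`` or the base name).
    format : {"wfdb", "csv", "npy"}, optional
        Inferred from the file suffix when omitted.
    fs : float
        Fallback sampling rate when no sidecar/header states one.
    """
    path = Path(path)
    if format is None:
        format = {".hea": "wfdb", ".dat": "wfdb", ".csv": "csv", ".npy": "npy"}.get(
            path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "wfdb":
        return _read_wfdb(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_csv(path, fs) if format == "csv" else _read_npy(path, fs)


def write_record(record: EcgRecord, path, format: str | None = None) -> Path:
    """Write a record in the named format; emits a metadata sidecar/header."""
    path = Path(path)
    if format is None:
        format = {".hea": "wfdb", ".dat": "wfdb", ".csv": "csv", ".npy": "npy"}.get(
            path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "wfdb":
        _write_wfdb(record, path)
    elif format == "csv":
        _write_csv(record, path)
    elif format == "npy":
        _write_npy(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def resample(record: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample a record to ``target_fs`` with a polyphase filter.

    A no-op (bitwise-identical samples) when the rates already match; output
    length is ``round(n * target_fs / fs)``.
    """
    if target_fs <= 0 or record.fs <= 0:
        raise ValueError("sampling rates must be positive")
    if target_fs == record.fs:
        return EcgRecord(record.samples.copy(), record.fs, record.lead_names,
                         dict(record.meta))
    frac = Fraction(target_fs / record.fs).limit_denominator(10000)
    out = resample_poly(record.samples, frac.numerator, frac.denominator, axis=1)
    n_out = int(round(record.n_samples * target_fs / record.fs))
    if out.shape[1] >= n_out:
        out = out[:, :n_out]
    else:
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])))
    meta = dict(record.meta)
    meta["resampled_from_fs"] = record.fs
    return EcgRecord(out, target_fs, record.lead_names, meta)


def window_record(record: EcgRecord, window_len: int = WINDOW_LEN) -> list:
    """Cut a 12-lead record into non-overlapping fixed-length windows.

    The tail is zero-padded up to a multiple of ``window_len``; the last
    window's ``pad_len`` records how many trailing samples are padding.
    A 5000-sample record therefore yields 5 windows, the last carrying
    120 padded samples.
    """
    if record.n_leads != 12:
        raise ValueError(f"windowing requires 12 leads, got {record.n_leads}")
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    n = record.n_samples
    if n == 0:
        raise ValueError("cannot window an empty record")
    n_windows = math.ceil(n / window_len)
    total = n_windows * window_len
    padded = np.pad(record.samples, ((0, 0), (0, total - n)))
    rec_id = str(record.meta.get("record_id", ""))
    windows = []
    for w in range(n_windows):
        chunk = padded[:, w * window_len:(w + 1) * window_len]
        pad_len = total - n if w == n_windows - 1 else 0
        if window_len == WINDOW_LEN:
            windows.append(EcgWindow(chunk, rec_id, w, pad_len))
        else:  # non-canonical window length: bypass the fixed-shape type
            win = EcgWindow.__new__(EcgWindow)
            win.samples, win.source_record = chunk, rec_id
            win.window_index, win.pad_len = w, pad_len
            windows.append(win)
    return windows


def stitch_windows(windows, original_len: int, fs: float = CANONICAL_FS,
                   meta: dict | None = None) -> EcgRecord:
    """Inverse of :func:`window_record`: concatenate windows and drop padding."""
    if not windows:
        raise ValueError("no windows to stitch")
    order = sorted(windows, key=lambda w: w.window_index)
    sources = {w.source_record for w in order}
    if len(sources) > 1:
        raise ValueError(f"windows come from different records: {sorted(sources)}")
    indices = [w.window_index for w in order]
    expected = list(range(len(order)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ValueError(f"missing window index(es): {missing}")
    full = np.concatenate([w.samples for w in order], axis=1)
    if original_len > full.shape[1]:
        raise ValueError(f"original_len {original_len} exceeds stitched length {full.shape[1]}")
    meta = dict(meta or {})
    meta.setdefault("record_id", order[0].source_record)
    return EcgRecord(full[:, :original_len], fs, LEAD_NAMES, meta)
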