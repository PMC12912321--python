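"""Synthetic 12-lead ECG with exact lead algebra and known R-peak times.

The generator models the heart as a rotating 3-D dipole whose trajectory is
a sum of five Gaussian waves (P, Q, R, S, T) in beat phase, in the spirit of
dynamical ECG models.  Leads I, II and V1-V6 are fixed linear projections of
the dipole (a Dower-style projection matrix ships as a documented constant);
the remaining limb leads are derived through the exact Einthoven/Goldberger
identities

    III = II - I,   aVR = -(I + II)/2,   aVL = I - II/2,   aVF = II - I/2,

so at zero noise those identities hold to machine precision - the structure
the reconstruction method exploits.  Independent Gaussian sensor noise is
added per lead *after* projection, so beats still occur simultaneously
across leads in the underlying source, as feature-level evaluation assumes.

Ground truth (R-peak times, heart rate, rate-based labels) is known by
construction, which makes the generator the test bed for every level of the
benchmark without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_windowing import CANONICAL_FS, LEAD_NAMES, EcgRecord

#: Dower-style projection of the dipole (x, y, z) onto the 8 measured leads,
#: rows ordered (I, II, V1..V6).  Values follow the classical Dower image-
#: space matrix; III/aVR/aVL/aVF are *derived*, never projected.
DOWER_LEAD_VECTORS = np.array([
    [0.632, -0.235, 0.059],   # I
    [0.235, 1.066, -0.132],   # II
    [-0.515, 0.157, -0.917],  # V1
    [0.044, 0.164, -1.387],   # V2
    [0.882, 0.098, -1.277],   # V3
    [1.213, 0.127, -0.601],   # V4
    [1.125, 0.127, -0.086],   # V5
    [0.831, 0.076, 0.230],    # V6
])

#: Per-wave (3-axis amplitude mV, Gaussian width rad, phase center rad).
#: R sits at phase 0 of each beat; P leads it, T trails it; amplitudes give
#: a dominant R and a broad T after projection.
DEFAULT_WAVE_PARAMS = {
    "P": {"amp": (0.06, 0.14, 0.01), "width": 0.22, "center": -1.05},
    "Q": {"amp": (-0.06, -0.10, 0.05), "width": 0.08, "center": -0.22},
    "R": {"amp": (1.00, 1.20, 0.30), "width": 0.11, "center": 0.0},
    "S": {"amp": (-0.10, -0.20, 0.10), "width": 0.09, "center": 0.22},
    "T": {"amp": (0.18, 0.30, -0.05), "width": 0.45, "center": 1.75},
}


@dataclass
class SynthConfig:
    """Simulator parameters; defaults produce a clean 10-s sinus recording."""

    fs: float = CANONICAL_FS
    duration: float = 10.0
    hr_bpm: float = 72.0
    hr_jitter: float = 0.02       # fractional RR variability (sd of RR / RR)
    wave_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_WAVE_PARAMS.items()})
    lead_vectors: np.ndarray = field(
        default_factory=lambda: DOWER_LEAD_VECTORS.copy())
    noise_sd: float = 0.0         # mV, per lead, after projection
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration <= 0 or self.hr_bpm <= 0:
            raise ValueError("fs, duration and hr_bpm must be positive")
        if self.noise_sd < 0 or self.hr_jitter < 0:
            raise ValueError("noise_sd and hr_jitter must be >= 0")
        self.lead_vectors = np.asarray(self.lead_vectors, dtype=np.float64)
        if self.lead_vectors.shape != (8, 3):
            raise ValueError("lead_vectors must be 8 x 3 (rows I, II, V1..V6)")


@dataclass
class SynthRecord:
    """A simulated recording plus its ground truth."""

    record: EcgRecord
    rpeak_times: np.ndarray
    true_hr: float
    labels: tuple = ()

    @property
    def samples(self) -> np.ndarray:
        return self.record.samples


def _rate_labels(hr_bpm: float) -> tuple:
    labels = []
    if hr_bpm < 60.0:
        labels.append("bradycardia")
    if hr_bpm > 100.0:
        labels.append("tachycardia")
    return tuple(labels)


def simulate_record(cfg: SynthConfig, record_id: str = "synth") -> SynthRecord:
    """Simulate one 12-lead recording; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    rr = 60.0 / cfg.hr_bpm
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    # R-peak times: jittered RR intervals, first R mid-way into the record's
    # first cycle; extend knots past both ends so phase interpolation covers
    # [0, duration].
    n_beats = int(np.ceil(cfg.duration / rr)) + 4
    jit = rng.standard_normal(n_beats + 2)
    if cfg.hr_jitter > 0:
        jit = np.clip(jit, -3.0, 3.0) * cfg.hr_jitter
    else:
        jit = np.zeros(n_beats + 2)
    rr_k = rr * (1.0 + jit)
    first_r = 0.35 * rr
    knots = first_r + np.concatenate([[-rr_k[0] - rr_k[1], -rr_k[1], 0.0],
                                      np.cumsum(rr_k[2:])])
    theta_knots = 2.0 * np.pi * np.arange(len(knots), dtype=np.float64)
    theta = np.interp(t, knots, theta_knots)

    # dipole trajectory: sum of Gaussians in wrapped phase
    dipole = np.zeros((3, n))
    for wave in cfg.wave_params.values():
        amp = np.asarray(wave["amp"], dtype=np.float64)
        d = np.mod(theta - wave["center"] + np.pi, 2.0 * np.pi) - np.pi
        g = np.exp(-0.5 * (d / wave["width"]) ** 2)
        dipole += amp[:, None] * g[None, :]

    projected = cfg.lead_vectors @ dipole  # rows: I, II, V1..V6
    lead_i, lead_ii = projected[0], projected[1]
    samples = np.empty((12, n))
    samples[0] = lead_i
    samples[1] = lead_ii
    samples[2] = lead_ii - lead_i                 # III
    samples[3] = -(lead_i + lead_ii) / 2.0        # aVR
    samples[4] = lead_i - lead_ii / 2.0           # aVL
    samples[5] = lead_ii - lead_i / 2.0           # aVF
    samples[6:] = projected[2:]                   # V1..V6
    if cfg.noise_sd > 0:
        samples = samples + rng.normal(0.0, cfg.noise_sd, size=samples.shape)

    rpeaks = knots[(knots >= 0.0) & (knots <= cfg.duration)]
    labels = _rate_labels(cfg.hr_bpm)
    meta = {"record_id": record_id, "true_hr": cfg.hr_bpm,
            "labels": list(labels), "seed": cfg.seed}
    record = EcgRecord(samples, cfg.fs, LEAD_NAMES, meta)
    return SynthRecord(record, rpeaks, cfg.hr_bpm, labels)


#: Per-record parameter ranges the dataset generator draws from.  Heart rate
#: spans bradycardic through tachycardic sinus rhythm; the two gain factors
#: vary overall voltage and T-wave prominence between "subjects".
DEFAULT_RANGES = {
    "hr_bpm": (50.0, 110.0),
    "gain": (0.85, 1.15),
    "t_gain": (0.8, 1.2),
}


def windows_from_records(records, per_record: int | None = None) -> list:
    """Cut simulated records into model windows (via :func:`window_record`).

    ``per_record`` keeps only the first windows of each record - e.g. 4 keeps
    the unpadded 1024-sample windows of a 10-s, 500-Hz recording and drops
    the mostly-padding fifth window.
    """
    from .io_windowing import window_record

    windows = []
    for rec in records:
        ws = window_record(rec.record if isinstance(rec, SynthRecord) else rec)
        windows.extend(ws if per_record is None else ws[:per_record])
    return windows


def make_dataset(n: int, cfg_ranges: dict | None = None, seed: int = 0,
                 base_config: SynthConfig | None = None):
    """Draw ``n`` records with per-record parameters from ``cfg_ranges``.

    Returns ``(records, manifest)`` where the manifest is a DataFrame of the
    per-record parameters and labels, for parameter-recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_RANGES)
    ranges.update(cfg_ranges or {})
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
    base = base_config or SynthConfig()
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for i in range(n):
        hr = float(rng.uniform(*ranges["hr_bpm"]))
        g = float(rng.uniform(*ranges["gain"]))
        tg = float(rng.uniform(*ranges["t_gain"]))
        waves = {k: dict(v) for k, v in base.wave_params.items()}
        for name, wave in waves.items():
            scale = g * (tg if name == "T" else 1.0)
            wave["amp"] = tuple(scale * a for a in wave["amp"])
        child_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(base, hr_bpm=hr, wave_params=waves, seed=child_seed)
        rec = simulate_record(cfg, record_id=f"synth{i:05d}")
        records.append(rec)
        rows.append({"record_id": f"synth{i:05d}", "hr_bpm": hr, "gain": g,
                     "t_gain": tg, "noise_sd": base.noise_sd,
                     "hr_jitter": base.hr_jitter, "seed": child_seed,
                     "labels": ";".join(rec.labels)})
    manifest = pd.DataFrame(rows)
    return records, manifest
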