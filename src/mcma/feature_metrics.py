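"""Feature-level evaluation: cross-lead heart-rate consistency.

Heart rate is a physiological invariant across leads - every lead of a real
12-lead ECG sees the same beats at the same times - so the spread of per-lead
mean heart-rate estimates (MHR) over the 12 leads of a *generated* ECG
measures whether the generator produced physiologically coherent beats.  The
summary statistics are the mean over leads (MMHR), their population standard
deviation (MHR_SD), max-min range (MHR_Range) and coefficient of variation
(MHR_CV = MHR_SD / MMHR).

R peaks come from a Pan-Tompkins-style detector (band-pass 5-15 Hz ->
derivative -> squaring -> 150 ms moving-window integration -> adaptive
signal/noise thresholds with a 200 ms refractory period).  The detector is a
plug-in seam: any callable ``(x, fs) -> RPeakTrain`` can replace it, and
reported results should name the detector used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .io_windowing import LEAD_NAMES


@dataclass
class RPeakTrain:
    """Detected R-peak times (seconds, strictly increasing) for one lead."""

    times: np.ndarray
    lead_index: int = 0
    fs: float = 500.0
    too_short: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValueError("times must be a 1-D array")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)


def detect_rpeaks(x, fs: float, lead_index: int = 0,
                  refractory_s: float = 0.2) -> RPeakTrain:
    """Pan-Tompkins-style R-peak detection.

    Works on upright or inverted QRS complexes (the decision statistic is the
    squared band-passed derivative).  Signals shorter than ~2 s return an
    empty, flagged train rather than an error.
    """
    x = np.asarray(x, dtype=np.float64)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.ndim != 1:
        raise ValueError("detect_rpeaks expects a single-lead vector")
    if x.size < int(2 * fs):
        return RPeakTrain(np.empty(0), lead_index, fs, too_short=True)
    if np.ptp(x) == 0:
        return RPeakTrain(np.empty(0), lead_index, fs)

    # band-pass 5-15 Hz (QRS energy band)
    b, a = butter(2, [5.0, 15.0], btype="band", fs=fs)
    bp = filtfilt(b, a, x)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refr = int(round(refractory_s * fs))
    # local maxima of the integrated signal, refractory-spaced
    from scipy.signal import find_peaks

    cand, _ = find_peaks(mwi, distance=refr)
    if cand.size == 0:
        return RPeakTrain(np.empty(0), lead_index, fs)

    # adaptive signal/noise threshold (classic running-estimate rule)
    spki = float(np.max(mwi[: int(2 * fs)]) * 0.5)
    npki = float(np.mean(mwi[: int(2 * fs)]) * 0.5)
    accepted = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] >= thr:
            accepted.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
    if not accepted:
        return RPeakTrain(np.empty(0), lead_index, fs)

    # refine each fiducial to the extremum of |band-passed signal| nearby
    half = int(round(0.075 * fs))
    peaks = []
    for c in accepted:
        lo = max(0, c - half)
        hi = min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(peaks)
    # enforce the refractory period after refinement
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] >= refr:
            kept.append(int(p))
    return RPeakTrain(np.asarray(kept) / fs, lead_index, fs)


def mhr(peaks: RPeakTrain):
    """Mean heart rate in bpm: 60 (n-1) / (last peak - first peak).

    Returns ``None`` (a flagged missing value) with fewer than 2 peaks.
    """
    if peaks.n < 2:
        return None
    span = float(peaks.times[-1] - peaks.times[0])
    if span <= 0:
        return None
    return 60.0 * (peaks.n - 1) / span


@dataclass
class HrConsistency:
    """Cross-lead heart-rate consistency summary for one 12-lead signal."""

    mhr: np.ndarray          # per-lead bpm, NaN where undetectable
    mmhr: float
    sd: float
    range: float
    cv: float
    n_leads_valid: int
    valid: bool = True

    def as_row(self) -> dict:
        return {"MHR_SD": self.sd, "MHR_CV": self.cv, "MHR_Range": self.range}


def hr_consistency(window12, fs: float, detector=detect_rpeaks) -> HrConsistency:
    """Per-lead MHR plus SD / Range / CV across leads.

    Leads with fewer than 2 detected peaks are excluded; divisors adjust to
    the number of valid leads.  With fewer than 2 valid leads the result is
    flagged invalid (statistics NaN).
    """
    window12 = np.asarray(window12, dtype=np.float64)
    if window12.ndim != 2 or window12.shape[0] != 12:
        raise ValueError(f"expected a 12 x L array, got {window12.shape}")
    rates = np.full(12, np.nan)
    for j in range(12):
        r = mhr(detector(window12[j], fs, lead_index=j))
        if r is not None:
            rates[j] = r
    valid = np.isfinite(rates)
    nv = int(valid.sum())
    if nv < 2:
        return HrConsistency(rates, np.nan, np.nan, np.nan, np.nan, nv, valid=False)
    v = rates[valid]
    mmhr = float(v.mean())
    rng_ = float(v.max() - v.min())
    # population SD over the valid leads; exactly 0 when all rates coincide
    sd = float(v.std()) if rng_ > 0 else 0.0
    cv = sd / mmhr if mmhr > 0 else np.nan
    return HrConsistency(rates, mmhr, sd, rng_, cv, nv)


def consistency_from_rates(rates) -> HrConsistency:
    """SD / Range / CV of an explicit per-lead MHR vector (no detection)."""
    rates = np.asarray(rates, dtype=np.float64)
    valid = np.isfinite(rates)
    nv = int(valid.sum())
    if nv < 2:
        return HrConsistency(rates, np.nan, np.nan, np.nan, np.nan, nv, valid=False)
    v = rates[valid]
    mmhr = float(v.mean())
    rng_ = float(v.max() - v.min())
    sd = float(v.std()) if rng_ > 0 else 0.0
    return HrConsistency(rates, mmhr, sd, rng_,
                         sd / mmhr if mmhr > 0 else np.nan, nv)


def _records_as_arrays(records):
    out = []
    for r in records:
        samples = getattr(r, "samples", r)
        out.append(np.asarray(samples, dtype=np.float64))
    return out


def evaluate_feature(generator, records, fs: float, leads=None,
                     detector=detect_rpeaks) -> pd.DataFrame:
    """Feature-level report: one row per input lead plus the original reference.

    ``records`` are full-duration 12-lead arrays/records (heart-rate
    statistics need several beats, so the unit here is the whole recording,
    stitched back from windows if the generator works window-wise).  The
    returned table has rows ``Original, I, II, ..., V6`` and columns
    ``MHR_SD``, ``MHR_CV`` (as percent) and ``MHR_Range``, each averaged over
    records with a valid consistency result.
    """
    arrays = _records_as_arrays(records)
    if not arrays:
        raise ValueError("no records to evaluate")
    leads = tuple(range(12)) if leads is None else tuple(int(i) for i in leads)

    def _mean_row(results):
        ok = [r for r in results if r.valid]
        if not ok:
            return {"MHR_SD": np.nan, "MHR_CV": np.nan, "MHR_Range": np.nan}
        return {
            "MHR_SD": float(np.mean([r.sd for r in ok])),
            "MHR_CV": float(np.mean([r.cv for r in ok])) * 100.0,
            "MHR_Range": float(np.mean([r.range for r in ok])),
        }

    rows = {}
    rows["Original"] = _mean_row(
        [hr_consistency(a, fs, detector) for a in arrays])
    for i in leads:
        results = []
        for a in arrays:
            gen = np.asarray(generator(a[i], i))
            if gen.shape != a.shape:
                raise ValueError(
                    f"generator returned shape {gen.shape} for lead {i}; "
                    f"expected {a.shape}")
            results.append(hr_consistency(gen, fs, detector))
        rows[LEAD_NAMES[i]] = _mean_row(results)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "Input"
    return df


def write_report(df: pd.DataFrame, path) -> None:
    """Write the feature-level table (CV column in percent) as CSV."""
    df.to_csv(path, float_format="%.4f")
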