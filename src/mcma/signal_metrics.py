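"""Signal-level evaluation: per-lead MSE and Pearson correlation.

The benchmark's signal level drives a generator (any
``callable(single_lead_vector, lead_index) -> 12 x L array``) with every
input lead of every window and scores each output lead against the truth,
yielding 12 x 12 matrices whose rows are input leads and columns output
leads, plus row means and grand means - the layout of the published
evaluation tables.

PCC uses population moments; a constant trace on either side is a degenerate
case and scores 0 (an uninformative flat reconstruction earns no credit, and
means remain well defined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_windowing import LEAD_NAMES, EcgWindow


def pcc(x, y) -> float:
    """Pearson correlation with population standard deviations.

    Returns 0 when either input is constant (zero sigma).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"pcc needs equal-length vectors, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("pcc needs at least 2 samples")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(((x * y).mean() - x.mean() * y.mean()) / (sx * sy))


def mse(x, y) -> float:
    """Mean squared difference."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"mse needs equal shapes, got {x.shape} and {y.shape}")
    return float(np.mean((x - y) ** 2))


@dataclass
class SignalEvalMatrix:
    """12 x 12 input-lead x output-lead evaluation matrices."""

    mse: np.ndarray
    pcc: np.ndarray
    n_windows: int
    input_leads: tuple

    @property
    def row_mean_mse(self) -> np.ndarray:
        return self.mse[list(self.input_leads)].mean(axis=1)

    @property
    def row_mean_pcc(self) -> np.ndarray:
        return self.pcc[list(self.input_leads)].mean(axis=1)

    @property
    def grand_mean_mse(self) -> float:
        return float(self.row_mean_mse.mean())

    @property
    def grand_mean_pcc(self) -> float:
        return float(self.row_mean_pcc.mean())

    def to_frame(self, which: str = "pcc") -> pd.DataFrame:
        """Tabulate one matrix with lead-name labels plus a Mean column/row."""
        mat = {"pcc": self.pcc, "mse": self.mse}[which]
        rows = [LEAD_NAMES[i] for i in self.input_leads]
        df = pd.DataFrame(mat[list(self.input_leads)], index=rows,
                          columns=list(LEAD_NAMES))
        df["Mean"] = df.mean(axis=1)
        df.loc["Mean"] = df.mean(axis=0)
        df.index.name = "input"
        return df


def evaluate_signal(generator, windows, leads=None) -> SignalEvalMatrix:
    """Score a generator on the signal level over a set of 12-lead windows.

    For each input lead ``i`` and window ``w`` the generator reconstructs all
    12 leads from ``w``'s lead ``i``; entry ``(i, j)`` of each matrix is the
    MSE / PCC between reconstruction and truth of output lead ``j``, averaged
    over windows.  Trailing padded samples (``w.pad_len``) are excluded.
    """
    if len(windows) == 0:
        raise ValueError("no windows to evaluate")
    leads = tuple(range(12)) if leads is None else tuple(int(i) for i in leads)
    mse_acc = np.zeros((12, 12))
    pcc_acc = np.zeros((12, 12))
    for w in windows:
        samples = w.samples if isinstance(w, EcgWindow) else np.asarray(w)
        pad_len = w.pad_len if isinstance(w, EcgWindow) else 0
        valid = samples.shape[1] - pad_len
        truth = samples[:, :valid]
        for i in leads:
            gen = np.asarray(generator(samples[i], i))
            if gen.shape != samples.shape:
                raise ValueError(
                    f"generator returned shape {gen.shape} for lead {i} of "
                    f"window {getattr(w, 'window_index', '?')}; expected {samples.shape}")
            gen = gen[:, :valid]
            for j in range(12):
                mse_acc[i, j] += mse(truth[j], gen[j])
                pcc_acc[i, j] += pcc(truth[j], gen[j])
    n = len(windows)
    return SignalEvalMatrix(mse_acc / n, pcc_acc / n, n, leads)


def write_report(result: SignalEvalMatrix, out_dir) -> list:
    """Write the MSE and PCC matrices as CSV files; returns the paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for which in ("mse", "pcc"):
        p = out_dir / f"signal_{which}.csv"
        result.to_frame(which).to_csv(p, float_format="%.6f")
        paths.append(p)
    return paths
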