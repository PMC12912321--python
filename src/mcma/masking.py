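"""Masked multi-channel input construction.

A single-lead ECG is embedded into the 12-channel frame the autoencoder
expects.  With the zero-padding strategy the signal keeps its own channel
position and the other 11 channels are zero, preserving the spatial identity
of the lead; with the copy-padding strategy all 12 channels are copies of the
signal.  Both operations are deterministic and parameter-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_windowing import WINDOW_LEN

N_LEADS = 12

STRATEGIES = ("zeros", "copy")


@dataclass
class MaskedWindow:
    """A 12 x 1024 masked frame: the model's input representation."""

    samples: np.ndarray
    lead_index: int
    strategy: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (N_LEADS, WINDOW_LEN):
            raise ValueError(f"masked window must be {N_LEADS} x {WINDOW_LEN}")
        if not (0 <= self.lead_index < N_LEADS):
            raise ValueError("lead_index must be in [0, 11]")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")


def _check_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.shape[0] != WINDOW_LEN:
        raise ValueError(f"expected a length-{WINDOW_LEN} vector, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal must be finite")
    return x


def zero_pad(x, lead_index: int) -> MaskedWindow:
    """Embed ``x`` at channel ``lead_index`` with all other channels zero."""
    x = _check_vector(x)
    if not (0 <= lead_index < N_LEADS):
        raise ValueError(f"lead_index {lead_index} out of range [0, 11]")
    frame = np.zeros((N_LEADS, WINDOW_LEN))
    frame[lead_index] = x
    return MaskedWindow(frame, lead_index, "zeros")


def copy_pad(x, lead_index: int = 0) -> MaskedWindow:
    """Replicate ``x`` into all 12 channels (the comparison strategy)."""
    x = _check_vector(x)
    if not (0 <= lead_index < N_LEADS):
        raise ValueError(f"lead_index {lead_index} out of range [0, 11]")
    frame = np.tile(x, (N_LEADS, 1))
    return MaskedWindow(frame, lead_index, "copy")


def pad(x, lead_index: int, strategy: str = "zeros") -> MaskedWindow:
    """Dispatch to :func:`zero_pad` or :func:`copy_pad` by name."""
    if strategy == "zeros":
        return zero_pad(x, lead_index)
    if strategy == "copy":
        return copy_pad(x, lead_index)
    raise ValueError(f"strategy must be one of {STRATEGIES}")


def extract_lead(w, i: int) -> np.ndarray:
    """Return channel ``i`` of a 12-channel frame (window, masked or plain array)."""
    samples = getattr(w, "samples", w)
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.shape[0] != N_LEADS:
        raise ValueError(f"expected a {N_LEADS}-channel frame, got shape {samples.shape}")
    if not (0 <= i < N_LEADS):
        raise ValueError(f"lead index {i} out of range [0, 11]")
    return samples[i].copy()
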