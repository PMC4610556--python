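"""Ground-truth fatigue assessment: observers, EEG band ratio, and self-report.

Three independent assessments label each window with one of the states
NF (non-fatigue), MF (moderate fatigue), SF (severe fatigue):

* three observers score the video 0/1/2; the floor of the mean score maps
  back to a state;
* a single-channel EEG window is classified by the drowsiness ratio
  ``r = (P_alpha + P_theta) / P_beta`` of Welch band powers
  (r < 3 -> NF, 3 <= r < 4 -> MF, r >= 4 -> SF);
* the 7-point Stanford Sleepiness Scale maps 1-2 -> NF, 3-5 -> MF,
  6-7 -> SF.

A window enters the ground-truth set only when all three agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .errors import DegenerateSpectrumError, InvalidInputError
from .recognizer import FatigueState

__all__ = [
    "ObserverScores",
    "EEGWindow",
    "DEFAULT_BANDS",
    "observer_consensus",
    "band_power",
    "eeg_classify",
    "sss_classify",
    "consensus",
]

# Conventional band edges (Hz).  The literal alternative that swaps the
# theta and alpha ranges can be passed explicitly.
DEFAULT_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 22.0)}


@dataclass(frozen=True)
class ObserverScores:
    """Scores from exactly three observers, each 0 (NF), 1 (MF) or 2 (SF)."""

    scores: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.scores) != 3 or any(s not in (0, 1, 2) for s in self.scores):
            raise InvalidInputError("need exactly three observer scores in {0, 1, 2}")


@dataclass
class EEGWindow:
    """A single-channel EEG segment (microvolts) with its sampling rate."""

    samples: np.ndarray
    sampling_rate: float
    bands: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        bands = self.bands or DEFAULT_BANDS
        edges = [e for pair in bands.values() for e in pair]
        if max(edges) * 2 > self.sampling_rate:
            raise InvalidInputError("sampling rate must exceed twice the highest band edge")
        self.bands = dict(bands)


def observer_consensus(scores: ObserverScores) -> FatigueState:
    """State from the floored mean of the three observer scores."""
    s = int(sum(scores.scores) // 3)
    return (FatigueState.NF, FatigueState.MF, FatigueState.SF)[s]


def band_power(eeg: EEGWindow, band: tuple[float, float], segment_s: float = 2.0) -> float:
    """Welch-integrated power in [low, high) Hz.

    Uses Hann segments of ``segment_s`` seconds with 50% overlap; power is
    the PSD integrated over the band (trapezoid on the periodogram grid).
    """
    low, high = band
    if high * 2 > eeg.sampling_rate:
        raise InvalidInputError("band extends beyond the Nyquist frequency")
    if low >= high:
        raise InvalidInputError("band edges must be increasing")
    n = eeg.samples.size
    if n < 2 * eeg.sampling_rate:
        raise InvalidInputError("need at least 2 s of samples")
    nperseg = min(int(segment_s * eeg.sampling_rate), n)
    freqs, psd = sp_signal.welch(
        eeg.samples, fs=eeg.sampling_rate, window="hann", nperseg=nperseg
    )
    sel = (freqs >= low) & (freqs < high)
    if not np.any(sel):
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def eeg_classify(eeg: EEGWindow) -> tuple[float, FatigueState]:
    """Drowsiness ratio ``(P_alpha + P_theta) / P_beta`` and its state.

    Thresholds: r < 3 -> NF, 3 <= r < 4 -> MF, r >= 4 -> SF.
    """
    bands = eeg.bands or DEFAULT_BANDS
    p_theta = band_power(eeg, bands["theta"])
    p_alpha = band_power(eeg, bands["alpha"])
    p_beta = band_power(eeg, bands["beta"])
    if p_beta <= 0.0:
        raise DegenerateSpectrumError("beta-band power is zero; ratio undefined")
    r = (p_alpha + p_theta) / p_beta
    return r, classify_ratio(r)


def classify_ratio(r: float) -> FatigueState:
    """State from a precomputed drowsiness ratio."""
    if r < 3.0:
        return FatigueState.NF
    if r < 4.0:
        return FatigueState.MF
    return FatigueState.SF


def sss_classify(points: int) -> FatigueState:
    """Stanford Sleepiness Scale points (1..7) to a fatigue state."""
    if points not in range(1, 8):
        raise InvalidInputError("SSS points must be an integer in 1..7")
    if points <= 2:
        return FatigueState.NF
    if points <= 5:
        return FatigueState.MF
    return FatigueState.SF


def consensus(
    obs: FatigueState, eeg: FatigueState, sss: FatigueState
) -> FatigueState | None:
    """The common state when all three assessments agree, else None (invalid).

    Windows without unanimous agreement are removed from the ground-truth set.
    """
    if obs == eeg == sss:
        return obs
    return None
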