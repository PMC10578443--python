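"""Electrodermal-activity decomposition and SCR detection.

Tonic (skin conductance level) is the zero-phase low-pass component of the
4 Hz EDA trace; phasic is the residual, so tonic + phasic reconstructs the
input exactly.  Skin conductance responses (SCRs) are prominence-filtered
local maxima of the phasic component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, peak_prominences

#: default low-pass cutoff separating tonic from phasic (Hz)
TONIC_CUTOFF_HZ = 0.05
#: default minimum SCR prominence (µS)
SCR_AMP_THRESHOLD = 0.01


def decompose_eda(x: np.ndarray, fs: float = 4.0,
                  cutoff_hz: float = TONIC_CUTOFF_HZ) -> Tuple[np.ndarray, np.ndarray]:
    """Split an EDA slice into (tonic, phasic) with tonic + phasic == x."""
    x = np.asarray(x, dtype=float)
    if x.size < 16 or np.ptp(x) == 0:
        tonic = np.full_like(x, x.mean() if x.size else 0.0)
        return tonic, x - tonic
    b, a = butter(4, cutoff_hz, btype="low", fs=fs)
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    tonic = filtfilt(b, a, x, padlen=padlen)
    return tonic, x - tonic


@dataclass
class SCR:
    onset_idx: int
    peak_idx: int
    amplitude: float        # µS, onset-to-peak
    rise_time: float        # s
    half_recovery: float    # s, NaN when recovery not observed in the slice


def detect_scrs(phasic: np.ndarray, fs: float = 4.0,
                amp_threshold: float = SCR_AMP_THRESHOLD) -> List[SCR]:
    """Prominence-filtered peaks of the phasic component."""
    phasic = np.asarray(phasic, dtype=float)
    if phasic.size < 3:
        return []
    peaks, _ = find_peaks(phasic, prominence=amp_threshold)
    if peaks.size == 0:
        return []
    _, left_bases, _ = peak_prominences(phasic, peaks)
    out: List[SCR] = []
    for pk, onset in zip(peaks, left_bases):
        amp = phasic[pk] - phasic[onset]
        half = phasic[pk] - amp / 2.0
        rec = np.nan
        below = np.flatnonzero(phasic[pk:] <= half)
        if below.size:
            rec = below[0] / fs
        out.append(SCR(onset_idx=int(onset), peak_idx=int(pk), amplitude=float(amp),
                       rise_time=float((pk - onset) / fs), half_recovery=float(rec)))
    return out
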