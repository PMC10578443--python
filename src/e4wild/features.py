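"""The 66-dimensional per-window feature vector and table standardization.

Each 5-min window yields 24 BVP, 9 HR, 5 TEMP and 28 EDA features, namespaced
``bvp.*`` / ``hr.*`` / ``temp.*`` / ``eda.*`` in a fixed order.  Spectra use a
Welch periodogram with 64-s Hann segments at 50% overlap.  Degenerate
(constant) signals fall back to zeros for shape statistics, spectral entropy
and dominant frequency so every vector stays finite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import welch

from .eda import decompose_eda, detect_scrs

logger = logging.getLogger(__name__)

BVP_BANDS = [(0.5, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 6.0), (6.0, 8.0)]
EDA_BANDS = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.5)]

META_COLUMNS = ["participant", "session", "label", "day_index", "start", "end"]


# ---------------------------------------------------------------------------
# Small statistics helpers (degenerate-signal conventions built in)
# ---------------------------------------------------------------------------

def _slope(x: np.ndarray, fs: float) -> float:
    """Least-squares slope per second."""
    t = np.arange(x.size) / fs
    t = t - t.mean()
    denom = np.dot(t, t)
    return float(np.dot(t, x - x.mean()) / denom) if denom > 0 else 0.0


def _skew(x: np.ndarray) -> float:
    return float(stats.skew(x)) if np.std(x) > 0 else 0.0


def _kurtosis(x: np.ndarray) -> float:
    return float(stats.kurtosis(x)) if np.std(x) > 0 else 0.0


def _zcr(x: np.ndarray, fs: float) -> float:
    """Mean-crossing rate per second."""
    c = x - x.mean()
    s = np.sign(c)
    s = s[s != 0]
    if s.size < 2:
        return 0.0
    return float(np.count_nonzero(np.diff(s)) / (x.size / fs))


def _welch(x: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    nperseg = min(x.size, int(64 * fs))
    return welch(x, fs=fs, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2)


def _bandpower(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    m = (f >= lo) & (f < hi)
    if not m.any():
        return 0.0
    return float(np.trapezoid(p[m], f[m]))


def _spectral_entropy(p: np.ndarray) -> float:
    """Shannon entropy of the normalized PSD, scaled to [0, 1]."""
    tot = p.sum()
    if tot <= 0 or p.size < 2:
        return 0.0
    q = p / tot
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() / np.log(p.size))


# ---------------------------------------------------------------------------
# Per-channel feature groups
# ---------------------------------------------------------------------------

def bvp_features(x: np.ndarray, fs: float = 64.0) -> Dict[str, float]:
    d = np.diff(x)
    d2 = np.diff(x, n=2)
    f, p = _welch(x, fs)
    band_p = [_bandpower(f, p, lo, hi) for lo, hi in BVP_BANDS]
    total = _bandpower(f, p, 0.5, 8.0)
    inband = (f > 0)
    if np.std(x) > 0 and inband.any():
        dom_freq = float(f[inband][np.argmax(p[inband])])
        centroid = float((f[inband] * p[inband]).sum() / p[inband].sum()) \
            if p[inband].sum() > 0 else 0.0
        entropy = _spectral_entropy(p[inband])
    else:
        dom_freq, centroid, entropy = 0.0, 0.0, 0.0
    out = {
        "mean": float(x.mean()), "sd": float(x.std()),
        "min": float(x.min()), "max": float(x.max()),
        "skewness": _skew(x), "kurtosis": _kurtosis(x),
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "mean_abs_diff": float(np.abs(d).mean()),
        "max_abs_diff": float(np.abs(d).max()),
        "sd_diff": float(d.std()),
        "mean_abs_diff2": float(np.abs(d2).mean()),
        "slope": _slope(x, fs),
    }
    for (lo, hi), bp in zip(BVP_BANDS, band_p):
        out[f"power_{lo:g}_{hi:g}hz"] = bp
    out["total_power"] = total
    out["dominant_band_relpower"] = float(max(band_p) / total) if total > 0 else 0.0
    out["spectral_entropy"] = entropy
    out["dominant_freq"] = dom_freq
    out["spectral_centroid"] = centroid
    out["zero_crossing_rate"] = _zcr(x, fs)
    return out


def hr_features(x: np.ndarray, fs: float = 1.0) -> Dict[str, float]:
    d = np.diff(x)
    return {
        "mean": float(x.mean()), "sd": float(x.std()),
        "min": float(x.min()), "max": float(x.max()),
        "range": float(np.ptp(x)),
        "slope": _slope(x, fs),
        "mean_abs_diff": float(np.abs(d).mean()) if d.size else 0.0,
        "rmssd": float(np.sqrt(np.mean(d ** 2))) if d.size else 0.0,
        "kurtosis": _kurtosis(x),
    }


def temp_features(x: np.ndarray, fs: float = 4.0) -> Dict[str, float]:
    return {
        "mean": float(x.mean()), "sd": float(x.std()),
        "min": float(x.min()), "max": float(x.max()),
        "slope": _slope(x, fs),
    }


def eda_features(x: np.ndarray, fs: float = 4.0) -> Dict[str, float]:
    d = np.diff(x)
    d2 = np.diff(x, n=2)
    tonic, phasic = decompose_eda(x, fs)
    scrs = detect_scrs(phasic, fs)
    amps = np.array([s.amplitude for s in scrs])
    rises = np.array([s.rise_time for s in scrs])
    recs = np.array([s.half_recovery for s in scrs])
    recs = recs[np.isfinite(recs)]
    f, p = _welch(x, fs)
    out = {
        "mean": float(x.mean()), "sd": float(x.std()),
        "min": float(x.min()), "max": float(x.max()),
        "slope": _slope(x, fs),
        "mean_abs_diff": float(np.abs(d).mean()),
        "sd_diff": float(d.std()),
        "mean_abs_diff2": float(np.abs(d2).mean()),
        "tonic_mean": float(tonic.mean()), "tonic_sd": float(tonic.std()),
        "tonic_min": float(tonic.min()), "tonic_max": float(tonic.max()),
        "tonic_slope": _slope(tonic, fs),
        "phasic_mean": float(phasic.mean()), "phasic_sd": float(phasic.std()),
        "phasic_max": float(phasic.max()),
        "phasic_rms": float(np.sqrt(np.mean(phasic ** 2))),
        "scr_count": float(len(scrs)),
        "scr_mean_amplitude": float(amps.mean()) if amps.size else 0.0,
        "scr_max_amplitude": float(amps.max()) if amps.size else 0.0,
        "scr_amplitude_sum": float(amps.sum()),
        "scr_mean_rise_time": float(rises.mean()) if rises.size else 0.0,
        "scr_mean_half_recovery": float(recs.mean()) if recs.size else 0.0,
        "phasic_area": float(np.trapezoid(np.clip(phasic, 0, None), dx=1.0 / fs)),
    }
    for lo, hi in EDA_BANDS:
        out[f"power_{lo:g}_{hi:g}hz"] = _bandpower(f, p, lo, hi)
    out["spectral_entropy"] = _spectral_entropy(p[f > 0]) if np.std(x) > 0 else 0.0
    return out


_GROUPS = {"bvp": (bvp_features, 64.0, "BVP", 24),
           "hr": (hr_features, 1.0, "HR", 9),
           "temp": (temp_features, 4.0, "TEMP", 5),
           "eda": (eda_features, 4.0, "EDA", 28)}


def feature_names() -> List[str]:
    """The 66 feature names in canonical order."""
    names: List[str] = []
    for prefix, (fn, fs, _, expected) in _GROUPS.items():
        keys = list(fn(_PROBE[prefix], fs))
        assert len(keys) == expected, (prefix, len(keys))
        names.extend(f"{prefix}.{k}" for k in keys)
    return names


def feature_groups() -> Dict[str, int]:
    return {prefix: expected for prefix, (_, _, _, expected) in _GROUPS.items()}


# cheap non-degenerate probe slices used once to enumerate names
_rng = np.random.default_rng(0)
_PROBE = {"bvp": _rng.normal(size=19200), "hr": 70 + _rng.normal(size=300),
          "temp": 33 + _rng.normal(size=1200) * 0.1,
          "eda": 1 + np.abs(_rng.normal(size=1200)) * 0.1}
FEATURE_NAMES: List[str] = feature_names()


def extract_features(slices: Mapping[str, np.ndarray]) -> Dict[str, float]:
    """Compute all 66 features from complete per-channel 5-min slices."""
    out: Dict[str, float] = {}
    for prefix, (fn, fs, channel, expected) in _GROUPS.items():
        vals = fn(np.asarray(slices[channel], dtype=float), fs)
        if len(vals) != expected:
            raise RuntimeError(f"{prefix} group returned {len(vals)} features")
        out.update({f"{prefix}.{k}": v for k, v in vals.items()})
    if any(not np.isfinite(v) for v in out.values()):
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite feature(s): {bad}")
    return out


def build_feature_table(windows: pd.DataFrame, sessions, masks=None) -> pd.DataFrame:
    """Feature table for a windows table (see :mod:`e4wild.windowing`).

    Windows whose slices are incomplete are dropped (counted in the log).
    """
    from .windowing import LabeledWindow, WindowRejected, segment_signals

    by_id = {(s.participant_id, s.session_id): s for s in sessions}
    rows = []
    n_rejected = 0
    for rec in windows.itertuples(index=False):
        session = by_id[(rec.participant, rec.session)]
        w = LabeledWindow(rec.participant, rec.session, rec.start, rec.end,
                          rec.label, getattr(rec, "source_tag", None),
                          getattr(rec, "day_index", 0))
        mask = masks.get((rec.participant, rec.session)) if masks else None
        try:
            slices = segment_signals(w, session, mask)
        except WindowRejected:
            n_rejected += 1
            continue
        row = {"participant": rec.participant, "session": rec.session,
               "label": rec.label, "day_index": getattr(rec, "day_index", 0),
               "start": rec.start, "end": rec.end}
        row.update(extract_features(slices))
        rows.append(row)
    if n_rejected:
        logger.info("dropped %d window(s) with incomplete slices", n_rejected)
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationRecord:
    means: pd.Series
    sds: pd.Series
    constant_columns: List[str]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        cols = self.means.index
        out[cols] = (table[cols] - self.means) / self.sds
        return out


def standardize(table: pd.DataFrame, fit_rows: Optional[Sequence[int]] = None,
                feature_cols: Optional[Sequence[str]] = None,
                ) -> Tuple[pd.DataFrame, StandardizationRecord]:
    """Zero-mean / unit-variance scaling fit on ``fit_rows`` (default: all).

    Constant columns (sd == 0 on the fit rows) pass through unscaled with a
    warning.  Statistics learned on the fit rows are applied to every row.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c in FEATURE_NAMES]
    fit = table if fit_rows is None else table.loc[fit_rows]
    if len(fit) == 0:
        raise ValueError("empty fit_rows")
    means = fit[feature_cols].mean()
    sds = fit[feature_cols].std(ddof=0)
    constant = [c for c in feature_cols if sds[c] < 1e-12]
    if constant:
        warnings.warn(f"constant feature column(s) left unscaled: {constant}",
                      stacklevel=2)
        means = means.copy()
        sds = sds.copy()
        means[constant] = 0.0
        sds[constant] = 1.0
    rec = StandardizationRecord(means=means, sds=sds, constant_columns=constant)
    return rec.apply(table), rec
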