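"""Synthetic wrist-biosensor cohorts with known ground truth.

Generates E4-style sessions (BVP 64 Hz, EDA 4 Hz, TEMP 4 Hz, HR 1 Hz, plus a
tags file of button presses) for a configurable cohort, injecting a known
physiological signature around each tag so that every downstream stage —
ingestion, wear filtering, windowing, feature extraction, modeling — can be
tested against ground truth.

Signal model
------------
* HR is a mean-reverting bounded random walk (AR(1)) around a per-participant
  baseline; event intervals add a bpm offset.
* BVP is an amplitude-modulated quasi-periodic pulse whose instantaneous
  frequency is the HR channel divided by 60, so the two channels are mutually
  consistent by construction.  Event intervals tilt the amplitude envelope
  by a configurable slope.
* EDA is a slowly drifting tonic level plus Poisson-arriving skin conductance
  responses (SCRs) with exponential rise/decay; event intervals multiply both
  SCR rate and amplitude.
* Cluster heterogeneity enters as i.i.d. per-participant shifts of the HR and
  tonic-EDA baselines — the random intercept a mixed-effect model can exploit.

Randomness is drawn with a fixed consumption pattern, so a zero-strength
effect specification yields byte-identical signals to an event-free run with
the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, lfilter

from . import intervals as iv
from .ingest import ChannelSeries, Session, write_session
from .reference import reference_cohort

SECONDS_PER_DAY = 86400
#: Default recording epoch (whole UTC day boundary).
EPOCH0 = 1_600_041_600  # 2020-09-14 00:00:00 UTC

RangeLike = Union[float, Tuple[float, float], Sequence[float]]


class SpecificationError(ValueError):
    """Invalid cohort or effect specification."""


@dataclass(frozen=True)
class EffectSpec:
    """Physiological signature injected around each tag.

    ``eda_phasic_gain`` multiplies SCR rate and amplitude (1 = no effect);
    ``bvp_slope_shift`` tilts the BVP amplitude envelope (units/s);
    ``hr_delta`` is a bpm offset.  The signature spans
    ``[tag - onset_lead, tag - onset_lead + duration)``.
    """

    eda_phasic_gain: float = 2.5
    bvp_slope_shift: float = 0.02
    hr_delta: float = 8.0
    onset_lead: float = 270.0
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SpecificationError("effect duration must be > 0")
        if self.onset_lead < 0:
            raise SpecificationError("onset_lead must be >= 0")
        for v in (self.eda_phasic_gain, self.bvp_slope_shift, self.hr_delta):
            if not math.isfinite(v):
                raise SpecificationError("effect gains must be finite")
        if self.eda_phasic_gain < 0:
            raise SpecificationError("eda_phasic_gain must be >= 0")

    @classmethod
    def null(cls) -> "EffectSpec":
        """Neutral signature: tags carry no physiological change."""
        return cls(eda_phasic_gain=1.0, bvp_slope_shift=0.0, hr_delta=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design knobs for one synthetic cohort.

    ``days``, ``hours_per_day`` and ``tag_rate`` accept a point value, a
    ``(lo, hi)`` range sampled per participant (per day for hours), or one
    value per participant.
    """

    n_participants: int = 8
    days: RangeLike = (4, 48)
    hours_per_day: RangeLike = (4.0, 11.0)
    tag_rate: RangeLike = 0.68          # events per wear-hour
    event_effect: EffectSpec = field(default_factory=EffectSpec)
    nonwear_fraction: float = 0.05
    sleep_window: Tuple[float, float] = (23.0, 7.0)
    seed: int = 0
    hr_intercept_sd: float = 5.0        # bpm
    eda_intercept_sd: float = 0.4       # µS

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SpecificationError("n_participants must be >= 1")
        if not 0 <= self.nonwear_fraction < 1:
            raise SpecificationError("nonwear_fraction must be in [0, 1)")
        for name in ("days", "hours_per_day", "tag_rate"):
            val = getattr(self, name)
            if isinstance(val, tuple) and len(val) == 2:
                lo, hi = val
                if hi < lo:
                    raise SpecificationError(f"{name} range is inverted: {val}")
            elif np.iterable(val):
                if len(list(val)) != self.n_participants:
                    raise SpecificationError(
                        f"per-participant {name} needs {self.n_participants} values")
        rates = self._resolve("tag_rate", None)
        if np.any(rates < 0):
            raise SpecificationError("tag_rate must be >= 0")

    def _resolve(self, name: str, rng: Optional[np.random.Generator]):
        """Per-participant values for a RangeLike field."""
        val = getattr(self, name)
        if isinstance(val, tuple) and len(val) == 2:
            lo, hi = float(val[0]), float(val[1])
            if rng is None:
                return np.full(self.n_participants, (lo + hi) / 2)
            return rng.uniform(lo, hi, size=self.n_participants)
        if np.iterable(val):
            return np.asarray(list(val), dtype=float)
        return np.full(self.n_participants, float(val))


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    intercepts: pd.DataFrame         # participant -> hr_shift, eda_shift
    event_intervals: pd.DataFrame    # participant, session, tag, start, end

    def intervals_for(self, participant: str) -> List[Tuple[float, float]]:
        sub = self.event_intervals[self.event_intervals["participant"] == participant]
        return list(zip(sub["start"], sub["end"]))

    def overlaps_event(self, participant: str, start: float, end: float) -> bool:
        return iv.overlaps_any(self.intervals_for(participant), start, end)


@dataclass
class Cohort:
    spec: CohortSpec
    sessions: List[Session]
    ground_truth: GroundTruth

    def by_participant(self) -> Dict[str, List[Session]]:
        out: Dict[str, List[Session]] = {}
        for s in self.sessions:
            out.setdefault(s.participant_id, []).append(s)
        return out


# ---------------------------------------------------------------------------
# Low-level signal builders
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, a: float, innov_sd: float) -> np.ndarray:
    e = rng.normal(0.0, innov_sd, size=n)
    return lfilter([1.0], [1.0, -a], e)


def _scr_kernel(fs: float, tau_rise: float = 0.7, tau_decay: float = 4.0,
                length_s: float = 30.0) -> np.ndarray:
    t = np.arange(int(length_s * fs)) / fs
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def draw_tags(rate_per_hour: float, wear_intervals: Sequence[Tuple[float, float]],
              rng: np.random.Generator) -> np.ndarray:
    """Poisson button presses over wear time, on whole seconds."""
    if rate_per_hour < 0:
        raise SpecificationError("tag_rate must be >= 0")
    times: List[float] = []
    for a, b in wear_intervals:
        lam = rate_per_hour * (b - a) / 3600.0
        n = rng.poisson(lam)
        if n:
            times.extend(np.floor(rng.uniform(a, b, size=n)))
    return np.unique(np.asarray(times, dtype=float))


def _event_mask(times: np.ndarray,
                intervals: Sequence[Tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for a, b in intervals:
        mask |= (times >= a) & (times < b)
    return mask


def _synthesize_channels(rng: np.random.Generator, start: float, duration_s: int,
                         effect: EffectSpec,
                         event_ivs: Sequence[Tuple[float, float]],
                         hr_shift: float, eda_shift: float,
                         ) -> Dict[str, ChannelSeries]:
    """Build the four channels for one session.

    The RNG consumption pattern is independent of ``effect`` and
    ``event_ivs`` so a neutral effect reproduces the no-event signals.
    """
    n1 = duration_s
    n4 = duration_s * 4
    n64 = duration_s * 64
    t1 = start + np.arange(n1)
    t4 = start + np.arange(n4) / 4.0
    t64 = start + np.arange(n64) / 64.0

    # --- HR (1 Hz): AR(1) around per-participant baseline, event bpm offset
    hr_base = 72.0 + hr_shift
    hr = hr_base + _ar1(rng, n1, a=0.995, innov_sd=0.6)
    hr = hr + effect.hr_delta * _event_mask(t1, event_ivs)
    hr = np.clip(hr, 45.0, 140.0)

    # --- BVP (64 Hz): pulse driven by instantaneous HR
    env_slow = _ar1(rng, n1, a=0.995, innov_sd=0.03)
    bvp_noise = rng.normal(0.0, 0.05, size=n64)
    f_inst = np.interp(t64, t1, hr) / 60.0
    phase = 2.0 * np.pi * np.cumsum(f_inst) / 64.0
    env = 0.8 * (1.0 + np.clip(np.interp(t64, t1, env_slow), -0.8, 0.8))
    if effect.bvp_slope_shift != 0.0:
        ramp = np.zeros(n64)
        for a, b in event_ivs:
            m = (t64 >= a) & (t64 < b)
            if m.any():
                ramp[m] += effect.bvp_slope_shift * (t64[m] - 0.5 * (a + b))
        env = env + ramp
    env = np.clip(env, 0.05, None)
    bvp = env * np.sin(phase) + 0.3 * env * np.sin(2.0 * phase + 1.2) + bvp_noise

    # --- EDA (4 Hz): tonic drift + Poisson SCR train convolved with kernel
    # drift is generated on a 4-s grid and interpolated so it stays below
    # the phasic band (real SCL wanders over minutes, not sub-second)
    t_slow = np.arange(0.0, duration_s + 4.0, 4.0)
    drift = _ar1(rng, t_slow.size, a=0.98, innov_sd=0.02)
    tonic = np.clip(1.5 + eda_shift + np.interp(t4 - start, t_slow, drift),
                    0.05, None)
    u = rng.uniform(size=n4)
    amps = rng.lognormal(mean=np.log(0.3), sigma=0.5, size=n4)
    # sensor noise floor kept below the SCR prominence threshold (0.01 µS)
    eda_noise = rng.normal(0.0, 0.001, size=n4)
    base_rate = 2.0 / 60.0          # nonspecific SCRs per second
    gain_t = np.where(_event_mask(t4, event_ivs), effect.eda_phasic_gain, 1.0)
    p_spike = np.clip(base_rate * gain_t / 4.0, 0.0, 1.0)
    impulses = np.where(u < p_spike, amps * gain_t, 0.0)
    phasic = fftconvolve(impulses, _scr_kernel(4.0))[:n4]
    eda = np.clip(tonic + phasic + eda_noise, 0.001, None)

    # --- TEMP (4 Hz): wrist skin temperature, slow drift
    temp_base = 33.2 + 0.2 * hr_shift / 5.0
    temp = temp_base + _ar1(rng, n4, a=0.9995, innov_sd=0.002) \
        + rng.normal(0.0, 0.01, size=n4)

    return {
        "BVP": ChannelSeries("BVP", start, 64.0, bvp),
        "EDA": ChannelSeries("EDA", start, 4.0, eda),
        "TEMP": ChannelSeries("TEMP", start, 4.0, temp),
        "HR": ChannelSeries("HR", start, 1.0, hr),
    }


def _apply_nonwear(channels: Dict[str, ChannelSeries],
                   nonwear: Sequence[Tuple[float, float]],
                   rng: np.random.Generator) -> None:
    """Overwrite non-wear stretches with off-wrist readings (in place)."""
    for a, b in nonwear:
        for name, ch in channels.items():
            i0 = int(round((a - ch.start_time) * ch.rate))
            i1 = int(round((b - ch.start_time) * ch.rate))
            i0, i1 = max(i0, 0), min(i1, ch.values.size)
            if i1 <= i0:
                continue
            n = i1 - i0
            if name == "EDA":
                ch.values[i0:i1] = 0.0
            elif name == "TEMP":
                ch.values[i0:i1] = 25.5 + rng.normal(0.0, 0.05, size=n)
            elif name == "BVP":
                ch.values[i0:i1] = rng.normal(0.0, 0.02, size=n)
            else:  # HR output is undefined off-wrist; hold a flat reading
                ch.values[i0:i1] = 70.0


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec, out_dir: Optional[Path | str] = None) -> Cohort:
    """Simulate a cohort of session folders with ground truth.

    One session per participant-day, starting between 08:00 and 12:00 UTC.
    With ``out_dir`` set, sessions are written as folders alongside a
    ``manifest.csv``, ``ground_truth_intervals.csv`` and ``intercepts.csv``.
    Identical spec (including seed) reproduces byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.round(spec._resolve("days", rng)).astype(int)
    rates = spec._resolve("tag_rate", rng)
    if np.any(rates < 0):
        raise SpecificationError("tag_rate must be >= 0")
    hr_shifts = rng.normal(0.0, spec.hr_intercept_sd, size=spec.n_participants)
    eda_shifts = rng.normal(0.0, spec.eda_intercept_sd, size=spec.n_participants)

    hours_val = spec.hours_per_day
    sessions: List[Session] = []
    gt_rows: List[Dict] = []
    effect = spec.event_effect

    for p in range(spec.n_participants):
        pid = f"P{p:02d}"
        for d in range(days[p]):
            if isinstance(hours_val, tuple) and len(hours_val) == 2:
                hours = rng.uniform(float(hours_val[0]), float(hours_val[1]))
            elif np.iterable(hours_val):
                hours = float(list(hours_val)[p])
            else:
                hours = float(hours_val)
            if hours <= 0:
                raise SpecificationError("zero wear time requested: hours_per_day "
                                         "must be > 0")
            duration_s = int(round(hours * 3600))
            day_start = EPOCH0 + d * SECONDS_PER_DAY
            start = day_start + int(rng.integers(8 * 3600, 12 * 3600))
            end = start + duration_s

            # one contiguous off-wrist block per session, if requested
            nonwear: List[Tuple[float, float]] = []
            if spec.nonwear_fraction > 0:
                block = spec.nonwear_fraction * duration_s
                b0 = start + rng.uniform(0, duration_s - block)
                nonwear = [(round(b0), round(b0 + block))]
            wear = iv.subtract([(start, end)], nonwear)

            tags = draw_tags(rates[p], wear, rng)
            event_ivs = [(t - effect.onset_lead,
                          t - effect.onset_lead + effect.duration) for t in tags]

            sid = f"{pid}_d{d:02d}"
            channels = _synthesize_channels(rng, start, duration_s, effect,
                                            event_ivs, hr_shifts[p], eda_shifts[p])
            _apply_nonwear(channels, nonwear, rng)
            sessions.append(Session(participant_id=pid, session_id=sid,
                                    channels=channels, tags=tags))
            for t, (a, b) in zip(tags, event_ivs):
                gt_rows.append({"participant": pid, "session": sid,
                                "tag": t, "start": a, "end": b})

    intercepts = pd.DataFrame({
        "participant": [f"P{p:02d}" for p in range(spec.n_participants)],
        "hr_shift": hr_shifts, "eda_shift": eda_shifts,
    }).set_index("participant")
    event_intervals = pd.DataFrame(
        gt_rows, columns=["participant", "session", "tag", "start", "end"])
    cohort = Cohort(spec=spec, sessions=sessions,
                    ground_truth=GroundTruth(intercepts, event_intervals))
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: Path | str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.sessions:
        folder = out / s.session_id
        write_session(s, folder)
        rows.append({"participant": s.participant_id, "session": s.session_id,
                     "folder": s.session_id})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    cohort.ground_truth.event_intervals.to_csv(
        out / "ground_truth_intervals.csv", index=False)
    cohort.ground_truth.intercepts.to_csv(out / "intercepts.csv")
    return out


def simulate_lab_session(condition: str, effect: Optional[EffectSpec] = None,
                         seed: int = 0, participant_id: str = "LAB",
                         duration_s: int = 300) -> Session:
    """One 5-min in-clinic segment: seated rest or symptom-provocation.

    The provocation (exposure) condition applies the effect signature
    continuously over the whole segment; rest applies none.  With a neutral
    effect the two conditions produce identical signals for the same seed.
    """
    if condition not in ("rest", "exposure"):
        raise SpecificationError(f"unknown lab condition {condition!r}")
    effect = effect if effect is not None else EffectSpec()
    rng = np.random.default_rng(seed)
    start = float(EPOCH0 + 10 * 3600)
    event_ivs = [(start, start + duration_s)] if condition == "exposure" else []
    channels = _synthesize_channels(rng, start, duration_s, effect, event_ivs,
                                    hr_shift=0.0, eda_shift=0.0)
    return Session(participant_id=participant_id,
                   session_id=f"{participant_id}_{condition}",
                   channels=channels, tags=np.empty(0))


def reference_cohort_spec(effect: Optional[EffectSpec] = None,
                          seed: int = 0) -> CohortSpec:
    """Cohort spec matching the reference cohort's per-participant marginals
    (wear days, mean hours/day, tags per wear-hour)."""
    ref = reference_cohort()
    return CohortSpec(
        n_participants=len(ref),
        days=ref["n_days"].to_list(),
        hours_per_day=ref["mean_hours_per_day"].to_list(),
        tag_rate=ref["mean_tags_per_hour"].to_list(),
        event_effect=effect if effect is not None else EffectSpec(),
        seed=seed,
    )
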