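"""Synthetic fluorescence traces and cohorts with analytic ground truth.

The trace generator emulates the morphology of skin-fluorescence recordings:
a slowly varying baseline, band-limited sinusoidal oscillations (endothelial,
neurogenic, myogenic) with a weak ~1 Hz cardiac component, and — for the full
occlusion protocol — an ischemic saturating rise with suppressed oscillations
while the cuff is inflated, a sharp post-release hyperemic drop to a minimum
below baseline over ~20-30 s, and an exponential reperfusion recovery with
oscillations restored at a per-band gain (the myogenic band is boosted,
mirroring the myogenic activation that drives the hypoxia response).

Oscillators are fixed-frequency sinusoids with seeded random phases, so the
expected flowmotion statistic is analytic: a sinusoid of amplitude A carries
mean squared amplitude A^2/2, hence

    expected FM = sum over sub-cardiac oscillators of (A/m)^2 / 2 * 1e6,

where m is the mean of the noise-free signal over the normalization window
(m ~ 1 for the default flat baseline).  Quadratic detrending absorbs a small
part of very slow tones (up to ~7% of power at 0.02 Hz over a 150 s window,
<2% at 0.04 Hz and above), so the analytic ground truth is accurate to ~2%
for oscillators at or above 0.04 Hz and is a mild overestimate below.

The cohort generator produces parameter tables with programmed covariate
relationships (flowmotion declining with age, reperfusion flowmotion
inversely related to blood pressure) and optional planted "disturbed
responder" subjects whose FM(R) and myo(R) fall below the cohort's lower
quartile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trace_io import ProtocolMarks, RawTrace

BAND_INTERVALS: dict[str, tuple[float, float]] = {
    "endo": (0.0, 0.021),
    "neuro": (0.021, 0.052),
    "myo": (0.052, 0.15),
    "cardiac": (0.6, 2.0),
}

SUB_CARDIAC = ("endo", "neuro", "myo")

#: reperfusion oscillator gain per band: the myogenic band roughly doubles in
#: amplitude during the hypoxia response while the slower bands persist
DEFAULT_REPERFUSION_GAIN: Mapping[str, float] = {
    "endo": 1.0, "neuro": 1.0, "myo": 2.0, "cardiac": 1.0,
}


@dataclass(frozen=True)
class OscillatorSpec:
    """A fixed-frequency sinusoid assigned to a physiological band.

    ``phase=None`` means: draw uniformly from the trace seed.
    """

    band: str
    frequency: float
    amplitude: float
    phase: float | None = None

    def __post_init__(self) -> None:
        if self.band not in BAND_INTERVALS:
            raise ValueError(f"unknown band {self.band!r}")
        lo, hi = BAND_INTERVALS[self.band]
        if not (lo < self.frequency <= hi):
            raise ValueError(
                f"{self.band} oscillator frequency {self.frequency} Hz outside "
                f"({lo}, {hi}] Hz")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def default_oscillators() -> tuple[OscillatorSpec, ...]:
    """One oscillator per band, bin-aligned on a 150 s window at 25 Hz.

    Amplitudes are on the normalized (unitless) scale and give a resting
    flowmotion parameter of 82 — mid-range for healthy adults.  The cardiac
    amplitude is kept far below the sub-cardiac ones, as the heartbeat is
    clearly visible but weak relative to total oscillation power.
    """
    return (
        OscillatorSpec("endo", 0.02, 0.008),
        OscillatorSpec("neuro", 0.04, 0.006),
        OscillatorSpec("myo", 0.10, 0.008),
        OscillatorSpec("cardiac", 1.00, 0.002),
    )


_BASELINE_SHAPES = ("flat", "ascending", "descending",
                    "ascending-to-plateau", "parabolic")


@dataclass(frozen=True)
class TraceSpec:
    """Full description of one synthetic trace.

    ``baseline`` is a named slow shape or explicit ``(b0, b1, b2)`` quadratic
    coefficients in absolute time.  ``reperfusion_oscillator_gain`` is either
    a single factor applied to all sub-cardiac oscillators or a per-band
    mapping.  Times are seconds; amplitudes are on the normalized scale.
    """

    duration_s: float = 300.0
    sampling_rate: float = 25.0
    baseline: str | tuple[float, float, float] = "flat"
    oscillators: tuple[OscillatorSpec, ...] = field(default_factory=default_oscillators)
    noise_sd: float = 5e-4
    protocol: str = "rest_only"  # or "full_porh"
    occlusion_start_s: float = 180.0
    occlusion_duration_s: float = 180.0
    ischemia_rise_amplitude: float = 0.2
    ischemia_time_constant_s: float = 150.0
    hyperemia_undershoot_depth: float = 0.15
    hyperemia_drop_time_s: float = 25.0
    reperfusion_recovery_time_constant_s: float = 90.0
    reperfusion_oscillator_gain: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPERFUSION_GAIN))
    intensity_scale: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hyperemia_undershoot_depth < 0:
            raise ValueError("hyperemia_undershoot_depth must be >= 0")
        if self.protocol not in ("rest_only", "full_porh"):
            raise ValueError("protocol must be 'rest_only' or 'full_porh'")
        if isinstance(self.baseline, str) and self.baseline not in _BASELINE_SHAPES:
            raise ValueError(f"unknown baseline shape {self.baseline!r}")
        if self.protocol == "full_porh":
            release = self.occlusion_start_s + self.occlusion_duration_s
            if not (0 < self.occlusion_start_s < release < self.duration_s):
                raise ValueError("occlusion interval must lie inside the trace")

    @classmethod
    def full_porh(cls, **kwargs) -> "TraceSpec":
        """Default full occlusion protocol: 3 min baseline, 3 min occlusion,
        4 min reperfusion (600 s total)."""
        kwargs.setdefault("duration_s", 600.0)
        kwargs.setdefault("protocol", "full_porh")
        return cls(**kwargs)

    def gain_for(self, band: str) -> float:
        g = self.reperfusion_oscillator_gain
        if isinstance(g, Mapping):
            return float(g.get(band, 1.0))
        return float(g) if band in SUB_CARDIAC else 1.0

    @property
    def release_s(self) -> float:
        return self.occlusion_start_s + self.occlusion_duration_s


@dataclass(frozen=True)
class GroundTruth:
    """Analytic expectations implied by a :class:`TraceSpec`."""

    expected_fm_rest: float
    expected_fm_reperfusion: float | None
    expected_pie_rest: dict[str, float]
    expected_pie_reperfusion: dict[str, float] | None
    norm_mean: float


def _baseline_values(spec: TraceSpec, t: np.ndarray) -> np.ndarray:
    if not isinstance(spec.baseline, str):
        b0, b1, b2 = spec.baseline
        return b0 + b1 * t + b2 * t ** 2
    d = spec.duration_s
    if spec.baseline == "flat":
        return np.ones_like(t)
    if spec.baseline == "ascending":
        return 1.0 + 0.10 * t / d
    if spec.baseline == "descending":
        return 1.0 - 0.10 * t / d
    if spec.baseline == "ascending-to-plateau":
        return 1.0 + 0.08 * (1.0 - np.exp(-t / 120.0))
    # parabolic: gentle arch peaking mid-trace
    return 1.0 + 0.2 * (t / d) * (1.0 - t / d)


def _pie_from_amps(amps: dict[str, float]) -> dict[str, float]:
    powers = {b: amps.get(b, 0.0) ** 2 / 2.0 for b in SUB_CARDIAC}
    total = sum(powers.values())
    if total == 0:
        return {b: 0.0 for b in SUB_CARDIAC}
    return {b: p / total for b, p in powers.items()}


def simulate_trace(spec: TraceSpec,
                   normalization_window: tuple[float, float] = (60.0, 120.0),
                   ) -> tuple[RawTrace, GroundTruth]:
    """Generate a trace from ``spec``; deterministic given ``spec.seed``.

    Returns the raw trace (arbitrary intensity units, with protocol marks for
    the full protocol) and the analytic ground truth.  Ground-truth FM values
    refer to an analysis normalized over ``normalization_window``, which must
    lie in the resting phase.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    phases = [osc.phase if osc.phase is not None
              else float(rng.uniform(0.0, 2.0 * math.pi))
              for osc in spec.oscillators]
    osc_rest = np.zeros(n)
    osc_reper = np.zeros(n)
    for osc, ph in zip(spec.oscillators, phases):
        tone = osc.amplitude * np.sin(2.0 * math.pi * osc.frequency * t + ph)
        osc_rest += tone
        osc_reper += spec.gain_for(osc.band) * tone

    base = _baseline_values(spec, t)
    signal = base.copy()
    marks = None
    if spec.protocol == "rest_only":
        signal += osc_rest
    else:
        occ, rel = spec.occlusion_start_s, spec.release_s
        drop_end = rel + spec.hyperemia_drop_time_s
        rest_m = t < occ
        occ_m = (t >= occ) & (t < rel)
        drop_m = (t >= rel) & (t < drop_end)
        rec_m = t >= drop_end

        signal[rest_m] += osc_rest[rest_m]
        rise = spec.ischemia_rise_amplitude * (
            1.0 - np.exp(-(t[occ_m] - occ) / spec.ischemia_time_constant_s))
        signal[occ_m] += rise
        v_rel = spec.ischemia_rise_amplitude * (
            1.0 - math.exp(-spec.occlusion_duration_s / spec.ischemia_time_constant_s))
        depth = spec.hyperemia_undershoot_depth
        # smooth half-cosine descent from the ischemic peak to -depth,
        # reaching the minimum with zero slope at drop_end
        frac = (t[drop_m] - rel) / spec.hyperemia_drop_time_s
        signal[drop_m] += (-depth + (v_rel + depth)
                           * 0.5 * (1.0 + np.cos(math.pi * frac)))
        signal[drop_m] += osc_reper[drop_m]
        signal[rec_m] += (-depth * np.exp(-(t[rec_m] - drop_end)
                                          / spec.reperfusion_recovery_time_constant_s))
        signal[rec_m] += osc_reper[rec_m]
        marks = ProtocolMarks(baseline_start_s=0.0, occlusion_start_s=occ,
                              release_s=rel, end_s=spec.duration_s)

    clean = signal.copy()
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=n)

    intensities = spec.intensity_scale * signal
    if np.any(intensities <= 0):
        raise ValueError("simulated intensities not strictly positive; "
                         "reduce amplitudes/undershoot or raise the baseline")
    trace = RawTrace(subject_id=f"sim-{spec.seed:04d}", times=t,
                     intensities=intensities, sampling_rate=fs, marks=marks)

    i0 = int(round(normalization_window[0] * fs))
    i1 = int(round(normalization_window[1] * fs))
    if not (0 <= i0 < i1 <= n):
        raise ValueError("normalization window outside the trace")
    m = float(np.mean(clean[i0:i1]))

    rest_pow: dict[str, float] = {b: 0.0 for b in BAND_INTERVALS}
    reper_pow: dict[str, float] = {b: 0.0 for b in BAND_INTERVALS}
    for osc in spec.oscillators:
        rest_pow[osc.band] += (osc.amplitude / m) ** 2 / 2.0
        reper_pow[osc.band] += (spec.gain_for(osc.band) * osc.amplitude / m) ** 2 / 2.0

    fm_rest = 1e6 * sum(rest_pow[b] for b in SUB_CARDIAC)
    three_rest = sum(rest_pow[b] for b in SUB_CARDIAC)
    pie_rest = {b: (rest_pow[b] / three_rest if three_rest > 0 else 0.0)
                for b in SUB_CARDIAC}
    if spec.protocol == "full_porh":
        fm_reper: float | None = 1e6 * sum(reper_pow[b] for b in SUB_CARDIAC)
        three_rep = sum(reper_pow[b] for b in SUB_CARDIAC)
        pie_reper = {b: (reper_pow[b] / three_rep if three_rep > 0 else 0.0)
                     for b in SUB_CARDIAC}
    else:
        fm_reper, pie_reper = None, None

    truth = GroundTruth(expected_fm_rest=fm_rest,
                        expected_fm_reperfusion=fm_reper,
                        expected_pie_rest=pie_rest,
                        expected_pie_reperfusion=pie_reper,
                        norm_mean=m)
    return trace, truth


# ---------------------------------------------------------------------------
# cohort simulation

#: covariate distributions echoing the two study groups (means +- SD)
_PROFILES = {
    "protocol1": dict(age=(50.5, 12.9, 31.0, 72.0), male_frac=17 / 40,
                      sbp=(125.8, 14.8), bmi=(25.3, 4.3)),
    "protocol2": dict(age=(38.4, 6.4, 30.0, 50.0), male_frac=22 / 35,
                      sbp=(124.2, 11.9), bmi=(24.8, 3.1)),
}

DEFAULT_RELATIONSHIPS: dict[str, float] = {
    # resting flowmotion declines with age
    "fm_age_slope": -1.6,
    "fm_age_intercept": 155.0,
    # reperfusion flowmotion declines with systolic pressure
    "fmr_sbp_slope": -2.5,
    "myo_r_power_mean": 140.0,
}

DEFAULT_NOISE: dict[str, float] = {
    "fm_noise_sd": 30.0,
    "myo_r_power_sd": 12.0,
    "other_r_power_sd": 12.0,
    "pie_myo_sd": 0.08,
    "within_subject_cv": 0.20,
}


def simulate_cohort(n: int = 35,
                    relationships: Mapping[str, float] | None = None,
                    planted_disturbed: int = 0,
                    noise: Mapping[str, float] | None = None,
                    seed: int = 0,
                    profile: str = "protocol2",
                    n_repeats: int = 1,
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Generate a cohort parameter table with programmed relationships.

    Healthy subjects get ``fm = intercept + slope*age + noise`` (clipped
    positive) and a mechanistic reperfusion response: the myogenic band power
    surges to a tight, near-saturating level, while the carried-over
    endothelial+neurogenic power varies widely between subjects and is
    stronger at lower systolic pressure (which is what makes FM(R) inversely
    related to blood pressure).  Because the myogenic surge is tight and the
    carried-over power varies, FM(R) and the myogenic share myo(R) are
    negatively associated among healthy responders.  ``planted_disturbed`` subjects show no
    myogenic activation: their ``fm_r`` and ``pie_myo_r`` are drawn below the
    healthy lower quartile, emulating a disturbed flowmotion response to
    hypoxia.

    With ``n_repeats > 1`` each subject's fm / fm_r values are re-drawn per
    repeat with a multiplicative within-subject scatter
    (``within_subject_cv``), for repeatability analyses.

    Returns the table (one row per subject and repeat) and the planted
    subject ids.
    """
    if n < 4:
        raise ValueError("cohort needs n >= 4")
    if planted_disturbed >= n / 4:
        raise ValueError("planted_disturbed must be fewer than n/4 subjects")
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    rel = dict(DEFAULT_RELATIONSHIPS) | dict(relationships or {})
    nz = dict(DEFAULT_NOISE) | dict(noise or {})
    rng = np.random.default_rng(seed)
    prof = _PROFILES[profile]

    a_mu, a_sd, a_lo, a_hi = prof["age"]
    age = np.clip(rng.normal(a_mu, a_sd, n), a_lo, a_hi)
    sex = np.where(rng.random(n) < prof["male_frac"], "male", "female")
    sbp_mu, sbp_sd = prof["sbp"]
    sbp = np.clip(rng.normal(sbp_mu, sbp_sd, n), 95.0, 175.0)
    dbp = np.clip(17.0 + 0.5 * sbp + rng.normal(0.0, 5.0, n), 55.0, sbp - 15.0)
    bmi_mu, bmi_sd = prof["bmi"]
    bmi = np.clip(rng.normal(bmi_mu, bmi_sd, n), 18.0, 38.0)

    fm = rel["fm_age_intercept"] + rel["fm_age_slope"] * age
    if nz["fm_noise_sd"] > 0:
        fm = fm + rng.normal(0.0, nz["fm_noise_sd"], n)
    fm = np.clip(fm, 5.0, None)

    pie_myo = np.clip(rng.normal(0.40, nz["pie_myo_sd"], n), 0.15, 0.65)
    myo_pow = pie_myo * fm
    other_pow = fm - myo_pow

    # myogenic surge: tight, near-saturating across healthy responders
    myo_r_pow = rel["myo_r_power_mean"] + rng.normal(0.0, nz["myo_r_power_sd"], n)
    myo_r_pow = np.clip(myo_r_pow, 60.0, None)
    # carried-over endothelial+neurogenic power, stronger at lower pressure
    other_r_pow = (other_pow + rel["fmr_sbp_slope"] * (sbp - sbp_mu)
                   + rng.normal(0.0, nz["other_r_power_sd"], n))
    other_r_pow = np.clip(other_r_pow, 5.0, None)
    fm_r = other_r_pow + myo_r_pow
    pie_myo_r = myo_r_pow / fm_r

    ids = np.array([f"S{i:03d}" for i in range(n)])
    planted_ids: list[str] = []
    if planted_disturbed > 0:
        planted = rng.choice(n, size=planted_disturbed, replace=False)
        healthy = np.setdiff1d(np.arange(n), planted)
        q1_fm_r = np.quantile(fm_r[healthy], 0.25)
        q1_pie = np.quantile(pie_myo_r[healthy], 0.25)
        fm_r[planted] = rng.uniform(0.4, 0.8, planted_disturbed) * q1_fm_r
        pie_myo_r[planted] = rng.uniform(0.4, 0.8, planted_disturbed) * q1_pie
        planted_ids = sorted(str(s) for s in ids[planted])

    frames = []
    for rep in range(1, n_repeats + 1):
        if n_repeats == 1:
            fm_rep, fm_r_rep = fm, fm_r
        else:
            cv = nz["within_subject_cv"]
            fm_rep = fm * np.clip(1.0 + rng.normal(0.0, cv, n), 0.05, None)
            fm_r_rep = fm_r * np.clip(1.0 + rng.normal(0.0, cv, n), 0.05, None)
        frames.append(pd.DataFrame({
            "subject_id": ids, "sex": sex, "age": age, "bmi": bmi,
            "sbp": sbp, "dbp": dbp, "fm": fm_rep, "fm_r": fm_r_rep,
            "pie_myo": pie_myo, "pie_myo_r": pie_myo_r,
            "repeat_index": rep,
        }))
    table = pd.concat(frames, ignore_index=True)
    return table, planted_ids
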