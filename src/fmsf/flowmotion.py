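"""Quadratic baseline fitting and the FM / FM(R) flowmotion statistics.

The resting fluorescence baseline is not always flat: across subjects it can
be ascending, descending, ascending to a plateau, or parabolic, and during
reperfusion the signal recovers along a rising saturating curve.  A second
order polynomial, fitted by least squares, is flexible enough to capture all
of these slow shapes while leaving the physiological oscillations in the
residuals.  The flowmotion parameter is then

    FM = MSE x 10**6,    MSE = SSE / n,

the mean squared residual about the quadratic, scaled into the convenient
range of units to hundreds.  Computed on a resting window it is called FM;
on a 150 s reperfusion window, FM(R).  Because the trace is normalized and
detrended, FM is unitless, operator-independent and comparable across
window lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np

from .preprocess import (
    Segment,
    SegmentationError,
    locate_hyperemia_minimum,
    normalize_trace,
    segment_occlusion,
    segment_reperfusion,
    segment_rest,
)
from .trace_io import AnalysisConfig, RawTrace

FM_SCALE = 1e6


@dataclass(frozen=True)
class BaselineFit:
    """Least-squares quadratic baseline of one segment.

    Coefficients are expressed on centered time ``tau = t - t_mid`` (seconds):
    ``baseline(tau) = c0 + c1*tau + c2*tau**2``.  ``mse`` is ``sse / n`` —
    the per-point normalization that makes windows of different lengths
    comparable.
    """

    c0: float
    c1: float
    c2: float
    n: int
    sse: float
    mse: float
    residuals: np.ndarray
    t_mid_s: float

    def predict(self, times_s: np.ndarray) -> np.ndarray:
        tau = np.asarray(times_s, dtype=float) - self.t_mid_s
        return self.c0 + self.c1 * tau + self.c2 * tau ** 2


@dataclass(frozen=True)
class FlowmotionResult:
    """FM statistic of one segment: ``fm = mse * 1e6``."""

    fm: float
    segment_label: str
    window_s: tuple[float, float]
    fit: BaselineFit


def fit_quadratic_baseline(segment: Segment) -> BaselineFit:
    """Fit ``a + b*t + c*t**2`` to a segment by least squares.

    Time is internally centered and scaled to [-1, 1] so the Vandermonde
    system stays well-conditioned on long windows; coefficients are mapped
    back to centered seconds.  Deterministic; requires >= 4 samples.
    """
    n = len(segment)
    if n < 4:
        raise ValueError(f"quadratic fit needs >= 4 samples, got {n}")
    t = segment.times
    t_mid = 0.5 * (t[0] + t[-1])
    half_span = 0.5 * (t[-1] - t[0])
    if half_span <= 0:
        raise ValueError("degenerate segment: zero time span")
    u = (t - t_mid) / half_span
    design = np.column_stack([np.ones(n), u, u * u])
    beta, *_ = np.linalg.lstsq(design, segment.values, rcond=None)
    residuals = segment.values - design @ beta
    sse = float(residuals @ residuals)
    # map coefficients from u = tau/half_span back to tau (centered seconds)
    c0 = float(beta[0])
    c1 = float(beta[1] / half_span)
    c2 = float(beta[2] / half_span ** 2)
    return BaselineFit(c0=c0, c1=c1, c2=c2, n=n, sse=sse, mse=sse / n,
                       residuals=residuals, t_mid_s=float(t_mid))


def flowmotion_parameter(segment: Segment,
                         fm_scale: float = FM_SCALE) -> FlowmotionResult:
    """Compute the FM statistic (mean squared residual x 10**6) of a segment."""
    fit = fit_quadratic_baseline(segment)
    return FlowmotionResult(fm=fit.mse * fm_scale,
                            segment_label=segment.label,
                            window_s=(segment.start_s, segment.end_s),
                            fit=fit)


def _segment_report(segment: Segment, config: AnalysisConfig) -> dict[str, Any]:
    from .spectral import compute_periodogram, summarize_bands

    result = flowmotion_parameter(segment, config.fm_scale)
    pg = compute_periodogram(result.fit, segment.sampling_rate)
    bands = summarize_bands(pg, config.band_edges, config.cardiac_band)
    return {
        "fm": result.fm,
        "window_s": list(result.window_s),
        "n_samples": result.fit.n,
        "baseline_coefficients": {
            "c0": result.fit.c0, "c1_per_s": result.fit.c1,
            "c2_per_s2": result.fit.c2, "t_mid_s": result.fit.t_mid_s,
        },
        "bands": bands.to_dict(),
    }


def analyze_trace(raw: RawTrace,
                  config: AnalysisConfig | None = None) -> dict[str, Any]:
    """Run the full single-trace analysis and return a JSON-ready report.

    Always computes resting FM with its band decomposition.  When protocol
    marks are present the report additionally carries FM(R) on the
    reperfusion window, an occlusion-segment FM as a quality check (no
    oscillations should survive under an inflated cuff, so this value should
    be a small fraction of resting FM), and per-segment band summaries.
    Without marks the analysis downgrades to rest-only with a notice.
    """
    config = config or AnalysisConfig()
    notices: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        trace = normalize_trace(raw, config.normalization_window)
        report: dict[str, Any] = {
            "subject_id": raw.subject_id,
            "sampling_rate_hz": raw.sampling_rate,
            "norm_constant": trace.norm_constant,
            "config": config.to_dict(),
        }
        rest = segment_rest(trace, config.rest_discard_s, config.rest_duration_s,
                            matched_interval=config.matched_rest_interval)
        segments = {"rest": _segment_report(rest, config)}
        report["fm"] = segments["rest"]["fm"]

        if raw.marks is None:
            report["protocol"] = "rest_only"
            notices.append("no protocol marks: rest-only analysis")
        else:
            report["protocol"] = "full_porh"
            marks = raw.marks
            occ = segment_occlusion(trace)
            segments["occlusion"] = _segment_report(occ, config)
            report["fm_occlusion_qc"] = segments["occlusion"]["fm"]

            if config.reperfusion_anchor == "minimum":
                start = locate_hyperemia_minimum(trace, marks,
                                                 config.hyperemia_search_s)
                report["hyperemia_minimum_s"] = start
            else:
                start = marks.release_s
            rep = segment_reperfusion(trace, start, config.reperfusion_duration_s,
                                      allow_truncation=config.allow_truncation)
            segments["reperfusion"] = _segment_report(rep, config)
            report["fm_r"] = segments["reperfusion"]["fm"]
            report["marks"] = marks.to_dict()

        report["segments"] = segments
    notices.extend(str(w.message) for w in caught)
    report["notices"] = notices
    from . import __version__
    report["fmsf_version"] = __version__
    return report
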