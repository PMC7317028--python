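"""Periodogram of detrended residuals and physiological band powers.

The oscillatory content of a detrended fluorescence segment is decomposed
with a plain FFT periodogram — rectangular window, no zero padding, frequency
step 1/T — normalized as a mean squared amplitude: the one-sided periodogram
sums (over all bins) to the mean squared residual.  This makes the link to
the flowmotion statistic exact: FM = 10**6 x total periodogram power of the
same residuals (Parseval), so the spectral decomposition is literally a
partition of FM across frequencies.

Band powers follow the conventional attribution of skin blood-flow
oscillations: endothelial <= 0.021 Hz, neurogenic (0.021-0.052 Hz],
myogenic (0.052-0.15 Hz], cardiac (0.6-2 Hz].  Intervals are left-open,
right-closed; 0 Hz (the mean, removed by the fit) is excluded.  Two
normalizations are reported: fractions of total residual power, and "pie"
fractions renormalized over the three sub-cardiac bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .flowmotion import BaselineFit

DEFAULT_BAND_EDGES: tuple[float, float, float] = (0.021, 0.052, 0.15)
DEFAULT_CARDIAC_BAND: tuple[float, float] = (0.6, 2.0)

#: absolute tolerance (Hz) when deciding band membership of a bin
_EDGE_TOL_HZ = 1e-9


@dataclass(frozen=True)
class Periodogram:
    """One-sided periodogram; ``psd`` sums to the mean squared residual."""

    freqs: np.ndarray
    psd: np.ndarray
    total_power: float  # sum over non-DC bins


@dataclass(frozen=True)
class BandSummary:
    """Residual power aggregated into physiological frequency bands."""

    power_endo: float
    power_neuro: float
    power_myo: float
    power_cardiac: float
    power_remainder: float
    total_power: float
    frac_endo: float
    frac_neuro: float
    frac_myo: float
    frac_cardiac: float
    pie_endo: float
    pie_neuro: float
    pie_myo: float

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        return asdict(self)


def compute_periodogram(fit: BaselineFit, sampling_rate: float) -> Periodogram:
    """One-sided rectangular-window periodogram of the fit residuals.

    Normalization: ``psd[k] = |X_k|^2 / n^2`` with the factor-2 fold-down on
    all bins except DC and (for even n) Nyquist, so ``sum(psd)`` equals the
    mean squared residual exactly.  A bin-centered sinusoid of amplitude A
    therefore carries ``A**2 / 2`` in its bin.
    """
    r = np.asarray(fit.residuals, dtype=float)
    n = len(r)
    if n < 8:
        raise ValueError(f"periodogram needs >= 8 residual samples, got {n}")
    spectrum = np.fft.rfft(r)
    psd = np.abs(spectrum) ** 2 / n ** 2
    if n % 2 == 0:
        psd[1:-1] *= 2.0  # Nyquist bin is unpaired
    else:
        psd[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    total = float(np.sum(psd[1:]))
    return Periodogram(freqs=freqs, psd=psd, total_power=total)


def _band_power(pg: Periodogram, lo: float, hi: float) -> float:
    """Sum of psd bins with frequency in (lo, hi] (edge tolerance 1e-9 Hz)."""
    mask = (pg.freqs > lo + _EDGE_TOL_HZ) & (pg.freqs <= hi + _EDGE_TOL_HZ)
    return float(np.sum(pg.psd[mask]))


def summarize_bands(pg: Periodogram,
                    band_edges: tuple[float, float, float] = DEFAULT_BAND_EDGES,
                    cardiac_band: tuple[float, float] = DEFAULT_CARDIAC_BAND,
                    ) -> BandSummary:
    """Aggregate periodogram power into endothelial/neurogenic/myogenic/cardiac bands.

    ``band_edges = (e0, e1, e2)`` define endothelial (0, e0], neurogenic
    (e0, e1] and myogenic (e1, e2].  Respiratory and other unclassified power
    (e.g. 0.15-0.6 Hz) is collected in ``power_remainder``.  Fractions are of
    ``total_power``; pie fractions renormalize over the three sub-cardiac
    bands (they sum to 1 whenever that sum is positive).
    """
    e0, e1, e2 = band_edges
    if not (0 < e0 < e1 < e2):
        raise ValueError("band edges must be positive and strictly increasing")
    endo = _band_power(pg, 0.0, e0)
    neuro = _band_power(pg, e0, e1)
    myo = _band_power(pg, e1, e2)
    cardiac = _band_power(pg, *cardiac_band)
    total = pg.total_power
    remainder = max(0.0, total - endo - neuro - myo - cardiac)
    three = endo + neuro + myo

    def frac(p: float) -> float:
        return p / total if total > 0 else 0.0

    def pie(p: float) -> float:
        return p / three if three > 0 else 0.0

    return BandSummary(
        power_endo=endo, power_neuro=neuro, power_myo=myo,
        power_cardiac=cardiac, power_remainder=remainder, total_power=total,
        frac_endo=frac(endo), frac_neuro=frac(neuro), frac_myo=frac(myo),
        frac_cardiac=frac(cardiac),
        pie_endo=pie(endo), pie_neuro=pie(neuro), pie_myo=pie(myo),
    )
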