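"""Per-region descriptors of simulated output signals.

Three descriptors summarise each region: the baseline potential (the
temporal mean of the post-transient output, in mV), the Welch power
spectral density, and the dominant frequency (location of the PSD
maximum within a search band, 0.5-45 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
import pandas as pd
from scipy.signal import welch

from .integrator import RegionTimeSeries

__all__ = [
    "RegionFeatures",
    "power_spectrum",
    "dominant_frequency",
    "baseline_potential",
    "extract_features",
    "feature_table",
]

DEFAULT_BAND = (0.5, 45.0)


@dataclass(frozen=True)
class RegionFeatures:
    """Per-region baseline (mV), dominant frequency (Hz) and PSD."""

    labels: tuple[str, ...]
    baseline: npt.NDArray[np.float64]
    dominant_freq: npt.NDArray[np.float64]
    freqs: npt.NDArray[np.float64]
    spectrum: npt.NDArray[np.float64]  # (N, F), nonnegative

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.spectrum) < 0):
            raise ValueError("power spectra must be nonnegative")


def power_spectrum(
    series: RegionTimeSeries,
    nperseg: int = 512,
    noverlap: int | None = None,
    window: str = "hann",
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch averaged-periodogram PSD per region.

    Defaults: 512-sample segments, 50% overlap, cosine (Hann) taper.
    ``normalize=True`` rescales each region's PSD to a unit maximum for
    display.  Returns ``(freqs, psd)`` with psd of shape (N, F).
    """
    t = series.n_samples
    if t < 256:
        raise ValueError(f"need at least 256 samples, got {t}")
    if t < nperseg:
        raise ValueError(f"series ({t} samples) shorter than one segment ({nperseg})")
    if noverlap is None:
        noverlap = nperseg // 2
    freqs, psd = welch(
        series.values, fs=series.fs, window=window, nperseg=nperseg, noverlap=noverlap
    )
    if normalize:
        peak = psd.max(axis=1, keepdims=True)
        psd = np.divide(psd, peak, out=np.zeros_like(psd), where=peak > 0)
    return freqs, psd


def dominant_frequency(
    freqs: npt.NDArray[np.float64],
    psd: npt.NDArray[np.float64],
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray:
    """Frequency of the per-region PSD maximum within ``band``.

    Ties break toward the lower frequency.  An all-zero in-band
    spectrum has no peak and raises ``ValueError``.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.atleast_2d(np.asarray(psd, dtype=float))
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no spectral bins")
    sub = psd[:, mask]
    if np.any(sub.max(axis=1) <= 0):
        raise ValueError("flat zero spectrum: dominant frequency undefined")
    return freqs[mask][np.argmax(sub, axis=1)]


def baseline_potential(series: RegionTimeSeries) -> np.ndarray:
    """Temporal mean of each region's post-transient output (mV)."""
    if series.n_samples == 0:
        raise ValueError("empty series")
    return series.values.mean(axis=1)


def extract_features(
    series: RegionTimeSeries | list[RegionTimeSeries],
    band: tuple[float, float] = DEFAULT_BAND,
    nperseg: int = 512,
    noverlap: int | None = None,
) -> RegionFeatures:
    """Descriptors for one run or, given a list of repetitions, with
    baselines and PSDs averaged across repetitions before the dominant
    frequency is located."""
    reps = [series] if isinstance(series, RegionTimeSeries) else list(series)
    if not reps:
        raise ValueError("no series given")
    base = np.mean([baseline_potential(r) for r in reps], axis=0)
    spectra = []
    for r in reps:
        freqs, psd = power_spectrum(r, nperseg=nperseg, noverlap=noverlap)
        spectra.append(psd)
    psd = np.mean(spectra, axis=0)
    return RegionFeatures(
        labels=reps[0].labels,
        baseline=base,
        dominant_freq=dominant_frequency(freqs, psd, band=band),
        freqs=freqs,
        spectrum=psd,
    )


def feature_table(features: RegionFeatures) -> pd.DataFrame:
    """(region_index, label, baseline_mV, dominant_freq_Hz) table."""
    return pd.DataFrame(
        {
            "region_index": np.arange(1, len(features.labels) + 1),
            "label": list(features.labels),
            "baseline_mV": features.baseline,
            "dominant_freq_Hz": features.dominant_freq,
        }
    )
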