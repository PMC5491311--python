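"""Spike-train statistics: rate, CV, LV, ISI histogram, spectrum, correlogram.

The two irregularity measures play complementary roles throughout the
package: the coefficient of variation (CV) of ISIs is a global measure that
is inflated by slow rate modulation, while the local variation (LV),
computed over pairs of successive ISIs, is insensitive to slow rate changes
and reflects the local renewal statistics.  For a stationary gamma renewal
process with shape κ, CV = 1/√κ and LV = 3/(2κ+1); for rate-modulated
trains CV exceeds LV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_fixtures import SpikeTrain

__all__ = [
    "StatSummary",
    "compute_cv",
    "compute_lv",
    "summarize",
    "isi_histogram",
    "power_spectrum",
    "cross_correlogram",
    "rmse_compare",
    "rmse_log_power",
]


@dataclass(frozen=True)
class StatSummary:
    mean_rate: float
    cv: float
    lv: float
    n_spikes: int
    duration: float
    label: str = ""


def _isis(train: SpikeTrain, min_spikes: int = 3) -> np.ndarray:
    if train.n_spikes < min_spikes:
        raise ValueError(
            f"need at least {min_spikes} spikes, got {train.n_spikes}"
        )
    return train.isis()


def compute_cv(train: SpikeTrain) -> float:
    """Coefficient of variation of the ISIs (sample SD, n−1, over mean)."""
    isis = _isis(train)
    return float(isis.std(ddof=1) / isis.mean())


def compute_lv(train: SpikeTrain) -> float:
    """Local variation of successive ISI pairs.

    LV = (1/(n−1)) Σ 3 (T_i − T_{i+1})² / (T_i + T_{i+1})² over the n−1
    pairs of consecutive ISIs.  Zero for a periodic train, 1 for Poisson,
    3/(2κ+1) for a gamma renewal process of shape κ.
    """
    isis = _isis(train)
    a, b = isis[:-1], isis[1:]
    return float(np.mean(3.0 * (a - b) ** 2 / (a + b) ** 2))


def summarize(train: SpikeTrain) -> StatSummary:
    return StatSummary(
        mean_rate=train.mean_rate,
        cv=compute_cv(train),
        lv=compute_lv(train),
        n_spikes=train.n_spikes,
        duration=train.duration,
        label=train.label,
    )


def isi_histogram(
    train: SpikeTrain, bin: float = 1e-3, max_isi: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ISI histogram.

    Returns ``(bin_centers, density)`` where the densities sum to 1 over
    the bins (ISIs beyond *max_isi* are dropped before normalization over
    the retained mass).
    """
    if bin <= 0:
        raise ValueError("bin must be > 0")
    isis = train.isis()
    edges = np.arange(0.0, max_isi + bin, bin)
    counts, _ = np.histogram(isis, bins=edges)
    total = counts.sum()
    dens = counts / total if total > 0 else counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def power_spectrum(
    train: SpikeTrain,
    method: str = "segment-averaged",
    bin: float = 1e-3,
    segment: float = 8.0,
    overlap: float = 0.5,
    nw: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the binned (1 ms) spike-count series.

    ``segment-averaged`` uses Welch's method (8 s Hann segments, 50%
    overlap); ``multitaper`` averages DPSS-tapered periodograms of the full
    record.  A Poisson train is flat at its counting-noise floor.
    Returns ``(freqs_hz, power)``.
    """
    if train.duration < 10.0:
        raise ValueError("need at least 10 s of data for a spectrum")
    n = int(round(train.duration / bin))
    counts = np.histogram(train.times, bins=n, range=(0.0, train.duration))[0].astype(float)
    fs = 1.0 / bin
    if method == "segment-averaged":
        nper = int(segment * fs)
        f, p = signal.welch(
            counts - counts.mean(),
            fs=fs,
            nperseg=min(nper, counts.size),
            noverlap=int(min(nper, counts.size) * overlap),
        )
    elif method == "multitaper":
        k = max(1, int(2 * nw) - 1)
        tapers, eigvals = signal.windows.dpss(counts.size, nw, Kmax=k, return_ratios=True)
        x = counts - counts.mean()
        spec = np.zeros(counts.size // 2 + 1)
        for tap in tapers:
            ft = np.fft.rfft(x * tap)
            spec += (ft.real**2 + ft.imag**2)
        spec /= k * fs
        f = np.fft.rfftfreq(counts.size, d=bin)
        p = spec
    else:
        raise ValueError("method must be 'segment-averaged' or 'multitaper'")
    return f, p


def cross_correlogram(
    a: SpikeTrain,
    b: SpikeTrain,
    bin: float = 1e-3,
    max_lag: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged coincidence counts between two trains.

    Returns ``(lags_s, counts)`` where ``counts[k]`` is the number of spike
    pairs (t_b − t_a) falling in lag bin k.  Computed by binning both
    trains at *bin* and correlating the count series, which is exact up to
    binning.
    """
    if a.n_spikes < 2 or b.n_spikes < 2:
        raise ValueError("need at least 2 spikes in each train")
    dur = max(a.duration, b.duration)
    n = int(round(dur / bin))
    ca = np.histogram(a.times, bins=n, range=(0.0, dur))[0].astype(float)
    cb = np.histogram(b.times, bins=n, range=(0.0, dur))[0].astype(float)
    m = int(round(max_lag / bin))
    full = signal.fftconvolve(cb, ca[::-1], mode="full")
    mid = n - 1
    counts = full[mid - m : mid + m + 1]
    lags = np.arange(-m, m + 1) * bin
    return lags, np.round(counts).astype(float)


def rmse_compare(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def rmse_log_power(p1: np.ndarray, p2: np.ndarray, floor: float = 1e-12) -> float:
    """RMSE between two spectra in log10-power units."""
    return rmse_compare(
        np.log10(np.maximum(p1, floor)), np.log10(np.maximum(p2, floor))
    )
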