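"""Neural feature extraction for the decoder.

Spike trains are counted in 20 ms bins, square-root transformed to stabilise
the Poisson variance, smoothed with a 50 ms-SD Gaussian kernel into
instantaneous rates, and stacked into a lagged design matrix covering 200 ms
of surrounding activity (p = 4 past bins, the concurrent bin, q = 5 future
bins) per predicted EMG bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d

#: Spike-count bin width (s).
BIN_WIDTH_S = 0.02
#: Gaussian smoothing SD (s).
SMOOTHING_SD_S = 0.05
#: Past / future lag counts.
N_PAST, N_FUTURE = 4, 5


class InsufficientDataError(ValueError):
    pass


def lag_window_ms(p: int = N_PAST, q: int = N_FUTURE,
                  bin_width_s: float = BIN_WIDTH_S) -> float:
    """Temporal extent of the lag window: (p + q + 1) bins, in ms."""
    return (p + q + 1) * bin_width_s * 1000.0


def bin_spikes(times: np.ndarray, bin_width_s: float = BIN_WIDTH_S,
               t0: float = 0.0, t1: float | None = None) -> np.ndarray:
    """Spike counts in half-open bins [t0 + k*w, t0 + (k+1)*w).

    A spike exactly on an interior edge is counted in the later bin; spikes
    at or beyond ``t1`` are excluded, so the counts sum to the number of
    spikes in [t0, t1).
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    times = np.asarray(times, dtype=float)
    if t1 is None:
        t1 = times.max() + bin_width_s if times.size else t0 + bin_width_s
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    n_bins = int(np.ceil((t1 - t0) / bin_width_s - 1e-9))
    inside = times[(times >= t0) & (times < t1)]
    idx = np.minimum(((inside - t0) / bin_width_s).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return counts


@dataclass
class BinnedRates:
    """Smoothed square-rooted spike counts, time bins x units."""

    rates: np.ndarray
    bin_width_s: float
    smoothing_sd_s: float
    unit_ids: list[int]

    @property
    def n_bins(self) -> int:
        return int(self.rates.shape[0])


def stabilize_and_smooth(counts: np.ndarray,
                         bin_width_s: float = BIN_WIDTH_S,
                         smoothing_sd_s: float = SMOOTHING_SD_S,
                         unit_ids: list[int] | None = None) -> BinnedRates:
    """Element-wise square root, then normalized Gaussian smoothing.

    The kernel SD is ``smoothing_sd_s / bin_width_s`` bins (2.5 bins at the
    defaults), truncated at 4 SD, normalised to unit sum, with reflective
    edge handling, so constant inputs are preserved exactly.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, np.newaxis]
    if np.any(counts < 0):
        raise ValueError("spike counts must be nonnegative")
    sigma_bins = smoothing_sd_s / bin_width_s
    smooth = gaussian_filter1d(np.sqrt(counts), sigma=sigma_bins, axis=0,
                               mode="reflect", truncate=4.0)
    if unit_ids is None:
        unit_ids = list(range(counts.shape[1]))
    return BinnedRates(rates=smooth, bin_width_s=bin_width_s,
                       smoothing_sd_s=smoothing_sd_s, unit_ids=list(unit_ids))


@dataclass
class LaggedDesign:
    """Lagged design matrix X: one row per usable (centre) time bin.

    Row ``t`` concatenates, unit by unit, the rates at bins
    ``t - p ... t + q``; the first ``p`` and last ``q`` bins have no
    complete window and are dropped.  ``centre_bins`` maps each row back to
    the time bin whose EMG sample it predicts.
    """

    X: np.ndarray
    p: int
    q: int
    bin_width_s: float
    unit_ids: list[int]
    centre_bins: np.ndarray

    @property
    def n_rows(self) -> int:
        return int(self.X.shape[0])

    @property
    def window_extent_s(self) -> float:
        return (self.p + self.q + 1) * self.bin_width_s


def build_lagged_design(rates: BinnedRates, p: int = N_PAST,
                        q: int = N_FUTURE) -> LaggedDesign:
    """Stack p past + concurrent + q future bins into the design matrix.

    With T input bins and U units the result is (T - p - q) x U*(p + q + 1),
    columns grouped per unit in lag order -p ... +q.
    """
    if p < 0 or q < 0:
        raise ValueError("p and q must be nonnegative")
    R = rates.rates
    T, U = R.shape
    window = p + q + 1
    if T <= p + q:
        raise InsufficientDataError(
            f"need more than p + q = {p + q} bins, got {T}")
    # windows[t, u, l] = R[t + l, u] for l in 0..window-1
    windows = sliding_window_view(R, window, axis=0)  # (T-p-q, U, window)
    X = windows.reshape(T - p - q, U * window)
    return LaggedDesign(X=np.ascontiguousarray(X), p=p, q=q,
                        bin_width_s=rates.bin_width_s,
                        unit_ids=list(rates.unit_ids),
                        centre_bins=np.arange(p, T - q))


def bin_emg(envelope: np.ndarray, sample_rate: float,
            bin_width_s: float = BIN_WIDTH_S,
            n_bins: int | None = None) -> np.ndarray:
    """Average an EMG envelope within each spike-count bin."""
    per_bin = int(round(sample_rate * bin_width_s))
    if per_bin < 1:
        raise ValueError("bin narrower than one EMG sample")
    if n_bins is None:
        n_bins = envelope.size // per_bin
    usable = envelope[: n_bins * per_bin]
    if usable.size < n_bins * per_bin:
        usable = np.pad(usable, (0, n_bins * per_bin - usable.size),
                        mode="edge")
    return usable.reshape(n_bins, per_bin).mean(axis=1)


__all__ = [
    "BIN_WIDTH_S",
    "SMOOTHING_SD_S",
    "N_PAST",
    "N_FUTURE",
    "BinnedRates",
    "InsufficientDataError",
    "LaggedDesign",
    "bin_emg",
    "bin_spikes",
    "build_lagged_design",
    "lag_window_ms",
    "stabilize_and_smooth",
]
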