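"""The 42-feature catalogue computed on each 90-s acceleration block.

Two features encode prior knowledge about the signal: the mean FFT magnitude
in the 2-4 Hz band (rumination's rhythmic jaw motion sits near 3 Hz) and the
spectral flatness (eating is broadband, i.e. flat; rumination is tonal). The
remaining 40 are generic time-series descriptors in the style of standard
feature-extraction libraries: moments, change statistics, run/count features,
autocorrelations, nonlinearity statistics and spectral summaries.

The catalogue order is fixed and versioned; every feature maps degenerate
(zero-variance) input to a finite value, by convention 0 for anything
variance-normalised.

Conventions
-----------
* spectra use the raw 900-sample block with a rectangular window;
* spectral flatness is geometric/arithmetic mean of the periodogram with a
  relative floor of 1e-12 on the bins, making it scale-invariant and exactly
  1 for an impulse;
* Welch-based entries use ``nperseg = min(n, 256)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import LabeledBlock

logger = logging.getLogger(__name__)

CATALOGUE_VERSION = "1.0"

_EPS_REL = 1e-12


# ---------------------------------------------------------------------------
# knowledge-specific features


def fft_band_amplitude(
    x: np.ndarray, f_lo: float = 2.0, f_hi: float = 4.0, fs: float = 10.0
) -> float:
    """Mean magnitude of real-FFT bins with frequency in [f_lo, f_hi] (inclusive)."""
    x = np.asarray(x, dtype=float)
    if not (0 <= f_lo < f_hi <= fs / 2.0):
        raise ValueError("need 0 <= f_lo < f_hi <= fs/2")
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValueError("band [f_lo, f_hi] contains no FFT bins")
    mag = np.abs(np.fft.rfft(x))
    return float(mag[mask].mean())


def spectral_flatness(x: np.ndarray) -> float:
    """Geometric over arithmetic mean of the periodogram; in [0, 1].

    1 for a perfectly flat magnitude spectrum (impulse, ideal white noise),
    near 0 for a tone. Constant signals return 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty signal")
    if np.ptp(x) == 0.0:
        return 0.0
    p = np.abs(np.fft.rfft(x)) ** 2
    pmax = p.max()
    if pmax == 0.0:
        return 0.0
    p = np.maximum(p, _EPS_REL * pmax)  # relative floor keeps scale invariance
    gm = np.exp(np.mean(np.log(p)))
    am = np.mean(p)
    return float(gm / am)


# ---------------------------------------------------------------------------
# generic time-series features


def _var(x):
    return float(np.var(x))


def _moments(x, order):
    mu = x.mean()
    s = x.std()
    if s == 0:
        return 0.0
    m = np.mean((x - mu) ** order)
    val = m / s**order
    return float(val - 3.0) if order == 4 else float(val)


def _mean_abs_change(x):
    return float(np.mean(np.abs(np.diff(x)))) if len(x) > 1 else 0.0


def _mean_change(x):
    return float((x[-1] - x[0]) / (len(x) - 1)) if len(x) > 1 else 0.0


def _mean_second_derivative_central(x):
    if len(x) < 3:
        return 0.0
    return float(np.mean(x[2:] - 2.0 * x[1:-1] + x[:-2]) / 2.0)


def _abs_sum_of_changes(x):
    return float(np.sum(np.abs(np.diff(x))))


def _ratio_beyond_r_sigma(x, r=2.0):
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean(np.abs(x - x.mean()) > r * s))


def _count_above_mean(x):
    return float(np.sum(x > x.mean()))


def _count_below_mean(x):
    return float(np.sum(x < x.mean()))


def count_above_global_mean(x, global_mean=0.0):
    """Count of samples above a dataset-level reference mean (catalogue param)."""
    return float(np.sum(x > global_mean))


def range_count(x, lower=-1.0, upper=1.0):
    """Count of samples in [lower, upper)."""
    return float(np.sum((x >= lower) & (x < upper)))


def _number_crossings(x, m=0.0):
    above = x > m
    return float(np.sum(above[1:] != above[:-1]))


def _longest_run(mask):
    if not mask.any():
        return 0.0
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    d = np.diff(padded)
    return float((np.flatnonzero(d == -1) - np.flatnonzero(d == 1)).max())


def _longest_strike_above_mean(x):
    return _longest_run(x > x.mean())


def _longest_strike_below_mean(x):
    return _longest_run(x < x.mean())


def _first_location_of_maximum(x):
    return float(np.argmax(x) / len(x))


def _last_location_of_maximum(x):
    return float(1.0 - np.argmax(x[::-1]) / len(x))


def _first_location_of_minimum(x):
    return float(np.argmin(x) / len(x))


def _last_location_of_minimum(x):
    return float(1.0 - np.argmin(x[::-1]) / len(x))


def _quantile(x, q):
    return float(np.quantile(x, q))


def _autocorrelation(x, lag):
    v = np.var(x)
    if v == 0 or len(x) <= lag:
        return 0.0
    mu = x.mean()
    return float(np.sum((x[:-lag] - mu) * (x[lag:] - mu)) / ((len(x) - lag) * v))


def _c3(x, lag=1):
    n = len(x)
    if n <= 2 * lag:
        return 0.0
    return float(np.mean(x[2 * lag :] * x[lag : n - lag] * x[: n - 2 * lag]))


def _cid_ce(x, normalize=True):
    x = np.asarray(x, dtype=float)
    if normalize:
        s = x.std()
        if s == 0:
            return 0.0
        x = (x - x.mean()) / s
    return float(np.sqrt(np.sum(np.diff(x) ** 2)))


def _time_reversal_asymmetry(x, lag=1):
    n = len(x)
    if n <= 2 * lag:
        return 0.0
    a = x[2 * lag :]
    b = x[lag : n - lag]
    c = x[: n - 2 * lag]
    return float(np.mean(a * a * b - b * c * c))


def _binned_entropy(x, bins=10):
    hist, _ = np.histogram(x, bins=bins)
    p = hist / len(x)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def fourier_entropy(x, bins=10):
    """Binned entropy of the max-normalised Welch power spectral density."""
    _, pxx = sps.welch(x, nperseg=min(len(x), 256))
    m = pxx.max()
    if m == 0:
        return 0.0
    return _binned_entropy(pxx / m, bins=bins)


def spectral_welch_density(x, freq=3.0, fs=10.0):
    """Welch PSD value at the frequency bin nearest ``freq``."""
    f, pxx = sps.welch(x, fs=fs, nperseg=min(len(x), 256))
    return float(pxx[np.argmin(np.abs(f - freq))])


def _fft_magnitudes(x, fs):
    return np.fft.rfftfreq(len(x), d=1.0 / fs), np.abs(np.fft.rfft(x))


def _fft_centroid(x, fs=10.0):
    f, m = _fft_magnitudes(x, fs)
    s = m.sum()
    if s == 0:
        return 0.0
    return float(np.sum(f * m) / s)


def _fft_variance(x, fs=10.0):
    f, m = _fft_magnitudes(x, fs)
    s = m.sum()
    if s == 0:
        return 0.0
    c = np.sum(f * m) / s
    return float(np.sum((f - c) ** 2 * m) / s)


def _number_peaks(x, n=3):
    if len(x) <= 2 * n:
        return 0.0
    core = x[n:-n]
    res = np.ones(len(core), dtype=bool)
    for i in range(1, n + 1):
        res &= core > x[n - i : len(x) - n - i]
        res &= core > x[n + i : len(x) - n + i]
    return float(np.sum(res))


# ---------------------------------------------------------------------------
# catalogue


@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    func: Callable[..., float]
    params: dict = field(default_factory=dict)

    def __call__(self, x: np.ndarray) -> float:
        return self.func(x, **self.params)


class FeatureCatalogue:
    """Ordered, named feature set; the unit of versioning for the pipeline."""

    def __init__(self, entries: list[CatalogueEntry], version: str = CATALOGUE_VERSION):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.entries = list(entries)
        self.version = version

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def compute(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        values = np.empty(len(self.entries))
        for i, entry in enumerate(self.entries):
            v = entry(x)
            if not np.isfinite(v):
                logger.debug("feature %s non-finite on degenerate block; using 0", entry.name)
                v = 0.0
            values[i] = v
        return values


def default_catalogue(
    fs: float = 10.0,
    global_mean: float = 0.0,
    range_lower: float = -1.0,
    range_upper: float = 1.0,
) -> FeatureCatalogue:
    """The fixed 42-entry catalogue used throughout the pipeline."""
    E = CatalogueEntry
    entries = [
        E("fft_amplitude_2_4hz", fft_band_amplitude, {"f_lo": 2.0, "f_hi": 4.0, "fs": fs}),
        E("spectral_flatness", spectral_flatness),
        E("mean", lambda x: float(np.mean(x))),
        E("median", lambda x: float(np.median(x))),
        E("standard_deviation", lambda x: float(np.std(x))),
        E("variance", _var),
        E("skewness", _moments, {"order": 3}),
        E("kurtosis", _moments, {"order": 4}),
        E("minimum", lambda x: float(np.min(x))),
        E("maximum", lambda x: float(np.max(x))),
        E("absolute_maximum", lambda x: float(np.max(np.abs(x)))),
        E("abs_energy", lambda x: float(np.dot(x, x))),
        E("root_mean_square", lambda x: float(np.sqrt(np.mean(x**2)))),
        E("mean_abs_change", _mean_abs_change),
        E("mean_change", _mean_change),
        E("mean_second_derivative_central", _mean_second_derivative_central),
        E("absolute_sum_of_changes", _abs_sum_of_changes),
        E("ratio_beyond_2_sigma", _ratio_beyond_r_sigma, {"r": 2.0}),
        E("count_above_mean", _count_above_mean),
        E("count_below_mean", _count_below_mean),
        E("count_above_global_mean", count_above_global_mean, {"global_mean": global_mean}),
        E("range_count", range_count, {"lower": range_lower, "upper": range_upper}),
        E("number_crossings_0", _number_crossings, {"m": 0.0}),
        E("longest_strike_above_mean", _longest_strike_above_mean),
        E("longest_strike_below_mean", _longest_strike_below_mean),
        E("first_location_of_maximum", _first_location_of_maximum),
        E("last_location_of_maximum", _last_location_of_maximum),
        E("first_location_of_minimum", _first_location_of_minimum),
        E("last_location_of_minimum", _last_location_of_minimum),
        E("quantile_q25", _quantile, {"q": 0.25}),
        E("quantile_q75", _quantile, {"q": 0.75}),
        E("autocorrelation_lag1", _autocorrelation, {"lag": 1}),
        E("autocorrelation_lag2", _autocorrelation, {"lag": 2}),
        E("autocorrelation_lag3", _autocorrelation, {"lag": 3}),
        E("c3_lag1", _c3, {"lag": 1}),
        E("cid_ce", _cid_ce),
        E("time_reversal_asymmetry_lag1", _time_reversal_asymmetry, {"lag": 1}),
        E("binned_entropy_10", _binned_entropy, {"bins": 10}),
        E("fourier_entropy", fourier_entropy, {"bins": 10}),
        E("spectral_welch_density", spectral_welch_density, {"freq": 3.0, "fs": fs}),
        E("fft_centroid", _fft_centroid, {"fs": fs}),
        E("number_peaks_3", _number_peaks, {"n": 3}),
    ]
    assert len(entries) == 42
    return FeatureCatalogue(entries)


def extract_features(block: LabeledBlock, catalogue: FeatureCatalogue) -> dict[str, float]:
    """Feature vector for one block, keyed by catalogue name, all finite."""
    values = catalogue.compute(block.samples)
    return dict(zip(catalogue.names, values))


def build_feature_table(
    blocks: list[LabeledBlock], catalogue: FeatureCatalogue | None = None
) -> pd.DataFrame:
    """Rows = blocks (steer-grouped, time-ordered); 42 feature columns + metadata."""
    if catalogue is None:
        catalogue = default_catalogue()
    meta = {
        "steer_id": [b.steer_id for b in blocks],
        "trial_id": [b.trial_id for b in blocks],
        "block_index": [b.block_index for b in blocks],
        "label": [b.label for b in blocks],
        "purity": [b.label_purity for b in blocks],
    }
    rows = np.array([catalogue.compute(b.samples) for b in blocks]).reshape(
        len(blocks), len(catalogue)
    )
    table = pd.DataFrame(meta)
    for j, name in enumerate(catalogue.names):
        table[name] = rows[:, j] if len(blocks) else np.array([])
    return table


META_COLUMNS = ["steer_id", "trial_id", "block_index", "label", "purity"]


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]
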