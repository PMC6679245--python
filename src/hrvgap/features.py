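"""HRV feature extraction: time, frequency and nonlinear (Poincaré) domains.

Eleven features are computed per 5-min window: mean heart rate, RMSSD, SDNN,
pNN50 (plus the raw NN50 count), VLF/LF/HF/total band powers from a
Lomb–Scargle periodogram, the LF/HF ratio, and the Poincaré descriptors
SD1/SD2.  Inputs may be a :class:`BeatSeries`, an :class:`RRSeries`
(timestamps reconstructed by cumulative sum) or a :class:`GapAwareView`, in
which case only durations between consecutive-flagged retained pairs enter
the statistics and the periodogram handles the uneven sampling directly —
no imputation needed.

Conventions: sample standard deviation (divisor N-1) throughout; the pNN50
threshold is 50 ms with strict inequality and its denominator is the number
of RR-intervals; each duration is placed at the midpoint of its two beat
timestamps for spectral estimation; undefined features are returned as NaN,
never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.signal import lombscargle

from .errors import InvalidParameterError
from .series import BeatSeries, GapAwareView, RRSeries

__all__ = [
    "SpectralBands",
    "Periodogram",
    "HRVFeatureSet",
    "FEATURE_NAMES",
    "default_grid",
    "hr_mean",
    "rmssd",
    "sdnn",
    "pnn50",
    "nn50",
    "lomb_psd",
    "band_powers",
    "poincare",
    "compute_all",
]

FeatureInput = Union[BeatSeries, RRSeries, GapAwareView]

#: the eleven canonical features, in reporting order
FEATURE_NAMES = (
    "hr_mean", "rmssd", "sdnn", "pnn50",
    "vlf", "lf", "hf", "lf_hf", "total_power",
    "sd1", "sd2",
)

PNN50_THRESHOLD_S = 0.050


@dataclass(frozen=True)
class SpectralBands:
    """Band edges in Hz; each band is half-open (lo, hi] with hi inclusive.

    Defaults follow the standard short-term HRV bands: VLF (0, 0.04],
    LF (0.04, 0.15], HF (0.15, 0.4]; total power spans (0, 0.4].
    """

    vlf_hi: float = 0.04
    lf_hi: float = 0.15
    hf_hi: float = 0.40

    def __post_init__(self):
        if not (0.0 < self.vlf_hi < self.lf_hi < self.hf_hi):
            raise InvalidParameterError("band edges must satisfy 0 < vlf < lf < hf")


@dataclass(frozen=True)
class Periodogram:
    """Lomb–Scargle power on a strictly increasing frequency grid (Hz)."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)
        if f.shape != p.shape:
            from .errors import ShapeError

            raise ShapeError("frequency grid and power array differ in length")
        if len(f) and not np.all(np.diff(f) > 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")


@dataclass(frozen=True)
class HRVFeatureSet:
    """The eleven per-window features (NaN marks an undefined feature)."""

    hr_mean: float = math.nan
    rmssd: float = math.nan
    sdnn: float = math.nan
    pnn50: float = math.nan
    vlf: float = math.nan
    lf: float = math.nan
    hf: float = math.nan
    lf_hf: float = math.nan
    total_power: float = math.nan
    sd1: float = math.nan
    sd2: float = math.nan
    nn50: float = math.nan  # raw exceedance count behind pnn50

    def as_dict(self) -> dict:
        """The eleven canonical features as an ordered dict."""
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    @property
    def all_defined(self) -> bool:
        return all(math.isfinite(v) for v in self.as_dict().values())


def default_grid(step: float = 0.002, f_max: float = 0.40) -> np.ndarray:
    """Default frequency grid: step..f_max inclusive, spacing `step` Hz.

    0.002 Hz spacing resolves the ~1/300 Hz limit of a 5-min window.
    """
    n = int(round(f_max / step))
    return step * np.arange(1, n + 1)


# ---------------------------------------------------------------------------
# internal: normalise the three input kinds to duration/pair arrays


def _durations(x: FeatureInput) -> np.ndarray:
    """Valid RR-interval durations of the input, in seconds."""
    if isinstance(x, BeatSeries):
        return x.durations
    if isinstance(x, RRSeries):
        return x.durations
    if isinstance(x, GapAwareView):
        return x.valid_durations
    raise InvalidParameterError(f"unsupported input type {type(x).__name__}")


def _lag1_pairs(x: FeatureInput) -> tuple[np.ndarray, np.ndarray]:
    """(d_n, d_{n+1}) arrays over valid lag-1 duration pairs.

    For a gap-aware view a pair is valid only when both of its durations are
    consecutive-flagged (they share a retained beat and no gap intrudes).
    """
    if isinstance(x, GapAwareView):
        d = x.durations
        ok = x.consecutive[:-1] & x.consecutive[1:]
        return d[:-1][ok], d[1:][ok]
    d = _durations(x)
    return d[:-1], d[1:]


def _sample_times(x: FeatureInput) -> tuple[np.ndarray, np.ndarray]:
    """(midpoint times, durations) for spectral estimation."""
    if isinstance(x, BeatSeries):
        ts = x.timestamps
        return (ts[:-1] + ts[1:]) / 2.0, x.durations
    if isinstance(x, RRSeries):
        ts = x.to_beats().timestamps
        return (ts[:-1] + ts[1:]) / 2.0, x.durations
    if isinstance(x, GapAwareView):
        ts = x.timestamps
        mid = (ts[:-1] + ts[1:]) / 2.0
        return mid[x.consecutive], x.valid_durations
    raise InvalidParameterError(f"unsupported input type {type(x).__name__}")


def _input_ok(x: FeatureInput) -> bool:
    """Reject series invalidated by interpolation (non-monotone / non-positive)."""
    if isinstance(x, BeatSeries):
        return x.is_strictly_increasing
    if isinstance(x, RRSeries):
        return x.is_physiologic
    return True


# ---------------------------------------------------------------------------
# time domain


def hr_mean(x: FeatureInput) -> float:
    """Mean instantaneous heart rate, beats/min: mean of 60/RR over valid pairs."""
    d = _durations(x)
    if len(d) < 1:
        return math.nan
    return float(np.mean(60.0 / d))


def rmssd(x: FeatureInput) -> float:
    """Root mean square of successive RR-interval differences, seconds.

    The mean runs over the valid squared successive differences (N-2 terms
    for N beats); for a gap-aware view a difference term requires both of its
    durations to be consecutive-flagged.
    """
    d1, d2 = _lag1_pairs(x)
    if len(d1) < 1:
        return math.nan
    return float(np.sqrt(np.mean((d2 - d1) ** 2)))


def sdnn(x: FeatureInput) -> float:
    """Sample standard deviation (divisor N-1) of RR-intervals, seconds."""
    d = _durations(x)
    if len(d) < 2:
        return math.nan
    return float(np.std(d, ddof=1))


def nn50(x: FeatureInput) -> float:
    """Count of successive differences exceeding 50 ms (strict)."""
    d1, d2 = _lag1_pairs(x)
    if len(d1) < 1:
        return math.nan
    return float(np.count_nonzero(np.abs(d2 - d1) > PNN50_THRESHOLD_S))


def pnn50(x: FeatureInput) -> float:
    """NN50 divided by the number of RR-intervals (not difference pairs)."""
    count = nn50(x)
    if math.isnan(count):
        return math.nan
    n_intervals = len(_durations(x))
    return count / n_intervals


# ---------------------------------------------------------------------------
# frequency domain


def lomb_psd(x: FeatureInput, grid: np.ndarray | None = None) -> Periodogram:
    """Lomb–Scargle periodogram of the mean-centred RR durations.

    Each duration is placed at the midpoint of its two beat timestamps, so
    unevenly sampled (gapped) data needs no imputation.  Power is the
    least-squares periodogram scaled by 2/N, making an injected tone of
    amplitude A contribute ~A^2/2 (its variance) at its peak — s^2-like
    units without variance normalisation.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    times, d = _sample_times(x)
    if len(d) < 3:
        return Periodogram(grid, np.full(len(grid), math.nan))
    y = d - np.mean(d)
    power = np.atleast_1d(lombscargle(times, y, 2.0 * np.pi * grid)) * 2.0 / len(y)
    return Periodogram(grid, power)


def band_powers(psd: Periodogram, bands: SpectralBands | None = None) -> dict:
    """Band powers by summing power over each (lo, hi] band.

    Returns a dict with vlf, lf, hf, total_power and lf_hf (NaN when hf = 0).
    """
    if bands is None:
        bands = SpectralBands()
    f, p = psd.frequencies, psd.power
    if len(p) == 0 or np.any(np.isnan(p)):
        return {k: math.nan for k in ("vlf", "lf", "hf", "total_power", "lf_hf")}

    def _band(lo, hi):
        return float(np.sum(p[(f > lo) & (f <= hi)]))

    vlf = _band(0.0, bands.vlf_hi)
    lf = _band(bands.vlf_hi, bands.lf_hi)
    hf = _band(bands.lf_hi, bands.hf_hi)
    total = _band(0.0, bands.hf_hi)
    lf_hf = lf / hf if hf > 0 else math.nan
    return {"vlf": vlf, "lf": lf, "hf": hf, "total_power": total, "lf_hf": lf_hf}


# ---------------------------------------------------------------------------
# nonlinear domain


def poincare(x: FeatureInput) -> tuple[float, float]:
    """Poincaré SD1/SD2 in seconds.

    SD1 is the dispersion perpendicular to the identity line of the lag-1
    scatter (RR_n, RR_{n+1}); SD2 the dispersion along it: sample standard
    deviations of (d_{n+1} - d_n)/sqrt(2) and (d_{n+1} + d_n)/sqrt(2).
    """
    d1, d2 = _lag1_pairs(x)
    if len(d1) < 2:
        return math.nan, math.nan
    sd1 = float(np.std((d2 - d1) / math.sqrt(2.0), ddof=1))
    sd2 = float(np.std((d2 + d1) / math.sqrt(2.0), ddof=1))
    return sd1, sd2


# ---------------------------------------------------------------------------


def compute_all(x: FeatureInput, bands: SpectralBands | None = None,
                grid: np.ndarray | None = None) -> HRVFeatureSet:
    """All eleven features of a window; undefined features come out as NaN.

    A series invalidated by interpolation (non-monotone timestamps or
    non-positive durations) yields an all-NaN feature set.
    """
    if not _input_ok(x):
        return HRVFeatureSet()
    sd1, sd2 = poincare(x)
    bp = band_powers(lomb_psd(x, grid), bands)
    return HRVFeatureSet(
        hr_mean=hr_mean(x),
        rmssd=rmssd(x),
        sdnn=sdnn(x),
        pnn50=pnn50(x),
        nn50=nn50(x),
        sd1=sd1,
        sd2=sd2,
        **bp,
    )
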