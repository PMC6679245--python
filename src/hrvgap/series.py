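"""Core beat-series containers.

Heartbeat data is carried in two equivalent representations: the sequence of
beat *timestamps* (seconds from window start) and the sequence of beat
*durations* (RR-intervals, the successive differences of the timestamps).
Gap handling operates on either representation, so both get a container, plus
a masked variant (:class:`GappedBeatSeries`) and a gap-aware view that keeps
the true timestamps and merely flags which adjacent retained pairs were
consecutive in the original recording (:class:`GapAwareView`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateWindowError, InvalidParameterError, ShapeError

__all__ = ["BeatSeries", "RRSeries", "GappedBeatSeries", "GapAwareView"]


@dataclass(frozen=True)
class BeatSeries:
    """Strictly increasing beat timestamps within a window, in seconds.

    Parameters
    ----------
    timestamps : array-like
        Beat times in seconds from the window start.
    validate : bool
        When True (default) a non-increasing sequence raises
        :class:`InvalidParameterError`.  Interpolation may produce a
        non-monotone result on purpose; such series are built unvalidated and
        flagged invalid for feature extraction via
        :attr:`is_strictly_increasing`.
    """

    timestamps: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise InvalidParameterError("timestamps must be one-dimensional")
        if self.validate and not self.is_strictly_increasing:
            raise InvalidParameterError("beat timestamps must be strictly increasing")

    @property
    def is_strictly_increasing(self) -> bool:
        if len(self.timestamps) < 2:
            return True
        return bool(np.all(np.diff(self.timestamps) > 0))

    @property
    def n_beats(self) -> int:
        return len(self.timestamps)

    @property
    def durations(self) -> np.ndarray:
        """RR-intervals in seconds: successive timestamp differences."""
        return np.diff(self.timestamps)

    @property
    def span(self) -> float:
        """Total window time covered by the beats (last - first), seconds."""
        if self.n_beats < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def shifted(self, offset: float) -> "BeatSeries":
        return BeatSeries(self.timestamps + offset, validate=self.validate)


@dataclass(frozen=True)
class RRSeries:
    """Ordered RR-interval durations in seconds.

    Durations reconstructed by interpolation may in principle be non-positive
    (spline overshoot); such series are built with ``validate=False`` and
    flagged through :attr:`is_physiologic`.
    """

    durations: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        d = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "durations", d)
        if d.ndim != 1:
            raise InvalidParameterError("durations must be one-dimensional")
        if self.validate and not self.is_physiologic:
            raise InvalidParameterError("RR-interval durations must all be positive")

    @property
    def is_physiologic(self) -> bool:
        return bool(np.all(self.durations > 0)) if len(self.durations) else True

    @property
    def n_intervals(self) -> int:
        return len(self.durations)

    def to_beats(self, anchor: float = 0.0) -> BeatSeries:
        """Reconstruct beat timestamps by cumulative sum anchored at `anchor`."""
        ts = anchor + np.concatenate([[0.0], np.cumsum(self.durations)])
        return BeatSeries(ts, validate=self.is_physiologic)


@dataclass(frozen=True)
class GappedBeatSeries:
    """A beat series with some beats marked missing.

    ``timestamps`` keeps the full original-length time axis so that indices in
    the series line up with indices in the gap mask; ``missing[i]`` is True
    when beat ``i`` was dropped.
    """

    timestamps: np.ndarray
    missing: np.ndarray

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        m = np.asarray(self.missing, dtype=bool)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "missing", m)
        if ts.shape != m.shape:
            raise ShapeError(
                f"timestamps ({ts.shape}) and missing mask ({m.shape}) differ in length"
            )

    @property
    def n_beats(self) -> int:
        return len(self.timestamps)

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.missing)

    @property
    def retained_timestamps(self) -> np.ndarray:
        return self.timestamps[~self.missing]

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(~self.missing))

    @property
    def is_degenerate(self) -> bool:
        """Fewer than two retained beats: no duration can be formed."""
        return self.n_retained < 2

    def require_nondegenerate(self):
        if self.is_degenerate:
            raise DegenerateWindowError(
                f"only {self.n_retained} retained beat(s); need at least 2"
            )


@dataclass(frozen=True)
class GapAwareView:
    """Retained beats with true timestamps plus per-pair adjacency flags.

    ``consecutive[k]`` is True when retained beats ``k`` and ``k+1`` were
    consecutive in the original series (no missing beat between them), so the
    duration between them is a genuine RR-interval.  Successive-difference
    statistics downstream use only flagged-true pairs.
    """

    timestamps: np.ndarray
    consecutive: np.ndarray

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        fl = np.asarray(self.consecutive, dtype=bool)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "consecutive", fl)
        if len(fl) != max(len(ts) - 1, 0):
            raise ShapeError(
                f"pair flag count {len(fl)} != retained beats - 1 = {len(ts) - 1}"
            )

    @property
    def n_beats(self) -> int:
        return len(self.timestamps)

    @property
    def durations(self) -> np.ndarray:
        """All adjacent-retained durations (valid and gap-spanning alike)."""
        return np.diff(self.timestamps)

    @property
    def valid_durations(self) -> np.ndarray:
        """Durations of consecutive-flagged pairs only."""
        return self.durations[self.consecutive]
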