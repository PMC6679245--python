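"""Gap filling on beat timestamps ("on time") or durations ("on duration").

The two pipelines differ only in the order of operations.  On time, the
missing *timestamps* are interpolated against beat index and durations are
obtained by differencing afterwards; this leaves every retained beat at its
true position, so the total window time is conserved exactly.  On duration,
the retained consecutive-pair *durations* are computed first and the missing
duration slots are interpolated; the reconstructed cumulative time then
generally drifts away from the true beat positions.

Kernels: nearest neighbour, linear, quadratic (the unique parabola through
three support points, evaluated in Lagrange form) and a global natural cubic
spline.  Nearest on time is rejected — it would duplicate a neighbouring
timestamp, which is physiologically impossible.  The abscissa for every
kernel is the integer beat (or duration-slot) index in the original,
pre-masking enumeration.

Support selection, which the kernels themselves do not fix: nearest/linear
use the closest retained point on each side of the gap; quadratic uses the
two nearest retained points before the gap and one after, falling back to
one-before/two-after at the left boundary and degrading to linear when only
two supports exist; the cubic spline is global over all retained points with
natural boundary conditions.  Gaps touching a window edge degrade rather
than extrapolate: trailing/leading missing beats are dropped on time, and
edge duration slots hold the nearest known duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateSupportError,
    DomainError,
    InvalidParameterError,
    UnsupportedCombinationError,
)
from .series import BeatSeries, GapAwareView, GappedBeatSeries, RRSeries

__all__ = [
    "InterpSpec",
    "kernel_nearest",
    "kernel_linear",
    "kernel_quadratic",
    "interpolate_on_time",
    "interpolate_on_duration",
    "no_interpolation_view",
]

HOWS = ("time", "duration", "none")
METHODS = ("nearest", "linear", "quadratic", "cubic_spline")


@dataclass(frozen=True)
class InterpSpec:
    """A (how, method) pipeline choice.

    ``how`` is one of ``time``, ``duration`` or ``none``; ``method`` is one of
    ``nearest``, ``linear``, ``quadratic``, ``cubic_spline`` and is ignored
    when ``how`` is ``none``.  The combination (time, nearest) is rejected:
    assigning a neighbour's timestamp to a missing beat would create a
    zero-length RR-interval.
    """

    how: str
    method: Optional[str] = None

    def __post_init__(self):
        if self.how not in HOWS:
            raise InvalidParameterError(f"how must be one of {HOWS}; got {self.how!r}")
        if self.how == "none":
            object.__setattr__(self, "method", None)
            return
        if self.method not in METHODS:
            raise InvalidParameterError(
                f"method must be one of {METHODS}; got {self.method!r}"
            )
        if self.how == "time" and self.method == "nearest":
            raise UnsupportedCombinationError(
                "nearest interpolation on time is rejected: it would duplicate "
                "a neighbouring beat timestamp"
            )

    @property
    def label(self) -> str:
        return self.how if self.how == "none" else f"{self.how}:{self.method}"


def kernel_nearest(i: float, a: float, x_a: float, b: float, x_b: float) -> float:
    """Value of the nearer known neighbour; exact midpoint goes to the later one.

    ``a < i < b`` with known values ``x_a`` at ``a`` and ``x_b`` at ``b``.
    """
    if not (a < i < b):
        raise DomainError(f"index {i} outside open support interval ({a}, {b})")
    return x_a if i < (a + b) / 2.0 else x_b


def kernel_linear(i: float, a: float, x_a: float, b: float, x_b: float) -> float:
    """Straight line through (a, x_a) and (b, x_b), evaluated at i."""
    if a == b:
        raise DegenerateSupportError("linear kernel needs two distinct support indices")
    return (x_a - x_b) / (a - b) * (i - b) + x_b


def kernel_quadratic(i: float, knots: Sequence[Tuple[float, float]]) -> float:
    """Unique parabola through three (index, value) knots, evaluated at i.

    Evaluated in Lagrange form, valid for arbitrary distinct supports; on
    equally spaced supports it reduces to the familiar central-difference
    closed form.
    """
    if len(knots) != 3:
        raise DegenerateSupportError("quadratic kernel needs exactly three knots")
    (i0, y0), (i1, y1), (i2, y2) = knots
    if len({i0, i1, i2}) != 3:
        raise DegenerateSupportError("quadratic kernel knots must have distinct indices")
    l0 = (i - i1) * (i - i2) / ((i0 - i1) * (i0 - i2))
    l1 = (i - i0) * (i - i2) / ((i1 - i0) * (i1 - i2))
    l2 = (i - i0) * (i - i1) / ((i2 - i0) * (i2 - i1))
    return y0 * l0 + y1 * l1 + y2 * l2


def _quadratic_supports(known: np.ndarray, gap_lo: int, gap_hi: int) -> Optional[np.ndarray]:
    """Pick three support indices from ``known`` for a gap spanning [gap_lo, gap_hi].

    Two nearest before + one after; at the left boundary one before + two
    after.  Returns None when fewer than three supports exist (caller degrades
    to linear).
    """
    before = known[known < gap_lo]
    after = known[known > gap_hi]
    if len(before) >= 2 and len(after) >= 1:
        return np.array([before[-2], before[-1], after[0]])
    if len(before) >= 1 and len(after) >= 2:
        return np.array([before[-1], after[0], after[1]])
    return None


def _fill_by_index(known_idx: np.ndarray, known_val: np.ndarray,
                   miss_idx: np.ndarray, method: str) -> np.ndarray:
    """Interpolate values at miss_idx from (known_idx, known_val) pairs.

    All miss_idx must lie strictly inside [known_idx[0], known_idx[-1]].
    """
    if method == "cubic_spline":
        if len(known_idx) < 2:
            raise DegenerateSupportError("cubic spline needs at least 2 retained points")
        if len(known_idx) == 2:
            # order degrades: a natural spline through two points is a line
            return np.interp(miss_idx, known_idx, known_val)
        cs = CubicSpline(known_idx, known_val, bc_type="natural")
        return cs(miss_idx)

    out = np.empty(len(miss_idx), dtype=float)
    known = np.asarray(known_idx)
    for j, i in enumerate(miss_idx):
        pos = np.searchsorted(known, i)
        a, b = known[pos - 1], known[pos]
        x_a = known_val[pos - 1]
        x_b = known_val[pos]
        if method == "nearest":
            out[j] = kernel_nearest(i, a, x_a, b, x_b)
        elif method == "linear":
            out[j] = kernel_linear(i, a, x_a, b, x_b)
        elif method == "quadratic":
            sup = _quadratic_supports(known, a + 1, b - 1)
            if sup is None:
                out[j] = kernel_linear(i, a, x_a, b, x_b)
            else:
                vals = known_val[np.searchsorted(known, sup)]
                out[j] = kernel_quadratic(i, list(zip(sup.tolist(), vals.tolist())))
        else:  # pragma: no cover - guarded by InterpSpec
            raise InvalidParameterError(f"unknown method {method!r}")
    return out


def interpolate_on_time(gapped: GappedBeatSeries, spec: InterpSpec) -> BeatSeries:
    """Fill missing beat timestamps by interpolating timestamp vs beat index.

    Retained timestamps are unchanged, so the window span between the first
    and last retained beat is conserved exactly.  Missing beats outside the
    retained range (leading/trailing) are dropped.  The returned series is not
    forced monotone: a non-monotone reconstruction is flagged through
    ``BeatSeries.is_strictly_increasing`` and should be treated as an invalid
    window for feature extraction rather than silently clamped.
    """
    if spec.how != "time":
        raise InvalidParameterError(f"spec.how must be 'time'; got {spec.how!r}")
    gapped.require_nondegenerate()
    known = gapped.retained_indices
    vals = gapped.timestamps[known]
    interior = np.flatnonzero(gapped.missing)
    interior = interior[(interior > known[0]) & (interior < known[-1])]
    n_out = known[-1] - known[0] + 1
    out = np.full(n_out, np.nan)
    out[known - known[0]] = vals
    if len(interior):
        out[interior - known[0]] = _fill_by_index(known, vals, interior, spec.method)
    return BeatSeries(out, validate=False)


def interpolate_on_duration(gapped: GappedBeatSeries, spec: InterpSpec) -> RRSeries:
    """Fill missing RR-interval durations by interpolating duration vs slot index.

    Duration slot ``i`` (between original beats ``i`` and ``i+1``) is known
    only when both beats are retained.  Unknown slots are interpolated from
    the known ones; slots outside the known range hold the nearest known
    duration.  Output length is always (original beat count - 1).  The
    reconstructed total window time is generally NOT preserved.
    """
    if spec.how != "duration":
        raise InvalidParameterError(f"spec.how must be 'duration'; got {spec.how!r}")
    gapped.require_nondegenerate()
    n = gapped.n_beats
    retained = ~gapped.missing
    known_slots = np.flatnonzero(retained[:-1] & retained[1:])
    if len(known_slots) == 0:
        # No two consecutive retained beats: fall back to the mean retained-pair
        # spacing so the output stays defined, though of degraded quality.
        ridx = gapped.retained_indices
        rts = gapped.retained_timestamps
        mean_d = (rts[-1] - rts[0]) / (ridx[-1] - ridx[0])
        return RRSeries(np.full(n - 1, mean_d), validate=False)

    known_vals = np.diff(gapped.timestamps)[known_slots]
    out = np.empty(n - 1, dtype=float)
    out[known_slots] = known_vals

    all_slots = np.arange(n - 1)
    unknown = np.setdiff1d(all_slots, known_slots)
    interior = unknown[(unknown > known_slots[0]) & (unknown < known_slots[-1])]
    if len(interior):
        out[interior] = _fill_by_index(known_slots, known_vals, interior, spec.method)
    # edge slots: hold the nearest known duration instead of extrapolating
    lead = unknown[unknown < known_slots[0]]
    trail = unknown[unknown > known_slots[-1]]
    out[lead] = known_vals[0]
    out[trail] = known_vals[-1]
    return RRSeries(out, validate=False)


def no_interpolation_view(gapped: GappedBeatSeries) -> GapAwareView:
    """Gap-aware view: retained beats at true timestamps, gaps left in place.

    Adjacent retained pairs are flagged consecutive when no missing beat lies
    between them; downstream statistics on successive differences use only
    flagged-true pairs.
    """
    gapped.require_nondegenerate()
    idx = gapped.retained_indices
    return GapAwareView(
        timestamps=gapped.timestamps[idx],
        consecutive=np.diff(idx) == 1,
    )


def apply_spec(gapped: GappedBeatSeries, spec: InterpSpec):
    """Dispatch a pipeline: returns BeatSeries, RRSeries or GapAwareView."""
    if spec.how == "time":
        return interpolate_on_time(gapped, spec)
    if spec.how == "duration":
        return interpolate_on_duration(gapped, spec)
    return no_interpolation_view(gapped)
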