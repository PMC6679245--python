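"""Gilbert two-state burst model for missing beats.

A two-state Markov chain (state 0 = good/observed, state 1 = bad/missing)
generates bursty missingness.  The chain is parametrised by the target
long-run missing fraction ``pchange`` and the mean burst length ``lburst``
(beats).  The transition probabilities follow:

    p = 1 / lburst                    (leave the bad state)
    P = pchange / (1 - pchange) * p   (enter the bad state)
    q = 1 - p                         (stay bad)
    Q = 1 - P                         (stay good)

which give the stationary missing rate  Pe = P / (p + P) = pchange, and
geometric bursts of missing beats with mean length 1/p = lburst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .series import BeatSeries, GappedBeatSeries

__all__ = [
    "GilbertParams",
    "GapMask",
    "derive_params",
    "stationary_missing_rate",
    "simulate_mask",
    "apply_mask",
]


@dataclass(frozen=True)
class GilbertParams:
    """Transition probabilities of the two-state burst chain.

    Attributes
    ----------
    pchange : float
        Target long-run missing fraction, in [0, 1).
    lburst : float
        Mean burst length in beats, >= 1.
    p, P, q, Q : float
        Leave-bad, enter-bad, stay-bad and stay-good probabilities;
        p + q = 1 and P + Q = 1 exactly.
    """

    pchange: float
    lburst: float
    p: float
    P: float
    q: float
    Q: float


@dataclass(frozen=True)
class GapMask:
    """Per-beat missing flags plus the RNG seed that produced them."""

    flags: np.ndarray
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=bool))

    @property
    def n_beats(self) -> int:
        return len(self.flags)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.flags)) if len(self.flags) else 0.0


def derive_params(pchange: float, lburst: float) -> GilbertParams:
    """Derive the chain's transition probabilities from (pchange, lburst).

    Raises
    ------
    InvalidParameterError
        If pchange is outside [0, 1), lburst < 1, or the combination yields an
        enter-bad probability P > 1 (no clipping is performed).
    """
    if not (0.0 <= pchange < 1.0):
        raise InvalidParameterError(f"pchange must be in [0, 1); got {pchange}")
    if lburst < 1.0:
        raise InvalidParameterError(f"lburst must be >= 1 beat; got {lburst}")
    p = 1.0 / lburst
    P = pchange / (1.0 - pchange) * p
    if P > 1.0:
        raise InvalidParameterError(
            f"pchange={pchange} with lburst={lburst} yields enter-bad "
            f"probability P={P:.4g} > 1; choose a longer burst or lower fraction"
        )
    return GilbertParams(pchange=pchange, lburst=lburst, p=p, P=P, q=1.0 - p, Q=1.0 - P)


def stationary_missing_rate(params: GilbertParams) -> float:
    """Long-run fraction of missing beats, Pe = P / (p + P).

    Algebraically equals ``params.pchange`` for parameters built by
    :func:`derive_params`.
    """
    denom = params.p + params.P
    if denom == 0.0:
        raise InvalidParameterError("p + P = 0: stationary rate undefined")
    return params.P / denom


def simulate_mask(params: GilbertParams, n_beats: int, seed: int) -> GapMask:
    """Simulate the burst chain over ``n_beats`` beats.

    The chain starts in the good state and one transition is drawn per beat;
    a beat is flagged missing when the chain is in state 1.  The first beat is
    never maskable: it anchors the window's time axis, so its flag is forced
    False and transitions apply from beat 2 onward.  The result is
    deterministic given (params, n_beats, seed).
    """
    if n_beats < 1:
        raise InvalidParameterError(f"n_beats must be >= 1; got {n_beats}")
    rng = np.random.default_rng(seed)
    u = rng.random(n_beats)
    flags = np.zeros(n_beats, dtype=bool)
    state = 0
    for i in range(1, n_beats):
        if state == 0:
            if u[i] < params.P:
                state = 1
        else:
            if u[i] < params.p:
                state = 0
        flags[i] = state == 1
    return GapMask(flags=flags, seed=seed)


def apply_mask(beats: BeatSeries, mask: GapMask) -> GappedBeatSeries:
    """Mark the masked beats of ``beats`` as missing.

    Retained beats keep their exact original timestamps; the input series is
    untouched.  A fully masked (or near-fully masked) result is representable
    but flagged degenerate via :attr:`GappedBeatSeries.is_degenerate`.
    """
    if beats.n_beats != mask.n_beats:
        from .errors import ShapeError

        raise ShapeError(
            f"series has {beats.n_beats} beats but mask has {mask.n_beats} flags"
        )
    return GappedBeatSeries(timestamps=beats.timestamps.copy(), missing=mask.flags.copy())


def burst_lengths(flags: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a flag sequence (diagnostics)."""
    f = np.asarray(flags, dtype=bool).astype(int)
    if len(f) == 0:
        return np.array([], dtype=int)
    padded = np.concatenate([[0], f, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts
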