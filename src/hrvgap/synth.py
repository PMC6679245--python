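"""Synthetic sinus-rhythm beat generator (integral pulse frequency modulation).

Beats are produced by an IPFM scheme: an instantaneous rate

    r(t) = hr_mean + lf_amp*sin(2*pi*lf_freq*t) + hf_amp*sin(2*pi*hf_freq*t) + noise(t)

in beats/min is integrated, and a beat fires each time the integral of
r(t)/60 crosses an integer.  The LF (default 0.1 Hz) and HF (default
0.25 Hz) tones emulate the baroreflex and respiratory modulation of normal
sinus rhythm; the noise term emulates the broadband beat-to-beat variability
of real RR series and is sampled as white Gaussian rate deviations held
constant over short blocks (~one beat), so it perturbs successive intervals
nearly independently.  Defaults target a mean heart rate of 75 beats/min,
typical of daytime sinus-rhythm recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .gilbert import apply_mask, derive_params, simulate_mask
from .series import BeatSeries, GappedBeatSeries

__all__ = ["SynthParams", "synth_beats", "make_table1_fixture"]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic sinus-rhythm generator.

    Amplitudes and noise are in beats/min on the instantaneous rate.  The
    invariant hr_mean - lf_amp - hf_amp - 3*noise_sd > 20 keeps the
    instantaneous rate positive and physiologic.
    """

    duration_s: float
    hr_mean: float = 75.0
    lf_amp: float = 3.0
    hf_amp: float = 2.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    noise_sd: float = 2.5
    noise_block_s: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        floor = self.hr_mean - self.lf_amp - self.hf_amp - 3.0 * self.noise_sd
        if floor <= 20.0:
            raise InvalidParameterError(
                f"hr_mean - lf_amp - hf_amp - 3*noise_sd = {floor:.1f} <= 20: "
                "instantaneous rate would leave the physiologic range"
            )


_DT = 0.001  # integration step, seconds


def synth_beats(params: SynthParams) -> BeatSeries:
    """Generate beat timestamps by IPFM on a 1-ms integration grid.

    The integer-crossing time is located by linear interpolation between grid
    points, giving sub-millisecond beat-time accuracy; for a constant rate
    the beat spacing is exact to floating-point precision.  Reproducible
    under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n_steps = int(np.ceil(params.duration_s / _DT))
    t = _DT * np.arange(n_steps)
    rate = (params.hr_mean
            + params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
            + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t))
    if params.noise_sd > 0:
        n_blocks = int(np.ceil(n_steps * _DT / params.noise_block_s))
        block_noise = rng.normal(0.0, params.noise_sd, n_blocks)
        rate = rate + block_noise[np.minimum(
            (t / params.noise_block_s).astype(int), n_blocks - 1)]
    # left-rectangle cumulative integral of r(t)/60; I[k] = integral up to t_k
    integral = np.concatenate([[0.0], np.cumsum(rate) * _DT / 60.0])
    grid = _DT * np.arange(n_steps + 1)
    n_beats = int(np.floor(integral[-1]))
    marks = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integral, marks)  # first k with integral[k] >= m
    lo = integral[idx - 1]
    hi = integral[idx]
    frac = (marks - lo) / (hi - lo)
    beat_times = grid[idx - 1] + frac * _DT
    beat_times = beat_times[beat_times <= params.duration_s]
    return BeatSeries(beat_times)


def make_table1_fixture(seed: int = 0) -> GappedBeatSeries:
    """A 100-beat synthetic window with a 10% burst mask (mean burst 10 beats).

    Used to demonstrate the structural contrast between the two pipelines:
    on-time interpolation conserves the window time spanned by the retained
    beats exactly, while on-duration interpolation changes the reconstructed
    total time.  At this short length the burst chain leaves roughly a third
    of draws gapless; since the fixture exists to exhibit missing values, the
    mask is re-drawn (deterministically from the seed) until it contains at
    least one missing beat.
    """
    # ~85 s at 75 bpm yields >100 beats; truncate to exactly 100
    beats = synth_beats(SynthParams(duration_s=100.0, seed=seed))
    if beats.n_beats < 100:  # pragma: no cover - defensive
        raise RuntimeError("synthetic window too short for the 100-beat fixture")
    beats100 = BeatSeries(beats.timestamps[:100])
    params = derive_params(0.10, 10.0)
    for attempt in range(1000):
        sub = int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0]
                  % (2**31))
        mask = simulate_mask(params, 100, sub)
        if mask.flags.any():
            break
    return apply_mask(beats100, mask)
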