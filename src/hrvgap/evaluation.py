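"""Factorial benchmark: gap injection x interpolation pipeline x HRV feature.

The study design: a long recording is split into non-overlapping 5-min
windows; burst missingness at target fractions (30/50/70% by default, mean
burst length 10 beats) is injected into each window; every interpolation
pipeline reconstructs the window; each HRV feature of the reconstruction is
compared against the gap-free ground truth by relative error (RE, percent)
and RMSE; methods are then ranked per feature and missing fraction by mean
RE, with ties broken toward the simpler method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ShapeError
from .features import FEATURE_NAMES, SpectralBands, compute_all
from .gilbert import apply_mask, derive_params, simulate_mask
from .interpolate import InterpSpec, apply_spec
from .series import BeatSeries

__all__ = [
    "ExperimentConfig",
    "ErrorSummary",
    "default_specs",
    "split_windows",
    "relative_error",
    "rmse",
    "run_experiment",
    "rank_methods",
]

#: tie-break complexity order for method ranking (simpler wins)
_METHOD_ORDER = {None: 0, "nearest": 1, "linear": 2, "quadratic": 3, "cubic_spline": 4}
_HOW_ORDER = {"none": 0, "time": 1, "duration": 2}


def default_specs() -> list[InterpSpec]:
    """All valid pipelines: none, 3 on-time kernels, 4 on-duration kernels."""
    specs = [InterpSpec("none")]
    specs += [InterpSpec("time", m) for m in ("linear", "quadratic", "cubic_spline")]
    specs += [InterpSpec("duration", m)
              for m in ("nearest", "linear", "quadratic", "cubic_spline")]
    return specs


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of the factorial missing-data experiment."""

    missing_fractions: tuple = (0.3, 0.5, 0.7)
    burst_length: float = 10.0
    specs: tuple = field(default_factory=lambda: tuple(default_specs()))
    window_s: float = 300.0
    seeds: tuple = (1,)
    min_retained_beats: int = 10
    bands: SpectralBands = field(default_factory=SpectralBands)

    def __post_init__(self):
        if not self.missing_fractions or not self.specs or not self.seeds:
            raise InvalidParameterError("missing_fractions, specs and seeds must be non-empty")
        if any(not (0.0 <= f < 1.0) for f in self.missing_fractions):
            raise InvalidParameterError("missing fractions must lie in [0, 1)")
        if self.window_s <= 0:
            raise InvalidParameterError("window_s must be positive")


@dataclass
class ErrorSummary:
    """Long-format per-window records plus exclusion bookkeeping.

    ``records`` columns: window, fraction, seed, how, method, feature,
    real, estimated, re (percent, NaN when undefined).
    """

    records: pd.DataFrame
    excluded_windows: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Per-cell summary: mean/median RE, RMSE and valid window count."""
        df = self.records
        grp = df.groupby(["fraction", "how", "method", "feature"], dropna=False)

        def _cell(g: pd.DataFrame) -> pd.Series:
            ok = g["re"].notna()
            diffs = g.loc[ok, "real"] - g.loc[ok, "estimated"]
            return pd.Series({
                "mean_re": g.loc[ok, "re"].mean(),
                "median_re": g.loc[ok, "re"].median(),
                "rmse": float(np.sqrt(np.mean(diffs**2))) if ok.any() else np.nan,
                "n_windows": int(ok.sum()),
            })

        out = grp.apply(_cell, include_groups=False).reset_index()
        return out


def split_windows(beats: BeatSeries, window_s: float = 300.0) -> list[BeatSeries]:
    """Split a long recording into consecutive non-overlapping windows.

    A beat belongs to the window containing its timestamp under the half-open
    convention [start, start + window_s); the trailing partial window is
    dropped; each window is re-anchored to start at its first beat.
    """
    if window_s <= 0:
        raise InvalidParameterError("window_s must be positive")
    ts = beats.timestamps
    if len(ts) == 0:
        return []
    t0 = ts[0]
    n_windows = int(np.floor((ts[-1] - t0) / window_s))
    windows = []
    for k in range(n_windows):
        lo, hi = t0 + k * window_s, t0 + (k + 1) * window_s
        sel = ts[(ts >= lo) & (ts < hi)]
        if len(sel):
            windows.append(BeatSeries(sel - sel[0]))
    return windows


def relative_error(x_real: float, x_k: float) -> float:
    """RE = |x_real - x_k| / |x_real| * 100; NaN when x_real is 0 or undefined."""
    if not np.isfinite(x_real) or not np.isfinite(x_k) or x_real == 0:
        return float("nan")
    return abs(x_real - x_k) / abs(x_real) * 100.0


def rmse(real: Sequence[float], estimated: Sequence[float]) -> float:
    """Root mean squared error between two equal-length value sequences."""
    r = np.asarray(real, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if r.shape != e.shape:
        raise ShapeError(f"length mismatch: {r.shape} vs {e.shape}")
    if len(r) < 1:
        raise InvalidParameterError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((r - e) ** 2)))


def _mask_seed(base_seed: int, window_id: int, frac_idx: int) -> int:
    """Distinct reproducible sub-seed per (window, fraction) cell."""
    ss = np.random.SeedSequence([int(base_seed), int(window_id), int(frac_idx)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(windows: Sequence[BeatSeries], cfg: ExperimentConfig) -> ErrorSummary:
    """Run the full factorial design over the given gap-free windows.

    For every window, missing fraction and replicate seed: simulate a Gilbert
    mask, apply it, reconstruct with every pipeline in ``cfg.specs``, extract
    features and record RE against the window's own gap-free features.
    Windows with fewer retained beats than ``cfg.min_retained_beats`` are
    excluded per-cell with counts reported.
    """
    if len(windows) == 0:
        raise InvalidParameterError("need at least one window")
    rows = []
    excluded = []
    for w_id, window in enumerate(windows):
        truth = compute_all(window, bands=cfg.bands).as_dict()
        for f_idx, frac in enumerate(cfg.missing_fractions):
            params = derive_params(frac, cfg.burst_length)
            for seed in cfg.seeds:
                mask = simulate_mask(params, window.n_beats,
                                     _mask_seed(seed, w_id, f_idx))
                gapped = apply_mask(window, mask)
                if gapped.n_retained < cfg.min_retained_beats:
                    excluded.append({"window": w_id, "fraction": frac, "seed": seed,
                                     "n_retained": gapped.n_retained})
                    continue
                for spec in cfg.specs:
                    est = compute_all(apply_spec(gapped, spec), bands=cfg.bands).as_dict()
                    for feat in FEATURE_NAMES:
                        rows.append({
                            "window": w_id,
                            "fraction": frac,
                            "seed": seed,
                            "how": spec.how,
                            "method": spec.method or "none",
                            "feature": feat,
                            "real": truth[feat],
                            "estimated": est[feat],
                            "re": relative_error(truth[feat], est[feat]),
                        })
    records = pd.DataFrame(rows)
    excluded_df = pd.DataFrame(excluded,
                               columns=["window", "fraction", "seed", "n_retained"])
    return ErrorSummary(records=records, excluded_windows=excluded_df)


def rank_methods(summary: ErrorSummary) -> pd.DataFrame:
    """Best (how, method) per feature per missing fraction, by mean RE.

    Ties break toward the simpler method (none < nearest < linear <
    quadratic < cubic_spline), then toward the simpler pipeline
    (none < time < duration).
    """
    agg = summary.aggregate()
    if len(agg) == 0:
        raise InvalidParameterError("empty summary: nothing to rank")
    agg = agg[agg["mean_re"].notna()].copy()
    agg["method_rank"] = agg["method"].map(
        lambda m: _METHOD_ORDER.get(None if m == "none" else m, 99))
    agg["how_rank"] = agg["how"].map(_HOW_ORDER)
    agg = agg.sort_values(["feature", "fraction", "mean_re", "method_rank", "how_rank"])
    best = agg.groupby(["feature", "fraction"], as_index=False).first()
    return best[["feature", "fraction", "how", "method", "mean_re", "median_re",
                 "rmse", "n_windows"]]
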