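"""Timecourse of target looking: proportion of on-display gaze contributions
on the target at each 33 ms interval, with by-subject bootstrap CIs and a
weighted local-quadratic (loess-style) overlay.

Each usable trial contributes one state per interval — the role occupying the
majority of the interval, ties toward the state at the interval's start — and
contributions are pooled over trials.  The plotted proportion at an interval
is (# TARGET contributions) / (# TARGET + DISTRACTOR contributions); AWAY
contributions are uninformative and never enter the denominator.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GazelexError
from .types import Role, Window
from .windowing import ClassifiedSession, bin_window

DEFAULT_GRID_MS = 33.0
DEFAULT_RANGE_MS = (-1000.0, 3500.0)


def _per_subject_counts(
    classified: Sequence[ClassifiedSession],
    grid_ms: float,
    range_ms: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(midpoints, n_target[S, K], n_either[S, K]) pooled over each subject's trials."""
    lo, hi = range_ms
    if hi - lo < grid_ms:
        raise GazelexError("empty timecourse grid")
    window = Window("PLOT", lo, hi)
    n_k = int(np.floor((hi - lo) / grid_ms))
    mids = lo + grid_ms * (np.arange(n_k) + 0.5)
    n_subj = len(classified)
    n_tgt = np.zeros((n_subj, n_k))
    n_eth = np.zeros((n_subj, n_k))
    for s, cs in enumerate(classified):
        for trial in cs.usable:
            states = bin_window(trial, window, grid_ms).states
            for k, st in enumerate(states):
                if st is Role.TARGET:
                    n_tgt[s, k] += 1
                    n_eth[s, k] += 1
                elif st is Role.DISTRACTOR:
                    n_eth[s, k] += 1
    return mids, n_tgt, n_eth


def proportion_curve(
    classified: Sequence[ClassifiedSession],
    grid_ms: float = DEFAULT_GRID_MS,
    range_ms: tuple[float, float] = DEFAULT_RANGE_MS,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Pooled target-looking proportion per interval with bootstrap CIs.

    The CI resamples subjects with replacement (each carrying all their trial
    contributions) and recomputes the pooled proportion per interval.
    Intervals where nobody is on-display get NaN proportions.
    """
    mids, n_tgt, n_eth = _per_subject_counts(classified, grid_ms, range_ms)
    tot_t = n_tgt.sum(axis=0)
    tot_e = n_eth.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(tot_e > 0, tot_t / np.where(tot_e > 0, tot_e, 1), np.nan)

    rng = np.random.default_rng(seed)
    n_subj = n_tgt.shape[0]
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boot_t = n_tgt[idx].sum(axis=1)  # (n_boot, K)
    boot_e = n_eth[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot_p = np.where(boot_e > 0, boot_t / np.where(boot_e > 0, boot_e, 1), np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN intervals
        lo_ci = np.nanquantile(boot_p, 0.025, axis=0)
        hi_ci = np.nanquantile(boot_p, 0.975, axis=0)

    return pd.DataFrame(
        {
            "t_ms": mids,
            "n_on_target": tot_t.astype(int),
            "n_on_either": tot_e.astype(int),
            "proportion": prop,
            "ci_low": np.where(tot_e > 0, lo_ci, np.nan),
            "ci_high": np.where(tot_e > 0, hi_ci, np.nan),
        }
    )


def smooth_curve(
    points: pd.DataFrame, span: float = 0.25, degree: int = 2
) -> pd.DataFrame:
    """Weighted local polynomial regression of the proportion curve.

    At each grid time, a degree-``degree`` polynomial is fit to the nearest
    ``span`` fraction of defined points, with tricube distance weights times
    the per-point ``n_on_either`` weights (zero-weight points are ignored).
    Output is on the input grid, with a ``smoothed`` column added.
    """
    pts = points.dropna(subset=["proportion"])
    pts = pts[pts["n_on_either"] > 0]
    t = pts["t_ms"].to_numpy(dtype=float)
    y = pts["proportion"].to_numpy(dtype=float)
    w_n = pts["n_on_either"].to_numpy(dtype=float)
    n = len(t)
    if n < 10:
        raise GazelexError("loess smoothing needs at least 10 defined points")
    k = max(degree + 2, int(np.ceil(span * n)))
    if k > n:
        raise GazelexError(f"span {span} too large for {n} points")
    if int(np.ceil(span * n)) < degree + 2:
        raise GazelexError(
            f"span {span} leaves too few points ({int(np.ceil(span * n))}) "
            f"for degree-{degree} local fits"
        )

    out_t = points["t_ms"].to_numpy(dtype=float)
    smoothed = np.full(len(out_t), np.nan)
    for j, t0 in enumerate(out_t):
        d = np.abs(t - t0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).eps
        tric = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        w = tric * w_n
        mask = w > 0
        if mask.sum() < degree + 1:
            continue
        B = np.vander((t[mask] - t0) / h, degree + 1, increasing=True)
        sw = np.sqrt(w[mask])
        coef, *_ = np.linalg.lstsq(B * sw[:, None], y[mask] * sw, rcond=None)
        smoothed[j] = coef[0]
    out = points.copy()
    out["smoothed"] = smoothed
    return out
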