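"""Threshold estimation from adaptive tracks.

Raw track levels are log10-transformed and fitted by maximum likelihood
with a guess-rate-floored cumulative Gaussian,

    p(x) = gamma + (1 - gamma - lambda) * Phi(beta * (x - alpha)),

with gamma fixed at 1/3 (3AFC) and the lapse rate lambda fixed small.
The reported threshold is the level at which the fitted function passes
through 0.5^(1/3) ≈ 79.4 % correct — the same point the three-down/
one-up staircase converges on.  Quality control discards fits with
non-positive slope or a threshold outside the range of levels the track
actually visited, and a 2.5 x IQR fence flags outlying thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .staircase import Track, TARGET_P

__all__ = [
    "PsychFitResult",
    "fit_track",
    "fit_levels",
    "qc_tracks",
    "iqr_outliers",
    "block_correlation",
    "threshold_table",
]

GUESS_3AFC = 1.0 / 3.0


@dataclass(frozen=True)
class PsychFitResult:
    """Outcome of one track fit (threshold and slope in log10 task units)."""

    threshold: float          # log10 task units, at the 79.4 % point
    slope: float              # per log10 unit
    gamma: float
    lapse: float
    valid: bool
    reject_reason: str | None = None  # None | negative_slope | out_of_range | too_few_trials
    loglik: float = np.nan

    @property
    def threshold_linear(self) -> float:
        """Threshold back on the task's linear scale."""
        return float(10.0 ** self.threshold)


def _neg_loglik(params, x, y, gamma, lapse):
    alpha, beta = params
    p = gamma + (1.0 - gamma - lapse) * stats.norm.cdf(beta * (x - alpha))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(np.where(y, np.log(p), np.log1p(-p)))


def fit_levels(levels, correct, gamma: float = GUESS_3AFC,
               lapse: float = 0.01, target_p: float = TARGET_P) -> PsychFitResult:
    """Maximum-likelihood psychometric fit to (level, correct) pairs.

    Levels are in linear task units and are log10-transformed
    internally.  The slope is left unconstrained during optimisation so
    that tracks where accuracy *decreases* with level surface as
    ``negative_slope`` rejections rather than boundary artefacts.
    """
    x = np.log10(np.asarray(levels, dtype=float))
    y = np.asarray(correct, dtype=bool)
    if x.size < 10 or np.unique(x).size < 2:
        return PsychFitResult(np.nan, np.nan, gamma, lapse, False, "too_few_trials")

    spread = max(x.max() - x.min(), 0.1)
    starts = [(np.median(x), 4.0 / spread), (np.median(x), -4.0 / spread)]
    best = None
    for a0, b0 in starts:
        res = optimize.minimize(_neg_loglik, x0=[a0, b0], args=(x, y, gamma, lapse),
                                method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = best.x
    loglik = -float(best.fun)

    if beta <= 0:
        return PsychFitResult(np.nan, float(beta), gamma, lapse, False,
                              "negative_slope", loglik)
    q = (target_p - gamma) / (1.0 - gamma - lapse)
    thr = float(alpha + stats.norm.ppf(q) / beta)
    if not (x.min() <= thr <= x.max()):
        return PsychFitResult(thr, float(beta), gamma, lapse, False,
                              "out_of_range", loglik)
    return PsychFitResult(thr, float(beta), gamma, lapse, True, None, loglik)


def fit_track(track: Track, lapse: float = 0.01,
              target_p: float = TARGET_P) -> PsychFitResult:
    """Fit a psychometric function to one track's non-practice trials."""
    trials = [t for t in track.trials if not t.practice]
    return fit_levels([t.level for t in trials], [t.correct for t in trials],
                      lapse=lapse, target_p=target_p)


def qc_tracks(fits: list[PsychFitResult]) -> tuple[list[int], list[int], float]:
    """Partition fits into kept/discarded indices; returns the discard fraction."""
    kept = [i for i, f in enumerate(fits) if f.valid]
    discarded = [i for i, f in enumerate(fits) if not f.valid]
    frac = len(discarded) / len(fits) if fits else 0.0
    return kept, discarded, frac


def iqr_outliers(values, k: float = 2.5) -> np.ndarray:
    """Flag values beyond ``k`` interquartile ranges outside [Q1, Q3].

    Quartiles use linear interpolation between order statistics.  The
    rule is applied once (no re-flagging of the surviving set).  Fewer
    than 4 values: nothing is flagged and a warning is issued.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("fewer than 4 values; outlier rule not applied", stacklevel=2)
        return np.zeros(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v > q3 + k * iqr) | (v < q1 - k * iqr)


def threshold_table(tracks_df: pd.DataFrame, lapse: float = 0.01,
                    outlier_k: float = 2.5) -> pd.DataFrame:
    """Fit every subject x task x session x block track in a trial table.

    Expects staircase-schema columns (subject, group, task, session,
    block, level, correct, practice).  Returns one row per track with the
    fitted log10 threshold, QC flags, and an IQR outlier flag computed
    per group x task x session over the valid thresholds.
    """
    rows = []
    keys = ["subject", "group", "task", "session", "block"]
    for key_vals, cell in tracks_df.groupby(keys, sort=True):
        cell = cell[cell["practice"] == 0] if "practice" in cell else cell
        fit = fit_levels(cell["level"].to_numpy(), cell["correct"].to_numpy().astype(bool),
                         lapse=lapse)
        rows.append(dict(zip(keys, key_vals)) | {
            "threshold_log10": fit.threshold if fit.valid else np.nan,
            "slope": fit.slope,
            "valid": fit.valid,
            "reject_reason": fit.reject_reason or "",
        })
    out = pd.DataFrame(rows)
    out["outlier"] = False
    for _, idx in out[out["valid"]].groupby(["group", "task", "session"]).groups.items():
        vals = out.loc[idx, "threshold_log10"].to_numpy()
        if len(vals) >= 4:
            out.loc[idx, "outlier"] = iqr_outliers(vals, k=outlier_k)
    return out


def block_correlation(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between block-1 and block-2 log10 thresholds.

    *records* is a threshold table (one row per track); the correlation
    is computed per task x session over subjects with two valid,
    non-outlier blocks.  Requires at least 3 complete pairs per cell.
    """
    usable = records[records["valid"] & ~records["outlier"]]
    rows = []
    for (task, session), cell in usable.groupby(["task", "session"], sort=True):
        wide = cell.pivot_table(index="subject", columns="block",
                                values="threshold_log10")
        if not {1, 2}.issubset(wide.columns):
            continue
        wide = wide[[1, 2]].dropna()
        if len(wide) < 3:
            raise ValueError(f"fewer than 3 block pairs for {task}/{session}")
        r, p = stats.pearsonr(wide[1], wide[2])
        rows.append({"task": task, "session": session, "r": float(r),
                     "p": float(p), "n_pairs": len(wide)})
    return pd.DataFrame(rows)
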