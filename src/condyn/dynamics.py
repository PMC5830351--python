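"""Univariate trial-by-trial dynamics of the conditioned response.

The per-trial β values (averaged over ROI voxels) are compared between an
early (onset < 5.6 min) and a late period, smoothed over trial time with a
Gaussian kernel, and differenced (CS+ minus CS−) to yield the adaptation
time course whose decline the change-point module quantifies.  Differencing
cancels condition-independent slow factors (arousal, scanner drift) to the
extent they vary slowly relative to the trial interleaving.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fdr_bh
from .betaseries import BetaSeries
from .design import CS_MINUS, CS_PLUS_UNPAIRED

__all__ = [
    "TrialSeries",
    "ConditionCurves",
    "DifferentialCurve",
    "EarlyLateSplit",
    "to_trial_series",
    "split_early_late",
    "early_late_test",
    "smooth_curves",
    "differential_curve",
    "adaptation_slope",
    "smoothing_sensitivity",
]


@dataclass
class TrialSeries:
    """One scalar response per analysed trial (ROI-mean β, or HR change)."""

    onsets: np.ndarray
    conditions: np.ndarray
    values: np.ndarray
    subject: str = "sub-01"
    roi: str = "roi"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.conditions = np.asarray(self.conditions)
        self.values = np.asarray(self.values, dtype=float)

    def of(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.conditions == condition
        return self.onsets[m], self.values[m]


def to_trial_series(
    beta: BetaSeries, exclude_post_us: bool = False
) -> TrialSeries:
    """ROI-level series: mean β across voxels for each analysed trial
    (US-paired CS+ trials are dropped)."""
    sel = beta.select(beta.analysis_mask(exclude_post_us))
    return TrialSeries(
        onsets=sel.onsets,
        conditions=sel.conditions,
        values=sel.betas.mean(axis=1),
        subject=beta.subject,
        roi=beta.roi,
    )


@dataclass
class EarlyLateSplit:
    """Per-period, per-condition mean responses and their differentials."""

    t_split_s: float
    means: dict  # (period, condition) -> mean value
    counts: dict
    differential: dict  # period -> CS+ minus CS−

    def as_row(self) -> dict:
        return {
            "early_diff": self.differential["early"],
            "late_diff": self.differential["late"],
            **{f"{p}_{c}": v for (p, c), v in self.means.items()},
        }


def _as_series(x: BetaSeries | TrialSeries) -> TrialSeries:
    return to_trial_series(x) if isinstance(x, BetaSeries) else x


def split_early_late(
    series: BetaSeries | TrialSeries, t_split_s: float = 336.0
) -> EarlyLateSplit:
    """Early (onset < t_split_s) versus late means per condition.

    The boundary uses time on task, not trial counts, so neither condition is
    favoured by the interleaving; the default 336 s is 5.6 minutes.
    """
    s = _as_series(series)
    means, counts, diff = {}, {}, {}
    early = s.onsets < t_split_s
    for period, mask in (("early", early), ("late", ~early)):
        for cond in (CS_PLUS_UNPAIRED, CS_MINUS):
            m = mask & (s.conditions == cond)
            if not m.any():
                raise ValueError(f"no {cond} trials in the {period} period")
            means[(period, cond)] = float(s.values[m].mean())
            counts[(period, cond)] = int(m.sum())
        diff[period] = means[(period, CS_PLUS_UNPAIRED)] - means[(period, CS_MINUS)]
    return EarlyLateSplit(t_split_s=t_split_s, means=means, counts=counts,
                          differential=diff)


def early_late_test(
    early: np.ndarray, late: np.ndarray, names: list[str] | None = None
) -> pd.DataFrame:
    """Paired t-test of early vs late differentials across subjects, per
    measure, with Benjamini–Hochberg correction across the measure set.

    ``early`` and ``late`` are subjects x measures arrays of CS+ minus CS−
    differentials.
    """
    early = np.atleast_2d(np.asarray(early, dtype=float))
    late = np.atleast_2d(np.asarray(late, dtype=float))
    if early.shape[0] < 2:
        raise ValueError("need at least 2 subjects for a paired test")
    if early.shape != late.shape:
        raise ValueError("early and late must have the same shape")
    t, p = stats.ttest_rel(early, late, axis=0)
    t, p = np.atleast_1d(np.asarray(t)), np.atleast_1d(np.asarray(p))
    degenerate = np.all(early == late, axis=0)  # no difference at all
    t[degenerate], p[degenerate] = 0.0, 1.0
    out = pd.DataFrame({
        "name": names if names is not None else
        [f"m{j}" for j in range(early.shape[1])],
        "early_mean": early.mean(axis=0),
        "late_mean": late.mean(axis=0),
        "t": t,
        "p": p,
    })
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out


def _gaussian_smooth(
    train_t: np.ndarray, train_y: np.ndarray, eval_t: np.ndarray, sigma_s: float
) -> np.ndarray:
    """Nadaraya–Watson estimate; weights renormalise at the block edges."""
    w = np.exp(-0.5 * ((np.asarray(eval_t)[:, None] - train_t[None, :]) / sigma_s) ** 2)
    return (w @ train_y) / w.sum(axis=1)


@dataclass
class ConditionCurves:
    """Gaussian-smoothed per-condition response curves on a shared grid."""

    grid_s: np.ndarray
    cs_plus: np.ndarray
    cs_minus: np.ndarray
    sigma_s: float
    bandwidth_trials: float
    plus_onsets: np.ndarray = field(repr=False, default=None)
    plus_values: np.ndarray = field(repr=False, default=None)
    minus_onsets: np.ndarray = field(repr=False, default=None)
    minus_values: np.ndarray = field(repr=False, default=None)
    subject: str = "sub-01"
    roi: str = "roi"

    def evaluate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            _gaussian_smooth(self.plus_onsets, self.plus_values, t, self.sigma_s),
            _gaussian_smooth(self.minus_onsets, self.minus_values, t, self.sigma_s),
        )


def smooth_curves(
    series: BetaSeries | TrialSeries,
    bandwidth_trials: float = 5.0,
    n_grid: int = 200,
) -> ConditionCurves:
    """Smooth each condition's responses over trial time.

    The kernel width is ``bandwidth_trials`` x the mean inter-trial spacing
    in seconds, so the bandwidth is expressed in trials regardless of the
    jittered intervals.
    """
    if bandwidth_trials <= 0:
        raise ValueError("bandwidth_trials must be positive")
    s = _as_series(series)
    tp, yp = s.of(CS_PLUS_UNPAIRED)
    tm, ym = s.of(CS_MINUS)
    if len(tp) < 3 or len(tm) < 3:
        raise ValueError("need at least 3 trials per condition to smooth")
    spacing = float(np.mean(np.diff(np.sort(s.onsets))))
    sigma_s = bandwidth_trials * spacing
    grid = np.linspace(s.onsets.min(), s.onsets.max(), n_grid)
    return ConditionCurves(
        grid_s=grid,
        cs_plus=_gaussian_smooth(tp, yp, grid, sigma_s),
        cs_minus=_gaussian_smooth(tm, ym, grid, sigma_s),
        sigma_s=sigma_s,
        bandwidth_trials=bandwidth_trials,
        plus_onsets=tp, plus_values=yp, minus_onsets=tm, minus_values=ym,
        subject=s.subject, roi=s.roi,
    )


@dataclass
class DifferentialCurve:
    """Smoothed CS+ minus CS− curve, plus the per-trial contrast series
    (the difference evaluated at each unpaired CS+ trial onset) that feeds
    the change-point analysis."""

    grid_s: np.ndarray
    values: np.ndarray
    trial_onsets: np.ndarray
    trial_values: np.ndarray
    subject: str = "sub-01"
    roi: str = "roi"

    def to_frame(self, curves: ConditionCurves | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.grid_s, "differential": self.values})
        if curves is not None:
            df["cs_plus"] = curves.cs_plus
            df["cs_minus"] = curves.cs_minus
        return df


def differential_curve(curves: ConditionCurves) -> DifferentialCurve:
    """Pointwise CS+ minus CS− on the shared grid, and the same difference at
    each unpaired CS+ trial onset (one contrast per analysed CS+ trial)."""
    plus_at, minus_at = curves.evaluate(curves.plus_onsets)
    return DifferentialCurve(
        grid_s=curves.grid_s,
        values=curves.cs_plus - curves.cs_minus,
        trial_onsets=curves.plus_onsets,
        trial_values=plus_at - minus_at,
        subject=curves.subject,
        roi=curves.roi,
    )


def raw_contrast_series(series: BetaSeries | TrialSeries,
                        bandwidth_trials: float = 5.0) -> np.ndarray:
    """Unsmoothed per-trial contrasts: each unpaired CS+ β minus the smoothed
    CS− curve at that trial's onset (the CS− must be interpolated because the
    two conditions never share a trial)."""
    s = _as_series(series)
    curves = smooth_curves(s, bandwidth_trials)
    tp, yp = s.of(CS_PLUS_UNPAIRED)
    minus_at = _gaussian_smooth(curves.minus_onsets, curves.minus_values, tp,
                                curves.sigma_s)
    return yp - minus_at


def adaptation_slope(curve: DifferentialCurve) -> float:
    """OLS slope of the per-trial contrast series against trial index
    (response units per trial); negative under adaptation."""
    y = curve.trial_values
    if len(y) < 3:
        raise ValueError("need at least 3 points for a slope")
    x = np.arange(1, len(y) + 1, dtype=float)
    return float(stats.linregress(x, y).slope)


def smoothing_sensitivity(
    series: BetaSeries | TrialSeries, bandwidths=(3.0, 5.0, 8.0)
) -> pd.DataFrame:
    """Re-derive the adaptation slope at several kernel bandwidths."""
    rows = []
    for bw in bandwidths:
        d = differential_curve(smooth_curves(series, bw))
        rows.append({"bandwidth_trials": bw, "slope": adaptation_slope(d)})
    return pd.DataFrame(rows)
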