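"""Stimulus-locked heart-rate deceleration curves from RR intervals.

RR intervals are converted to an instantaneous heart rate (60/RR, piecewise
constant over each inter-beat interval), averaged into 1-s bins from 1 s
before to 5 s after each stimulus onset — each interval weighted by the
fraction of the bin it occupies, i.e. an exact time-weighted mean — and
baseline-corrected by subtracting the prestimulus bin.  The transient
CS-locked slowing (deceleration) indexes defensive orienting; its CS+ minus
CS− difference is analysed with the same early/late and smoothing machinery
as the BOLD β-series.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CS_MINUS, ExperimentDesign

__all__ = [
    "RRSeries",
    "StepRate",
    "HrTrialMatrix",
    "instantaneous_hr",
    "weighted_bin",
    "trial_hr_curves",
    "hr_dynamics",
    "read_rr",
]


@dataclass
class RRSeries:
    """Beat times in seconds (first beat defines t = 0 unless given)."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size < 2:
            raise ValueError("need at least 2 beats")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @classmethod
    def from_intervals(cls, intervals_s, start_s: float = 0.0) -> "RRSeries":
        intervals_s = np.asarray(intervals_s, dtype=float)
        return cls(beat_times=start_s + np.concatenate(
            ([0.0], np.cumsum(intervals_s))))

    @property
    def intervals_s(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


def read_rr(path: str | Path) -> RRSeries:
    """One RR interval per line, seconds."""
    vals = np.loadtxt(path, dtype=float)
    return RRSeries.from_intervals(np.atleast_1d(vals))


@dataclass
class StepRate:
    """Piecewise-constant rate function: rate[i] on [times[i], times[i+1])."""

    times: np.ndarray
    rates: np.ndarray

    def __call__(self, t) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1,
                      0, len(self.rates) - 1)
        return self.rates[idx]

    def integral(self, a: float, b: float) -> float:
        """Exact integral over [a, b]; errors outside the defined span."""
        if a < self.times[0] - 1e-9 or b > self.times[-1] + 1e-9:
            raise ValueError(
                f"window [{a:.3f}, {b:.3f}] extends beyond the recording "
                f"[{self.times[0]:.3f}, {self.times[-1]:.3f}]")
        t = np.clip(self.times, a, b)
        return float(np.sum(np.diff(t) * self.rates))


def instantaneous_hr(
    rr: RRSeries, guard_s: tuple[float, float] = (0.2, 3.0)
) -> StepRate:
    """Instantaneous heart rate: 60/RR on the span of each interval.

    Intervals outside the physiological guard range are flagged and their
    rate value interpolated from neighbouring valid intervals (the beat grid
    is kept so the rate stays defined over every trial window).
    """
    iv = rr.intervals_s
    rates = 60.0 / iv
    bad = (iv < guard_s[0]) | (iv > guard_s[1])
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} RR interval(s) outside the "
                      f"{guard_s} s guard range; interpolated", stacklevel=2)
        if np.all(bad):
            raise ValueError("no valid RR intervals")
        mid = (rr.beat_times[:-1] + rr.beat_times[1:]) / 2
        rates = rates.copy()
        rates[bad] = np.interp(mid[bad], mid[~bad], rates[~bad])
    return StepRate(times=rr.beat_times, rates=rates)


def weighted_bin(
    rate: StepRate,
    onset_s: float,
    window: tuple[float, float] = (-1.0, 5.0),
    bin_s: float = 1.0,
) -> np.ndarray:
    """Time-weighted mean rate in consecutive bins around an onset.

    Each interval's rate contributes in proportion to the fraction of the bin
    it occupies, so the result is the exact mean of the piecewise-constant
    rate over each bin.
    """
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = onset_s + window[0] + bin_s * np.arange(n_bins + 1)
    return np.array([
        rate.integral(edges[j], edges[j + 1]) / bin_s for j in range(n_bins)
    ])


@dataclass
class HrTrialMatrix:
    """Per-trial binned heart rate (bpm) around stimulus onset."""

    values: np.ndarray  # trial x bin
    bin_edges_s: np.ndarray  # relative to onset
    conditions: np.ndarray
    onsets: np.ndarray
    subject: str = "sub-01"

    @property
    def change(self) -> np.ndarray:
        """Each bin minus the prestimulus bin (the first bin)."""
        return self.values - self.values[:, [0]]

    def bin_labels(self) -> list[str]:
        e = self.bin_edges_s
        return [f"bin_{e[j]:g}_{e[j + 1]:g}" for j in range(len(e) - 1)]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.bin_labels())
        for j, lab in enumerate(self.bin_labels()):
            df[f"change_{lab}"] = self.change[:, j]
        df.insert(0, "condition", self.conditions)
        df.insert(0, "trial_index", np.arange(1, len(self.onsets) + 1))
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def trial_hr_curves(
    rr: RRSeries,
    design: ExperimentDesign,
    window: tuple[float, float] = (-1.0, 5.0),
    bin_s: float = 1.0,
    guard_s: tuple[float, float] = (0.2, 3.0),
    subject: str = "sub-01",
) -> HrTrialMatrix:
    """Stimulus-locked binned HR for every analysed (non-US-paired) trial."""
    rate = instantaneous_hr(rr, guard_s)
    keep = [t for t in design.trials if t.us_onset_s is None]
    vals = np.stack([
        weighted_bin(rate, t.onset_s, window, bin_s) for t in keep
    ])
    n_bins = vals.shape[1]
    edges = window[0] + bin_s * np.arange(n_bins + 1)
    return HrTrialMatrix(
        values=vals,
        bin_edges_s=edges,
        conditions=np.array([t.condition for t in keep]),
        onsets=np.array([t.onset_s for t in keep]),
        subject=subject,
    )


def deceleration_response(
    matrix: HrTrialMatrix, decel_window_s: tuple[float, float] = (1.0, 4.0)
) -> np.ndarray:
    """Scalar per-trial HR response: mean baseline-corrected change over the
    bins covering the deceleration window (negative = slowing)."""
    e = matrix.bin_edges_s
    cover = [(e[j] >= decel_window_s[0] - 1e-9) and
             (e[j + 1] <= decel_window_s[1] + 1e-9)
             for j in range(len(e) - 1)]
    if not any(cover):
        raise ValueError("no bins inside the deceleration window")
    return matrix.change[:, np.asarray(cover)].mean(axis=1)


def hr_dynamics(
    matrix: HrTrialMatrix,
    t_split_s: float = 336.0,
    bandwidth_trials: float = 5.0,
    decel_window_s: tuple[float, float] = (1.0, 4.0),
):
    """Early/late statistics and smoothed difference curve of the per-trial
    HR deceleration, mirroring the univariate BOLD dynamics.

    Returns a dict with the early/late split, the condition curves, the
    differential curve, and the per-subject acquisition-mean CS+ minus CS−
    difference (the covariate used by the change-point concordance analysis).
    """
    from .dynamics import TrialSeries, differential_curve, smooth_curves, split_early_late

    series = TrialSeries(
        onsets=matrix.onsets,
        conditions=matrix.conditions,
        values=deceleration_response(matrix, decel_window_s),
        subject=matrix.subject,
        roi="hr",
    )
    split = split_early_late(series, t_split_s)
    curves = smooth_curves(series, bandwidth_trials)
    diff = differential_curve(curves)
    minus = series.values[series.conditions == CS_MINUS]
    plus = series.values[series.conditions != CS_MINUS]
    return {
        "series": series,
        "split": split,
        "curves": curves,
        "differential": diff,
        "mean_difference_bpm": float(plus.mean() - minus.mean()),
    }
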