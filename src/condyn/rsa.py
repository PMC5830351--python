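"""Sliding-window representational dissimilarity between CS+ and CS−.

Within a window of trials (default 50, stepped by 2), the voxel patterns of
unpaired CS+ trials and of CS− trials are separately averaged and the two
mean patterns Pearson-correlated across voxels; dissimilarity is D = 1 − r.
Group curves average the correlations on the Fisher-z scale before
re-transforming and subtracting from 1.  A decline of D over windows means
the two conditioned stimuli evoke increasingly similar multivoxel patterns —
representational convergence accompanying adaptation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pca_correlation
from .betaseries import BetaSeries
from .design import CS_MINUS, CS_PLUS_UNPAIRED

__all__ = [
    "DissimilarityCurve",
    "SlopeSet",
    "window_dissimilarity",
    "group_curve",
    "endpoint_test",
    "dissimilarity_slope",
    "slope_concordance",
]


@dataclass
class DissimilarityCurve:
    """Windowed CS+/CS− pattern dissimilarity over trial time."""

    center_trial: np.ndarray  # 1-based analysed-trial index of window centre
    center_s: np.ndarray
    r: np.ndarray
    window: int
    step: int
    subject: str = "sub-01"
    roi: str = "roi"

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.r

    @property
    def n_windows(self) -> int:
        return len(self.r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_center_trial": self.center_trial,
            "window_center_s": self.center_s,
            "r": self.r,
            "dissimilarity": self.dissimilarity,
        })


def window_dissimilarity(
    beta: BetaSeries,
    window: int = 50,
    step: int = 2,
    min_voxels: int = 4,
    min_per_condition: int = 3,
    exclude_post_us: bool = False,
) -> DissimilarityCurve:
    """Per-subject dissimilarity curve from a β-series.

    Windows slide over the chronological sequence of analysed trials
    (unpaired CS+ and CS−; US-paired trials are excluded before windowing so
    condition counts stay balanced), giving floor((n − window)/step) + 1
    windows.  A window with a zero-variance mean pattern yields an undefined
    correlation, recorded as NaN with a warning.
    """
    sel = beta.select(beta.analysis_mask(exclude_post_us))
    n = sel.n_trials
    if sel.n_voxels < min_voxels:
        raise ValueError(
            f"only {sel.n_voxels} voxels; a reliable multivoxel analysis "
            f"needs at least {min_voxels}")
    if window > n:
        raise ValueError("window longer than the analysed-trial sequence")
    starts = np.arange(0, n - window + 1, step)
    r = np.empty(len(starts))
    centers_t = np.empty(len(starts))
    centers_s = np.empty(len(starts))
    is_plus = sel.conditions == CS_PLUS_UNPAIRED
    is_minus = sel.conditions == CS_MINUS
    for w, s0 in enumerate(starts):
        idx = slice(s0, s0 + window)
        plus, minus = is_plus[idx], is_minus[idx]
        if plus.sum() < min_per_condition or minus.sum() < min_per_condition:
            raise ValueError(
                f"window at trial {s0 + 1} has fewer than "
                f"{min_per_condition} trials of one condition")
        mp = sel.betas[idx][plus].mean(axis=0)
        mm = sel.betas[idx][minus].mean(axis=0)
        if np.std(mp) == 0 or np.std(mm) == 0:
            warnings.warn(f"zero-variance pattern in window {w}; "
                          "dissimilarity undefined", stacklevel=2)
            r[w] = np.nan
        else:
            r[w] = np.corrcoef(mp, mm)[0, 1]
        centers_t[w] = s0 + (window + 1) / 2  # 1-based centre index
        centers_s[w] = sel.onsets[idx].mean()
    return DissimilarityCurve(
        center_trial=centers_t, center_s=centers_s, r=r,
        window=window, step=step, subject=beta.subject, roi=beta.roi,
    )


def group_curve(curves: list[DissimilarityCurve]) -> DissimilarityCurve:
    """Fisher-z average across subjects per window.

    r values are atanh-transformed, averaged, and tanh-back-transformed
    before D = 1 − r̄ (the spherically correct way to average correlations);
    |r| = 1 is clipped just inside the open interval with a warning.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 subjects")
    grids = {tuple(np.round(c.center_trial, 6)) for c in curves}
    if len(grids) != 1:
        raise ValueError("curves must share the same window grid")
    R = np.stack([c.r for c in curves])
    if np.any(np.abs(R) >= 1):
        warnings.warn("|r| = 1 clipped before Fisher-z averaging", stacklevel=2)
        R = np.clip(R, -(1 - 1e-6), 1 - 1e-6)
    r_bar = np.tanh(np.arctanh(R).mean(axis=0))
    c0 = curves[0]
    return DissimilarityCurve(
        center_trial=c0.center_trial,
        center_s=np.mean([c.center_s for c in curves], axis=0),
        r=r_bar, window=c0.window, step=c0.step,
        subject="group", roi=c0.roi,
    )


def endpoint_test(curves: list[DissimilarityCurve], k: int = 10):
    """Paired t-test of each subject's mean D over the first k windows
    against the last k windows (two-sided).

    Returns (t, p, first_means, last_means).
    """
    if any(c.n_windows < 2 * k for c in curves):
        raise ValueError(f"every curve needs at least {2 * k} windows")
    first = np.array([np.nanmean(c.dissimilarity[:k]) for c in curves])
    last = np.array([np.nanmean(c.dissimilarity[-k:]) for c in curves])
    if np.array_equal(first, last):  # perfectly flat: no effect by definition
        return 0.0, 1.0, first, last
    t, p = stats.ttest_rel(first, last)
    return float(t), float(p), first, last


def dissimilarity_slope(curve: DissimilarityCurve) -> float:
    """OLS slope of D against window index (D per window step)."""
    D = curve.dissimilarity
    ok = np.isfinite(D)
    if ok.sum() < 3:
        raise ValueError("need at least 3 windows for a slope")
    x = np.arange(len(D), dtype=float)
    return float(stats.linregress(x[ok], D[ok]).slope)


@dataclass
class SlopeSet:
    """Per-subject dissimilarity slopes per ROI with concordance statistics."""

    slopes: np.ndarray  # subjects x ROIs
    roi_names: list[str]
    pairwise_r: np.ndarray
    pairwise_p: np.ndarray
    eigen_fractions: np.ndarray
    pc1_scores: np.ndarray
    external_r: float | None = None
    external_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "pairwise_r": self.pairwise_r.tolist(),
            "pairwise_p": self.pairwise_p.tolist(),
            "eigen_fractions": self.eigen_fractions.tolist(),
            "pc1_scores": self.pc1_scores.tolist(),
            "external_r": self.external_r,
            "external_p": self.external_p,
        }


def slope_concordance(
    slopes: np.ndarray,
    external_slope: np.ndarray | None = None,
    roi_names: list[str] | None = None,
) -> SlopeSet:
    """Cross-ROI agreement of dissimilarity slopes.

    Pairwise Pearson correlations between ROI slope columns, PCA on their
    correlation matrix (PC1 fraction = 1/k for independent columns), and —
    when supplied — the correlation of PC1 scores with an external
    per-subject slope such as the univariate adaptation slope of another
    region.
    """
    X = np.asarray(slopes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need a subjects x ROIs matrix with >= 3 subjects, >= 2 ROIs")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("zero-variance slope column")
    n, k = X.shape
    if roi_names is None:
        roi_names = [f"roi{j}" for j in range(k)]
    pr = np.eye(k)
    pp = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            r, p = stats.pearsonr(X[:, a], X[:, b])
            pr[a, b] = pr[b, a] = r
            pp[a, b] = pp[b, a] = p
    fractions, scores, _ = pca_correlation(data=X)
    pc1 = scores[:, 0]
    ext_r = ext_p = None
    if external_slope is not None:
        external_slope = np.asarray(external_slope, dtype=float)
        if external_slope.shape != (n,):
            raise ValueError("external_slope must have one value per subject")
        ext_r, ext_p = (float(v) for v in stats.pearsonr(pc1, external_slope))
    return SlopeSet(
        slopes=X, roi_names=roi_names, pairwise_r=pr, pairwise_p=pp,
        eigen_fractions=fractions, pc1_scores=pc1,
        external_r=ext_r, external_p=ext_p,
    )
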