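"""CUSUM change-point detection with a permutation null, and cross-ROI
concordance of the estimated change points.

The CUSUM chart cumulates deviations of the per-trial contrast series from
its overall mean; a sustained shift in the mean bends the chart, and the
range of the chart (max minus min) measures the magnitude of change.  The
chart is compared against charts of randomly reordered series: the
percentage of permutations with a smaller magnitude is the confidence level,
declared significant above a 95% threshold.  The change point is the CUSUM
estimator — the index at which the chart is farthest from zero.

Concordance across regions is assessed with a one-way ANOVA on the
subject-level change points (ROI as factor) and a PCA on their correlation
matrix; the first component's score per subject can be correlated with an
external covariate such as each subject's heart-rate conditioning effect.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._stats import pca_correlation

__all__ = [
    "CusumResult",
    "ConcordanceResult",
    "cusum_chart",
    "change_magnitude",
    "permutation_confidence",
    "estimate_change_point",
    "detect_change",
    "roi_concordance",
]


def cusum_chart(values: np.ndarray) -> np.ndarray:
    """Cumulative sums of deviations from the series mean.

    S_0 = 0 and S_i = S_{i-1} + (x_i - mean(x)); length n + 1, and S_n = 0
    exactly because the deviations sum to zero.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D series of length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains missing values")
    return np.concatenate(([0.0], np.cumsum(x - x.mean())))


def change_magnitude(cusum: np.ndarray) -> float:
    """Range of the chart: max(S) - min(S), non-negative."""
    cusum = np.asarray(cusum, dtype=float)
    return float(cusum.max() - cusum.min())


def _batch_magnitudes(series_matrix: np.ndarray) -> np.ndarray:
    """Magnitudes of many series at once (rows are series); S_0 = 0 is
    implicit via clipping the running max/min at zero."""
    dev = series_matrix - series_matrix.mean(axis=1, keepdims=True)
    S = np.cumsum(dev, axis=1)
    return np.maximum(S.max(axis=1), 0.0) - np.minimum(S.min(axis=1), 0.0)


def permutation_confidence(
    values: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Percentage of random reorderings whose magnitude of change is strictly
    smaller than the observed one (ties count against significance).

    Invariant to affine transforms of the input: permuting a*x + b permutes
    the magnitudes by |a|, leaving the comparison unchanged.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if np.ptp(x) == 0:
        warnings.warn("constant series: no variation to permute", stacklevel=2)
        return 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = change_magnitude(cusum_chart(x))
    perms = rng.permuted(np.broadcast_to(x, (n_permutations, len(x))), axis=1)
    mags = _batch_magnitudes(perms)
    return 100.0 * float(np.count_nonzero(mags < observed)) / n_permutations


def estimate_change_point(values: np.ndarray) -> int:
    """CUSUM estimator: the 1-based index i (1..n-1) maximising |S_i|.

    The absolute chart is used so that both rising and falling mean shifts —
    whose charts are predominantly one-signed — are handled; ties break to
    the earliest index.
    """
    S = cusum_chart(values)
    interior = np.abs(S[1:-1])
    if np.all(interior == 0):
        raise ValueError("no change point: cumulative-sum chart is all zero")
    return int(np.argmax(interior)) + 1


@dataclass
class CusumResult:
    """Chart, magnitude, permutation confidence and estimated change point."""

    values: np.ndarray = field(repr=False)
    cusum: np.ndarray = field(repr=False)
    magnitude: float
    confidence: float
    change_point: int | None
    n_permutations: int
    seed: int | None
    threshold: float = 95.0

    @property
    def significant(self) -> bool:
        return self.confidence > self.threshold

    def to_dict(self) -> dict:
        return {
            "change_point": self.change_point,
            "magnitude": self.magnitude,
            "confidence": self.confidence,
            "significant": self.significant,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def detect_change(
    values: np.ndarray,
    n_permutations: int = 1000,
    threshold: float = 95.0,
    seed: int | None = None,
) -> CusumResult:
    """Full change-point analysis of one contrast series."""
    x = np.asarray(values, dtype=float)
    S = cusum_chart(x)
    mag = change_magnitude(S)
    if np.ptp(x) == 0:
        conf, cp = 0.0, None
    else:
        conf = permutation_confidence(x, n_permutations, seed=seed)
        cp = estimate_change_point(x)
    return CusumResult(values=x, cusum=S, magnitude=mag, confidence=conf,
                       change_point=cp, n_permutations=n_permutations,
                       seed=seed, threshold=threshold)


@dataclass
class ConcordanceResult:
    """Cross-ROI agreement of subject-level change points."""

    change_points: np.ndarray  # subjects x ROIs
    roi_names: list[str]
    f: float
    df: tuple[int, int]
    p: float
    eigen_fractions: np.ndarray
    pc1_scores: np.ndarray
    covariate_r: float | None = None
    covariate_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "F": self.f,
            "df": list(self.df),
            "p": self.p,
            "eigen_fractions": self.eigen_fractions.tolist(),
            "pc1_scores": self.pc1_scores.tolist(),
            "covariate_r": self.covariate_r,
            "covariate_p": self.covariate_p,
        }


def roi_concordance(
    change_points: np.ndarray,
    covariate: np.ndarray | None = None,
    roi_names: list[str] | None = None,
) -> ConcordanceResult:
    """ANOVA and PCA across ROI columns of a subjects x ROIs matrix.

    The one-way ANOVA (ROI as factor; df = (k-1, k(n-1))) asks whether the
    regions' change points differ systematically; the PCA on the correlation
    matrix asks whether they covary across subjects.  When all columns are
    identical F = 0 and the first component carries all the variance; for
    independent columns the population PC1 fraction is 1/k.
    """
    X = np.asarray(change_points, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need a subjects x ROIs matrix with >= 3 subjects, >= 2 ROIs")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells in the change-point matrix")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("zero-variance ROI column")
    n, k = X.shape
    if roi_names is None:
        roi_names = [f"roi{j}" for j in range(k)]

    f, p = stats.f_oneway(*(X[:, j] for j in range(k)))
    if not np.isfinite(f):  # identical groups
        f, p = 0.0, 1.0
    f = max(float(f), 0.0)  # guard tiny negative rounding
    fractions, scores, _ = pca_correlation(data=X)
    pc1 = scores[:, 0]

    cov_r = cov_p = None
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if covariate.shape != (n,):
            raise ValueError("covariate must have one value per subject")
        cov_r, cov_p = stats.pearsonr(pc1, covariate)
        cov_r, cov_p = float(cov_r), float(cov_p)
    return ConcordanceResult(
        change_points=X, roi_names=roi_names, f=float(f),
        df=(k - 1, k * (n - 1)), p=float(p),
        eigen_fractions=fractions, pc1_scores=pc1,
        covariate_r=cov_r, covariate_p=cov_p,
    )
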