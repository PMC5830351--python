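"""Single-trial response estimation (β-series GLM).

Every conditioned-stimulus presentation gets its own regressor — a boxcar of
the stimulus duration convolved with a canonical double-gamma hemodynamic
response function and sampled at scan times.  Solving the resulting general
linear model per voxel yields one β (response amplitude) per trial per voxel:
the β-series.  The data are global-scaled (each scan's spatial mean set to
100) and high-pass filtered with a discrete-cosine basis (cutoff period
128 s); the same cosine basis is appended to the design matrix as confound
columns so data and model are treated consistently.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .design import CS_PLUS_PAIRED, ExperimentDesign

__all__ = [
    "HrfParams",
    "RoiTimeSeries",
    "BetaSeries",
    "canonical_hrf",
    "build_design_matrix",
    "high_pass",
    "dct_basis",
    "global_scale",
    "estimate_beta_series",
]


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma parameters (seconds), SPM-style defaults."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0


def canonical_hrf(t_grid_s: np.ndarray, params: HrfParams | None = None) -> np.ndarray:
    """Canonical hemodynamic response: difference of two gamma densities.

    Peak-normalised so the maximum of the response equals 1; identically zero
    at t = 0 and beyond ``params.length``.
    """
    p = params or HrfParams()
    t = np.asarray(t_grid_s, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid_s must be non-negative and increasing")

    def raw(x: np.ndarray) -> np.ndarray:
        h = gamma_dist.pdf(x, a=p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
        h = h - p.undershoot_ratio * gamma_dist.pdf(
            x, a=p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
        )
        return np.where(x <= p.length, h, 0.0)

    dense = np.arange(0, p.length, 1e-3)
    peak = raw(dense).max()
    return raw(t) / peak


def event_regressors(
    onsets: np.ndarray,
    durations: np.ndarray,
    tr_s: float,
    n_scans: int,
    hrf_params: HrfParams | None = None,
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved boxcar regressors sampled at scan times (scan x event).

    Shared by the GLM design-matrix builder and the forward BOLD simulator, so
    the simulator's planted amplitudes are exactly the GLM's coefficients.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    dt = tr_s / oversample
    p = hrf_params or HrfParams()
    kernel = canonical_hrf(np.arange(0, p.length + dt, dt), p)
    X = np.zeros((n_scans, onsets.size))
    scan_idx = np.arange(n_scans) * oversample
    templates: dict[int, np.ndarray] = {}  # boxcar length -> convolved template
    for j, (on, dur) in enumerate(zip(onsets, durations)):
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + dur) / dt)))
        n_box = i1 - i0
        tmpl = templates.get(n_box)
        if tmpl is None:
            tmpl = np.convolve(np.ones(n_box), kernel) * dt
            templates[n_box] = tmpl
        rel = scan_idx - i0
        valid = (rel >= 0) & (rel < len(tmpl))
        X[valid, j] = tmpl[rel[valid]]
    return X


@dataclass
class RoiTimeSeries:
    """Voxel x scan BOLD matrix for one region of interest."""

    data: np.ndarray
    tr_s: float
    nuisance: np.ndarray | None = None
    roi: str = "roi"
    subject: str = "sub-01"
    global_signal: np.ndarray | None = None  # whole-brain mean per scan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be voxel x scan with >= 2 scans")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains missing values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.global_signal is not None:
            self.global_signal = np.asarray(self.global_signal, dtype=float)
            if self.global_signal.shape != (self.data.shape[1],):
                raise ValueError("global_signal must have one value per scan")
        if self.nuisance is not None and len(self.nuisance):
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.shape[0] != self.data.shape[1]:
                raise ValueError("nuisance must be scan x k")
        else:
            self.nuisance = None

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.data).to_csv(path, sep="\t", index=False, header=False)
        sidecar = Path(path).with_suffix(".json")
        meta = {"tr_s": self.tr_s, "n_voxels": int(self.n_voxels),
                "roi": self.roi, "subject": self.subject}
        if self.global_signal is not None:
            meta["global_signal"] = self.global_signal.tolist()
        sidecar.write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoiTimeSeries":
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        gs = meta.get("global_signal")
        return cls(data=data, tr_s=meta["tr_s"], roi=meta.get("roi", "roi"),
                   subject=meta.get("subject", "sub-01"),
                   global_signal=None if gs is None else np.asarray(gs))


@dataclass
class BetaSeries:
    """Per-trial, per-voxel response amplitudes with trial metadata."""

    betas: np.ndarray  # trial x voxel
    onsets: np.ndarray
    conditions: np.ndarray
    subject: str = "sub-01"
    roi: str = "roi"
    residual_variance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if not (len(self.betas) == len(self.onsets) == len(self.conditions)):
            raise ValueError("betas, onsets, conditions must align")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("trials must be in chronological order")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def analysis_mask(self, exclude_post_us: bool = False) -> np.ndarray:
        """Trials entering the analyses: US-paired CS+ trials are excluded
        (their responses are contaminated by the US); optionally also drop
        trials immediately preceded by a US."""
        mask = self.conditions != CS_PLUS_PAIRED
        if exclude_post_us:
            prev_paired = np.concatenate(
                ([False], self.conditions[:-1] == CS_PLUS_PAIRED)
            )
            mask &= ~prev_paired
        return mask

    def select(self, mask: np.ndarray) -> "BetaSeries":
        return BetaSeries(
            betas=self.betas[mask],
            onsets=self.onsets[mask],
            conditions=self.conditions[mask],
            subject=self.subject,
            roi=self.roi,
            residual_variance=self.residual_variance,
        )

    def to_tsv(self, path: str | Path, options: dict | None = None) -> None:
        df = pd.DataFrame(self.betas, columns=[f"v{j}" for j in range(self.n_voxels)])
        df.insert(0, "condition", self.conditions)
        df.insert(0, "onset", self.onsets)
        df.insert(0, "trial_index", np.arange(1, self.n_trials + 1))
        df.to_csv(path, sep="\t", index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps({"subject": self.subject, "roi": self.roi,
                        "options": options or {}})
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BetaSeries":
        df = pd.read_csv(path, sep="\t")
        vox = [c for c in df.columns if c.startswith("v")]
        meta_path = Path(path).with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            betas=df[vox].to_numpy(dtype=float),
            onsets=df["onset"].to_numpy(dtype=float),
            conditions=df["condition"].to_numpy(),
            subject=meta.get("subject", "sub-01"),
            roi=meta.get("roi", "roi"),
        )


def dct_basis(n_scans: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis (scan x k), periods >= cutoff, no constant.

    The k-th function has period 2 * n_scans * tr_s / k, so k runs to
    floor(2 * n_scans * tr_s / cutoff_s).  Each function sums to zero over the
    scan grid, so removing them leaves per-voxel means untouched.
    """
    n_basis = int(np.floor(2.0 * n_scans * tr_s / cutoff_s))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def high_pass(data: np.ndarray, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Remove slow drift by regressing out the discrete-cosine basis.

    Returns the residual; per-voxel means are unchanged (the constant is left
    for the GLM intercept to absorb).  If the record is shorter than one
    cutoff period the filter is skipped with a warning.
    """
    data = np.asarray(data, dtype=float)
    n_scans = data.shape[1]
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff_s must exceed twice the TR")
    if n_scans * tr_s < cutoff_s:
        warnings.warn("record shorter than the cutoff period; filter skipped",
                      stacklevel=2)
        return data.copy()
    C = dct_basis(n_scans, tr_s, cutoff_s)
    if C.shape[1] == 0:
        return data.copy()
    coef, *_ = np.linalg.lstsq(C, data.T, rcond=None)
    return data - (C @ coef).T


def global_scale(data: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Divide each scan by its spatial mean and multiply by 100.

    Afterwards every scan's spatial mean is exactly 100; the operation is
    idempotent and invariant to overall rescaling of the input.

    When scaling an ROI extracted from a larger acquisition, pass the
    whole-brain mean per scan as ``reference``: dividing a small ROI by its
    own spatial mean would remove the evoked response itself, since within a
    functionally homogeneous ROI the spatial mean *is* the task signal.
    """
    data = np.asarray(data, dtype=float)
    means = data.mean(axis=0) if reference is None else np.asarray(reference, float)
    if np.any(means <= 0):
        raise ValueError("non-positive scan mean; cannot global-scale")
    return data / means * 100.0


def build_design_matrix(
    design: ExperimentDesign,
    tr_s: float,
    n_scans: int,
    nuisance: np.ndarray | None = None,
    include_us_regressors: bool = True,
    hrf_params: HrfParams | None = None,
    dct_cutoff_s: float | None = None,
    oversample: int = 16,
) -> tuple[np.ndarray, list[str]]:
    """One column per stimulus: CS trials, then US events, then nuisance,
    then cosine drift confounds, then the intercept.

    Returns the scan x p matrix and matching column labels
    (``trial012_CSminus``, ``us03``, ``nuisance0``, ``dct1``, ``intercept``).
    """
    onsets = design.onsets()
    if np.any(onsets >= n_scans * tr_s):
        raise ValueError("trial onset beyond the scanned interval")
    durations = np.array([t.duration_s for t in design.trials])
    X_tr = event_regressors(onsets, durations, tr_s, n_scans, hrf_params, oversample)
    labels = [
        f"trial{i + 1:03d}_{t.condition}" for i, t in enumerate(design.trials)
    ]
    cols = [X_tr]

    us = [(i, t.us_onset_s) for i, t in enumerate(design.trials)
          if t.us_onset_s is not None]
    if include_us_regressors and us:
        us_onsets = np.array([o for _, o in us])
        us_durs = np.array([
            design.trials[i].duration_s - (o - design.trials[i].onset_s)
            for i, o in us
        ])
        close = [f"trial{i + 1:03d}" for i, o in us
                 if abs(o - design.trials[i].onset_s) < tr_s / 2]
        if close:
            warnings.warn(
                "US onsets within TR/2 of their CS onsets (collinearity risk): "
                + ", ".join(close), stacklevel=2,
            )
        cols.append(event_regressors(us_onsets, us_durs, tr_s, n_scans,
                                     hrf_params, oversample))
        labels += [f"us{i + 1:03d}" for i, _ in us]

    if nuisance is not None and np.size(nuisance):
        nuisance = np.asarray(nuisance, dtype=float)
        cols.append(nuisance)
        labels += [f"nuisance{k}" for k in range(nuisance.shape[1])]
    if dct_cutoff_s is not None:
        C = dct_basis(n_scans, tr_s, dct_cutoff_s)
        if C.shape[1]:
            cols.append(C)
            labels += [f"dct{k + 1}" for k in range(C.shape[1])]
    cols.append(np.ones((n_scans, 1)))
    labels.append("intercept")

    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = vt[rank:]
        offending = sorted(
            {labels[j] for row in bad for j in np.argsort(-np.abs(row))[:2]}
        )
        raise ValueError(f"design matrix rank deficient; offending columns: "
                         f"{', '.join(offending)}")
    return X, labels


def estimate_beta_series(
    roi: RoiTimeSeries,
    design: ExperimentDesign,
    global_scaling: bool = True,
    highpass_cutoff_s: float | None = 128.0,
    include_us_regressors: bool = True,
    hrf_params: HrfParams | None = None,
    ridge: float = 0.0,
    condition_number_warn: float = 1e6,
) -> BetaSeries:
    """Fit the per-trial GLM and return the trial coefficients only.

    Ordinary least squares per voxel on the (optionally scaled and high-pass
    filtered) data; the cosine basis used for filtering is also included as
    confound columns.  ``ridge`` adds an L2 penalty on all non-intercept
    columns (off by default).
    """
    data = roi.data
    if global_scaling:
        data = global_scale(data, reference=roi.global_signal)
    if highpass_cutoff_s is not None:
        data = high_pass(data, roi.tr_s, highpass_cutoff_s)
    X, labels = build_design_matrix(
        design, roi.tr_s, roi.n_scans, nuisance=roi.nuisance,
        include_us_regressors=include_us_regressors, hrf_params=hrf_params,
        dct_cutoff_s=highpass_cutoff_s,
    )
    cond = np.linalg.cond(X)
    if cond > condition_number_warn:
        warnings.warn(f"design matrix condition number {cond:.3g} exceeds "
                      f"{condition_number_warn:.3g}", stacklevel=2)
    if ridge > 0:
        penalty = ridge * np.eye(X.shape[1])
        penalty[-1, -1] = 0.0  # never shrink the intercept
        coef = np.linalg.solve(X.T @ X + penalty, X.T @ data.T)
    else:
        coef, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    resid = data.T - X @ coef
    dof = max(roi.n_scans - X.shape[1], 1)
    trial_rows = [i for i, lab in enumerate(labels) if lab.startswith("trial")]
    return BetaSeries(
        betas=coef[trial_rows],  # (n_trials, n_voxels)
        onsets=design.onsets(),
        conditions=design.conditions,
        subject=roi.subject,
        roi=roi.roi,
        residual_variance=(resid ** 2).sum(axis=0) / dof,
    )
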