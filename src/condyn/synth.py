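"""Forward models with known planted parameters.

These generators emulate the study conditions the analysis modules are built
for — a 120-trial differential-conditioning block whose CS+/CS− amplitude
difference declines after a change point, multivoxel patterns whose
CS+/CS− separation decays over trials, and a CS-locked heart-rate
deceleration — so every downstream stage can be tested against ground truth
without any recorded data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .betaseries import HrfParams, RoiTimeSeries, event_regressors
from .design import CS_MINUS, ExperimentDesign
from .heartrate import RRSeries

__all__ = [
    "GroundTruth",
    "acquisition_truth",
    "habituation_truth",
    "simulate_bold_roi",
    "simulate_rr",
]


@dataclass
class GroundTruth:
    """Planted parameters for one subject's ROI and heart-rate series.

    Amplitude arrays are indexed by trial position in the design (a trial uses
    the array matching its condition); ``separation`` (in [0, 1]) mixes the
    shared voxel pattern with the condition-specific one per trial; the HR
    bump is a negative Gaussian added to the instantaneous rate after each CS
    onset.
    """

    amp_cs_plus: np.ndarray
    amp_cs_minus: np.ndarray
    us_amplitude: float
    change_point: int  # 1-based trial index where the differential starts to decline
    separation: np.ndarray
    pattern_shared: np.ndarray = field(repr=False)
    pattern_cs_plus: np.ndarray = field(repr=False)
    pattern_cs_minus: np.ndarray = field(repr=False)
    pattern_us: np.ndarray = field(repr=False)
    noise_sd: float = 0.5
    drift_coefs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    baseline: float = 100.0
    hr_amp_cs_plus_bpm: float = 5.0
    hr_amp_cs_minus_bpm: float = 1.0
    hr_latency_s: float = 2.5
    hr_width_s: float = 1.5
    hr_noise_sd_bpm: float = 2.0
    # per-trial multiplier (in [0, 1]) of the CS+ excess deceleration, so the
    # conditioned HR difference can decay over trials like the BOLD contrast
    hr_diff_shape: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if np.any(self.separation < 0) or np.any(self.separation > 1):
            raise ValueError("separation coefficients must lie in [0, 1]")

    def amplitude(self, trial_index: int, condition: str) -> float:
        if condition == CS_MINUS:
            return float(self.amp_cs_minus[trial_index])
        return float(self.amp_cs_plus[trial_index])

    def hr_amplitude(self, trial_index: int, condition: str) -> float:
        if condition == CS_MINUS:
            return self.hr_amp_cs_minus_bpm
        excess = self.hr_amp_cs_plus_bpm - self.hr_amp_cs_minus_bpm
        shape = (1.0 if self.hr_diff_shape is None
                 else float(self.hr_diff_shape[trial_index]))
        return self.hr_amp_cs_minus_bpm + excess * shape

    def pattern(self, trial_index: int, condition: str) -> np.ndarray:
        c = self.separation[trial_index]
        specific = (self.pattern_cs_minus if condition == CS_MINUS
                    else self.pattern_cs_plus)
        return (1 - c) * self.pattern_shared + c * specific


def _unit_mean_pattern(n_voxels: int, rng: np.random.Generator,
                       spread: float = 0.8) -> np.ndarray:
    p = 1.0 + spread * rng.uniform(-1, 1, size=n_voxels)
    return p / p.mean()


def _make_patterns(n_voxels: int, rng: np.random.Generator,
                   orthogonal: bool = False):
    shared = _unit_mean_pattern(n_voxels, rng)
    p_plus = _unit_mean_pattern(n_voxels, rng)
    p_minus = _unit_mean_pattern(n_voxels, rng)
    if orthogonal:
        # orthogonalise the centred condition patterns so their Pearson r is 0
        a = p_plus - p_plus.mean()
        b = p_minus - p_minus.mean()
        b = b - (a @ b) / (a @ a) * a
        p_minus = b - b.mean() + 1.0
        p_minus /= p_minus.mean()
    p_us = _unit_mean_pattern(n_voxels, rng)
    return shared, p_plus, p_minus, p_us


def acquisition_truth(
    n_trials: int = 120,
    n_voxels: int = 24,
    change_point: int = 60,
    base_amplitude: float = 0.5,
    diff_amplitude: float = 1.0,
    noise_sd: float = 0.5,
    us_amplitude: float = 2.0,
    separation_start: float = 1.0,
    separation_end: float = 0.0,
    drift_scale: float = 0.0,
    hr_amp_cs_plus_bpm: float = 5.0,
    hr_amp_cs_minus_bpm: float = 1.0,
    orthogonal_patterns: bool = True,
    seed: int = 0,
) -> GroundTruth:
    """Acquisition-style truth: the CS+ exceeds the CS− by ``diff_amplitude``
    until the planted change point, then the difference declines linearly to
    zero by the last trial; pattern separation decays linearly across the
    block; the CS+ evokes a stronger heart-rate deceleration than the CS−."""
    rng = np.random.default_rng(seed)
    amp_minus = np.full(n_trials, base_amplitude)
    diff = np.full(n_trials, diff_amplitude, dtype=float)
    if change_point < n_trials:
        tail = np.arange(n_trials - change_point + 1)
        decline = diff_amplitude * (1 - tail / tail[-1]) if len(tail) > 1 else [0.0]
        diff[change_point - 1:] = decline
    sep = np.linspace(separation_start, separation_end, n_trials)
    shared, p_plus, p_minus, p_us = _make_patterns(n_voxels, rng,
                                                  orthogonal_patterns)
    n_drift = 3 if drift_scale else 0
    return GroundTruth(
        amp_cs_plus=amp_minus + diff,
        amp_cs_minus=amp_minus,
        us_amplitude=us_amplitude,
        change_point=change_point,
        separation=sep,
        pattern_shared=shared,
        pattern_cs_plus=p_plus,
        pattern_cs_minus=p_minus,
        pattern_us=p_us,
        noise_sd=noise_sd,
        drift_coefs=drift_scale * rng.normal(size=n_drift),
        hr_amp_cs_plus_bpm=hr_amp_cs_plus_bpm,
        hr_amp_cs_minus_bpm=hr_amp_cs_minus_bpm,
        hr_diff_shape=(diff / diff_amplitude if diff_amplitude else None),
        seed=seed,
    )


def habituation_truth(
    n_trials: int = 120,
    n_voxels: int = 24,
    amplitude: float = 0.5,
    noise_sd: float = 0.5,
    separation: float = 0.2,
    hr_amp_bpm: float = 2.0,
    seed: int = 0,
) -> GroundTruth:
    """Habituation-style truth: no condition difference in amplitude, pattern,
    or heart rate — the null the habituation block realises."""
    truth = acquisition_truth(
        n_trials=n_trials, n_voxels=n_voxels, change_point=n_trials,
        base_amplitude=amplitude, diff_amplitude=0.0, noise_sd=noise_sd,
        us_amplitude=0.0, separation_start=separation,
        separation_end=separation, hr_amp_cs_plus_bpm=hr_amp_bpm,
        hr_amp_cs_minus_bpm=hr_amp_bpm, seed=seed,
    )
    return truth


def simulate_bold_roi(
    design: ExperimentDesign,
    truth: GroundTruth,
    n_voxels: int | None = None,
    tr_s: float = 1.98,
    n_scans: int | None = None,
    hrf_params: HrfParams | None = None,
    rng: np.random.Generator | None = None,
    roi: str = "roi",
    subject: str = "sub-01",
) -> RoiTimeSeries:
    """Voxel x time BOLD matrix implied by the design and ground truth.

    Each trial contributes amplitude x pattern x HRF-convolved boxcar; paired
    trials additionally contribute a US response; a low-order Legendre drift
    and white noise are added on top of a constant baseline.  The event
    regressors are the same ones the GLM uses, so with zero noise and drift
    the β-series stage recovers the planted amplitudes exactly.
    """
    n_voxels = truth.pattern_shared.size if n_voxels is None else n_voxels
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels (pattern analyses undefined)")
    if n_voxels != truth.pattern_shared.size:
        raise ValueError("n_voxels does not match the truth's pattern vectors")
    if n_scans is None:
        n_scans = int(np.ceil((design.total_duration_s + 20.0) / tr_s))
    if n_scans * tr_s < design.total_duration_s + 20.0:
        raise ValueError("scan too short: need total_duration_s + 20 s of data")
    if rng is None:
        rng = np.random.default_rng(truth.seed)

    onsets = design.onsets()
    durations = np.array([t.duration_s for t in design.trials])
    X = event_regressors(onsets, durations, tr_s, n_scans, hrf_params)
    weighted = np.stack([
        truth.amplitude(i, t.condition) * truth.pattern(i, t.condition)
        for i, t in enumerate(design.trials)
    ])  # trial x voxel
    data = (X @ weighted).T  # voxel x scan

    us = [(i, t.us_onset_s) for i, t in enumerate(design.trials)
          if t.us_onset_s is not None]
    if us and truth.us_amplitude:
        us_onsets = np.array([o for _, o in us])
        us_durs = np.array([
            design.trials[i].duration_s - (o - design.trials[i].onset_s)
            for i, o in us
        ])
        X_us = event_regressors(us_onsets, us_durs, tr_s, n_scans, hrf_params)
        data += np.outer(truth.us_amplitude * truth.pattern_us,
                         X_us.sum(axis=1))

    # whole-brain reference for global scaling: baseline plus averaged-out
    # noise from a large virtual brain, free of the ROI's evoked signal
    global_signal = truth.baseline + rng.normal(
        scale=truth.noise_sd / np.sqrt(2000.0), size=n_scans)

    data += truth.baseline
    if truth.drift_coefs.size:
        t = np.linspace(-1, 1, n_scans)
        basis = np.polynomial.legendre.legvander(t, truth.drift_coefs.size)[:, 1:]
        per_voxel = rng.normal(size=(n_voxels, truth.drift_coefs.size))
        data += (per_voxel * truth.drift_coefs) @ basis.T
    if truth.noise_sd:
        data += rng.normal(scale=truth.noise_sd, size=data.shape)
    return RoiTimeSeries(data=data, tr_s=tr_s, roi=roi, subject=subject,
                         global_signal=global_signal)


def simulate_rr(
    design: ExperimentDesign,
    truth: GroundTruth,
    baseline_bpm: float = 70.0,
    duration_s: float | None = None,
    seed: int | None = None,
    dt_s: float = 0.005,
    noise_step_s: float = 0.25,
) -> RRSeries:
    """RR-interval series from an instantaneous-rate model.

    The rate is the baseline plus one negative Gaussian bump (condition's
    amplitude, shared latency/width) after every CS onset, plus white rate
    noise held constant over ``noise_step_s`` spans.  Beats are placed where
    the integrated rate accumulates one beat, so a constant 60-bpm rate gives
    RR intervals of exactly 1 s.
    """
    if baseline_bpm <= 0:
        raise ValueError("baseline_bpm must be positive")
    amp_max = max(truth.hr_amp_cs_plus_bpm, truth.hr_amp_cs_minus_bpm)
    if amp_max >= baseline_bpm:
        raise ValueError("deceleration amplitude must be below the baseline rate")
    if duration_s is None:
        duration_s = design.total_duration_s + 10.0
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    t = np.arange(0.0, duration_s + dt_s, dt_s)
    rate = np.full_like(t, baseline_bpm)
    for i, trial in enumerate(design.trials):
        amp = truth.hr_amplitude(i, trial.condition)
        if amp == 0:
            continue
        centre = trial.onset_s + truth.hr_latency_s
        # the bump is negligible beyond 6 widths; evaluate it locally
        lo = max(0, int((centre - 6 * truth.hr_width_s) / dt_s))
        hi = min(len(t), int((centre + 6 * truth.hr_width_s) / dt_s) + 1)
        rate[lo:hi] -= amp * np.exp(
            -0.5 * ((t[lo:hi] - centre) / truth.hr_width_s) ** 2)
    if truth.hr_noise_sd_bpm:
        n_steps = int(np.ceil(duration_s / noise_step_s)) + 1
        steps = rng.normal(scale=truth.hr_noise_sd_bpm, size=n_steps)
        rate = rate + steps[np.minimum((t / noise_step_s).astype(int),
                                       n_steps - 1)]
        rate = np.maximum(rate, 1.0)  # physiological floor

    beats_cum = np.concatenate(([0.0], np.cumsum(
        (rate[1:] + rate[:-1]) / 2 * dt_s / 60.0)))
    n_beats = int(np.floor(beats_cum[-1]))
    beat_times = np.interp(np.arange(n_beats + 1), beats_cum, t)
    return RRSeries(beat_times=beat_times)
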