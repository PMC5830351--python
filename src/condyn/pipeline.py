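"""End-to-end orchestration: simulate a cohort, estimate β-series, run the
univariate dynamics, change-point, RSA and heart-rate analyses, and collect
every group-level statistic into one report.

The synthetic cohort couples subjects through a latent factor: a subject with
a later change point also shows a stronger heart-rate deceleration and slower
representational convergence, which is what gives the concordance statistics
(ANOVA/PCA across ROIs, PC1–HR and PC1–adaptation-slope correlations)
something real to recover.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .betaseries import RoiTimeSeries, estimate_beta_series
from .changepoint import detect_change, roi_concordance
from .design import ExperimentDesign, generate_design, read_events_tsv
from .dynamics import (adaptation_slope, differential_curve, early_late_test,
                       smooth_curves, split_early_late, to_trial_series)
from .heartrate import hr_dynamics, read_rr, trial_hr_curves
from .rsa import (dissimilarity_slope, endpoint_test, group_curve,
                  slope_concordance, window_dissimilarity)
from .synth import acquisition_truth, habituation_truth, simulate_bold_roi, simulate_rr

__all__ = ["RoiSpec", "RunConfig", "run_full", "validate_inputs"]


@dataclass
class RoiSpec:
    n_voxels: int = 24
    rsa: bool = True  # include in the dissimilarity-slope concordance
    univariate: bool = True  # include in the change-point ANOVA/PCA


@dataclass
class RunConfig:
    """All knobs of one full run; serialised verbatim into the report."""

    seed: int = 7
    n_subjects: int = 18
    block: str = "acquisition"  # or "habituation"
    # paradigm
    n_trials: int = 120
    pairing_rate: float = 0.25
    n_initial_paired: int = 4
    iti_mean_s: float = 4.6
    iti_sd_s: float = 1.5
    cs_duration_s: float = 1.0
    us_lag_s: float = 0.5
    tr_s: float = 1.98
    # planted effects
    change_point_trial: int = 60
    diff_amplitude: float = 1.0
    base_amplitude: float = 0.5
    noise_sd: float = 0.5
    hr_baseline_bpm: float = 70.0
    hr_amp_cs_plus_bpm: float = 5.0
    hr_amp_cs_minus_bpm: float = 1.0
    hr_noise_sd_bpm: float = 2.0
    # analysis options
    rois: dict = field(default_factory=lambda: {
        "amygdala": {"n_voxels": 12, "rsa": False, "univariate": True},
        "insula": {"n_voxels": 24, "rsa": True, "univariate": True},
        "dacc": {"n_voxels": 24, "rsa": True, "univariate": True},
    })
    global_scaling: bool = True
    highpass_cutoff_s: float = 128.0
    include_us_regressors: bool = True
    exclude_post_us: bool = False
    t_split_s: float = 336.0
    bandwidth_trials: float = 5.0
    n_permutations: int = 1000
    cp_threshold: float = 95.0
    rsa_window: int = 50
    rsa_step: int = 2
    endpoint_k: int = 10
    decel_window_s: tuple = (1.0, 4.0)
    stages: tuple = ("early_late", "changepoint", "rsa", "hr", "concordance")

    def roi_specs(self) -> dict[str, RoiSpec]:
        return {name: RoiSpec(**spec) for name, spec in self.rois.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.decel_window_s = tuple(cfg.decel_window_s)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["decel_window_s"] = list(self.decel_window_s)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _subject_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def simulate_subject(config: RunConfig, subject_seed: int, subject: str):
    """One subject's designs, ground truths, ROI time series and RR series.

    A standard-normal latent factor shifts the subject's change point
    (±18 trials per sd, jittered ±5 across ROIs), heart-rate deceleration
    (±1.5 bpm per sd) and pattern-convergence endpoint (±0.15 per sd), so
    the cross-ROI and cross-modal couplings reported at the group level are
    planted at the subject level.
    """
    rng = np.random.default_rng(subject_seed)
    acquisition = config.block == "acquisition"
    design = generate_design(
        n_trials=config.n_trials,
        pairing_rate=config.pairing_rate if acquisition else 0.0,
        n_initial_paired=config.n_initial_paired if acquisition else 0,
        iti_mean_s=config.iti_mean_s, iti_sd_s=config.iti_sd_s,
        cs_duration_s=config.cs_duration_s, us_lag_s=config.us_lag_s,
        block_label=config.block, rng=rng,
    )
    latent = rng.normal()
    truths, rois = {}, {}
    for name, spec in config.roi_specs().items():
        t_seed = int(rng.integers(2 ** 31))
        if acquisition:
            cp = int(np.clip(round(config.change_point_trial + 18 * latent
                                   + 5 * rng.normal()), 25, config.n_trials - 20))
            sep_end = (float(np.clip(0.45 + 0.3 * latent, 0.0, 0.95))
                       if spec.rsa else 0.55)
            sep_start = 1.0 if spec.rsa else 0.6
            truth = acquisition_truth(
                n_trials=config.n_trials, n_voxels=spec.n_voxels,
                change_point=cp, base_amplitude=config.base_amplitude,
                diff_amplitude=config.diff_amplitude, noise_sd=config.noise_sd,
                separation_start=sep_start, separation_end=sep_end,
                hr_amp_cs_plus_bpm=float(np.clip(
                    config.hr_amp_cs_plus_bpm + 1.5 * latent, 0.5,
                    config.hr_baseline_bpm - 1)),
                hr_amp_cs_minus_bpm=config.hr_amp_cs_minus_bpm,
                seed=t_seed,
            )
        else:
            truth = habituation_truth(
                n_trials=config.n_trials, n_voxels=spec.n_voxels,
                amplitude=config.base_amplitude, noise_sd=config.noise_sd,
                hr_amp_bpm=2.0, seed=t_seed,
            )
        truth.hr_noise_sd_bpm = config.hr_noise_sd_bpm
        truths[name] = truth
        rois[name] = simulate_bold_roi(
            design, truth, tr_s=config.tr_s, rng=rng, roi=name, subject=subject,
        )
    rr = simulate_rr(design, truths[next(iter(truths))],
                     baseline_bpm=config.hr_baseline_bpm,
                     seed=int(rng.integers(2 ** 31)))
    return design, truths, rois, rr


def _analyse_subject(config: RunConfig, subject: str, design: ExperimentDesign,
                     rois: dict[str, RoiTimeSeries], rr, cp_seed: int) -> dict:
    out: dict = {"subject": subject, "betas": {}, "series": {},
                 "early": {}, "late": {}, "contrast": {}, "slope": {},
                 "cusum": {}, "rsa": {}}
    for name, roi in rois.items():
        beta = estimate_beta_series(
            roi, design,
            global_scaling=config.global_scaling,
            highpass_cutoff_s=config.highpass_cutoff_s,
            include_us_regressors=config.include_us_regressors,
        )
        out["betas"][name] = beta
        series = to_trial_series(beta, config.exclude_post_us)
        out["series"][name] = series
        split = split_early_late(series, config.t_split_s)
        out["early"][name] = split.differential["early"]
        out["late"][name] = split.differential["late"]
        diff = differential_curve(smooth_curves(series, config.bandwidth_trials))
        out["contrast"][name] = diff.trial_values
        out["slope"][name] = adaptation_slope(diff)
        if "changepoint" in config.stages:
            out["cusum"][name] = detect_change(
                diff.trial_values, config.n_permutations,
                config.cp_threshold, seed=cp_seed)
        if "rsa" in config.stages:
            out["rsa"][name] = window_dissimilarity(
                beta, config.rsa_window, config.rsa_step,
                exclude_post_us=config.exclude_post_us)
    if "hr" in config.stages:
        matrix = trial_hr_curves(rr, design, subject=subject)
        out["hr"] = hr_dynamics(matrix, config.t_split_s,
                                config.bandwidth_trials, config.decel_window_s)
    return out


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage for every subject and assemble the group report.

    The report mirrors the statistics a conditioning-dynamics study reports:
    the early/late table with FDR-corrected paired t-tests, group change
    points with permutation confidence, the cross-ROI change-point ANOVA/PCA
    and its correlation with the heart-rate effect, group dissimilarity
    curves with endpoint tests, and the dissimilarity-slope concordance with
    its correlation against the univariate adaptation slope.
    """
    roi_specs = config.roi_specs()
    roi_names = list(roi_specs)
    seeds = _subject_seeds(config.seed, config.n_subjects + 1)
    group_seed, subject_seeds = seeds[0], seeds[1:]

    subjects = []
    for i, s_seed in enumerate(subject_seeds):
        sid = f"sub-{i + 1:02d}"
        design, truths, rois, rr = simulate_subject(config, s_seed, sid)
        try:
            subjects.append(_analyse_subject(config, sid, design, rois, rr,
                                             cp_seed=s_seed))
        except Exception as exc:  # halt with the failing stage named
            raise RuntimeError(f"analysis failed for {sid}: {exc}") from exc

    report: dict = {
        "version": _version,
        "config": {**asdict(config),
                   "decel_window_s": list(config.decel_window_s),
                   "stages": list(config.stages)},
        "subjects": [s["subject"] for s in subjects],
    }

    # early/late table is cheap and anchors every run, so always reported
    names = roi_names + (["hr"] if "hr" in config.stages else [])
    early = np.array([
            [s["early"][r] for r in roi_names]
            + ([s["hr"]["split"].differential["early"]]
               if "hr" in config.stages else [])
            for s in subjects])
    late = np.array([
        [s["late"][r] for r in roi_names]
        + ([s["hr"]["split"].differential["late"]]
           if "hr" in config.stages else [])
        for s in subjects])
    table = early_late_test(early, late, names)
    report["early_late"] = table.to_dict(orient="records")

    if "changepoint" in config.stages:
        uni = [r for r in roi_names if roi_specs[r].univariate]
        group_cp = {}
        for r in uni:
            contrasts = np.stack([s["contrast"][r] for s in subjects])
            group_cp[r] = detect_change(
                contrasts.mean(axis=0), config.n_permutations,
                config.cp_threshold, seed=group_seed).to_dict()
        report["group_change_points"] = group_cp
        cp_matrix = np.array([[s["cusum"][r].change_point for r in uni]
                              for s in subjects], dtype=float)
        report["subject_change_points"] = {
            "roi_names": uni, "matrix": cp_matrix.tolist()}
        if "concordance" in config.stages:
            covariate = None
            if "hr" in config.stages:
                covariate = np.array([s["hr"]["mean_difference_bpm"]
                                      for s in subjects])
            try:
                report["changepoint_concordance"] = roi_concordance(
                    cp_matrix, covariate, uni).to_dict()
            except ValueError as exc:  # degenerate at tiny cohorts
                report["changepoint_concordance"] = {"error": str(exc)}

    if "rsa" in config.stages:
        rsa_rois = [r for r in roi_names if roi_specs[r].rsa]
        rsa_section: dict = {"curves": {}, "endpoint": {}}
        for r in roi_names:
            curves = [s["rsa"][r] for s in subjects]
            g = group_curve(curves)
            rsa_section["curves"][r] = g.to_frame().to_dict(orient="list")
            t, p, first, last = endpoint_test(curves, config.endpoint_k)
            rsa_section["endpoint"][r] = {
                "t": t, "p": p,
                "first_mean": float(first.mean()),
                "last_mean": float(last.mean()),
            }
        if len(rsa_rois) >= 2 and "concordance" in config.stages:
            slopes = np.array([[dissimilarity_slope(s["rsa"][r])
                                for r in rsa_rois] for s in subjects])
            external = None
            if "amygdala" in roi_names:
                external = np.array([s["slope"]["amygdala"] for s in subjects])
            try:
                rsa_section["slope_concordance"] = slope_concordance(
                    slopes, external, rsa_rois).to_dict()
            except ValueError as exc:
                rsa_section["slope_concordance"] = {"error": str(exc)}
        report["rsa"] = rsa_section

    if "hr" in config.stages:
        report["hr"] = {
            "mean_difference_bpm": [s["hr"]["mean_difference_bpm"]
                                    for s in subjects],
        }

    report["adaptation_slopes"] = {
        r: [s["slope"][r] for s in subjects] for r in roi_names}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2))
        if "changepoint" in config.stages:
            pd.DataFrame(
                report["subject_change_points"]["matrix"],
                columns=report["subject_change_points"]["roi_names"],
            ).to_csv(out_dir / "change_points.csv", index=False)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def validate_inputs(paths: dict) -> list[dict]:
    """Schema and consistency diagnostics for file-based inputs.

    ``paths`` may contain ``events`` (events.tsv), ``roi`` (matrix TSV with
    JSON sidecar) and ``rr`` (RR intervals, one per line).  Returns a list of
    machine-readable issues; an empty list means all checks passed.
    """
    issues: list[dict] = []
    design = None
    if "events" in paths:
        try:
            df = pd.read_csv(paths["events"], sep="\t", na_values=["n/a"])
            missing = {"onset", "duration", "trial_type"} - set(df.columns)
            if missing:
                issues.append({"file": str(paths["events"]),
                               "issue": f"missing columns: {sorted(missing)}"})
            elif np.any(np.diff(df["onset"].to_numpy()) <= 0):
                issues.append({"file": str(paths["events"]),
                               "issue": "onsets not strictly increasing"})
            else:
                design = read_events_tsv(paths["events"])
        except Exception as exc:
            issues.append({"file": str(paths["events"]), "issue": str(exc)})
    if "roi" in paths:
        try:
            roi = RoiTimeSeries.from_tsv(paths["roi"])
            if design is not None:
                span = roi.n_scans * roi.tr_s
                last = design.trials[-1].onset_s + design.trials[-1].duration_s
                if span < last:
                    issues.append({"file": str(paths["roi"]),
                                   "issue": f"scan span {span:.1f}s shorter "
                                            f"than the design ({last:.1f}s)"})
        except Exception as exc:
            issues.append({"file": str(paths["roi"]), "issue": str(exc)})
    if "rr" in paths:
        try:
            rr = read_rr(paths["rr"])
            if design is not None:
                end = design.trials[-1].onset_s + 5.0
                if rr.beat_times[-1] < end or rr.beat_times[0] > \
                        design.trials[0].onset_s - 1.0:
                    issues.append({"file": str(paths["rr"]),
                                   "issue": "RR series does not cover every "
                                            "trial window"})
        except Exception as exc:
            issues.append({"file": str(paths["rr"]), "issue": str(exc)})
    return issues
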