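"""Experiment designs for differential conditioning blocks.

A block interleaves two conditioned stimuli — a CS+ that is partially
reinforced by an aversive unconditioned stimulus (US) and a CS− that never is
— in pseudo-random order with jittered intertrial intervals.  The generator
reproduces the paradigm used throughout the package: 120 trials per block,
the first four CS+ trials always paired with the US to establish the
contingency, an exact 25% pairing rate among the remaining CS+ trials, a 1-s
CS, a US starting 0.5 s after CS+ onset, and intertrial intervals drawn from
a truncated normal (mean 4.6 s, sd 1.5 s, floor 1.5 s).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CS_PLUS_UNPAIRED = "CSplus_unpaired"
CS_PLUS_PAIRED = "CSplus_paired"
CS_MINUS = "CSminus"
CONDITIONS = (CS_PLUS_UNPAIRED, CS_PLUS_PAIRED, CS_MINUS)

__all__ = [
    "Trial",
    "ExperimentDesign",
    "generate_design",
    "read_events_tsv",
    "CS_PLUS_UNPAIRED",
    "CS_PLUS_PAIRED",
    "CS_MINUS",
]


@dataclass(frozen=True)
class Trial:
    onset_s: float
    duration_s: float
    condition: str
    us_onset_s: float | None = None


@dataclass
class ExperimentDesign:
    """One block's trial timeline with condition labels and US pairing."""

    block_label: str
    trials: list[Trial]
    iti_mean_s: float
    iti_sd_s: float
    total_duration_s: float
    itis_s: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        onsets = np.array([t.onset_s for t in self.trials])
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        lags = []
        for t in self.trials:
            if t.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {t.condition!r}")
            if (t.us_onset_s is not None) != (t.condition == CS_PLUS_PAIRED):
                raise ValueError("us_onset_s present iff condition is CSplus_paired")
            if t.us_onset_s is not None:
                lags.append(t.us_onset_s - t.onset_s)
        if lags and not np.allclose(lags, lags[0]):
            raise ValueError("US lag must be identical across paired trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def onsets(self, conditions: tuple[str, ...] | None = None) -> np.ndarray:
        sel = self.trials if conditions is None else [
            t for t in self.trials if t.condition in conditions
        ]
        return np.array([t.onset_s for t in sel])

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    def count(self, condition: str) -> int:
        return sum(t.condition == condition for t in self.trials)

    def to_events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [t.onset_s for t in self.trials],
                "duration": [t.duration_s for t in self.trials],
                "trial_type": [t.condition for t in self.trials],
                "us_onset": [
                    t.us_onset_s if t.us_onset_s is not None else np.nan
                    for t in self.trials
                ],
            }
        )

    def to_events_tsv(self, path: str | Path) -> None:
        """Write a BIDS-style events table (3-decimal seconds, n/a for no US)."""
        df = self.to_events_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.3f", na_rep="n/a")


def read_events_tsv(
    path: str | Path,
    block_label: str = "acquisition",
    iti_mean_s: float = float("nan"),
    iti_sd_s: float = float("nan"),
) -> ExperimentDesign:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    trials = [
        Trial(
            onset_s=float(r.onset),
            duration_s=float(r.duration),
            condition=str(r.trial_type),
            us_onset_s=None if pd.isna(r.us_onset) else float(r.us_onset),
        )
        for r in df.itertuples()
    ]
    total = trials[-1].onset_s + trials[-1].duration_s + 10.0
    return ExperimentDesign(block_label, trials, iti_mean_s, iti_sd_s, total)


def _pseudo_random_sequence(
    n_plus: int, n_minus: int, max_run: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean sequence (True = CS+) with exact counts and runs <= max_run."""
    for _ in range(1000):
        remaining = np.array([n_plus, n_minus])
        seq: list[bool] = []
        run_cond, run_len = None, 0
        ok = True
        for _pos in range(n_plus + n_minus):
            allowed = [c for c in (0, 1) if remaining[c] > 0]
            if run_len >= max_run and run_cond in allowed and len(allowed) > 1:
                allowed.remove(run_cond)
            elif run_len >= max_run and allowed == [run_cond]:
                ok = False
                break
            probs = remaining[allowed] / remaining[allowed].sum()
            c = int(rng.choice(allowed, p=probs))
            seq.append(c == 0)
            remaining[c] -= 1
            run_len = run_len + 1 if c == run_cond else 1
            run_cond = c
        if ok:
            return np.array(seq)
    raise RuntimeError("could not build a pseudo-random order")  # pragma: no cover


def _truncated_normal(
    n: int, mean: float, sd: float, floor: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(n, max(mean, floor))
    out = np.empty(n)
    for i in range(n):
        x = rng.normal(mean, sd)
        while x < floor:
            x = rng.normal(mean, sd)
        out[i] = x
    return out


def generate_design(
    n_trials: int = 120,
    pairing_rate: float = 0.25,
    n_initial_paired: int = 4,
    iti_mean_s: float = 4.6,
    iti_sd_s: float = 1.5,
    cs_duration_s: float = 1.0,
    us_lag_s: float = 0.5,
    us_duration_s: float = 1.0,
    iti_floor_s: float = 1.5,
    start_s: float = 10.0,
    max_run: int = 4,
    block_label: str = "acquisition",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExperimentDesign:
    """Generate one conditioning block.

    CS+ and CS− occur in equal numbers in a pseudo-random order (no more than
    ``max_run`` consecutive trials of one condition).  The first
    ``n_initial_paired`` CS+ trials are paired with the US; of the remaining
    CS+ trials exactly ``round(pairing_rate * count)`` are paired, chosen at
    random, so the nominal pairing rate is reproduced exactly rather than in
    expectation.  Paired trials carry ``us_onset_s = onset_s + us_lag_s`` and
    last until the US ends (``us_lag_s + us_duration_s``).

    Intertrial intervals are drawn from a normal truncated at ``iti_floor_s``;
    one ITI follows every trial (the last one pads the end of the block).
    """
    if n_trials % 2 != 0 or n_trials < 2:
        raise ValueError("n_trials must be even and >= 2")
    if not 0 <= pairing_rate <= 1:
        raise ValueError("pairing_rate must be in [0, 1]")
    if iti_sd_s < 0:
        raise ValueError("iti_sd_s must be >= 0")
    if iti_floor_s < 0:
        raise ValueError("ITI floor must be non-negative")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)

    n_each = n_trials // 2
    is_plus = _pseudo_random_sequence(n_each, n_each, max_run, rng)

    plus_positions = np.flatnonzero(is_plus)
    n_initial_paired = min(n_initial_paired, n_each)
    n_rest = n_each - n_initial_paired
    n_paired_rest = int(np.floor(pairing_rate * n_rest + 0.5))
    if pairing_rate > 0 and n_rest > 0 and n_paired_rest == 0:
        warnings.warn(
            "pairing_rate rounds to zero paired trials beyond the initial set",
            stacklevel=2,
        )
    paired = set(plus_positions[:n_initial_paired])
    if n_paired_rest:
        rest = plus_positions[n_initial_paired:]
        paired |= set(rng.choice(rest, size=n_paired_rest, replace=False))

    itis = _truncated_normal(n_trials, iti_mean_s, iti_sd_s, iti_floor_s, rng)
    trials: list[Trial] = []
    onset = start_s
    for i in range(n_trials):
        if is_plus[i] and i in paired:
            dur = us_lag_s + us_duration_s
            trials.append(Trial(onset, dur, CS_PLUS_PAIRED, onset + us_lag_s))
        elif is_plus[i]:
            dur = cs_duration_s
            trials.append(Trial(onset, dur, CS_PLUS_UNPAIRED))
        else:
            dur = cs_duration_s
            trials.append(Trial(onset, dur, CS_MINUS))
        onset += dur + itis[i]
    return ExperimentDesign(
        block_label=block_label,
        trials=trials,
        iti_mean_s=iti_mean_s,
        iti_sd_s=iti_sd_s,
        total_duration_s=onset,
        itis_s=itis,
    )
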