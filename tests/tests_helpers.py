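"""Shared constructors for pattern-based β-series used across test modules."""
import numpy as np

from condyn.betaseries import BetaSeries
from condyn.design import CS_MINUS, CS_PLUS_UNPAIRED


def patterned_beta(n_trials=120, n_voxels=16, orthogonal=False,
                   identical=False, seed=99):
    """Alternating CS+/CS− β-series with fixed condition patterns."""
    rng = np.random.default_rng(seed)
    p_plus = rng.normal(size=n_voxels)
    if identical:
        p_minus = p_plus.copy()
    elif orthogonal:
        raw = rng.normal(size=n_voxels)
        a = p_plus - p_plus.mean()
        p_minus = raw - (a @ (raw - raw.mean())) / (a @ a) * a
    else:
        p_minus = rng.normal(size=n_voxels)
    conds = np.array([CS_PLUS_UNPAIRED, CS_MINUS] * (n_trials // 2))
    betas = np.where((conds == CS_PLUS_UNPAIRED)[:, None], p_plus, p_minus)
    onsets = 10.0 + 5.6 * np.arange(n_trials)
    return BetaSeries(betas=betas.astype(float), onsets=onsets,
                      conditions=conds)
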