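"""Block-design event structure: randomized interleaving of speech blocks.

A session presents each stimulation condition ``blocks_per_condition``
times in a randomized interleaved order. Blocks last ``block_duration_s``
and are separated by rests drawn uniformly from ``rest_range_s``. A small
number of behavioural control trials occur 2 s after randomly chosen
blocks; the rest period following a control trial is extended by 5 s.
The recording starts with a lead-in rest of ``rest_range_s[0]`` seconds
and ends after the final rest period.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CONTROL_REST_EXTENSION_S, CONTROL_TRIAL_DELAY_S, SimulationConfig
from .errors import ConfigurationError


@dataclass(frozen=True)
class DesignSpec:
    """Condition onsets/durations plus control-trial structure for one run."""

    #: Mapping condition label -> tuple of block onset times in seconds.
    onsets: dict
    block_duration_s: float
    control_onsets: tuple
    total_duration_s: float

    @property
    def conditions(self) -> tuple:
        return tuple(self.onsets)

    def all_onsets(self) -> np.ndarray:
        """Onsets of every stimulation block regardless of condition, sorted."""
        return np.sort(np.concatenate([np.asarray(v, float) for v in self.onsets.values()]))

    def n_samples(self, fs: float) -> int:
        return int(round(self.total_duration_s * fs))


def generate_design(config: SimulationConfig, rng_seed=None) -> DesignSpec:
    """Draw a randomized block design consistent with ``config``.

    The same seed always yields the identical design. Rest durations are
    uniform on ``rest_range_s``; each condition appears exactly
    ``blocks_per_condition`` times; rests following control trials are
    extended by 5 s.
    """
    lo, hi = config.rest_range_s
    if lo > hi:
        raise ConfigurationError(f"rest_range min {lo} exceeds max {hi}")
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)

    sequence = [c for c in config.conditions for _ in range(config.blocks_per_condition)]
    order = rng.permutation(len(sequence))
    sequence = [sequence[i] for i in order]

    n_blocks = len(sequence)
    n_control = min(config.control_trial_count, n_blocks)
    control_blocks = set(
        rng.choice(n_blocks, size=n_control, replace=False).tolist()
    ) if n_control else set()

    onsets = {c: [] for c in config.conditions}
    control_onsets = []
    t = float(lo)  # lead-in rest
    for i, cond in enumerate(sequence):
        onsets[cond].append(round(t, 6))
        t += config.block_duration_s
        rest = float(rng.uniform(lo, hi))
        if i in control_blocks:
            control_onsets.append(round(t + CONTROL_TRIAL_DELAY_S, 6))
            rest += CONTROL_REST_EXTENSION_S
        t += rest
    return DesignSpec(
        onsets={c: tuple(v) for c, v in onsets.items()},
        block_duration_s=float(config.block_duration_s),
        control_onsets=tuple(sorted(control_onsets)),
        total_duration_s=round(t, 6),
    )
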