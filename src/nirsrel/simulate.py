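"""Forward simulation of multi-subject, two-session fNIRS cohorts.

The observed signal at each channel is modelled as a mixture of a
functional component F(t) and a systemic component S(t):

    dHbO(t) = F(t) + S(t)
    dHbR(t) = k_f * F(t) + k_s * S(t),        k_f < 0 < k_s

F is the sum over conditions of the true amplitude times the HRF-convolved
boxcar; S collects cardiac, Mayer-wave, drift, a stimulus-locked slow
negative trend in superficial haemoglobin, and white physiological noise.
Concentrations are mapped to per-wavelength optical density through the
modified Beer-Lambert law, and motion artifacts (spikes / baseline steps,
identical at both wavelengths of a channel) can be injected on top.

Concentration units are arbitrary: without a partial-volume correction
only relative amplitudes are interpretable, so no absolute calibration is
attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig, MotionModel, extinction_matrix
from .design import DesignSpec, generate_design
from .errors import ConfigurationError
from .hrf import block_regressor, canonical_hrf


@dataclass(frozen=True)
class MotionEvent:
    channel: int  # 1-based
    time_s: float
    kind: str  # "spike" | "shift"
    amplitude: float


@dataclass
class GroundTruth:
    """Per-recording simulation truth carried alongside the observations."""

    #: True session amplitudes, shape (n_channels, n_conditions).
    amplitudes: np.ndarray
    #: Noise-free functional HbO component, shape (n_channels, n_samples).
    functional: np.ndarray
    #: Systemic HbO component (incl. physiological noise), same shape.
    systemic: np.ndarray
    k_f: float
    k_s: float
    #: Variance-ratio ICC of the amplitude model that generated the cohort.
    true_icc: float
    motion_log: list = field(default_factory=list)


@dataclass
class RawRecording:
    """One subject-session of simulated per-wavelength optical density."""

    subject: str
    session: int
    time: np.ndarray
    #: Optical density, shape (n_channels, n_wavelengths, n_samples).
    od: np.ndarray
    design: DesignSpec
    fs: float
    wavelengths: tuple
    dpf: float
    source_detector_separation_mm: float
    conditions: tuple
    ground_truth: GroundTruth

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]


def _stimulus_locked_trend(design: DesignSpec, n_samples: int, fs: float,
                           decline_lag_s: float, recovery_s: float) -> np.ndarray:
    """Piecewise-linear superficial trend: 0 at block onset, minimum -1 at
    ``decline_lag_s`` after block offset, linear recovery over ``recovery_s``."""
    t = np.arange(n_samples) / fs
    trend = np.zeros(n_samples)
    for onset in design.all_onsets():
        t0 = onset
        t1 = onset + design.block_duration_s + decline_lag_s
        t2 = t1 + recovery_s
        trend += np.interp(t, [t0, t1, t2], [0.0, -1.0, 0.0], left=0.0, right=0.0)
    return trend


def simulate_haemo(design: DesignSpec, config: SimulationConfig,
                   amplitudes, rng_seed=None):
    """Simulate true dHbO/dHbR for one recording.

    Parameters
    ----------
    amplitudes : array (n_channels, n_conditions)
        True response amplitude per channel and condition (column order
        matching ``config.conditions``).

    Returns
    -------
    (hbo, hbr, (functional, systemic)) : arrays (n_channels, n_samples)
        ``functional``/``systemic`` are the HbO-scale components; the HbR
        components follow exactly as ``k_f*functional`` and ``k_s*systemic``.
    """
    if not (config.k_f < 0 < config.k_s):
        raise ConfigurationError(
            f"component separation requires k_f < 0 < k_s, got k_f={config.k_f}, k_s={config.k_s}"
        )
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if not np.all(np.isfinite(amplitudes)):
        raise ConfigurationError("amplitudes must be finite")
    if amplitudes.shape[1] != len(config.conditions):
        raise ConfigurationError(
            f"amplitudes have {amplitudes.shape[1]} columns for {len(config.conditions)} conditions"
        )
    n = design.n_samples(config.fs)
    kernel = canonical_hrf(config.fs)
    regressors = np.stack([
        block_regressor(design.onsets[c], design.block_duration_s, n, config.fs, kernel)
        for c in config.conditions
    ])
    functional = amplitudes @ regressors  # (C, n)

    sy = config.systemic
    rng = np.random.default_rng(rng_seed)
    t = np.arange(n) / config.fs
    trend = sy.stim_locked_amplitude * _stimulus_locked_trend(
        design, n, config.fs, sy.stim_decline_lag_s, sy.stim_recovery_s
    )
    systemic = np.empty_like(functional)
    for ch in range(functional.shape[0]):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        s = (
            sy.cardiac_amplitude * np.sin(2 * np.pi * sy.cardiac_freq_hz * t + phases[0])
            + sy.mayer_amplitude * np.sin(2 * np.pi * sy.mayer_freq_hz * t + phases[1])
            + sy.drift_amplitude * np.sin(2 * np.pi * sy.drift_freq_hz * t + phases[2])
            + trend
        )
        if sy.noise_sd > 0:
            s = s + rng.normal(0.0, sy.noise_sd, size=n)
        systemic[ch] = s

    hbo = functional + systemic
    hbr = config.k_f * functional + config.k_s * systemic
    return hbo, hbr, (functional, systemic)


def forward_mbll(hbo: np.ndarray, hbr: np.ndarray, config: SimulationConfig,
                 extinction_table=None) -> np.ndarray:
    """Map concentration changes to per-wavelength optical density.

    dOD(lambda, t) = [eps_HbO(lambda)*dHbO + eps_HbR(lambda)*dHbR] * d * DPF,
    with the source-detector separation d expressed in cm to match the
    cm^-1 mM^-1 extinction units.
    """
    E = extinction_matrix(config.wavelengths, extinction_table)
    pathlength_cm = config.source_detector_separation_mm / 10.0 * config.dpf
    conc = np.stack([np.atleast_2d(hbo), np.atleast_2d(hbr)], axis=1)  # (C, 2, n)
    return pathlength_cm * np.einsum("wk,ckn->cwn", E, conc)


def inject_motion(od: np.ndarray, motion: MotionModel, fs: float, rng_seed=None):
    """Add spike and baseline-shift artifacts to an OD array.

    Each event hits one random channel at a random time and is applied
    identically to both wavelengths. Returns ``(corrupted_od, log)`` where
    the log records channel (1-based), time, kind, and signed amplitude.
    """
    od = np.array(od, dtype=float, copy=True)
    if motion.rate_per_minute < 0:
        raise ConfigurationError("artifact rate must be >= 0")
    log: list[MotionEvent] = []
    if motion.rate_per_minute == 0:
        return od, log
    n_channels, _, n = od.shape
    rng = np.random.default_rng(rng_seed)
    n_events = int(rng.poisson(motion.rate_per_minute * n / fs / 60.0))
    channel_sd = od.std(axis=(1, 2))
    idx = np.arange(n)
    for _ in range(n_events):
        ch = int(rng.integers(n_channels))
        i = int(rng.integers(n))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        scale = channel_sd[ch] if channel_sd[ch] > 0 else 1.0
        if rng.random() < 0.5:
            amp = sign * motion.spike_amplitude_sd * scale
            half_width = max(1.0, motion.spike_duration_s * fs / 2.0)
            od[ch, :, :] += amp * np.exp(-0.5 * ((idx - i) / half_width) ** 2)
            kind = "spike"
        else:
            amp = sign * motion.shift_amplitude_sd * scale
            od[ch, :, i:] += amp
            kind = "shift"
        log.append(MotionEvent(channel=ch + 1, time_s=i / fs, kind=kind, amplitude=amp))
    return od, log


def channel_amplitudes(config: SimulationConfig, session_amps: np.ndarray) -> np.ndarray:
    """Expand per-condition session amplitudes to the per-channel map.

    Channels listed in ``config.responsive_channels`` receive the session
    amplitude; all other channels are null responders.
    """
    amps = np.zeros((config.n_channels, len(config.conditions)))
    for ch in config.responsive_channels:
        amps[ch - 1] = session_amps
    return amps


def simulate_cohort(config: SimulationConfig) -> list:
    """Simulate ``n_subjects x n_sessions`` recordings.

    Subject-level amplitudes are drawn once per subject from the
    between-subject distribution; each session adds an independent
    between-session deviation, so the cohort's true amplitude ICC is the
    configured variance ratio (recorded in every recording's ground truth).
    Identical configs and seeds produce bit-identical cohorts.
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    n_cond = len(config.conditions)
    means = np.array([config.amplitude.condition_means[c] for c in config.conditions])
    subject_effects = master.normal(
        0.0, config.amplitude.between_subject_sd, size=(config.n_subjects, n_cond)
    )
    session_effects = master.normal(
        0.0, config.amplitude.between_session_sd,
        size=(config.n_subjects, config.n_sessions, n_cond),
    )
    stage_seeds = master.integers(
        0, 2 ** 31 - 1, size=(config.n_subjects, config.n_sessions, 3)
    )
    true_icc = config.amplitude.true_icc

    recordings = []
    for s in range(config.n_subjects):
        for k in range(config.n_sessions):
            design = generate_design(config, rng_seed=int(stage_seeds[s, k, 0]))
            session_amps = means + subject_effects[s] + session_effects[s, k]
            amps = channel_amplitudes(config, session_amps)
            hbo, hbr, (functional, systemic) = simulate_haemo(
                design, config, amps, rng_seed=int(stage_seeds[s, k, 1])
            )
            od = forward_mbll(hbo, hbr, config)
            od, motion_log = inject_motion(
                od, config.motion, config.fs, rng_seed=int(stage_seeds[s, k, 2])
            )
            n = design.n_samples(config.fs)
            recordings.append(
                RawRecording(
                    subject=f"sub-{s + 1:02d}",
                    session=k + 1,
                    time=np.arange(n) / config.fs,
                    od=od,
                    design=design,
                    fs=config.fs,
                    wavelengths=tuple(config.wavelengths),
                    dpf=config.dpf,
                    source_detector_separation_mm=config.source_detector_separation_mm,
                    conditions=tuple(config.conditions),
                    ground_truth=GroundTruth(
                        amplitudes=amps,
                        functional=functional,
                        systemic=systemic,
                        k_f=config.k_f,
                        k_s=config.k_s,
                        true_icc=true_icc,
                        motion_log=motion_log,
                    ),
                )
            )
    return recordings
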