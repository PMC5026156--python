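"""Configuration objects and physical constants.

All defaults reflect the acquisition and analysis settings of the study
design this package emulates: a continuous-wave optical-topography system
sampling 24 channels at 10 Hz with wavelengths 695/830 nm and a fixed
30 mm source-detector separation, a block paradigm of 24-s speech blocks
interleaved with 20-40 s rests (three conditions, five blocks each), and
the standard analysis constants (DPF = 6, 0.01-0.5 Hz band, IQR factor
1.5, alpha = q = 0.05).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError

#: Molar extinction coefficients in cm^-1 mM^-1 as (HbO, HbR) pairs,
#: taken from the Gratzer/Kollias compilation of haemoglobin spectra
#: (as distributed by S. Prahl, Oregon Medical Laser Center), linearly
#: interpolated to the instrument wavelengths.
EXTINCTION_COEFFICIENTS = {
    695.0: (0.2830, 1.9231),
    830.0: (0.9740, 0.6930),
}

#: Region-of-interest channel triplets over posterior superior temporal
#: cortex, 1-based channel numbering.
LEFT_ROI_CHANNELS = (9, 10, 12)
RIGHT_ROI_CHANNELS = (20, 21, 23)

#: Behavioural control trials: probe appears 2 s after the chosen block
#: ends and the ensuing rest period is extended by 5 s.
CONTROL_TRIAL_DELAY_S = 2.0
CONTROL_REST_EXTENSION_S = 5.0

#: Haemodynamic measures assessed downstream of preprocessing.
MEASURES = ("functional", "hbo", "hbr")


def extinction_matrix(wavelengths, table=None) -> np.ndarray:
    """Return the 2x2 extinction matrix E with E[w] = (eps_HbO, eps_HbR).

    Raises ``ConfigurationError`` if a wavelength is not tabulated or if
    the matrix is (numerically) singular, in which case the two-chromophore
    inversion is ill-posed.
    """
    table = EXTINCTION_COEFFICIENTS if table is None else table
    try:
        rows = [table[float(w)] for w in wavelengths]
    except KeyError as exc:
        raise ConfigurationError(
            f"no extinction coefficients tabulated for wavelength {exc} nm"
        ) from None
    E = np.asarray(rows, dtype=float)
    if E.shape != (2, 2) or abs(np.linalg.det(E)) < 1e-12:
        raise ConfigurationError("extinction matrix is singular or not 2x2")
    return E


@dataclass
class AmplitudeModel:
    """Population model of the true haemodynamic response amplitude.

    Amplitudes are in the same arbitrary concentration units as the
    haemoglobin series (absolute values are not interpretable without a
    partial-volume correction, only relative magnitudes matter). The
    auditory conditions evoke a strong response, silent speechreading a
    weak one. A subject's amplitude is drawn once per subject; each
    session adds an independent between-session deviation, so the true
    test-retest ICC equals
    ``between_subject_sd**2 / (between_subject_sd**2 + between_session_sd**2)``.
    """

    condition_means: dict = field(
        default_factory=lambda: {"A-ONLY": 0.07, "V-ONLY": 0.035, "AV": 0.075}
    )
    between_subject_sd: float = 0.04
    between_session_sd: float = 0.025

    @property
    def true_icc(self) -> float:
        b2 = self.between_subject_sd ** 2
        s2 = self.between_session_sd ** 2
        return b2 / (b2 + s2) if (b2 + s2) > 0 else float("nan")


@dataclass
class SystemicModel:
    """Amplitudes/frequencies of the simulated systemic physiology.

    Components: cardiac pulsation (~1.1 Hz), Mayer waves (~0.1 Hz), slow
    baseline drift, a stimulus-locked slow negative trend in superficial
    haemoglobin (declines from stimulus onset to a minimum a few seconds
    after offset, then recovers), and white physiological noise. All
    amplitudes share the arbitrary concentration units of the functional
    response.
    """

    cardiac_amplitude: float = 0.015
    cardiac_freq_hz: float = 1.1
    mayer_amplitude: float = 0.03
    mayer_freq_hz: float = 0.095
    drift_amplitude: float = 0.05
    drift_freq_hz: float = 0.004
    stim_locked_amplitude: float = 0.03
    stim_decline_lag_s: float = 8.0
    stim_recovery_s: float = 15.0
    noise_sd: float = 0.01


@dataclass
class MotionModel:
    """Motion-artifact injection parameters.

    Artifacts are brief high-amplitude spikes and step baseline shifts,
    applied identically to both wavelengths of a channel (the positively
    co-registered signature that wavelet correction exploits). Amplitudes
    are expressed as multiples of the channel's clean optical-density SD.
    """

    rate_per_minute: float = 0.3
    spike_amplitude_sd: float = 8.0
    shift_amplitude_sd: float = 3.0
    spike_duration_s: float = 0.4


@dataclass
class SimulationConfig:
    """Full specification of a simulated two-session fNIRS cohort."""

    n_subjects: int = 17
    n_sessions: int = 2
    fs: float = 10.0
    n_channels: int = 24
    wavelengths: tuple = (695.0, 830.0)
    source_detector_separation_mm: float = 30.0
    dpf: float = 6.0
    conditions: tuple = ("A-ONLY", "V-ONLY", "AV")
    blocks_per_condition: int = 5
    block_duration_s: float = 24.0
    rest_range_s: tuple = (20.0, 40.0)
    control_trial_count: int = 2
    roi_channels: dict = field(
        default_factory=lambda: {"left": LEFT_ROI_CHANNELS, "right": RIGHT_ROI_CHANNELS}
    )
    #: 1-based channels carrying a non-zero true response; all others are null.
    responsive_channels: tuple = LEFT_ROI_CHANNELS + RIGHT_ROI_CHANNELS
    amplitude: AmplitudeModel = field(default_factory=AmplitudeModel)
    #: Functional HbR/HbO coupling ratio (fixed, negative).
    k_f: float = -0.6
    #: Systemic HbR/HbO coupling ratio (positive; estimated downstream).
    k_s: float = 2.0
    systemic: SystemicModel = field(default_factory=SystemicModel)
    motion: MotionModel = field(default_factory=MotionModel)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        lo, hi = self.rest_range_s
        if lo > hi:
            raise ConfigurationError(f"rest_range min {lo} exceeds max {hi}")
        if self.block_duration_s <= 0:
            raise ConfigurationError("block_duration_s must be positive")
        if self.blocks_per_condition < 1:
            raise ConfigurationError("blocks_per_condition must be >= 1")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not self.k_f < 0:
            raise ConfigurationError(f"k_f must be negative, got {self.k_f}")
        if not self.k_s > 0:
            raise ConfigurationError(f"k_s must be positive, got {self.k_s}")
        missing = [c for c in self.conditions if c not in self.amplitude.condition_means]
        if missing:
            raise ConfigurationError(f"no amplitude mean for conditions {missing}")
        bad = [ch for ch in self.responsive_channels if not 1 <= ch <= self.n_channels]
        if bad:
            raise ConfigurationError(f"responsive channels out of range: {bad}")


@dataclass
class PreprocessingConfig:
    iqr_factor: float = 1.5
    wavelet: str = "db5"
    decomposition_level: Optional[int] = None
    #: Detail levels with fewer coefficients than this are left untouched
    #: (quartile thresholds are unreliable there and the sparse evoked
    #: response would be flagged as artifact).
    min_level_size: int = 64
    low_hz: float = 0.01
    high_hz: float = 0.5
    filter_order: int = 3
    motion_correct: bool = True


@dataclass
class HMSConfig:
    k_f: float = -0.6
    grid_min: float = 0.05
    grid_max: float = 20.0
    grid_size: int = 60
    n_bins: Optional[int] = None


@dataclass
class GLMConfig:
    alpha: float = 0.05
    q: float = 0.05
    hrf_duration_s: float = 32.0
    iterate_cochrane_orcutt: bool = False


@dataclass
class ReliabilityConfig:
    #: Block-average epoch window relative to stimulus onset, seconds.
    window_s: tuple = (-5.0, 40.0)
    #: Baseline interval for epoch baseline subtraction, seconds.
    baseline_s: tuple = (-5.0, 0.0)


@dataclass
class PipelineConfig:
    """Nested configuration for the end-to-end pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    hms: HMSConfig = field(default_factory=HMSConfig)
    glm: GLMConfig = field(default_factory=GLMConfig)
    reliability: ReliabilityConfig = field(default_factory=ReliabilityConfig)
    #: Overrides ``simulation.seed`` when not None.
    seed: Optional[int] = None

    def resolved_seed(self) -> int:
        return self.simulation.seed if self.seed is None else self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})

        def build(klass, payload):
            if payload is None:
                return klass()
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown {klass.__name__} field(s): {sorted(unknown)}"
                )
            return klass(**payload)

        sim = data.get("simulation") or {}
        sim = dict(sim)
        for key, klass in (("amplitude", AmplitudeModel), ("systemic", SystemicModel), ("motion", MotionModel)):
            if key in sim and isinstance(sim[key], dict):
                sim[key] = build(klass, sim[key])
        for key in ("wavelengths", "conditions", "rest_range_s", "responsive_channels"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        if "roi_channels" in sim and isinstance(sim["roi_channels"], dict):
            sim["roi_channels"] = {k: tuple(v) for k, v in sim["roi_channels"].items()}
        cfg = cls(
            simulation=build(SimulationConfig, sim),
            preprocessing=build(PreprocessingConfig, data.get("preprocessing")),
            hms=build(HMSConfig, data.get("hms")),
            glm=build(GLMConfig, data.get("glm")),
            reliability=build(ReliabilityConfig, data.get("reliability")),
            seed=data.get("seed"),
        )
        for key in ("window_s", "baseline_s"):
            value = getattr(cfg.reliability, key)
            if isinstance(value, list):
                setattr(cfg.reliability, key, tuple(value))
        return cfg
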