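"""Synthetic two-state single-voxel BOLD datasets.

The generator emulates the study design the decoding method targets: a cohort
of subjects each recorded in two continuous task states (SI, self-initiated;
VG, visually guided), one series per state per subject, sampled at TR = 2 s
for 230 time points.  Each series is a 1/f^beta Gaussian background plus a
sinusoid at one (or more) effect band(s); the task effect is a pure
multiplicative amplitude difference between states at those bands, with a
per-subject amplitude factor shared across a subject's two states.  Everything is a pure function of the config (including the seed).

What this does NOT emulate: hemodynamic response shapes (continuous states
have no event structure to convolve), spatial structure (single voxel only),
and structured physiological noise (cardiac/respiratory aliasing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bold_io import BoldSeries, LabeledDataset

__all__ = ["SimConfig", "LabeledDataset", "simulate_subject_series", "simulate_dataset"]

STATE_POSITIVE = "SI"
STATE_NEGATIVE = "VG"
_STATE_CODE = {STATE_NEGATIVE: 0, STATE_POSITIVE: 1}


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated dataset.

    Parameters
    ----------
    n_subjects : number of subjects; each contributes one SI and one VG series.
    n_timepoints : samples per series.
    tr_seconds : sampling interval in seconds.
    noise_exponent : spectral slope beta of the 1/f^beta background.
    effect_band_hz : center frequency (Hz) carrying the state effect.
    effect_ratio : SI/VG amplitude ratio at the effect band (>= 1).
    extra_effects : optional additional (band_hz, ratio) amplitude effects.
    subject_sd : between-subject amplitude variability as a fraction of 1.
    base_amplitude : oscillation amplitude in signal units (the VG amplitude
        for an average subject); the background noise has unit SD, so this is
        also the per-band signal-to-noise dial.
    noise_sd : standard deviation of the 1/f^beta background.
    zscore : z-score each series (mean 0, SD 1) before returning; makes all
        downstream inputs scale-free.  Disable to study absolute amplitudes.
    seed : master seed; the whole dataset is a pure function of this config.
    """

    n_subjects: int = 42
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    noise_exponent: float = 1.0
    effect_band_hz: float = 0.103
    effect_ratio: float = 2.0
    extra_effects: tuple[tuple[float, float], ...] = ()
    subject_sd: float = 0.2
    base_amplitude: float = 1.0
    noise_sd: float = 1.0
    zscore: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be >= 16")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.effect_ratio < 1:
            raise ValueError("effect_ratio must be >= 1 (SI is the larger-amplitude state)")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if self.effect_band_hz >= nyquist:
            warnings.warn(
                f"effect band {self.effect_band_hz:g} Hz is at or above the Nyquist "
                f"limit {nyquist:g} Hz; the injected oscillation will alias",
                stacklevel=2,
            )

    def all_effects(self) -> tuple[tuple[float, float], ...]:
        return ((self.effect_band_hz, self.effect_ratio), *self.extra_effects)


def _one_over_f_noise(
    n: int, tr: float, beta: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian background with power spectrum proportional to 1/f^beta.

    Built in the frequency domain: complex Gaussian Fourier coefficients are
    scaled by f^(-beta/2) (DC left at zero) and inverted, then the series is
    rescaled to the requested SD.  Simple, seedable, controllable slope.
    """
    if sd == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=tr)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    coefs = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    noise = np.fft.irfft(coefs, n=n)
    noise_sd = noise.std()
    if noise_sd < 1e-300:
        return np.zeros(n)
    return noise * (sd / noise_sd)


def simulate_subject_series(
    config: SimConfig,
    subject_effect: float,
    state: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one series: 1/f^beta background + amplitude-modulated sinusoids.

    The sinusoid amplitude at each effect band is
    ``base_amplitude * subject_effect * (ratio if state == SI else 1)`` with a
    random phase per band.  The series is z-scored before return unless the
    config disables it; an (almost) constant series cannot be z-scored and is
    returned as zeros with a warning.
    """
    if state not in _STATE_CODE:
        raise ValueError(f"state must be one of {sorted(_STATE_CODE)}, got {state!r}")
    n, tr = config.n_timepoints, config.tr_seconds
    t = np.arange(n) * tr
    series = _one_over_f_noise(n, tr, config.noise_exponent, config.noise_sd, rng)
    for band_hz, ratio in config.all_effects():
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amplitude = config.base_amplitude * subject_effect
        if state == STATE_POSITIVE:
            amplitude *= ratio
        series = series + amplitude * np.sin(2.0 * np.pi * band_hz * t + phase)
    if config.zscore:
        sd = series.std()
        if sd < 1e-12:
            warnings.warn("degenerate (constant) series cannot be z-scored; returning zeros")
            return np.zeros(n)
        series = (series - series.mean()) / sd
    return series


def _subject_rng(config: SimConfig, subject_index: int, state: str) -> np.random.Generator:
    """Deterministic per-(subject, state) stream; stable under cohort growth."""
    ss = np.random.SeedSequence([config.seed, subject_index, _STATE_CODE[state]])
    return np.random.default_rng(ss)


def _subject_effect(config: SimConfig, subject_index: int) -> float:
    """Per-subject amplitude factor, shared by the subject's two states."""
    ss = np.random.SeedSequence([config.seed, subject_index, 2])
    draw = np.random.default_rng(ss).standard_normal()
    return max(0.1, 1.0 + config.subject_sd * draw)


def simulate_dataset(config: SimConfig) -> LabeledDataset:
    """Simulate the full labeled dataset: 2 series (SI + VG) per subject.

    Labels are exactly balanced by construction and the result is bitwise
    reproducible from the config.  Per-subject random streams are derived
    from (seed, subject, state), so adding subjects never perturbs the series
    of existing ones.
    """
    series: list[BoldSeries] = []
    for s in range(config.n_subjects):
        effect = _subject_effect(config, s)
        for state in (STATE_POSITIVE, STATE_NEGATIVE):
            values = simulate_subject_series(config, effect, state, _subject_rng(config, s, state))
            series.append(
                BoldSeries(
                    values=values,
                    tr_seconds=config.tr_seconds,
                    subject_id=f"sub{s:03d}",
                    state_label=state,
                    voxel_id="sim",
                )
            )
    return LabeledDataset(series=series)
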