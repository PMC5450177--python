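"""Annotated synthetic ECG records.

Two generators:

* :func:`generate_beats` — a morphology-parameterized beat train
  (Ricker-kernel QRS, Gaussian P and T lobes) for exercising the
  detector against known fiducials;
* :func:`generate_from_ap` — an action-potential-driven record whose
  repolarization wave is exactly the left/right epicardial template
  difference ``h_R C_R(k tau) - h_L C_L(k tau)`` time-locked to each
  beat, plus a biphasic depolarization spike at the beat onset.  The
  spike is a Ricker (Mexican-hat) kernel, chosen because it integrates
  to zero from its center outward, so the per-beat energy integral of
  the record equals the template-difference integral — the quantity the
  inverse fit inverts for ``k``.

:func:`corrupt` adds, per configuration, white noise at a target SNR,
powerline interference, sinusoidal baseline drift and a stepwise
amplitude change.

All outputs are reproducible bit-for-bit from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ap_model import APParams, APTemplate, ap_forward, build_default_templates

__all__ = [
    "SimConfig",
    "Annotation",
    "generate_beats",
    "generate_from_ap",
    "corrupt",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic record.

    Amplitudes are in millivolts; the 5:1 QRS:T ratio, 0.10 s QRS and
    0.16 s T widths follow textbook adult surface-ECG morphology.
    ``heart_rate_sd`` models sinus variability (sd of the instantaneous
    rate in bpm); set it to 0 for strictly periodic beats.
    """

    fs: float = 250.0
    duration: float = 30.0
    heart_rate: float = 60.0
    heart_rate_sd: float = 3.0
    qrs_amplitude: float = 1.0
    t_amplitude: float = 0.2
    p_amplitude: float = 0.05
    qrs_width: float = 0.10
    t_width: float = 0.16
    p_width: float = 0.08
    t_offset: float = 0.30
    p_offset: float = 0.16
    noise_snr_db: float | None = None
    powerline_hz: float | None = None
    powerline_amplitude: float = 0.05
    baseline_drift_amp: float = 0.0
    baseline_drift_freq: float = 0.3
    amplitude_step_at: float | None = None
    amplitude_step_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValueError(f"fs must be >= 100 Hz, got {self.fs}")
        if self.duration < 2:
            raise ValueError(f"duration must be >= 2 s, got {self.duration}")
        if not 30 <= self.heart_rate <= 220:
            raise ValueError(
                f"heart_rate must lie in [30, 220] bpm, got {self.heart_rate}"
            )
        if self.heart_rate_sd < 0:
            raise ValueError("heart_rate_sd must be >= 0")
        for name in ("qrs_width", "t_width", "p_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Annotation:
    """Ground truth for one synthetic beat."""

    beat_index: int
    r_time: float
    t_time: float
    true_params: APParams | None = None


def _schedule_beats(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Beat onset times; first beat at 0.3 s, last fully inside the record."""
    t0 = 0.3
    tail = 0.45  # room for the T wave of the final beat
    times = []
    t = t0
    while t <= config.duration - tail:
        times.append(t)
        hr = config.heart_rate
        if config.heart_rate_sd > 0:
            hr = hr + config.heart_rate_sd * rng.standard_normal()
            hr = float(np.clip(hr, 30.0, 220.0))
        t = t + 60.0 / hr
    return np.asarray(times)


def _ricker(t: np.ndarray, sigma: float) -> np.ndarray:
    """Mexican-hat kernel, unit peak; integrates to zero over the line
    and, by symmetry of its antiderivative, also from 0 to infinity."""
    z = (t / sigma) ** 2
    return (1.0 - z) * np.exp(-0.5 * z)


def _add_kernel(signal: np.ndarray, fs: float, center: float, half_support: float,
                func) -> None:
    i0 = max(0, int(np.floor((center - half_support) * fs)))
    i1 = min(len(signal), int(np.ceil((center + half_support) * fs)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs - center
    signal[i0:i1] += func(t)


def generate_beats(config: SimConfig | None = None):
    """Morphology-parameterized beat train with annotations.

    The QRS is a Ricker kernel (peak value = ``qrs_amplitude`` at the
    annotated R time); P and T are Gaussian lobes at fixed offsets.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    signal = np.zeros(n)
    beat_times = _schedule_beats(config, rng)

    sigma_q = config.qrs_width / 6.0
    sigma_t = config.t_width / 4.0
    sigma_p = config.p_width / 4.0
    annotations = []
    for idx, rt in enumerate(beat_times):
        _add_kernel(signal, config.fs, rt, 6 * sigma_q,
                    lambda t: config.qrs_amplitude * _ricker(t, sigma_q))
        _add_kernel(signal, config.fs, rt + config.t_offset, 5 * sigma_t,
                    lambda t: config.t_amplitude * np.exp(-0.5 * (t / sigma_t) ** 2))
        if config.p_amplitude > 0:
            _add_kernel(
                signal, config.fs, rt - config.p_offset, 5 * sigma_p,
                lambda t: config.p_amplitude * np.exp(-0.5 * (t / sigma_p) ** 2))
        annotations.append(
            Annotation(beat_index=idx, r_time=float(rt),
                       t_time=float(rt + config.t_offset))
        )
    signal = corrupt(signal, config, rng=rng)
    return signal, annotations


def generate_from_ap(
    params: APParams,
    templates: tuple[APTemplate, APTemplate] | None = None,
    config: SimConfig | None = None,
):
    """Action-potential-driven record with known ``(k, h_R, h_L)``.

    Each beat contributes a depolarization spike (Ricker, amplitude
    ``qrs_amplitude``) at the R time and the body-surface repolarization
    wave ``h_R C_R(k tau) - h_L C_L(k tau)`` with ``tau`` measured from
    the R time.  The annotated T time is the extremum of that
    difference.
    """
    config = config or SimConfig()
    templates = templates or build_default_templates()
    left, right = templates
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    signal = np.zeros(n)
    beat_times = _schedule_beats(config, rng)
    sigma_q = config.qrs_width / 6.0

    # T annotation: extremum of the template difference on a fine grid
    tau_fine = np.arange(0.0, right.duration / params.k + 1e-9, 1e-4)
    w_fine = ap_forward(right, tau_fine, params.k, params.h_r) - ap_forward(
        left, tau_fine, params.k, params.h_l
    )
    tau_star = float(tau_fine[np.argmax(np.abs(w_fine))])

    support = right.duration / params.k
    annotations = []
    for idx, rt in enumerate(beat_times):
        _add_kernel(signal, config.fs, rt, 6 * sigma_q,
                    lambda t: config.qrs_amplitude * _ricker(t, sigma_q))

        def wave(t):
            tau = t  # t is already centered on the R time
            return ap_forward(right, tau, params.k, params.h_r) - ap_forward(
                left, tau, params.k, params.h_l
            )

        i0 = int(np.ceil(rt * config.fs))
        i1 = min(n, int(np.ceil((rt + support) * config.fs)) + 1)
        if i1 > i0:
            t = np.arange(i0, i1) / config.fs - rt
            signal[i0:i1] += wave(t)
        annotations.append(
            Annotation(beat_index=idx, r_time=float(rt),
                       t_time=float(rt + tau_star), true_params=params)
        )
    signal = corrupt(signal, config, rng=rng)
    return signal, annotations


def corrupt(signal, config: SimConfig, rng: np.random.Generator | None = None):
    """Apply the configured corruptions; identity when all are off."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = x.copy()
    t = np.arange(len(x)) / config.fs

    if config.amplitude_step_at is not None:
        i = int(round(config.amplitude_step_at * config.fs))
        out[i:] = out[i:] * config.amplitude_step_factor
    if config.powerline_hz:
        out = out + config.powerline_amplitude * np.sin(
            2 * np.pi * config.powerline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if config.baseline_drift_amp:
        out = out + config.baseline_drift_amp * np.sin(
            2 * np.pi * config.baseline_drift_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if config.noise_snr_db is not None:
        p_signal = float(np.mean(x * x))
        p_noise = p_signal / (10.0 ** (config.noise_snr_db / 10.0))
        noise = rng.standard_normal(len(x))
        noise *= np.sqrt(p_noise) / np.sqrt(np.mean(noise * noise))
        out = out + noise
    return out
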