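"""Standard epicardial action-potential templates and their scaling model.

The surface ECG's repolarization wave arises from the spatial gradient of
ventricular action potentials; here it is reduced to the difference of a
*left* and a *right* epicardial template, ``h_R*C_R(k*t) - h_L*C_L(k*t)``,
where ``k`` rescales time (k < 1 stretches the action potential, i.e.
prolongs repolarization) and ``h_R``, ``h_L`` rescale the two amplitudes.
The templates are analytic: a fast logistic upstroke, a Gaussian phase-1
notch, an exponentially sagging plateau, and a logistic repolarization
fall.  They are normalized to rest 0 / peak 1 — physical millivolt scale
cancels in the fitted amplitude ratios.  The left template repolarizes
earlier than the right one, which is what gives the template difference a
single upright T-like hump.

Ionic single-cell formulations (Hodgkin–Huxley-type models with a dozen
transmembrane currents and hundreds of parameters) describe the same
waveform mechanistically but are deliberately not solved here: the
inverse problem below only needs a stable template shape with two or
three interpretable scaling knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "APTemplate",
    "APParams",
    "ap_forward",
    "template_integral",
    "build_default_templates",
]

TEMPLATE_DURATION_S = 0.30  # typical epicardial APD90 is ~300 ms
TEMPLATE_GRID_HZ = 1000.0


@dataclass(frozen=True)
class APTemplate:
    """A sampled, amplitude-normalized action-potential waveform."""

    side: str
    grid: np.ndarray  # seconds, strictly increasing, 0..duration
    values: np.ndarray  # normalized potential: rest 0, peak 1
    duration: float

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if g.ndim != 1 or v.shape != g.shape:
            raise ValueError("grid and values must be 1-D and equal length")
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        if v[0] != 0.0:
            raise ValueError("template must start at rest (values[0] == 0)")
        if v[-1] > 0.02:
            raise ValueError("template must return to rest (end value <= 0.02)")
        if v.min() < -0.1 or v.max() > 1.0 + 1e-12:
            raise ValueError("template values must lie in [-0.1, 1]")
        peaks = np.flatnonzero(v == v.max())
        if len(peaks) != 1:
            raise ValueError("template must have exactly one global maximum")
        if g[peaks[0]] > 0.05 * self.duration:
            raise ValueError(
                "global maximum must occur within the first 5% of the "
                "duration (fast upstroke)"
            )

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation on the grid; 0 outside the support."""
        return np.interp(np.asarray(t, dtype=float), self.grid, self.values,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class APParams:
    """Time-scale and amplitude scaling factors of the two templates."""

    k: float
    h_r: float
    h_l: float

    def __post_init__(self) -> None:
        for name, value in (("k", self.k), ("h_r", self.h_r), ("h_l", self.h_l)):
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value}")


def ap_forward(template: APTemplate, t, k: float, h: float):
    """Scaled template ``h * C(k * t)``; zero beyond the scaled support.

    Linear in ``h``; ``k`` compresses (k > 1) or stretches (k < 1) time.
    """
    if k <= 0 or h <= 0:
        raise ValueError("k and h must be positive")
    return h * template(np.asarray(t, dtype=float) * k)


def template_integral(template: APTemplate, k: float = 1.0) -> float:
    """Integral of ``C(k*t)`` over its support (trapezoidal).

    By change of variables this equals ``integral(C) / k``, so the product
    ``k * template_integral(k)`` is constant in ``k``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    return float(np.trapezoid(template.values, template.grid) / k)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _epicardial_waveform(
    t: np.ndarray,
    upstroke_center: float,
    upstroke_width: float,
    notch_depth: float,
    notch_center: float,
    notch_width: float,
    plateau_level: float,
    plateau_tau: float,
    repol_center: float,
    repol_width: float,
) -> np.ndarray:
    up = _logistic((t - upstroke_center) / upstroke_width)
    notch = 1.0 - notch_depth * np.exp(-(((t - notch_center) / notch_width) ** 2))
    sag = plateau_level + (1.0 - plateau_level) * np.exp(-t / plateau_tau)
    repol = _logistic((repol_center - t) / repol_width)
    v = up * notch * sag * repol
    v = v - v[0]
    return v / v.max()


def build_default_templates(
    duration: float = TEMPLATE_DURATION_S,
    grid_hz: float = TEMPLATE_GRID_HZ,
) -> tuple[APTemplate, APTemplate]:
    """Packaged analytic left/right epicardial templates.

    Deterministic (no randomness).  The left template repolarizes ~90 ms
    earlier and has a shallower notch than the right one, so the unit
    difference ``C_R - C_L`` is an upright hump late in the beat — the
    synthetic T wave consumed by the inverse fit.
    """
    t = np.arange(0.0, duration + 0.5 / grid_hz, 1.0 / grid_hz)
    scale = duration / 0.30  # keep phase landmarks proportional
    left = _epicardial_waveform(
        t,
        upstroke_center=0.004 * scale,
        upstroke_width=0.0009 * scale,
        notch_depth=0.05,
        notch_center=0.025 * scale,
        notch_width=0.010 * scale,
        plateau_level=0.80,
        plateau_tau=0.060 * scale,
        repol_center=0.165 * scale,
        repol_width=0.012 * scale,
    )
    right = _epicardial_waveform(
        t,
        upstroke_center=0.004 * scale,
        upstroke_width=0.0009 * scale,
        notch_depth=0.12,
        notch_center=0.025 * scale,
        notch_width=0.010 * scale,
        plateau_level=0.84,
        plateau_tau=0.060 * scale,
        repol_center=0.250 * scale,
        repol_width=0.011 * scale,
    )
    return (
        APTemplate(side="left", grid=t, values=left, duration=duration),
        APTemplate(side="right", grid=t, values=right, duration=duration),
    )
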