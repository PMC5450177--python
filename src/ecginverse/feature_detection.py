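"""R/T peak localization by windowed-energy thresholding of wavelet subbands.

The detector works on the detail subbands of the QRS band (10-20 Hz)
and the T band (3-8 Hz), extracted in their shift-invariant
(undecimated) form: the decimated cascade assigns a transient an energy
that depends on its position modulo the decimation factor (a measured
~8x per-beat spread near the band crossover), which would starve any
one-sided adaptive threshold; the stationary form of the same subband
makes per-beat energy uniform.  Each coefficient stream is squared and
summed over a short causal window; a 0/1 extraction function marks
samples whose windowed energy exceeds an adaptive threshold, which is
updated by exponential forgetting every time it is exceeded.  The
midpoint of each run of ones, mapped back through the filter delay, is
the event time.

R peaks are then refined to the waveform extremum on the raw signal
(sub-sample, by parabolic interpolation).  T peaks are searched per
beat — the QRS leaks more energy into the T subband than the T wave
itself carries, so QRS neighbourhoods are masked and the candidate is
the windowed-energy argmax after each known R — then refined to the
crest of the baseline-corrected waveform on the sample grid, so every
recorded (latency, amplitude) pair refers to one instant on the
underlying repolarization waveform, which is what the downstream
inverse fit assumes.  Each beat also records the on-curve samples
around its T peak (``t_support``); the inverse fit needs this latency
spread because a steady rhythm makes single per-beat latencies nearly
identical and the amplitude regression singular.

Baseline is estimated from per-beat isoelectric anchors (the short quiet
segment preceding each QRS) joined by linear interpolation.  An anchored
baseline, unlike a fixed-window median filter, does not bite into slow
repolarization segments whose support can exceed half the beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .wavelet_core import (
    Band,
    SubbandSeries,
    WaveletSpec,
    extract_band_stationary,
    plan_subband,
    stationary_detail_bank,
)

__all__ = [
    "DetectorConfig",
    "BeatFeatures",
    "DetectionOutcome",
    "windowed_energy",
    "binarize_adaptive",
    "localize_midpoints",
    "detect_beats",
    "beats_to_frame",
    "BeatDetector",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the beat detector.

    lambda_ : forgetting factor of the adaptive threshold; must be in
        (0, 0.25].  Larger values track energy bursts faster.
    r_duration_s : assumed R-wave duration T; the energy window is T/2.
    m0_fraction : the initial squared threshold is this fraction of the
        maximum windowed energy over the calibration stretch.
    refractory_s : minimum separation of two R detections.
    """

    lambda_: float = 0.125
    r_duration_s: float = 0.10
    t_duration_s: float = 0.16
    qrs_energy_window_s: float = 0.22
    t_energy_window_s: float = 0.12
    m0_fraction: float = 0.3
    calibration_s: float = 2.0
    refractory_s: float = 0.25
    trigger_fraction: float = 0.5
    relax_tau_s: float = 1.5
    floor_fraction: float = 0.5
    qrs_band: tuple[float, float] = (10.0, 20.0)
    t_band: tuple[float, float] = (3.0, 8.0)
    t_search_min_s: float = 0.08
    t_search_max_rr: float = 0.6
    t_refine_s: float = 0.12
    t_support_halfwidth_s: float = 0.07
    qrs_mask_s: float = 0.12
    r_refine_s: float = 0.06
    baseline_anchor_offset_s: float = 0.15
    baseline_anchor_halfwidth_s: float = 0.02
    onset_search_s: float = 0.08
    delta_pre_s: float = 0.08
    rest_threshold_frac: float = 0.05
    rest_hold_s: float = 0.04
    rest_max_rr: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_ <= 0.25:
            raise ValueError("lambda_ must lie in (0, 0.25]")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")
        if self.r_duration_s <= 0 or self.t_duration_s <= 0:
            raise ValueError("wave durations must be positive")


@dataclass(frozen=True)
class BeatFeatures:
    """Per-beat eigenvalues: fiducial times, amplitudes and the energy
    integral from the R peak to electrical rest."""

    r_time: float
    r_amplitude: float
    t_time: float | None = None
    t_amplitude: float | None = None
    delta: float | None = None
    rr_interval: float | None = None
    onset_time: float | None = None
    rest_time: float | None = None
    # on-curve repolarization samples around the T peak:
    # (latencies relative to the R peak, baseline-corrected amplitudes)
    t_support: tuple | None = None

    def __post_init__(self) -> None:
        if self.t_time is not None:
            if self.t_time <= self.r_time:
                raise ValueError("t_time must follow r_time")
            if self.rr_interval is not None and (
                self.t_time - self.r_time
            ) >= self.rr_interval:
                raise ValueError("t_time must fall within the RR interval")

    @property
    def latency(self) -> float | None:
        """T-peak latency relative to the R peak, seconds."""
        if self.t_time is None:
            return None
        return self.t_time - self.r_time

    @property
    def complete(self) -> bool:
        return self.t_amplitude is not None and self.delta is not None


@dataclass
class DetectionOutcome:
    """Beat list plus diagnostics; iterates over the beats."""

    beats: list[BeatFeatures]
    flags: list[str] = field(default_factory=list)
    baseline: np.ndarray | None = None

    def __iter__(self):
        return iter(self.beats)

    def __len__(self):
        return len(self.beats)

    def __getitem__(self, i):
        return self.beats[i]

    @property
    def r_times(self) -> np.ndarray:
        return np.array([b.r_time for b in self.beats])

    @property
    def t_times(self) -> np.ndarray:
        return np.array([b.t_time for b in self.beats if b.t_time is not None])


def windowed_energy(chi, L: int) -> np.ndarray:
    """Causal windowed energy ``E(t) = sum_{k=0..L} chi^2(t-k)``.

    Out-of-range indices contribute 0; output length equals input length.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    x = np.asarray(chi, dtype=float)
    if x.size == 0:
        raise ValueError("sequence must be non-empty")
    return np.convolve(x * x, np.ones(L + 1))[: len(x)]


def binarize_adaptive(E, m0: float, lambda_: float = 0.125):
    """0/1 extraction with adaptive threshold.

    ``Z(t) = 1`` iff ``E(t) >= M^2``.  Whenever the trigger fires, the
    squared threshold is updated ``M^2 <- M^2 (1 - lambda) + lambda E(t)``
    (the threshold is maintained in energy units so the comparison and
    the update are dimensionally consistent).  Returns ``(Z, M_final)``
    with ``M_final`` on the amplitude-like scale of ``m0``.
    """
    if m0 <= 0:
        raise ValueError("initial threshold m0 must be positive")
    if not 0.0 <= lambda_ <= 0.25:
        raise ValueError("lambda_ must lie in [0, 0.25]")
    E = np.asarray(E, dtype=float)
    m_sq = m0 * m0
    z = np.zeros(len(E), dtype=np.uint8)
    for t in range(len(E)):
        if E[t] >= m_sq:
            z[t] = 1
            m_sq = m_sq * (1.0 - lambda_) + lambda_ * E[t]
    return z, float(np.sqrt(m_sq))


def _binarize_tracking(
    E,
    m0: float,
    lambda_: float,
    alpha: float,
    relax: float,
    floor: float,
) -> np.ndarray:
    """Two-rate adaptive 0/1 extraction used inside the detector.

    The trigger-only update of :func:`binarize_adaptive` is monotone
    non-decreasing (a triggering sample has ``E >= M^2``, so the convex
    update can only raise the threshold); its fixed point is the supremum
    of the burst energy, at which identical beats stop triggering.  The
    detector therefore (a) pulls the threshold toward ``alpha * E`` on
    trigger, placing the fixed point a stable factor below the burst
    peaks, and (b) relaxes it by a slow per-sample factor toward a
    calibration-derived floor during silence, so it recovers after an
    amplitude drop.
    """
    E = np.asarray(E, dtype=float)
    m_sq = m0 * m0
    z = np.zeros(len(E), dtype=np.uint8)
    keep = 1.0 - relax
    for t in range(len(E)):
        if E[t] >= m_sq:
            z[t] = 1
            m_sq = m_sq * (1.0 - lambda_) + lambda_ * alpha * E[t]
            if m_sq < floor:
                m_sq = floor
        else:
            m_sq *= keep
            if m_sq < floor:
                m_sq = floor
    return z


def _runs(z: np.ndarray) -> list[tuple[int, int]]:
    z = np.asarray(z).astype(bool)
    if z.ndim != 1:
        raise ValueError("Z must be one-dimensional")
    edges = np.flatnonzero(np.diff(np.concatenate(([0], z.view(np.uint8), [0]))))
    return [(int(a), int(b - 1)) for a, b in zip(edges[::2], edges[1::2])]


def localize_midpoints(z, refractory: int = 0, energy=None) -> list[int]:
    """Midpoint index of each run of ones in a 0/1 sequence.

    Runs whose midpoints are closer than ``refractory`` samples are
    merged, keeping the run with the larger summed energy (run length if
    no energy sequence is supplied).
    """
    runs = _runs(np.asarray(z))
    if not runs:
        return []
    if energy is not None:
        energy = np.asarray(energy, dtype=float)
        weight = [float(energy[a : b + 1].sum()) for a, b in runs]
    else:
        weight = [float(b - a + 1) for a, b in runs]
    mids = [(a + b) // 2 for a, b in runs]
    kept_mid: list[int] = []
    kept_w: list[float] = []
    for m, w in zip(mids, weight):
        if kept_mid and m - kept_mid[-1] < refractory:
            if w > kept_w[-1]:
                kept_mid[-1], kept_w[-1] = m, w
        else:
            kept_mid.append(m)
            kept_w.append(w)
    return kept_mid


def _localize_band(
    series: SubbandSeries,
    window_s: float,
    config: DetectorConfig,
    mask_times: np.ndarray | None = None,
    mask_halfwidth_s: float = 0.0,
):
    """Windowed energy -> adaptive 0/1 -> merged run midpoints -> times.

    The energy window spans the whole wave including the cumulative
    filter smear, so the per-burst peak energy is insensitive to where
    the beat falls relative to the decimation grid.  The causal window
    biases run midpoints late by L/2 samples; the returned times
    compensate for this.
    """
    fs_sub = 1.0 / series.step_s
    L = max(1, int(np.ceil(window_s * fs_sub)))
    E = windowed_energy(series.coefficients, L)
    if mask_times is not None and len(mask_times):
        t_coeff = series.times()
        for mt in mask_times:
            E[np.abs(t_coeff - mt) <= mask_halfwidth_s] = 0.0
    n_cal = max(1, int(np.ceil(config.calibration_s * fs_sub)))
    e_max = float(E[:n_cal].max()) if len(E) else 0.0
    if e_max <= 0.0:
        e_max = float(E.max())
    if e_max <= 0.0:
        return [], E
    m0 = float(np.sqrt(config.m0_fraction * e_max))
    relax = 1.0 - np.exp(-1.0 / (config.relax_tau_s * fs_sub))
    z = _binarize_tracking(
        E, m0, config.lambda_, config.trigger_fraction, relax,
        config.floor_fraction * m0 * m0,
    )
    refr = int(round(config.refractory_s * fs_sub))
    mids = localize_midpoints(z, refractory=refr, energy=E)
    times = series.index_to_time(np.asarray(mids, dtype=float) - L / 2.0)
    return list(zip(mids, np.atleast_1d(times))), E


def _refine_peak(x: np.ndarray, fs: float, t: float, halfwidth_s: float):
    """Sub-sample peak of |x| near time t via parabolic interpolation."""
    i0 = max(0, int(round((t - halfwidth_s) * fs)))
    i1 = min(len(x), int(round((t + halfwidth_s) * fs)) + 1)
    if i1 - i0 < 3:
        i = min(max(int(round(t * fs)), 0), len(x) - 1)
        return i / fs, x[i]
    seg = x[i0:i1]
    j = int(np.argmax(np.abs(seg))) + i0
    if 0 < j < len(x) - 1:
        y0, y1, y2 = x[j - 1], x[j], x[j + 1]
        denom = y0 - 2 * y1 + y2
        off = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        off = float(np.clip(off, -0.5, 0.5))
        amp = y1 - 0.25 * (y0 - y2) * off
        return (j + off) / fs, float(amp)
    return j / fs, float(x[j])


def _anchored_baseline(
    x: np.ndarray, fs: float, r_times: np.ndarray, config: DetectorConfig
) -> np.ndarray:
    """Linear baseline through per-beat isoelectric anchors before each R."""
    anchors_t, anchors_v = [], []
    hw = int(round(config.baseline_anchor_halfwidth_s * fs))
    for rt in r_times:
        c = int(round((rt - config.baseline_anchor_offset_s) * fs))
        a, b = max(0, c - hw), min(len(x), c + hw + 1)
        if b - a >= 1:
            anchors_t.append(c / fs)
            anchors_v.append(float(np.median(x[a:b])))
    if not anchors_t:
        return np.zeros_like(x)
    t_all = np.arange(len(x)) / fs
    return np.interp(t_all, anchors_t, anchors_v)


def _trapz_fractional(x: np.ndarray, fs: float, t0: float, t1: float) -> float:
    """Trapezoidal integral of sampled x between fractional times t0 < t1."""
    if t1 <= t0:
        return 0.0
    s0, s1 = t0 * fs, t1 * fs
    i0, i1 = int(np.ceil(s0)), int(np.floor(s1))
    i0 = max(i0, 0)
    i1 = min(i1, len(x) - 1)
    if i1 < i0:
        # both endpoints inside one sample interval
        va = np.interp(s0, np.arange(len(x)), x)
        vb = np.interp(s1, np.arange(len(x)), x)
        return float(0.5 * (va + vb) * (t1 - t0))
    total = float(np.trapezoid(x[i0 : i1 + 1])) / fs
    if s0 < i0:
        va = np.interp(s0, np.arange(len(x)), x)
        total += 0.5 * (va + x[i0]) * (i0 - s0) / fs
    if s1 > i1:
        vb = np.interp(s1, np.arange(len(x)), x)
        total += 0.5 * (x[i1] + vb) * (s1 - i1) / fs
    return total


def _find_rest(
    x: np.ndarray, fs: float, t_start: float, t_max: float, threshold: float,
    hold_s: float,
) -> float:
    """First time after t_start where |x| stays below threshold for hold_s."""
    i = int(round(t_start * fs))
    i_max = min(len(x) - 1, int(round(t_max * fs)))
    hold = max(1, int(round(hold_s * fs)))
    quiet = np.abs(x) < threshold
    count = 0
    for j in range(i, i_max + 1):
        count = count + 1 if quiet[j] else 0
        if count >= hold:
            return j / fs
    return i_max / fs


def detect_beats(
    ecg,
    fs: float,
    config: DetectorConfig | None = None,
    spec: WaveletSpec | None = None,
    detail_bank: dict | None = None,
) -> DetectionOutcome:
    """Full beat delineation: band extraction, localization, eigenvalues.

    Returns a :class:`DetectionOutcome` whose ``beats`` are in time
    order.  Beats without a locatable T wave carry ``None`` T fields; a
    record with no R peaks yields an empty outcome with a diagnostic
    flag.
    """
    config = config or DetectorConfig()
    spec = spec or WaveletSpec()
    x = np.asarray(ecg, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("record must be at least 2 seconds long")

    qrs_band = Band(*config.qrs_band, fs_hz=fs)
    t_band = Band(*config.t_band, fs_hz=fs)
    plan_q = plan_subband(qrs_band)
    plan_t = plan_subband(t_band)
    if detail_bank is None:
        detail_bank = stationary_detail_bank(
            x, spec, max(plan_q.level, plan_t.level)
        )
    chi_q = extract_band_stationary(
        x, fs, spec=spec, plan=plan_q, detail_bank=detail_bank
    )
    chi_t = extract_band_stationary(
        x, fs, spec=spec, plan=plan_t, detail_bank=detail_bank
    )

    flags: list[str] = []
    r_raw, _Eq = _localize_band(chi_q, config.qrs_energy_window_s, config)
    if not r_raw:
        flags.append("no_r_peaks")
        return DetectionOutcome(beats=[], flags=flags)

    # refine R peaks on the raw signal and deduplicate
    r_times: list[float] = []
    for _mid, t in r_raw:
        if t < 0 or t > len(x) / fs:
            continue
        rt, _amp = _refine_peak(x, fs, float(t), config.r_refine_s)
        if r_times and rt - r_times[-1] < config.refractory_s:
            continue
        r_times.append(rt)
    if not r_times:
        flags.append("no_r_peaks")
        return DetectionOutcome(beats=[], flags=flags)
    r_times_arr = np.asarray(r_times)

    baseline = _anchored_baseline(x, fs, r_times_arr, config)
    corrected = x - baseline

    # T localization is per-beat: the QRS leaks far more energy into the
    # T subband than the T wave itself carries (the global adaptive
    # threshold would lock onto QRS skirts), so the QRS neighbourhoods
    # are zeroed in the coefficient stream and the T peak is the
    # windowed-energy argmax inside the physiological search window
    # after each already-known R peak.
    t_coef = chi_t.coefficients.copy()
    t_times_coef = chi_t.times()
    for rt in r_times_arr:
        t_coef[np.abs(t_times_coef - rt) <= config.qrs_mask_s] = 0.0
    fs_sub_t = 1.0 / chi_t.step_s
    L_t = max(1, int(np.ceil(config.t_energy_window_s * fs_sub_t)))
    E_t = windowed_energy(t_coef, L_t)
    # centre times of the causal energy window
    E_t_times = chi_t.index_to_time(np.arange(len(E_t), dtype=float) - L_t / 2.0)

    rr = np.diff(r_times_arr)
    median_rr = float(np.median(rr)) if len(rr) else None

    beats: list[BeatFeatures] = []
    n_missing_t = 0
    for i, rt in enumerate(r_times):
        _t_ref, r_amp = _refine_peak(corrected, fs, rt, config.r_refine_s)
        rr_i = float(rr[i - 1]) if i > 0 else None
        rr_fwd = float(rr[i]) if i < len(rr) else (median_rr or 0.8)

        # onset: last zero-crossing of the corrected signal before the R peak
        onset = None
        i_r = int(round(rt * fs))
        i_lo = max(0, i_r - int(round(config.onset_search_s * fs)))
        seg = corrected[i_lo : i_r + 1]
        sign_ref = np.sign(corrected[i_r]) or 1.0
        crossings = np.flatnonzero(np.diff(np.sign(seg + 1e-30)) != 0)
        if len(crossings):
            onset = (i_lo + int(crossings[-1])) / fs
        else:
            onset = i_lo / fs

        t_time = t_amp = delta = rest = None
        t_support = None
        lo = rt + config.t_search_min_s
        hi = rt + config.t_search_max_rr * rr_fwd
        in_win = np.flatnonzero((E_t_times > lo) & (E_t_times <= hi))
        if len(in_win) and E_t[in_win].max() > 0.0:
            j = in_win[np.argmax(E_t[in_win])]
            t_est = float(E_t_times[j])
            # the subband energy of a wide repolarization hump peaks on
            # its steep edges; refine to the waveform crest of the
            # baseline-corrected signal (sample grid, so the recorded
            # (latency, amplitude) pair refers to one instant)
            s0 = int(np.ceil(max(lo, t_est - config.t_refine_s) * fs))
            s1 = int(np.floor(min(hi, t_est + config.t_refine_s) * fs))
            s0 = max(s0, 0)
            s1 = min(s1, len(x) - 1)
            if s1 >= s0:
                t_idx = s0 + int(np.argmax(np.abs(corrected[s0 : s1 + 1])))
                t_time = t_idx / fs
                t_amp = float(corrected[t_idx])
                if t_time <= rt:
                    t_time = t_amp = None
        if t_time is not None:
            hw = int(round(config.t_support_halfwidth_s * fs))
            t_idx = int(round(t_time * fs))
            a0 = max(int(np.ceil((rt + config.t_search_min_s) * fs)), t_idx - hw)
            a1 = min(len(x) - 1, t_idx + hw)
            if a1 >= a0:
                idx = np.arange(a0, a1 + 1)
                t_support = (idx / fs - rt, corrected[idx].copy())
        if t_time is not None and abs(t_amp) > 0:
            thr = config.rest_threshold_frac * abs(t_amp)
            rest = _find_rest(
                corrected, fs, t_time, rt + config.rest_max_rr * rr_fwd,
                thr, config.rest_hold_s,
            )
            rest_end = min(rest + config.rest_hold_s, (len(x) - 1) / fs)
            # start ahead of the QRS: the depolarization deflection has
            # zero net area, so including it whole makes the integral
            # insensitive to sub-sample error in the R fiducial, whereas
            # starting exactly at the detected peak leaks the truncated
            # spike tail into Delta
            delta_start = max(rt - config.delta_pre_s, 0.0)
            delta = _trapz_fractional(corrected, fs, delta_start, rest_end)
        else:
            n_missing_t += 1
        if rr_i is not None and t_time is not None and t_time - rt >= rr_i:
            t_time = t_amp = delta = rest = t_support = None  # out-of-interval
        beats.append(
            BeatFeatures(
                r_time=rt,
                r_amplitude=float(r_amp),
                t_time=t_time,
                t_amplitude=t_amp,
                delta=delta,
                rr_interval=rr_i,
                onset_time=onset,
                rest_time=rest,
                t_support=t_support,
            )
        )
    if n_missing_t:
        flags.append(f"missing_t:{n_missing_t}")
    return DetectionOutcome(beats=beats, flags=flags, baseline=baseline)


def beats_to_frame(beats) -> pd.DataFrame:
    """Beat features as a DataFrame (the beats-table CSV schema)."""
    rows = [
        {
            "r_time_s": b.r_time,
            "r_amp": b.r_amplitude,
            "t_time_s": b.t_time,
            "t_amp": b.t_amplitude,
            "delta": b.delta,
            "rr_s": b.rr_interval,
        }
        for b in beats
    ]
    return pd.DataFrame(
        rows, columns=["r_time_s", "r_amp", "t_time_s", "t_amp", "delta", "rr_s"]
    )


class BeatDetector(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around :func:`detect_beats`.

    Stateless; ``fit`` validates parameters and returns ``self``;
    ``transform`` maps a 1-D signal to the beats table.
    """

    def __init__(
        self,
        fs: float = 250.0,
        lambda_: float = 0.125,
        r_duration_s: float = 0.10,
        refractory_s: float = 0.25,
        wavelet: str = "db4",
    ):
        self.fs = fs
        self.lambda_ = lambda_
        self.r_duration_s = r_duration_s
        self.refractory_s = refractory_s
        self.wavelet = wavelet

    def _config(self) -> DetectorConfig:
        return DetectorConfig(
            lambda_=self.lambda_,
            r_duration_s=self.r_duration_s,
            refractory_s=self.refractory_s,
        )

    def fit(self, X=None, y=None):
        self._config()  # parameter validation
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        outcome = self.detect(X)
        return beats_to_frame(outcome.beats)

    def detect(self, X) -> DetectionOutcome:
        return detect_beats(
            np.asarray(X, dtype=float).ravel(),
            self.fs,
            config=self._config(),
            spec=WaveletSpec.from_name(self.wavelet),
        )
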