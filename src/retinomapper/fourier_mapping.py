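"""Per-pixel Fourier response at the stimulus frequency.

Each pixel's time course is projected onto a single complex exponential
``exp(-i 2 pi f t)`` (a direct single-bin sum — T need not be a power of
two and only one frequency is needed).  The magnitude of the coefficient,
divided by the pixel's temporal mean, is the fractional modulation
(Delta-R/R-like); the argument is the raw Fourier phase.

Sign convention: intrinsic signals DARKEN on activation, so a response
peaking at time ``t0`` contributes ``-cos(2 pi f (t - t0))`` and its raw
Fourier phase is ``pi - 2 pi f t0``.  :func:`retinotopy_from_phases`
undoes this (``signal_sign=-1`` by default) to recover the package-wide
"phase increases with response time" convention before inverting the
sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movie_io import BinnedMovie
from .stimulus_model import StimulusSpec, phase_to_stimulus_time, stimulus_position_at

__all__ = ["ComplexResponseMap", "RetinotopyPair", "extract_response",
           "retinotopy_from_phases", "map_fidelity"]


@dataclass
class ComplexResponseMap:
    """Per-pixel complex Fourier coefficient at ``f_stim_hz``."""

    coeff: np.ndarray           # H x W complex, raw-count units
    f_stim_hz: float
    n_frames_used: int
    frame_rate_hz: float
    mean_image: np.ndarray      # H x W temporal mean

    @property
    def magnitude_counts(self) -> np.ndarray:
        """Modulation amplitude in raw camera counts."""
        return np.abs(self.coeff)

    @property
    def magnitude(self) -> np.ndarray:
        """Fractional modulation: |coeff| / temporal mean."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.abs(self.coeff) / self.mean_image
        return np.nan_to_num(out, nan=0.0, posinf=0.0)

    @property
    def phase(self) -> np.ndarray:
        """Raw Fourier phase, in [-pi, pi)."""
        p = np.angle(self.coeff)
        # np.angle returns (-pi, pi]; fold +pi onto -pi for the contract
        return np.where(p == np.pi, -np.pi, p)


@dataclass
class RetinotopyPair:
    """Azimuth/elevation preference maps in degrees."""

    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    delay_s: float


def extract_response(movie: BinnedMovie, f_stim_hz: float,
                     subtract_mean: bool = True) -> ComplexResponseMap:
    """Project each pixel's time course onto the stimulus frequency.

    ``coeff[p] = (2 / T) * sum_t x_p[t] * exp(-i 2 pi f t dt)``, with the
    temporal mean removed first by default.  Requires at least two
    stimulus cycles and ``f_stim_hz`` below the Nyquist rate.
    """
    h, w, t = movie.data.shape
    dt = 1.0 / movie.frame_rate_hz
    if f_stim_hz >= movie.frame_rate_hz / 2.0:
        raise ValueError(
            f"f_stim {f_stim_hz} Hz is at or above Nyquist "
            f"({movie.frame_rate_hz / 2} Hz)")
    if t * dt < 2.0 / f_stim_hz:
        raise ValueError(
            f"movie covers {t * dt * f_stim_hz:.2f} stimulus cycles; need >= 2")
    x = movie.data.reshape(h * w, t).astype(np.float64)
    mean = x.mean(axis=1)
    if subtract_mean:
        x = x - mean[:, None]
    kernel = np.exp(-2j * np.pi * f_stim_hz * np.arange(t) * dt)
    coeff = (2.0 / t) * (x @ kernel)
    return ComplexResponseMap(
        coeff=coeff.reshape(h, w),
        f_stim_hz=f_stim_hz,
        n_frames_used=t,
        frame_rate_hz=movie.frame_rate_hz,
        mean_image=mean.reshape(h, w),
    )


def response_phase(cmap: ComplexResponseMap, signal_sign: int = -1) -> np.ndarray:
    """Phase in the "increases with response time" convention.

    ``signal_sign=-1`` (default) treats the signal as a reflectance
    decrease on activation; ``+1`` as an increase.
    """
    if signal_sign not in (-1, 1):
        raise ValueError("signal_sign must be -1 or +1")
    raw = cmap.phase
    if signal_sign == -1:
        return np.mod(np.pi - raw, 2 * np.pi)
    return np.mod(-raw, 2 * np.pi)


def retinotopy_from_phases(
    azi_map: ComplexResponseMap,
    elev_map: ComplexResponseMap,
    azi_spec: StimulusSpec,
    elev_spec: StimulusSpec,
    delay_s: float = 0.0,
    signal_sign: int = -1,
) -> RetinotopyPair:
    """Phase maps -> preferred bar position in degrees, per pixel.

    Per pixel: phase -> time within the sweep cycle (removing the
    hemodynamic delay) -> swept position at that time.
    """
    if azi_map.coeff.shape != elev_map.coeff.shape:
        raise ValueError(
            f"map shapes differ: {azi_map.coeff.shape} vs {elev_map.coeff.shape}")
    out = []
    for cmap, spec in ((azi_map, azi_spec), (elev_map, elev_spec)):
        ph = response_phase(cmap, signal_sign)
        t = phase_to_stimulus_time(ph, spec, delay_s)
        lo, hi = spec.sweep_range_deg
        out.append(lo + (t / spec.period_s) * (hi - lo))
    return RetinotopyPair(azimuth_deg=out[0], elevation_deg=out[1], delay_s=delay_s)


def map_fidelity(movie: BinnedMovie, f_stim_hz: float,
                 brightest_decile: float = 0.1,
                 flank_halfwidth_bins: int = 10,
                 guard_bins: int = 2) -> float:
    """SNR of the stimulus-frequency response, for the map-quality gate.

    Per pixel, the ratio of power at the stimulus frequency to the noise
    power estimated from a flanking band of DFT bins (band median,
    corrected by 1/ln 2 so it is unbiased for exponentially distributed
    noise power; a guard band around the stimulus bin is excluded).  The
    ratio is averaged over the brightest decile of pixels of the response
    map (largest stimulus-band power) and divided by the analytic
    expectation of that top-decile average under pure noise
    (``1 + ln(1/decile)``), so the statistic is ~1 for pure noise and
    >> 1 for a clean retinotopic signal.
    """
    h, w, t = movie.data.shape
    x = movie.data.reshape(h * w, t).astype(np.float64)
    x -= x.mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(x, axis=1)
    freqs = np.fft.rfftfreq(t, d=1.0 / movie.frame_rate_hz)
    stim_bin = int(np.argmin(np.abs(freqs - f_stim_hz)))
    power = np.abs(spectrum) ** 2
    stim_power = power[:, stim_bin]

    lo = max(stim_bin - guard_bins - flank_halfwidth_bins, 1)
    hi = min(stim_bin + guard_bins + flank_halfwidth_bins, power.shape[1] - 1)
    flank_idx = [i for i in range(lo, hi + 1)
                 if abs(i - stim_bin) > guard_bins]
    flank_power = np.median(power[:, flank_idx], axis=1) / np.log(2.0)

    n_top = max(int(round(h * w * brightest_decile)), 1)
    top = np.argsort(stim_power)[-n_top:]
    stim_top, flank_top = stim_power[top], flank_power[top]
    if np.any((flank_top == 0) & (stim_top > 0)):
        return float("inf")  # modulated pixels over a silent noise floor
    with np.errstate(invalid="ignore"):
        snr = np.where(flank_top > 0,
                       stim_top / np.where(flank_top > 0, flank_top, 1.0), 0.0)
    # top-decile mean of Exp(1) is 1 + ln(1/q); dividing by it calibrates
    # the pure-noise expectation to 1
    bias = 1.0 + np.log(1.0 / brightest_decile)
    return float(np.mean(snr) / bias)
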