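"""Multitaper spectral estimation and band-level statistics.

All power estimates use the multitaper method with a single Slepian taper
(time-bandwidth product 1), the minimal-taper setting of the classic
electrophysiology toolboxes. A 500 ms analysis window therefore gives a
2 Hz frequency grid; the 250 ms moving spectrogram window gives 4 Hz.

The central per-subject statistic is the stimulus-induced change in band
power,

    dPower [dB] = 10 * log10( sum_f ST(f) / sum_f BL(f) )

with ST and BL the stimulus-window (250-750 ms) and baseline-window
(-500-0 ms) power spectra summed over the band's bins (inclusive edges).
The sum-then-log order matters: lower-frequency bins carry more absolute
power and dominate the ratio, which is part of the statistic's definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.signal.windows import dpss

__all__ = [
    "BandDefinition",
    "BANDS",
    "PSDEstimate",
    "Spectrogram",
    "BandPowerResult",
    "SlopeFit",
    "ERPResult",
    "BASELINE_WINDOW",
    "STIMULUS_WINDOW",
    "extract_window",
    "multitaper_psd",
    "spectrogram",
    "change_power",
    "delta_power",
    "fit_psd_slope",
    "orientation_selectivity",
    "ssvep_power",
    "compute_erp",
]

BASELINE_WINDOW: Tuple[float, float] = (-0.5, 0.0)
STIMULUS_WINDOW: Tuple[float, float] = (0.25, 0.75)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"bad band {self.name}: [{self.f_lo}, {self.f_hi}]")


#: Built-in analysis bands (Hz).
BANDS: Dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("alpha", 8, 12),
        BandDefinition("slow_gamma", 20, 34),
        BandDefinition("fast_gamma", 36, 66),
        BandDefinition("slow_sensitive", 26, 34),
        BandDefinition("fast_sensitive", 44, 56),
        BandDefinition("combined_gamma", 20, 66),
        BandDefinition("traditional_gamma", 30, 80),
    )
}


@dataclass
class PSDEstimate:
    freqs: np.ndarray          # Hz, spacing 1/T
    power: np.ndarray          # uV^2/Hz, one-sided density, same grid
    window: str = ""           # e.g. "baseline" / "stimulus"
    n_repeats: int = 1

    def band_sum(self, band: BandDefinition) -> float:
        mask = (self.freqs >= band.f_lo) & (self.freqs <= band.f_hi)
        if not mask.any():
            raise ValueError(f"band {band.name} has no bins on this grid")
        return float(np.sum(self.power[mask]))


@dataclass
class Spectrogram:
    times: np.ndarray          # s, window centers
    freqs: np.ndarray          # Hz
    power: np.ndarray          # (n_times, n_freqs), uV^2/Hz


@dataclass
class BandPowerResult:
    band: BandDefinition
    delta_power: float         # dB
    st_sum: float              # summed stimulus band power
    bl_sum: float              # summed baseline band power


@dataclass
class SlopeFit:
    A: float
    beta: float
    fit_band: Tuple[float, float]
    residual: float


@dataclass
class ERPResult:
    time: np.ndarray
    waveform: np.ndarray                       # trial-averaged, uV
    peaks: Dict[str, Tuple[float, float]]      # name -> (latency s, amplitude uV)
    onset_rms: float


def extract_window(time: np.ndarray, t_lo: float, t_hi: float) -> np.ndarray:
    """Boolean mask for t_lo <= t < t_hi (half-open, sample-aligned)."""
    return (time >= t_lo - 1e-9) & (time < t_hi - 1e-9)


@lru_cache(maxsize=32)
def _taper(n: int) -> np.ndarray:
    w = dpss(n, NW=1, Kmax=1)[0]
    return w / np.sqrt(np.sum(w * w))


def multitaper_psd(
    segment: np.ndarray,
    fs: float,
    window: str = "",
    average: bool = True,
) -> PSDEstimate:
    """Single-Slepian-taper PSD of ``segment`` (samples on the last axis).

    Leading axes (repeats, channels, ...) are averaged when ``average`` is
    true; ``n_repeats`` records how many spectra went into the mean. The
    one-sided density satisfies sum(power) * df ~= taper-weighted segment
    variance (Parseval).
    """
    segment = np.asarray(segment, dtype=float)
    if np.isnan(segment).any():
        raise ValueError("segment contains NaN; artifact rejection must precede PSD")
    n = segment.shape[-1]
    w = _taper(n)
    spec = np.fft.rfft(segment * w, axis=-1)
    power = (np.abs(spec) ** 2) / fs
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    n_repeats = int(np.prod(segment.shape[:-1])) if segment.ndim > 1 else 1
    if average and segment.ndim > 1:
        power = power.reshape(-1, power.shape[-1]).mean(axis=0)
    return PSDEstimate(freqs=freqs, power=power, window=window, n_repeats=n_repeats)


def spectrogram(
    epoch: np.ndarray,
    fs: float,
    time: np.ndarray,
    window_s: float = 0.25,
    step_s: float = 0.025,
) -> Spectrogram:
    """Moving-window single-taper spectrogram (250 ms window, 25 ms step).

    Window start samples are placed at round(k * fs * step_s); at fs values
    where the step is not an integer number of samples, successive spacings
    alternate around the nominal step with the correct mean.
    """
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    wlen = int(round(window_s * fs))
    if n < wlen:
        raise ValueError("epoch shorter than one spectrogram window")
    starts = np.unique(np.round(np.arange(0, n - wlen + 1e-9, step_s * fs)).astype(int))
    starts = starts[starts + wlen <= n]
    segs = np.stack([epoch[..., s : s + wlen] for s in starts], axis=-2)
    w = _taper(wlen)
    spec = np.fft.rfft(segs * w, axis=-1)
    power = (np.abs(spec) ** 2) / fs
    power[..., 1:] *= 2.0
    if wlen % 2 == 0:
        power[..., -1] /= 2.0
    if power.ndim > 2:
        power = power.reshape(-1, power.shape[-2], power.shape[-1]).mean(axis=0)
    freqs = np.fft.rfftfreq(wlen, d=1.0 / fs)
    centers = time[starts] + (wlen - 1) / (2 * fs)
    return Spectrogram(times=centers, freqs=freqs, power=power)


def change_power(
    spec: Spectrogram, baseline: Tuple[float, float] = BASELINE_WINDOW, window_s: float = 0.25
) -> np.ndarray:
    """Change-in-power spectrogram, dB re mean baseline power per frequency.

    Baseline windows are those lying fully inside the baseline interval.
    """
    half = window_s / 2
    in_bl = (spec.times - half >= baseline[0] - 1e-9) & (spec.times + half <= baseline[1] + 1e-9)
    if not in_bl.any():
        raise ValueError("no spectrogram window fully inside the baseline interval")
    bl = spec.power[in_bl].mean(axis=0)
    return 10.0 * np.log10(spec.power / bl)


def delta_power(st: PSDEstimate, bl: PSDEstimate, band: BandDefinition) -> BandPowerResult:
    """Stimulus-induced change in band power, 10*log10(sum ST / sum BL)."""
    if st.freqs.shape != bl.freqs.shape or not np.allclose(st.freqs, bl.freqs):
        raise ValueError("stimulus and baseline spectra are on different grids")
    st_sum = st.band_sum(band)
    bl_sum = bl.band_sum(band)
    if bl_sum <= 0:
        raise ValueError(f"baseline power in band {band.name} is not positive")
    return BandPowerResult(
        band=band, delta_power=10.0 * np.log10(st_sum / bl_sum), st_sum=st_sum, bl_sum=bl_sum
    )


def fit_psd_slope(
    psd: PSDEstimate, band: Tuple[float, float] = (56.0, 84.0), refine: bool = True
) -> SlopeFit:
    """Fit P(f) = A * f**(-beta) over ``band``.

    Closed-form log-log regression seeds a Nelder-Mead simplex refinement of
    the squared error in the linear power domain (``refine=False`` skips the
    simplex and keeps the closed-form estimate, which has the same sign and
    is much cheaper inside the rejection cascade). Requires at least five
    strictly positive bins in the band.
    """
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    f = psd.freqs[mask]
    p = np.atleast_1d(np.squeeze(psd.power))[mask]
    if f.size < 5:
        raise ValueError("need at least 5 bins in the slope-fit band")
    if np.any(p <= 0):
        raise ValueError("non-positive power in slope-fit band")
    # log-log least squares: log p = log A - beta log f
    slope, intercept = np.polyfit(np.log(f), np.log(p), 1)
    beta0, logA0 = -slope, intercept

    def sse(theta):
        logA, beta = theta
        return float(np.sum((p - np.exp(logA) * f ** (-beta)) ** 2))

    if not refine:
        return SlopeFit(A=float(np.exp(logA0)), beta=float(beta0), fit_band=band,
                        residual=sse([logA0, beta0]))
    res = minimize(sse, x0=[logA0, beta0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-24, "maxiter": 2000})
    logA, beta = res.x
    return SlopeFit(A=float(np.exp(logA)), beta=float(beta), fit_band=band,
                    residual=float(res.fun))


def orientation_selectivity(
    R: Sequence[float], thetas_deg: Sequence[float] = (0.0, 45.0, 90.0, 135.0)
) -> float:
    """Circular orientation selectivity |sum R_i exp(j 2 theta_i)| / sum R_i.

    ``R`` holds absolute stimulus-window band power per orientation (already
    averaged across spatial frequencies); the result lies in [0, 1].
    """
    R = np.asarray(R, dtype=float)
    th = np.deg2rad(np.asarray(thetas_deg, dtype=float))
    if R.shape != th.shape:
        raise ValueError("R and thetas must have matching lengths")
    if np.any(R < 0):
        raise ValueError("powers must be non-negative")
    total = R.sum()
    if total <= 0:
        raise ValueError("sum of powers is zero; selectivity undefined")
    return float(np.abs(np.sum(R * np.exp(2j * th))) / total)


def ssvep_power(
    epochs: np.ndarray,
    fs: float,
    time: np.ndarray,
    freq: float = 32.0,
    stimulus: Tuple[float, float] = STIMULUS_WINDOW,
    baseline: Tuple[float, float] = BASELINE_WINDOW,
) -> BandPowerResult:
    """Change in power at the steady-state response frequency (32 Hz for
    16 cps counterphase gratings), stimulus window vs baseline window.

    Errors if ``freq`` does not land on the analysis-window frequency grid.
    """
    st = multitaper_psd(epochs[..., extract_window(time, *stimulus)], fs, "stimulus")
    bl = multitaper_psd(epochs[..., extract_window(time, *baseline)], fs, "baseline")
    if not np.isclose(st.freqs, freq).any():
        raise ValueError(f"{freq} Hz is not on the {st.freqs[1] - st.freqs[0]} Hz grid")
    band = BandDefinition(f"ssvep_{freq:g}Hz", freq - 1e-6, freq + 1e-6)
    return delta_power(st, bl, band)


def compute_erp(
    epochs: np.ndarray,
    time: np.ndarray,
    baseline: Tuple[float, float] = BASELINE_WINDOW,
    p1_window: Tuple[float, float] = (0.075, 0.125),
    n1_window: Tuple[float, float] = (0.125, 0.200),
    p2_window: Tuple[float, float] = (0.175, 0.300),
    onset_window: Tuple[float, float] = (0.0, 0.250),
) -> ERPResult:
    """Trial-averaged evoked response with P1/N1/P2 peaks and onset RMS.

    Each epoch is baseline-mean corrected before averaging. Peak windows are
    conventional visual-ERP defaults and configurable. Requires >= 10 epochs.
    """
    epochs = np.asarray(epochs, dtype=float)
    flat = epochs.reshape(-1, epochs.shape[-1]) if epochs.ndim > 1 else epochs[None, :]
    if flat.shape[0] < 10:
        raise ValueError("need at least 10 clean repeats for an ERP")
    for w in (p1_window, n1_window, p2_window, onset_window, baseline):
        if w[0] < time[0] - 1e-9 or w[1] > time[-1] + 1e-9:
            raise ValueError(f"window {w} outside the epoch")
    bl_mask = extract_window(time, *baseline)
    corrected = flat - flat[:, bl_mask].mean(axis=1, keepdims=True)
    avg = corrected.mean(axis=0)

    def peak(window, sign):
        m = extract_window(time, *window)
        idx = np.argmax(sign * avg[m])
        return float(time[m][idx]), float(avg[m][idx])

    peaks = {"P1": peak(p1_window, +1), "N1": peak(n1_window, -1), "P2": peak(p2_window, +1)}
    om = extract_window(time, *onset_window)
    return ERPResult(time=time, waveform=avg, peaks=peaks,
                     onset_rms=float(np.sqrt(np.mean(avg[om] ** 2))))
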