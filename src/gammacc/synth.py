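"""Synthetic elderly-cohort EEG + eye-trace generator.

The generator is a forward model of the statistical structure the analysis
assumes, not a biophysical simulation. Per channel it sums:

* 1/f background noise with power-law PSD ``A * f**(-beta)``,
* narrow-band alpha (8-12 Hz filtered noise) that is suppressed by the
  stimulus,
* stimulus-gated slow (20-34 Hz) and fast (36-66 Hz) gamma, realised as
  amplitude-gated band-pass-filtered Gaussian noise (4th-order Butterworth,
  zero-phase) switching on 50 ms after stimulus onset,
* a 32 Hz steady-state component for counterphase (16 cps) trials,
* a P1/N1/P2-like evoked transient built from signed Gaussians
  (group-independent by design).

Oscillatory components are independent across channels and scaled by a
smooth occipito-parietal gain map; case groups (MCI/AD) carry a gamma
amplitude deficit while alpha and the evoked response are group-neutral, so
the generator makes the analysis null (alpha) and alternative (gamma)
simultaneously true. Eye traces carry slow fixational drift, ballistic
minimum-jerk microsaccades with a lawful main sequence, blinks as NaN runs,
and a stimulus-evoked pupil constriction.

A single integer seed drives a hierarchical RNG (cohort -> subject ->
condition block), so any subset of the cohort regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt, sosfreqz

from .eye import EyeTrace
from .montage import build_layout

__all__ = [
    "SubjectProfile",
    "StimulusCondition",
    "GeneratorParams",
    "TrialRecording",
    "MatchingError",
    "generate_trial",
    "generate_cohort",
    "inject_artifacts",
    "calibrate_gamma_amp",
    "erp_template",
    "GAMMA_EXPERIMENT_CONDITIONS",
]

_GROUPS = ("healthy", "MCI", "AD")
_GENDERS = ("male", "female")
_CDR_BY_GROUP = {"healthy": (0.0,), "MCI": (0.5,), "AD": (1.0, 3.0)}


class MatchingError(RuntimeError):
    """A case subject cannot be given an age/gender-matched control."""


@dataclass(frozen=True)
class SubjectProfile:
    id: str
    age: int
    gender: str
    group: str
    cdr: float

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.gender not in _GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if not 50 <= self.age <= 92:
            raise ValueError(f"age {self.age} outside 50-92")
        if self.cdr not in _CDR_BY_GROUP[self.group]:
            raise ValueError(f"CDR {self.cdr} inconsistent with group {self.group}")


@dataclass(frozen=True)
class StimulusCondition:
    spatial_frequency: int = 2      # cycles per degree
    orientation: int = 0            # degrees
    temporal_frequency: int = 0     # cycles per second; 16 = counterphase

    def __post_init__(self) -> None:
        if self.spatial_frequency not in (1, 2, 4):
            raise ValueError("spatial frequency must be 1, 2 or 4 cpd")
        if self.orientation not in (0, 45, 90, 135):
            raise ValueError("orientation must be one of 0/45/90/135 deg")
        if self.temporal_frequency not in (0, 16):
            raise ValueError("temporal frequency must be 0 (static) or 16 cps")


#: Full static-grating stimulus set: 3 spatial frequencies x 4 orientations.
GAMMA_EXPERIMENT_CONDITIONS: Tuple[StimulusCondition, ...] = tuple(
    StimulusCondition(sf, ori, 0) for sf in (1, 2, 4) for ori in (0, 45, 90, 135)
)


@dataclass
class GeneratorParams:
    """Forward-model parameters. Amplitudes are uV at unit topographic gain."""

    fs: float = 500.0
    epoch: Tuple[float, float] = (-1.0, 0.8)
    background_A: float = 20.0           # uV^2/Hz at 1 Hz
    background_beta: float = 1.8         # 1/f exponent
    alpha_power: float = 4.0             # uV^2 variance of the alpha component
    alpha_band: Tuple[float, float] = (8.0, 12.0)
    alpha_suppression: float = 0.5       # stimulus amplitude ratio (<1 suppresses)
    gamma_amp: Dict[str, float] = field(default_factory=lambda: {"slow": 1.5, "fast": 1.3})
    gamma_bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"slow": (20.0, 34.0), "fast": (36.0, 66.0)}
    )
    deficit_factor: Dict[str, float] = field(
        default_factory=lambda: {"healthy": 1.0, "MCI": 0.6, "AD": 0.6}
    )
    sf_gamma_factor: Dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 1.0, 4: 1.0}
    )
    gamma_onset_latency: float = 0.05    # s after stimulus onset
    ramp: float = 0.02                   # s, cosine on/off ramp for gates
    ssvep_amp: float = 1.5               # uV, 32 Hz component on counterphase trials
    erp_amp: float = 3.0                 # uV, evoked-transient scale
    subject_sigma: float = 0.25          # lognormal sigma of per-subject amplitudes
    topography_base: float = 0.3         # floor of the occipito-parietal gain map
    topography_sigma: float = 0.6        # gain-map width in layout units
    artifact_rate: float = 0.02          # per-repeat transient probability
    artifact_scale: float = 8.0          # transient size in channel SDs
    saccade_rate: float = 0.6            # microsaccades per second
    saccade_sd: float = 0.25             # deg, SD of fixation-offset targets
    saccade_duration: float = 0.02       # s, ballistic movement duration
    blink_rate: float = 0.1              # blinks per second
    blink_duration: float = 0.15         # s
    jitter_sd: float = 0.15              # deg, fixational drift SD
    jitter_tau: float = 0.2              # s, drift correlation time
    jitter_cutoff: float = 10.0          # Hz, drift low-pass (drift is slow)
    tracker_noise: float = 0.003         # deg, residual measurement noise
    pupil_base: float = 1000.0           # arbitrary units
    pupil_response: float = 0.08         # fractional stimulus-evoked constriction
    pupil_noise: float = 5.0
    channels: Optional[Tuple[str, ...]] = None   # None = all 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * 84:
            raise ValueError("fs must exceed twice the 84 Hz slope-band edge")
        for name, amp in self.gamma_amp.items():
            if amp < 0:
                raise ValueError(f"gamma amplitude {name} must be >= 0")
        for g, d in self.deficit_factor.items():
            if not 0 < d <= 1:
                raise ValueError(f"deficit_factor[{g}] must be in (0, 1]")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch[1] - self.epoch[0]) * self.fs))

    @property
    def time(self) -> np.ndarray:
        return self.epoch[0] + np.arange(self.n_samples) / self.fs

    def channel_names(self) -> Tuple[str, ...]:
        return self.channels if self.channels is not None else _all_channels()


@dataclass
class TrialRecording:
    data: np.ndarray                 # (n_channels, n_samples), uV
    time: np.ndarray                 # s re stimulus onset
    channel_names: Tuple[str, ...]
    condition: StimulusCondition
    eye: EyeTrace
    repeat_index: int = 0


@lru_cache(maxsize=1)
def _layout_coords() -> Dict[str, Tuple[float, float]]:
    return dict(build_layout().entries)


@lru_cache(maxsize=1)
def _all_channels() -> Tuple[str, ...]:
    return tuple(_layout_coords())


def _topography(params: GeneratorParams) -> np.ndarray:
    """Occipito-parietal amplitude gain per generated channel."""
    coords = _layout_coords()
    cx, cy = coords["Oz"]
    gains = []
    for name in params.channel_names():
        x, y = coords[name]
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        gains.append(
            params.topography_base
            + (1 - params.topography_base) * np.exp(-d2 / (2 * params.topography_sigma**2))
        )
    return np.asarray(gains)


@lru_cache(maxsize=32)
def _band_psd_shape(fs: float, lo: float, hi: float, n: int) -> np.ndarray:
    """Unit-variance PSD of white noise passed through a zero-phase
    4th-order Butterworth band-pass (|H|^4 on the rFFT grid)."""
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    _, h = sosfreqz(sos, worN=freqs, fs=fs)
    psd = np.abs(h) ** 4  # forward + backward pass squares the magnitude
    df = fs / n
    var = np.sum(psd) * df  # one-sided integral (rFFT grid)
    return psd / var


def _noise_from_psd(
    rng: np.random.Generator, shape: Tuple[int, ...], fs: float, psd: np.ndarray
) -> np.ndarray:
    """Gaussian noise with the given one-sided PSD on the rFFT grid,
    synthesized in the frequency domain (float32 internals)."""
    n = shape[-1]
    scale = np.sqrt(psd * fs * n / 4.0).astype(np.float32)
    zshape = shape[:-1] + (psd.size,)
    z = rng.standard_normal(zshape, dtype=np.float32) + 1j * rng.standard_normal(
        zshape, dtype=np.float32
    )
    return np.fft.irfft(z * scale, n=n, axis=-1)


def _filtered_noise(
    rng: np.random.Generator, shape: Tuple[int, ...], fs: float, band: Tuple[float, float]
) -> np.ndarray:
    """Band-limited Gaussian noise with the spectral shape of zero-phase
    4th-order Butterworth filtering, unit variance, synthesized spectrally
    (statistically identical to filtering white noise, without the cost or
    the edge transients)."""
    return _noise_from_psd(rng, shape, fs, _band_psd_shape(fs, band[0], band[1], shape[-1]))


def _one_over_f(
    rng: np.random.Generator, shape: Tuple[int, ...], fs: float, A: float, beta: float
) -> np.ndarray:
    """Gaussian noise with one-sided PSD A * f**(-beta), exact power law on
    the FFT grid, zero DC."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    psd[1:] = A * freqs[1:] ** (-beta)
    return _noise_from_psd(rng, shape, fs, psd)


def _gate(time: np.ndarray, t_on: float, t_off: float, ramp: float) -> np.ndarray:
    """Cosine-ramped on/off gate in [0, 1]."""
    g = np.zeros_like(time)
    g[(time >= t_on + ramp) & (time < t_off - ramp)] = 1.0
    up = (time >= t_on) & (time < t_on + ramp)
    g[up] = 0.5 * (1 - np.cos(np.pi * (time[up] - t_on) / ramp))
    dn = (time >= t_off - ramp) & (time < t_off)
    g[dn] = 0.5 * (1 + np.cos(np.pi * (time[dn] - (t_off - ramp)) / ramp))
    return g


def erp_template(time: np.ndarray, amp: float = 1.0) -> np.ndarray:
    """Signed-Gaussian evoked transient with P1 (100 ms), N1 (170 ms) and
    P2 (230 ms) peaks, in uV for unit topographic gain."""

    def g(mu, sd):
        return np.exp(-0.5 * ((time - mu) / sd) ** 2)

    # narrow components: the transient is essentially over by 250 ms, which
    # is why the stimulus analysis window starts there
    out = amp * (0.8 * g(0.100, 0.015) - 1.0 * g(0.170, 0.020) + 0.9 * g(0.230, 0.018))
    out[time < 0] = 0.0
    return out


def _min_jerk(n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@lru_cache(maxsize=8)
def _lowpass_sos(fs: float, cutoff: float) -> np.ndarray:
    return butter(4, cutoff, btype="lowpass", fs=fs, output="sos")


def _ou_block(
    rng: np.random.Generator, m: int, n: int, dt: float, sd: float, tau: float
) -> np.ndarray:
    """m stationary AR(1) (Ornstein-Uhlenbeck) rows of length n."""
    a = np.exp(-dt / tau)
    e = rng.standard_normal((m, n)) * (sd * np.sqrt(1 - a * a))
    e[:, 0] = rng.normal(0, sd, m)
    return lfilter([1.0], [1.0, -a], e, axis=-1)


def _saccades_and_blinks(params: GeneratorParams, rng: np.random.Generator):
    """Per-trial ballistic fixation-offset path, ground-truth events, and a
    blink mask."""
    time = params.time
    n = params.n_samples
    duration = params.epoch[1] - params.epoch[0]
    n_sacc = rng.poisson(params.saccade_rate * duration)
    t_sorted = np.sort(rng.uniform(params.epoch[0] + 0.05, params.epoch[1] - 0.05, n_sacc))
    t_sacc: List[float] = []
    for t in t_sorted:  # enforce a 100 ms refractory gap between saccades
        if not t_sacc or t - t_sacc[-1] >= 0.1:
            t_sacc.append(float(t))
    off_x = np.zeros(n)
    off_y = np.zeros(n)
    cur = np.array([rng.normal(0, 0.1), rng.normal(0, 0.1)])
    pos = cur.copy()
    events = []
    nm = max(2, int(round(params.saccade_duration * params.fs)))
    prof = _min_jerk(nm)
    pointer = 0
    for t0 in t_sacc:
        i0 = int(round((t0 - params.epoch[0]) * params.fs))
        if i0 + nm >= n or i0 <= pointer:
            continue
        for _ in range(100):
            target = rng.normal(0, params.saccade_sd, size=2)
            amp = float(np.hypot(*(target - pos)))
            if 0.15 <= amp <= 1.2 and np.all(np.abs(target) < 1.5):
                break
        step = target - pos
        off_x[i0 : i0 + nm] = pos[0] + step[0] * prof
        off_y[i0 : i0 + nm] = pos[1] + step[1] * prof
        off_x[i0 + nm :] = target[0]
        off_y[i0 + nm :] = target[1]
        off_x[pointer:i0] = pos[0]
        off_y[pointer:i0] = pos[1]
        events.append(
            {
                "onset": time[i0],
                "offset": time[i0 + nm - 1],
                "amplitude": amp,
                "peak_velocity": 1.875 * amp / params.saccade_duration,
            }
        )
        pos = target
        pointer = i0 + nm
    off_x[pointer:] = pos[0]
    off_y[pointer:] = pos[1]
    if not events:
        off_x[:] = cur[0]
        off_y[:] = cur[1]

    blink = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(params.blink_rate * duration)
    for _ in range(n_blinks):
        t0 = rng.uniform(params.epoch[0], params.epoch[1])
        dur = params.blink_duration * rng.uniform(0.8, 1.2)
        blink |= (time >= t0) & (time < t0 + dur)
    return off_x, off_y, tuple(events), blink


def _generate_eyes(
    params: GeneratorParams, rng: np.random.Generator, n_trials: int
) -> List[EyeTrace]:
    """Eye traces for a block, with drift/pupil noise vectorized across
    trials and per-trial microsaccade/blink structure."""
    time = params.time
    n = params.n_samples
    dt = 1.0 / params.fs
    xy = _ou_block(rng, 2 * n_trials, n, dt, params.jitter_sd, params.jitter_tau)
    # drift is slow: remove the OU process's unphysiological high-frequency
    # content so data-driven velocity thresholds behave as on real traces
    sos = _lowpass_sos(params.fs, params.jitter_cutoff)
    xy = sosfiltfilt(sos, xy, axis=-1)
    pn = _ou_block(rng, n_trials, n, dt, params.pupil_noise, 0.3)
    tracker = rng.normal(0, params.tracker_noise, (2 * n_trials, n))
    bump = np.where(time > 0, (time / 0.3) * np.exp(1 - time / 0.3), 0.0)
    pupil_mean = params.pupil_base * (1 - params.pupil_response * bump)

    traces = []
    for k in range(n_trials):
        off_x, off_y, events, blink = _saccades_and_blinks(params, rng)
        x = xy[k] + tracker[k] + off_x
        y = xy[n_trials + k] + tracker[n_trials + k] + off_y
        pupil = pupil_mean + pn[k]
        x[blink] = np.nan
        y[blink] = np.nan
        pupil[blink] = np.nan
        traces.append(EyeTrace(time=time, x=x, y=y, pupil=pupil, true_events=events))
    return traces


def _generate_block(
    profile: SubjectProfile,
    condition: StimulusCondition,
    params: GeneratorParams,
    rng: np.random.Generator,
    n_trials: int,
    gamma_factor: float = 1.0,
    alpha_factor: float = 1.0,
    first_repeat_index: int = 0,
) -> List[TrialRecording]:
    """Vectorized generation of ``n_trials`` repeats of one condition."""
    ch = params.channel_names()
    n_ch = len(ch)
    n = params.n_samples
    time = params.time
    gains = _topography(params).astype(np.float32)[:, None]

    data = _one_over_f(rng, (n_trials, n_ch, n), params.fs, params.background_A,
                       params.background_beta)

    t_on = params.gamma_onset_latency
    t_off = params.epoch[1]
    alpha_env = (1.0 + (params.alpha_suppression - 1.0)
                 * _gate(time, t_on, t_off + params.ramp, params.ramp)).astype(np.float32)
    alpha = _filtered_noise(rng, (n_trials, n_ch, n), params.fs, params.alpha_band)
    data += alpha * (np.float32(np.sqrt(params.alpha_power) * alpha_factor) * gains) * alpha_env

    deficit = params.deficit_factor[profile.group]
    sf_fac = params.sf_gamma_factor.get(condition.spatial_frequency, 1.0)
    gamma_env = _gate(time, t_on, t_off + params.ramp, params.ramp)
    # the two independent band carriers share the stimulus gate, so they sum
    # to a single Gaussian process with the summed PSD
    psd_tot = np.zeros(n // 2 + 1)
    for band_name, band in params.gamma_bands.items():
        amp = params.gamma_amp.get(band_name, 0.0) * deficit * sf_fac * gamma_factor
        if amp > 0:
            psd_tot = psd_tot + amp**2 * _band_psd_shape(params.fs, band[0], band[1], n)
    if psd_tot.any():
        carrier = _noise_from_psd(rng, (n_trials, n_ch, n), params.fs, psd_tot)
        data += carrier * gains * gamma_env.astype(np.float32)

    if condition.temporal_frequency == 16 and params.ssvep_amp > 0:
        all_idx = {name: i for i, name in enumerate(_all_channels())}
        phases = np.array([2 * np.pi * ((0.6180339887 * all_idx[c] + 0.1) % 1.0) for c in ch])
        ssvep_env = _gate(time, 0.0, t_off + params.ramp, params.ramp)
        tone = np.sin(2 * np.pi * 32.0 * time[None, :] + phases[:, None])
        data += (params.ssvep_amp * gains * tone * ssvep_env).astype(np.float32)

    if params.erp_amp > 0:
        data += (erp_template(time, params.erp_amp) * gains).astype(np.float32)

    eyes = _generate_eyes(params, rng, n_trials)
    return [
        TrialRecording(
            data=data[k].astype(np.float32),
            time=time,
            channel_names=ch,
            condition=condition,
            eye=eyes[k],
            repeat_index=first_repeat_index + k,
        )
        for k in range(n_trials)
    ]


def generate_trial(
    subject: SubjectProfile,
    condition: StimulusCondition,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> TrialRecording:
    """One stimulus repeat for ``subject``; deterministic given ``rng`` state."""
    return _generate_block(subject, condition, params, rng, n_trials=1)[0]


def inject_artifacts(
    trial: TrialRecording,
    params: GeneratorParams,
    rng: np.random.Generator,
    mode: str = "transient",
    electrodes: Optional[Sequence[str]] = None,
) -> TrialRecording:
    """Return a copy of ``trial`` with artifacts injected.

    ``transient`` adds a high-amplitude Gaussian bump (``artifact_scale``
    channel SDs, well above the 6-MAD flagging threshold) with probability
    ``artifact_rate``; ``rising`` replaces an electrode's signal with noise
    whose spectrum rises with frequency, so the fitted power-law slope
    becomes negative and trips the slope rule.
    """
    data = trial.data.astype(np.float64).copy()
    names = list(trial.channel_names)
    if mode == "transient":
        if rng.uniform() < params.artifact_rate:
            if electrodes is None:
                picks = rng.choice(len(names), size=min(2, len(names)), replace=False)
            else:
                picks = [names.index(e) for e in electrodes]
            t0 = rng.uniform(trial.time[0] + 0.05, trial.time[-1] - 0.05)
            bump = np.exp(-0.5 * ((trial.time - t0) / 0.01) ** 2)
            for c in picks:
                data[c] += params.artifact_scale * np.std(data[c]) * bump
    elif mode == "rising":
        picks = (
            [names.index(e) for e in electrodes]
            if electrodes is not None
            else [int(rng.integers(len(names)))]
        )
        for c in picks:
            var = float(np.var(data[c]))
            # steeply rising PSD (f^2) so the fitted power-law exponent is
            # reliably negative even from a modest number of repeats
            repl = _one_over_f(rng, (trial.data.shape[-1],), params.fs, 1.0, -2.0)
            data[c] = repl * np.sqrt(var / np.var(repl))
    else:
        raise ValueError(f"unknown artifact mode {mode!r}")
    return replace(trial, data=data.astype(np.float32))


def _draw_profile(
    rng: np.random.Generator, idx: int, group: str, age: Optional[int] = None,
    gender: Optional[str] = None,
) -> SubjectProfile:
    age = int(rng.integers(50, 93)) if age is None else age
    gender = _GENDERS[int(rng.integers(2))] if gender is None else gender
    cdrs = _CDR_BY_GROUP[group]
    cdr = cdrs[0] if len(cdrs) == 1 else float(rng.choice(cdrs, p=[0.8, 0.2]))
    return SubjectProfile(id=f"{group[:1].lower()}{idx:03d}", age=age, gender=gender,
                          group=group, cdr=cdr)


def _has_match(case: SubjectProfile, pool: Sequence[SubjectProfile]) -> bool:
    return any(abs(p.age - case.age) <= 1 and p.gender == case.gender for p in pool)


def generate_cohort(
    n_healthy: int,
    n_mci: int,
    n_ad: int,
    repeats_per_condition: int,
    params: GeneratorParams,
    conditions: Optional[Sequence[StimulusCondition]] = None,
) -> List[Tuple[SubjectProfile, List[TrialRecording]]]:
    """Generate a cohort with guaranteed age (+-1 year) / gender matching.

    Case profiles are resampled (up to 500 draws, then pinned to a random
    control's demographics) until every case has at least one matched
    healthy control; :class:`MatchingError` is raised when that is
    impossible (no healthy subjects). Per-subject trial lists cover
    ``conditions`` (default: the full 12-condition static-grating set) with
    ``repeats_per_condition`` repeats each, artifact injection included.
    """
    if min(n_healthy, n_mci, n_ad, repeats_per_condition) < 0:
        raise ValueError("counts must be non-negative")
    if (n_mci + n_ad) > 0 and n_healthy == 0:
        raise MatchingError("cases requested but no healthy controls to match")
    conditions = tuple(conditions) if conditions is not None else GAMMA_EXPERIMENT_CONDITIONS

    root = np.random.SeedSequence(params.seed)
    ss_profiles, ss_subjects = root.spawn(2)
    prof_rng = np.random.default_rng(ss_profiles)

    healthy = [_draw_profile(prof_rng, i, "healthy") for i in range(n_healthy)]
    cases: List[SubjectProfile] = []
    for j, group in enumerate(["MCI"] * n_mci + ["AD"] * n_ad):
        prof = None
        for _ in range(500):
            cand = _draw_profile(prof_rng, j, group)
            if _has_match(cand, healthy):
                prof = cand
                break
        if prof is None:
            anchor = healthy[int(prof_rng.integers(len(healthy)))]
            age = int(np.clip(anchor.age + int(prof_rng.integers(-1, 2)), 50, 92))
            prof = _draw_profile(prof_rng, j, group, age=age, gender=anchor.gender)
            if not _has_match(prof, healthy):
                prof = _draw_profile(prof_rng, j, group, age=anchor.age, gender=anchor.gender)
        cases.append(prof)

    subjects = healthy + cases
    cohort = []
    for prof, ss in zip(subjects, ss_subjects.spawn(len(subjects))):
        rng = np.random.default_rng(ss)
        gamma_factor = float(np.exp(params.subject_sigma * rng.standard_normal()))
        alpha_factor = float(np.exp(params.subject_sigma * rng.standard_normal()))
        trials: List[TrialRecording] = []
        for cond in conditions:
            block = _generate_block(
                prof, cond, params, rng, repeats_per_condition,
                gamma_factor=gamma_factor, alpha_factor=alpha_factor,
                first_repeat_index=len(trials),
            )
            if params.artifact_rate > 0:
                block = [inject_artifacts(t, params, rng) for t in block]
            trials.extend(block)
        cohort.append((prof, trials))
    return cohort


def calibrate_gamma_amp(
    params: GeneratorParams,
    band_name: str,
    power_ratio: float,
    channel: str = "Oz",
    n_trials: int = 200,
    seed: int = 12345,
) -> float:
    """Amplitude that forces the stimulus/baseline band-power ratio.

    Simulates ``n_trials`` repeats twice (gamma off, and unit amplitude in
    ``band_name``), measures the single-taper band sums at ``channel`` in
    the standard analysis windows, and solves for the amplitude giving
    ``power_ratio``. Deterministic for fixed ``seed``.
    """
    from .spectral import BandDefinition, extract_window, multitaper_psd

    band = BandDefinition(band_name, *params.gamma_bands[band_name])
    subj = SubjectProfile("cal000", 70, "male", "healthy", 0.0)
    cond = StimulusCondition(2, 0, 0)
    time = params.time
    bl_m = extract_window(time, -0.5, 0.0)
    st_m = extract_window(time, 0.25, 0.75)

    def band_sums(amps: Dict[str, float]) -> Tuple[float, float]:
        p = replace(params, gamma_amp=amps, channels=(channel,), artifact_rate=0.0)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        block = _generate_block(subj, cond, p, rng, n_trials)
        data = np.stack([t.data[0] for t in block]).astype(float)
        st = multitaper_psd(data[:, st_m], params.fs)
        bl = multitaper_psd(data[:, bl_m], params.fs)
        return st.band_sum(band), bl.band_sum(band)

    zero = {k: 0.0 for k in params.gamma_amp}
    st0, bl0 = band_sums(zero)
    st1, _ = band_sums({**zero, band_name: 1.0})
    unit_gain = st1 - st0
    target = power_ratio * bl0 - st0
    if target <= 0 or unit_gain <= 0:
        raise ValueError("requested power ratio is below the gamma-free floor")
    return float(np.sqrt(target / unit_gain))
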