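"""Per-subject analysis pipeline and matched case-control comparison.

Order of operations per subject, mirroring the study design:
fixation-break screening -> artifact cascade -> bipolar re-referencing ->
condition filtering (spatial frequencies 2 and 4 cpd for the gamma
analysis; counterphase trials only for the steady-state analysis) ->
per-repeat single-taper spectra -> averaging across repeats and the clean
analysis pairs -> band power change. Subjects whose block fails the
three-group pair rule are excluded with a logged reason.

Group comparison is pairwise: each case against the mean change in power
of its age/gender-matched controls, with bootstrap medians,
Kruskal-Wallis, directional Bayes factors (right-tailed for gamma bands,
left-tailed for alpha) and the CDR regression in matched and unmatched
form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import spectral
from .artifacts import RejectionParams, apply_cascade, flag_repeats_per_electrode
from .eye import EyeParams, detect_fixation_breaks, detect_microsaccades, pupil_cv
from .montage import apply_bipolar, build_layout, derive_bipolar
from .spectral import BandDefinition, PSDEstimate
from .stats import (
    MatchingError,
    bayes_factor_paired_t,
    bootstrap_median,
    fit_linear_model,
    kruskal_wallis,
    match_controls,
)
from .synth import (
    GeneratorParams,
    StimulusCondition,
    SubjectProfile,
    TrialRecording,
    generate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SubjectSummary",
    "run_subject",
    "run_comparison",
    "effect_pattern_replicate",
    "effect_pattern_rates",
    "ANALYSIS_ELECTRODES",
]

#: Unipolar electrodes feeding the nine analysis pairs.
ANALYSIS_ELECTRODES: Tuple[str, ...] = (
    "PO3", "P1", "P3", "POz", "PO4", "P2", "P4", "Oz", "O1", "O2"
)


@lru_cache(maxsize=1)
def _montage():
    return derive_bipolar(build_layout())


@dataclass
class PipelineConfig:
    """Every analysis parameter in one place (YAML round-trippable)."""

    bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (8, 12), "slow_gamma": (20, 34),
                                 "fast_gamma": (36, 66)}
    )
    baseline_window: Tuple[float, float] = spectral.BASELINE_WINDOW
    stimulus_window: Tuple[float, float] = spectral.STIMULUS_WINDOW
    rejection: RejectionParams = field(default_factory=RejectionParams)
    eye: EyeParams = field(default_factory=EyeParams)
    spatial_frequencies: Tuple[int, ...] = (2, 4)
    orientations: Tuple[int, ...] = (0, 45, 90, 135)
    microsaccade_filter: str = "none"        # none | without | with
    ssvep_freq: float = 32.0
    n_boot: int = 10000
    bf_prior_scale: float = 1.0
    limit_controls: Optional[int] = None
    pool_cases: bool = True                  # MCI and AD pooled as cases
    slope_refine: bool = True
    seed: int = 0

    def band_defs(self) -> Dict[str, BandDefinition]:
        return {name: BandDefinition(name, lo, hi) for name, (lo, hi) in self.bands.items()}

    def to_yaml(self, path) -> None:
        payload = {
            "bands": {k: list(v) for k, v in self.bands.items()},
            "baseline_window": list(self.baseline_window),
            "stimulus_window": list(self.stimulus_window),
            "rejection": vars(self.rejection) | {"slope_band": list(self.rejection.slope_band),
                                                 "analysis_window": list(self.rejection.analysis_window)},
            "eye": vars(self.eye) | {"analysis_window": list(self.eye.analysis_window)},
            "spatial_frequencies": list(self.spatial_frequencies),
            "orientations": list(self.orientations),
            "microsaccade_filter": self.microsaccade_filter,
            "ssvep_freq": self.ssvep_freq,
            "n_boot": self.n_boot,
            "bf_prior_scale": self.bf_prior_scale,
            "limit_controls": self.limit_controls,
            "pool_cases": self.pool_cases,
            "slope_refine": self.slope_refine,
            "seed": self.seed,
        }
        with open(path, "w") as f:
            yaml.safe_dump(payload, f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        rej = raw.pop("rejection", {})
        eye = raw.pop("eye", {})
        cfg = cls(
            bands={k: tuple(v) for k, v in raw.pop("bands").items()},
            baseline_window=tuple(raw.pop("baseline_window")),
            stimulus_window=tuple(raw.pop("stimulus_window")),
            rejection=RejectionParams(**{**rej,
                                         "slope_band": tuple(rej.get("slope_band", (56, 84))),
                                         "analysis_window": tuple(rej.get("analysis_window", (-0.5, 0.75)))}),
            eye=EyeParams(**{**eye, "analysis_window": tuple(eye.get("analysis_window", (-0.5, 0.75)))}),
            spatial_frequencies=tuple(raw.pop("spatial_frequencies")),
            orientations=tuple(raw.pop("orientations")),
            **raw,
        )
        return cfg


@dataclass
class SubjectSummary:
    id: str
    profile: SubjectProfile
    n_analyzable_repeats: int
    delta_power_db: Dict[str, float]
    ssvep_db: Optional[float]
    erp_peaks: Optional[Dict[str, Tuple[float, float]]]
    microsaccade_rate: float
    pupil_cv: float
    counts: Dict[str, int]
    freqs: np.ndarray
    st_spectrum: np.ndarray
    bl_spectrum: np.ndarray


def _psd_pair(
    data: np.ndarray, time: np.ndarray, fs: float, cfg: PipelineConfig
) -> Tuple[PSDEstimate, PSDEstimate]:
    st = spectral.multitaper_psd(
        data[..., spectral.extract_window(time, *cfg.stimulus_window)], fs, "stimulus")
    bl = spectral.multitaper_psd(
        data[..., spectral.extract_window(time, *cfg.baseline_window)], fs, "baseline")
    return st, bl


def run_subject(
    profile: SubjectProfile,
    trials: Sequence[TrialRecording],
    config: Optional[PipelineConfig] = None,
    input_bad: Sequence[str] = (),
) -> Optional[SubjectSummary]:
    """Full per-subject pipeline; returns None when the subject is excluded
    (no analyzable block, or too few clean repeats for robust statistics)."""
    cfg = config or PipelineConfig()
    if not trials:
        raise ValueError("no trials for subject")
    montage = _montage()
    time = trials[0].time
    fs = 1.0 / float(np.median(np.diff(time)))
    ch_names = trials[0].channel_names
    counts: Dict[str, int] = {"n_trials": len(trials)}

    # 1. fixation-break screening
    keep = [i for i, tr in enumerate(trials) if not detect_fixation_breaks(tr.eye, cfg.eye)]
    counts["fixation_rejected"] = len(trials) - len(keep)
    if len(keep) < 8:
        logger.info("subject %s excluded: reason=insufficient_repeats n=%d",
                    profile.id, len(keep))
        return None
    kept = [trials[i] for i in keep]
    data = np.stack([t.data for t in kept]).astype(float)  # (rep, elec, samp)

    # 2-3. artifact cascade (robust flags, 30%/10% rules, slope rule, block rule)
    flags = flag_repeats_per_electrode(data, time, fs, cfg.rejection)
    bl_mask = spectral.extract_window(time, *cfg.baseline_window)
    slopes: Dict[str, float] = {}
    for ei, name in enumerate(ch_names):
        ok = ~flags[ei]
        if not ok.any():
            slopes[name] = np.nan
            continue
        psd = spectral.multitaper_psd(data[ok, ei][:, bl_mask], fs, "baseline")
        slopes[name] = spectral.fit_psd_slope(
            psd, cfg.rejection.slope_band, refine=cfg.slope_refine).beta
    report = apply_cascade(flags, ch_names, montage, slopes, cfg.rejection, input_bad)
    counts.update(report.counts)
    if not report.block_ok:
        logger.info("subject %s excluded: reason=block_rule", profile.id)
        return None

    clean_pairs = [p for p in montage.analysis_set
                   if p not in report.bad_pairs
                   and all(e in ch_names for e in montage.electrodes_of(p))]
    clean_idx = [k for k in range(len(kept)) if k not in report.bad_repeats]

    # 4. condition filtering
    def cond_ok(tr: TrialRecording) -> bool:
        c = tr.condition
        return (c.temporal_frequency == 0
                and c.spatial_frequency in cfg.spatial_frequencies
                and c.orientation in cfg.orientations)

    gamma_idx = [k for k in clean_idx if cond_ok(kept[k])]
    ssvep_idx = [k for k in clean_idx if kept[k].condition.temporal_frequency == 16]

    # optional microsaccade-based repeat filter
    ms_events = {k: detect_microsaccades(kept[k].eye, cfg.eye) for k in clean_idx}
    if cfg.microsaccade_filter == "without":
        gamma_idx = [k for k in gamma_idx if not ms_events[k]]
        counts["microsaccade_filtered"] = counts.get("n_trials", 0)
    elif cfg.microsaccade_filter == "with":
        gamma_idx = [k for k in gamma_idx if ms_events[k]]
    elif cfg.microsaccade_filter != "none":
        raise ValueError(f"unknown microsaccade_filter {cfg.microsaccade_filter!r}")
    counts["n_gamma_repeats"] = len(gamma_idx)
    counts["n_ssvep_repeats"] = len(ssvep_idx)
    if len(gamma_idx) < 2:
        logger.info("subject %s excluded: reason=no_clean_gamma_repeats", profile.id)
        return None

    # 5. spectra averaged across repeats and clean analysis pairs
    bip = apply_bipolar(data[gamma_idx], ch_names, montage, clean_pairs)
    st, bl = _psd_pair(bip, time, fs, cfg)
    bands = cfg.band_defs()
    delta = {name: spectral.delta_power(st, bl, b).delta_power for name, b in bands.items()}

    ssvep_db = None
    if ssvep_idx:
        bip_ss = apply_bipolar(data[ssvep_idx], ch_names, montage, clean_pairs)
        ssvep_db = spectral.ssvep_power(bip_ss, fs, time, cfg.ssvep_freq,
                                        cfg.stimulus_window, cfg.baseline_window).delta_power

    erp_peaks = None
    if len(gamma_idx) * len(clean_pairs) >= 10:
        erp_peaks = spectral.compute_erp(bip, time, baseline=cfg.baseline_window).peaks

    win = cfg.eye.analysis_window
    duration = (win[1] - win[0]) * max(len(clean_idx), 1)
    rate = sum(len(v) for v in ms_events.values()) / duration
    cv = float(np.mean([pupil_cv(kept[k].eye, win) for k in clean_idx])) if clean_idx else np.nan

    return SubjectSummary(
        id=profile.id, profile=profile, n_analyzable_repeats=len(gamma_idx),
        delta_power_db=delta, ssvep_db=ssvep_db, erp_peaks=erp_peaks,
        microsaccade_rate=rate, pupil_cv=cv, counts=counts,
        freqs=st.freqs, st_spectrum=np.asarray(st.power), bl_spectrum=np.asarray(bl.power),
    )


def _delta_from_spectra(freqs, st_pow, bl_pow, band: BandDefinition) -> float:
    st = PSDEstimate(freqs=freqs, power=st_pow, window="stimulus")
    bl = PSDEstimate(freqs=freqs, power=bl_pow, window="baseline")
    return spectral.delta_power(st, bl, band).delta_power


def run_comparison(
    summaries: Sequence[SubjectSummary],
    config: Optional[PipelineConfig] = None,
    case_groups: Optional[Tuple[str, ...]] = None,
) -> Dict:
    """Matched pairwise case-control statistics per band.

    Each case is compared with the mean change in power of its age/gender-
    matched healthy controls: per band, the controls' dB power changes are
    averaged (averaging the raw spectra instead would give the control
    statistic a different null mean than the cases', because the log-ratio
    is nonlinear in the averaged power). ``case_groups`` restricts the case
    set (default: MCI and AD pooled when ``config.pool_cases``, else MCI
    only).
    """
    cfg = config or PipelineConfig()
    if case_groups is None:
        case_groups = ("MCI", "AD") if cfg.pool_cases else ("MCI",)
    by_id = {s.id: s for s in summaries}
    healthy = [s for s in summaries if s.profile.group == "healthy"]
    cases = [s for s in summaries if s.profile.group in case_groups]
    if not cases:
        raise ValueError("no case subjects in the summary set")
    pool = [s.profile for s in healthy]

    matched = []
    for case in cases:
        try:
            ms = match_controls(case.profile, pool, limit_n=cfg.limit_controls)
        except MatchingError:
            logger.info("case %s dropped: reason=no_matched_control", case.id)
            continue
        ctrl = [by_id[cid] for cid in ms.control_ids]
        if all(c.st_spectrum is not None for c in ctrl):
            st_avg = np.mean([c.st_spectrum for c in ctrl], axis=0)
            bl_avg = np.mean([c.bl_spectrum for c in ctrl], axis=0)
            ms.averaged_control_spectra = (st_avg, bl_avg)
        else:
            st_avg = bl_avg = None
        matched.append((case, ms, st_avg, bl_avg, ctrl))
    if not matched:
        raise ValueError("no case has a matched control")

    rng = np.random.default_rng(cfg.seed)
    bands = cfg.band_defs()
    out: Dict = {"n_cases": len(matched), "bands": {},
                 "pairs": {c.id: ms.control_ids for c, ms, *_ in matched}}
    for name, band in bands.items():
        case_vals = [c.delta_power_db[name] for c, *_ in matched]
        ctrl_vals = [float(np.mean([k.delta_power_db[name] for k in ctrl]))
                     for _c, _ms, _st, _bl, ctrl in matched]
        tail = "left" if name.startswith("alpha") else "right"
        kw = kruskal_wallis([ctrl_vals, case_vals])
        bc = bootstrap_median(case_vals, cfg.n_boot, rng)
        bk = bootstrap_median(ctrl_vals, cfg.n_boot, rng)
        bf = bayes_factor_paired_t(ctrl_vals, case_vals, tail, cfg.bf_prior_scale)
        out["bands"][name] = {
            "case_values": list(map(float, case_vals)),
            "control_values": list(map(float, ctrl_vals)),
            "case_median": bc.median, "case_boot_sd": bc.sd_of_median,
            "control_median": bk.median, "control_boot_sd": bk.sd_of_median,
            "H": kw.H, "df": kw.df, "p": kw.p,
            "bf10": bf.bf10, "bf_tail": bf.tail,
        }

    ssvep_cases = [(c, ctrl) for c, _ms, _st, _bl, ctrl in matched
                   if c.ssvep_db is not None and all(k.ssvep_db is not None for k in ctrl)]
    if ssvep_cases:
        cv = [c.ssvep_db for c, _ in ssvep_cases]
        kv = [float(np.mean([k.ssvep_db for k in ctrl])) for _, ctrl in ssvep_cases]
        kw = kruskal_wallis([kv, cv])
        out["ssvep"] = {"case_values": cv, "control_values": kv,
                        "H": kw.H, "df": kw.df, "p": kw.p}

    out["regression"] = {}
    for name in bands:
        # matched condition: each case plus its averaged control
        y, cdr, age, gender = [], [], [], []
        for case, _ms, st, bl, ctrl in matched:
            p = case.profile
            y.append(case.delta_power_db[name]); cdr.append(p.cdr)
            age.append(p.age); gender.append(0 if p.gender == "male" else 1)
            y.append(float(np.mean([k.delta_power_db[name] for k in ctrl])))
            cdr.append(0.0); age.append(int(round(np.mean([k.profile.age for k in ctrl]))))
            gender.append(0 if p.gender == "male" else 1)
        res_m = fit_linear_model(y, cdr, age, gender)
        # unmatched condition: every subject enters individually
        allsub = healthy + cases
        res_u = fit_linear_model(
            [s.delta_power_db[name] for s in allsub],
            [s.profile.cdr for s in allsub],
            [s.profile.age for s in allsub],
            [0 if s.profile.gender == "male" else 1 for s in allsub],
        )
        out["regression"][name] = {
            "matched": {"beta_cdr": res_m.params["beta_cdr"], "p_cdr": res_m.p["beta_cdr"],
                        "n": res_m.n},
            "unmatched": {"beta_cdr": res_u.params["beta_cdr"], "p_cdr": res_u.p["beta_cdr"],
                          "n": res_u.n},
        }
    return out


def effect_pattern_replicate(
    seed: int,
    deficit_factor: float = 0.6,
    n_cases: int = 12,
    n_controls: int = 74,
    repeats_per_condition: int = 12,
    params: Optional[GeneratorParams] = None,
    config: Optional[PipelineConfig] = None,
) -> Dict[str, float]:
    """One seeded end-to-end cohort replicate; returns per-band K-W p.

    Runs the full pipeline at a reduced, documented problem size: only the
    electrodes feeding the nine analysis pairs are synthesized, with the
    2 and 4 cpd conditions at one orientation. The cohort structure (12
    cases against a 74-control pool, amplitude deficit 0.6) is the study
    condition being replicated.
    """
    base = params or GeneratorParams()
    p = replace(
        base,
        seed=int(seed),
        channels=ANALYSIS_ELECTRODES,
        deficit_factor={"healthy": 1.0, "MCI": deficit_factor, "AD": deficit_factor},
    )
    conditions = [StimulusCondition(2, 0, 0), StimulusCondition(4, 0, 0)]
    cfg = config or PipelineConfig(n_boot=200, slope_refine=False, seed=int(seed))
    cohort = generate_cohort(n_controls, n_cases, 0, repeats_per_condition, p, conditions)
    summaries = []
    for prof, trials in cohort:
        s = run_subject(prof, trials, cfg)
        if s is not None:
            summaries.append(s)
    comp = run_comparison(summaries, cfg)
    return {name: res["p"] for name, res in comp["bands"].items()}


def effect_pattern_rates(
    n_seeds: int,
    deficit_factor: float,
    alpha_level: float = 0.05,
    seed0: int = 0,
    **kwargs,
) -> Dict[str, float]:
    """Fraction of seeded replicates with K-W p below ``alpha_level``."""
    hits: Dict[str, int] = {}
    for s in range(n_seeds):
        ps = effect_pattern_replicate(seed0 + s, deficit_factor, **kwargs)
        for band, pv in ps.items():
            hits[band] = hits.get(band, 0) + (pv < alpha_level)
    return {band: h / n_seeds for band, h in hits.items()}
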