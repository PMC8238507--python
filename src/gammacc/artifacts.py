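"""Repeat / electrode / block artifact-rejection cascade.

Per electrode, a repeat is flagged when either its maximum absolute
amplitude or its mean log power spectral density over the -500-750 ms
analysis window exceeds the median plus ``k`` times the (unscaled) median
absolute deviation across that electrode's repeats. The cascade then runs
in a fixed order:

1. discard electrodes with more than 30% of repeats flagged,
2. discard repeats flagged on more than 10% of the remaining electrodes,
3. discard electrodes whose baseline power-law slope (56-84 Hz) is
   negative,
4. evaluate the block rule: at least one clean bipolar pair must remain in
   each of the three occipito-parietal analysis groups.

Impedance-based rejection is represented as an input bad-electrode list
(the synthetic data carry no impedance). The exact thresholding constants
of stage flagging are configurable; the median + 6*MAD default is robust,
scale-free, and rejects little clean data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np

from .montage import BipolarMontage, propagate_bad
from .spectral import extract_window, multitaper_psd

logger = logging.getLogger(__name__)

__all__ = [
    "RejectionParams",
    "RejectionReport",
    "flag_repeats_per_electrode",
    "apply_cascade",
]


@dataclass
class RejectionParams:
    waveform_k: float = 6.0
    psd_k: float = 6.0
    electrode_bad_repeat_frac: float = 0.30
    repeat_bad_electrode_frac: float = 0.10
    slope_band: Tuple[float, float] = (56.0, 84.0)
    analysis_window: Tuple[float, float] = (-0.5, 0.75)

    def __post_init__(self) -> None:
        for frac in (self.electrode_bad_repeat_frac, self.repeat_bad_electrode_frac):
            if not 0 < frac < 1:
                raise ValueError("cascade fractions must lie in (0, 1)")


@dataclass
class RejectionReport:
    bad_electrodes: Dict[str, str]      # name -> reason
    bad_repeats: Set[int]
    block_ok: bool
    counts: Dict[str, int] = field(default_factory=dict)
    bad_pairs: Set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "bad_electrodes": dict(sorted(self.bad_electrodes.items())),
                "bad_repeats": sorted(self.bad_repeats),
                "block_ok": self.block_ok,
                "counts": self.counts,
                "bad_pairs": sorted(self.bad_pairs),
            },
            indent=2,
        )


def flag_repeats_per_electrode(
    data: np.ndarray,
    time: np.ndarray,
    fs: float,
    params: RejectionParams | None = None,
) -> np.ndarray:
    """Boolean flag matrix (electrodes x repeats) from robust thresholds.

    ``data`` is (repeats, electrodes, samples). A repeat is flagged for an
    electrode when its max |amplitude| or mean log-PSD in the analysis
    window exceeds median + k*MAD across that electrode's repeats. Channels
    containing NaN are flagged wholesale.
    """
    params = params or RejectionParams()
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (repeats, electrodes, samples)")
    n_rep = data.shape[0]
    if n_rep < 8:
        raise ValueError("robust repeat statistics need at least 8 repeats")
    m = extract_window(time, *params.analysis_window)
    seg = data[..., m]

    nan_entry = np.isnan(seg).any(axis=-1)            # (rep, elec)
    seg = np.where(np.isnan(seg), 0.0, seg)

    wave = np.max(np.abs(seg), axis=-1)               # (rep, elec)
    psd = multitaper_psd(seg, fs, average=False)
    logp = np.mean(np.log10(np.maximum(psd.power[..., 1:], 1e-30)), axis=-1)

    flags = np.zeros((data.shape[1], n_rep), dtype=bool)
    for metric, k in ((wave, params.waveform_k), (logp, params.psd_k)):
        med = np.median(metric, axis=0)
        mad = np.median(np.abs(metric - med), axis=0)
        flags |= (metric > med + k * mad).T
    flags |= nan_entry.T
    flags |= (wave <= 0).T  # dead (flat-zero) channel-repeats are unusable
    return flags


def apply_cascade(
    flags: np.ndarray,
    electrode_names: Sequence[str],
    montage: BipolarMontage,
    slopes: Mapping[str, float],
    params: RejectionParams | None = None,
    input_bad: Iterable[str] = (),
) -> RejectionReport:
    """Run the ordered electrode/repeat/slope/block rejection cascade.

    ``slopes`` maps electrode name to the fitted baseline power-law
    exponent (NaN allowed for electrodes with no surviving repeats, which
    the 30% rule will already have removed).
    """
    params = params or RejectionParams()
    flags = np.asarray(flags, dtype=bool)
    names = list(electrode_names)
    if flags.shape[0] != len(names):
        raise ValueError("flags row count must match electrode_names")
    n_rep = flags.shape[1]

    bad: Dict[str, str] = {}
    for e in input_bad:
        if e not in names:
            raise ValueError(f"unknown input-bad electrode {e!r}")
        bad[e] = "impedance"

    # stage 1: electrodes bad on >30% of repeats
    frac_bad = flags.mean(axis=1)
    for i, name in enumerate(names):
        if name not in bad and frac_bad[i] > params.electrode_bad_repeat_frac:
            bad[name] = "repeat_fraction"
    n_stage1 = sum(1 for r in bad.values() if r == "repeat_fraction")

    # stage 2: repeats bad on >10% of the remaining electrodes
    remaining = [i for i, n in enumerate(names) if n not in bad]
    bad_repeats: Set[int] = set()
    if remaining:
        rep_frac = flags[remaining].mean(axis=0)
        bad_repeats = set(np.flatnonzero(rep_frac > params.repeat_bad_electrode_frac).tolist())

    # stage 3: electrodes with non-physiological (negative) spectral slope
    for name in names:
        if name not in bad and slopes.get(name, np.nan) < 0:
            bad[name] = "slope"
    n_stage3 = sum(1 for r in bad.values() if r == "slope")

    # stage 4: block rule over the three analysis pair-groups
    bad_pairs = propagate_bad(montage, set(bad))
    block_ok = bool(names) and all(
        any(p not in bad_pairs for p in group) for group in montage.analysis_groups.values()
    )
    if not names:
        block_ok = False

    counts = {
        "n_electrodes": len(names),
        "n_repeats": n_rep,
        "impedance": sum(1 for r in bad.values() if r == "impedance"),
        "repeat_fraction": n_stage1,
        "bad_repeats": len(bad_repeats),
        "slope": n_stage3,
        "bad_pairs": len(bad_pairs),
    }
    for stage in ("impedance", "repeat_fraction", "bad_repeats", "slope"):
        logger.info("rejection stage %s: %d", stage, counts[stage])
    if not block_ok:
        logger.info("block rejected: an analysis group has no clean bipolar pair")
    return RejectionReport(bad_electrodes=bad, bad_repeats=bad_repeats, block_ok=block_ok,
                           counts=counts, bad_pairs=bad_pairs)
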