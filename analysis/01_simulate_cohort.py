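#!/usr/bin/env python
"""Simulate a demonstration cohort of elderly subjects.

Generates 16 healthy controls, 4 MCI and 1 AD subject with trial-level EEG
(the ten electrodes feeding the nine occipito-parietal analysis pairs) and
eye traces for the 2 and 4 cpd static-grating conditions plus a
counterphase (16 cps) block, then writes the HDF5 cohort container to
scratch/ (binary) and its metadata mirror to results/ (text).
"""

from pathlib import Path

import numpy as np

from gammacc.io import save_cohort, write_metadata_tsv
from gammacc.pipeline import ANALYSIS_ELECTRODES
from gammacc.synth import GeneratorParams, StimulusCondition, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 2021

CONDITIONS = [
    StimulusCondition(2, 0, 0),
    StimulusCondition(4, 0, 0),
    StimulusCondition(2, 0, 16),   # counterphase block for the SSVEP analysis
]


def main() -> None:
    params = GeneratorParams(channels=ANALYSIS_ELECTRODES, seed=SEED)
    cohort = generate_cohort(16, 4, 1, 12, params, conditions=CONDITIONS)

    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    save_cohort(ROOT / "scratch" / "cohort.h5", cohort)
    write_metadata_tsv(ROOT / "results" / "cohort_metadata.tsv", cohort)

    n_trials = sum(len(t) for _, t in cohort)
    groups = {g: sum(p.group == g for p, _ in cohort) for g in ("healthy", "MCI", "AD")}
    ages = [p.age for p, _ in cohort]
    print(f"simulated {len(cohort)} subjects ({groups}) with {n_trials} trials total")
    print(f"ages {min(ages)}-{max(ages)}; seed {SEED}")
    print("wrote scratch/cohort.h5 and results/cohort_metadata.tsv")


if __name__ == "__main__":
    main()
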