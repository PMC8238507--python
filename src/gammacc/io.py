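"""Cohort container and results I/O.

The synthetic cohort lives in an HDF5 file laid out as
``/subjects/<id>/trials/<k>/{data,time,eye}`` with the stimulus condition
and subject profile stored as attributes, mirrored by a plain-TSV metadata
table. Results are written as TSV (per-subject band powers) and JSON
(group comparison), with stable key order and float formatting so that
identical configs and seeds produce byte-identical files.
"""

from __future__ import annotations

import json
from typing import Dict, List, Tuple

import h5py
import numpy as np
import pandas as pd

from .eye import EyeTrace
from .synth import StimulusCondition, SubjectProfile, TrialRecording

__all__ = [
    "save_cohort",
    "load_cohort",
    "write_metadata_tsv",
    "write_summaries_tsv",
    "read_summaries_tsv",
    "write_comparison_json",
    "write_eye_trace_csv",
    "read_eye_trace_csv",
]

Cohort = List[Tuple[SubjectProfile, List[TrialRecording]]]


def save_cohort(path, cohort: Cohort) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for profile, trials in cohort:
            g = root.create_group(profile.id)
            for key in ("age", "gender", "group", "cdr"):
                g.attrs[key] = getattr(profile, key)
            tg = g.create_group("trials")
            for k, tr in enumerate(trials):
                t = tg.create_group(str(k))
                t.create_dataset("data", data=tr.data.astype(np.float32),
                                 compression="gzip", compression_opts=1)
                t.create_dataset("time", data=tr.time)
                eye = np.stack([tr.eye.x, tr.eye.y, tr.eye.pupil])
                t.create_dataset("eye", data=eye.astype(np.float32))
                t.attrs["channel_names"] = list(tr.channel_names)
                t.attrs["spatial_frequency"] = tr.condition.spatial_frequency
                t.attrs["orientation"] = tr.condition.orientation
                t.attrs["temporal_frequency"] = tr.condition.temporal_frequency
                t.attrs["repeat_index"] = tr.repeat_index


def load_cohort(path) -> Cohort:
    cohort: Cohort = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            profile = SubjectProfile(
                id=sid, age=int(g.attrs["age"]), gender=str(g.attrs["gender"]),
                group=str(g.attrs["group"]), cdr=float(g.attrs["cdr"]),
            )
            trials = []
            for k in sorted(g["trials"], key=int):
                t = g["trials"][k]
                time = np.asarray(t["time"])
                eye = np.asarray(t["eye"], dtype=float)
                trials.append(
                    TrialRecording(
                        data=np.asarray(t["data"]),
                        time=time,
                        channel_names=tuple(str(c) for c in t.attrs["channel_names"]),
                        condition=StimulusCondition(
                            int(t.attrs["spatial_frequency"]),
                            int(t.attrs["orientation"]),
                            int(t.attrs["temporal_frequency"]),
                        ),
                        eye=EyeTrace(time=time, x=eye[0], y=eye[1], pupil=eye[2]),
                        repeat_index=int(t.attrs["repeat_index"]),
                    )
                )
            cohort.append((profile, trials))
    return cohort


def write_metadata_tsv(path, cohort: Cohort) -> None:
    rows = [
        {"id": p.id, "age": p.age, "gender": p.gender, "group": p.group,
         "cdr": p.cdr, "n_trials": len(trials)}
        for p, trials in cohort
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summaries_tsv(path, summaries) -> None:
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.id, "group": s.profile.group, "age": s.profile.age,
            "gender": s.profile.gender, "cdr": s.profile.cdr,
            "n_analyzable_repeats": s.n_analyzable_repeats,
            "microsaccade_rate": f"{s.microsaccade_rate:.6f}",
            "pupil_cv": f"{s.pupil_cv:.6f}",
        }
        for band, db in sorted(s.delta_power_db.items()):
            row[f"delta_{band}_db"] = f"{db:.6f}"
        if s.ssvep_db is not None:
            row["ssvep_db"] = f"{s.ssvep_db:.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_summaries_tsv(path) -> List:
    """Rebuild subject summaries from the TSV written by
    :func:`write_summaries_tsv` (band powers and eye metrics only; the
    per-frequency spectra are not serialized there)."""
    from .pipeline import SubjectSummary

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        delta = {c[len("delta_"):-len("_db")]: float(r[c])
                 for c in df.columns if c.startswith("delta_") and c.endswith("_db")}
        out.append(SubjectSummary(
            id=r["subject_id"],
            profile=SubjectProfile(id=r["subject_id"], age=int(r["age"]),
                                   gender=r["gender"], group=r["group"],
                                   cdr=float(r["cdr"])),
            n_analyzable_repeats=int(r["n_analyzable_repeats"]),
            delta_power_db=delta,
            ssvep_db=float(r["ssvep_db"]) if "ssvep_db" in df.columns else None,
            erp_peaks=None,
            microsaccade_rate=float(r["microsaccade_rate"]),
            pupil_cv=float(r["pupil_cv"]),
            counts={},
            freqs=np.array([]),
            st_spectrum=None,
            bl_spectrum=None,
        ))
    return out


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_comparison_json(path, comparison: Dict) -> None:
    with open(path, "w") as f:
        json.dump(_round_floats(comparison), f, indent=2, sort_keys=True)
        f.write("\n")


def write_eye_trace_csv(path, trace: EyeTrace) -> None:
    pd.DataFrame({"t_s": trace.time, "x_deg": trace.x, "y_deg": trace.y,
                  "pupil": trace.pupil}).to_csv(path, index=False)


def read_eye_trace_csv(path) -> EyeTrace:
    df = pd.read_csv(path)
    return EyeTrace(time=df["t_s"].to_numpy(), x=df["x_deg"].to_numpy(),
                    y=df["y_deg"].to_numpy(), pupil=df["pupil"].to_numpy())
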