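"""Delimited-text interchange for subject datasets and result tables.

A subject dataset is a directory of TSV files plus a ``subject.yaml`` with
metadata and ground truth:

* ``schedule.tsv``  — frame_start_s, frame_duration_s
* ``tacs.tsv``      — tissue, frame_start_s, frame_duration_s, suv
* ``blood.tsv``     — time_min, plasma_suv, blood_suv
* ``species.tsv``   — time_min, parent, conjugate, other
* ``excretion.tsv`` — time_min, bladder_pct_id, gallbladder_pct_id

TSV means tab-delimited, header row, UTF-8, '.' decimal.  Floats are
written with ``repr`` precision so a round trip is lossless.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biodistribution import ExcretionSample
from .kinetics import TimeActivityCurve
from .schedule import FrameSchedule
from .simulate import SubjectDataset, SubjectParams, TissueKineticParams

__all__ = [
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
    "write_table",
    "read_table",
]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees a lossless float64 round trip through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_subject(ds: SubjectDataset, outdir: str | Path) -> Path:
    """Write one subject dataset as a directory of interchange files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sched = pd.DataFrame(
        {
            "frame_start_s": (ds.schedule.frame_starts_min * 60.0).round(6),
            "frame_duration_s": ds.schedule.frame_durations_s,
        }
    )
    write_table(sched, outdir / "schedule.tsv")
    tac_rows = []
    for tissue, tac in ds.tacs.items():
        for start, dur, value in zip(
            ds.schedule.frame_starts_min * 60.0, ds.schedule.frame_durations_s, tac.values
        ):
            tac_rows.append(
                {"tissue": tissue, "frame_start_s": round(start, 6),
                 "frame_duration_s": dur, "suv": value}
            )
    write_table(pd.DataFrame(tac_rows), outdir / "tacs.tsv")
    write_table(ds.blood, outdir / "blood.tsv")
    write_table(ds.species, outdir / "species.tsv")
    write_table(ds.excretion, outdir / "excretion.tsv")
    meta = {
        "occasion": ds.occasion,
        "ground_truth": asdict(ds.params),
        "urine_sample": asdict(ds.urine_sample) if ds.urine_sample else None,
    }
    (outdir / "subject.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return outdir


def read_subject(subdir: str | Path) -> SubjectDataset:
    """Read back a subject directory written by :func:`write_subject`."""
    subdir = Path(subdir)
    meta = yaml.safe_load((subdir / "subject.yaml").read_text())
    gt = meta["ground_truth"]
    gt["tissue_params"] = tuple(
        TissueKineticParams(**tp) for tp in gt["tissue_params"]
    )
    params = SubjectParams(**gt)
    sched_df = read_table(subdir / "schedule.tsv")
    schedule = FrameSchedule(sched_df["frame_duration_s"].to_numpy(float))
    tacs_df = read_table(subdir / "tacs.tsv")
    tacs = {}
    for tissue, grp in tacs_df.groupby("tissue", sort=False):
        grp = grp.sort_values("frame_start_s")
        tacs[tissue] = TimeActivityCurve.from_schedule(
            tissue, schedule, grp["suv"].to_numpy(float)
        )
    urine = meta.get("urine_sample")
    return SubjectDataset(
        schedule=schedule,
        params=params,
        tacs=tacs,
        blood=read_table(subdir / "blood.tsv"),
        species=read_table(subdir / "species.tsv"),
        excretion=read_table(subdir / "excretion.tsv"),
        urine_sample=ExcretionSample(**urine) if urine else None,
        occasion=meta["occasion"],
    )


def write_cohort(datasets: list[SubjectDataset], outdir: str | Path) -> Path:
    """Write a cohort as one sub-directory per scan (subject_occasion)."""
    outdir = Path(outdir)
    for ds in datasets:
        write_subject(ds, outdir / f"{ds.params.subject_id}_{ds.occasion}")
    return outdir


def read_cohort(outdir: str | Path) -> list[SubjectDataset]:
    outdir = Path(outdir)
    subdirs = sorted(p for p in outdir.iterdir() if (p / "subject.yaml").exists())
    return [read_subject(p) for p in subdirs]
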