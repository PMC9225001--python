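"""Container and standard-format IO.

Cohorts are stored in a single HDF5 file with the layout::

    /subjects/<id>/runs/<task>/<k>/levels     light levels (meas x time)
    /subjects/<id>/runs/<task>/<k>/events     onsets/durations + labels
    /truth/subjects/<id>                      generative parameters (JSON attr)
    /truth/roi_masks/<name>                   boolean voxel masks

Images and ROI masks export to NIfTI on the 3 mm grid affine; statistics
export to CSV with documented headers.  HDF5 files are written with
``track_times=False`` so identical cohorts serialize to identical bytes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .grids import Grid
from .synthetic_data import CohortTruth, RawRun, StimulusSchedule, SubjectTruth


class ContainerError(KeyError):
    pass


def _write_run(grp: h5py.Group, run: RawRun) -> None:
    grp.create_dataset("levels", data=run.levels, track_times=False)
    sch = run.schedule
    ev = np.array([(o, d) for o, d, _ in sch.events], float).reshape(-1, 2)
    grp.create_dataset("events", data=ev, track_times=False)
    labels = [c for _, _, c in sch.events]
    grp.create_dataset("event_labels", data=np.array(labels, dtype="S16"),
                       track_times=False)
    grp.attrs.update({"rate_hz": run.rate_hz, "duration_s": sch.duration_s,
                      "task": sch.task, "run_id": sch.run_id,
                      "subject_id": run.subject_id})


def _read_run(grp: h5py.Group) -> RawRun:
    ev = grp["events"][()]
    labels = [s.decode() for s in grp["event_labels"][()]]
    events = [(float(o), float(d), lbl) for (o, d), lbl in zip(ev, labels)]
    sch = StimulusSchedule(events, int(grp.attrs["run_id"]),
                           float(grp.attrs["duration_s"]), str(grp.attrs["task"]))
    return RawRun(grp["levels"][()], float(grp.attrs["rate_hz"]), sch,
                  str(grp.attrs["subject_id"]))


def _truth_to_json(st: SubjectTruth) -> str:
    d = {
        "subject_id": st.subject_id, "group": st.group,
        "roi_amplitudes_um": st.roi_amplitudes_um,
        "superficial_scale": st.superficial_scale,
        "attenuated_optodes": [list(x) for x in st.attenuated_optodes],
        "attenuation": st.attenuation, "seed": st.seed,
        "behavior": {
            "speech_score": st.behavior["speech_score"],
            "ci_side": st.behavior["ci_side"],
            "audiogram": {f"{ear}|{cond}": ag for (ear, cond), ag
                          in st.behavior["audiogram"].items()},
        },
    }
    return json.dumps(d)


def _truth_from_json(s: str) -> SubjectTruth:
    d = json.loads(s)
    beh = d["behavior"]
    audiogram = {}
    for key, ag in beh["audiogram"].items():
        ear, cond = key.split("|")
        audiogram[(ear, cond)] = {int(f): v for f, v in ag.items()}
    return SubjectTruth(
        subject_id=d["subject_id"], group=d["group"],
        roi_amplitudes_um=d["roi_amplitudes_um"],
        superficial_scale=d["superficial_scale"],
        attenuated_optodes=[(k, int(i)) for k, i in d["attenuated_optodes"]],
        attenuation=d["attenuation"],
        behavior={"speech_score": beh["speech_score"], "ci_side": beh["ci_side"],
                  "audiogram": audiogram},
        seed=d["seed"])


def save_cohort(path, runs: dict, truth: CohortTruth) -> None:
    """Write a cohort (see :func:`cidot.synthetic_data.simulate_cohort`)."""
    with h5py.File(path, "w", track_order=True) as f:
        subs = f.create_group("subjects")
        for sid in sorted(runs):
            sgrp = subs.create_group(sid).create_group("runs")
            for task in sorted(runs[sid]):
                tgrp = sgrp.create_group(task)
                for k, run in enumerate(runs[sid][task]):
                    _write_run(tgrp.create_group(str(k)), run)
        tg = f.create_group("truth")
        tg.attrs["master_seed"] = truth.master_seed
        sg = tg.create_group("subjects")
        for st in truth.subjects:
            sg.attrs[st.subject_id] = _truth_to_json(st)
        sg.attrs["order"] = json.dumps([st.subject_id for st in truth.subjects])
        rg = tg.create_group("roi_masks")
        for name, mask in truth.roi_masks.items():
            rg.create_dataset(name, data=np.asarray(mask, bool), track_times=False)


def load_cohort(path) -> tuple[dict, CohortTruth]:
    with h5py.File(path, "r") as f:
        runs: dict = {}
        for sid, sgrp in f["subjects"].items():
            runs[sid] = {}
            for task, tgrp in sgrp["runs"].items():
                runs[sid][task] = [_read_run(tgrp[k])
                                   for k in sorted(tgrp, key=int)]
        tg = f["truth"]
        order = json.loads(tg["subjects"].attrs["order"])
        subjects = [_truth_from_json(tg["subjects"].attrs[sid]) for sid in order]
        roi_masks = {name: ds[()] for name, ds in tg["roi_masks"].items()}
        return runs, CohortTruth(subjects, int(tg.attrs["master_seed"]), roi_masks)


def load_run(path, subject_id: str, task: str, run_index: int) -> RawRun:
    with h5py.File(path, "r") as f:
        key = f"subjects/{subject_id}/runs/{task}/{run_index}"
        if key not in f:
            raise ContainerError(f"missing container entry {key!r}")
        return _read_run(f[key])


# --------------------------------------------------------------------------
# NIfTI / CSV export
# --------------------------------------------------------------------------

def export_nifti(flat_image: np.ndarray, grid: Grid, path) -> None:
    """Write a flattened voxel image (or voxels x time series) as NIfTI with
    the grid's 3 mm affine."""
    import nibabel as nib
    vol = grid.to_volume(np.asarray(flat_image))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), grid.affine()), str(path))


def read_nifti(path) -> np.ndarray:
    import nibabel as nib
    return np.asarray(nib.load(str(path)).dataobj)


def beta_table(subject_betas: dict, truth: CohortTruth,
               chromophore: str = "hbo") -> pd.DataFrame:
    """Long-format table: subject, group, roi, chromophore, beta."""
    rows = []
    for roi, per_subject in subject_betas.items():
        for sid, beta in per_subject.items():
            rows.append((sid, truth.get(sid).group, roi, chromophore, beta))
    return pd.DataFrame(rows, columns=["subject", "group", "roi", "chromophore", "beta"])


def group_result_table(group_results: dict) -> pd.DataFrame:
    rows = []
    for name, g in group_results.items():
        rows.append((name, g.mean_a, g.sd_a, g.n_a, g.mean_b, g.sd_b, g.n_b,
                     g.t, g.df, g.df_display, g.p, g.tail, g.welch,
                     g.alpha_corrected, g.significant))
    return pd.DataFrame(rows, columns=[
        "roi", "mean_ci", "sd_ci", "n_ci", "mean_control", "sd_control",
        "n_control", "t", "df", "df_display", "p", "tail", "welch",
        "alpha_corrected", "significant"])


def quality_report(quality, path=None) -> pd.DataFrame:
    """Channel-QC CSV report (measurement id, std fraction, retained)."""
    df = quality.report()
    if path is not None:
        df.to_csv(path, index=False)
    return df
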