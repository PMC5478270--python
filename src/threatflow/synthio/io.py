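"""File emission/ingestion for simulated cohorts.

fMRI subjects go out as 4-D NIfTI + 3-D mask NIfTI + confounds TSV; MEG
cohorts as one HDF5 container; EMG sessions as trace + events TSV. Every
file embeds the generator configuration: NIfTI via a comment header
extension, HDF5 via root attributes, TSV via a ``# config:`` comment line.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from ..fmri_conn import SubjectTimeseries
from ..meg_spectral import SensorEpochs
from ..physio import EmgTrace

__all__ = [
    "config_json",
    "write_fmri_subject",
    "read_fmri_subject",
    "write_meg_cohort",
    "read_meg_cohort",
    "write_emg_session",
    "read_emg_session",
]


def config_json(cfg) -> str:
    """Serialize a sim config (dataclass or dict) to canonical JSON."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    return json.dumps(cfg, sort_keys=True, default=default)


def write_fmri_subject(out_dir, ts: SubjectTimeseries, cfg=None) -> dict:
    """Emit <subject>_bold.nii, <subject>_mask.nii, <subject>_confounds.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = ts.subject_id or "sub-00"
    meta = config_json(cfg) if cfg is not None else "{}"

    vol = np.zeros((*ts.mask.shape, ts.n_frames), np.float32)
    vol[ts.mask] = ts.data
    img = nib.Nifti1Image(vol, ts.affine)
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension("comment", meta.encode())
    )
    bold_path = out_dir / f"{sid}_bold.nii"
    nib.save(img, bold_path)
    mask_path = out_dir / f"{sid}_mask.nii"
    nib.save(nib.Nifti1Image(ts.mask.astype(np.uint8), ts.affine), mask_path)

    conf = pd.DataFrame(
        np.asarray(ts.motion, float),
        columns=[f"motion_{i}" for i in range(6)],
    )
    conf["label"] = ts.labels
    conf["censor"] = ts.censor.astype(int)
    conf["run"] = ts.run_index
    conf["shock"] = 0
    conf.loc[conf.index.isin(ts.shock_frames.tolist()), "shock"] = 1
    conf_path = out_dir / f"{sid}_confounds.tsv"
    with open(conf_path, "w") as fh:
        fh.write(f"# config: {meta}\n")
        conf.to_csv(fh, sep="\t", index=False)
    return {"bold": bold_path, "mask": mask_path, "confounds": conf_path}


def read_fmri_subject(out_dir, subject_id: str) -> SubjectTimeseries:
    out_dir = Path(out_dir)
    img = nib.load(out_dir / f"{subject_id}_bold.nii")
    mask = nib.load(out_dir / f"{subject_id}_mask.nii").get_fdata().astype(bool)
    conf = pd.read_csv(out_dir / f"{subject_id}_confounds.tsv", sep="\t", comment="#")
    vol = img.get_fdata()
    return SubjectTimeseries(
        data=vol[mask],
        mask=mask,
        labels=conf["label"].to_numpy(),
        censor=conf["censor"].to_numpy(bool),
        motion=conf[[f"motion_{i}" for i in range(6)]].to_numpy(),
        run_index=conf["run"].to_numpy(int),
        affine=img.affine,
        subject_id=subject_id,
        shock_frames=np.flatnonzero(conf["shock"].to_numpy() == 1),
    )


def write_meg_cohort(path, subjects, source_model=None, cfg=None) -> Path:
    """Single HDF5 container: per-subject epochs plus shared geometry."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.attrs["config"] = config_json(cfg) if cfg is not None else "{}"
        for ep in subjects:
            grp = h5.create_group(ep.subject_id or f"sub-{len(h5):02d}")
            grp.create_dataset("epochs", data=ep.epochs)
            grp.create_dataset(
                "conditions", data=np.char.encode(ep.conditions.astype(str))
            )
            grp.create_dataset("reject", data=ep.reject)
            grp.attrs["fs_hz"] = ep.fs_hz
            if ep.sensor_positions is not None:
                grp.create_dataset("sensor_pos", data=ep.sensor_positions)
        if source_model is not None:
            grp = h5.create_group("source_model")
            grp.create_dataset("positions", data=source_model.positions)
            grp.create_dataset("orientations", data=source_model.orientations)
            grp.create_dataset("leadfields", data=source_model.leadfields)
            grp.attrs["sphere_radius"] = source_model.sphere_radius
            grp.attrs["grid_spacing"] = source_model.grid_spacing
            grp.attrs["sphere_center"] = source_model.sphere_center
    return path


def read_meg_cohort(path):
    """Return (list of SensorEpochs, SourceModel or None, config dict)."""
    from ..dics_source import SourceModel

    subjects, model = [], None
    with h5py.File(path, "r") as h5:
        cfg = json.loads(h5.attrs.get("config", "{}"))
        for name, grp in h5.items():
            if name == "source_model":
                model = SourceModel(
                    positions=grp["positions"][()],
                    orientations=grp["orientations"][()],
                    leadfields=grp["leadfields"][()],
                    sphere_center=np.asarray(grp.attrs["sphere_center"]),
                    sphere_radius=float(grp.attrs["sphere_radius"]),
                    grid_spacing=float(grp.attrs["grid_spacing"]),
                )
                continue
            subjects.append(
                SensorEpochs(
                    epochs=grp["epochs"][()],
                    fs_hz=float(grp.attrs["fs_hz"]),
                    conditions=np.char.decode(grp["conditions"][()]),
                    sensor_positions=(
                        grp["sensor_pos"][()] if "sensor_pos" in grp else None
                    ),
                    reject=grp["reject"][()],
                    subject_id=name,
                )
            )
    return subjects, model, cfg


def write_emg_session(out_dir, trace: EmgTrace, ratings: pd.DataFrame, cfg=None,
                      subject_id: str = "sub-00") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = config_json(cfg) if cfg is not None else "{}"
    trace_path = out_dir / f"{subject_id}_emg.tsv"
    with open(trace_path, "w") as fh:
        fh.write(f"# config: {meta}\n# fs_hz: {trace.fs_hz}\n")
        pd.DataFrame({"emg_uv": trace.samples}).to_csv(fh, sep="\t", index=False)
    events_path = out_dir / f"{subject_id}_events.tsv"
    with open(events_path, "w") as fh:
        fh.write(f"# config: {meta}\n")
        ratings.to_csv(fh, sep="\t", index=False)
    return {"trace": trace_path, "events": events_path}


def read_emg_session(out_dir, subject_id: str = "sub-00"):
    out_dir = Path(out_dir)
    trace_path = out_dir / f"{subject_id}_emg.tsv"
    fs = 600.0
    with open(trace_path) as fh:
        for line in fh:
            if line.startswith("# fs_hz:"):
                fs = float(line.split(":", 1)[1])
            if not line.startswith("#"):
                break
    samples = pd.read_csv(trace_path, sep="\t", comment="#")["emg_uv"].to_numpy()
    events = pd.read_csv(out_dir / f"{subject_id}_events.tsv", sep="\t", comment="#")
    trace = EmgTrace(
        samples=samples,
        fs_hz=fs,
        probe_onsets=events["onset_sample"].to_numpy(int),
        conditions=events["condition"].to_numpy(),
        habituation=events["habituation"].to_numpy(bool),
    )
    return trace, events
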