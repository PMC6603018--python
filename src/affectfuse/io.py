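"""Readers and writers for the standard neuroimaging/behavioural formats.

BOLD travels as NIfTI-1 with the TR in the header; EEG as delimited text
with a channel-label header (EDF is read through mne when available);
schedules and report traces as BIDS-style tab-separated tables; ground
truth and run manifests as JSON sidecars.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .eeg import AsymmetrySeries, EegRecording
from .synth import (
    AffectTrajectory,
    BoldSeries,
    GroundTruth,
    Trial,
    TrialSchedule,
    circumplex_target,
)

__all__ = [
    "write_bold",
    "read_bold",
    "write_eeg",
    "read_eeg",
    "write_events",
    "read_events",
    "write_reports",
    "read_reports",
    "write_asymmetry",
    "write_ground_truth",
    "write_manifest",
]

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "stimulus_id",
    "target_region_1",
    "target_region_2",
    "target_v1",
    "target_a1",
    "target_v2",
    "target_a2",
    "jitter",
]


def write_bold(bold: BoldSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms((*np.abs(np.diag(bold.affine)[:3]), bold.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_bold(path: str | Path) -> BoldSeries:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4-D NIfTI, got {img.ndim}-D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        raise ValueError("NIfTI header carries no repetition time (TR)")
    data = np.asarray(img.dataobj, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("BOLD volume contains non-finite values")
    return BoldSeries(data=data, tr=tr, affine=np.asarray(img.affine))


def write_eeg(rec: EegRecording, path: str | Path) -> Path:
    """Delimited text: a `time` column then one column per channel (uV)."""
    path = Path(path)
    frame = pd.DataFrame(rec.samples.T, columns=list(rec.labels))
    frame.insert(0, "time", rec.times)
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_eeg(path: str | Path) -> EegRecording:
    """Read EEG from delimited text (or EDF when the suffix is .edf)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        # mne resamples mixed-rate EDFs to a common rate; files are read
        # at raw.info["sfreq"], the only dialect supported here
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        samples = raw.get_data() * 1e6  # volts -> microvolts
        return EegRecording(
            samples=samples, rate=float(raw.info["sfreq"]), labels=tuple(raw.ch_names)
        )
    with open(path) as fh:
        header = fh.readline().strip()
    sep = "\t" if "\t" in header else ","
    raw_labels = header.split(sep)
    if len(set(raw_labels)) != len(raw_labels):
        raise ValueError("duplicate channel labels in EEG file")
    frame = pd.read_csv(path, sep=sep)
    if "time" not in frame.columns:
        raise ValueError("EEG text file needs a 'time' column")
    labels = [c for c in frame.columns if c != "time"]
    t = frame["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("EEG file too short to infer a sample rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise ValueError("EEG time column is not uniformly sampled")
    return EegRecording(
        samples=frame[labels].to_numpy(dtype=float).T,
        rate=1.0 / float(dt[0]),
        labels=tuple(labels),
    )


def write_events(schedule: TrialSchedule, path: str | Path) -> Path:
    rows = []
    for t in schedule.trials:
        rows.append(
            {
                "onset": t.onset,
                "duration": t.duration,
                "trial_type": t.trial_type,
                "stimulus_id": t.stimulus_id,
                "target_region_1": t.target_region_1,
                "target_region_2": t.target_region_2,
                "target_v1": t.target_1[0],
                "target_a1": t.target_1[1],
                "target_v2": t.target_2[0],
                "target_a2": t.target_2[1],
                "jitter": t.jitter,
            }
        )
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.17g")
    return Path(path)


def read_events(path: str | Path, half_duration: float | None = None) -> TrialSchedule:
    """Load and validate an events table (the schedule constraints apply)."""
    frame = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    if not frame["onset"].is_monotonic_increasing:
        warnings.warn("events rows out of order; re-sorting by onset", stacklevel=2)
        frame = frame.sort_values("onset", ignore_index=True)
    trials = [
        Trial(
            onset=float(r.onset),
            duration=float(r.duration),
            trial_type=str(r.trial_type),
            stimulus_id=int(r.stimulus_id),
            target_region_1=int(r.target_region_1),
            target_region_2=int(r.target_region_2),
            target_1=(float(r.target_v1), float(r.target_a1)),
            target_2=(float(r.target_v2), float(r.target_a2)),
            jitter=float(r.jitter),
        )
        for r in frame.itertuples()
    ]
    if half_duration is None:
        half_duration = trials[0].duration / 2 if trials else 20.0
    return TrialSchedule(trials=trials, half_duration=half_duration)


def write_reports(traj: AffectTrajectory, path: str | Path) -> Path:
    frame = pd.DataFrame(
        {"time": traj.times, "valence": traj.valence, "arousal": traj.arousal}
    )
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.6f")
    return Path(path)


def read_reports(path: str | Path, kind: str = "reported") -> AffectTrajectory:
    frame = pd.read_csv(Path(path), sep="\t")
    for col in ("time", "valence", "arousal"):
        if col not in frame.columns:
            raise ValueError(f"reports table missing column {col!r}")
    vals = frame[["valence", "arousal"]].to_numpy(dtype=float)
    if np.nanmax(np.abs(vals)) > 1.0 + 1e-9:
        raise ValueError("valence/arousal values outside [-1, 1]")
    return AffectTrajectory(
        times=frame["time"].to_numpy(dtype=float),
        valence=vals[:, 0],
        arousal=vals[:, 1],
        kind=kind,
    )


def write_asymmetry(asym: AsymmetrySeries, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# band={asym.band.name} low_hz={asym.band.low} "
            f"high_hz={asym.band.high} rate_hz={asym.rate}\n"
        )
        fh.write("time\tvalue\n")
        for t, v in zip(asym.times, asym.values):
            fh.write(f"{t:.6f}\t{v:.9g}\n")
    return path


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    payload = {
        "seed": truth.seed,
        "eeg_valence_gain": truth.eeg_valence_gain,
        "entropy_gain": truth.entropy_gain,
        "rois": {
            name: {
                "driver": truth.roi_drivers[name],
                "amplitude": truth.roi_amplitudes[name],
                "voxel_indices": np.argwhere(mask).tolist(),
            }
            for name, mask in truth.roi_masks.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return Path(path)


def write_manifest(path: str | Path, seed: int, config: dict, inputs: dict | None = None) -> Path:
    """Run manifest: config snapshot, seed and input digests, for re-runs."""
    digests = {}
    for name, p in (inputs or {}).items():
        digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    payload = {"seed": seed, "config": config, "input_digests": digests}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
    return Path(path)
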