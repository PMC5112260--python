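"""Cohort and time-series I/O: CSV, HDF5 bundles, events TSV, optional NIfTI."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import ROITimeSeries
from .simulate import COGNITIVE_FEATURES, SyntheticCohort

__all__ = [
    "write_cognitive_csv",
    "read_cognitive_csv",
    "write_roi_timeseries_h5",
    "read_roi_timeseries_h5",
    "write_cohort",
    "read_events_tsv",
    "write_events_tsv",
    "roi_timeseries_from_nifti",
]


def write_cognitive_csv(cohort: SyntheticCohort, path) -> None:
    cohort.cognitive_frame().to_csv(path)


def read_cognitive_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    missing = [c for c in ("group", *COGNITIVE_FEATURES) if c not in df.columns]
    if missing:
        raise ValueError(f"cognitive CSV missing columns: {missing}")
    if "has_imaging" not in df.columns:
        df["has_imaging"] = False
    return df


def write_roi_timeseries_h5(ts: ROITimeSeries, path) -> None:
    labels = np.empty(ts.n_volumes, dtype="S10")
    labels[ts.structured_idx] = b"structured"
    labels[ts.random_idx] = b"random"
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=ts.Y)
        f.create_dataset("coords", data=ts.coords)
        f.create_dataset("volume_labels", data=labels)
        f.attrs["roi"] = ts.roi_name
        f.attrs["session"] = ts.session
        f.attrs["subject_id"] = ts.subject_id


def read_roi_timeseries_h5(path) -> ROITimeSeries:
    with h5py.File(path, "r") as f:
        Y = f["Y"][()]
        coords = f["coords"][()]
        labels = np.array([s.decode() for s in f["volume_labels"][()]])
        roi = f.attrs.get("roi", "")
        session = f.attrs.get("session", "")
        subject = f.attrs.get("subject_id", "")
    return ROITimeSeries(
        Y=Y,
        coords=coords,
        structured_idx=np.flatnonzero(labels == "structured"),
        random_idx=np.flatnonzero(labels == "random"),
        roi_name=str(roi),
        session=str(session),
        subject_id=str(subject),
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Cognitive CSV plus one HDF5 bundle per (subject, ROI, session)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cognitive_csv(cohort, out / "cognitive.csv")
    img_dir = out / "imaging"
    img_dir.mkdir(exist_ok=True)
    for subj, entry in cohort.imaging.items():
        for (roi, session), ts in entry.items():
            write_roi_timeseries_h5(ts, img_dir / f"{subj}_{roi}_{session}.h5")
    return out


def write_events_tsv(ts: ROITimeSeries, path) -> None:
    labels = np.empty(ts.n_volumes, dtype=object)
    labels[ts.structured_idx] = "structured"
    labels[ts.random_idx] = "random"
    pd.DataFrame({"volume_index": np.arange(ts.n_volumes), "condition": labels}) \
        .to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    for col in ("volume_index", "condition"):
        if col not in df.columns:
            raise ValueError(f"events TSV missing column {col!r}")
    s = df.loc[df["condition"] == "structured", "volume_index"].to_numpy(int)
    r = df.loc[df["condition"] == "random", "volume_index"].to_numpy(int)
    return s, r


def roi_timeseries_from_nifti(image_path, mask_path, events_path,
                              roi_name: str = "", session: str = "",
                              subject_id: str = "") -> ROITimeSeries:
    """Load a 4-D NIfTI series restricted to a binary ROI mask.

    Voxel centres come from the image affine; condition labels from a
    two-column events TSV.  Requires nibabel (``pip install pilvq[nifti]``).
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI image")
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    ijk = np.argwhere(mask)
    coords = nib.affines.apply_affine(img.affine, ijk)
    Y = data[mask]
    s_idx, r_idx = read_events_tsv(events_path)
    return ROITimeSeries(
        Y=Y, coords=coords, structured_idx=s_idx, random_idx=r_idx,
        roi_name=roi_name, session=session, subject_id=subject_id,
    )
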