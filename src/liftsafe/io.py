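"""Plain-text readers and writers for every pipeline artifact.

Signals travel as CSV with header ``t,ax,ay,az,vx,vy,vz`` (time in seconds,
acceleration in m/s^2, angular velocity in deg/s), one file per subject-trial
named ``S{id}_{safe|unsafe}.csv``.  ROI tables, feature tables and the
statistics / metrics reports are CSV or JSON.  All sample, subject and
lifting indices in files are 0-based; ROI intervals are half-open.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .features import FEATURE_COLUMNS
from .segmentation import ROI
from .synth import SixChannelSignal

__all__ = [
    "write_signal",
    "read_signal",
    "write_cohort",
    "write_roi_table",
    "read_roi_table",
    "write_feature_table",
    "read_feature_table",
]

SIGNAL_COLUMNS = ["t", "ax", "ay", "az", "vx", "vy", "vz"]
_NAME_RE = re.compile(r"S(\d+)_(safe|unsafe)\.csv$")


def signal_filename(subject_id: int, posture_class: str) -> str:
    return f"S{subject_id}_{posture_class}.csv"


def write_signal(signal: SixChannelSignal, path: str | Path) -> None:
    """Write one trial as a 7-column CSV (t + six channels)."""
    t = signal.times
    df = pd.DataFrame(
        np.column_stack([t, signal.samples]), columns=SIGNAL_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_signal(
    path: str | Path,
    subject_id: int | None = None,
    posture_class: str | None = None,
    rel_tol: float = 1e-3,
) -> SixChannelSignal:
    """Read a trial CSV back into a :class:`SixChannelSignal`.

    Subject id and posture class are parsed from the ``S{id}_{class}.csv``
    filename unless given explicitly.  The time column must advance on a
    uniform grid; the first row violating the tolerance is named in the
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: unparseable CSV ({exc})") from exc
    if list(df.columns) != SIGNAL_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {SIGNAL_COLUMNS}, found {list(df.columns)}"
        )
    for col in SIGNAL_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise FormatError(f"{path}: non-numeric or missing value in column "
                              f"{col!r} at row {row}")
        df[col] = numeric
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    t = df["t"].to_numpy()
    dt = np.diff(t)
    step = np.median(dt)
    if step <= 0:
        raise FormatError(f"{path}: non-increasing time column")
    off = np.abs(dt - step) > rel_tol * step
    if off.any():
        row = int(np.argmax(off)) + 1
        raise FormatError(f"{path}: irregular time step at row {row}")

    if subject_id is None or posture_class is None:
        m = _NAME_RE.search(path.name)
        if m is None:
            raise FormatError(
                f"{path}: cannot infer subject/class from filename; pass them explicitly"
            )
        subject_id = int(m.group(1)) if subject_id is None else subject_id
        posture_class = m.group(2) if posture_class is None else posture_class

    return SixChannelSignal(
        samples=df[SIGNAL_COLUMNS[1:]].to_numpy(),
        sampling_rate=1.0 / step,
        subject_id=subject_id,
        posture_class=posture_class,
    )


def write_cohort(
    cohort, out_dir: str | Path, cohort_seed: int | None = None
) -> dict:
    """Write every trial of a cohort plus a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"cohort_seed": cohort_seed, "trials": []}
    for profile, safe_sig, unsafe_sig in cohort:
        for sig in (safe_sig, unsafe_sig):
            fname = signal_filename(sig.subject_id, sig.posture_class)
            write_signal(sig, out_dir / fname)
            manifest["trials"].append(
                {
                    "file": fname,
                    "subject": sig.subject_id,
                    "label": sig.posture_class,
                    "n_samples": sig.n_samples,
                    "sampling_rate": sig.sampling_rate,
                    "rng_seed": profile.rng_seed,
                }
            )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ------------------------------------------------------------------- ROI I/O
def write_roi_table(
    rois_by_trial: dict[tuple[int, str], list[ROI]], path: str | Path
) -> None:
    """ROI table CSV: subject, trial (class label), lifting_index, start, stop."""
    rows = [
        {"subject": sid, "trial": label, "lifting_index": roi.lifting_index,
         "start": roi.start, "stop": roi.stop}
        for (sid, label), rois in rois_by_trial.items()
        for roi in rois
    ]
    pd.DataFrame(
        rows, columns=["subject", "trial", "lifting_index", "start", "stop"]
    ).to_csv(path, index=False)


def read_roi_table(path: str | Path) -> dict[tuple[int, str], list[ROI]]:
    df = pd.read_csv(path)
    expected = ["subject", "trial", "lifting_index", "start", "stop"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    out: dict[tuple[int, str], list[ROI]] = {}
    for _, r in df.iterrows():
        key = (int(r["subject"]), str(r["trial"]))
        out.setdefault(key, []).append(
            ROI(start=int(r["start"]), stop=int(r["stop"]),
                subject_id=int(r["subject"]), lifting_index=int(r["lifting_index"]))
        )
    for rois in out.values():
        rois.sort(key=lambda r: r.start)
    return out


# --------------------------------------------------------------- feature I/O
def write_feature_table(dataset: pd.DataFrame, path: str | Path) -> None:
    """Write the supervised feature table (54 feature columns + identifiers)."""
    required = ["subject", "lifting_id", "label", *FEATURE_COLUMNS]
    missing = [c for c in required if c not in dataset.columns]
    if missing:
        raise DataError(f"feature table missing columns: {missing[:5]}...")
    if dataset.duplicated(subset=["subject", "lifting_id", "label"]).any():
        raise DataError("duplicate (subject, lifting_id, label) rows in feature table")
    dataset[required].to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["subject", "lifting_id", "label", *FEATURE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature columns {missing[:5]}...")
    if df[list(FEATURE_COLUMNS)].isna().any().any():
        raise FormatError(f"{path}: missing values in feature columns")
    return df
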