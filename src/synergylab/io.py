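"""On-disk formats for EMG datasets and pipeline products.

Everything is comma-delimited UTF-8 text with a header row, plus one JSON
report per run. Signals are stored one CSV per trial (samples x 8 muscle
columns, header = muscle names) next to a ``metadata.csv`` table. Vendor
acquisition formats (C3D, OTB) are deliberately unsupported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

N_MUSCLES = 8
DEFAULT_MUSCLES = [
    "trapezius", "deltoid_ant", "deltoid_med", "deltoid_post",
    "pectoralis", "infraspinatus", "biceps", "triceps",
]
TRIAL_TYPES = ("reach", "mvc", "baseline")
GROUPS = ("control", "study")

METADATA_COLUMNS = [
    "trial_id", "subject", "group", "target", "repetition", "trial_type", "mvc_muscle",
]


class DatasetError(ValueError):
    """Raised when a dataset on disk or in memory violates the study design."""


@dataclass
class EmgDataset:
    """Raw multichannel recordings plus the trial-metadata table.

    ``signals`` maps trial-id to a (samples x 8) float array in volts;
    ``metadata`` is indexed by trial-id with columns subject, group, target,
    repetition, trial_type, mvc_muscle. Reach trials carry target 1..9 and
    repetition 1..5; each MVC trial names exactly one muscle.
    """

    signals: Dict[str, np.ndarray]
    metadata: pd.DataFrame
    sampling_rate: float = 2000.0
    muscle_names: List[str] = field(default_factory=lambda: list(DEFAULT_MUSCLES))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.muscle_names) != N_MUSCLES:
            raise DatasetError(f"expected {N_MUSCLES} muscles, got {len(self.muscle_names)}")
        if self.sampling_rate <= 0:
            raise DatasetError("sampling_rate must be positive")
        md = self.metadata
        missing = set(self.signals) ^ set(md.index)
        if missing:
            raise DatasetError(f"metadata/signal mismatch for trials: {sorted(missing)[:5]}")
        for trial_id, sig in self.signals.items():
            if sig.ndim != 2 or sig.shape[1] != N_MUSCLES:
                raise DatasetError(
                    f"trial {trial_id!r}: expected samples x {N_MUSCLES} array, got shape {sig.shape}"
                )
            if not np.isfinite(sig).all():
                raise DatasetError(f"trial {trial_id!r}: non-finite sample values")
        for trial_id, row in md.iterrows():
            ttype = row["trial_type"]
            if ttype not in TRIAL_TYPES:
                raise DatasetError(f"trial {trial_id!r}: unknown trial_type {ttype!r}")
            if row["group"] not in GROUPS:
                raise DatasetError(f"trial {trial_id!r}: unknown group {row['group']!r}")
            if ttype == "reach":
                target, rep = row["target"], row["repetition"]
                if pd.isna(target) or not 1 <= int(target) <= 9:
                    raise DatasetError(f"trial {trial_id!r}: reach target must be 1..9, got {target!r}")
                if pd.isna(rep) or not 1 <= int(rep) <= 5:
                    raise DatasetError(f"trial {trial_id!r}: repetition must be 1..5, got {rep!r}")
            elif ttype == "mvc":
                muscle = row["mvc_muscle"]
                if muscle not in self.muscle_names:
                    raise DatasetError(f"trial {trial_id!r}: mvc_muscle {muscle!r} not a recorded muscle")

    @property
    def trial_ids(self) -> List[str]:
        return list(self.metadata.index)

    def trials_of_type(self, trial_type: str) -> pd.DataFrame:
        return self.metadata[self.metadata["trial_type"] == trial_type]

    @property
    def subjects(self) -> List[str]:
        return sorted(self.metadata["subject"].unique())


def _read_signal_file(path: Path, muscle_names: Optional[List[str]]) -> tuple[np.ndarray, List[str]]:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise DatasetError(f"cannot read signal file {path}: {exc}") from exc
    if frame.shape[1] != N_MUSCLES:
        raise DatasetError(f"{path}: expected {N_MUSCLES} channels, found {frame.shape[1]}")
    header = [str(c) for c in frame.columns]
    if muscle_names is not None:
        if set(header) != set(muscle_names):
            raise DatasetError(f"{path}: muscle header {header} does not match canonical {muscle_names}")
        frame = frame[muscle_names]  # enforce canonical channel order
        header = muscle_names
    values = frame.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DatasetError(f"{path}: non-numeric or non-finite cell")
    return values, header


def read_dataset(signals_dir: str | Path, metadata_file: str | Path) -> EmgDataset:
    """Load an :class:`EmgDataset` from a signals directory and a metadata CSV.

    Muscle order is taken from the first trial's file (metadata order) and
    enforced on every other file; files with permuted headers are reordered.
    """
    signals_dir = Path(signals_dir)
    metadata_file = Path(metadata_file)
    if not metadata_file.exists():
        raise DatasetError(f"metadata file not found: {metadata_file}")
    md = pd.read_csv(metadata_file)
    missing_cols = set(METADATA_COLUMNS) - set(md.columns)
    if missing_cols:
        raise DatasetError(f"metadata missing columns: {sorted(missing_cols)}")
    md = md.set_index("trial_id")
    if md.index.has_duplicates:
        raise DatasetError("duplicate trial_id in metadata")

    meta_path = metadata_file.parent / "dataset.json"
    sampling_rate = 2000.0
    if meta_path.exists():
        sampling_rate = float(json.loads(meta_path.read_text()).get("sampling_rate", 2000.0))

    signals: Dict[str, np.ndarray] = {}
    muscle_names: Optional[List[str]] = None
    for trial_id in md.index:
        path = signals_dir / f"{trial_id}.csv"
        if not path.exists():
            raise DatasetError(f"trial {trial_id!r}: signal file missing ({path})")
        values, header = _read_signal_file(path, muscle_names)
        if muscle_names is None:
            muscle_names = header
        signals[str(trial_id)] = values
    md.index = md.index.astype(str)
    return EmgDataset(signals=signals, metadata=md, sampling_rate=sampling_rate,
                      muscle_names=muscle_names or list(DEFAULT_MUSCLES))


def write_dataset(dataset: EmgDataset, out_dir: str | Path) -> Path:
    """Write a dataset as per-trial CSVs plus metadata.csv and dataset.json."""
    out_dir = Path(out_dir)
    sig_dir = out_dir / "signals"
    sig_dir.mkdir(parents=True, exist_ok=True)
    for trial_id, sig in dataset.signals.items():
        frame = pd.DataFrame(sig, columns=dataset.muscle_names)
        frame.to_csv(sig_dir / f"{trial_id}.csv", index=False, float_format="%.17g")
    dataset.metadata.reset_index().rename(columns={"index": "trial_id"}).to_csv(
        out_dir / "metadata.csv", index=False
    )
    (out_dir / "dataset.json").write_text(json.dumps({
        "sampling_rate": dataset.sampling_rate,
        "muscle_names": dataset.muscle_names,
        "n_trials": len(dataset.signals),
    }, indent=2))
    return out_dir


def write_matrix(values: np.ndarray, path: str | Path,
                 row_labels=None, col_labels=None) -> Path:
    """Write a labelled matrix as CSV at full double precision."""
    values = np.asarray(values)
    frame = pd.DataFrame(values, index=row_labels, columns=col_labels)
    frame.to_csv(path, index=row_labels is not None, float_format="%.17g")
    return Path(path)


def read_matrix(path: str | Path, has_index: bool = True) -> np.ndarray:
    frame = pd.read_csv(path, index_col=0 if has_index else None)
    return frame.to_numpy(dtype=float)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, out_dir: str | Path) -> List[Path]:
    """Write pipeline products: arrays/frames as CSV, scalars into report.json.

    ``results`` maps names to numpy arrays, DataFrames, scalars, or nested
    dicts of scalars. Returns the list of written paths; an empty ``results``
    still produces a report.json with run metadata only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    scalars: dict = {}
    for name, value in results.items():
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            value.to_csv(path, float_format="%.17g")
            written.append(path)
        elif isinstance(value, np.ndarray):
            written.append(write_matrix(value, out_dir / f"{name}.csv"))
        else:
            scalars[name] = _jsonable(value)
    report = out_dir / "report.json"
    report.write_text(json.dumps({"artifacts": [p.name for p in written], **scalars},
                                 indent=2, sort_keys=False))
    written.append(report)
    return written
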