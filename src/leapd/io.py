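"""Reading and writing EEG recordings and subject tables.

The canonical fixture format is a plain TSV matrix (channels as rows)
with a JSON sidecar carrying the subject id, channel labels and sample
rate — language-neutral and diff-able.  BrainVision and EDF reading
delegate to MNE when it is installed.  Subject tables are CSV with a
header ``id,group,age,<score...>``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "SubjectRecord",
    "Dataset",
    "read_eeg",
    "write_matrix",
    "load_subject_table",
    "write_subject_table",
    "validate_dataset",
]

GROUPS = ("PD", "control")
#: score columns recognised by name in subject tables
KNOWN_SCORES = ("moca", "pvt", "pcpst", "dccst", "ficat", "psmt")


@dataclass
class EEGRecording:
    """One subject's multichannel recording (channels x samples)."""

    subject_id: str
    channel_labels: list[str]
    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.shape[1] / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        """Samples of one channel by exact (case-sensitive) label."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording {self.subject_id!r}"
            ) from None
        return self.samples[i]


@dataclass
class SubjectRecord:
    id: str
    group: str
    age: float
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (self.age > 0):
            raise ValueError(f"age must be positive, got {self.age}")
        moca = self.scores.get("moca")
        if moca is not None:
            if moca != int(moca) or not (0 <= moca <= 30):
                raise ValueError(
                    f"MoCA must be an integer in [0, 30], got {moca} "
                    f"(subject {self.id})"
                )


@dataclass
class Dataset:
    """Subject table plus one recording per subject."""

    subjects: list[SubjectRecord]
    recordings: dict[str, EEGRecording]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def sample_rate(self) -> float:
        return next(iter(self.recordings.values())).sample_rate

    @property
    def channel_labels(self) -> list[str]:
        return next(iter(self.recordings.values())).channel_labels

    def scores(self, name: str) -> np.ndarray:
        return np.array([s.scores[name] for s in self.subjects], dtype=float)

    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_matrix(rec: EEGRecording, path) -> None:
    """Write a recording as TSV (channels as rows) + JSON sidecar."""
    if rec.n_channels == 0:
        raise ValueError("cannot write a recording with 0 channels")
    path = Path(path)
    np.savetxt(path, rec.samples, delimiter="\t", fmt="%.10g")
    meta = {
        "subject_id": rec.subject_id,
        "channel_labels": list(rec.channel_labels),
        "sample_rate": rec.sample_rate,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_matrix(path: Path) -> EEGRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"matrix recording {path} is missing its metadata sidecar {sidecar} "
            "(required fields: subject_id, channel_labels, sample_rate)"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("subject_id", "channel_labels", "sample_rate"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required field {key!r}")
    samples = np.loadtxt(path, delimiter="\t", ndmin=2)
    return EEGRecording(
        subject_id=str(meta["subject_id"]),
        channel_labels=[str(c) for c in meta["channel_labels"]],
        sample_rate=float(meta["sample_rate"]),
        samples=samples,
    )


def _read_mne(path: Path, format: str) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            f"reading {format} files requires the 'mne' package "
            "(pip install leapd[eeg-formats])"
        ) from exc
    reader = {
        "brainvision": mne.io.read_raw_brainvision,
        "edf": mne.io.read_raw_edf,
    }[format]
    raw = reader(str(path), preload=True, verbose="error")
    return EEGRecording(
        subject_id=path.stem,
        channel_labels=list(raw.ch_names),
        sample_rate=float(raw.info["sfreq"]),
        samples=raw.get_data(),
    )


def read_eeg(path, format: str = "matrix") -> EEGRecording:
    """Read one recording. ``format`` is 'matrix', 'brainvision' or 'edf'."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix":
        return _read_matrix(path)
    if format in ("brainvision", "edf"):
        return _read_mne(path, format)
    raise ValueError(f"unknown EEG format {format!r}")


def load_subject_table(path) -> list[SubjectRecord]:
    """Load a subject CSV with columns id, group, age and >=1 score column."""
    df = pd.read_csv(path)
    required = {"id", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table is missing columns: {sorted(missing)}")
    score_cols = [c for c in df.columns if c not in required]
    if not score_cols:
        raise ValueError("subject table needs at least one score column")
    dup = df["id"].astype(str)[df["id"].astype(str).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")
    if df["age"].isna().any():
        bad = df.loc[df["age"].isna(), "id"].tolist()
        raise ValueError(
            f"missing age for subjects {bad}; age is required "
            "(it is the covariate of the partial correlations)"
        )
    records = []
    for row in df.itertuples(index=False):
        scores = {
            c: float(getattr(row, c))
            for c in score_cols
            if pd.notna(getattr(row, c))
        }
        records.append(
            SubjectRecord(
                id=str(row.id), group=str(row.group), age=float(row.age),
                scores=scores,
            )
        )
    return records


def write_subject_table(subjects: list[SubjectRecord], path) -> None:
    score_names = sorted({k for s in subjects for k in s.scores})
    rows = [
        {"id": s.id, "group": s.group, "age": s.age,
         **{k: s.scores.get(k) for k in score_names}}
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_dataset(ds: Dataset) -> list[str]:
    """Integrity report: empty list iff the dataset invariants hold."""
    problems: list[str] = []
    ids = ds.ids
    seen = set()
    for i in ids:
        if i in seen:
            problems.append(f"duplicate subject id {i!r}")
        seen.add(i)
    for i in ids:
        if i not in ds.recordings:
            problems.append(f"subject {i!r} has no recording")
    if ds.recordings:
        ref = next(iter(ds.recordings.values()))
        for i, rec in ds.recordings.items():
            if rec.sample_rate != ref.sample_rate:
                problems.append(
                    f"recording {i!r} sample rate {rec.sample_rate} != "
                    f"{ref.sample_rate}"
                )
            if rec.channel_labels != ref.channel_labels:
                problems.append(f"recording {i!r} channel labels differ")
    return problems


def load_dataset(data_dir, subjects_csv) -> Dataset:
    """Load a directory of matrix recordings (<id>.tsv) plus a subject CSV."""
    subjects = load_subject_table(subjects_csv)
    data_dir = Path(data_dir)
    recordings = {}
    for s in subjects:
        recordings[s.id] = read_eeg(data_dir / f"{s.id}.tsv", format="matrix")
    return Dataset(subjects=subjects, recordings=recordings)


def save_dataset(ds: Dataset, data_dir, subjects_csv=None) -> None:
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    for i, rec in ds.recordings.items():
        write_matrix(rec, data_dir / f"{i}.tsv")
    write_subject_table(ds.subjects, subjects_csv or data_dir / "subjects.csv")
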