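"""Plain-text I/O for center-of-pressure (COP) trials, cohort manifests and
feature tables.

All files are comma-separated UTF-8 with ``.`` as the decimal mark and
missing values spelled ``NA``.  A COP trial file carries one quiet-stance
recording as three columns ``t_s,ap_mm,ml_mm`` (time in seconds,
anteroposterior and mediolateral COP coordinates in millimetres).  The
stance condition (eyes open / eyes closed) is *not* encoded in the trial
file; it is carried by the cohort manifest, which maps each subject to one
eyes-open and one eyes-closed recording.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Group",
    "CopTrial",
    "SubjectRecord",
    "CopFormatError",
    "ManifestError",
    "read_cop_csv",
    "write_cop_csv",
    "read_manifest",
    "write_manifest",
    "read_feature_table",
    "write_feature_table",
]

#: Relative tolerance on sampling-interval dispersion before a trial file is
#: rejected as non-uniformly sampled.
DT_TOLERANCE = 0.01


class Condition(str, enum.Enum):
    """Stance condition of a trial: eyes open or eyes closed."""

    EO = "EO"
    EC = "EC"


class Group(str, enum.Enum):
    """Cohort arm: healthy older adult control or Parkinson's disease."""

    HOA = "HOA"
    PD = "PD"


class CopFormatError(ValueError):
    """Raised when a COP trial file violates the expected CSV schema."""


class ManifestError(ValueError):
    """Raised when a cohort manifest is inconsistent."""


@dataclass(frozen=True)
class CopTrial:
    """One condition's COP trajectory.

    Parameters
    ----------
    condition : Condition
        Stance condition the trajectory was recorded under.
    fs : float
        Sampling rate in Hz (10 Hz for the reference protocol).
    ap, ml : ndarray
        Anteroposterior and mediolateral COP coordinates in mm, equal
        length, at least 3 samples, all finite.
    """

    condition: Condition
    fs: float
    ap: np.ndarray
    ml: np.ndarray

    def __post_init__(self) -> None:
        ap = np.asarray(self.ap, dtype=float)
        ml = np.asarray(self.ml, dtype=float)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "condition", Condition(self.condition))
        if ap.ndim != 1 or ml.ndim != 1 or len(ap) != len(ml):
            raise ValueError("ap and ml must be 1-D sequences of equal length")
        if len(ap) < 3:
            raise CopFormatError(
                f"trial too short: {len(ap)} samples, need at least 3"
            )
        if not (np.isfinite(ap).all() and np.isfinite(ml).all()):
            raise ValueError("COP coordinates must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.ap)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.ap) / self.fs


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: group label plus exactly one EO and one EC trial."""

    subject_id: str
    group: Group
    trials: dict[Condition, CopTrial] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        trials = {Condition(c): t for c, t in self.trials.items()}
        object.__setattr__(self, "trials", trials)
        if set(trials) != {Condition.EO, Condition.EC}:
            raise ValueError(
                f"subject {self.subject_id!r} needs exactly one EO and one "
                f"EC trial, got {sorted(c.value for c in trials)}"
            )
        for cond, trial in trials.items():
            if trial.condition != cond:
                raise ValueError(
                    f"trial stored under {cond.value} is labelled "
                    f"{trial.condition.value}"
                )


def read_cop_csv(path: str | Path, condition: Condition | str) -> CopTrial:
    """Read a COP trial CSV (``t_s,ap_mm,ml_mm``).

    The sampling rate is inferred as ``1 / median(dt)`` rounded to three
    decimals, never trusted from metadata; files whose sampling interval
    varies by more than 1% relative to the median are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except ValueError as exc:
        raise CopFormatError(f"{path}: non-numeric cell ({exc})") from exc
    expected = ["t_s", "ap_mm", "ml_mm"]
    if list(df.columns) != expected:
        raise CopFormatError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    if len(df) < 3:
        raise CopFormatError(f"{path}: trial too short ({len(df)} rows)")
    if df.isna().any().any():
        raise CopFormatError(f"{path}: missing cells in trial file")
    t = df["t_s"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise CopFormatError(f"{path}: time column not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > DT_TOLERANCE * med:
        raise CopFormatError(
            f"{path}: non-uniform sampling (dt varies by more than "
            f"{DT_TOLERANCE:.0%} around the median {med:g} s)"
        )
    fs = round(1.0 / med, 3)
    return CopTrial(
        condition=Condition(condition),
        fs=fs,
        ap=df["ap_mm"].to_numpy(),
        ml=df["ml_mm"].to_numpy(),
    )


def write_cop_csv(trial: CopTrial, path: str | Path) -> None:
    """Write a trial as ``t_s,ap_mm,ml_mm`` on a uniform time grid."""
    t = np.arange(len(trial)) / trial.fs
    df = pd.DataFrame({"t_s": t, "ap_mm": trial.ap, "ml_mm": trial.ml})
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort manifest CSV ``subject_id,group,eo_path,ec_path``.

    Trial paths are resolved relative to the manifest's directory.
    Manifest order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["subject_id", "group", "eo_path", "ec_path"]
    if list(df.columns) != expected:
        raise ManifestError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestError(f"{path}: duplicate subject_id(s): {dupes}")
    records = []
    for row in df.itertuples(index=False):
        try:
            group = Group(row.group)
        except ValueError:
            raise ManifestError(
                f"{path}: unknown group label {row.group!r} for subject "
                f"{row.subject_id!r}"
            ) from None
        trials = {}
        for cond, rel in ((Condition.EO, row.eo_path), (Condition.EC, row.ec_path)):
            trial_path = path.parent / rel
            if not trial_path.exists():
                raise ManifestError(f"{path}: missing trial file {trial_path}")
            trials[cond] = read_cop_csv(trial_path, cond)
        records.append(
            SubjectRecord(subject_id=row.subject_id, group=group, trials=trials)
        )
    return records


def write_manifest(
    records: list[SubjectRecord], directory: str | Path, name: str = "manifest.csv"
) -> Path:
    """Write all trials plus a manifest CSV into ``directory``.

    Returns the manifest path.  Trial files are named
    ``<subject_id>_<EO|EC>.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        paths = {}
        for cond in (Condition.EO, Condition.EC):
            fname = f"{rec.subject_id}_{cond.value}.csv"
            write_cop_csv(rec.trials[cond], directory / fname)
            paths[cond] = fname
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group.value,
                "eo_path": paths[Condition.EO],
                "ec_path": paths[Condition.EC],
            }
        )
    manifest_path = directory / name
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def _feature_columns() -> list[str]:
    from .features import FEATURE_NAMES

    return ["subject_id", "group", *FEATURE_NAMES]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (id, label and the 34 canonical parameters).

    Columns are reordered into canonical order; a table with missing or
    extra columns is rejected.  Floats are written at full precision so the
    round trip through :func:`read_feature_table` is lossless; missing
    cells are spelled ``NA``.
    """
    cols = _feature_columns()
    if set(table.columns) != set(cols):
        missing = sorted(set(cols) - set(table.columns))
        extra = sorted(set(table.columns) - set(cols))
        raise ValueError(
            f"feature table columns mismatch (missing {missing}, extra {extra})"
        )
    table[cols].to_csv(path, index=False, na_rep="NA")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    cols = _feature_columns()
    df = pd.read_csv(
        path,
        keep_default_na=False,
        na_values=["NA"],
        dtype={"subject_id": str, "group": str},
        float_precision="round_trip",
    )
    if list(df.columns) != cols:
        raise ValueError(
            f"{path}: expected canonical feature-table columns, got "
            f"{list(df.columns)}"
        )
    for c in cols[2:]:
        df[c] = df[c].astype(float)
    return df
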