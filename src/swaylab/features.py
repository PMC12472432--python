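"""The 17 stabilometric parameters per stance condition (34 per subject).

Time domain (11): total oscillation displacement (TOD, mm), per-axis
standard deviation and RMS of COP displacement (mm), per-axis peak-to-peak
displacement amplitude (mm), per-axis and total mean sway velocity (mm/s),
and the 95% confidence-ellipse area (mm^2).  Frequency domain (6): per-axis
power summed in three bands of the FFT periodogram — LF 0.01-0.1 Hz,
MF >0.1-0.5 Hz, HF >0.5-1.0 Hz (mm^2/Hz).

All parameters are computed from bandpass-filtered, linearly detrended
signals, so Std (about the mean) and RMS (about zero) coincide to
within numerical tolerance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .io_formats import Condition, CopTrial, SubjectRecord
from .preprocess import FilterSpec, preprocess_axis

__all__ = [
    "FEATURE_NAMES",
    "BASE_FEATURE_NAMES",
    "CHI2_95_2DF",
    "compute_tod",
    "compute_std_rms",
    "compute_amplitude",
    "compute_velocity",
    "compute_total_velocity",
    "compute_ellipse_area",
    "compute_band_powers",
    "condition_features",
    "extract_features",
    "build_feature_table",
]

#: Canonical per-condition parameter order.
BASE_FEATURE_NAMES: tuple[str, ...] = (
    "TOD",
    "Std-AP",
    "Std-ML",
    "RMS-AP",
    "RMS-ML",
    "DA-AP",
    "DA-ML",
    "V-AP",
    "V-ML",
    "Area",
    "V-T",
    "LF-AP",
    "MF-AP",
    "HF-AP",
    "LF-ML",
    "MF-ML",
    "HF-ML",
)

#: Canonical 34-name order: eyes-open block then the ``_EC`` block.
FEATURE_NAMES: tuple[str, ...] = BASE_FEATURE_NAMES + tuple(
    f"{n}_EC" for n in BASE_FEATURE_NAMES
)

#: 95th percentile of chi-square with 2 df — the confidence-ellipse multiplier.
CHI2_95_2DF: float = float(_stats.chi2.ppf(0.95, df=2))

#: Spectral band edges in Hz: LF = [0.01, 0.1], MF = (0.1, 0.5], HF = (0.5, 1.0].
BANDS: tuple[tuple[float, float], ...] = ((0.01, 0.1), (0.1, 0.5), (0.5, 1.0))


def _check_pair(ap: np.ndarray, ml: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ap = np.asarray(ap, dtype=float)
    ml = np.asarray(ml, dtype=float)
    if ap.shape != ml.shape or ap.ndim != 1:
        raise ValueError("ap and ml must be 1-D arrays of equal length")
    return ap, ml


def compute_tod(ap: np.ndarray, ml: np.ndarray) -> float:
    """Total oscillation displacement: sum of distances of each COP sample
    from the mean COP position (mm)."""
    ap, ml = _check_pair(ap, ml)
    if len(ap) < 1:
        raise ValueError("empty trajectory")
    return float(np.sum(np.hypot(ap - ap.mean(), ml - ml.mean())))


def compute_std_rms(x: np.ndarray) -> tuple[float, float]:
    """Standard deviation about the sample mean (N-1 denominator) and RMS
    about zero (N denominator), both in mm."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    std = float(np.std(x, ddof=1))
    rms = float(np.sqrt(np.mean(x**2)))
    return std, rms


def compute_amplitude(x: np.ndarray) -> float:
    """Peak-to-peak displacement amplitude: max(x) - min(x) (mm)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 1:
        raise ValueError("empty sequence")
    return float(np.max(x) - np.min(x))


def compute_velocity(x: np.ndarray, fs: float) -> float:
    """Mean sway velocity along one axis (mm/s): sum of absolute successive
    differences times the sampling rate, divided by the number of
    displacement intervals (N-1)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))) * fs / (len(x) - 1))


def compute_total_velocity(ap: np.ndarray, ml: np.ndarray, fs: float) -> float:
    """Total mean sway velocity (mm/s): sum of 2-D step magnitudes times the
    sampling rate, divided by the number of intervals."""
    ap, ml = _check_pair(ap, ml)
    if len(ap) < 2:
        raise ValueError("need at least 2 samples")
    steps = np.hypot(np.diff(ap), np.diff(ml))
    return float(np.sum(steps) * fs / (len(ap) - 1))


def compute_ellipse_area(
    ap: np.ndarray, ml: np.ndarray, multiplier: float = CHI2_95_2DF
) -> float:
    """Area of the 95% confidence ellipse (mm^2).

    ``pi * multiplier * sqrt(det(S))`` with ``S`` the 2x2 sample covariance
    (N-1) of the AP/ML pair and the multiplier defaulting to the 95th
    chi-square percentile with 2 df (5.991...).  A degenerate (singular)
    covariance — e.g. collinear points — yields area 0.
    """
    ap, ml = _check_pair(ap, ml)
    if len(ap) < 3:
        raise ValueError("need at least 3 samples for a covariance ellipse")
    cov = np.cov(ap, ml, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0:
        # numerically singular covariance: flag by returning exactly 0
        return 0.0
    return float(np.pi * multiplier * np.sqrt(det))


def periodogram_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided boxcar periodogram with density scaling.

    Normalised so that ``sum(P) * df == mean(x**2)`` (Parseval); for a
    detrended signal this equals the (N-denominator) variance.
    """
    x = np.asarray(x, dtype=float)
    return _signal.periodogram(
        x, fs=fs, window="boxcar", detrend=False, scaling="density"
    )


def compute_band_powers(
    x: np.ndarray, fs: float, integrate: bool = False
) -> tuple[float, float, float]:
    """LF/MF/HF spectral power of one axis.

    Band values are sums of periodogram density ordinates (mm^2/Hz) over
    LF = [0.01, 0.1] Hz, MF = (0.1, 0.5] Hz, HF = (0.5, 1.0] Hz.  With
    ``integrate=True`` each sum is multiplied by the bin width, yielding
    integrated band power in mm^2 instead.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 samples for band powers")
    if fs < 2.0:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve the 1.0 Hz band edge"
        )
    f, p = periodogram_psd(x, fs)
    df = f[1] - f[0]
    out = []
    for i, (lo, hi) in enumerate(BANDS):
        if i == 0:
            mask = (f >= lo) & (f <= hi)  # LF includes its lower edge
        else:
            mask = (f > lo) & (f <= hi)
        val = float(np.sum(p[mask]))
        out.append(val * df if integrate else val)
    return tuple(out)  # type: ignore[return-value]


def condition_features(
    ap: np.ndarray, ml: np.ndarray, fs: float, integrate_bands: bool = False
) -> dict[str, float]:
    """All 17 parameters from one condition's *preprocessed* AP/ML pair."""
    std_ap, rms_ap = compute_std_rms(ap)
    std_ml, rms_ml = compute_std_rms(ml)
    lf_ap, mf_ap, hf_ap = compute_band_powers(ap, fs, integrate_bands)
    lf_ml, mf_ml, hf_ml = compute_band_powers(ml, fs, integrate_bands)
    return {
        "TOD": compute_tod(ap, ml),
        "Std-AP": std_ap,
        "Std-ML": std_ml,
        "RMS-AP": rms_ap,
        "RMS-ML": rms_ml,
        "DA-AP": compute_amplitude(ap),
        "DA-ML": compute_amplitude(ml),
        "V-AP": compute_velocity(ap, fs),
        "V-ML": compute_velocity(ml, fs),
        "Area": compute_ellipse_area(ap, ml),
        "V-T": compute_total_velocity(ap, ml, fs),
        "LF-AP": lf_ap,
        "MF-AP": mf_ap,
        "HF-AP": hf_ap,
        "LF-ML": lf_ml,
        "MF-ML": mf_ml,
        "HF-ML": hf_ml,
    }


def extract_features(
    rec: SubjectRecord,
    spec: FilterSpec = FilterSpec(),
    integrate_bands: bool = False,
) -> pd.Series:
    """Extract the 34-parameter feature vector for one subject.

    Each trial's axes are bandpass-filtered and detrended, then the 17
    parameters are computed per condition; the eyes-closed block carries
    the ``_EC`` suffix.  Returns a Series indexed by :data:`FEATURE_NAMES`.
    """
    values: dict[str, float] = {}
    for cond, suffix in ((Condition.EO, ""), (Condition.EC, "_EC")):
        trial: CopTrial = rec.trials[cond]
        ap = preprocess_axis(trial.ap, trial.fs, spec)
        ml = preprocess_axis(trial.ml, trial.fs, spec)
        feats = condition_features(ap, ml, trial.fs, integrate_bands)
        for name, val in feats.items():
            values[f"{name}{suffix}"] = val
    out = pd.Series(values).reindex(FEATURE_NAMES)
    assert not out.isna().any()
    return out


def build_feature_table(
    records: list[SubjectRecord],
    spec: FilterSpec = FilterSpec(),
    integrate_bands: bool = False,
) -> pd.DataFrame:
    """Feature table for a cohort: ``subject_id``, ``group`` and the 34
    canonical parameters, one row per subject in input order."""
    seen = set()
    rows = []
    for rec in records:
        if rec.subject_id in seen:
            raise ValueError(f"duplicate subject_id {rec.subject_id!r}")
        seen.add(rec.subject_id)
        row = {"subject_id": rec.subject_id, "group": rec.group.value}
        row.update(extract_features(rec, spec, integrate_bands))
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "group", *FEATURE_NAMES])
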