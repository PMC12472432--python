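"""COP signal conditioning: bandpass filtering, linear detrending, and
feature-level mean imputation.

The reference protocol filters each COP axis with a 4th-order Butterworth
bandpass (0.005-4.9 Hz) and removes the residual linear trend.  At a 10 Hz
sampling rate the upper cutoff sits at 0.98 of Nyquist, so the filter is
designed in second-order sections.  Application is zero-phase
(forward-backward) by default, which preserves the temporal alignment of
the AP/ML pair; a single-pass mode is retained as a sensitivity switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FilterSpec",
    "bandpass_filter",
    "detrend_linear",
    "MeanImputer",
    "impute_train_mean",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design parameters.

    ``order`` is the design order passed to the Butterworth design (before
    the forward-backward pass, which squares the magnitude response).
    """

    order: int = 4
    low_hz: float = 0.005
    high_hz: float = 4.9
    mode: str = "zero_phase"  # or "single_pass"

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz must lie below Nyquist "
                f"({fs / 2} Hz)"
            )
        if self.mode not in ("zero_phase", "single_pass"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order-section coefficients for ``spec`` at sampling rate ``fs``."""
    spec.validate(fs)
    return signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs,
        output="sos",
    )


def bandpass_filter(
    x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Bandpass-filter one COP axis.

    Zero-phase mode runs the filter forward and backward with odd-symmetric
    edge padding of length ``3 * order``; single-pass mode runs it once
    (causal, with phase lag).  Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    if len(x) < 3 * spec.order:
        raise ValueError(
            f"sequence too short to filter: {len(x)} < {3 * spec.order}"
        )
    sos = design_sos(spec, fs)
    if spec.mode == "zero_phase":
        return signal.sosfiltfilt(sos, x, padtype="odd", padlen=3 * spec.order)
    return signal.sosfilt(sos, x)


def detrend_linear(x: np.ndarray) -> np.ndarray:
    """Residuals of the least-squares straight line through ``x``.

    The result is orthogonal to both the constant and the linear basis, so
    detrending is idempotent and the output has (numerically) zero mean.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to detrend")
    return signal.detrend(x, type="linear")


def preprocess_axis(
    x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Standard conditioning for one axis: bandpass filter then detrend."""
    return detrend_linear(bandpass_filter(x, fs, spec))


class MeanImputer:
    """Per-feature mean imputation fitted on training rows only.

    Mirrors the leak-free protocol: fill values are the column means of the
    *training* partition and are reused verbatim on held-out rows.
    """

    def __init__(self) -> None:
        self.means_: pd.Series | None = None

    def fit(self, table: pd.DataFrame, columns: list[str]) -> "MeanImputer":
        means = table[columns].mean(axis=0, skipna=True)
        empty = means.index[means.isna()].tolist()
        if empty:
            raise ValueError(
                f"feature(s) entirely missing in the training rows: {empty}"
            )
        self.means_ = means
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise RuntimeError("imputer not fitted")
        out = table.copy()
        out[self.means_.index] = out[self.means_.index].fillna(self.means_)
        return out


def impute_train_mean(
    table: pd.DataFrame,
    train_index: np.ndarray,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, MeanImputer]:
    """Fill missing feature cells with training-partition column means.

    Parameters
    ----------
    table : DataFrame
        Feature table (may contain NaN cells in feature columns).
    train_index : array of positional row indices
        Rows whose values define the fill means.
    columns : list of str, optional
        Feature columns to impute; defaults to the canonical 34.

    Returns
    -------
    (filled table, fitted MeanImputer)
    """
    if columns is None:
        from .features import FEATURE_NAMES

        columns = [c for c in FEATURE_NAMES if c in table.columns]
    imputer = MeanImputer().fit(table.iloc[np.asarray(train_index)], columns)
    return imputer.transform(table), imputer
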