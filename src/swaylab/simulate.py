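"""Synthetic quiet-stance cohort generator.

Each COP axis is modelled as a stationary damped stochastic oscillator —
a second-order linear system driven by Gaussian white noise,

    x'' = -2*zeta*omega * x' - omega**2 * x + sigma * xi(t),

discretised *exactly* (matrix-exponential state transition plus the
matching discrete noise covariance), so trajectory scale is strictly
proportional to the drive amplitude ``sigma``.  The generator has no
pretence of biomechanical detail; it is a minimal stationary process
whose sway magnitude and velocity can be steered per group, condition and
axis.

Group structure is applied as multiplicative parameter maps on a healthy
baseline: the PD arm has reduced anteroposterior drive with eyes open
(lower sway velocity) and increased drive plus reduced damping with eyes
closed (larger sway path), with anteroposterior effects larger than
mediolateral ones.  Between-subject heterogeneity is lognormal jitter on
the drive amplitude.  An optional additive tremor sinusoid is off by
default (quiet-stance recordings of medicated patients screened for
confounding involuntary movement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .io_formats import Condition, CopTrial, Group, SubjectRecord

__all__ = [
    "AxisParams",
    "SimConfig",
    "GroundTruth",
    "generate_trial",
    "generate_cohort",
    "blank_features",
]

AXES = ("ap", "ml")


@dataclass(frozen=True)
class AxisParams:
    """Oscillator parameters for one sway axis.

    drive_sd : white-noise drive intensity, mm * s**-1/2
    damping : dimensionless damping ratio zeta (> 0 for stability)
    natural_freq : undamped natural frequency, Hz
    """

    drive_sd: float
    damping: float
    natural_freq: float

    def validate(self) -> None:
        if self.damping <= 0:
            raise ValueError(f"damping must be > 0, got {self.damping}")
        if self.natural_freq <= 0:
            raise ValueError("natural_freq must be > 0")
        if self.drive_sd < 0:
            raise ValueError("drive_sd must be >= 0")

    def scaled(self, drive_mult: float = 1.0, damping_mult: float = 1.0):
        return replace(
            self,
            drive_sd=self.drive_sd * drive_mult,
            damping=self.damping * damping_mult,
        )


def _default_baseline() -> dict[tuple[str, str], AxisParams]:
    """Healthy-control baseline per (condition, axis).

    Calibrated so the extracted features sit at the magnitude of published
    healthy quiet-stance values (AP std ~1.4 mm and AP velocity ~4.7 mm/s
    eyes open; smaller, slower sway eyes closed on the AP axis).
    """
    return {
        ("EO", "ap"): AxisParams(drive_sd=11.4, damping=0.20, natural_freq=0.67),
        ("EO", "ml"): AxisParams(drive_sd=7.2, damping=0.20, natural_freq=0.79),
        ("EC", "ap"): AxisParams(drive_sd=2.4, damping=0.20, natural_freq=0.28),
        ("EC", "ml"): AxisParams(drive_sd=5.1, damping=0.20, natural_freq=0.57),
    }


def _default_pd_drive() -> dict[tuple[str, str], float]:
    # EO: hypokinetic (reduced AP drive, velocity ratio ~0.45);
    # EC: destabilised (raised drive, AP-dominant, sway-path ratio ~2.9)
    return {
        ("EO", "ap"): 0.45,
        ("EO", "ml"): 0.85,
        ("EC", "ap"): 3.1,
        ("EC", "ml"): 1.6,
    }


def _default_pd_damping() -> dict[tuple[str, str], float]:
    return {
        ("EO", "ap"): 1.0,
        ("EO", "ml"): 1.0,
        ("EC", "ap"): 0.8,
        ("EC", "ml"): 0.8,
    }


@dataclass
class SimConfig:
    """Generative parameters for a synthetic sway cohort.

    ``subject_cv`` is the coefficient of variation of the lognormal
    between-subject multiplier applied to each axis drive amplitude.
    ``missing_rate`` is the probability that a feature cell is blanked by
    :func:`blank_features` (exercising mean imputation downstream).
    """

    n_hoa: int = 37
    n_pd: int = 26
    fs: float = 10.0
    duration: float = 15.0
    baseline: dict = field(default_factory=_default_baseline)
    pd_drive_mult: dict = field(default_factory=_default_pd_drive)
    pd_damping_mult: dict = field(default_factory=_default_pd_damping)
    tremor_amp: float = 0.0  # mm
    tremor_freq: float = 0.0  # Hz
    subject_cv: float = 0.35
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_hoa < 2 or self.n_pd < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.duration * self.fs < 16:
            raise ValueError("need at least 16 samples per trial")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        for p in self.baseline.values():
            p.validate()

    @classmethod
    def default(cls, seed: int = 0) -> "SimConfig":
        return cls(seed=seed)

    @classmethod
    def null(cls, seed: int = 0) -> "SimConfig":
        """Null cohort: identical generative process in both groups."""
        ones = {k: 1.0 for k in _default_pd_drive()}
        return cls(pd_drive_mult=dict(ones), pd_damping_mult=dict(ones),
                   seed=seed)

    def params_for(self, group: Group, condition: Condition, axis: str
                   ) -> AxisParams:
        key = (Condition(condition).value, axis)
        base = self.baseline[key]
        if Group(group) == Group.PD:
            return base.scaled(
                self.pd_drive_mult[key], self.pd_damping_mult[key]
            )
        return base


@dataclass(frozen=True)
class GroundTruth:
    """Labels and expected feature orderings for parameter-recovery tests."""

    labels: dict[str, str]
    expected_orderings: dict[str, str]


def _simulate_axis(
    params: AxisParams, fs: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample one axis of the oscillator at ``fs`` Hz, stationary start."""
    params.validate()
    if params.drive_sd == 0:
        return np.zeros(n)
    omega = 2 * np.pi * params.natural_freq
    zeta = params.damping
    A = np.array([[0.0, 1.0], [-(omega**2), -2 * zeta * omega]])
    Qc = np.array([[0.0, 0.0], [0.0, params.drive_sd**2]])
    # stationary state covariance and exact one-step discretisation
    P = solve_continuous_lyapunov(A, -Qc)
    Ad = expm(A / fs)
    Qd = P - Ad @ P @ Ad.T
    Qd = (Qd + Qd.T) / 2

    def sqrt_psd(M: np.ndarray) -> np.ndarray:
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.sqrt(np.clip(w, 0, None)))

    sqrtP, sqrtQ = sqrt_psd(P), sqrt_psd(Qd)
    z = sqrtP @ rng.standard_normal(2)
    noise = rng.standard_normal((n, 2)) @ sqrtQ.T
    x = np.empty(n)
    for i in range(n):
        x[i] = z[0]
        z = Ad @ z + noise[i]
    return x


def generate_trial(
    ap_params: AxisParams,
    ml_params: AxisParams,
    fs: float,
    duration: float,
    condition: Condition,
    rng: np.random.Generator | int,
    tremor_amp: float = 0.0,
    tremor_freq: float = 0.0,
) -> CopTrial:
    """Generate one COP trial: independent AP and ML oscillator axes,
    optionally with an additive tremor sinusoid on both axes."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = int(round(duration * fs))
    ap = _simulate_axis(ap_params, fs, n, rng)
    ml = _simulate_axis(ml_params, fs, n, rng)
    if tremor_amp > 0 and tremor_freq > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi, size=2)
        ap = ap + tremor_amp * np.sin(2 * np.pi * tremor_freq * t + phase[0])
        ml = ml + tremor_amp * np.sin(2 * np.pi * tremor_freq * t + phase[1])
    return CopTrial(condition=condition, fs=fs, ap=ap, ml=ml)


def generate_cohort(cfg: SimConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate a full synthetic cohort.

    Subjects are drawn independently; each subject's axis drive amplitudes
    receive a unit-mean lognormal multiplier (CV = ``cfg.subject_cv``)
    creating within-group spread.  Returns the records (HOA block first)
    and a :class:`GroundTruth` describing the built-in group contrasts.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(np.log1p(cfg.subject_cv**2))
    records: list[SubjectRecord] = []
    labels: dict[str, str] = {}
    plan = [(Group.HOA, i + 1) for i in range(cfg.n_hoa)] + [
        (Group.PD, i + 1) for i in range(cfg.n_pd)
    ]
    for group, num in plan:
        subject_id = f"{group.value}{num:03d}"
        trials = {}
        for cond in (Condition.EO, Condition.EC):
            axis_params = {}
            for axis in AXES:
                base = cfg.params_for(group, cond, axis)
                jitter = float(
                    np.exp(rng.normal(-sigma**2 / 2, sigma))
                ) if sigma > 0 else 1.0
                axis_params[axis] = base.scaled(drive_mult=jitter)
            trials[cond] = generate_trial(
                axis_params["ap"],
                axis_params["ml"],
                cfg.fs,
                cfg.duration,
                cond,
                rng,
                tremor_amp=cfg.tremor_amp,
                tremor_freq=cfg.tremor_freq,
            )
        records.append(
            SubjectRecord(subject_id=subject_id, group=group, trials=trials)
        )
        labels[subject_id] = group.value
    truth = GroundTruth(
        labels=labels,
        expected_orderings={
            "V-AP": "HOA > PD",      # eyes-open AP sway velocity
            "TOD_EC": "PD > HOA",    # eyes-closed total sway path
        },
    )
    return records, truth


def blank_features(
    table, missing_rate: float, seed: int = 0
):
    """Blank feature cells independently with probability ``missing_rate``.

    Only the 34 canonical feature columns are eligible; ids and labels are
    never blanked.  Reproducible given ``seed``.
    """
    from .features import FEATURE_NAMES

    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must lie in [0, 0.5)")
    out = table.copy()
    if missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    cols = list(FEATURE_NAMES)
    mask = rng.random((len(out), len(cols))) < missing_rate
    vals = out[cols].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[cols] = vals
    return out
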