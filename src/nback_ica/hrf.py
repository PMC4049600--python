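"""Hemodynamic response basis set and GLM design matrix.

The canonical HRF is the conventional double-gamma: a response gamma
peaking near 5 s minus an undershoot gamma peaking later, with the
undershoot scaled to 1/6 of the response.  Its temporal derivative
(finite difference with respect to a 1 s onset shift) and dispersion
derivative (finite difference with respect to the peak dispersion
parameter, increment 0.01) complete the three-function basis, which
jointly absorbs between-subject latency and width variability in the
response — the reason the basis is used for mixed-age cohorts, where
neurovascular coupling differs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .task import CONDITIONS, TaskSchedule, condition_onsets

logger = logging.getLogger(__name__)

# double-gamma parameters: response/undershoot delay (s), dispersions,
# response:undershoot ratio, support length (s)
PEAK_DELAY = 6.0
UNDERSHOOT_DELAY = 16.0
PEAK_DISP = 1.0
UNDERSHOOT_DISP = 1.0
RATIO = 6.0
DURATION = 32.0

CONDITION_NUMBER_WARN = 1e6


def _double_gamma(t: np.ndarray, peak_delay: float = PEAK_DELAY,
                  peak_disp: float = PEAK_DISP) -> np.ndarray:
    """Unnormalized double-gamma response at times t (seconds)."""
    resp = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = gamma_dist.pdf(t, UNDERSHOOT_DELAY / UNDERSHOOT_DISP,
                           scale=UNDERSHOOT_DISP)
    return resp - under / RATIO


def canonical_hrf(step: float, duration: float = DURATION) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``step`` s, peak-normalized."""
    if step <= 0:
        raise ValueError("sampling step must be > 0")
    t = np.arange(0.0, duration + step / 2, step)
    h = _double_gamma(t)
    return h / h.max()


@dataclass(frozen=True)
class BasisSet:
    step: float
    canonical: np.ndarray
    time_derivative: np.ndarray
    dispersion_derivative: np.ndarray
    duration: float = DURATION

    @property
    def curves(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.canonical, self.time_derivative, self.dispersion_derivative)

    @property
    def names(self) -> tuple[str, str, str]:
        return ("canonical", "time_derivative", "dispersion_derivative")


def basis_set(step: float, duration: float = DURATION,
              onset_shift: float = 1.0,
              dispersion_increment: float = 0.01) -> BasisSet:
    """Canonical HRF plus finite-difference temporal/dispersion derivatives.

    All three curves share the canonical peak normalization, so the
    canonical component equals :func:`canonical_hrf` exactly.
    """
    if step <= 0:
        raise ValueError("sampling step must be > 0")
    t = np.arange(0.0, duration + step / 2, step)
    raw = _double_gamma(t)
    scale = raw.max()

    shifted = _double_gamma(t - onset_shift)  # later onset
    time_deriv = (raw - shifted) / onset_shift

    dispersed = _double_gamma(t, peak_disp=PEAK_DISP + dispersion_increment)
    disp_deriv = (raw - dispersed) / dispersion_increment

    return BasisSet(step=step, canonical=raw / scale,
                    time_derivative=time_deriv / scale,
                    dispersion_derivative=disp_deriv / scale,
                    duration=duration)


@dataclass(frozen=True)
class DesignMatrix:
    values: np.ndarray          # scan x regressor
    labels: tuple[str, ...]
    tr: float

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))

    def columns(self, prefix: str) -> np.ndarray:
        """Indices of columns whose label starts with ``prefix:``."""
        return np.array([i for i, lab in enumerate(self.labels)
                         if lab.split(":")[0] == prefix])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.labels))


def _event_regressors(onsets: np.ndarray, duration: float, basis: BasisSet,
                      n_scans: int, tr: float) -> np.ndarray:
    """Convolve a boxcar event train with each basis curve; sample at TR."""
    dt = basis.step
    n_fine = int(np.ceil(n_scans * tr / dt)) + 1
    stim = np.zeros(n_fine)
    for onset in onsets:
        if onset >= n_scans * tr:
            raise ValueError(f"event onset {onset} s beyond run end "
                             f"({n_scans * tr} s)")
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + duration) / dt)))
        stim[i0:min(i1, n_fine)] = 1.0
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    cols = []
    for curve in basis.curves:
        conv = np.convolve(stim, curve)[:n_fine]
        cols.append(conv[scan_idx])
    return np.column_stack(cols)


def _convolve_at_tr(series: np.ndarray, basis: BasisSet, tr: float) -> np.ndarray:
    """Convolve a scan-sampled series with each basis resampled at TR."""
    n = len(series)
    cols = []
    for curve in basis.curves:
        idx = np.round(np.arange(0, basis.duration / tr + 1)).astype(int)
        kernel = curve[np.minimum((idx * tr / basis.step).round().astype(int),
                                  len(curve) - 1)]
        cols.append(np.convolve(series, kernel)[:n])
    return np.column_stack(cols)


def build_design(schedule: TaskSchedule, motion: np.ndarray | pd.DataFrame,
                 basis: BasisSet, *, convolve_motion: bool = True,
                 event_duration: float = 0.5) -> DesignMatrix:
    """GLM design: 3 conditions x 3 bases, motion (+ first derivatives),
    constant.

    Condition event trains (boxcars of ``event_duration``) are convolved
    with each basis on the basis' fine grid and sampled at the TR.  The
    six motion series and their backward first differences are likewise
    convolved with the bases (set ``convolve_motion=False`` for the
    conventional unconvolved nuisance columns, in which case the basis
    replicates collapse to the raw series).  All columns except the
    constant are mean-centered.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    if motion.shape[0] != schedule.n_scans:
        raise ValueError(
            f"motion rows ({motion.shape[0]}) != n_scans ({schedule.n_scans})")
    tr = schedule.tr_seconds
    n_scans = schedule.n_scans
    onsets = condition_onsets(schedule)

    cols: list[np.ndarray] = []
    labels: list[str] = []
    for condition in CONDITIONS:
        block = _event_regressors(onsets[condition], event_duration, basis,
                                  n_scans, tr)
        cols.append(block)
        labels += [f"{condition}:{b}" for b in basis.names]

    motion_deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    for kind, series_block in (("motion", motion), ("motion_deriv", motion_deriv)):
        for j in range(6):
            series = series_block[:, j]
            if convolve_motion:
                block = _convolve_at_tr(series, basis, tr)
                cols.append(block)
                labels += [f"{kind}{j + 1}:{b}" for b in basis.names]
            else:
                cols.append(series[:, None])
                labels.append(f"{kind}{j + 1}:raw")

    X = np.hstack(cols)
    X = X - X.mean(axis=0)
    X = np.column_stack([X, np.ones(n_scans)])
    labels.append("constant")

    design = DesignMatrix(values=X, labels=tuple(labels), tr=tr)
    cond = design.condition_number
    if cond > CONDITION_NUMBER_WARN:
        warnings.warn(f"design matrix ill-conditioned (cond={cond:.3g})",
                      RuntimeWarning, stacklevel=2)
    logger.debug("design built: %d scans x %d regressors, cond=%.3g",
                 n_scans, X.shape[1], cond)
    return design
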