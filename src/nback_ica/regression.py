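"""Temporal regression of component time courses and the AUC statistic.

Each subject-level component time course is regressed (ordinary least
squares) on the GLM design matrix, yielding three coefficients per task
condition — one per HRF basis function.  These are collapsed to a single
activation value per condition via the area under the reconstructed
response,

    AUC = (b1 * sum(canonical) + b2 * sum(time_deriv)
           + b3 * sum(dispersion_deriv)) / sum(canonical),

i.e. the summed reconstructed BOLD response normalized by the summed
canonical HRF.  When the derivative curves sum to ~0, AUC collapses to
the canonical coefficient; when a subject's response is shifted or
broadened, the derivative terms absorb the mismatch and the AUC remains
an unbiased amplitude estimate.  The per-component contrast
``activation(2-back) - activation(0-back)`` is the BOLD load effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hrf import BasisSet, DesignMatrix
from .ica import ICADecomposition
from .task import CONDITIONS


@dataclass(frozen=True)
class ComponentFit:
    coefficients: np.ndarray                  # one per design column
    residual_variance: float
    condition_betas: dict[str, tuple[float, float, float]]


def fit_component(timecourse: np.ndarray, design: DesignMatrix) -> ComponentFit:
    """OLS fit of one component time course on the design matrix."""
    y = np.asarray(timecourse, dtype=float)
    X = design.values
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"time course length {y.shape[0]} != design rows "
                         f"{X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report which columns are linearly dependent (small R diagonal)
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.labels[i] for i in
               np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"offending columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    cond_betas = {}
    for cond in CONDITIONS:
        idx = design.columns(cond)
        cond_betas[cond] = tuple(float(beta[i]) for i in idx)
    return ComponentFit(coefficients=beta,
                        residual_variance=float(resid @ resid / dof),
                        condition_betas=cond_betas)


def auc_activation(b_canonical: float, b_time_deriv: float,
                   b_dispersion_deriv: float, basis: BasisSet) -> float:
    """Area under the reconstructed response, normalized by the summed
    canonical HRF.  Linear in each coefficient."""
    s_can = float(basis.canonical.sum())
    if s_can == 0:
        raise ZeroDivisionError("canonical HRF sums to zero")
    if s_can < 0:
        raise ValueError("canonical HRF has negative sum; refusing to "
                         "normalize by it")
    s_td = float(basis.time_derivative.sum())
    s_dd = float(basis.dispersion_derivative.sum())
    return (b_canonical * s_can + b_time_deriv * s_td
            + b_dispersion_deriv * s_dd) / s_can


@dataclass(frozen=True)
class ActivationTable:
    """Subject x component x condition AUC activations and load effects."""
    activation: np.ndarray        # M x C x 3 (conditions in CONDITIONS order)
    load_effect: np.ndarray       # M x C: activation(2back) - activation(0back)
    residual_variance: np.ndarray # M x C
    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    components: tuple[int, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.activation).all():
            raise ValueError("activation table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, sid in enumerate(self.subject_ids):
            for ci, comp in enumerate(self.components):
                for ki, cond in enumerate(CONDITIONS):
                    rows.append((sid, self.groups[si], comp, cond,
                                 self.activation[si, ci, ki]))
        return pd.DataFrame(rows, columns=["subject", "group", "component",
                                           "condition", "activation"])

    def load_effect_frame(self) -> pd.DataFrame:
        rows = []
        for si, sid in enumerate(self.subject_ids):
            for ci, comp in enumerate(self.components):
                rows.append((sid, self.groups[si], comp,
                             self.load_effect[si, ci]))
        return pd.DataFrame(rows, columns=["subject", "group", "component",
                                           "load_effect"])


def compute_activation_table(
    decomposition: ICADecomposition,
    designs: list[DesignMatrix],
    basis: BasisSet,
    groups: list[str] | tuple[str, ...],
    components: list[int] | None = None,
) -> ActivationTable:
    """AUC activation per subject x component x condition.

    ``designs`` holds one design matrix per subject (in dataset order).
    Per-subject failures are aggregated and reported together.
    """
    M = decomposition.subject_timecourses.shape[0]
    if len(designs) != M:
        raise ValueError(f"need one design per subject ({M}), got "
                         f"{len(designs)}")
    comp_idx = (list(components) if components is not None
                else list(range(decomposition.n_components)))
    activation = np.empty((M, len(comp_idx), 3))
    resid = np.empty((M, len(comp_idx)))
    errors = []
    for si in range(M):
        try:
            for cj, comp in enumerate(comp_idx):
                tc = decomposition.subject_timecourses[si, comp]
                fit = fit_component(tc, designs[si])
                resid[si, cj] = fit.residual_variance
                for ki, cond in enumerate(CONDITIONS):
                    activation[si, cj, ki] = auc_activation(
                        *fit.condition_betas[cond], basis)
        except (ValueError, np.linalg.LinAlgError) as exc:
            errors.append(f"subject {decomposition.subject_ids[si]}: {exc}")
    if errors:
        raise RuntimeError("temporal regression failed for "
                           f"{len(errors)} subject(s):\n" + "\n".join(errors))
    load = activation[:, :, 2] - activation[:, :, 0]
    return ActivationTable(activation=activation, load_effect=load,
                           residual_variance=resid,
                           subject_ids=decomposition.subject_ids,
                           groups=tuple(groups),
                           components=tuple(comp_idx))
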