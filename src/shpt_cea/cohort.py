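"""Deterministic cohort trace over the expanded five-state space.

The published model has four states (HD, PD, TX, DEAD) with separate
"1 year" and ">1 year" transition tables and a separate first-year
transplant cost.  A memoryless engine honours both by splitting the
transplant state into a one-cycle tunnel (TX_Y1) and an established
state (TX_EST):

* dialysis rows route their ->TX mass into TX_Y1;
* the TX_Y1 row carries the "1 year" transplant row (first year after
  the graft), the TX_EST row the ">1 year" row, regardless of model
  time; surviving transplant mass flows TX_Y1 -> TX_EST -> TX_EST;
* HD/PD rows switch from the "1 year" to the ">1 year" table at cycle 2
  of model time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    EXPANDED_STATES,
    TransitionModel,
    ValidationError,
    normalize_matrix,
)

__all__ = ["CohortTrace", "expand_matrices", "initial_occupancy", "run_cohort"]

#: Tolerance for probability-mass conservation in a trace row.
CONSERVATION_TOL = 1e-12


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle; row 0 is the initial cohort."""

    occupancy: np.ndarray
    states: tuple[str, ...] = field(default=EXPANDED_STATES)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(self.states):
            raise ValidationError(
                f"trace must be (cycles+1) x {len(self.states)}, got {occ.shape}"
            )
        object.__setattr__(self, "occupancy", occ)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def validate(self, tol: float = CONSERVATION_TOL) -> None:
        occ = self.occupancy
        if np.any(occ < -tol) or np.any(occ > 1 + tol):
            raise ValidationError("occupancy outside [0, 1]")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > tol:
            raise ValidationError("occupancy rows do not conserve probability mass")
        dead = occ[:, self.states.index("DEAD")]
        if np.any(np.diff(dead) < -tol):
            raise ValidationError("DEAD occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.lower() for s in self.states])
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def expand_matrices(model: TransitionModel) -> tuple[np.ndarray, np.ndarray]:
    """Expand an arm's pair of 4x4 matrices onto the five-state space.

    Returns ``(cycle-1 matrix, later matrix)``; printed rounding residue
    is repaired on the diagonal first, so expanded rows sum to 1 to
    machine precision.
    """
    model.validate()
    m1 = normalize_matrix(model.matrix_cycle1)
    m2 = normalize_matrix(model.matrix_later)
    tx_first, tx_later = m1[2], m2[2]

    def build(dialysis: np.ndarray) -> np.ndarray:
        m = np.zeros((5, 5))
        for i in (0, 1):  # HD, PD: ->TX mass enters the tunnel
            m[i, 0] = dialysis[i, 0]
            m[i, 1] = dialysis[i, 1]
            m[i, 2] = dialysis[i, 2]
            m[i, 4] = dialysis[i, 3]
        for i, tx in ((2, tx_first), (3, tx_later)):
            m[i, 0] = tx[0]
            m[i, 1] = tx[1]
            m[i, 3] = tx[2]  # staying in transplant establishes the graft
            m[i, 4] = tx[3]
        m[4, 4] = 1.0
        return m

    return build(m1), build(m2)


def initial_occupancy(hd_fraction: float) -> np.ndarray:
    """Initial cohort split between hemodialysis and peritoneal dialysis."""
    if not (0.0 <= hd_fraction <= 1.0):
        raise ValidationError(f"hd_fraction must be in [0, 1], got {hd_fraction}")
    return np.array([hd_fraction, 1.0 - hd_fraction, 0.0, 0.0, 0.0])


def run_cohort(
    initial: np.ndarray,
    matrices: tuple[np.ndarray, np.ndarray],
    horizon: int,
) -> CohortTrace:
    """Propagate the cohort for ``horizon`` annual cycles.

    ``occupancy[k] = occupancy[k-1] @ M(k)`` with ``M(1)`` the cycle-1
    matrix and ``M(k>=2)`` the later matrix.  The whole cohort starts on
    dialysis (mass only on HD and PD).
    """
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (5,):
        raise ValidationError(f"initial occupancy must have length 5, got {initial.shape}")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ValidationError("initial occupancy must sum to 1")
    if np.any(initial[2:] != 0.0):
        raise ValidationError("initial mass is allowed only on HD and PD")
    m1, m2 = matrices
    occ = np.zeros((horizon + 1, 5))
    occ[0] = initial
    for k in range(1, horizon + 1):
        occ[k] = occ[k - 1] @ (m1 if k == 1 else m2)
    trace = CohortTrace(occ)
    trace.validate()
    return trace
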