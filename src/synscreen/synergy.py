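"""Checkerboard dose-matrix synergy scoring.

A drug pair is screened on an n×n checkerboard whose axes are ascending dose
ladders (starting at dose 0) and whose cells hold the relative growth
``W = AUC_drug / AUC_control``. The primary score is the Bliss multiplicative
deviation per cell,

    ε = W_AB − W_A · W_B,

with the matrix-level summary ``AvgS`` = mean ε over the dual-drug cells
(negative ⇒ synergy). Because Bliss alone over-calls synergy, three
confirmatory models are applied — Loewe additivity (combination index on
interpolated equi-effective doses), highest single agent (HSA), and
potentiation (fold-shift of the interpolated midpoint dose) — and a
combination is classified synergistic only when all four models agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseMatrix",
    "EpsilonMatrix",
    "SynergyCall",
    "bliss_epsilon",
    "epsilon_matrix",
    "call_bliss",
    "call_loewe",
    "call_hsa",
    "call_potentiation",
    "consensus_call",
]

#: Relative growth above 1 allowed for mild stimulation.
W_MAX = 1.2


@dataclass(frozen=True)
class DoseMatrix:
    """n_a × n_b grid of relative growth for a drug pair.

    Row ``i`` is dose ``doses_a[i]`` of drug A; column ``j`` is dose
    ``doses_b[j]`` of drug B. Both ladders must start at 0, so row 0 and
    column 0 are the single-agent margins (W_B and W_A respectively) and
    ``w[0, 0]`` is the no-drug self-comparison (≈ 1).
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if w.shape != (len(da), len(db)):
            raise ValueError("w grid shape must be len(doses_a) x len(doses_b)")
        if da[0] != 0 or db[0] != 0:
            raise ValueError("dose ladders must start at 0")
        if not (np.all(np.diff(da) > 0) and np.all(np.diff(db) > 0)):
            raise ValueError("dose ladders must be ascending")
        if np.any(w < 0):
            raise ValueError("relative growth must be >= 0")
        if abs(w[0, 0] - 1.0) > 0.05:
            raise ValueError(f"w[0,0]={w[0, 0]:.3f} not ~1: bad no-drug cell")
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "w", w)

    def transpose(self) -> "DoseMatrix":
        """Swap the two drugs (checkerboard symmetry)."""
        return DoseMatrix(
            drug_a=self.drug_b,
            drug_b=self.drug_a,
            doses_a=self.doses_b,
            doses_b=self.doses_a,
            w=self.w.T,
        )


@dataclass(frozen=True)
class EpsilonMatrix:
    """Cellwise Bliss deviations for a dose matrix.

    ``eps[i, j] = w[i, j] − w[i, 0]·w[0, j]``; margins and the no-drug cell
    are NaN. ``avg_s`` averages the (n_a−1)×(n_b−1) dual-drug cells only.
    """

    drug_a: str
    drug_b: str
    eps: np.ndarray
    avg_s: float

    @property
    def min_eps(self) -> float:
        return float(np.nanmin(self.eps))


@dataclass(frozen=True)
class SynergyCall:
    """Outcome of the four synergy models for one drug pair."""

    drug_a: str
    drug_b: str
    bliss: bool
    loewe: bool
    hsa: bool
    potentiation: bool
    min_eps: float
    avg_s: float

    @property
    def consensus(self) -> bool:
        return self.bliss and self.loewe and self.hsa and self.potentiation


def bliss_epsilon(w_a: float, w_b: float, w_ab: float) -> float:
    """Bliss multiplicative deviation ε = W_AB − W_A·W_B.

    Negative ε means the combination inhibits more than the product of the
    single agents predicts (synergy); positive means antagonism.
    """
    for v in (w_a, w_b, w_ab):
        if not 0 <= v <= W_MAX:
            raise ValueError(f"relative growth {v} outside [0, {W_MAX}]")
    return w_ab - w_a * w_b


def epsilon_matrix(m: DoseMatrix) -> EpsilonMatrix:
    """Cellwise ε over a checkerboard, and its AvgS summary.

    The single-agent margins W_A (column 0) and W_B (row 0) provide the
    Bliss expectation for every dual-drug cell; AvgS is the mean ε over the
    dual-drug cells alone (margins would be identically ~0 and dilute it).
    """
    w = m.w
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError("dose matrix needs at least one non-zero dose per axis")
    eps = np.full_like(w, np.nan)
    eps[1:, 1:] = w[1:, 1:] - np.outer(w[1:, 0], w[0, 1:])
    avg_s = float(np.mean(eps[1:, 1:]))
    return EpsilonMatrix(drug_a=m.drug_a, drug_b=m.drug_b, eps=eps, avg_s=avg_s)


def call_bliss(
    e: EpsilonMatrix,
    avg_threshold: float = -0.05,
    cell_threshold: float = -0.20,
    mode: str = "avg",
) -> bool:
    """Bliss synergy call.

    ``mode="avg"`` tests ``AvgS < avg_threshold`` (the 6×6 screens);
    ``mode="min_cell"`` tests ``min ε < cell_threshold`` (the 4×4 random and
    prediction screens). Both inequalities are strict.
    """
    if mode == "avg":
        return e.avg_s < avg_threshold
    if mode == "min_cell":
        return e.min_eps < cell_threshold
    raise ValueError(f"unknown mode {mode!r}")


def _equieffective_dose(doses: np.ndarray, w: np.ndarray, target: float) -> float | None:
    """Dose on a single-agent margin giving growth ``target``.

    Linear interpolation of effect against log dose over the non-zero doses;
    requires the margin (including the w=1 anchor at dose→0) to be
    non-increasing and to span the target. Returns None when not evaluable.
    """
    d = doses[1:]  # zero dose is never placed on the log axis
    y = w[1:]
    if len(d) < 2:
        return None
    if np.any(np.diff(y) > 1e-9):  # must be non-increasing
        return None
    if target > y[0] or target < y[-1]:
        return None
    logd = np.interp(-target, -y, np.log(d))
    return float(np.exp(logd))


def call_loewe(m: DoseMatrix, ci_threshold: float = 0.9, effect_ceiling: float = 0.8) -> bool:
    """Loewe additivity call via the combination index.

    For every dual-drug cell with ``w_ab <= effect_ceiling``, the
    combination index is ``CI = d_a/D_A(w_ab) + d_b/D_B(w_ab)``, where
    ``D_X(w)`` is the single-agent dose of drug X producing growth ``w``
    (log-linear interpolation along the margin). Under Loewe additivity a
    drug combined with itself gives CI = 1; CI well below 1 means the pair
    reaches the effect with a fraction of the equi-effective doses. The call
    is true when the median CI over evaluable cells is below ``ci_threshold``;
    with no evaluable cell the call is indeterminate and reported false.
    """
    cis = []
    for i in range(1, len(m.doses_a)):
        for j in range(1, len(m.doses_b)):
            w_ab = m.w[i, j]
            if w_ab > effect_ceiling:
                continue
            da_eq = _equieffective_dose(m.doses_a, m.w[:, 0], w_ab)
            db_eq = _equieffective_dose(m.doses_b, m.w[0, :], w_ab)
            if da_eq is None or db_eq is None:
                continue
            cis.append(m.doses_a[i] / da_eq + m.doses_b[j] / db_eq)
    if not cis:
        return False
    return float(np.median(cis)) < ci_threshold


def call_hsa(m: DoseMatrix, excess_threshold: float = 0.10) -> bool:
    """Highest-single-agent call.

    True when some dual-drug cell inhibits more than the better of its two
    single agents by more than ``excess_threshold`` growth units.
    """
    w_a = m.w[1:, 0][:, None]
    w_b = m.w[0, 1:][None, :]
    excess = np.minimum(w_a, w_b) - m.w[1:, 1:]
    return bool(np.any(excess > excess_threshold))


def _midpoint_dose(doses: np.ndarray, w: np.ndarray, level: float = 0.5) -> float | None:
    return _equieffective_dose(doses, w, level)


def call_potentiation(m: DoseMatrix, shift_threshold: float = 2.0) -> bool:
    """Potentiation call: partner-induced leftward dose-response shift.

    For each axis, the IC50-equivalent dose (interpolated where the
    dose-response crosses w = 0.5) is compared with and without the lowest
    non-zero dose of the partner; a fold-decrease of at least
    ``shift_threshold`` on either axis calls potentiation. Axes whose
    response never brackets the midpoint, or is protective (w increasing),
    are skipped; if both are skipped the call is indeterminate (false).
    """
    checks = []
    # axis A: dose-response of drug A alone (col 0) vs with lowest dose of B
    for alone, partnered, doses in (
        (m.w[:, 0], m.w[:, 1], m.doses_a),
        (m.w[0, :], m.w[1, :], m.doses_b),
    ):
        d_alone = _midpoint_dose(doses, alone)
        d_part = _midpoint_dose(doses, partnered)
        if d_alone is None or d_part is None or d_part <= 0:
            continue
        checks.append(d_alone / d_part)
    if not checks:
        return False
    return max(checks) >= shift_threshold


def consensus_call(m: DoseMatrix, mode: str = "avg") -> SynergyCall:
    """Run all four synergy models and report their conjunction."""
    e = epsilon_matrix(m)
    return SynergyCall(
        drug_a=m.drug_a,
        drug_b=m.drug_b,
        bliss=call_bliss(e, mode=mode),
        loewe=call_loewe(m),
        hsa=call_hsa(m),
        potentiation=call_potentiation(m),
        min_eps=e.min_eps,
        avg_s=e.avg_s,
    )
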