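"""Decision-level evidence fusion over the fatigue frame of discernment.

The frame of discernment is Theta = {NF, MF, SF} (non-fatigue, moderate
fatigue, severe fatigue).  Evidence is represented by mass functions whose
focal sets are the three singletons plus Theta itself; no mass is ever
allocated to two-element subsets, so a :class:`MassVector` stores exactly
four numbers.

The module provides

* conversion of raw fuzzy-network outputs into a dynamic basic probability
  assignment (BPA),
* Dempster's combination rule with its conflict degree ``K``,
* an evidence-distance / belief-factor correction that discounts mutually
  conflicting evidence toward the vacuous mass before combining, gated by a
  conflict threshold ``k_T``.

The correction follows the classic discounting recipe: for each piece of
evidence a confidence level ``c_ij = K_ij * d_ij`` is computed against every
other piece (conflict times Euclidean distance between the mass vectors),
averaged into ``c_i``, and turned into a belief factor
``eta_i = (1 - c_i) * exp(c_i)``; singleton masses are multiplied by
``eta_i`` and the removed mass is transferred to Theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, TotalConflictError, UninformativeEvidenceError

__all__ = [
    "MassVector",
    "FusionConfig",
    "ConflictReport",
    "bpa_from_outputs",
    "conflict_degree",
    "dempster_combine",
    "evidence_distance",
    "belief_factors",
    "discount_bpa",
    "combine_with_correction",
]

_SUM_TOL = 1e-9
_CONFLICT_EPS = 1e-12


@dataclass(frozen=True)
class MassVector:
    """Mass function over {NF, MF, SF} with optional mass on Theta itself.

    Invariants: all masses are non-negative and ``nf + mf + sf + theta = 1``
    (to 1e-9); the empty set carries no mass by construction.
    """

    nf: float
    mf: float
    sf: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.nf, self.mf, self.sf, self.theta)
        if any((not math.isfinite(v)) or v < -_SUM_TOL for v in vals):
            raise InvalidInputError(f"masses must be finite and non-negative, got {vals}")
        total = sum(vals)
        if abs(total - 1.0) > 1e-6:
            raise InvalidInputError(f"masses must sum to 1, got {total!r}")

    @property
    def singletons(self) -> tuple[float, float, float]:
        return (self.nf, self.mf, self.sf)

    def as_array(self) -> np.ndarray:
        """The four focal-set coordinates (nf, mf, sf, theta)."""
        return np.array([self.nf, self.mf, self.sf, self.theta], dtype=float)

    @staticmethod
    def vacuous() -> "MassVector":
        """Total ignorance: all mass on Theta (neutral element of combination)."""
        return MassVector(0.0, 0.0, 0.0, 1.0)

    @staticmethod
    def from_singletons(values: Sequence[float], theta: float = 0.0) -> "MassVector":
        a, b, c = values
        return MassVector(float(a), float(b), float(c), float(theta))

    @staticmethod
    def from_unnormalized(values: Sequence[float], theta: float = 0.0) -> "MassVector":
        """Build a mass function from values that may not sum exactly to 1.

        Useful for vectors transcribed from rounded printed tables; negative
        values are rejected, the vector is rescaled to unit sum.
        """
        arr = np.append(np.asarray(values, dtype=float), theta)
        if np.any(arr < 0) or arr.sum() <= 0:
            raise InvalidInputError("masses must be non-negative with positive sum")
        arr = arr / arr.sum()
        return MassVector(*arr)

    def normalized(self) -> "MassVector":
        """Rescale to unit sum (guards accumulated rounding)."""
        arr = self.as_array()
        return MassVector(*(arr / arr.sum()))


@dataclass(frozen=True)
class FusionConfig:
    """Thresholds of the gated combination and of the decision rule.

    ``conflict_threshold`` (k_T) gates the belief-factor correction: plain
    Dempster combination below it, discounted combination at or above it.
    ``eps_t1`` / ``eps_t2`` are the decision-rule margins (see
    :mod:`drowsefuse.recognizer`).  ``pairwise_mean_over_others``
    selects the averaging convention for the confidence level: the default
    averages c_ij over the other pieces only (1/(n-1)); the alternative
    includes the identically-zero self term (1/n).
    """

    conflict_threshold: float = 0.9
    eps_t1: float = 0.2
    eps_t2: float = 0.5
    pairwise_mean_over_others: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.conflict_threshold <= 1.0):
            raise InvalidInputError("conflict_threshold must lie in (0, 1]")
        for name in ("eps_t1", "eps_t2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidInputError(f"{name} must lie in (0, 1)")


@dataclass
class ConflictReport:
    """Diagnostics of one (possibly corrected) combination."""

    K: float
    distances: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    confidences: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    mean_confidences: np.ndarray = field(default_factory=lambda: np.zeros(0))
    belief_factors: np.ndarray = field(default_factory=lambda: np.ones(0))
    corrected: bool = False


def bpa_from_outputs(y: Sequence[float]) -> MassVector:
    """Dynamic BPA from the raw outputs of a fuzzy network.

    Negative components are clamped to zero, then the vector is normalised to
    unit sum: ``m(A_i) = y_i / sum(y)``.  All mass goes to singletons.

    Raises
    ------
    UninformativeEvidenceError
        If no component is positive after clamping (callers typically
        substitute the vacuous mass and log the event).
    """
    arr = np.clip(np.asarray(y, dtype=float), 0.0, None)
    if arr.shape != (3,):
        raise InvalidInputError(f"expected 3 outputs, got shape {arr.shape}")
    total = arr.sum()
    if total <= 0.0:
        raise UninformativeEvidenceError("all network outputs non-positive")
    return MassVector.from_singletons(arr / total)


def conflict_degree(m1: MassVector, m2: MassVector) -> float:
    """Dempster conflict K: total product mass on empty intersections.

    Theta intersects every focal set, so only singleton-vs-different-singleton
    products contribute.
    """
    s1 = np.asarray(m1.singletons)
    s2 = np.asarray(m2.singletons)
    return float(s1.sum() * s2.sum() - s1 @ s2)


def dempster_combine(m1: MassVector, m2: MassVector) -> MassVector:
    """Dempster's rule of combination on the {singletons, Theta} frame.

    ``m(B) = (1/(1-K)) * sum_{X ∩ Y = B} m1(X) m2(Y)``.

    Raises
    ------
    TotalConflictError
        If K = 1 (within 1e-12): the rule is undefined.
    """
    K = conflict_degree(m1, m2)
    if K >= 1.0 - _CONFLICT_EPS:
        raise TotalConflictError(f"total conflict between evidence (K={K})")
    s1, t1 = np.asarray(m1.singletons), m1.theta
    s2, t2 = np.asarray(m2.singletons), m2.theta
    # singleton B receives m1(B)m2(B) + m1(B)m2(Theta) + m1(Theta)m2(B)
    sing = s1 * s2 + s1 * t2 + t1 * s2
    theta = t1 * t2
    out = np.append(sing, theta) / (1.0 - K)
    return MassVector(*(out / out.sum()))


def evidence_distance(m1: MassVector, m2: MassVector) -> float:
    """Euclidean-form distance between two mass vectors.

    ``d = sqrt((||m1||^2 + ||m2||^2 - 2 <m1, m2>) / 2)`` over the four focal
    coordinates; equals ``||m1 - m2|| / sqrt(2)`` and lies in [0, 1].
    """
    diff = m1.as_array() - m2.as_array()
    return float(np.sqrt(max(diff @ diff, 0.0) / 2.0))


def belief_factors(
    evidence: Sequence[MassVector], cfg: FusionConfig | None = None
) -> ConflictReport:
    """Confidence levels and belief factors for a set of evidence.

    For each ordered pair ``(i, j)``: ``c_ij = K_ij * d_ij`` (pairwise
    conflict weighted by evidence distance).  The average confidence ``c_i``
    uses the configured convention (over the other pieces by default), and
    the belief factor is ``eta_i = (1 - c_i) * exp(c_i)``, clamped to [0, 1].
    ``eta`` is 1 at ``c = 0``, 0 at ``c = 1`` and strictly decreasing between.
    """
    cfg = cfg or FusionConfig()
    n = len(evidence)
    if n < 2:
        raise InvalidInputError("belief factors need at least two pieces of evidence")
    d = np.zeros((n, n))
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d[i, j] = evidence_distance(evidence[i], evidence[j])
            c[i, j] = conflict_degree(evidence[i], evidence[j]) * d[i, j]
    denom = (n - 1) if cfg.pairwise_mean_over_others else n
    c_mean = c.sum(axis=1) / denom
    eta = np.clip((1.0 - c_mean) * np.exp(c_mean), 0.0, 1.0)
    K = conflict_degree(evidence[0], evidence[1]) if n == 2 else float("nan")
    return ConflictReport(
        K=K, distances=d, confidences=c, mean_confidences=c_mean, belief_factors=eta
    )


def discount_bpa(m: MassVector, eta: float) -> MassVector:
    """Discount a mass function by belief factor ``eta``.

    Singleton masses shrink by ``eta``; the removed mass (including any prior
    Theta mass) is transferred to Theta: ``m'(Theta) = 1 - eta * sum_j m(A_j)``.
    ``eta = 1`` leaves a Theta-free mass unchanged, ``eta = 0`` yields the
    vacuous mass.
    """
    if not (0.0 <= eta <= 1.0):
        raise InvalidInputError(f"belief factor must lie in [0, 1], got {eta}")
    sing = np.asarray(m.singletons) * eta
    return MassVector(*sing, 1.0 - sing.sum())


def combine_with_correction(
    m1: MassVector, m2: MassVector, cfg: FusionConfig | None = None
) -> tuple[MassVector, ConflictReport]:
    """Conflict-gated combination of two pieces of evidence.

    If ``K < k_T`` the original BPAs are combined directly by Dempster's
    rule.  Otherwise each BPA is discounted by its belief factor before
    combination, which moves conflicting mass onto Theta and keeps the rule
    well-defined even under complete conflict between singletons.
    """
    cfg = cfg or FusionConfig()
    K = conflict_degree(m1, m2)
    if K < cfg.conflict_threshold:
        fused = dempster_combine(m1, m2)
        report = ConflictReport(K=K, belief_factors=np.ones(2), corrected=False)
        return fused, report
    report = belief_factors([m1, m2], cfg)
    report.corrected = True
    m1d = discount_bpa(m1, float(report.belief_factors[0]))
    m2d = discount_bpa(m2, float(report.belief_factors[1]))
    fused = dempster_combine(m1d, m2d)
    return fused, report
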