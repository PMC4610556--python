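"""End-to-end fatigue recognition: two fuzzy networks, two levels of fusion.

Per 60 s recognition step:

1. the facial network maps (bf, ecd, yf) and the vehicle network maps
   (pns, sdsa, fald, sdvs) to three raw state scores each;
2. both score vectors become dynamic basic probability assignments
   (clamp negatives, normalise to unit sum);
3. the two BPAs are fused by the conflict-gated Dempster combination
   (first, feature-source fusion);
4. the normalised intermediate result is fused with the previous step's
   decision-level mass (temporal fusion), making the recognizer recursive;
5. the decision rule picks the top-mass state only when its margin over the
   runner-up exceeds ``eps_t1`` and its own mass exceeds ``eps_t2``;
   otherwise the previous decision is retained.

A source whose network output is entirely non-positive contributes the
vacuous mass (total ignorance) instead of aborting the step — this is what
keeps the recognizer stable through sensor dropouts such as GPS loss in a
tunnel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UninformativeEvidenceError
from .evidence_fusion import (
    ConflictReport,
    FusionConfig,
    MassVector,
    bpa_from_outputs,
    combine_with_correction,
)
from .signal_features import FEATURE_NAMES, FeatureWindow
from .tsfnn import SCAConfig, TrainConfig, TSFNNModel, fit_tsfnn

__all__ = [
    "FatigueState",
    "RecognizerState",
    "RecognizerBundle",
    "StepDiagnostics",
    "decide",
    "step",
    "run_session",
    "train_bundle",
]

FACIAL_INPUTS = ("bf", "ecd", "yf")
VEHICLE_INPUTS = ("pns", "sdsa", "fald", "sdvs")


class FatigueState(enum.IntEnum):
    """The three recognized driver states."""

    NF = 0
    MF = 1
    SF = 2


@dataclass
class RecognizerState:
    """Recursive state: previous fused mass and previous decision.

    At session start the mass is vacuous (all mass on Theta — the neutral
    element of Dempster combination) and the decision is NF: sessions are
    assumed to begin alert.
    """

    prev_mass: MassVector = field(default_factory=MassVector.vacuous)
    prev_decision: FatigueState = FatigueState.NF
    step_index: int = 0


@dataclass
class RecognizerBundle:
    """The two trained networks plus the fusion thresholds."""

    facial_model: TSFNNModel
    vehicle_model: TSFNNModel
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def __post_init__(self) -> None:
        if self.facial_model.structure.r != 3 or self.vehicle_model.structure.r != 3:
            raise InvalidInputError("both networks must have three outputs (NF, MF, SF)")
        if self.facial_model.structure.n != 3 or self.vehicle_model.structure.n != 4:
            raise InvalidInputError("facial network takes 3 inputs, vehicle network 4")

    def to_dict(self) -> dict:
        return {
            "facial": self.facial_model.to_dict(),
            "vehicle": self.vehicle_model.to_dict(),
            "fusion": {
                "k_T": self.fusion.conflict_threshold,
                "eps_t1": self.fusion.eps_t1,
                "eps_t2": self.fusion.eps_t2,
            },
        }

    @staticmethod
    def from_dict(doc: dict) -> "RecognizerBundle":
        f = doc.get("fusion", {})
        return RecognizerBundle(
            TSFNNModel.from_dict(doc["facial"]),
            TSFNNModel.from_dict(doc["vehicle"]),
            FusionConfig(
                conflict_threshold=f.get("k_T", 0.9),
                eps_t1=f.get("eps_t1", 0.2),
                eps_t2=f.get("eps_t2", 0.5),
            ),
        )


@dataclass
class StepDiagnostics:
    """Per-step record of the fusion pipeline."""

    facial_mass: MassVector
    vehicle_mass: MassVector
    intermediate: MassVector
    final: MassVector
    first_report: ConflictReport
    second_report: ConflictReport
    facial_vacuous: bool = False
    vehicle_vacuous: bool = False


def decide(
    m: MassVector, cfg: FusionConfig, prev: FatigueState = FatigueState.NF
) -> FatigueState:
    """Threshold-gated argmax decision on the singleton masses.

    Returns the top-mass state iff its lead over the runner-up exceeds
    ``eps_t1`` and its own mass exceeds ``eps_t2``; otherwise the previous
    decision stands.  Exact ties fail the margin test, so tie order never
    changes the outcome.
    """
    sing = np.asarray(m.singletons)
    order = np.argsort(-sing, kind="stable")  # NF < MF < SF tie order
    top, second = sing[order[0]], sing[order[1]]
    if (top - second) > cfg.eps_t1 and top > cfg.eps_t2:
        return FatigueState(int(order[0]))
    return prev


def _source_mass(outputs: np.ndarray) -> tuple[MassVector, bool]:
    try:
        return bpa_from_outputs(outputs), False
    except UninformativeEvidenceError:
        return MassVector.vacuous(), True


def step(
    fw: FeatureWindow, state: RecognizerState, bundle: RecognizerBundle
) -> tuple[FatigueState, MassVector, StepDiagnostics]:
    """One recognition step; advances ``state`` in place."""
    y1 = bundle.facial_model.predict(fw.facial_vector())
    y2 = bundle.vehicle_model.predict(fw.vehicle_vector())
    m1, facial_vac = _source_mass(y1)
    m2, vehicle_vac = _source_mass(y2)

    intermediate, first_report = combine_with_correction(m1, m2, bundle.fusion)
    final, second_report = combine_with_correction(
        intermediate.normalized(), state.prev_mass, bundle.fusion
    )
    if facial_vac and vehicle_vac:
        decision = state.prev_decision
    else:
        decision = decide(final, bundle.fusion, state.prev_decision)
    diag = StepDiagnostics(
        m1, m2, intermediate, final, first_report, second_report, facial_vac, vehicle_vac
    )
    state.prev_mass = final
    state.prev_decision = decision
    state.step_index += 1
    return decision, final, diag


def run_session(
    features: pd.DataFrame,
    bundle: RecognizerBundle,
    state: RecognizerState | None = None,
) -> pd.DataFrame:
    """Sequentially recognize every window of a feature table.

    Returns one row per processed window with the fused masses, conflict
    degrees, correction flags and the decision.  Rows with missing or
    non-finite feature values are skipped (and noted with a log entry).
    """
    import logging

    logger = logging.getLogger(__name__)
    state = state or RecognizerState()
    records = []
    for _, row in features.iterrows():
        try:
            vals = {name: float(row[name]) for name in FEATURE_NAMES}
        except (KeyError, TypeError, ValueError):
            logger.warning("run_session: skipping malformed row %r", dict(row))
            continue
        if any(not np.isfinite(v) for v in vals.values()):
            logger.warning("run_session: skipping non-finite row %r", vals)
            continue
        fw = FeatureWindow(**vals, window_start=float(row.get("window_start", state.step_index * 60.0)))
        decision, final, diag = step(fw, state, bundle)
        records.append(
            {
                "window_start": fw.window_start,
                "m_nf": final.nf,
                "m_mf": final.mf,
                "m_sf": final.sf,
                "theta": final.theta,
                "K_first": diag.first_report.K,
                "K_second": diag.second_report.K,
                "corrected": diag.first_report.corrected or diag.second_report.corrected,
                "decision": FatigueState(decision).name,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "window_start", "m_nf", "m_mf", "m_sf", "theta",
            "K_first", "K_second", "corrected", "decision",
        ],
    )


def train_bundle(
    features: pd.DataFrame,
    targets: np.ndarray,
    fusion: FusionConfig | None = None,
    sca_cfg: SCAConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> RecognizerBundle:
    """Train both networks from a labelled feature table.

    ``targets`` is the (N, 3) matrix of encoded state probabilities (0.8 for
    the assessed state, 0.1 elsewhere).  The facial network is fitted on
    (bf, ecd, yf), the vehicle network on (pns, sdsa, fald, sdvs); each
    network's rule count comes from subtractive clustering of its own inputs.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape != (len(features), 3):
        raise InvalidInputError("targets must have shape (n_rows, 3)")
    facial = fit_tsfnn(features[list(FACIAL_INPUTS)].to_numpy(), targets, sca_cfg, train_cfg)
    vehicle = fit_tsfnn(features[list(VEHICLE_INPUTS)].to_numpy(), targets, sca_cfg, train_cfg)
    return RecognizerBundle(facial, vehicle, fusion or FusionConfig())
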