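"""Synthetic sessions, training tables, and embedded worked-example fixtures.

Two generators are provided.

``generate_training_table`` draws the eight features directly from
per-state Gaussians — the cheap generator used to train and unit-test the
fuzzy networks.  Targets use the 0.8/0.1 encoding: the assessed state's
output is 0.8 and the other two outputs are 0.1 each.

``generate_session`` synthesises raw frame/vehicle streams under a Markov
fatigue-state path, constructed so that the feature extractors recover the
configured per-state distributions:

* eye closures are placed as explicit runs — long runs (>= 2 s) realise the
  ECD fraction, short runs top the closed-frame count up to the BF fraction;
* yawns are mouth-ratio excursions above the yawn threshold;
* non-steering is a per-sample Bernoulli on a dedicated steering-rate
  channel, while the steering-angle channel is an independent Gaussian
  series scaled to the target SDSA (the two channels are deliberately
  decoupled so each feature is calibrated exactly);
* lane departures are per-frame Bernoulli events realised through the
  lane-line slope-angle geometry;
* speed is white Gaussian around a cruising mean.

Expected feature values per state account for the small-sample bias of the
population SD (``E[S]/sigma = sqrt(2/N) Gamma(N/2) / Gamma((N-1)/2)``) so
round-trip calibration checks compare like with like.

``fixtures`` returns the printed worked-example tables of the source study
(network output pairs, first-fusion rows, decision-level rows), with the
three internally inconsistent rows flagged for exclusion from assertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .recognizer import FatigueState
from .signal_features import (
    FEATURE_NAMES,
    FeatureConfig,
    FeatureWindow,
    FrameStream,
    VehicleStream,
    windowize,
    windows_to_frame,
)

__all__ = [
    "SimConfig",
    "LabeledSession",
    "generate_training_table",
    "generate_session",
    "population_sd_bias",
    "fixtures",
    "WorkedExample",
]

STATES = (FatigueState.NF, FatigueState.MF, FatigueState.SF)

# Per-state targets for the raw-stream generator.  Fractions are realised
# exactly by construction; monotone in fatigue except MEOL and SDSA, which
# decrease (alert drivers keep their eyes wider open and make more frequent
# small steering corrections).
STREAM_TARGETS: dict[str, tuple[float, float, float]] = {
    "bf": (0.08, 0.15, 0.30),
    "ecd": (0.00, 0.05, 0.20),
    "meol_open": (11.0, 9.0, 6.0),  # eyelid aperture on open frames, px
    "yf": (0.02, 0.08, 0.16),
    "pns": (0.15, 0.30, 0.50),
    "sdsa": (14.0, 12.0, 9.0),
    "fald": (0.02, 0.08, 0.20),
    "sdvs": (3.0, 5.0, 8.0),
}

# Per-window noise SDs of the drawn fraction targets.
STREAM_NOISE: dict[str, float] = {
    "bf": 0.02,
    "ecd": 0.015,
    "yf": 0.01,
    "pns": 0.0,  # realised as per-sample Bernoulli; no extra window noise
    "fald": 0.0,
}

# Cheap feature-table generator: per-state means and SDs for all eight
# features (MEOL here is the extracted whole-window mean, i.e. open-frame
# aperture scaled by the open fraction).
TABLE_MEANS: dict[str, tuple[float, float, float]] = {
    "bf": (0.08, 0.15, 0.30),
    "ecd": (0.00, 0.05, 0.20),
    "meol": (10.1, 7.65, 4.2),
    "yf": (0.02, 0.08, 0.16),
    "pns": (0.15, 0.30, 0.50),
    "sdsa": (14.0, 12.0, 9.0),
    "fald": (0.02, 0.08, 0.20),
    "sdvs": (3.0, 5.0, 8.0),
}
TABLE_SDS: dict[str, float] = {
    "bf": 0.02,
    "ecd": 0.015,
    "meol": 0.6,
    "yf": 0.01,
    "pns": 0.03,
    "sdsa": 1.0,
    "fald": 0.015,
    "sdvs": 0.5,
}

FRACTION_FEATURES = ("bf", "ecd", "yf", "pns", "fald")


@dataclass
class SimConfig:
    """Study conditions for the generators.

    ``transition`` is the row-stochastic Markov matrix over (NF, MF, SF);
    the default favours staying in the current state with occasional
    one-step moves, so sessions contain sustained episodes of each state.
    """

    seed: int = 0
    session_windows: int = 50
    transition: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.90, 0.10, 0.00], [0.05, 0.85, 0.10], [0.00, 0.10, 0.90]]
        )
    )
    initial_state: FatigueState = FatigueState.NF
    frame_rate: float = 10.0  # camera frames / s
    vehicle_rate: float = 10.0  # steering & GPS samples / s
    speed_mean: float = 100.0  # km/h cruising speed
    mouth_width: float = 50.0  # px
    yawn_ratio: float = 0.7  # mouth h/w during a yawn (above default threshold)
    rest_ratio: float = 0.2  # mouth h/w otherwise
    stream_targets: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(STREAM_TARGETS)
    )
    table_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(TABLE_MEANS)
    )
    table_sds: Mapping[str, float] = field(default_factory=lambda: dict(TABLE_SDS))
    independent_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (3, 3) or np.any(self.transition < 0):
            raise InvalidInputError("transition must be a nonnegative 3x3 matrix")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("transition rows must sum to 1")


@dataclass
class LabeledSession:
    """A full synthetic session with its ground truth."""

    frames: FrameStream
    vehicle: VehicleStream
    windows: list[FeatureWindow]
    states: list[FatigueState]
    feature_table: pd.DataFrame
    expected_means: dict[FatigueState, dict[str, float]]


def population_sd_bias(n: int) -> float:
    """E[sample population SD] / sigma for n iid Gaussian samples."""
    if n < 2:
        return 0.0
    return math.sqrt(2.0 / n) * math.exp(math.lgamma(n / 2.0) - math.lgamma((n - 1) / 2.0))


def generate_training_table(
    n_per_state: int, cfg: SimConfig | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table drawn from per-state Gaussians, with encoded targets.

    Rows come in state blocks (NF, MF, SF), ``n_per_state`` each.  The
    target row for a state puts 0.8 on that state's output and 0.1 on each
    of the others, so every row sums to 1.  Features listed in
    ``cfg.independent_features`` are drawn from the pooled (state-averaged)
    distribution instead — useful for screening benchmarks.
    """
    cfg = cfg or SimConfig()
    if n_per_state < 1:
        raise InvalidInputError("n_per_state must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    rows = {}
    for name in FEATURE_NAMES:
        means = np.asarray(cfg.table_means[name])
        sd = cfg.table_sds[name]
        if name in cfg.independent_features:
            mu = np.full(3, means.mean())
        else:
            mu = means
        draws = np.concatenate(
            [rng.normal(mu[s], sd, size=n_per_state) for s in range(3)]
        )
        if name in FRACTION_FEATURES:
            draws = np.clip(draws, 0.0, 1.0)
        else:
            draws = np.clip(draws, 0.0, None)
        rows[name] = draws
    table = pd.DataFrame(rows)
    targets = np.full((3 * n_per_state, 3), 0.1)
    for s in range(3):
        targets[s * n_per_state : (s + 1) * n_per_state, s] = 0.8
    return table, targets


# ---------------------------------------------------------------------------
# Raw-stream synthesis


def _split_runs(total: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` frames into runs of length in [lo, hi] (last may absorb)."""
    runs: list[int] = []
    rem = total
    while rem > 0:
        d = min(int(rng.integers(lo, hi + 1)), rem)
        if rem - d < lo:
            d = rem
        runs.append(d)
        rem -= d
    return runs


def _place_runs(n_frames: int, runs: list[int], rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with the given runs placed in random order, separated by gaps."""
    mask = np.zeros(n_frames, dtype=bool)
    if not runs:
        return mask
    runs = list(runs)
    rng.shuffle(runs)
    k = len(runs)
    free = n_frames - sum(runs) - (k - 1)
    if free < 0:
        raise InvalidInputError("run lengths exceed the window")
    # k+1 gap slots around the runs; 1-frame separators already reserved
    gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
    pos = gaps[0]
    for i, d in enumerate(runs):
        mask[pos : pos + d] = True
        pos += d + 1 + gaps[i + 1]
    return mask


def _stochastic_round_to_min(total: int, minimum: int, rng: np.random.Generator) -> int:
    """Round totals below ``minimum`` to 0 or ``minimum`` preserving the mean."""
    if total >= minimum or total <= 0:
        return max(total, 0)
    return minimum if rng.uniform() < total / minimum else 0


def _draw_fraction(target: float, sd: float, rng: np.random.Generator, hi: float = 1.0) -> float:
    """Noisy per-window target; the noise SD shrinks near 0 so that clipping
    cannot bias the mean (a target of exactly 0 is realised exactly)."""
    sd_eff = min(sd, target / 2.0)
    if sd_eff <= 0.0:
        return float(np.clip(target, 0.0, hi))
    return float(np.clip(rng.normal(target, sd_eff), 0.0, hi))


def _window_closed_mask(
    bf_t: float, ecd_t: float, n_frames: int, fps: float, rng: np.random.Generator
) -> np.ndarray:
    bf_w = _draw_fraction(bf_t, STREAM_NOISE["bf"], rng, hi=0.9)
    ecd_w = _draw_fraction(ecd_t, STREAM_NOISE["ecd"], rng, hi=bf_w)
    min_long = int(round(2.0 * fps))
    total_long = _stochastic_round_to_min(int(round(ecd_w * n_frames)), min_long, rng)
    long_runs = _split_runs(total_long, min_long, 2 * min_long, rng)
    total_short = max(int(round(bf_w * n_frames)) - total_long, 0)
    short_runs = _split_runs(total_short, 2, min_long - 2, rng) if total_short else []
    return _place_runs(n_frames, long_runs + short_runs, rng)


def _window_yawn_mask(
    yf_t: float, n_frames: int, fps: float, rng: np.random.Generator
) -> np.ndarray:
    yf_w = _draw_fraction(yf_t, STREAM_NOISE["yf"], rng, hi=0.5)
    min_yawn = int(round(3.0 * fps))
    total = _stochastic_round_to_min(int(round(yf_w * n_frames)), min_yawn, rng)
    runs = _split_runs(total, min_yawn, 2 * min_yawn, rng)
    return _place_runs(n_frames, runs, rng)


def generate_session(cfg: SimConfig | None = None) -> LabeledSession:
    """Synthesise raw streams for a Markov state path and extract features.

    Returns the streams, the per-window features recomputed by the feature
    extractors, the true state per window, and the expected per-state feature
    means implied by the configuration (SD features bias-corrected for the
    10 s evaluation sub-window).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    fps, vhz = cfg.frame_rate, cfg.vehicle_rate
    nf_frames = int(round(60.0 * fps))
    nv = int(round(60.0 * vhz))
    tgt = cfg.stream_targets

    # Markov state path
    states: list[FatigueState] = []
    s = int(cfg.initial_state)
    for _ in range(cfg.session_windows):
        states.append(FatigueState(s))
        s = int(rng.choice(3, p=cfg.transition[s]))

    f_t, f_closed, f_eyelid, f_mh = [], [], [], []
    v_t, v_angle, v_rate, v_thl, v_thr, v_speed = [], [], [], [], [], []
    theta_r = 2.0 * np.pi / 3.0
    for w, st in enumerate(states):
        start = 60.0 * w
        si = int(st)
        closed = _window_closed_mask(tgt["bf"][si], tgt["ecd"][si], nf_frames, fps, rng)
        yawn = _window_yawn_mask(tgt["yf"][si], nf_frames, fps, rng)
        eyelid = np.where(
            closed, 0.0, np.clip(rng.normal(tgt["meol_open"][si], 1.0, nf_frames), 0.0, None)
        )
        ratio = np.where(yawn, cfg.yawn_ratio, cfg.rest_ratio)
        f_t.append(start + np.arange(nf_frames) / fps)
        f_closed.append(closed)
        f_eyelid.append(eyelid)
        f_mh.append(ratio * cfg.mouth_width)

        nonsteer = rng.uniform(size=nv) < tgt["pns"][si]
        rate = np.where(
            nonsteer,
            rng.uniform(-0.09, 0.09, nv),
            rng.uniform(0.3, 3.0, nv) * rng.choice([-1.0, 1.0], nv),
        )
        angle = rng.normal(0.0, tgt["sdsa"][si], nv)
        speed = np.clip(rng.normal(cfg.speed_mean, tgt["sdvs"][si], nv), 0.0, None)
        deviating = rng.uniform(size=nv) < tgt["fald"][si]
        side = rng.choice([True, False], nv)
        xi = np.where(
            deviating,
            np.where(side, rng.uniform(1.3, 2.0, nv), rng.uniform(0.5, 0.75, nv)),
            rng.uniform(0.9, 1.1, nv),
        )
        theta_l = np.pi / 2.0 - xi * (theta_r - np.pi / 2.0)
        v_t.append(start + np.arange(nv) / vhz)
        v_angle.append(angle)
        v_rate.append(rate)
        v_thl.append(theta_l)
        v_thr.append(np.full(nv, theta_r))
        v_speed.append(speed)

    frames = FrameStream(
        np.concatenate(f_t),
        np.concatenate(f_closed),
        np.concatenate(f_eyelid),
        np.concatenate(f_mh),
        np.full(cfg.session_windows * nf_frames, cfg.mouth_width),
        fps,
    )
    vehicle = VehicleStream(
        np.concatenate(v_t),
        np.concatenate(v_angle),
        np.concatenate(v_thl),
        np.concatenate(v_thr),
        np.concatenate(v_speed),
        steer_rate=np.concatenate(v_rate),
    )
    windows = windowize(frames, vehicle, FeatureConfig())
    table = windows_to_frame(windows)
    table["state"] = [int(s) for s in states[: len(windows)]]

    n_sub = int(round(10.0 * vhz))  # SD features evaluated on the last 10 s
    bias = population_sd_bias(n_sub)
    expected = {
        FatigueState(s): {
            "bf": tgt["bf"][s],
            "ecd": tgt["ecd"][s],
            "meol": tgt["meol_open"][s] * (1.0 - tgt["bf"][s]),
            "yf": tgt["yf"][s],
            "pns": tgt["pns"][s],
            "sdsa": tgt["sdsa"][s] * bias,
            "fald": tgt["fald"][s],
            "sdvs": tgt["sdvs"][s] * bias,
        }
        for s in range(3)
    }
    return LabeledSession(frames, vehicle, windows, states, table, expected)


# ---------------------------------------------------------------------------
# Worked-example fixtures


@dataclass(frozen=True)
class WorkedExample:
    """The printed worked-example tables, with self-consistency flags.

    ``network_outputs``: six pairs of raw (facial, vehicle) output vectors.
    ``first_fusion``: per row the normalised evidence pair, conflict degree
    K', fused mass and decisions.  ``decision_fusion``: per row the
    previous-step mass, normalised intermediate mass, K, final mass and
    decision.  Rows whose printed numbers cannot be re-derived from their own
    printed inputs carry ``consistent=False`` and are excluded from numeric
    assertions (first-fusion row 1; decision rows 2 and 6).
    """

    network_outputs: tuple
    first_fusion: tuple
    decision_fusion: tuple

    @property
    def flagged_rows(self) -> list[tuple[str, int]]:
        out = [("first_fusion", i + 1) for i, r in enumerate(self.first_fusion) if not r["consistent"]]
        out += [("decision_fusion", i + 1) for i, r in enumerate(self.decision_fusion) if not r["consistent"]]
        return out


def fixtures() -> WorkedExample:
    """Embedded worked-example tables (six verification samples)."""
    network_outputs = (
        ((0.812, 0.087, 0.103), (0.782, 0.311, 0.074)),
        ((0.203, 0.763, 0.052), (0.402, 0.432, 0.207)),
        ((0.237, 0.624, 0.178), (0.383, 0.552, 0.134)),
        ((0.412, 0.488, 0.106), (0.721, 0.234, 0.071)),
        ((0.127, 0.073, 0.811), (0.442, 0.551, 0.107)),
        ((0.292, 0.457, 0.393), (0.112, 0.476, 0.389)),
    )
    first_fusion = (
        dict(m1=(0.810, 0.087, 0.103), m2=(0.670, 0.266, 0.064), K=0.441,
             fused=(0.971, 0.476, 0.012), decision="NF", assessed="NF", consistent=False),
        dict(m1=(0.199, 0.750, 0.051), m2=(0.386, 0.415, 0.199), K=0.603,
             fused=(0.193, 0.784, 0.026), decision="MF", assessed="MF", consistent=True),
        dict(m1=(0.228, 0.601, 0.171), m2=(0.359, 0.516, 0.125), K=0.587,
             fused=(0.198, 0.751, 0.052), decision="MF", assessed="MF", consistent=True),
        dict(m1=(0.410, 0.485, 0.105), m2=(0.703, 0.228, 0.069), K=0.593,
             fused=(0.708, 0.272, 0.018), decision="NF", assessed="NF", consistent=True),
        dict(m1=(0.126, 0.072, 0.802), m2=(0.402, 0.501, 0.097), K=0.835,
             fused=(0.307, 0.219, 0.471), decision="SF", assessed="SF", consistent=True),
        dict(m1=(0.256, 0.400, 0.344), m2=(0.115, 0.487, 0.398), K=0.640,
             fused=(0.082, 0.541, 0.380), decision="MF", assessed="SF", consistent=True),
    )
    decision_fusion = (
        dict(prev=(0.793, 0.102, 0.105), inter=(0.665, 0.326, 0.009), K=0.44,
             fused=(0.942, 0.059, 0.002), decision="NF", consistent=True),
        dict(prev=(0.192, 0.713, 0.095), inter=(0.192, 0.782, 0.026), K=0.304,
             fused=(0.053, 0.801, 0.004), decision="MF", consistent=False),
        dict(prev=(0.179, 0.599, 0.222), inter=(0.198, 0.75, 0.052), K=0.503,
             fused=(0.071, 0.904, 0.023), decision="MF", consistent=True),
        dict(prev=(0.647, 0.285, 0.068), inter=(0.709, 0.273, 0.018), K=0.463,
             fused=(0.854, 0.145, 0.002), decision="NF", consistent=True),
        dict(prev=(0.186, 0.127, 0.687), inter=(0.308, 0.220, 0.472), K=0.591,
             fused=(0.140, 0.068, 0.793), decision="SF", consistent=True),
        dict(prev=(0.135, 0.079, 0.786), inter=(0.082, 0.539, 0.379), K=0.608,
             fused=(0.028, 0.109, 0.760), decision="SF", consistent=False),
    )
    return WorkedExample(network_outputs, first_fusion, decision_fusion)
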