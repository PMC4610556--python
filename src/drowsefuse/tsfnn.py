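"""Takagi–Sugeno fuzzy neural network: structure, forward pass and training.

The network has five layers: input, fuzzification (one Gaussian membership
per input and linguistic value), rule (product firing strengths), strength
normalisation, and a linear output layer.  With ``n`` inputs, ``m`` rules and
``r`` outputs the trainable parameters are the membership centers ``c_ij``
and widths ``sigma_ij`` (n x m each) and the output weights ``w_kj`` (r x m):

    mu_ij    = exp(-(x_i - c_ij)^2 / sigma_ij^2)
    alpha_j  = prod_i mu_ij
    abar_j   = alpha_j / sum_j alpha_j
    y_k      = sum_j w_kj * abar_j

Structure is found by subtractive clustering (Chiu-style potential
maximisation) — the number of extracted clusters becomes both the rule count
and the number of linguistic values per input, which shrinks the parameter
count from the full grid's ``2nL + r L^n`` to ``2nm + rm``.  Parameters are
then learned by global-best particle swarm optimisation of the mean
sum-of-squares fitness.

Firing strengths are evaluated in log space (max-subtracted before
exponentiation) so that inputs far from every rule center normalise
correctly instead of underflowing to 0/0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "TSFNNStructure",
    "TSFNNParams",
    "ForwardTrace",
    "SCAConfig",
    "TrainConfig",
    "TSFNNModel",
    "forward",
    "predict_batch",
    "count_parameters",
    "subtractive_clustering",
    "init_from_clusters",
    "fitness",
    "pso_train",
    "fit_tsfnn",
]


@dataclass(frozen=True)
class TSFNNStructure:
    """Network shape: ``n`` inputs, ``m`` fuzzy rules, ``r`` outputs.

    ``linguistic_values`` is the number of fuzzy sets per input: equal to
    ``m`` when the structure comes from subtractive clustering, or the grid
    resolution ``L`` for the full rule grid (``L**n`` rules).
    """

    n: int
    m: int
    r: int
    linguistic_values: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1 or self.r < 1:
            raise InvalidInputError("n, m, r must all be >= 1")


@dataclass
class TSFNNParams:
    """Membership centers/widths (n x m) and output weights (r x m)."""

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centers.shape != self.widths.shape:
            raise InvalidInputError("centers and widths must share shape (n, m)")
        if self.weights.ndim != 2 or self.weights.shape[1] != self.centers.shape[1]:
            raise InvalidInputError("weights must have shape (r, m)")
        if np.any(self.widths <= 0):
            raise InvalidInputError("all membership widths must be positive")

    @property
    def n(self) -> int:
        return self.centers.shape[0]

    @property
    def m(self) -> int:
        return self.centers.shape[1]

    @property
    def r(self) -> int:
        return self.weights.shape[0]

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.centers.ravel(), self.widths.ravel(), self.weights.ravel()]
        )

    @staticmethod
    def unflatten(vec: np.ndarray, n: int, m: int, r: int) -> "TSFNNParams":
        nm = n * m
        return TSFNNParams(
            vec[:nm].reshape(n, m),
            vec[nm : 2 * nm].reshape(n, m),
            vec[2 * nm :].reshape(r, m),
        )


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass."""

    memberships: np.ndarray
    firing: np.ndarray
    normalized: np.ndarray
    outputs: np.ndarray


def _log_firing(params: TSFNNParams, X: np.ndarray) -> np.ndarray:
    """Log firing strengths, shape (N, m), for sample matrix X of shape (N, n)."""
    z = (X[:, :, None] - params.centers[None, :, :]) / params.widths[None, :, :]
    return -(z**2).sum(axis=1)


def forward(params: TSFNNParams, x: Sequence[float]) -> ForwardTrace:
    """Evaluate the network on one input vector, returning the full trace."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n,):
        raise InvalidInputError(f"expected input of shape ({params.n},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("input must be finite")
    z = (x[:, None] - params.centers) / params.widths
    memberships = np.exp(-(z**2))
    log_alpha = -(z**2).sum(axis=0)
    alpha = np.exp(log_alpha)
    abar = np.exp(log_alpha - log_alpha.max())
    abar /= abar.sum()
    y = params.weights @ abar
    return ForwardTrace(memberships, alpha, abar, y)


def predict_batch(params: TSFNNParams, X: np.ndarray) -> np.ndarray:
    """Network outputs for a sample matrix X of shape (N, n); returns (N, r)."""
    X = np.asarray(X, dtype=float)
    log_alpha = _log_firing(params, X)
    a = np.exp(log_alpha - log_alpha.max(axis=1, keepdims=True))
    abar = a / a.sum(axis=1, keepdims=True)
    return abar @ params.weights.T


def count_parameters(structure: TSFNNStructure, with_sca: bool = True) -> int:
    """Trainable-parameter count: ``2nm + rm`` with clustering, ``2nL + r L^n`` for the grid."""
    if with_sca:
        return 2 * structure.n * structure.m + structure.r * structure.m
    L = structure.linguistic_values
    if L is None:
        raise InvalidInputError("grid structure needs linguistic_values")
    return 2 * structure.n * L + structure.r * L**structure.n


@dataclass(frozen=True)
class SCAConfig:
    """Subtractive-clustering constants (on features scaled to comparable ranges).

    ``accept_radius`` (r_a) sets the neighbourhood that feeds a point's
    potential; ``squash_radius`` (r_b, conventionally 1.5 r_a) the
    neighbourhood suppressed around each accepted center.  ``accept_ratio``
    and ``reject_ratio`` bound the grey zone of the acceptance test.
    """

    accept_radius: float = 0.5
    squash_radius: float | None = None
    accept_ratio: float = 0.5
    reject_ratio: float = 0.15

    def __post_init__(self) -> None:
        if self.accept_radius <= 0:
            raise InvalidInputError("accept_radius must be positive")
        rb = self.squash_radius
        if rb is not None and rb < self.accept_radius:
            raise InvalidInputError("squash_radius must be >= accept_radius")
        if not (0 < self.reject_ratio < self.accept_ratio <= 1):
            raise InvalidInputError("need 0 < reject_ratio < accept_ratio <= 1")

    @property
    def rb(self) -> float:
        return self.squash_radius if self.squash_radius is not None else 1.5 * self.accept_radius


def subtractive_clustering(samples: np.ndarray, cfg: SCAConfig | None = None) -> np.ndarray:
    """Chiu-style subtractive clustering; returns selected data points as centers.

    Each point's potential is the kernel-density-like sum
    ``P_i = sum_j exp(-4 ||x_i - x_j||^2 / r_a^2)``.  The highest-potential
    point becomes a center; potentials near it are then revised downward with
    radius ``r_b`` and the process repeats.  Candidates in the grey zone
    between the accept and reject ratios are kept only if they are far enough
    from existing centers (``d_min/r_a + P/P_1 >= 1``).
    """
    cfg = cfg or SCAConfig()
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N = X.shape[0]
    if N == 0:
        raise InvalidInputError("subtractive clustering needs at least one sample")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    P = np.exp(-4.0 * sq / cfg.accept_radius**2).sum(axis=1)
    centers: list[int] = []
    P = P.copy()
    p_first = None
    while True:
        k = int(np.argmax(P))
        pk = P[k]
        if pk <= 0:
            break
        if p_first is None:
            p_first = pk
            accept = True
        elif pk > cfg.accept_ratio * p_first:
            accept = True
        elif pk < cfg.reject_ratio * p_first:
            break
        else:
            d_min = np.sqrt(min(sq[k, c] for c in centers))
            if d_min / cfg.accept_radius + pk / p_first >= 1.0:
                accept = True
            else:
                P[k] = 0.0
                continue
        if accept:
            centers.append(k)
            P = P - pk * np.exp(-4.0 * sq[:, k] / cfg.rb**2)
            P = np.clip(P, 0.0, None)
            if len(centers) == N:
                break
    return X[centers]


def init_from_clusters(
    centers: np.ndarray,
    n_outputs: int,
    seed: int | np.random.Generator = 0,
    sigma_floor: float = 0.1,
) -> TSFNNParams:
    """Initial network parameters from cluster centers.

    The rule count equals the cluster count; ``c'_ij`` is coordinate ``i`` of
    center ``j``.  Initial widths are shared across rules:
    ``sigma'_i = |x_{i,1} - x_{i,S}| / 2`` where center ``S`` is the
    Euclidean-nearest center to the first one.  With a single cluster (or a
    zero coordinate gap) widths fall back to ``sigma_floor``.  Output weights
    start uniform in [0, 1] under the given seed.
    """
    C = np.asarray(centers, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    m, n = C.shape
    if m < 1:
        raise InvalidInputError("need at least one cluster center")
    if m == 1:
        sigma = np.full(n, sigma_floor)
    else:
        dist = np.linalg.norm(C[1:] - C[0], axis=1)
        s = 1 + int(np.argmin(dist))
        sigma = np.abs(C[0] - C[s]) / 2.0
        sigma = np.where(sigma > 0, sigma, sigma_floor)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = rng.uniform(0.0, 1.0, size=(n_outputs, m))
    return TSFNNParams(C.T.copy(), np.tile(sigma[:, None], (1, m)), weights)


def fitness(params: TSFNNParams, dataset: tuple[np.ndarray, np.ndarray]) -> float:
    """Mean over samples of the sum over outputs of squared prediction error."""
    X, Y = dataset
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise InvalidInputError("empty dataset")
    if Y.shape != (X.shape[0], params.r):
        raise InvalidInputError(f"targets must have shape ({X.shape[0]}, {params.r})")
    resid = predict_batch(params, X) - Y
    return float((resid**2).sum() / X.shape[0])


@dataclass(frozen=True)
class TrainConfig:
    """Global-best PSO controls.

    Defaults: swarm of 30, accelerations c1 = c2 = 2, inertia decayed
    linearly 0.9 -> 0.4, velocities clamped to ``velocity_clamp`` times each
    coordinate's bound range, early stop at ``target_fitness``.  Search
    bounds: centers within the data range padded by one SD, widths in
    [``sigma_floor``, data range], weights in [-2, 2].
    """

    swarm_size: int = 30
    max_iters: int = 2000
    inertia: tuple[float, float] = (0.9, 0.4)
    c1: float = 2.0
    c2: float = 2.0
    velocity_clamp: float = 0.2
    target_fitness: float = 1e-4
    seed: int = 0
    sigma_floor: float = 1e-3
    weight_bound: float = 2.0
    restart_after: int = 75  # re-scatter the swarm after this many stagnant iters

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise InvalidInputError("swarm_size must be >= 2")
        if self.target_fitness <= 0:
            raise InvalidInputError("target_fitness must be positive")


def _bounds(X: np.ndarray, structure: TSFNNStructure, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    n, m, r = structure.n, structure.m, structure.r
    lo_x = X.min(axis=0) - X.std(axis=0)
    hi_x = X.max(axis=0) + X.std(axis=0)
    rng_x = np.maximum(X.max(axis=0) - X.min(axis=0), 10 * cfg.sigma_floor)
    lo = np.concatenate(
        [
            np.repeat(lo_x, m),
            np.full(n * m, cfg.sigma_floor),
            np.full(r * m, -cfg.weight_bound),
        ]
    )
    hi = np.concatenate(
        [
            np.repeat(hi_x, m),
            np.repeat(rng_x, m),
            np.full(r * m, cfg.weight_bound),
        ]
    )
    return lo, hi


def pso_train(
    dataset: tuple[np.ndarray, np.ndarray],
    structure: TSFNNStructure,
    init: TSFNNParams,
    cfg: TrainConfig | None = None,
) -> tuple[TSFNNParams, np.ndarray]:
    """Global-best PSO over the flattened (centers, widths, weights) vector.

    The initial parameters seed one particle; the rest start uniform within
    the bounds.  Width coordinates are clamped to the positivity floor
    throughout.  Returns the best parameters found and the per-iteration
    best-fitness trace (monotone non-increasing, entry 0 = initial swarm
    best).  Bit-reproducible for a fixed ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    X, Y = dataset
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise InvalidInputError("empty dataset")
    if init.n != structure.n or init.m != structure.m or init.r != structure.r:
        raise InvalidInputError("init parameters inconsistent with structure")
    n, m, r = structure.n, structure.m, structure.r
    dim = 2 * n * m + r * m
    if cfg.max_iters == 0:
        return init, np.array([fitness(init, (X, Y))])

    lo, hi = _bounds(X, structure, cfg)
    span = hi - lo
    vmax = cfg.velocity_clamp * span
    sigma_slice = slice(n * m, 2 * n * m)

    def clamp(pos: np.ndarray) -> np.ndarray:
        pos = np.clip(pos, lo, hi)
        pos[:, sigma_slice] = np.maximum(pos[:, sigma_slice], cfg.sigma_floor)
        return pos

    def evaluate(pos: np.ndarray) -> np.ndarray:
        vals = np.empty(pos.shape[0])
        for i, p in enumerate(pos):
            vals[i] = fitness(TSFNNParams.unflatten(p, n, m, r), (X, Y))
        return vals

    rng = np.random.default_rng(cfg.seed)
    pos = lo + rng.uniform(size=(cfg.swarm_size, dim)) * span
    pos[0] = np.clip(init.flatten(), lo, hi)
    pos = clamp(pos)
    vel = rng.uniform(-1.0, 1.0, size=(cfg.swarm_size, dim)) * vmax * 0.1

    fit = evaluate(pos)
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    best, best_fit = gbest.copy(), gbest_fit  # archive across restarts
    trace = [best_fit]

    w0, w1 = cfg.inertia
    stagnant = 0
    for it in range(cfg.max_iters):
        if best_fit <= cfg.target_fitness:
            break
        if cfg.restart_after and stagnant >= cfg.restart_after:
            # premature-convergence escape: start a fresh, independent swarm.
            # The archived best stays out of the new swarm so it cannot drag
            # the re-scattered particles back into the stalled basin.
            pos = clamp(lo + rng.uniform(size=(cfg.swarm_size, dim)) * span)
            vel = rng.uniform(-1.0, 1.0, size=(cfg.swarm_size, dim)) * vmax * 0.1
            fit = evaluate(pos)
            pbest, pbest_fit = pos.copy(), fit.copy()
            g = int(np.argmin(fit))
            gbest, gbest_fit = pos[g].copy(), float(fit[g])
            stagnant = 0
        w = w0 + (w1 - w0) * (it / max(cfg.max_iters - 1, 1))
        r1 = rng.uniform(size=(cfg.swarm_size, dim))
        r2 = rng.uniform(size=(cfg.swarm_size, dim))
        vel = w * vel + cfg.c1 * r1 * (pbest - pos) + cfg.c2 * r2 * (gbest - pos)
        vel = np.clip(vel, -vmax, vmax)
        pos = clamp(pos + vel)
        fit = evaluate(pos)
        improved = fit < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            # only a material (0.1% relative) gain resets the stagnation clock
            if pbest_fit[g] < gbest_fit * (1.0 - 1e-3):
                stagnant = 0
            else:
                stagnant += 1
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        else:
            stagnant += 1
        if gbest_fit < best_fit:
            best, best_fit = gbest.copy(), gbest_fit
        trace.append(best_fit)
    return TSFNNParams.unflatten(best, n, m, r), np.asarray(trace)


@dataclass
class TSFNNModel:
    """A trained network plus the input min-max scaling it was fitted under."""

    structure: TSFNNStructure
    params: TSFNNParams
    scale_min: np.ndarray
    scale_max: np.ndarray
    train_meta: dict = field(default_factory=dict)

    def scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = np.maximum(self.scale_max - self.scale_min, 1e-12)
        return (X - self.scale_min) / span

    def predict(self, x: Sequence[float]) -> np.ndarray:
        """Outputs for one raw (unscaled) input vector."""
        x = self.scale(np.asarray(x, dtype=float)[None, :])[0]
        return forward(self.params, x).outputs

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return predict_batch(self.params, self.scale(np.atleast_2d(X)))

    def to_dict(self) -> dict:
        return {
            "structure": {
                "n": self.structure.n,
                "m": self.structure.m,
                "r": self.structure.r,
                "linguistic_values": self.structure.linguistic_values,
            },
            "scaling": {"min": self.scale_min.tolist(), "max": self.scale_max.tolist()},
            "centers": self.params.centers.tolist(),
            "widths": self.params.widths.tolist(),
            "weights": self.params.weights.tolist(),
            "train_meta": self.train_meta,
        }

    @staticmethod
    def from_dict(doc: dict) -> "TSFNNModel":
        s = doc["structure"]
        return TSFNNModel(
            TSFNNStructure(s["n"], s["m"], s["r"], s.get("linguistic_values")),
            TSFNNParams(
                np.asarray(doc["centers"]),
                np.asarray(doc["widths"]),
                np.asarray(doc["weights"]),
            ),
            np.asarray(doc["scaling"]["min"], dtype=float),
            np.asarray(doc["scaling"]["max"], dtype=float),
            doc.get("train_meta", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def from_json(path) -> "TSFNNModel":
        with open(path) as fh:
            return TSFNNModel.from_dict(json.load(fh))


def fit_tsfnn(
    X: np.ndarray,
    Y: np.ndarray,
    sca_cfg: SCAConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> TSFNNModel:
    """Structure-then-parameter learning on a raw training table.

    Inputs are min-max scaled to [0, 1]; subtractive clustering on the scaled
    inputs fixes the rule count and the initial centers/widths; PSO then
    learns all parameters.  The scaling is stored with the model.
    """
    train_cfg = train_cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    scale_min, scale_max = X.min(axis=0), X.max(axis=0)
    span = np.maximum(scale_max - scale_min, 1e-12)
    Xs = (X - scale_min) / span
    centers = subtractive_clustering(Xs, sca_cfg)
    init = init_from_clusters(centers, Y.shape[1], seed=train_cfg.seed)
    structure = TSFNNStructure(X.shape[1], init.m, Y.shape[1], linguistic_values=init.m)
    params, trace = pso_train((Xs, Y), structure, init, train_cfg)
    meta = {
        "seed": train_cfg.seed,
        "iterations": int(trace.size - 1),
        "final_fitness": float(trace[-1]),
    }
    return TSFNNModel(structure, params, scale_min, scale_max, meta)
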