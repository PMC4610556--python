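"""Fatigue-feature screening: normality check, log transform, Pearson test.

Each candidate feature is first checked for normality with a one-sample
Kolmogorov–Smirnov test against a normal with the sample's own mean and SD
(asymptotic critical value 1.36/sqrt(n) at alpha = 0.05; an optional
Lilliefors-style Monte-Carlo critical value corrects for the estimated
parameters).  Features failing the check are log-transformed and re-tested.
The feature is then correlated with the ordinal fatigue labels (0/1/2) and
retained when the Student-t statistic ``t = r sqrt((n-2)/(1-r^2))`` exceeds
the two-sided critical value — screening is by correlation magnitude, so
negatively correlated features survive on equal terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "FeatureScreen",
    "ScreeningResult",
    "ks_normality",
    "log_normalize",
    "pearson_screen",
    "select_features",
]

_KS_ASYMPTOTIC_05 = 1.36


@dataclass
class FeatureScreen:
    """Screening record for a single feature."""

    name: str
    ks_statistic: float = float("nan")
    ks_critical: float = float("nan")
    normal: bool = False
    log_transformed: bool = False
    shift: float = 0.0
    correlation: float = float("nan")
    t_statistic: float = float("nan")
    t_critical: float = float("nan")
    retained: bool = False
    degenerate: bool = False


@dataclass
class ScreeningResult:
    """Per-feature screening records plus the retained-feature list."""

    screens: dict[str, FeatureScreen] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return [name for name, s in self.screens.items() if s.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.screens.values()]).set_index("name")


def ks_normality(
    samples: np.ndarray, alpha: float = 0.05, lilliefors: bool = False, seed: int = 0
) -> tuple[float, bool]:
    """One-sample KS statistic against N(mean, sd) fitted to the sample.

    Passes when the statistic is below the critical value.  Default critical
    value is the asymptotic 1.36/sqrt(n) at alpha = 0.05 with the estimated
    parameters plugged in uncorrected; ``lilliefors=True`` replaces it with a
    Monte-Carlo quantile that accounts for the estimation.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise InvalidInputError("KS normality check needs at least 8 samples")
    sd = x.std(ddof=1)
    if sd <= max(abs(float(x.mean())), 1.0) * 1e-12:  # constant to rounding
        return float("inf"), False
    stat = float(stats.kstest(x, "norm", args=(x.mean(), sd)).statistic)
    crit = _ks_critical(x.size, alpha, lilliefors, seed)
    return stat, stat < crit


import functools


@functools.lru_cache(maxsize=128)
def _ks_critical(n: int, alpha: float, lilliefors: bool, seed: int) -> float:
    if not lilliefors:
        if abs(alpha - 0.05) > 1e-12:
            # generic asymptotic quantile sqrt(-ln(alpha/2)/2)/sqrt(n)
            return math.sqrt(-0.5 * math.log(alpha / 2.0)) / math.sqrt(n)
        return _KS_ASYMPTOTIC_05 / math.sqrt(n)
    rng = np.random.default_rng(seed)
    reps = 500
    stats_mc = np.empty(reps)
    for i in range(reps):
        z = rng.standard_normal(n)
        stats_mc[i] = stats.kstest(z, "norm", args=(z.mean(), z.std(ddof=1))).statistic
    return float(np.quantile(stats_mc, 1.0 - alpha))


def log_normalize(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Elementwise natural log; non-positive values trigger a shift by 1 - min.

    Returns the transformed sample and the shift applied (0 when none).
    """
    x = np.asarray(samples, dtype=float)
    shift = 0.0
    if np.any(x <= 0):
        shift = 1.0 - x.min()
        x = x + shift
    return np.log(x), shift


def pearson_screen(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float, bool]:
    """Pearson correlation of a feature with ordinal labels, with t screen.

    Returns ``(r, t, critical, retained)`` where ``t = r sqrt((n-2)/(1-r^2))``
    and ``critical`` is the two-sided Student-t quantile at ``alpha`` with
    n - 2 degrees of freedom.  Degenerate inputs (zero variance) are never
    retained.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need matched samples of length >= 3")
    n = x.size
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 2))
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan"), crit, False
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, float("inf"), crit, True
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return r, t, crit, abs(t) > crit


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    lilliefors: bool = False,
) -> tuple[list[str], ScreeningResult]:
    """Screen every column of a feature table against the fatigue labels.

    Non-normal features (per the KS check) are log-transformed before the
    correlation test.  Returns the retained feature names and the full
    per-feature records.
    """
    y = np.asarray(labels, dtype=float)
    if len(table) != y.size:
        raise InvalidInputError("labels must match the table length")
    result = ScreeningResult()
    for name in table.columns:
        screen = FeatureScreen(name=name)
        x = table[name].to_numpy(dtype=float)
        if x.std(ddof=1) == 0 or y.std() == 0:
            screen.degenerate = True
            result.screens[name] = screen
            continue
        stat, ok = ks_normality(x, alpha, lilliefors)
        screen.ks_statistic, screen.normal = stat, ok
        screen.ks_critical = _ks_critical(x.size, alpha, lilliefors, seed=0)
        if not ok:
            x, screen.shift = log_normalize(x)
            screen.log_transformed = True
        r, t, crit, retained = pearson_screen(x, y, alpha)
        screen.correlation, screen.t_statistic = r, t
        screen.t_critical, screen.retained = crit, retained
        result.screens[name] = screen
    return result.retained, result
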