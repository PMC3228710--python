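"""Trait-like stability via the intraclass correlation coefficient.

The ICC of a per-animal-per-day measure is the ratio of between-animal
variance to total variance under a one-way random-intercept model

    y_ij = mu + a_i + e_ij,   a_i ~ N(0, s2_a),  e_ij ~ N(0, s2_e),

estimated either by REML (profiled likelihood over the variance ratio,
exact scalar optimisation) or by the classical ANOVA moment estimator with
negative between-variance truncated at zero.  On balanced designs with a
positive ANOVA estimate the two coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

BENCHMARKS = (
    (0.0, 0.2, "slight"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "substantial"),
    (0.8, 1.0, "almost perfect"),
)


@dataclass
class ICCResult:
    icc: float
    var_between: float
    var_within: float
    label: str
    estimator: str


def benchmark_label(icc: float) -> str:
    """Benchmark category for an ICC; boundaries are assigned upward.

    Half-open ranges [0, 0.2) "slight", [0.2, 0.4) "fair", [0.4, 0.6)
    "moderate", [0.6, 0.8) "substantial", [0.8, 1.0] "almost perfect".
    """
    if not (0.0 <= icc <= 1.0):
        raise ValueError(f"ICC out of range [0, 1]: {icc}")
    for lo, hi, name in BENCHMARKS:
        if lo <= icc < hi:
            return name
    return "almost perfect"


def _check(df: pd.DataFrame) -> tuple[np.ndarray, list[np.ndarray]]:
    if not {"animal", "value"} <= set(df.columns):
        raise ValueError("need columns 'animal' and 'value'")
    groups = [g["value"].to_numpy(float) for _, g in df.groupby("animal")]
    if len(groups) < 2:
        raise ValueError("ICC requires at least 2 animals")
    if sum(len(g) >= 2 for g in groups) < 2:
        raise ValueError("ICC requires replication (>= 2 values) in >= 2 animals")
    return df["value"].to_numpy(float), groups


def _anova_components(groups: list[np.ndarray]) -> tuple[float, float]:
    k = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n0 = (N - (n_i ** 2).sum() / N) / (k - 1)
    var_b = max((msb - msw) / n0, 0.0)
    return var_b, msw


def _reml_components(groups: list[np.ndarray]) -> tuple[float, float]:
    """Profiled REML for the one-way model.

    For a fixed ratio lam = s2_a / s2_e the GLS mean and the REML estimate of
    s2_e are closed-form; the scalar profile in log(lam) is minimised
    numerically.
    """
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    means = np.array([g.mean() for g in groups])
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))

    def neg_profile(loglam: float) -> float:
        lam = np.exp(loglam)
        d = 1.0 + n_i * lam                   # V_i = s2_e (I + lam J); det factor
        w = n_i / d
        mu = (w * means).sum() / w.sum()
        # quadratic form y' V^{-1} y / s2_e
        q = ssw + ((means - mu) ** 2 * n_i / d).sum()
        s2e = q / (N - 1)
        # -2 * REML log-likelihood up to constants
        return (N - 1) * np.log(s2e) + np.log(d).sum() + np.log(w.sum())

    res = minimize_scalar(neg_profile, bounds=(-30.0, 30.0), method="bounded",
                          options={"xatol": 1e-12})
    lam = float(np.exp(res.x))
    d = 1.0 + n_i * lam
    w = n_i / d
    mu = (w * means).sum() / w.sum()
    q = ssw + ((means - mu) ** 2 * n_i / d).sum()
    s2e = q / (N - 1)
    # boundary: ratios at the optimisation edge collapse to zero variance
    if res.x <= -29.0:
        lam = 0.0
    return lam * s2e, float(s2e)


def icc_one_way(data: pd.DataFrame, estimator: str = "reml") -> ICCResult:
    """ICC from a long table with columns ``animal`` and ``value``.

    ``estimator`` is "reml" (default) or "anova".  Degenerate all-identical
    data yields ICC 0 by the truncation convention.
    """
    values, groups = _check(data)
    if np.allclose(values, values[0]):
        logger.warning("all values identical; ICC defined as 0 by convention")
        return ICCResult(0.0, 0.0, 0.0, benchmark_label(0.0), estimator)
    if estimator == "anova":
        var_b, var_w = _anova_components(groups)
    elif estimator == "reml":
        var_b, var_w = _reml_components(groups)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    total = var_b + var_w
    icc = float(np.clip(var_b / total, 0.0, 1.0)) if total > 0 else 0.0
    return ICCResult(icc, float(var_b), float(var_w), benchmark_label(icc), estimator)


def bootstrap_ci(
    data: pd.DataFrame,
    estimator: str = "reml",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the ICC, resampling animals."""
    rng = np.random.default_rng(seed)
    animals = data["animal"].unique()
    stats = []
    for _ in range(n_boot):
        pick = rng.choice(animals, size=len(animals), replace=True)
        parts = [data[data["animal"] == a].assign(animal=f"{a}#{i}")
                 for i, a in enumerate(pick)]
        boot = pd.concat(parts, ignore_index=True)
        try:
            stats.append(icc_one_way(boot, estimator).icc)
        except ValueError:
            continue
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha))
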