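"""Replicate variability (CV) and two-sample t-test power planning.

Replicate scatter is summarized per feature as the coefficient of
variation CV = 100·SD/mean of its signal across hybridizations, with CVs
expressed on a 100-based rank scale (the CV at rank 90 is the P90
summary).  The planning question — how many replicates detect a given
fold change at a given CV — is answered analytically for a two-sample
t test under two noise models:

* ``lognormal`` (default): a raw-scale CV maps to a log-scale SD
  σ = sqrt(ln(1 + cv²)); the test is the equal-variance t test on log
  values, so power follows a noncentral t with df = 2n−2 and
  noncentrality ln(fold)/(σ·sqrt(2/n)).  Ratios are analyzed in log
  space throughout the toolkit, which is why this is the default.
* ``additive_cv``: group SDs are cv·mean on the raw scale (means 1 and
  fold), with Welch–Satterthwaite degrees of freedom.

Inverse planning (minimum detectable fold, maximum tolerable CV) is by
bisection on the analytic power function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CVRecord",
    "PowerSpec",
    "cv_per_feature",
    "cv_rank_scale",
    "power_two_sample_t",
    "min_detectable_fold",
    "max_cv_for_power",
    "monte_carlo_power",
]


@dataclass(frozen=True)
class CVRecord:
    feature_id: str
    mean: float
    sd: float
    cv: float          # percent
    rank_100: float = float("nan")


@dataclass(frozen=True)
class PowerSpec:
    n_per_group: int = 6
    cv: float = 35.0          # percent
    fold: float = 2.0         # ratio >= 1
    alpha: float = 0.10       # two-sided
    noise_model: str = "lognormal"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1 (use the reciprocal)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.noise_model not in ("lognormal", "additive_cv"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def cv_per_feature(feature_id: str, values) -> CVRecord:
    """CV (%) = 100·sample SD / mean over >= 2 measurements."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 measurements")
    m = x.mean()
    if m <= 0:
        raise ValueError("mean must be positive for a CV")
    sd = x.std(ddof=1)
    return CVRecord(feature_id=feature_id, mean=float(m), sd=float(sd),
                    cv=float(100.0 * sd / m))


def cv_rank_scale(records) -> list[CVRecord]:
    """Attach rank_100 = 100·rank/count (ties share the mean rank)."""
    records = list(records)
    if not records:
        raise ValueError("need at least one CV")
    cvs = pd.Series([r.cv for r in records])
    ranks = cvs.rank(method="average")
    scale = 100.0 / len(records)
    return [replace(r, rank_100=float(rk * scale)) for r, rk in zip(records, ranks)]


def cv_p90(records) -> float:
    """The CV at rank 90 on the 100-based scale (90th percentile CV)."""
    cvs = np.array([r.cv for r in records], dtype=float)
    return float(np.percentile(cvs, 90))


# ---------------------------------------------------------------------------
# Analytic power
# ---------------------------------------------------------------------------

def _lognormal_sigma(cv_pct: float) -> float:
    return float(np.sqrt(np.log1p((cv_pct / 100.0) ** 2)))


def power_two_sample_t(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t test under the spec's model."""
    n = spec.n_per_group
    if spec.noise_model == "lognormal":
        sigma = _lognormal_sigma(spec.cv)
        if sigma == 0.0:
            return 1.0 if spec.fold > 1.0 else spec.alpha
        ncp = np.log(spec.fold) / (sigma * np.sqrt(2.0 / n))
        df = 2 * n - 2
    else:  # additive_cv: group SDs cv*mean_g, Welch-Satterthwaite df
        cv = spec.cv / 100.0
        if cv == 0.0:
            return 1.0 if spec.fold > 1.0 else spec.alpha
        v1 = (cv * 1.0) ** 2
        v2 = (cv * spec.fold) ** 2
        se = np.sqrt((v1 + v2) / n)
        ncp = (spec.fold - 1.0) / se
        df = (v1 / n + v2 / n) ** 2 / (
            (v1 / n) ** 2 / (n - 1) + (v2 / n) ** 2 / (n - 1)
        )
    if ncp > 50.0:  # noncentral t underflows; rejection is certain
        return 1.0
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(
        1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def min_detectable_fold(n: int, cv: float, alpha: float = 0.10,
                        target_power: float = 0.90,
                        noise_model: str = "lognormal",
                        rel_tol: float = 1e-4) -> float:
    """Smallest fold with power >= target_power, by bisection."""
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    base = PowerSpec(n_per_group=n, cv=cv, fold=1.0, alpha=alpha,
                     noise_model=noise_model)

    def pw(fold: float) -> float:
        return power_two_sample_t(replace(base, fold=fold))

    lo, hi = 1.0, 2.0
    while pw(hi) < target_power:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no attainable fold found")
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if pw(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def max_cv_for_power(n: int, fold: float, alpha: float = 0.10,
                     target_power: float = 0.90,
                     noise_model: str = "lognormal",
                     rel_tol: float = 1e-4) -> float:
    """Largest CV (%) with power >= target_power, by bisection."""
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    base = PowerSpec(n_per_group=n, cv=1.0, fold=fold, alpha=alpha,
                     noise_model=noise_model)

    def pw(cv: float) -> float:
        return power_two_sample_t(replace(base, cv=cv))

    lo, hi = 1e-6, 10.0
    while pw(hi) >= target_power:
        lo, hi = hi, hi * 2.0
        if hi > 1e6:
            raise RuntimeError("power never drops below target")
    # pw(lo) >= target > pw(hi)
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if pw(mid) >= target_power:
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# Monte-Carlo cross-check
# ---------------------------------------------------------------------------

def monte_carlo_power(spec: PowerSpec, n_draws: int = 100_000, seed: int = 0) -> float:
    """Simulated rejection rate of the two-sided t test; independent
    check of the analytic power."""
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    if spec.noise_model == "lognormal":
        sigma = _lognormal_sigma(spec.cv)
        x1 = rng.normal(0.0, sigma, size=(n_draws, n))
        x2 = rng.normal(np.log(spec.fold), sigma, size=(n_draws, n))
        df = 2 * n - 2
        sp = np.sqrt((x1.var(axis=1, ddof=1) + x2.var(axis=1, ddof=1)) / 2.0)
        t = (x2.mean(axis=1) - x1.mean(axis=1)) / (sp * np.sqrt(2.0 / n))
        tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(np.mean(np.abs(t) > tcrit))
    cv = spec.cv / 100.0
    x1 = rng.normal(1.0, cv * 1.0, size=(n_draws, n))
    x2 = rng.normal(spec.fold, cv * spec.fold, size=(n_draws, n))
    v1 = x1.var(axis=1, ddof=1) / n
    v2 = x2.var(axis=1, ddof=1) / n
    t = (x2.mean(axis=1) - x1.mean(axis=1)) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n - 1) + v2**2 / (n - 1))
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(np.mean(np.abs(t) > tcrit))
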