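"""Reference-range estimation from aggregated study data.

Two estimators are provided, matching how normative CMR compendia report
"normal values":

* a **single-study** range, mean ± 2·SD, for parameters where only one
  eligible cohort exists;
* a **pooled** range combining several studies' (n, mean, SD) triples with
  a DerSimonian–Laird random-effects model and estimating the 2.5th/97.5th
  population quantiles of the combined healthy population as
  ``mu_hat ± z · sqrt(sigma2_within + tau2)``.

The pooled interval targets the spread of *individuals*, not the standard
error of the pooled mean: the between-study variance ``tau2`` is added to
the pooled within-study variance so that the range covers the central 95%
of a subject population whose study means themselves vary.

Printed limits are rounded half-away-from-zero to the measurement
precision of the parameter (``RoundingSpec``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PooledEstimate", "RoundingSpec", "mean_sd_range", "pool_random_effects",
    "frequentist_reference_range", "round_limits", "round_half_away",
]


@dataclass(frozen=True)
class RoundingSpec:
    """Rounding of reference limits to printed precision.

    decimals
        Number of decimal places the parameter is reported with
        (0 for volumes in mL, 1 for ratios, ...).
    mode
        Only ``half_away_from_zero`` is supported: 22.5 -> 23, -22.5 -> -23,
        22.2 -> 22. This matches the printed limits of the packaged tables
        (e.g. 27.4 - 2*2.6 = 22.2 printed as 22).
    """

    decimals: int = 0
    mode: str = "half_away_from_zero"

    def __post_init__(self) -> None:
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")
        if self.mode != "half_away_from_zero":
            raise ValueError(f"unsupported rounding mode: {self.mode!r}")


@dataclass(frozen=True)
class PooledEstimate:
    """Random-effects pooled summary of k studies reporting (n, mean, SD).

    Attributes
    ----------
    mu_hat
        Inverse-variance weighted pooled mean (random-effects weights).
    se_mu
        Standard error of ``mu_hat``.
    tau2
        Between-study variance of the true study means
        (DerSimonian–Laird moment estimator, truncated at zero).
    sigma2_within
        Pooled within-study variance, Σ(nᵢ−1)·sdᵢ² / Σ(nᵢ−1).
    k, n_total
        Number of studies and total number of subjects.
    """

    mu_hat: float
    se_mu: float
    tau2: float
    sigma2_within: float
    k: int
    n_total: int

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma2_within < 0:
            raise ValueError("variances must be non-negative")
        if self.k < 1 or self.n_total < self.k:
            raise ValueError("need k >= 1 studies and n_total >= k")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def mean_sd_range(mean: float, sd: float, k_sd: float = 2.0,
                  rounding: RoundingSpec | None = None):
    """Single-study reference range: mean ± k_sd·SD, rounded.

    Returns a :class:`cmrnorms.registry.ReferenceRange` with method tag
    ``single_study_mean_2sd``.
    """
    from cmrnorms.registry import ReferenceRange  # cycle-free at call time

    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    rounding = rounding or RoundingSpec()
    rng = ReferenceRange(lower=mean - k_sd * sd, upper=mean + k_sd * sd,
                         mean=mean, sd=sd, n_total=0,
                         method="single_study_mean_2sd",
                         precision=rounding.decimals)
    return round_limits(rng, rounding)


def pool_random_effects(studies: Sequence) -> PooledEstimate:
    """DerSimonian–Laird random-effects pooling of study-level aggregates.

    Each study contributes its sample mean with within-study variance of the
    mean sdᵢ²/nᵢ.  The between-study variance τ² is the DL moment estimator

        τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)),   wᵢ = nᵢ/sdᵢ²

    and the pooled mean uses random-effects weights wᵢ* = 1/(sdᵢ²/nᵢ + τ²).

    Parameters
    ----------
    studies
        Sequence of :class:`cmrnorms.registry.StudySummary` (or any objects
        with ``n``, ``mean``, ``sd`` and ``parameter_id`` attributes); all
        must share the same ``parameter_id`` and have n ≥ 2.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("cannot pool an empty list of studies")
    pids = {getattr(s, "parameter_id", None) for s in studies}
    if len(pids) > 1:
        raise ValueError(f"cannot pool mixed parameters: {sorted(map(str, pids))}")
    for s in studies:
        if s.n < 2:
            raise ValueError(
                f"study {getattr(s, 'study_id', '?')} has n={s.n} < 2; "
                "the variance of its mean is undefined")

    n = np.array([s.n for s in studies], dtype=float)
    y = np.array([s.mean for s in studies], dtype=float)
    sd = np.array([s.sd for s in studies], dtype=float)

    k = len(studies)
    vi = sd ** 2 / n                      # variance of each study mean
    sigma2_within = float(np.sum((n - 1) * sd ** 2) / np.sum(n - 1))

    if k == 1:
        tau2 = 0.0
        w_star = 1.0 / vi if vi[0] > 0 else np.array([1.0])
    else:
        if np.any(vi <= 0):
            # Degenerate zero-variance studies: fall back to equal weights
            # for Q; tau2 from spread of means.
            vi = np.where(vi <= 0, np.finfo(float).tiny, vi)
        w = 1.0 / vi
        mu_fixed = float(np.sum(w * y) / np.sum(w))
        q = float(np.sum(w * (y - mu_fixed) ** 2))
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (vi + tau2)

    mu_hat = float(np.sum(w_star * y) / np.sum(w_star))
    se_mu = float(np.sum(w_star) ** -0.5)
    return PooledEstimate(mu_hat=mu_hat, se_mu=se_mu, tau2=tau2,
                          sigma2_within=sigma2_within, k=k,
                          n_total=int(np.sum(n)))


def frequentist_reference_range(est: PooledEstimate, level: float = 0.95,
                                rounding: RoundingSpec | None = None,
                                variant: str = "normal"):
    """Population reference range from a pooled estimate.

    The default ``normal`` variant estimates the (1±level)/2 population
    quantiles as

        mu_hat ± z_{(1+level)/2} · sqrt(sigma2_within + tau2)

    i.e. a normal population whose total individual-level variance is the
    pooled within-study variance plus the between-study variance.  The
    ``t`` variant additionally propagates the uncertainty of the pooled
    mean (adds ``se_mu²`` under the root) and uses a t quantile with k−1
    degrees of freedom — wider, and closer to a prediction-style interval
    for a new individual from a new study.
    """
    from cmrnorms.registry import ReferenceRange

    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    rounding = rounding or RoundingSpec()
    pop_sd = math.sqrt(est.sigma2_within + est.tau2)
    if variant == "normal":
        q = stats.norm.ppf((1.0 + level) / 2.0)
        half = q * pop_sd
    elif variant == "t":
        df = max(est.k - 1, 1)
        q = stats.t.ppf((1.0 + level) / 2.0, df)
        half = q * math.sqrt(est.sigma2_within + est.tau2 + est.se_mu ** 2)
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    rng = ReferenceRange(lower=est.mu_hat - half, upper=est.mu_hat + half,
                         mean=est.mu_hat, sd=pop_sd, n_total=est.n_total,
                         method="pooled_frequentist",
                         precision=rounding.decimals)
    return round_limits(rng, rounding)


def round_limits(rng, rounding: RoundingSpec):
    """Round both limits of a range half-away-from-zero; idempotent."""
    return replace(rng,
                   lower=round_half_away(rng.lower, rounding.decimals),
                   upper=round_half_away(rng.upper, rounding.decimals),
                   precision=rounding.decimals)
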