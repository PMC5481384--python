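"""Model-data agreement checks and the trial-order randomness check.

Two descriptive diagnostics assess whether the fitted mixture is a
plausible account of an infant's scores: the maximum discrepancy between
the empirical distribution function and the fitted CDF (a KS-type
statistic, reported without a p-value because the parameters were
estimated from the same data), and the ratio of model-implied to sample
variance, aggregated per assessment occasion across a cohort.

The i.i.d. assumption within an infant-occasion — trial order carries no
information — is checked by the correlation of the pairs ``(d_t, t)``
with a permutation (or bootstrap) null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import LookingMixture, TrialSeries, mixture_cdf, mixture_moments

__all__ = [
    "FitDiagnostics",
    "SerialCorrelationResult",
    "ecdf_vs_model",
    "cohort_variance_ratio",
    "serial_correlation_check",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitDiagnostics:
    ks_discrepancy: float
    model_variance: float
    sample_variance: float
    variance_ratio: float


@dataclass(frozen=True)
class SerialCorrelationResult:
    r: float
    p: float
    defined: bool
    B: int


def ecdf_vs_model(series: TrialSeries, model: LookingMixture) -> FitDiagnostics:
    """KS-type discrepancy between the ECDF and the fitted CDF, plus variances.

    The ECDF is right-continuous, ``F_n(x) = #{d <= x}/T``; the discrepancy
    is evaluated at the observed points and their left limits (the standard
    two-sided KS evaluation).  Sample variance uses denominator ``T - 1``.
    No p-value is attached: with estimated parameters the statistic is
    descriptive only.
    """
    if series.T < 2 or (series.d.min() == series.d.max() and model.a == model.f):
        raise ValueError("degenerate series/model: discrepancy undefined")
    xs = np.sort(series.d)
    T = series.T
    F = np.asarray(mixture_cdf(model, xs))
    upper = np.arange(1, T + 1) / T
    lower = np.arange(0, T) / T
    ks = float(max(np.max(np.abs(upper - F)), np.max(np.abs(F - lower))))
    _, mvar = mixture_moments(model)
    svar = series.sample_variance()
    return FitDiagnostics(
        ks_discrepancy=ks,
        model_variance=float(mvar),
        sample_variance=float(svar),
        variance_ratio=float(mvar / svar) if svar > 0 else np.inf,
    )


def cohort_variance_ratio(fits) -> dict[float, float]:
    """Per-occasion ratio of average model variance to average sample variance.

    ``fits`` is an iterable of ``(series, model)`` pairs; pairs are grouped
    by ``series.occasion``.  Ratios near one indicate the fitted mixtures
    collectively account for the spread of the data; below one,
    under-fitting; above, over-fitting.
    """
    groups: dict[float, list[tuple[float, float]]] = {}
    for series, model in fits:
        _, mvar = mixture_moments(model)
        groups.setdefault(float(series.occasion), []).append(
            (mvar, series.sample_variance())
        )
    out = {}
    for occ, vals in sorted(groups.items()):
        mvars, svars = zip(*vals)
        mean_s = float(np.mean(svars))
        if mean_s <= 0:
            log.warning("occasion %s skipped: zero average sample variance", occ)
            continue
        out[occ] = float(np.mean(mvars)) / mean_s
    return out


def serial_correlation_check(
    series: TrialSeries, B: int = 2000, seed=None, null: str = "permutation"
) -> SerialCorrelationResult:
    """Correlation of scores with trial number, with a resampling null.

    Under within-infant random sampling the trial order is irrelevant and
    the correlation of ``(d_t, t)`` is zero.  The two-sided p-value comes
    from ``B`` random permutations of the trial order (default) or, with
    ``null="bootstrap"``, from resampling the scores with replacement
    against the fixed trial index.  P-values use the add-one convention
    ``(k + 1)/(B + 1)``.
    """
    if series.T < 4:
        raise ValueError("need at least 4 trials")
    if null not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown null {null!r}")
    d = series.d
    t = np.arange(1, series.T + 1, dtype=float)
    if np.ptp(d) == 0:
        return SerialCorrelationResult(r=0.0, p=1.0, defined=False, B=B)
    dc = d - d.mean()
    tc = t - t.mean()
    denom = np.sqrt((dc @ dc) * (tc @ tc))
    r_obs = float(dc @ tc / denom)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if null == "permutation":
        perms = rng.permuted(np.broadcast_to(d, (B, series.T)).copy(), axis=1)
    else:
        perms = d[rng.integers(0, series.T, size=(B, series.T))]
    pc = perms - perms.mean(axis=1, keepdims=True)
    norms = np.sqrt((pc * pc).sum(axis=1) * (tc @ tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_null = np.where(norms > 0, pc @ tc / np.where(norms > 0, norms, 1.0), 0.0)
    k = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))
    p = (k + 1) / (B + 1)
    return SerialCorrelationResult(r=r_obs, p=float(min(p, 1.0)), defined=True, B=B)
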