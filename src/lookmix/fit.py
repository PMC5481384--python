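"""Per-infant estimation of the looking-style mixture.

Estimation strategy
-------------------
Difference scores are integer video-frame counts, so every uniform
component contributes a discrete mass of ``1/(width + 1)`` per integer
point (see :func:`lookmix.model.component_mass`); this bounds the
likelihood, which for continuous uniform mixtures is otherwise unbounded
in the band endpoints.

Maximum-likelihood endpoints of uniform components are order statistics,
so the outer endpoints are fixed at the observed extremes ``a = min(d)``,
``f = max(d)``.  The inner band endpoints ``(b, e)`` only matter through
which observations they cover, so the distinct negative observed values
(for ``b``) and positive observed values (for ``e``) form an exhaustive
candidate grid.  Two estimation layers run over this grid:

1. *Likelihood layer* — for each candidate pair an EM algorithm maximises
   the likelihood over the weights ``(pi, lam)``:

   * E-step: responsibility of the short component for trial ``t``,
     ``r_t = pi*u_s(d_t) / [pi*u_s(d_t) + (1-pi)*u_long(d_t)]``;
   * M-step: ``pi <- mean(r_t)``; ``lam`` <- long-responsibility mass on
     the negative side over total long mass (zero scores carry no long
     information and are ignored in the ``lam`` step).

   Because the components are uniform, all trials in the same region
   (negative band / gap / positive band) share one responsibility, so each
   iteration works on three region counts.  The best candidate's
   log-likelihood is reported as ``FitResult.loglik``.

2. *Posterior layer* — at 24 trials the likelihood surface over ``(b, e)``
   is typically a plateau: several band choices fit almost equally well but
   imply rather different ``pi``.  Rather than trusting the argmax, the fit
   weights every candidate by its marginal likelihood under flat priors
   (``(b, e)`` uniform over the continuous admissible rectangle, integrated
   in closed form over each candidate's equivalence cell; ``(pi, lam)``
   uniform on the unit square, integrated on a grid).  The reported
   ``pi_hat`` is the average over trials of the per-trial posterior
   short-look probabilities, themselves posterior-averaged over ``(pi,
   lam)`` and over candidates.  Narrow "spike" bands that graze a couple of
   boundary points carry almost no prior mass and are suppressed
   automatically.

The same marginal-likelihood machinery selects among three model
structures — short-only (one uniform, the degenerate ``pi = 1`` fit),
long-only (bands only, ``pi = 0``) and the full mixture — with Jeffreys
simplicity-postulate prior odds ``P(M) proportional to 2**(-k)`` for a
structure with ``k`` free parameters.  Purely uniform-looking data hence
collapse to ``pi_hat = 1`` exactly, and data clustered entirely at the
range boundaries to ``pi_hat = 0``, mirroring the vanishing components of
the archetypal short- and long-looking infants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import betaln, logsumexp

from .model import (
    FRAME_MAX,
    LookingMixture,
    ParameterError,
    TrialSeries,
    mixture_density,
)

__all__ = [
    "FitResult",
    "ClassificationRecord",
    "BootstrapResult",
    "fit_mixture",
    "posterior_short",
    "classify",
    "bootstrap_fit",
    "FittingError",
    "STRONG_EPS",
]

log = logging.getLogger(__name__)

#: Tolerance on pi_hat for the strong SL/LL criterion (pi = 1 resp. pi = 0):
#: estimates rarely hit the boundary bit-exactly outside degenerate fits.
STRONG_EPS = 1e-6

_MIN_TRIALS = 4  # 4 endpoint parameters + pi + lam make shorter series vacuous

# quadrature grid (midpoint rule) for integrating over (pi, lam)
_NGRID = 48
_GRID = (np.arange(_NGRID) + 0.5) / _NGRID


class FittingError(ValueError):
    """Raised when a series cannot be fitted (too short, invalid, ...)."""


@dataclass
class FitResult:
    """Fitted mixture, per-trial posteriors and convergence metadata.

    ``pi_hat`` is by construction the arithmetic mean of ``posteriors``.
    ``loglik`` is the profile maximum likelihood over the candidate band
    grid (the EM layer); ``structure`` records which model structure the
    marginal-likelihood comparison selected (``"short"``, ``"long"``,
    ``"mixture"`` or ``"degenerate"`` for constant data).
    """

    model: LookingMixture
    posteriors: np.ndarray = field(repr=False)
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    pi_hat: float = np.nan
    structure: str = "mixture"
    degenerate: bool = False
    bands_identified: bool = True
    loglik_trace: np.ndarray = field(default=None, repr=False)
    n_candidates: int = 0


@dataclass(frozen=True)
class ClassificationRecord:
    """Weak and strong looking-style labels for one infant-occasion.

    Weak: SL iff ``pi_hat > 1/2``, LL iff ``< 1/2``, indeterminate at 1/2.
    Strong: SL iff ``pi_hat >= 1 - eps``, LL iff ``<= eps``, else neither.
    """

    infant_id: str
    occasion: float
    pi_hat: float
    weak_label: str
    strong_label: str


@dataclass(frozen=True)
class BootstrapResult:
    """Resampled-trials uncertainty for pi_hat and the mean difference."""

    pi_se: float
    pi_ci: tuple[float, float]
    d_bar_se: float
    d_bar_ci: tuple[float, float]
    B: int
    pi_samples: np.ndarray = field(repr=False)
    d_bar_samples: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# likelihood layer: region counts and EM over (pi, lam)
# ---------------------------------------------------------------------------


def _region_loglik(n1, n2, g, hs, hn, hp, pi, lam) -> float:
    ll = 0.0
    for n, dens in (
        (n1, pi * hs + (1 - pi) * lam * hn),
        (n2, pi * hs + (1 - pi) * (1 - lam) * hp),
        (g, pi * hs),
    ):
        if n:
            if dens <= 0:
                return -np.inf
            ll += n * np.log(dens)
    return ll


def _run_em(n1, n2, g, hs, hn, hp, pi0, lam0, lam_free,
            tol=1e-8, max_iter=500):
    """EM on (pi, lam) for fixed bands.

    Returns ``(pi, lam, loglik, trace, n_iter, converged)``.  The trace is
    the log-likelihood after each iteration; EM guarantees it never
    decreases.
    """
    T = n1 + n2 + g
    pi, lam = pi0, lam0
    trace = [_region_loglik(n1, n2, g, hs, hn, hp, pi, lam)]
    converged = False
    for _ in range(max_iter):
        d_nb = pi * hs + (1 - pi) * lam * hn
        d_pb = pi * hs + (1 - pi) * (1 - lam) * hp
        r_nb = pi * hs / d_nb if d_nb > 0 else 0.0
        r_pb = pi * hs / d_pb if d_pb > 0 else 0.0
        r_gap = 1.0 if pi > 0 else 0.0
        pi = (n1 * r_nb + n2 * r_pb + g * r_gap) / T
        if lam_free:
            num = n1 * (1 - r_nb)
            den = num + n2 * (1 - r_pb)
            if den > 0:
                lam = num / den
        ll = _region_loglik(n1, n2, g, hs, hn, hp, pi, lam)
        trace.append(ll)
        prev = trace[-2]
        if np.isfinite(ll) and abs(ll - prev) <= tol * max(abs(prev), 1.0):
            converged = True
            break
    return pi, lam, trace[-1], np.asarray(trace), len(trace) - 1, converged


# ---------------------------------------------------------------------------
# posterior layer: closed-form cell integrals and grid posteriors
# ---------------------------------------------------------------------------


def _log_cell_length(lo: float, hi: float, origin: float, n: int) -> float:
    """log of ``integral_lo^hi ((lo - origin + 1)/(x - origin + 1))^n dx``.

    The effective length of a band-endpoint equivalence cell ``[lo, hi)``:
    within the cell the covered observations are fixed but the band width
    grows, so the n-th power of the relative component mass decays; the
    integral is the cell's contribution to a flat prior on the endpoint.
    """
    u0, u1 = lo - origin + 1.0, hi - origin + 1.0
    if u1 <= u0:
        return -np.inf
    if n == 0:
        return float(np.log(u1 - u0))
    if n == 1:
        return float(np.log(u0 * np.log(u1 / u0)))
    return float(n * np.log(u0) + np.log((u0 ** (1.0 - n) - u1 ** (1.0 - n)) / (n - 1.0)))


def _grid_posterior(n1, n2, g, hs, hn, hp, lam_fixed=None):
    """Flat-prior posterior over (pi, lam) on the quadrature grid.

    Returns ``(log_evidence, mean_r_nb, mean_r_pb, mean_lam)`` where the
    means are posterior expectations of the region-wise short-look
    responsibilities and of ``lam``.  ``log_evidence`` is the log of the
    likelihood integrated over the grid (midpoint rule, flat prior).
    """
    if lam_fixed is None:
        pi_g = _GRID[:, None]
        lam_g = _GRID[None, :]
        log_dv = -2.0 * np.log(_NGRID)
    else:
        pi_g = _GRID
        lam_g = lam_fixed
        log_dv = -np.log(_NGRID)
    d_nb = pi_g * hs + (1 - pi_g) * lam_g * hn
    d_pb = pi_g * hs + (1 - pi_g) * (1 - lam_g) * hp
    ll = g * np.log(pi_g * hs)
    if n1:
        ll = ll + n1 * np.log(d_nb)
    if n2:
        ll = ll + n2 * np.log(d_pb)
    ll = np.broadcast_to(ll, np.broadcast_shapes(np.shape(d_nb), np.shape(ll)))
    m = ll.max()
    w = np.exp(ll - m)
    z = w.sum()
    r_nb = np.where(d_nb > 0, pi_g * hs / np.where(d_nb > 0, d_nb, 1.0), 0.0)
    r_pb = np.where(d_pb > 0, pi_g * hs / np.where(d_pb > 0, d_pb, 1.0), 0.0)
    mean_r_nb = float((np.broadcast_to(r_nb, ll.shape) * w).sum() / z)
    mean_r_pb = float((np.broadcast_to(r_pb, ll.shape) * w).sum() / z)
    mean_lam = float((np.broadcast_to(lam_g, ll.shape) * w).sum() / z)
    return float(m + np.log(z) + log_dv), mean_r_nb, mean_r_pb, mean_lam


_LOG2 = float(np.log(2.0))


def fit_mixture(
    series: TrialSeries,
    lam_rule: str = "long",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Fit the looking-style mixture to one infant-occasion's scores.

    Parameters
    ----------
    series
        The trial series; at least 4 trials are required.
    lam_rule
        ``"long"`` (default): ``lam`` is the share of *long-look* mass on
        the negative side, estimated jointly with ``pi``.  ``"all"``:
        ``lam`` is fixed at the fraction of negative among nonzero scores
        (the coarser reading of the band-weight parameter).
    tol, max_iter
        EM convergence controls (relative log-likelihood change).

    Returns
    -------
    FitResult
        ``pi_hat`` is the mean per-trial posterior short-look probability;
        the degenerate values 0 and 1 are genuine outcomes (the
        corresponding components vanish).
    """
    if lam_rule not in ("long", "all"):
        raise ParameterError(f"unknown lam_rule {lam_rule!r}")
    if series.T < _MIN_TRIALS:
        raise FittingError(
            f"series has T={series.T} < {_MIN_TRIALS} trials; refusing to fit"
        )
    d = series.d
    T = series.T
    a = float(np.clip(d.min(), -FRAME_MAX, FRAME_MAX))
    f = float(np.clip(d.max(), -FRAME_MAX, FRAME_MAX))

    if a == f:  # constant series: pure short point mass
        model = LookingMixture(a=a, f=f, b=None, e=None, lam=0.5, pi=1.0)
        return FitResult(
            model=model,
            posteriors=np.ones(T),
            loglik=0.0,  # unit point mass on every trial
            n_iter=0,
            converged=True,
            pi_hat=1.0,
            structure="degenerate",
            degenerate=True,
            bands_identified=False,
            loglik_trace=np.array([]),
            n_candidates=0,
        )

    hs = 1.0 / (f - a + 1.0)
    neg = np.unique(d[d < 0])
    pos = np.unique(d[d > 0])
    n_neg = int((d < 0).sum())
    n_pos = int((d > 0).sum())
    n_zero = T - n_neg - n_pos
    two_sided = bool(neg.size and pos.size)

    # ---- structure: short-only (single uniform over [a, f]) --------------
    ll_short = T * np.log(hs)
    log_marg = {"short": ll_short - 2 * _LOG2}

    # ---- structure: long-only (two bands, no short component) ------------
    # Feasible only when both sides are occupied and no score is zero
    # (zeros sit in the open gap, which has no long mass).
    ml_long = None
    if two_sided and n_zero == 0:
        b0, e0 = float(neg.max()), float(pos.min())
        lam_mle = n_neg / T
        h_n0 = 1.0 / (b0 - a + 1.0)
        h_p0 = 1.0 / (f - e0 + 1.0)
        ll_long = n_neg * np.log(lam_mle * h_n0) + n_pos * np.log((1 - lam_mle) * h_p0)
        lam_int = betaln(n_neg + 1, n_pos + 1) - (
            n_neg * np.log(lam_mle) + n_pos * np.log(1 - lam_mle)
        )
        cell_b = _log_cell_length(b0, 0.0, a, n_neg)
        cell_e = _log_cell_length(-e0, 0.0, -f, n_pos)
        log_prior_be = -np.log(-a) - np.log(f)
        log_marg["long"] = ll_long + lam_int + cell_b + cell_e + log_prior_be - 5 * _LOG2
        ml_long = (b0, e0, lam_mle, ll_long)

    # ---- structure: mixture over the candidate band grid -----------------
    lam_all = n_neg / (n_neg + n_pos) if (n_neg + n_pos) else 0.5
    if two_sided:
        b_cands = [float(v) for v in neg]
        e_cands = [float(v) for v in pos]
        k_mix = 6
        log_prior_be = -np.log(-a) - np.log(f)
    elif pos.size:  # no negative scores: single positive band
        b_cands = [None]
        e_cands = [float(v) for v in pos if v > a]
        k_mix = 4
        log_prior_be = -np.log(f - max(0.0, a)) if f > max(0.0, a) else 0.0
    else:  # no positive scores: single negative band
        b_cands = [float(v) for v in neg if v < f]
        e_cands = [None]
        k_mix = 4
        log_prior_be = -np.log(min(0.0, f) - a) if min(0.0, f) > a else 0.0

    best_ml = None   # (ll, pi, lam, b, e, trace, n_iter, converged)
    cand_rows = []   # (logw, b, e, in_nb mask, in_pb mask, r_nb, r_pb, lam_mean)
    for i, b in enumerate(b_cands):
        if b is not None:
            b_hi = b_cands[i + 1] if i + 1 < len(b_cands) else min(0.0, f)
            in_nb = d <= b
            hn = 1.0 / (b - a + 1.0)
            cell_b = _log_cell_length(b, b_hi, a, int(in_nb.sum()))
        else:
            in_nb = np.zeros(T, dtype=bool)
            hn, cell_b = 0.0, 0.0
        for j, e in enumerate(e_cands):
            if e is not None:
                e_lo = e_cands[j - 1] if j > 0 else max(0.0, a)
                in_pb = d >= e
                hp = 1.0 / (f - e + 1.0)
                cell_e = _log_cell_length(-e, -e_lo, -f, int(in_pb.sum()))
            else:
                in_pb = np.zeros(T, dtype=bool)
                hp, cell_e = 0.0, 0.0
            n1, n2 = int(in_nb.sum()), int(in_pb.sum())
            g = T - n1 - n2

            if b is None:
                lam0, lam_free, lam_fixed = 0.0, False, 0.0
            elif e is None:
                lam0, lam_free, lam_fixed = 1.0, False, 1.0
            elif lam_rule == "all":
                lam0, lam_free, lam_fixed = lam_all, False, lam_all
            else:
                lam0 = min(max(lam_all, 0.05), 0.95)
                lam_free, lam_fixed = True, None
            pi0 = max(0.5, g / T) if g else 0.5

            pi, lam, ll, trace, n_it, conv = _run_em(
                n1, n2, g, hs, hn, hp, pi0, lam0, lam_free,
                tol=tol, max_iter=max_iter,
            )
            if best_ml is None or ll > best_ml[0]:
                best_ml = (ll, pi, lam, b, e, trace, n_it, conv)

            log_ev, r_nb, r_pb, lam_mean = _grid_posterior(
                n1, n2, g, hs, hn, hp, lam_fixed=lam_fixed
            )
            logw = log_ev + cell_b + cell_e + log_prior_be
            cand_rows.append((logw, b, e, in_nb, in_pb, r_nb, r_pb, lam_mean))

    logws = np.array([c[0] for c in cand_rows])
    log_marg["mixture"] = logsumexp(logws) - k_mix * _LOG2

    # ---- select structure and assemble the result -------------------------
    structure = max(("short", "long", "mixture"),
                    key=lambda s: log_marg.get(s, -np.inf))
    ll_ml, pi_ml, lam_ml, b_ml, e_ml, trace, n_it, conv = best_ml

    if structure == "short":
        posteriors = np.ones(T)
        pi_hat = 1.0
        # bands are non-identified; report the profile-ML values anyway
        model = LookingMixture(a=a, f=f, b=b_ml, e=e_ml, lam=lam_ml, pi=1.0)
        bands_identified = False
    elif structure == "long":
        b0, e0, lam_mle, _ = ml_long
        posteriors = np.zeros(T)
        pi_hat = 0.0
        model = LookingMixture(a=a, f=f, b=b0, e=e0, lam=lam_mle, pi=0.0)
        bands_identified = True
    else:
        w = np.exp(logws - logws.max())
        w /= w.sum()
        posteriors = np.zeros(T)
        lam_bar = 0.0
        for wk, (_, b, e, in_nb, in_pb, r_nb, r_pb, lam_mean) in zip(w, cand_rows):
            p_cand = np.where(in_nb, r_nb, np.where(in_pb, r_pb, 1.0))
            posteriors += wk * p_cand
            lam_bar += wk * lam_mean
        pi_hat = float(posteriors.mean())
        k_map = int(np.argmax(logws))
        b_map, e_map = cand_rows[k_map][1], cand_rows[k_map][2]
        model = LookingMixture(
            a=a, f=f, b=b_map, e=e_map,
            lam=0.0 if b_map is None else (1.0 if e_map is None else float(lam_bar)),
            pi=pi_hat,
        )
        bands_identified = pi_hat < 1.0 - STRONG_EPS

    return FitResult(
        model=model,
        posteriors=posteriors,
        loglik=float(ll_ml),
        n_iter=n_it,
        converged=conv,
        pi_hat=float(pi_hat),
        structure=structure,
        degenerate=False,
        bands_identified=bands_identified,
        loglik_trace=trace,
        n_candidates=len(cand_rows),
    )


def posterior_short(model: LookingMixture, x):
    """Posterior probability that a score arose from the short component.

    ``P(short | x) = pi * u_short(x) / u_mix(x)`` for the continuous
    mixture.  Scores in the open gap between the bands have zero long
    density, hence posterior 1 whenever ``pi > 0``; with ``pi = 0`` the
    posterior is 0 everywhere.  ``x`` must lie within ``[a, f]``.
    """
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xs < model.a) or np.any(xs > model.f):
        raise ParameterError(f"x outside the model support [{model.a}, {model.f}]")
    if model.pi == 0:
        out = np.zeros_like(xs)
        return out if np.ndim(x) else float(out[0])
    if model.f > model.a:
        # same arithmetic as mixture_density so the gap ratio is exactly 1
        num = model.pi * (1.0 / (model.f - model.a)) * np.ones_like(xs)
    else:
        num = np.full_like(xs, np.inf)
    den = mixture_density(model, xs)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(den) & np.isinf(num), 1.0,
                       np.where(np.isinf(den), 0.0,
                                np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)))
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(x) else float(out[0])


def classify(
    pi_hat: float,
    infant_id: str = "",
    occasion: float = 0.0,
    eps: float = STRONG_EPS,
) -> ClassificationRecord:
    """Weak (pi > 1/2) and strong (pi = 1, within eps) SL/LL labels."""
    if not (0.0 <= pi_hat <= 1.0):
        raise ParameterError(f"pi_hat must lie in [0, 1], got {pi_hat}")
    if pi_hat > 0.5:
        weak = "SL"
    elif pi_hat < 0.5:
        weak = "LL"
    else:
        weak = "indeterminate"
    if pi_hat >= 1.0 - eps:
        strong = "SL"
    elif pi_hat <= eps:
        strong = "LL"
    else:
        strong = "neither"
    return ClassificationRecord(
        infant_id=infant_id,
        occasion=occasion,
        pi_hat=float(pi_hat),
        weak_label=weak,
        strong_label=strong,
    )


def bootstrap_fit(
    series: TrialSeries, B: int = 1000, seed=None, **fit_kwargs
) -> BootstrapResult:
    """Nonparametric bootstrap over trials for pi_hat and the mean score.

    Resamples the ``T`` trials with replacement ``B`` times, refits the
    mixture on each resample, and returns standard errors and 2.5/97.5
    percentile intervals for ``pi_hat`` and ``d_bar``.
    """
    if B < 100:
        raise FittingError("B < 100 gives meaningless intervals; refusing")
    if series.T < _MIN_TRIALS:
        raise FittingError("series too short to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, series.T, size=(B, series.T))
    pis = np.empty(B)
    dbars = np.empty(B)
    for k in range(B):
        resampled = TrialSeries(
            infant_id=series.infant_id, occasion=series.occasion, d=series.d[idx[k]]
        )
        pis[k] = fit_mixture(resampled, **fit_kwargs).pi_hat
        dbars[k] = resampled.d_bar
    return BootstrapResult(
        pi_se=float(pis.std(ddof=1)),
        pi_ci=(float(np.percentile(pis, 2.5)), float(np.percentile(pis, 97.5))),
        d_bar_se=float(dbars.std(ddof=1)),
        d_bar_ci=(float(np.percentile(dbars, 2.5)), float(np.percentile(dbars, 97.5))),
        B=B,
        pi_samples=pis,
        d_bar_samples=dbars,
    )
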