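"""Linking looking style to stimulus preference across occasions.

All analyses operate on a *cohort table*: one row per infant-occasion with
the estimated short-look probability ``pi_hat``, the mean difference score
``d_bar`` (negative = preference for the stimulus coded negative, e.g. the
other-race face), the weak SL/LL label and the preference label (ORP for
``d_bar < 0``, SRP for ``d_bar > 0``).

Provided analyses:

* longitudinal SL/LL transition probabilities between occasion pairs;
* occasion means of ``d_bar``, unconditional and conditional on looking
  style, with one-sample t-tests and an SL-vs-LL Welch test;
* delta-curves: means of ``d_bar`` conditioned on ``pi_hat <= delta`` and
  ``>= delta`` over a grid of thresholds;
* a permutation test of independence between looking style and preference
  based on the delta-curve slopes;
* the ORP/SL precedence comparison ``P1 = P(SL | ORP)`` vs
  ``P2 = P(ORP | SL)`` with a bootstrap test (the larger conditional
  identifies the developmentally later event);
* per-infant linear extrapolation of the ``pi_hat`` trajectory to a target
  age (e.g. one week = 0.25 months), predictions clamped to [0, 1];
* a binomial calculator for the probability that sampled cohorts contain
  enough short-looking infants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FitResult, classify
from .model import TrialSeries

__all__ = [
    "cohort_table",
    "validate_cohort",
    "TransitionTable",
    "transition_probabilities",
    "CellStats",
    "OccasionMeans",
    "conditional_means",
    "DeltaCurve",
    "delta_curve",
    "IndependenceResult",
    "independence_test",
    "PrecedenceResult",
    "precedence_test",
    "TrajectorySummary",
    "trajectory_extrapolation",
    "sampling_probability",
]

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["infant_id", "occasion", "pi_hat", "d_bar",
                  "weak_label", "preference_label", "T"]


def _preference_label(d_bar: float) -> str:
    if d_bar < 0:
        return "ORP"
    if d_bar > 0:
        return "SRP"
    return "none"


def cohort_table(items: Iterable[tuple[TrialSeries, FitResult]]) -> pd.DataFrame:
    """Build the cohort table from fitted series.

    One row per infant-occasion: ``infant_id, occasion, pi_hat, d_bar,
    weak_label, preference_label, T``.
    """
    rows = []
    for series, fit in items:
        rec = classify(fit.pi_hat, series.infant_id, series.occasion)
        rows.append({
            "infant_id": str(series.infant_id),
            "occasion": float(series.occasion),
            "pi_hat": float(fit.pi_hat),
            "d_bar": series.d_bar,
            "weak_label": rec.weak_label,
            "preference_label": _preference_label(series.d_bar),
            "T": series.T,
        })
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and normalise) an externally supplied cohort table."""
    missing = [c for c in ("infant_id", "occasion", "pi_hat", "d_bar") if c not in df]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    df = df.copy()
    df["infant_id"] = df["infant_id"].astype(str)
    if ((df["pi_hat"] < 0) | (df["pi_hat"] > 1)).any():
        raise ValueError("pi_hat outside [0, 1]")
    if ((df["d_bar"] < -130) | (df["d_bar"] > 130)).any():
        raise ValueError("d_bar outside [-130, 130]")
    if df.duplicated(["infant_id", "occasion"]).any():
        raise ValueError("duplicate infant-occasion rows")
    if "weak_label" not in df:
        df["weak_label"] = [classify(p).weak_label for p in df["pi_hat"]]
    if "preference_label" not in df:
        df["preference_label"] = df["d_bar"].map(_preference_label)
    if "T" not in df:
        df["T"] = -1
    return df[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionTable:
    """Conditional SL/LL transition probabilities for one occasion pair.

    ``probs[(earlier, later)]`` is ``P(later label | earlier label)``;
    ``counts[(earlier, later)]`` the supporting count and
    ``n_earlier[label]`` the conditioning count.  Probabilities with a zero
    conditioning count are ``nan`` (undefined, not 0).
    """

    pair: tuple[float, float]
    probs: dict
    counts: dict
    n_earlier: dict
    n_infants: int
    n_excluded_indeterminate: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for y in ("SL", "LL"):
            for x in ("SL", "LL"):
                rows.append({
                    "earlier": y, "later": x,
                    "prob": self.probs[(y, x)],
                    "count": self.counts[(y, x)],
                    "n_earlier": self.n_earlier[y],
                })
        return pd.DataFrame(rows)


def transition_probabilities(
    cohort: pd.DataFrame, pair: tuple[float, float]
) -> TransitionTable:
    """Estimate ``P(label at later occasion | label at earlier occasion)``.

    Uses infants observed at both occasions; rows with an indeterminate
    weak label (``pi_hat`` exactly 1/2) are excluded and counted.
    """
    early, late = float(pair[0]), float(pair[1])
    a = cohort[cohort["occasion"] == early].set_index("infant_id")["weak_label"]
    b = cohort[cohort["occasion"] == late].set_index("infant_id")["weak_label"]
    both = a.index.intersection(b.index)
    a, b = a.loc[both], b.loc[both]
    keep = (a != "indeterminate") & (b != "indeterminate")
    n_excl = int((~keep).sum())
    if n_excl:
        log.info("transition %s->%s: %d indeterminate rows excluded",
                 early, late, n_excl)
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError(f"no infants observed at both occasions {pair}")
    probs, counts, n_earlier = {}, {}, {}
    for y in ("SL", "LL"):
        ny = int((a == y).sum())
        n_earlier[y] = ny
        for x in ("SL", "LL"):
            nxy = int(((a == y) & (b == x)).sum())
            counts[(y, x)] = nxy
            probs[(y, x)] = nxy / ny if ny > 0 else np.nan
    return TransitionTable(
        pair=(early, late), probs=probs, counts=counts,
        n_earlier=n_earlier, n_infants=int(len(a)),
        n_excluded_indeterminate=n_excl,
    )


# ---------------------------------------------------------------------------
# conditional means
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellStats:
    """Mean of ``d_bar`` in one cell with a one-sample t-test against 0.

    ``t``/``p`` are ``None`` when the test is suppressed (fewer than two
    rows, or zero variance)."""

    n: int
    mean: Optional[float]
    se: Optional[float]
    t: Optional[float]
    df: Optional[float]
    p: Optional[float]


@dataclass(frozen=True)
class OccasionMeans:
    occasion: float
    unconditional: CellStats
    sl: CellStats
    ll: CellStats
    welch_t: Optional[float]
    welch_df: Optional[float]
    welch_p: Optional[float]
    n_indeterminate: int


def _cell(values: np.ndarray) -> CellStats:
    n = len(values)
    if n == 0:
        return CellStats(0, None, None, None, None, None)
    mean = float(np.mean(values))
    if n < 2:
        return CellStats(n, mean, None, None, None, None)
    sd = float(np.std(values, ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0:
        return CellStats(n, mean, 0.0, None, None, None)
    t, p = stats.ttest_1samp(values, 0.0)
    return CellStats(n, mean, se, float(t), float(n - 1), float(p))


def _welch(x: np.ndarray, y: np.ndarray):
    """Welch's unequal-variance t with Welch-Satterthwaite df.

    Handles a zero-variance group (df collapses towards the other group's
    ``n - 1``); suppressed when both variances vanish or a group has < 2
    rows."""
    if len(x) < 2 or len(y) < 2:
        return None, None, None
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    n1, n2 = len(x), len(y)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return None, None, None
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    denom = 0.0
    if v1 > 0:
        denom += (v1 / n1) ** 2 / (n1 - 1)
    if v2 > 0:
        denom += (v2 / n2) ** 2 / (n2 - 1)
    df = se2 ** 2 / denom
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def conditional_means(cohort: pd.DataFrame, occasion: float) -> OccasionMeans:
    """Occasion means of ``d_bar``: unconditional, given SL, given LL.

    One-sample two-sided t-tests against zero per cell (suppressed for
    cells with one row or zero variance), plus Welch's unequal-variance
    test of SL vs LL.  Indeterminate rows (``pi_hat`` exactly 1/2) enter
    the unconditional cell only.
    """
    sub = cohort[cohort["occasion"] == float(occasion)]
    if len(sub) == 0:
        raise ValueError(f"no rows at occasion {occasion}")
    d = sub["d_bar"].to_numpy(float)
    d_sl = sub.loc[sub["weak_label"] == "SL", "d_bar"].to_numpy(float)
    d_ll = sub.loc[sub["weak_label"] == "LL", "d_bar"].to_numpy(float)
    n_ind = int((sub["weak_label"] == "indeterminate").sum())
    wt, wdf, wp = _welch(d_sl, d_ll)
    return OccasionMeans(
        occasion=float(occasion),
        unconditional=_cell(d),
        sl=_cell(d_sl),
        ll=_cell(d_ll),
        welch_t=wt, welch_df=wdf, welch_p=wp,
        n_indeterminate=n_ind,
    )


# ---------------------------------------------------------------------------
# delta-curves and the independence test
# ---------------------------------------------------------------------------

_DELTAS = np.round(np.linspace(0.0, 1.0, 11), 1)


@dataclass(frozen=True)
class DeltaCurve:
    """Threshold-conditioned means of ``d_bar`` along a grid of deltas.

    For each delta: ``mean_le`` averages rows with ``pi_hat <= delta`` and
    ``mean_ge`` rows with ``pi_hat >= delta`` (both inclusive).  At
    ``delta = 0`` the ``>=`` curve — and at ``delta = 1`` the ``<=``
    curve — equals the unconditional mean.  Cells with no rows are ``nan``
    (flagged by ``n = 0``), never fabricated; standard errors are
    suppressed for ``n < 2``."""

    occasion: float
    table: pd.DataFrame = field(repr=False)

    @property
    def deltas(self) -> np.ndarray:
        return self.table["delta"].to_numpy()


def delta_curve(cohort: pd.DataFrame, occasion: float) -> DeltaCurve:
    sub = cohort[cohort["occasion"] == float(occasion)]
    if len(sub) == 0:
        raise ValueError(f"no rows at occasion {occasion}")
    pi = sub["pi_hat"].to_numpy(float)
    d = sub["d_bar"].to_numpy(float)
    rows = []
    for delta in _DELTAS:
        for side, mask in (("le", pi <= delta), ("ge", pi >= delta)):
            vals = d[mask]
            n = int(mask.sum())
            mean = float(vals.mean()) if n else np.nan
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            rows.append({"delta": float(delta), "side": side,
                         "mean": mean, "n": n, "se": se})
    return DeltaCurve(occasion=float(occasion), table=pd.DataFrame(rows))


@dataclass(frozen=True)
class IndependenceResult:
    occasion: float
    slope_le: float
    slope_ge: float
    p_le: float
    p_ge: float
    B: int
    null: str


def _slope_operator(deltas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row vector ``c`` with weighted-OLS slope = ``c @ means``."""
    w = weights.astype(float)
    xbar = (w * deltas).sum() / w.sum()
    cx = deltas - xbar
    return w * cx / (w * cx * cx).sum()


def independence_test(
    cohort: pd.DataFrame,
    occasion: float,
    B: int = 2000,
    seed=None,
    null: str = "permutation",
) -> IndependenceResult:
    """Test independence of looking style and preference via curve slopes.

    Under independence of ``pi_hat`` and ``d_bar`` both delta-curves are
    flat in expectation.  The statistic is the n-weighted OLS slope of each
    curve's defined points against delta; the two-sided p-value comes from
    ``B`` resamples under the independence null — by default random
    re-pairings (permutations) of ``d_bar`` against ``pi_hat``, or with
    ``null="bootstrap"`` independent with-replacement resampling of the
    two columns.  Requires at least 10 rows and 3 defined grid points per
    curve.
    """
    if null not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown null {null!r}")
    sub = cohort[cohort["occasion"] == float(occasion)]
    n = len(sub)
    if n < 10:
        raise ValueError(f"need >= 10 rows at occasion {occasion}, have {n}")
    pi = sub["pi_hat"].to_numpy(float)
    d = sub["d_bar"].to_numpy(float)

    masks = {"le": np.array([pi <= t for t in _DELTAS]),
             "ge": np.array([pi >= t for t in _DELTAS])}
    ops = {}
    slopes = {}
    for side, M in masks.items():
        counts = M.sum(axis=1)
        defined = counts > 0
        if defined.sum() < 3:
            raise ValueError(f"{side}-curve defined on fewer than 3 grid points")
        c = _slope_operator(_DELTAS[defined], counts[defined])
        # slope = c @ (per-delta means) = c/counts @ (M @ d)
        ops[side] = (M[defined] / counts[defined, None], c)
        slopes[side] = float(c @ (ops[side][0] @ d))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if null == "permutation":
        D = rng.permuted(np.broadcast_to(d, (B, n)).copy(), axis=1)
    else:
        D = d[rng.integers(0, n, size=(B, n))]
    ps = {}
    for side, (Mn, c) in ops.items():
        null_slopes = (Mn @ D.T).T @ c
        k = int(np.sum(np.abs(null_slopes) >= abs(slopes[side]) - 1e-15))
        ps[side] = min((k + 1) / (B + 1), 1.0)
    return IndependenceResult(
        occasion=float(occasion),
        slope_le=slopes["le"], slope_ge=slopes["ge"],
        p_le=float(ps["le"]), p_ge=float(ps["ge"]),
        B=B, null=null,
    )


# ---------------------------------------------------------------------------
# precedence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecedenceResult:
    """``P1 = P(SL | ORP)`` vs ``P2 = P(ORP | SL)`` at one occasion.

    If other-race preference develops after short looking, ``P1`` should
    exceed ``P2`` (the conditioning event of the larger conditional is the
    later one).  ``p`` is a two-sided bootstrap achieved significance level
    for ``P1 - P2 = 0`` from resampling infants with replacement."""

    occasion: float
    p1: float
    p2: float
    diff: float
    p: float
    B: int
    n: int
    n_orp: int
    n_sl: int
    n_sl_orp: int


def precedence_test(
    cohort: pd.DataFrame, occasion: float, B: int = 2000, seed=None
) -> PrecedenceResult:
    sub = cohort[cohort["occasion"] == float(occasion)]
    sub = sub[(sub["weak_label"].isin(["SL", "LL"]))
              & (sub["preference_label"].isin(["ORP", "SRP"]))]
    n = len(sub)
    sl = (sub["weak_label"] == "SL").to_numpy()
    orp = (sub["preference_label"] == "ORP").to_numpy()
    n_sl, n_orp = int(sl.sum()), int(orp.sum())
    n_sl_orp = int((sl & orp).sum())
    if n_orp == 0 or n_sl == 0:
        empty = "ORP" if n_orp == 0 else "SL"
        raise ValueError(f"no {empty} infants at occasion {occasion}")
    p1 = n_sl_orp / n_orp
    p2 = n_sl_orp / n_sl
    # bootstrap over infants: each row falls in one of 4 cells
    cells = np.array([
        n_sl_orp,                        # SL & ORP
        n_sl - n_sl_orp,                 # SL & SRP
        n_orp - n_sl_orp,                # LL & ORP
        n - n_sl - (n_orp - n_sl_orp),   # LL & SRP
    ])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multinomial(n, cells / n, size=B)
    orp_b = draws[:, 0] + draws[:, 2]
    sl_b = draws[:, 0] + draws[:, 1]
    ok = (orp_b > 0) & (sl_b > 0)
    diffs = draws[ok, 0] / orp_b[ok] - draws[ok, 0] / sl_b[ok]
    B_eff = int(ok.sum())
    lo = (int((diffs <= 0).sum()) + 1) / (B_eff + 1)
    hi = (int((diffs >= 0).sum()) + 1) / (B_eff + 1)
    p = min(2 * min(lo, hi), 1.0)
    return PrecedenceResult(
        occasion=float(occasion), p1=float(p1), p2=float(p2),
        diff=float(p1 - p2), p=float(p), B=B, n=n,
        n_orp=n_orp, n_sl=n_sl, n_sl_orp=n_sl_orp,
    )


# ---------------------------------------------------------------------------
# trajectories and sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySummary:
    target_age: float
    predictions: pd.DataFrame = field(repr=False)
    mean_prediction: float = np.nan
    proportion_sl: float = np.nan
    n_included: int = 0
    n_excluded: int = 0


def trajectory_extrapolation(
    cohort: pd.DataFrame,
    target_age: float = 0.25,
    occasions: Sequence[float] = (3.0, 6.0, 9.0),
) -> TrajectorySummary:
    """Extrapolate each complete ``pi_hat`` trajectory to a target age.

    Only infants observed at every listed occasion are used.  Per infant,
    ordinary least squares of ``pi_hat`` on occasion; the prediction at
    ``target_age`` (default 0.25 months, i.e. one week — a newborn) is
    clamped to [0, 1].  The summary reports the mean prediction and the
    proportion of infants with a predicted value above 1/2 (predicted weak
    short-lookers).
    """
    occs = [float(o) for o in occasions]
    sub = cohort[cohort["occasion"].isin(occs)]
    counts = sub.groupby("infant_id")["occasion"].nunique()
    complete = counts[counts == len(occs)].index
    n_excluded = int(cohort["infant_id"].nunique() - len(complete))
    rows = []
    x = np.array(occs)
    for iid in complete:
        traj = (sub[sub["infant_id"] == iid]
                .set_index("occasion")["pi_hat"].loc[occs].to_numpy(float))
        slope, intercept = np.polyfit(x, traj, 1)
        raw = intercept + slope * target_age
        rows.append({
            "infant_id": iid, "slope": float(slope),
            "intercept": float(intercept), "raw_prediction": float(raw),
            "prediction": float(np.clip(raw, 0.0, 1.0)),
        })
    preds = pd.DataFrame(
        rows, columns=["infant_id", "slope", "intercept",
                       "raw_prediction", "prediction"])
    if len(preds):
        mean_pred = float(preds["prediction"].mean())
        prop_sl = float((preds["prediction"] > 0.5).mean())
    else:
        mean_pred, prop_sl = np.nan, np.nan
    return TrajectorySummary(
        target_age=float(target_age), predictions=preds,
        mean_prediction=mean_pred, proportion_sl=prop_sl,
        n_included=len(preds), n_excluded=n_excluded,
    )


def sampling_probability(
    n_per_sample: int, p_sl: float, min_sl: int, n_samples: int = 1
) -> float:
    """Probability that ``n_samples`` independent cohorts each contain at
    least ``min_sl`` short-looking infants.

    Sampling is Bernoulli with per-infant SL probability ``p_sl``;
    ``q = P(Binomial(n_per_sample, p_sl) >= min_sl)`` and the result is
    ``q ** n_samples``.
    """
    if not (0.0 <= p_sl <= 1.0):
        raise ValueError("p_sl must lie in [0, 1]")
    if min_sl < 0 or n_per_sample < 0 or min_sl > n_per_sample:
        raise ValueError("need 0 <= min_sl <= n_per_sample")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    q = float(stats.binom.sf(min_sl - 1, n_per_sample, p_sl))
    return q ** n_samples
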