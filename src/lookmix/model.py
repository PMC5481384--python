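"""Three-rectangle uniform mixture model of a single infant's looking style.

A trial in a paired-preference session yields a difference score
``d = frames on stimulus B - frames on stimulus A`` in ``[-130, 130]``
(130 video frames per trial).  Within one infant-occasion the scores are
modelled as i.i.d. draws from a finite mixture

    u_mix(d) = pi * u(a, f) + (1 - pi) * [lam * u(a, b) + (1 - lam) * u(e, f)]

where ``u(alpha, beta)`` is the uniform density on ``[alpha, beta]``.  The
wide component ``u(a, f)`` models *short* looks (gaze split between the two
stimuli); the two narrow boundary bands ``u(a, b)`` and ``u(e, f)`` model
*long* looks (near-exclusive gaze to one stimulus).  ``pi`` is the
probability a look is short; ``lam`` splits the long-look mass between the
negative and positive bands.

This module is pure computation on fixed parameter values: density, CDF,
moments and random variates.  Estimation lives in :mod:`lookmix.fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FRAME_MAX",
    "TrialSeries",
    "LookingMixture",
    "mixture_density",
    "mixture_cdf",
    "mixture_moments",
    "sample_trials",
    "log_likelihood",
    "ParameterError",
]

#: Frames per trial; difference scores live in [-FRAME_MAX, FRAME_MAX].
FRAME_MAX = 130.0


class ParameterError(ValueError):
    """Raised when a model or series violates its invariants."""


@dataclass(frozen=True)
class TrialSeries:
    """One infant-occasion's ordered difference scores.

    Parameters
    ----------
    infant_id
        Opaque identifier for the infant.
    occasion
        Assessment age in months (positive real; 3, 6, 9 in the motivating
        longitudinal design).
    d
        Ordered per-trial difference scores, each in ``[-130, 130]``.
    """

    infant_id: str
    occasion: float
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.d, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ParameterError("d must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("d contains non-finite values")
        if arr.min() < -FRAME_MAX or arr.max() > FRAME_MAX:
            bad = arr[(arr < -FRAME_MAX) | (arr > FRAME_MAX)]
            raise ParameterError(
                f"difference scores outside [-130, 130]: {bad[:5].tolist()}"
            )
        if float(self.occasion) <= 0:
            raise ParameterError("occasion (age in months) must be positive")
        object.__setattr__(self, "d", arr)

    @property
    def T(self) -> int:
        """Number of trials."""
        return int(self.d.size)

    @property
    def d_bar(self) -> float:
        """Mean difference score — the substantive preference summary."""
        return float(self.d.mean())

    def sample_variance(self) -> float:
        """Sample variance of the scores (denominator T - 1)."""
        if self.T < 2:
            return 0.0
        return float(self.d.var(ddof=1))


@dataclass(frozen=True)
class LookingMixture:
    """Parameters of the three-rectangle mixture for one infant-occasion.

    ``a <= b < 0 < e <= f``.  A band may be absent (``b is None`` /
    ``e is None``) when the data contain no observation on that side; its
    weight is then pinned (``lam = 0`` without the negative band, ``lam = 1``
    without the positive one).  Zero-width components (``a == b`` etc.) are
    treated as point masses, which arises only for degenerate data.
    """

    a: float
    f: float
    b: Optional[float] = None
    e: Optional[float] = None
    lam: float = 0.5
    pi: float = 0.5

    def __post_init__(self) -> None:
        a, f = float(self.a), float(self.f)
        if not (-FRAME_MAX <= a <= f <= FRAME_MAX):
            raise ParameterError(f"need -130 <= a <= f <= 130, got a={a}, f={f}")
        if not (0.0 <= self.pi <= 1.0):
            raise ParameterError(f"pi must lie in [0, 1], got {self.pi}")
        if not (0.0 <= self.lam <= 1.0):
            raise ParameterError(f"lam must lie in [0, 1], got {self.lam}")
        if self.b is not None:
            b = float(self.b)
            if not (a <= b < 0.0):
                raise ParameterError(f"need a <= b < 0, got a={a}, b={b}")
        elif self.pi < 1.0 and self.lam > 0.0:
            raise ParameterError("negative band absent: lam must be 0 (or pi = 1)")
        if self.e is not None:
            e = float(self.e)
            if not (0.0 < e <= f):
                raise ParameterError(f"need 0 < e <= f, got e={e}, f={f}")
        elif self.pi < 1.0 and self.lam < 1.0:
            raise ParameterError("positive band absent: lam must be 1 (or pi = 1)")

    @property
    def components(self) -> list[tuple[float, float, float]]:
        """(weight, lower, upper) for each component with positive weight."""
        out = []
        if self.pi > 0:
            out.append((self.pi, self.a, self.f))
        w_long = 1.0 - self.pi
        if w_long > 0:
            if self.b is not None and self.lam > 0:
                out.append((w_long * self.lam, self.a, float(self.b)))
            if self.e is not None and self.lam < 1:
                out.append((w_long * (1.0 - self.lam), float(self.e), self.f))
        return out


def _uniform_pdf(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Uniform density on the closed interval; point mass -> inf at the atom."""
    if hi > lo:
        return np.where((x >= lo) & (x <= hi), 1.0 / (hi - lo), 0.0)
    return np.where(x == lo, np.inf, 0.0)


def _uniform_cdf(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi > lo:
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return np.where(x >= lo, 1.0, 0.0)


def mixture_density(model: LookingMixture, x) -> np.ndarray | float:
    """Mixture density ``pi*u_short(x) + (1-pi)*u_long(x)``.

    Zero outside ``[a, f]``; integrates to one.  Vectorised over ``x``.
    """
    xs = np.asarray(x, dtype=float)
    out = np.zeros_like(xs)
    for w, lo, hi in model.components:
        out = out + w * _uniform_pdf(xs, lo, hi)
    return out if out.shape else float(out)


def mixture_cdf(model: LookingMixture, x) -> np.ndarray | float:
    """Piecewise-linear mixture CDF; 0 at ``x <= a``, 1 at ``x >= f``."""
    xs = np.asarray(x, dtype=float)
    out = np.zeros_like(xs)
    for w, lo, hi in model.components:
        out = out + w * _uniform_cdf(xs, lo, hi)
    return out if out.shape else float(out)


def mixture_moments(model: LookingMixture) -> tuple[float, float]:
    """Closed-form mean and variance of the mixture.

    A uniform on ``[alpha, beta]`` has mean ``(alpha+beta)/2`` and second
    moment ``(alpha^2 + alpha*beta + beta^2)/3``; the mixture moments are the
    weight-averaged component moments.
    """
    mean = 0.0
    m2 = 0.0
    for w, lo, hi in model.components:
        mean += w * (lo + hi) / 2.0
        m2 += w * (lo * lo + lo * hi + hi * hi) / 3.0
    var = m2 - mean * mean
    return mean, max(var, 0.0)


def sample_trials(
    model: LookingMixture,
    T: int,
    seed=None,
    integerize: bool = True,
    infant_id: str = "sim",
    occasion: float = 3.0,
    return_components: bool = False,
):
    """Draw ``T`` trials from the mixture.

    Each trial first draws its component (short with probability ``pi``,
    otherwise the negative band with probability ``lam``), then a uniform
    variate on that component's interval.  With ``integerize`` the draw is
    rounded to the nearest integer and clamped to ``[-130, 130]``, mimicking
    frame counts.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  With
    ``return_components`` also returns the 0/1/2 component label per trial
    (short / negative band / positive band).
    """
    if T < 1:
        raise ParameterError("T must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u_comp = rng.random(T)
    u_side = rng.random(T)
    u_val = rng.random(T)

    comp = np.full(T, 0, dtype=int)
    is_long = u_comp >= model.pi
    comp[is_long & (u_side < model.lam)] = 1
    comp[is_long & (u_side >= model.lam)] = 2

    lo = np.empty(T)
    hi = np.empty(T)
    lo[comp == 0], hi[comp == 0] = model.a, model.f
    if np.any(comp == 1):
        if model.b is None:
            raise ParameterError("negative band drawn but absent (b is None)")
        lo[comp == 1], hi[comp == 1] = model.a, model.b
    if np.any(comp == 2):
        if model.e is None:
            raise ParameterError("positive band drawn but absent (e is None)")
        lo[comp == 2], hi[comp == 2] = model.e, model.f

    d = lo + u_val * (hi - lo)
    if integerize:
        d = np.clip(np.rint(d), -FRAME_MAX, FRAME_MAX)
    series = TrialSeries(infant_id=infant_id, occasion=occasion, d=d)
    if return_components:
        return series, comp
    return series


def component_mass(lo: float, hi: float) -> float:
    """Per-integer probability mass of a uniform component on ``[lo, hi]``.

    Difference scores are integer video-frame counts, so a component
    spanning ``hi - lo`` frames puts mass ``1/(hi - lo + 1)`` on each of its
    integer support points.  This discrete convention bounds the likelihood:
    a zero-width component is a unit point mass, not an infinite density.
    """
    return 1.0 / (hi - lo + 1.0)


def log_likelihood(model: LookingMixture, d) -> float:
    """Observed-data log-likelihood of integer scores ``d`` under the mixture.

    Uses the discrete per-integer masses of :func:`component_mass`, the
    convention under which the model is fitted.
    """
    xs = np.asarray(d, dtype=float)
    mass = np.zeros_like(xs)
    for w, lo, hi in model.components:
        mass = mass + w * component_mass(lo, hi) * ((xs >= lo) & (xs <= hi))
    if np.any(mass <= 0):
        return -np.inf
    return float(np.log(mass).sum())
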