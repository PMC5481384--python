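"""Synthetic longitudinal cohorts with known ground truth.

The motivating study's raw data were never deposited, so every downstream
analysis is exercised on generated cohorts that mimic its structure: ~74
infants assessed at 3, 6 and 9 months (46 complete, 21 at two adjacent
ages, 7 once), 24 trials per session, difference scores integer in
[-130, 130].

Looking style matures with age: each infant's short-look probability
follows a logistic curve in age with a random midpoint and slope, and a
fraction of infants are "special" — either strongly short-looking at every
age (pi = 1 throughout) or step-like (pi = 0 at the first age, 1 after),
mirroring the qualitative trajectory types reported for real cohorts.

Preference is induced through the only two mechanisms the mixture offers:
the split ``lam`` of long-look mass between the negative and positive
bands, and the midpoint of the short component.  The mixture mean is
``pi*(a+f)/2 + (1-pi)*[lam*(a+b)/2 + (1-lam)*(e+f)/2]``, so a ``lam``
above 1/2 pushes long-lookers negative (other-stimulus preference) and a
positive short-component offset pushes short-lookers positive.  Defaults
reproduce the study's qualitative pattern: at 3 months short-lookers lean
positive (same-race) and long-lookers negative; at later ages everyone
drifts mildly negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FRAME_MAX, LookingMixture, sample_trials

__all__ = ["CohortScenario", "generate_cohort"]


@dataclass
class CohortScenario:
    """Parameters of a synthetic longitudinal cohort.

    Attrition counts are (complete, two adjacent ages, one age) and must
    sum to ``n_infants``.
    """

    n_infants: int = 74
    occasions: Sequence[float] = (3.0, 6.0, 9.0)
    trials_per_session: int = 24
    attrition: Sequence[int] = (46, 21, 7)
    #: fraction of infants with special trajectories (half always-SL, half step)
    frac_special: float = 0.15
    #: logistic maturation: age at pi = 1/2 ~ N(mu, sd), scale ~ U(lo, hi)
    midpoint_mu: float = 4.5
    midpoint_sd: float = 1.5
    scale_range: Sequence[float] = (0.8, 2.0)
    #: long-band widths (frames) ~ U(lo, hi)
    band_width_range: Sequence[float] = (8.0, 25.0)
    #: mean share of long-look mass on the negative side (other-stimulus)
    lam_mean: float = 0.55
    lam_sd: float = 0.08
    #: short-component midpoint offset (frames): early occasion vs later ones
    short_shift_early: float = 12.0
    short_shift_late: float = -10.0
    short_shift_sd: float = 3.0
    integerize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.attrition) != self.n_infants:
            raise ValueError("attrition counts must sum to n_infants")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if not (0.0 <= self.frac_special <= 1.0):
            raise ValueError("frac_special must lie in [0, 1]")
        lo, hi = self.band_width_range
        if not (0 < lo <= hi < FRAME_MAX):
            raise ValueError("band widths must lie in (0, 130)")


def _pi_trajectory(scenario: CohortScenario, rng, kind: str) -> dict[float, float]:
    occs = [float(o) for o in scenario.occasions]
    if kind == "always_sl":
        return {o: 1.0 for o in occs}
    if kind == "step":
        return {o: (0.0 if o == min(occs) else 1.0) for o in occs}
    mid = rng.normal(scenario.midpoint_mu, scenario.midpoint_sd)
    scale = rng.uniform(*scenario.scale_range)
    return {o: float(1.0 / (1.0 + np.exp(-(o - mid) / scale))) for o in occs}


def _draw_mixture(scenario: CohortScenario, rng, pi: float, occasion: float,
                  first_occasion: float) -> LookingMixture:
    w_neg = rng.uniform(*scenario.band_width_range)
    w_pos = rng.uniform(*scenario.band_width_range)
    lam = float(np.clip(rng.normal(scenario.lam_mean, scenario.lam_sd), 0.05, 0.95))
    base = (scenario.short_shift_early if occasion == first_occasion
            else scenario.short_shift_late)
    # preference follows looking style: the short-component offset scales
    # with pi, so strong short-lookers carry the full early positive lean
    # while long-lookers keep their bands anchored at the range boundaries
    # (their preference comes from lam > 1/2 alone)
    shift = pi * base + rng.normal(0.0, scenario.short_shift_sd)
    a, f = -FRAME_MAX, FRAME_MAX
    if shift > 0:
        a = min(-FRAME_MAX + 2 * shift, -1.0)
    elif shift < 0:
        f = max(FRAME_MAX + 2 * shift, 1.0)
    b = a + w_neg
    e = f - w_pos
    return LookingMixture(a=a, f=f, b=float(min(b, -1.0)), e=float(max(e, 1.0)),
                          lam=lam, pi=float(pi))


def generate_cohort(scenario: CohortScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long-format trial table and the ground-truth table.

    Returns
    -------
    trials : DataFrame
        Columns ``infant_id, occasion, trial, d`` (trial index 1-based).
    truth : DataFrame
        One row per trial with the generating parameters and the true
        component label (``short`` / ``neg_band`` / ``pos_band``).
    """
    rng = np.random.default_rng(scenario.seed)
    occs = [float(o) for o in scenario.occasions]
    first = min(occs)
    n_complete, n_two, n_one = scenario.attrition

    # which occasions each infant attends
    schedules: list[list[float]] = []
    for _ in range(n_complete):
        schedules.append(occs)
    adjacent = [occs[i:i + 2] for i in range(len(occs) - 1)] or [occs]
    for _ in range(n_two):
        schedules.append(list(adjacent[rng.integers(len(adjacent))]))
    for _ in range(n_one):
        schedules.append([occs[rng.integers(len(occs))]])

    n_special = int(round(scenario.frac_special * scenario.n_infants))
    kinds = ["always_sl"] * (n_special // 2) + ["step"] * (n_special - n_special // 2)
    kinds += ["logistic"] * (scenario.n_infants - n_special)
    # specials drawn from the complete-data infants, as in real cohorts the
    # clearest trajectories come from infants seen at every age
    comp_labels = ["short", "neg_band", "pos_band"]
    trial_rows = []
    truth_rows = []
    for i, (sched, kind) in enumerate(zip(schedules, kinds)):
        iid = f"S{i + 1:04d}"
        traj = _pi_trajectory(scenario, rng, kind)
        for occ in sched:
            model = _draw_mixture(scenario, rng, traj[occ], occ, first)
            series, comp = sample_trials(
                model, scenario.trials_per_session, seed=rng,
                integerize=scenario.integerize, infant_id=iid, occasion=occ,
                return_components=True,
            )
            for t, (dval, c) in enumerate(zip(series.d, comp), start=1):
                trial_rows.append({"infant_id": iid, "occasion": occ,
                                   "trial": t, "d": dval})
                truth_rows.append({
                    "infant_id": iid, "occasion": occ, "trial": t,
                    "component": comp_labels[c], "pi": model.pi,
                    "lam": model.lam, "a": model.a, "b": model.b,
                    "e": model.e, "f": model.f, "trajectory_kind": kind,
                })
    trials = pd.DataFrame(trial_rows)
    if scenario.integerize:
        trials["d"] = trials["d"].astype(int)
    return trials, pd.DataFrame(truth_rows)
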