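"""Reading and writing trial data and results.

Trial files are long-format CSV/TSV with one row per (infant, occasion,
trial): either a ``d`` column (the difference score) or two raw
frame-count columns from which ``d`` is computed.  Results are written as
plain CSV tables plus a JSON run report.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fit import FitResult
from .model import FRAME_MAX, TrialSeries

__all__ = [
    "ValidationError",
    "compute_differences",
    "read_trials",
    "series_from_frame",
    "write_results",
    "FLOAT_FORMAT",
]

log = logging.getLogger(__name__)

#: numeric round-trip precision for CSV output
FLOAT_FORMAT = "%.12g"

REQUIRED = ("infant_id", "occasion", "trial")


class ValidationError(ValueError):
    """Input rows violating the trial-table invariants, with row numbers."""


def compute_differences(
    raw: pd.DataFrame,
    positive: str = "frames_stimB",
    negative: str = "frames_stimA",
) -> pd.DataFrame:
    """Compute ``d = positive - negative`` from per-trial frame counts.

    The column named by ``positive`` is the stimulus mapped to the positive
    pole of the difference score (recorded in ``DataFrame.attrs`` so the
    sign convention travels with the table).  Frames must be nonnegative
    and sum to at most 130 per trial (looks away from both stimuli are
    allowed, so the sum may fall short).
    """
    for col in (positive, negative):
        if col not in raw:
            raise ValidationError(f"missing frame-count column {col!r}")
    pos = raw[positive].to_numpy(float)
    neg = raw[negative].to_numpy(float)
    bad = np.where((pos < 0) | (neg < 0) | (pos + neg > FRAME_MAX))[0]
    if bad.size:
        raise ValidationError(
            "invalid frame counts (negative, or summing beyond 130 frames) "
            f"in rows: {bad.tolist()[:20]}"
        )
    out = raw.copy()
    out["d"] = (pos - neg).astype(int)
    out.attrs["positive_pole"] = positive
    return out


def _detect_sep(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_trials(
    path,
    sep: Optional[str] = None,
    positive: str = "frames_stimB",
    negative: str = "frames_stimA",
) -> list[TrialSeries]:
    """Read and validate a trial table, grouped into per-infant-occasion series.

    The file needs columns ``infant_id, occasion, trial`` and either ``d``
    or the two frame-count columns.  Rows are sorted by trial index within
    each group; validation failures name the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if "d" not in df.columns:
        df = compute_differences(df, positive=positive, negative=negative)

    d = pd.to_numeric(df["d"], errors="coerce")
    bad = df.index[d.isna()].tolist()
    if bad:
        raise ValidationError(f"non-numeric d in rows: {bad[:20]}")
    nonint = df.index[(d != np.round(d))].tolist()
    if nonint:
        raise ValidationError(f"non-integer d in rows: {nonint[:20]}")
    out_of_range = df.index[(d < -FRAME_MAX) | (d > FRAME_MAX)].tolist()
    if out_of_range:
        raise ValidationError(f"d outside [-130, 130] in rows: {out_of_range[:20]}")
    dupes = df.duplicated(subset=["infant_id", "occasion", "trial"], keep=False)
    if dupes.any():
        raise ValidationError(
            f"duplicate trial indices in rows: {df.index[dupes].tolist()[:20]}"
        )

    series = []
    for (iid, occ), grp in df.groupby(["infant_id", "occasion"], sort=True):
        grp = grp.sort_values("trial")
        if len(grp) == 0:
            log.warning("empty group (%s, %s) dropped", iid, occ)
            continue
        series.append(TrialSeries(infant_id=str(iid), occasion=float(occ),
                                  d=grp["d"].to_numpy(float)))
    return series


def series_from_frame(df: pd.DataFrame) -> list[TrialSeries]:
    """Group an in-memory long-format trial table into TrialSeries."""
    out = []
    for (iid, occ), grp in df.groupby(["infant_id", "occasion"], sort=True):
        grp = grp.sort_values("trial")
        out.append(TrialSeries(infant_id=str(iid), occasion=float(occ),
                               d=grp["d"].to_numpy(float)))
    return out


def write_results(
    fits: Sequence[tuple[TrialSeries, FitResult]],
    params_path=None,
    posteriors_path=None,
    report_path=None,
    config: Optional[dict] = None,
) -> dict:
    """Write the parameter table, posterior table and JSON run report.

    The parameter table has one row per infant-occasion (endpoints, lam,
    pi_hat, log-likelihood, structure and identifiability flags); the
    posterior table one row per trial with its short-look posterior.
    Numeric fields are written at 12 significant digits so a read/write
    round trip is lossless at that precision.  Returns the report dict.
    """
    param_rows = []
    post_rows = []
    for series, fit in fits:
        m = fit.model
        param_rows.append({
            "infant_id": series.infant_id, "occasion": series.occasion,
            "T": series.T, "a": m.a, "b": m.b, "e": m.e, "f": m.f,
            "lam": m.lam, "pi_hat": fit.pi_hat, "d_bar": series.d_bar,
            "loglik": fit.loglik, "structure": fit.structure,
            "converged": fit.converged, "degenerate": fit.degenerate,
            "bands_identified": fit.bands_identified,
        })
        for t, (dval, p) in enumerate(zip(series.d, fit.posteriors), start=1):
            post_rows.append({
                "infant_id": series.infant_id, "occasion": series.occasion,
                "trial": t, "d": int(dval), "p_short": p,
            })
    params = pd.DataFrame(param_rows)
    posts = pd.DataFrame(post_rows)
    if params_path is not None:
        params.to_csv(params_path, index=False, float_format=FLOAT_FORMAT)
    if posteriors_path is not None:
        posts.to_csv(posteriors_path, index=False, float_format=FLOAT_FORMAT)
    report = {
        "n_series": len(fits),
        "n_trials": int(sum(s.T for s, _ in fits)),
        "config": config or {},
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report, indent=2, default=str))
    return report
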