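"""Small built-in example data.

The worked example used throughout the docs: a 3-month-old infant (id
2523) from a longitudinal same-race/other-race face-preference study, 24
paired-presentation trials of 130 video frames each.  Each score is the
frame count on the same-race stimulus minus the frame count on the
other-race stimulus.  The infant is a "mixed" looker: full-trial looks to
either stimulus (|d| near 130) interleaved with trials where gaze was
split (|d| small or zero).
"""

from __future__ import annotations

import numpy as np

from .model import TrialSeries

__all__ = ["example_infant"]

_EXAMPLE_D = [
    -117, 120, -124, 130, 97, 112, -108, 126, -130, -34, -122, 129,
    129, -76, 103, -103, 0, 0, -117, 130, -112, -108, 115, 0,
]


def example_infant() -> TrialSeries:
    """The 24-trial worked-example series (infant 2523, age 3 months)."""
    return TrialSeries(infant_id="2523", occasion=3.0,
                       d=np.array(_EXAMPLE_D, dtype=float))
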