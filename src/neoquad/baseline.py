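"""The standard comparator: constant daily cause-specific mortality.

Health-system planning conventionally spreads a cause's 28-day
cumulative risk evenly over the neonatal period.  Under that reading the
cumulative prediction at an age bound of h hours is simply
``cause_nmr * h / 672`` — linear allocation by elapsed time, exact at 28
days by construction.  (A constant-hazard exponential allocation differs
only at O(q^2) for neonatal-scale probabilities and would be equally
exact at 28 days.)
"""

from __future__ import annotations

import numpy as np

from .cohort import NEONATAL_HOURS, AgeGroupScheme
from .logquad import Prediction


def standard_predict(
    cause_nmr: float, scheme: AgeGroupScheme | None = None, cause: str = ""
) -> Prediction:
    """Constant-daily-rate cumulative mortality at each cumulative age bound."""
    scheme = scheme or AgeGroupScheme()
    if not 0.0 <= cause_nmr <= 1.0:
        raise ValueError("cause_nmr must be a probability")
    # fraction first: the last entry is then exactly 1.0 and the 28-day
    # prediction reproduces cause_nmr bit-exactly
    fractions = np.asarray(scheme.bounds, dtype=float) / NEONATAL_HOURS
    cum_q = cause_nmr * fractions
    return Prediction(cause=cause, age_labels=scheme.labels, cum_q=cum_q)
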