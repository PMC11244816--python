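"""Leave-one-quarter-out cross-validation of the three estimators.

Each calendar quarter is held out in turn; the log-quadratic model is
refit on the remaining quarters and the holdout's cumulative
cause-specific mortality is predicted three ways:

* ``k0`` — log-quadratic with shape parameter k = 0 (the typical age
  pattern at the holdout's observed all-cause NMR);
* ``best_k`` — log-quadratic with k calibrated to the holdout's observed
  cause-specific NMR (exact at 28 days by construction);
* ``standard`` — constant daily rate from the same observed
  cause-specific NMR (also exact at 28 days).

The holdout's observed all-cause NMR and cause-specific NMR are treated
as known at prediction time: the exercise validates the estimated AGE
PATTERN given the mortality level.  Absolute errors are averaged over
holdouts; relative errors average |error|/observed over holdouts with a
non-zero observation and are reported only for causes common enough for
that ratio to be meaningful (by default preterm and asphyxia — the rare
causes' quarterly observations are often zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline import standard_predict
from .cohort import AgeGroupScheme, QuarterLifeTable
from .errors import NoDeviationSignal, SingularDesignError
from .logquad import DEFAULT_OFFSET, calibrate_k, estimate_deviation_vector, fit_quadratic, predict

METHODS = ("k0", "best_k", "standard")
DEFAULT_REL_ERROR_CAUSES = ("preterm", "asphyxia")


@dataclass(frozen=True)
class CVErrorSummary:
    """Cross-validation error summaries plus per-holdout detail.

    ``summary`` has one row per (cause, age_label, method) with the
    average absolute error (probability units) and the average relative
    error (NaN where undefined).  ``details`` has one row per (holdout
    quarter, cause, age_label, method) with observed and predicted
    values.
    """

    summary: pd.DataFrame
    details: pd.DataFrame

    def abs_error(self, cause: str, age_label: str, method: str) -> float:
        row = self.summary[
            (self.summary.cause == cause)
            & (self.summary.age_label == age_label)
            & (self.summary.method == method)
        ]
        return float(row.abs_err.iloc[0])

    def rel_error(self, cause: str, age_label: str, method: str) -> float:
        row = self.summary[
            (self.summary.cause == cause)
            & (self.summary.age_label == age_label)
            & (self.summary.method == method)
        ]
        return float(row.rel_err.iloc[0])

    def to_table1_frame(self, decimals: int = 5) -> pd.DataFrame:
        """Wide per-cause table: absolute then relative error per method.

        Values are rounded to ``decimals`` places (relative errors to
        3); undefined relative errors are left empty.
        """
        wide = self.summary.pivot_table(
            index=["cause", "age_label"],
            columns="method",
            values=["abs_err", "rel_err"],
            sort=False,
        )
        out = pd.DataFrame(
            {
                "cause": [c for c, _ in wide.index],
                "age_label": [a for _, a in wide.index],
            }
        )
        for stat, dec in (("abs_err", decimals), ("rel_err", 3)):
            for method in METHODS:
                col = wide[(stat, method)].round(dec)
                out[f"{stat}_{method}"] = col.to_numpy()
        return out


def loqo_cv(
    tables: Sequence[QuarterLifeTable],
    causes: Sequence[str] | None = None,
    scheme: AgeGroupScheme | None = None,
    offset: float = DEFAULT_OFFSET,
    rel_error_causes: Sequence[str] = DEFAULT_REL_ERROR_CAUSES,
) -> CVErrorSummary:
    """Leave-one-quarter-out cross-validation over all causes and methods."""
    if len(tables) < 5:
        raise SingularDesignError(
            f"need at least 5 tables so every training fold is identifiable, "
            f"got {len(tables)}"
        )
    scheme = scheme or AgeGroupScheme()
    if causes is None:
        causes = tuple(c for c in tables[0].causes if c != "other")

    detail_rows = []
    for held_idx, held in enumerate(tables):
        training = [t for i, t in enumerate(tables) if i != held_idx]
        for cause in causes:
            try:
                fit = fit_quadratic(training, cause, offset)
            except SingularDesignError as exc:
                raise SingularDesignError(
                    f"training fold holding out {held.quarter}: {exc}"
                ) from exc
            try:
                v = estimate_deviation_vector(fit.residuals)
            except NoDeviationSignal:
                # exact model surface: deviation confined to the last age
                # keeps the 28-day calibration exact and perturbs nothing
                v = np.zeros(fit.n_ages)
                v[-1] = 1.0
            fit = fit.with_deviation(v)

            observed = held.cause_q(cause)
            cause_nmr = held.cause_nmr(cause)
            k = calibrate_k(fit, held.nmr, cause_nmr, offset)
            preds = {
                "k0": predict(fit, held.nmr, 0.0).cum_q,
                "best_k": predict(fit, held.nmr, k.k).cum_q,
                "standard": standard_predict(cause_nmr, scheme, cause).cum_q,
            }
            for method in METHODS:
                for xi, label in enumerate(scheme.labels):
                    detail_rows.append(
                        {
                            "quarter": str(held.quarter),
                            "cause": cause,
                            "age_label": label,
                            "method": method,
                            "observed": observed[xi],
                            "predicted": preds[method][xi],
                        }
                    )

    details = pd.DataFrame(detail_rows)
    details["abs_err"] = (details.predicted - details.observed).abs()

    summary_rows = []
    for cause in causes:
        for label in scheme.labels:
            for method in METHODS:
                cell = details[
                    (details.cause == cause)
                    & (details.age_label == label)
                    & (details.method == method)
                ]
                abs_err = float(cell.abs_err.mean())
                if cause in rel_error_causes:
                    nz = cell[cell.observed > 0.0]
                    rel_err = (
                        float((nz.abs_err / nz.observed).mean())
                        if len(nz)
                        else np.nan
                    )
                else:
                    rel_err = np.nan
                summary_rows.append(
                    {
                        "cause": cause,
                        "age_label": label,
                        "method": method,
                        "abs_err": abs_err,
                        "rel_err": rel_err,
                    }
                )
    return CVErrorSummary(summary=pd.DataFrame(summary_rows), details=details)
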