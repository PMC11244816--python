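"""The adapted log-quadratic model for cumulative cause-specific mortality.

For a cause c and cumulative age group x, the model relates the log of
the cumulative mortality probability q[x, c] to the log all-cause
neonatal mortality rate z = log(nmr):

    log q[x, c] = a[x, c] + b[x, c] * z + c[x, c] * z**2 + v[x, c] * k

The quadratic coefficients are fit by ordinary least squares across
quarterly life tables.  The deviation vector v captures the dominant
pattern of age-specific departures from the quadratic surface: it is the
first right singular vector of the training residual matrix, normalized
so that v at the last cumulative age equals 1.  The per-life-table shape
parameter k then has a closed form: calibrating to an observed
cause-specific NMR shifts the whole age pattern so the 28-day prediction
matches that NMR exactly.

Any zero cumulative-mortality cell is replaced by a small offset
(default 1e-5) before taking logs, in both fitting and calibration; this
matters only for rare causes whose quarterly counts can be zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cohort import QuarterLifeTable
from .errors import DegenerateDeviation, NoDeviationSignal, SingularDesignError
from .quarters import Quarter

DEFAULT_OFFSET = 1e-5


@dataclass(frozen=True)
class LogQuadFit:
    """Fitted log-quadratic model for one cause.

    ``a``, ``b``, ``c`` hold one coefficient per cumulative age group;
    ``v`` is the deviation vector (``v[-1] == 1`` by normalization), or
    None when only the k = 0 model is usable.  ``residuals`` is the
    training residual matrix (quarters x ages) kept for deviation
    estimation; it is not serialized.
    """

    cause: str
    age_labels: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    v: np.ndarray | None = None
    offset: float = DEFAULT_OFFSET
    training_quarters: tuple[Quarter, ...] = ()
    residuals: np.ndarray | None = field(default=None, repr=False)
    se_b: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_ages(self) -> int:
        return len(self.age_labels)

    def with_deviation(self, v: np.ndarray) -> "LogQuadFit":
        return replace(self, v=np.asarray(v, dtype=float))

    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "age_labels": list(self.age_labels),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "v": self.v.tolist() if self.v is not None else None,
            "offset": self.offset,
            "training_quarters": [str(q) for q in self.training_quarters],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "LogQuadFit":
        return cls(
            cause=d["cause"],
            age_labels=tuple(d["age_labels"]),
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            c=np.asarray(d["c"], dtype=float),
            v=None if d["v"] is None else np.asarray(d["v"], dtype=float),
            offset=float(d["offset"]),
            training_quarters=tuple(
                Quarter.parse(q) for q in d["training_quarters"]
            ),
        )

    @classmethod
    def from_json(cls, path) -> "LogQuadFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ShapeParameter:
    """Per-life-table shape parameter k for one cause."""

    cause: str
    k: float
    quarter: Quarter | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.k):
            raise ValueError("shape parameter k must be finite")


@dataclass(frozen=True)
class Prediction:
    """Predicted cumulative cause-specific mortality per cumulative age."""

    cause: str
    age_labels: tuple[str, ...]
    cum_q: np.ndarray


def _log_with_offset(q: np.ndarray, offset: float) -> np.ndarray:
    """log(q) with exact zeros replaced by the offset first."""
    q = np.asarray(q, dtype=float)
    return np.log(np.where(q == 0.0, offset, q))


def fit_quadratic(
    tables: Sequence[QuarterLifeTable],
    cause: str,
    offset: float = DEFAULT_OFFSET,
) -> LogQuadFit:
    """OLS fit of log q[x, cause] on z = log(nmr) and z**2, per age group.

    Requires at least 4 tables with at least 3 distinct nmr values (the
    quadratic is otherwise unidentifiable) and strictly positive nmr in
    every table.  Zero q cells enter the regression as log(offset).
    The residual matrix is retained on the returned fit.
    """
    if len(tables) < 4:
        raise SingularDesignError(
            f"need at least 4 training tables, got {len(tables)}"
        )
    nmr = np.array([t.nmr for t in tables], dtype=float)
    if np.any(nmr <= 0.0):
        bad = tables[int(np.argmax(nmr <= 0.0))].quarter
        raise SingularDesignError(f"non-positive all-cause nmr in quarter {bad}")
    if len(np.unique(nmr)) < 3:
        raise SingularDesignError(
            f"only {len(np.unique(nmr))} distinct nmr values; quadratic "
            "design is singular"
        )
    z = np.log(nmr)
    X = np.column_stack([np.ones_like(z), z, z * z])
    Y = np.stack(
        [_log_with_offset(t.cause_q(cause), offset) for t in tables]
    )  # quarters x ages
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta

    # per-age standard error of the linear coefficient, for recovery checks
    dof = len(tables) - 3
    se_b = None
    if dof > 0:
        xtx_inv = np.linalg.inv(X.T @ X)
        sigma2 = (resid**2).sum(axis=0) / dof
        se_b = np.sqrt(sigma2 * xtx_inv[1, 1])

    return LogQuadFit(
        cause=cause,
        age_labels=tables[0].age_labels,
        a=beta[0],
        b=beta[1],
        c=beta[2],
        offset=offset,
        training_quarters=tuple(t.quarter for t in tables),
        residuals=resid,
        se_b=se_b,
    )


def estimate_deviation_vector(residual_matrix: np.ndarray) -> np.ndarray:
    """Deviation vector from a (quarters x ages) residual matrix.

    The first right singular vector, sign-fixed so its last entry is
    positive and rescaled so the last entry equals 1 exactly.  Raises
    :class:`NoDeviationSignal` when the residuals are numerically zero
    and :class:`DegenerateDeviation` when the leading singular vector
    vanishes at the last age (k would be unidentifiable).
    """
    R = np.asarray(residual_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("residual matrix must be 2-D with at least 2 quarters")
    _, s, vt = np.linalg.svd(R, full_matrices=False)
    if s[0] < 1e-12:
        raise NoDeviationSignal("residual matrix is numerically zero")
    v = vt[0]
    if abs(v[-1]) < 1e-8:
        raise DegenerateDeviation(
            "deviation vector vanishes at the last cumulative age"
        )
    return v / v[-1]


def fit_logquad(
    tables: Sequence[QuarterLifeTable],
    cause: str,
    offset: float = DEFAULT_OFFSET,
) -> LogQuadFit:
    """Convenience: quadratic fit plus deviation vector in one call."""
    fit = fit_quadratic(tables, cause, offset)
    return fit.with_deviation(estimate_deviation_vector(fit.residuals))


def predict(fit: LogQuadFit, nmr: float, k: float = 0.0) -> Prediction:
    """Predicted cumulative mortality at each age for a given nmr and k.

    With k = 0 the deviation vector is not consulted at all.
    """
    if nmr <= 0.0:
        raise ValueError("nmr must be strictly positive")
    z = np.log(nmr)
    log_q = fit.a + fit.b * z + fit.c * z * z
    if k != 0.0:
        if fit.v is None:
            raise ValueError("fit carries no deviation vector; cannot apply k != 0")
        log_q = log_q + fit.v * k
    # unstable small-sample fits can push log_q past the float range;
    # the raw model output is reported as-is (overflow -> inf), with no
    # truncation or monotonicity repair
    with np.errstate(over="ignore"):
        cum_q = np.exp(log_q)
    return Prediction(cause=fit.cause, age_labels=fit.age_labels, cum_q=cum_q)


def calibrate_k(
    fit: LogQuadFit,
    nmr: float,
    cause_nmr: float,
    offset: float = DEFAULT_OFFSET,
) -> ShapeParameter:
    """Closed-form k matching the 28-day prediction to the cause-specific NMR.

    Because v is normalized to 1 at the last cumulative age, the shape
    parameter that reproduces an observed cause-specific NMR is simply
    the log-scale gap at 28 days between the observation and the k = 0
    prediction.  A zero cause_nmr is replaced by the offset before the
    log, mirroring the zero-cell rule in fitting.
    """
    if fit.v is None:
        raise ValueError("fit carries no deviation vector; calibrate after fit_logquad")
    if abs(fit.v[-1] - 1.0) > 1e-9:
        raise DegenerateDeviation("deviation vector is not normalized to v[last] = 1")
    if nmr <= 0.0:
        raise ValueError("nmr must be strictly positive")
    if cause_nmr < 0.0:
        raise ValueError("cause_nmr must be non-negative")
    z = np.log(nmr)
    log_q28 = float(fit.a[-1] + fit.b[-1] * z + fit.c[-1] * z * z)
    target = np.log(offset) if cause_nmr == 0.0 else np.log(cause_nmr)
    return ShapeParameter(cause=fit.cause, k=float(target - log_q28))
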