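"""Post-operative PROM score prediction by linear regression.

The post-operative patient-reported outcome measure (PROM) score is modelled
as a linear function of the pre-operative score, age, age squared, and any
further covariates:

    PROM_post = b0 * PROM_pre + b1 * Age + b2 * Age^2 + sum_k b_k x_k (+ c)

fitted by ordinary least squares (minimum mean squared error). The quadratic
age term captures the empirically curved age dependence of recovery. An
intercept ``c`` is included by default and can be disabled. Predicted scores
are rounded half-up to the nearest integer and clamped to the instrument's
score range (default [0, 48], the Oxford Hip/Knee Score scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .covariates import CovariateVector, Term, encode_record, schema_names
from .errors import ValidationError

__all__ = ["PromModel", "design_row", "fit_prom", "predict_prom", "predict_prom_raw"]

DEFAULT_SCORE_RANGE = (0, 48)


@dataclass(frozen=True)
class PromModel:
    """OLS coefficients for the PROM regression.

    ``coef`` is ordered (PROM_pre, Age, Age^2, extra design columns...,
    intercept-if-included); ``covariate_names`` labels each slot. ``schema``
    describes how the extra covariates are encoded from a patient record.
    """

    coef: np.ndarray
    covariate_names: tuple[str, ...]
    schema: tuple[Term, ...] = field(default_factory=tuple)
    intercept_included: bool = True
    score_range: tuple[int, int] = DEFAULT_SCORE_RANGE

    def __post_init__(self):
        coef = np.asarray(self.coef, dtype=float).ravel()
        if coef.size != len(self.covariate_names):
            raise ValidationError(
                f"coefficient vector length {coef.size} does not match "
                f"{len(self.covariate_names)} design columns"
            )
        if self.score_range[0] > self.score_range[1]:
            raise ValidationError("score_range must be (low, high) with low <= high")
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "schema", tuple(self.schema))
        object.__setattr__(
            self, "score_range", (int(self.score_range[0]), int(self.score_range[1]))
        )

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "covariate_names": list(self.covariate_names),
            "schema": [t.to_dict() for t in self.schema],
            "intercept_included": self.intercept_included,
            "score_range": list(self.score_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PromModel":
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            covariate_names=tuple(d["covariate_names"]),
            schema=tuple(Term.from_dict(t) for t in d.get("schema", ())),
            intercept_included=d.get("intercept_included", True),
            score_range=tuple(d.get("score_range", DEFAULT_SCORE_RANGE)),
        )


def _design_names(schema: tuple[Term, ...], intercept: bool) -> tuple[str, ...]:
    names = ["prom_pre", "age", "age_sq", *schema_names(schema)]
    if intercept:
        names.append("intercept")
    return tuple(names)


def design_row(record, model: PromModel) -> CovariateVector:
    """Encode one patient record into the model's design vector.

    Order: (PROM_pre, Age, Age^2, extra covariates..., intercept). Age enters
    raw (years) and squared; every missing field is reported by name.
    """
    problems: dict[str, str] = {}
    prom_pre = getattr(record, "prom_pre", None) if not isinstance(record, dict) \
        else record.get("prom_pre")
    age = getattr(record, "age", None) if not isinstance(record, dict) \
        else record.get("age")
    if prom_pre is None or (isinstance(prom_pre, float) and math.isnan(prom_pre)):
        problems["prom_pre"] = "missing"
    if age is None or (isinstance(age, float) and math.isnan(age)):
        problems["age"] = "missing"
    extras = None
    if model.schema:
        try:
            extras = encode_record(record, model.schema)
        except ValidationError as err:
            problems.update(err.fields)
    if problems:
        raise ValidationError(
            "invalid PROM inputs: "
            + ", ".join(f"{k} ({v})" for k, v in problems.items()),
            fields=problems,
        )
    values = [float(prom_pre), float(age), float(age) ** 2]
    if extras is not None:
        values.extend(extras.values)
    if model.intercept_included:
        values.append(1.0)
    return CovariateVector(tuple(values), model.covariate_names)


def fit_prom(
    records,
    post_scores,
    schema: tuple[Term, ...] = (),
    intercept: bool = True,
    score_range: tuple[int, int] = DEFAULT_SCORE_RANGE,
) -> PromModel:
    """Fit the PROM regression by ordinary least squares.

    ``records`` supply PROM_pre, age and the schema covariates;
    ``post_scores`` are the observed post-operative scores. Raises a
    :class:`ValidationError` naming the collinear columns when the design is
    rank deficient.
    """
    names = _design_names(schema, intercept)
    probe = PromModel(
        coef=np.zeros(len(names)),
        covariate_names=names,
        schema=schema,
        intercept_included=intercept,
        score_range=score_range,
    )
    X = np.asarray([design_row(r, probe).values for r in records], dtype=float)
    y = np.asarray(post_scores, dtype=float)
    if X.shape[0] != y.size:
        raise ValidationError("records and post_scores must have equal length")
    if X.shape[0] < X.shape[1] + 1:
        raise ValidationError(
            f"need at least {X.shape[1] + 1} rows to fit {X.shape[1]} coefficients"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns past the numerical rank are the dependent ones
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise ValidationError(
            f"design matrix is rank deficient; collinear columns: {', '.join(bad)}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return PromModel(
        coef=coef,
        covariate_names=names,
        schema=schema,
        intercept_included=intercept,
        score_range=score_range,
    )


def predict_prom_raw(model: PromModel, record) -> float:
    """Unrounded linear prediction (used by validation metrics)."""
    return float(model.coef @ design_row(record, model).as_array())


def predict_prom(model: PromModel, record) -> int:
    """Predicted integer PROM score: round half-up, clamp to score_range."""
    raw = predict_prom_raw(model, record)
    score = math.floor(raw + 0.5)
    lo, hi = model.score_range
    return int(min(max(score, lo), hi))
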