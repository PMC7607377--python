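"""Covariate schema and design-vector encoding shared by all models.

A schema is an ordered tuple of :class:`Term` objects. Continuous terms may
carry a centre/scale (clinical models routinely centre age, say, per decade);
categorical terms are one-hot encoded against a declared reference level.
Terms marked ``clinic_only`` require input from a healthcare professional
(surgical choices such as implant fixation) and are forbidden in
community-facing model bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

__all__ = ["Term", "CovariateVector", "encode_record", "encode_table", "schema_names"]


@dataclass(frozen=True)
class Term:
    name: str
    kind: str = "continuous"  # "continuous" | "categorical"
    center: float = 0.0
    scale: float = 1.0
    reference: str | None = None
    levels: tuple[str, ...] = field(default_factory=tuple)
    clinic_only: bool = False

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValidationError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical":
            if self.reference is None or not self.levels:
                raise ValidationError(
                    f"categorical term {self.name!r} needs reference and levels"
                )
            if self.reference in self.levels:
                raise ValidationError(
                    f"term {self.name!r}: reference level must not appear in levels"
                )
        if self.scale == 0:
            raise ValidationError(f"term {self.name!r}: scale must be nonzero")

    @property
    def column_names(self) -> tuple[str, ...]:
        if self.kind == "continuous":
            return (self.name,)
        return tuple(f"{self.name}[{lvl}]" for lvl in self.levels)

    def encode(self, value) -> tuple[float, ...]:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValidationError(f"missing covariate {self.name!r}",
                                  fields={self.name: "missing"})
        if self.kind == "continuous":
            v = float(value)
            if not np.isfinite(v):
                raise ValidationError(f"non-finite covariate {self.name!r}",
                                      fields={self.name: "non-finite"})
            return ((v - self.center) / self.scale,)
        value = str(value)
        if value != self.reference and value not in self.levels:
            raise ValidationError(
                f"covariate {self.name!r}: unknown level {value!r}",
                fields={self.name: f"unknown level {value!r}"},
            )
        return tuple(1.0 if value == lvl else 0.0 for lvl in self.levels)

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind}
        if self.kind == "continuous":
            if self.center != 0.0:
                d["center"] = self.center
            if self.scale != 1.0:
                d["scale"] = self.scale
        else:
            d["reference"] = self.reference
            d["levels"] = list(self.levels)
        if self.clinic_only:
            d["clinic_only"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Term":
        return cls(
            name=d["name"],
            kind=d.get("kind", "continuous"),
            center=d.get("center", 0.0),
            scale=d.get("scale", 1.0),
            reference=d.get("reference"),
            levels=tuple(d.get("levels", ())),
            clinic_only=d.get("clinic_only", False),
        )


@dataclass(frozen=True)
class CovariateVector:
    """An encoded design vector with its column labels."""

    values: tuple[float, ...]
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValidationError("values and names must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("covariate values must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def schema_names(schema: tuple[Term, ...]) -> tuple[str, ...]:
    """Flattened design-column names for a schema."""
    names: list[str] = []
    for term in schema:
        names.extend(term.column_names)
    return tuple(names)


def _get(record, name):
    if isinstance(record, Mapping):
        return record.get(name)
    if hasattr(record, name):
        return getattr(record, name)
    extras = getattr(record, "extras", None)
    if extras is not None:
        return extras.get(name)
    return None


def encode_record(record, schema: tuple[Term, ...]) -> CovariateVector:
    """Encode a single record (mapping or PatientRecord) into a design vector.

    Collects *all* missing/invalid fields before raising so that a request
    form can report every problem at once.
    """
    values: list[float] = []
    names: list[str] = []
    problems: dict[str, str] = {}
    for term in schema:
        try:
            values.extend(term.encode(_get(record, term.name)))
            names.extend(term.column_names)
        except ValidationError as err:
            problems.update(err.fields or {term.name: str(err)})
    if problems:
        raise ValidationError(
            "invalid covariates: " + ", ".join(f"{k} ({v})" for k, v in problems.items()),
            fields=problems,
        )
    return CovariateVector(tuple(values), tuple(names))


def encode_table(records, schema: tuple[Term, ...]) -> np.ndarray:
    """Encode a sequence of records into an ``(n, p)`` design matrix."""
    rows = [encode_record(r, schema).values for r in records]
    return np.asarray(rows, dtype=float).reshape(len(rows), len(schema_names(schema)))
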