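"""Model registry and the end-to-end personalised risk calculation.

A :class:`ModelBundle` packages the three fitted models for one surgery
group — PROM regression, mortality survival model, revision survival model —
together with the shared covariate schema, and is keyed by
``(surgery_group, model_type, dataset_version)``. Bundles serialise to a
human-auditable JSON file so the coefficients driving a clinical prediction
can always be inspected.

:func:`calculate` runs the full pipeline for one patient request: validate
the inputs against the same rules used to filter training cohorts, select
the bundle, predict the PROM score, and evaluate yearly cumulative mortality
and revision risks (converted to probabilities via 1 - exp(-Lambda)). The
headline figures are mortality within one year and revision within ten.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import filters as _filters
from .covariates import Term, encode_record, schema_names
from .errors import (
    BundleFormatError,
    RegistryIntegrityError,
    RegistryLookupError,
    ValidationError,
)
from .filters import SURGERY_GROUPS, PatientRecord
from .prom import PromModel, predict_prom
from .survival import FlexPHModel, event_probability

__all__ = [
    "ModelBundle",
    "RiskCurve",
    "ResultSet",
    "ModelRegistry",
    "select_models",
    "calculate",
    "load_bundle",
    "save_bundle",
]

BUNDLE_FORMAT_VERSION = "1"
MODEL_TYPES = ("community", "clinic")
DEFAULT_HORIZON_YEARS = 10
MORTALITY_HEADLINE_YEAR = 1
REVISION_HEADLINE_YEAR = 10


@dataclass(frozen=True)
class RiskCurve:
    """Cumulative event probability at integer year horizons."""

    years: tuple[int, ...]
    cumulative_risk: tuple[float, ...]

    def __post_init__(self):
        if len(self.years) != len(self.cumulative_risk):
            raise ValidationError("years and cumulative_risk must align")
        if any(not (0.0 <= p <= 1.0) for p in self.cumulative_risk):
            raise ValidationError("risks must lie in [0, 1]")
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(
            self, "cumulative_risk", tuple(float(p) for p in self.cumulative_risk)
        )

    def at(self, year: int) -> float:
        try:
            return self.cumulative_risk[self.years.index(year)]
        except ValueError:
            raise ValidationError(f"year {year} not in curve horizon") from None

    def to_dict(self) -> dict:
        return {str(y): r for y, r in zip(self.years, self.cumulative_risk)}


@dataclass(frozen=True)
class ResultSet:
    """Output of one personalised calculation."""

    prom_score: int
    mortality: RiskCurve
    revision: RiskCurve

    def __post_init__(self):
        # headline years must be present
        self.mortality.at(MORTALITY_HEADLINE_YEAR)
        self.revision.at(REVISION_HEADLINE_YEAR)

    @property
    def headline(self) -> dict:
        return {
            "prom_score": self.prom_score,
            "mortality_1yr": self.mortality.at(MORTALITY_HEADLINE_YEAR),
            "revision_10yr": self.revision.at(REVISION_HEADLINE_YEAR),
        }

    def to_dict(self) -> dict:
        return {
            "prom_score": self.prom_score,
            "mortality": self.mortality.to_dict(),
            "revision": self.revision.to_dict(),
            "headline": self.headline,
        }


@dataclass(frozen=True)
class ModelBundle:
    """The (PROM, mortality, revision) model triple for one surgery group."""

    surgery_group: str
    model_type: str
    dataset_version: str
    schema: tuple[Term, ...]
    prom: PromModel
    mortality: FlexPHModel
    revision: FlexPHModel

    def __post_init__(self):
        if self.surgery_group not in SURGERY_GROUPS:
            raise ValidationError(
                f"unknown surgery_group {self.surgery_group!r}"
            )
        if self.model_type not in MODEL_TYPES:
            raise ValidationError(f"unknown model_type {self.model_type!r}")
        object.__setattr__(self, "schema", tuple(self.schema))
        names = schema_names(self.schema)
        for label, model in (("mortality", self.mortality), ("revision", self.revision)):
            if model.covariate_names and tuple(model.covariate_names) != names:
                raise RegistryIntegrityError(
                    f"{label} model covariates {model.covariate_names} do not "
                    f"match bundle schema columns {names}"
                )
        if self.model_type == "community":
            clinic = [t.name for t in self.schema if t.clinic_only]
            if clinic:
                raise RegistryIntegrityError(
                    "community bundle must not require clinic-only covariates: "
                    + ", ".join(clinic)
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.surgery_group, self.model_type, self.dataset_version)


class ModelRegistry:
    """In-memory collection of bundles keyed by (group, type, version).

    Version ordering for "latest" is lexicographic on the version string
    (so ``v2 > v1``, ``2024-06 > 2024-01``).
    """

    def __init__(self, bundles=()):
        self._bundles: dict[tuple[str, str, str], ModelBundle] = {}
        for b in bundles:
            self.add(b)

    def add(self, bundle: ModelBundle) -> None:
        if bundle.key in self._bundles:
            raise RegistryIntegrityError(f"duplicate bundle key {bundle.key}")
        self._bundles[bundle.key] = bundle

    def keys(self):
        return sorted(self._bundles)

    def __len__(self):
        return len(self._bundles)

    def select(self, surgery_group: str, model_type: str,
               dataset_version: str | None = None) -> ModelBundle:
        if dataset_version is not None:
            try:
                return self._bundles[(surgery_group, model_type, dataset_version)]
            except KeyError:
                raise RegistryLookupError(
                    f"no bundle for ({surgery_group!r}, {model_type!r}, "
                    f"{dataset_version!r}); available: {self.keys()}"
                ) from None
        candidates = [
            b for b in self._bundles.values()
            if b.surgery_group == surgery_group and b.model_type == model_type
        ]
        if not candidates:
            raise RegistryLookupError(
                f"no bundle for ({surgery_group!r}, {model_type!r}); "
                f"available: {self.keys()}"
            )
        return max(candidates, key=lambda b: b.dataset_version)


def select_models(registry: ModelRegistry, surg_type: str, model_type: str,
                  dsver: str | None = None) -> ModelBundle:
    """Select the bundle for a surgery group / model type / dataset version."""
    return registry.select(surg_type, model_type, dsver)


def _validate_request(record: PatientRecord, bundle: ModelBundle) -> None:
    problems: dict[str, str] = {}
    required = ["age", "sex", "bmi", "asa", "surgery_group", "prom_pre"]
    for name in required:
        if getattr(record, name, None) is None:
            problems[name] = "missing"
    if "age" not in problems and not (
        _filters.AGE_RANGE[0] <= float(record.age) <= _filters.AGE_RANGE[1]
    ):
        problems["age"] = f"outside [{_filters.AGE_RANGE[0]:g}, {_filters.AGE_RANGE[1]:g}]"
    if "asa" not in problems and int(record.asa) not in _filters.ASA_ALLOWED:
        problems["asa"] = f"not in {_filters.ASA_ALLOWED}"
    if "bmi" not in problems and not (
        _filters.BMI_RANGE[0] <= float(record.bmi) <= _filters.BMI_RANGE[1]
    ):
        problems["bmi"] = f"outside [{_filters.BMI_RANGE[0]:g}, {_filters.BMI_RANGE[1]:g}]"
    if "surgery_group" not in problems and record.surgery_group != bundle.surgery_group:
        problems["surgery_group"] = (
            f"request is for {record.surgery_group!r} but bundle covers "
            f"{bundle.surgery_group!r}"
        )
    # schema completeness (clinic covariates etc.)
    if not problems:
        try:
            encode_record(record, bundle.schema)
        except ValidationError as err:
            problems.update(err.fields)
    if problems:
        raise ValidationError(
            "invalid request: "
            + "; ".join(f"{k}: {v}" for k, v in sorted(problems.items())),
            fields=problems,
        )


def _risk_curve(model: FlexPHModel, x, horizon: int) -> RiskCurve:
    years = tuple(range(1, horizon + 1))
    risks = tuple(float(event_probability(model, x, float(t))) for t in years)
    return RiskCurve(years, risks)


def calculate(request: PatientRecord, bundle: ModelBundle | None = None,
              registry: ModelRegistry | None = None,
              model_type: str = "community",
              dataset_version: str | None = None,
              horizon_years: int = DEFAULT_HORIZON_YEARS) -> ResultSet:
    """Run the full personalised calculation for one patient request.

    Either pass a ``bundle`` directly, or a ``registry`` from which the
    bundle is selected using the request's surgery group. The request is
    validated first (same ranges as the cohort filters plus completeness for
    the bundle's covariate schema); validation failure raises before any
    model is evaluated, so a partial result is never produced. The function
    is deterministic: identical requests yield identical results.
    """
    if bundle is None:
        if registry is None:
            raise ValidationError("either bundle or registry must be provided")
        if request.surgery_group is None:
            raise ValidationError("request must specify surgery_group",
                                  fields={"surgery_group": "missing"})
        bundle = registry.select(request.surgery_group, model_type, dataset_version)
    _validate_request(request, bundle)
    x = encode_record(request, bundle.schema)
    prom_score = predict_prom(bundle.prom, request)
    mortality = _risk_curve(bundle.mortality, x, horizon_years)
    revision = _risk_curve(bundle.revision, x, horizon_years)
    return ResultSet(prom_score=prom_score, mortality=mortality, revision=revision)


# --- bundle serialisation ---------------------------------------------------

def _require(d: dict, key: str, where: str):
    if key not in d:
        raise BundleFormatError(f"bundle file missing {key!r} in {where}")
    return d[key]


def bundle_to_dict(bundle: ModelBundle) -> dict:
    return {
        "format_version": BUNDLE_FORMAT_VERSION,
        "surgery_group": bundle.surgery_group,
        "model_type": bundle.model_type,
        "dataset_version": bundle.dataset_version,
        "schema": [t.to_dict() for t in bundle.schema],
        "prom": bundle.prom.to_dict(),
        "mortality": bundle.mortality.to_dict(),
        "revision": bundle.revision.to_dict(),
    }


def bundle_from_dict(d: dict) -> ModelBundle:
    version = _require(d, "format_version", "bundle")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleFormatError(
            f"unsupported bundle format_version {version!r}; "
            f"this build reads version {BUNDLE_FORMAT_VERSION!r}"
        )
    surv = {}
    for label in ("mortality", "revision"):
        sub = _require(d, label, "bundle")
        for key in ("beta", "gamma", "knots"):
            _require(sub, key, label)
        surv[label] = FlexPHModel.from_dict(sub)
    prom_dict = _require(d, "prom", "bundle")
    _require(prom_dict, "coef", "prom")
    return ModelBundle(
        surgery_group=_require(d, "surgery_group", "bundle"),
        model_type=_require(d, "model_type", "bundle"),
        dataset_version=_require(d, "dataset_version", "bundle"),
        schema=tuple(Term.from_dict(t) for t in _require(d, "schema", "bundle")),
        prom=PromModel.from_dict(prom_dict),
        mortality=surv["mortality"],
        revision=surv["revision"],
    )


def save_bundle(bundle: ModelBundle, path) -> None:
    """Write a bundle as JSON; floats round-trip bit-exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle_to_dict(bundle), fh, indent=2)
        fh.write("\n")


def load_bundle(path) -> ModelBundle:
    try:
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
    except json.JSONDecodeError as err:
        raise BundleFormatError(
            f"malformed bundle file {path}: {err.msg} at line {err.lineno}, "
            f"column {err.colno}"
        ) from err
    if not isinstance(d, dict):
        raise BundleFormatError(f"bundle file {path} must contain a JSON object")
    return bundle_from_dict(d)
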