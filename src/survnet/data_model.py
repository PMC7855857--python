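"""Censored cohorts with missing covariates, and their numeric encoding.

A cohort is a list of :class:`PatientRecord` triplets (covariates, event
state, survival time) described by a :class:`CohortSchema`.  Encoding maps it
to the numeric form the network consumes: a covariate matrix ``X`` where
categorical labels become nonzero integer codes, continuous values are
standardized on observed training values, and missing entries are zero-filled
with a companion indicator matrix ``R`` (``R=0`` marks missing, and zero is
reserved exclusively for missingness — category codes are never zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

CovariateValue = Union[float, int, str, None]


class SchemaError(ValueError):
    """A record or configuration does not conform to the cohort schema."""


class CohortValidationError(ValueError):
    """A cohort-level invariant (times, events, shapes) is violated."""


def symmetric_codes(n_levels: int) -> tuple[int, ...]:
    """Integer category codes symmetric around zero, skipping zero.

    Zero is reserved for "missing", so codes are consecutive integers
    starting at ``-(n_levels // 2)`` with 0 skipped, e.g. ``(-1, 1)`` for two
    levels, ``(-2, -1, 1, 2)`` for four and ``(-2, -1, 1, 2, 3)`` for five.
    """
    if n_levels < 2:
        raise ValueError("a categorical covariate needs at least 2 levels")
    codes: list[int] = []
    i = -(n_levels // 2)
    while len(codes) < n_levels:
        if i != 0:
            codes.append(i)
        i += 1
    return tuple(codes)


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: a name, a kind, and (for categoricals) a code map."""

    name: str
    kind: str  # "continuous" | "categorical"
    codes: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.codes:
                raise SchemaError(f"covariate {self.name!r}: categorical without codes")
            values = list(self.codes.values())
            if len(set(values)) != len(values):
                raise SchemaError(f"covariate {self.name!r}: duplicate category codes")
            if any(v == 0 for v in values):
                raise SchemaError(
                    f"covariate {self.name!r}: code 0 is reserved for missing values"
                )
        elif self.codes is not None:
            raise SchemaError(f"covariate {self.name!r}: continuous covariate has codes")


@dataclass(frozen=True)
class CohortSchema:
    """Ordered covariate descriptors shared by every record of a cohort."""

    covariates: tuple[CovariateSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate covariate names in schema")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    def continuous_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates if c.kind == "continuous")


@dataclass(frozen=True)
class PatientRecord:
    """One subject: covariate values (``None`` = absent), time and event.

    ``values`` is ordered to match the cohort schema.  ``time`` is the
    observed survival time in months (positive); ``event`` is 1 when death
    was observed and 0 for censored subjects.
    """

    id: str
    values: tuple[CovariateValue, ...]
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise CohortValidationError(
                f"record {self.id!r}: time must be positive, got {self.time}"
            )
        if self.event not in (0, 1):
            raise CohortValidationError(
                f"record {self.id!r}: event must be 0 or 1, got {self.event}"
            )


@dataclass(frozen=True)
class StandardizationStats:
    """Per-continuous-covariate location/scale learned on observed training values."""

    location: dict[str, float]
    scale: dict[str, float]


@dataclass
class EncodedCohort:
    """Numeric cohort: covariate matrix, missingness indicators, outcomes.

    Invariants: ``R`` is binary, ``X`` is exactly zero wherever ``R`` is zero,
    and all arrays share the leading dimension.
    """

    X: np.ndarray
    R: np.ndarray
    t: np.ndarray
    s: np.ndarray
    ids: tuple[str, ...]
    standardization_stats: Optional[StandardizationStats] = None
    schema: Optional[CohortSchema] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = self.X.shape[0]
        if not (self.R.shape == self.X.shape and self.t.shape == (n,)
                and self.s.shape == (n,) and len(self.ids) == n):
            raise CohortValidationError("X, R, t, s, ids must share leading dimension")
        if not np.isin(self.R, (0.0, 1.0)).all():
            raise CohortValidationError("R must be binary")
        if np.any(self.X * (1.0 - self.R) != 0.0):
            raise CohortValidationError("X must be zero wherever R is zero")
        if np.any(self.t <= 0):
            raise CohortValidationError("times must be positive")
        if not np.isin(self.s, (0.0, 1.0)).all():
            raise CohortValidationError("events must be binary")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, index: np.ndarray) -> "EncodedCohort":
        """Row subset sharing schema and standardization stats."""
        index = np.asarray(index)
        return EncodedCohort(
            X=self.X[index].copy(),
            R=self.R[index].copy(),
            t=self.t[index].copy(),
            s=self.s[index].copy(),
            ids=tuple(np.asarray(self.ids, dtype=object)[index]),
            standardization_stats=self.standardization_stats,
            schema=self.schema,
        )


def _compute_stats(
    records: Sequence[PatientRecord], schema: CohortSchema
) -> StandardizationStats:
    location: dict[str, float] = {}
    scale: dict[str, float] = {}
    for j, spec in enumerate(schema.covariates):
        if spec.kind != "continuous":
            continue
        observed = [float(r.values[j]) for r in records if r.values[j] is not None]
        if not observed:
            raise CohortValidationError(
                f"covariate {spec.name!r}: no observed values to compute "
                "standardization statistics"
            )
        arr = np.asarray(observed, dtype=float)
        loc = float(arr.mean())
        # sample (n-1) convention; a single observation has undefined spread
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        if sd == 0.0:
            warnings.warn(
                f"covariate {spec.name!r}: zero observed spread, using scale 1.0",
                stacklevel=3,
            )
            sd = 1.0
        location[spec.name] = loc
        scale[spec.name] = sd
    return StandardizationStats(location=location, scale=scale)


def encode_cohort(
    records: Sequence[PatientRecord],
    schema: CohortSchema,
    stats: Optional[StandardizationStats] = None,
    standardize: bool = True,
) -> EncodedCohort:
    """Encode records into the zero-filled numeric form.

    Continuous covariates are standardized to zero location / unit scale
    using observed entries only; when ``stats`` is omitted they are computed
    from these records (training mode) and returned on the cohort so that
    validation/test encoding can reuse them.  Categorical labels are mapped
    through the schema's code maps.  Absent entries become ``X = 0, R = 0``.
    """
    if not records:
        raise CohortValidationError("cannot encode an empty cohort")
    p = schema.n_covariates
    for r in records:
        if len(r.values) != p:
            raise SchemaError(
                f"record {r.id!r}: {len(r.values)} covariates, schema has {p}"
            )
    if standardize and stats is None:
        stats = _compute_stats(records, schema)

    n = len(records)
    X = np.zeros((n, p))
    R = np.zeros((n, p))
    for i, rec in enumerate(records):
        for j, spec in enumerate(schema.covariates):
            v = rec.values[j]
            if v is None:
                continue
            if spec.kind == "categorical":
                if v not in spec.codes:  # type: ignore[operator]
                    raise SchemaError(
                        f"covariate {spec.name!r}: unknown category label {v!r}"
                    )
                X[i, j] = spec.codes[v]  # type: ignore[index]
            else:
                x = float(v)
                if standardize:
                    x = (x - stats.location[spec.name]) / stats.scale[spec.name]
                X[i, j] = x
            R[i, j] = 1.0
    # a standardized value may land exactly on 0; nudge R bookkeeping is not
    # allowed, so keep the entry but note it is observed (R=1 already set).
    X[R == 0.0] = 0.0
    return EncodedCohort(
        X=X,
        R=R,
        t=np.asarray([r.time for r in records], dtype=float),
        s=np.asarray([r.event for r in records], dtype=float),
        ids=tuple(r.id for r in records),
        standardization_stats=stats,
        schema=schema,
    )


def decode_cohort(cohort: EncodedCohort, schema: CohortSchema) -> list[PatientRecord]:
    """Invert :func:`encode_cohort` (missing entries come back as ``None``)."""
    stats = cohort.standardization_stats
    records = []
    inverse = [
        {code: label for label, code in spec.codes.items()}
        if spec.kind == "categorical" else None
        for spec in schema.covariates
    ]
    for i in range(cohort.n):
        values: list[CovariateValue] = []
        for j, spec in enumerate(schema.covariates):
            if cohort.R[i, j] == 0.0:
                values.append(None)
            elif spec.kind == "categorical":
                values.append(inverse[j][int(cohort.X[i, j])])
            else:
                x = cohort.X[i, j]
                if stats is not None and spec.name in stats.location:
                    x = x * stats.scale[spec.name] + stats.location[spec.name]
                values.append(float(x))
        records.append(
            PatientRecord(
                id=cohort.ids[i],
                values=tuple(values),
                time=float(cohort.t[i]),
                event=int(cohort.s[i]),
            )
        )
    return records


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    remainder = n - sum(sizes)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for k in range(remainder):
        sizes[order[k]] += 1
    return sizes


def split_cohort(
    cohort: EncodedCohort,
    fractions: Sequence[float],
    seed: int,
) -> tuple[EncodedCohort, EncodedCohort, EncodedCohort]:
    """Random, disjoint, exhaustive three-way row partition.

    Partition sizes follow largest-remainder rounding of ``fractions``;
    the permutation is deterministic given ``seed``.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must have exactly three entries")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if cohort.n < 3:
        raise CohortValidationError("need at least 3 rows to split")
    sizes = _largest_remainder_sizes(cohort.n, fractions)
    if any(sz == 0 for sz in sizes):
        raise CohortValidationError(f"split produces an empty partition: sizes {sizes}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    bounds = np.cumsum(sizes)
    parts = (
        cohort.subset(np.sort(perm[: bounds[0]])),
        cohort.subset(np.sort(perm[bounds[0]: bounds[1]])),
        cohort.subset(np.sort(perm[bounds[1]:])),
    )
    return parts
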