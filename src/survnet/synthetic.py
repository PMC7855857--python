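"""Synthetic censored cohorts with known ground-truth risk.

The generative model is Weibull proportional hazards: covariates are drawn
(continuous standard normal, categorical uniform over their integer codes),
the true log-hazard is a linear predictor plus optional interaction terms,
and event times come from inverse-transform sampling with rate multiplier
``exp(eta)``.  Independent exponential censoring is calibrated by bisection
so the realized censored fraction approaches a target; an administrative
follow-up cap truncates long times.  Per-entry MCAR masking then removes
covariate values.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .data_model import (
    CohortSchema,
    CovariateSpec,
    PatientRecord,
    symmetric_codes,
)

#: level counts for the default 7 categorical covariates (a 9-covariate
#: schema with 2 continuous ones, mirroring a mixed clinical table).
DEFAULT_CATEGORICAL_LEVELS: tuple[int, ...] = (2, 5, 2, 2, 2, 2, 2)

DEFAULT_BETA: tuple[float, ...] = (1.0, -1.0, 0.8, -0.3, 0.5, -0.5, 0.4, -0.4, 0.3)


@dataclass(frozen=True)
class InteractionTerm:
    """A nonlinear log-hazard term: product of one or two covariate columns.

    ``kind`` is ``"product"`` (x_a * x_b) or ``"square"`` (x_a ** 2).
    Indices refer to encoded covariate columns.
    """

    kind: str
    indices: tuple[int, ...]
    coefficient: float

    def __post_init__(self) -> None:
        if self.kind not in ("product", "square"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        want = 2 if self.kind == "product" else 1
        if len(self.indices) != want:
            raise ValueError(f"{self.kind} term needs {want} indices")


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 1000
    p_continuous: int = 2
    p_categorical: int = 7
    categorical_levels: Optional[tuple[int, ...]] = None
    beta: Optional[tuple[float, ...]] = None
    nonlinear_terms: tuple[InteractionTerm, ...] = ()
    weibull_shape: float = 1.5
    weibull_scale: float = 60.0
    censor_rate_target: float = 0.0
    missing_rate: float = 0.0
    admin_cap: float = float("inf")
    covariate_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.censor_rate_target < 1.0):
            raise ValueError("censor_rate_target must be in [0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if not (0.0 <= self.covariate_correlation < 1.0):
            raise ValueError("covariate_correlation must be in [0, 1)")
        if self.p_continuous < 0 or self.p_categorical < 0:
            raise ValueError("covariate counts must be nonnegative")
        if self.p_continuous + self.p_categorical < 1:
            raise ValueError("need at least one covariate")
        levels = self.levels
        if len(levels) != self.p_categorical:
            raise ValueError("categorical_levels length must equal p_categorical")
        if self.beta is not None and len(self.beta) != self.p_total:
            raise ValueError("beta length must equal total covariate count")

    @property
    def p_total(self) -> int:
        return self.p_continuous + self.p_categorical

    @property
    def levels(self) -> tuple[int, ...]:
        if self.categorical_levels is not None:
            return self.categorical_levels
        base = DEFAULT_CATEGORICAL_LEVELS
        out = tuple(base[i % len(base)] for i in range(self.p_categorical))
        return out

    @property
    def coefficients(self) -> np.ndarray:
        if self.beta is not None:
            return np.asarray(self.beta, dtype=float)
        base = DEFAULT_BETA
        return np.asarray([base[i % len(base)] for i in range(self.p_total)])


def make_schema(config: SimulationConfig) -> CohortSchema:
    """The cohort schema implied by a simulation config."""
    specs = [
        CovariateSpec(name=f"cont{i + 1}", kind="continuous")
        for i in range(config.p_continuous)
    ]
    for i, k in enumerate(config.levels):
        codes = {f"L{c}": c for c in symmetric_codes(k)}
        specs.append(CovariateSpec(name=f"cat{i + 1}", kind="categorical", codes=codes))
    return CohortSchema(covariates=tuple(specs))


@dataclass
class SimulatedCohort:
    """Simulation output: raw records, schema, and the true per-subject risk."""

    records: list[PatientRecord]
    schema: CohortSchema
    true_log_hazard: np.ndarray


def _calibrate_censoring_rate(
    event_times: np.ndarray, target: float, admin_cap: float
) -> float:
    """Exponential censoring rate whose expected censored fraction hits ``target``.

    The administrative cap participates in the objective: a subject is
    censored when the exponential time undercuts the event time or the event
    time exceeds the cap.  Monotone in the rate, solved by bisection.
    """

    def censored_fraction(rate: float) -> float:
        prob = np.where(
            event_times > admin_cap, 1.0, 1.0 - np.exp(-rate * event_times)
        )
        return float(prob.mean())

    if censored_fraction(0.0) >= target:
        return 0.0
    lo, hi = 0.0, 1.0
    while censored_fraction(hi) < target and hi < 1e12:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a cohort from the Weibull proportional-hazards model."""
    rng = np.random.default_rng(config.seed)
    schema = make_schema(config)
    n, p = config.n, config.p_total

    X = np.zeros((n, p))
    rho = config.covariate_correlation
    if rho > 0.0:
        # single latent factor: marginals stay standard normal / uniform
        # over codes, but covariates become mutually informative (so the
        # reconstruction task has signal to exploit under missingness)
        factor = rng.standard_normal((n, 1))
        latent = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * rng.standard_normal(
            (n, p)
        )
        if config.p_continuous:
            X[:, : config.p_continuous] = latent[:, : config.p_continuous]
        for i, k in enumerate(config.levels):
            codes = np.asarray(symmetric_codes(k), dtype=float)
            col = config.p_continuous + i
            u = sps.norm.cdf(latent[:, col])
            X[:, col] = codes[np.minimum((u * k).astype(int), k - 1)]
    else:
        if config.p_continuous:
            X[:, : config.p_continuous] = rng.standard_normal(
                (n, config.p_continuous)
            )
        for i, k in enumerate(config.levels):
            codes = np.asarray(symmetric_codes(k), dtype=float)
            col = config.p_continuous + i
            X[:, col] = rng.choice(codes, size=n)

    eta = X @ config.coefficients
    for term in config.nonlinear_terms:
        if term.kind == "product":
            a, b = term.indices
            eta = eta + term.coefficient * X[:, a] * X[:, b]
        else:
            (a,) = term.indices
            eta = eta + term.coefficient * X[:, a] ** 2

    # inverse-transform Weibull PH: S(t|eta) = exp(-(t/scale)^shape * e^eta)
    u = rng.uniform(size=n)
    event_times = config.weibull_scale * (
        -np.log(u) / np.exp(eta)
    ) ** (1.0 / config.weibull_shape)
    event_times = np.maximum(event_times, 1e-8)

    if config.censor_rate_target > 0.0:
        rate = _calibrate_censoring_rate(
            event_times, config.censor_rate_target, config.admin_cap
        )
        censor_times = (
            rng.exponential(1.0 / rate, size=n) if rate > 0 else np.full(n, np.inf)
        )
    else:
        censor_times = np.full(n, np.inf)
    censor_times = np.minimum(censor_times, config.admin_cap)

    observed = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    observed = np.maximum(observed, 1e-8)

    missing = (
        rng.uniform(size=(n, p)) < config.missing_rate
        if config.missing_rate > 0.0
        else np.zeros((n, p), dtype=bool)
    )

    records = []
    for i in range(n):
        values: list = []
        for j, spec in enumerate(schema.covariates):
            if missing[i, j]:
                values.append(None)
            elif spec.kind == "continuous":
                values.append(float(X[i, j]))
            else:
                values.append(f"L{int(X[i, j])}")
        records.append(
            PatientRecord(
                id=f"P{i:06d}",
                values=tuple(values),
                time=float(observed[i]),
                event=int(events[i]),
            )
        )
    return SimulatedCohort(records=records, schema=schema, true_log_hazard=eta)


def oracle_cindex(
    true_log_hazard: np.ndarray, t: np.ndarray, s: np.ndarray
) -> float:
    """Concordance of the true risk against the simulated outcomes.

    This is the ceiling any fitted model can approach on the cohort.
    """
    from .evaluation import concordance_index

    return concordance_index(true_log_hazard, t, s)
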