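"""Core model: normalization to D and closed-form rate relations.

Reversible phenotypic plasticity ("acclimation" in the thermal-biology
literature) moves a trait from the value expressed in an initial environment,
``z0``, towards the value expressed after full acclimation to a new
environment, ``z_inf``.  The proportion of the full plastic response still
remaining at time ``t`` after transfer is

    D(t) = (z_t - z_inf) / (z0 - z_inf),

which equals 1 at the reference point and decays towards 0 as the organism
acclimates.  Under first-order kinetics, dD/dt = -lam * D, so
D(t) = exp(-lam * t) and a single observation gives lam = -ln(D)/t.  When the
approach is instead linear, D(t) = max(1 - lam*t, 0) and lam = (1 - D)/t.
``lam`` (written λ in the literature) has units of inverse time; the time for
the remaining deviation to halve is ln(2)/lam under exponential decay.

This module is pure computation: no file formats, no fitting. Datasets are
small (tens to hundreds of rows), so clarity beats vectorization throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    DataValidationError,
    DesignError,
    EstimatorDomainError,
    NonMonotoneWarning,
    NoPlasticResponseError,
    SingleControlWarning,
)

GroupLabel = Literal["initial_control", "new_control", "shifted"]
GROUP_LABELS: tuple[str, ...] = ("initial_control", "new_control", "shifted")

Shape = Literal["exponential", "linear"]
SHAPES: tuple[str, ...] = ("exponential", "linear")

Z0Policy = Literal["earliest_shifted", "initial_control"]
ZinfPolicy = Literal["new_control", "last_shifted"]


@dataclass(frozen=True)
class Record:
    """One phenotype measurement.

    ``time`` is time since transfer to the new environment for the shifted
    group; control records carry their measurement time but are pooled.
    """

    group: str
    time: float
    phenotype: float
    replicate_id: str = ""

    def __post_init__(self):
        if self.group not in GROUP_LABELS:
            raise DataValidationError(
                f"unknown group label {self.group!r}; allowed: {GROUP_LABELS}",
                group=self.group,
            )
        if not math.isfinite(self.time) or self.time < 0:
            raise DataValidationError(f"time must be finite and >= 0, got {self.time!r}")
        if not math.isfinite(self.phenotype):
            raise DataValidationError(f"phenotype must be finite, got {self.phenotype!r}")


@dataclass
class AcclimationDataset:
    """Long-format acclimation experiment: grouped phenotype measurements over time."""

    records: list[Record]
    time_unit: str = "h"
    trait_name: str = "phenotype"

    def __post_init__(self):
        self.records = [
            r if isinstance(r, Record) else Record(*r) for r in self.records
        ]

    # -- accessors -------------------------------------------------------
    def group_values(self, group: str) -> np.ndarray:
        return np.array([r.phenotype for r in self.records if r.group == group], float)

    def shifted_times(self) -> np.ndarray:
        """Distinct shifted-group measurement times, sorted ascending."""
        return np.unique([r.time for r in self.records if r.group == "shifted"])

    def shifted_at(self, t: float) -> np.ndarray:
        return np.array(
            [r.phenotype for r in self.records if r.group == "shifted" and r.time == t],
            float,
        )

    def has_group(self, group: str) -> bool:
        return any(r.group == group for r in self.records)

    def validate(self, require_dual_control: bool = False) -> None:
        if not self.records:
            raise DataValidationError("dataset has no records")
        if len(self.shifted_times()) < 2:
            raise DataValidationError(
                "shifted group must be measured at >= 2 distinct time points"
            )
        if require_dual_control:
            for g in GROUP_LABELS:
                if not self.has_group(g):
                    raise DesignError(
                        f"group {g!r} is missing; estimating the true rate of "
                        "plasticity requires two control groups, one acclimated "
                        "to the initial environment and one acclimated to the "
                        "new environment",
                        missing_group=g,
                    )

    def pooled_within_group_sd(self) -> float:
        """Pooled SD of residuals around each group/time-point mean."""
        ss, df = 0.0, 0
        cells: dict[tuple[str, float], list[float]] = {}
        for r in self.records:
            key = (r.group, r.time if r.group == "shifted" else -1.0)
            cells.setdefault(key, []).append(r.phenotype)
        for vals in cells.values():
            if len(vals) > 1:
                v = np.asarray(vals)
                ss += float(np.sum((v - v.mean()) ** 2))
                df += len(vals) - 1
        return math.sqrt(ss / df) if df > 0 else 0.0


@dataclass
class NormalizedSeries:
    """(t, D) pairs plus the reference phenotypes that produced them.

    Times are re-referenced so the earliest shifted measurement is t = 0;
    under the default z0 policy the first point is exactly (0, 1).
    """

    times: np.ndarray
    d: np.ndarray
    z0: float
    z_inf: float
    n_per_point: np.ndarray
    time_unit: str = "h"
    trait_name: str = "phenotype"
    replicate_level: bool = False  # tied times allowed in replicate-level mode

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.d = np.asarray(self.d, float)
        self.n_per_point = np.asarray(self.n_per_point, int)
        if self.z0 == self.z_inf:
            raise DataValidationError("z0 and z_inf must differ")
        diffs = np.diff(self.times)
        if self.replicate_level:
            if not np.all(diffs >= 0):
                raise DataValidationError("times must be non-decreasing")
        elif not np.all(diffs > 0):
            raise DataValidationError("times must be strictly increasing")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.d.tolist()))

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RateFit:
    """One fitted response shape: the rate, its fit quality and derived half-time."""

    shape: str
    lam: float
    rse: float
    n_points: int
    residuals: list[float] = field(default_factory=list)
    half_time: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise DataValidationError(f"unknown shape {self.shape!r}")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_series(
    dataset: AcclimationDataset,
    z0_policy: Z0Policy = "earliest_shifted",
    zinf_policy: ZinfPolicy = "new_control",
    response_tolerance: float = 0.1,
    replicate_level: bool = False,
) -> NormalizedSeries:
    """Normalize a time course to the proportion of the response remaining.

    Parameters
    ----------
    dataset
        Validated acclimation experiment.
    z0_policy
        ``"earliest_shifted"`` (default): z0 is the mean shifted phenotype at
        the earliest post-shift time point — the first measurement in the new
        environment.  ``"initial_control"``: use the initial-environment
        control mean instead (the anchor D(0) = 1 then no longer holds
        exactly in noisy data).
    zinf_policy
        ``"new_control"`` (default): z_inf is the mean of the control group
        fully acclimated to the new environment.  ``"last_shifted"`` (opt-in,
        warns): use the final shifted time point's mean, for re-analysis of
        legacy single-control studies; it biases the rate if acclimation was
        incomplete.
    response_tolerance
        |z0 - z_inf| must exceed this multiple of the pooled within-group SD,
        otherwise there is no detectable plastic response to normalize by.
    replicate_level
        If True, emit one (t, D) point per replicate instead of per
        time-point mean (times within a time point are then tied, so the
        result is returned per-replicate via repeated times and the strict
        monotonicity invariant is relaxed to non-decreasing).

    Returns one (t, D) point per distinct shifted time point (default mode),
    D computed from per-time-point mean phenotypes.
    """
    dataset.validate()
    if zinf_policy == "new_control" and not dataset.has_group("new_control"):
        raise DesignError(
            "no new_control group: estimating z_inf requires a second control "
            "group fully acclimated to the new environment (dual-control "
            "design); pass zinf_policy='last_shifted' to opt out",
            missing_group="new_control",
        )
    if z0_policy == "initial_control" and not dataset.has_group("initial_control"):
        raise DesignError("z0_policy='initial_control' but no initial_control group",
                          missing_group="initial_control")

    times = dataset.shifted_times()
    if len(times) < 2:
        raise DataValidationError("need >= 2 distinct shifted time points")
    means = np.array([dataset.shifted_at(t).mean() for t in times])
    n_per = np.array([len(dataset.shifted_at(t)) for t in times])

    if z0_policy == "earliest_shifted":
        z0 = float(means[0])
    else:
        z0 = float(dataset.group_values("initial_control").mean())

    if zinf_policy == "new_control":
        z_inf = float(dataset.group_values("new_control").mean())
    else:
        warnings.warn(
            "using the last shifted time point as z_inf; without a "
            "new-environment control group the estimated rate is only valid "
            "if acclimation was complete by the final measurement",
            SingleControlWarning,
        )
        z_inf = float(means[-1])

    span = abs(z0 - z_inf)
    noise = dataset.pooled_within_group_sd()
    if span == 0.0 or (noise > 0 and span <= response_tolerance * noise):
        raise NoPlasticResponseError(
            f"no detectable plastic response: |z0 - z_inf| = {span:g} does not "
            f"exceed {response_tolerance} x pooled within-group SD ({noise:g})",
            span=span, noise_sd=noise,
        )

    _warn_if_non_monotone(times, means, dataset)

    t0 = float(times[0])
    if replicate_level:
        ts, ds, ns = [], [], []
        for t in times:
            for z in dataset.shifted_at(t):
                ts.append(float(t) - t0)
                ds.append((z - z_inf) / (z0 - z_inf))
                ns.append(1)
        return NormalizedSeries(
            times=np.asarray(ts, float), d=np.asarray(ds, float),
            z0=z0, z_inf=z_inf, n_per_point=np.asarray(ns, int),
            time_unit=dataset.time_unit, trait_name=dataset.trait_name,
            replicate_level=True,
        )

    d = (means - z_inf) / (z0 - z_inf)
    if z0_policy == "earliest_shifted":
        d[0] = 1.0  # exact by construction: the anchor is its own reference
    return NormalizedSeries(
        times=times - t0, d=d, z0=z0, z_inf=z_inf, n_per_point=n_per,
        time_unit=dataset.time_unit, trait_name=dataset.trait_name,
    )


def _warn_if_non_monotone(times: np.ndarray, means: np.ndarray,
                          dataset: AcclimationDataset) -> None:
    """Warn when successive shifted means reverse direction beyond noise.

    The rate estimators assume a unidirectional approach to the new
    phenotype; responses that overshoot and return homeostatically are
    outside the model.  A reversal counts only when both adjacent steps
    exceed twice their pooled standard error.
    """
    if len(times) < 3:
        return
    sd = dataset.pooled_within_group_sd()
    n = np.array([len(dataset.shifted_at(t)) for t in times])
    diffs = np.diff(means)
    se_steps = sd * np.sqrt(1.0 / n[:-1] + 1.0 / n[1:]) if sd > 0 else np.zeros_like(diffs)
    big = np.abs(diffs) > 2.0 * se_steps
    signs = np.sign(diffs)
    for i in range(len(diffs) - 1):
        if big[i] and big[i + 1] and signs[i] != 0 and signs[i + 1] == -signs[i]:
            warnings.warn(
                "shifted-group means are non-monotone beyond noise; the "
                "unidirectional-response assumption of the rate model may be "
                "violated (overshoot/homeostatic return is outside its scope)",
                NonMonotoneWarning,
            )
            return


# ---------------------------------------------------------------------------
# closed-form single-point estimators
# ---------------------------------------------------------------------------

def lambda_point_exponential(d: float, t: float, allow_negative: bool = False) -> float:
    """Rate from one observation under exponential decay: -ln(D)/t.

    Requires 0 < D <= 1 and t > 0.  D <= 0 means the observation crossed the
    asymptote (overshoot or noise); the estimator is undefined there.  D > 1
    would imply a negative rate; returned only when ``allow_negative=True``.
    """
    if t <= 0:
        raise EstimatorDomainError(f"t must be > 0, got {t}")
    if d <= 0:
        raise EstimatorDomainError(
            f"D = {d} <= 0: response overshot the asymptote (or noise crossed "
            "it); the single-point exponential estimator is undefined"
        )
    if d > 1:
        if not allow_negative:
            raise EstimatorDomainError(
                f"D = {d} > 1 implies a negative rate; pass allow_negative=True "
                "to accept it"
            )
        warnings.warn(f"D = {d} > 1: returning a negative rate", UserWarning)
    return -math.log(d) / t


def lambda_point_linear(d: float, t: float) -> float:
    """Rate from one observation under linear decline: (1 - D)/t.

    Requires t > 0 and D <= 1.
    """
    if t <= 0:
        raise EstimatorDomainError(f"t must be > 0, got {t}")
    if d > 1:
        raise EstimatorDomainError(f"D = {d} > 1 implies a negative linear rate")
    return (1.0 - d) / t


def half_time(lam: float, shape: Shape = "exponential") -> float:
    """Time for the deviation from the initial phenotype to halve.

    ln(2)/lam under exponential decay; 0.5/lam for the linear shape (the time
    at which 1 - lam*t = 0.5 — a package convention, since the two shapes
    have no common rate currency).
    """
    if lam <= 0:
        raise EstimatorDomainError(f"lam must be > 0, got {lam}")
    if shape == "exponential":
        return math.log(2.0) / lam
    if shape == "linear":
        return 0.5 / lam
    raise DataValidationError(f"unknown shape {shape!r}")
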