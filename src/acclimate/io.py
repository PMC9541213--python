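"""File formats, run configuration and the end-to-end fitting pipeline.

The time-course CSV dialect is long-format with header columns
``group,time,phenotype[,replicate_id]``; ``group`` is one of
``initial_control``, ``new_control``, ``shifted``.  ``run_fit`` binds the
computation modules into one reproducible report: normalize, fit/compare,
optionally bootstrap, and serialize everything (including any design
warnings, each with a machine-readable code) as JSON.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import (
    AcclimationDataset,
    GROUP_LABELS,
    NormalizedSeries,
    RateFit,
    Record,
    normalize_series,
)
from .errors import AcclimateError, AcclimateWarning, DataValidationError
from .fitting import (
    TIE_TOLERANCE,
    ModelComparison,
    bootstrap_lambda,
    compare_models,
    fit_exponential,
    fit_segmented_linear,
)

logger = logging.getLogger(__name__)

REPORT_VERSION = 1

CSV_COLUMNS = ("group", "time", "phenotype")


@dataclass
class RunConfig:
    """Configuration of one fitting run; flags > file > defaults precedence
    is handled by the CLI layer."""

    input: str | Path
    time_unit: str = "h"
    trait_name: str = "phenotype"
    z0_policy: str = "earliest_shifted"
    zinf_policy: str = "new_control"
    shape: str = "auto"  # auto -> compare both; explicit shape skips comparison
    bootstrap: bool = False
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0
    tie_tolerance: float = TIE_TOLERANCE
    response_tolerance: float = 0.1
    output: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.shape not in ("auto", "exponential", "linear"):
            raise DataValidationError(f"shape must be auto/exponential/linear, "
                                      f"got {self.shape!r}")


def read_acclimation_csv(path: str | Path, time_unit: str = "h",
                         trait_name: str = "phenotype") -> AcclimationDataset:
    """Read a long-format time-course CSV into a validated dataset.

    Error messages carry the 1-based data row number (header excluded) so a
    malformed cell can be found in a spreadsheet.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: missing required column(s) {missing}; "
            f"required: {list(CSV_COLUMNS)}")
    has_rep = "replicate_id" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        group = str(getattr(row, "group")).strip()
        if group not in GROUP_LABELS:
            raise DataValidationError(
                f"{path}, row {i}: unknown group label {group!r}; "
                f"allowed: {list(GROUP_LABELS)}", row=i)
        try:
            t = float(getattr(row, "time"))
            z = float(getattr(row, "phenotype"))
        except ValueError as e:
            raise DataValidationError(f"{path}, row {i}: non-numeric time or "
                                      f"phenotype ({e})", row=i) from None
        rep = str(getattr(row, "replicate_id")) if has_rep else f"row{i}"
        try:
            records.append(Record(group, t, z, rep))
        except DataValidationError as e:
            raise DataValidationError(f"{path}, row {i}: {e}", row=i) from None
    if not records:
        raise DataValidationError(f"{path}: no data rows")
    # Full design invariants (>= 2 shifted time points, control presence)
    # are checked at normalization time, not parse time, so partial files
    # remain readable and writable.
    return AcclimationDataset(records=records, time_unit=time_unit,
                              trait_name=trait_name)


def write_acclimation_csv(dataset: AcclimationDataset, path: str | Path) -> None:
    pd.DataFrame(
        [{"group": r.group, "time": r.time, "phenotype": r.phenotype,
          "replicate_id": r.replicate_id} for r in dataset.records]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def _fit_payload(fit: RateFit) -> dict[str, Any]:
    return {
        "shape": fit.shape,
        "lambda": fit.lam,
        "rse": fit.rse,
        "half_time": fit.half_time,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "residuals": fit.residuals,
        "display": {
            "lambda": _round_sig(fit.lam, 4),
            "half_time": _round_sig(fit.half_time, 3),
            "rse": _round_sig(fit.rse, 3),
        },
    }


def run_fit(config: RunConfig,
            dataset: AcclimationDataset | None = None) -> dict[str, Any]:
    """Execute normalize -> (compare or single fit) -> optional bootstrap.

    Returns a JSON-serializable report.  All warnings raised along the way
    are captured into the report with their codes rather than printed; no
    timestamps are embedded, so identical config + input + seed gives a
    byte-identical report.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if dataset is None:
        dataset = read_acclimation_csv(config.input, time_unit=config.time_unit,
                                       trait_name=config.trait_name)
    report: dict[str, Any] = {"report_version": REPORT_VERSION,
                              "input": str(config.input),
                              "trait_name": dataset.trait_name,
                              "time_unit": dataset.time_unit,
                              "warnings": []}
    captured: list[warnings.WarningMessage] = []
    try:
        with warnings.catch_warnings(record=True) as captured:
            warnings.simplefilter("always")
            series = normalize_series(
                dataset, z0_policy=config.z0_policy,
                zinf_policy=config.zinf_policy,
                response_tolerance=config.response_tolerance)
            report["z0"] = series.z0
            report["z_inf"] = series.z_inf
            report["d_series"] = [
                {"t": float(t), "d": float(d), "n": int(n)}
                for t, d, n in zip(series.times, series.d, series.n_per_point)]

            if config.shape == "auto":
                cmp = compare_models(series, tie_tolerance=config.tie_tolerance)
                report["fits"] = {"exponential": _fit_payload(cmp.fit_exponential),
                                  "linear": _fit_payload(cmp.fit_linear)}
                report["selected"] = cmp.selected
                report["rse_margin"] = cmp.rse_margin
            else:
                fit = (fit_exponential(series) if config.shape == "exponential"
                       else fit_segmented_linear(series))
                report["fits"] = {config.shape: _fit_payload(fit)}
                report["selected"] = config.shape
                report["rse_margin"] = None

            if config.bootstrap:
                shape = report["selected"]
                if shape == "indistinguishable":
                    shape = "exponential"  # working default; flagged by 'selected'
                boot = bootstrap_lambda(
                    dataset, shape, n_boot=config.n_boot, level=config.level,
                    seed=config.seed, z0_policy=config.z0_policy,
                    zinf_policy=config.zinf_policy)
                report["bootstrap"] = {
                    "shape": boot.shape, "lambda_hat": boot.lam_hat,
                    "ci_low": boot.ci_low, "ci_high": boot.ci_high,
                    "level": boot.level, "n_boot": boot.n_boot,
                    "seed": boot.seed, "n_failed": boot.n_failed,
                    "lam_hat_outside_ci": boot.lam_hat_outside_ci,
                }
    except AcclimateError as e:
        report["error"] = {"code": e.code, "message": str(e)}
    finally:
        for w in captured:
            cat = w.category
            code = getattr(cat, "code", None) if issubclass(cat, AcclimateWarning) \
                else None
            report["warnings"].append({"code": code or "warning",
                                       "message": str(w.message)})
    report["exit_status"] = 1 if "error" in report else 0
    if config.output is not None:
        Path(config.output).write_text(json.dumps(report, indent=2) + "\n")
    return report


def plot_fit(series: NormalizedSeries, comparison: ModelComparison,
             path: str | Path | None = None):
    """D-vs-t scatter with both fitted curves (solid exponential, dashed
    segmented linear).  Requires matplotlib (optional dependency)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(series.times, series.d, color="k", zorder=3, label="observed D")
    tt = np.linspace(0, float(series.times.max()), 200)
    ax.plot(tt, np.exp(-comparison.fit_exponential.lam * tt), "-",
            label=f"exponential (RSE {comparison.fit_exponential.rse:.3g})")
    ax.plot(tt, np.maximum(1 - comparison.fit_linear.lam * tt, 0), "--",
            label=f"segmented linear (RSE {comparison.fit_linear.rse:.3g})")
    ax.set_xlabel(f"time since shift ({series.time_unit})")
    ax.set_ylabel("D (proportion of response remaining)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
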