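"""Exception and warning hierarchy.

Every error and warning carries a short machine-readable ``code`` so that
reports and CLI output can surface them without parsing prose.
"""

from __future__ import annotations


class AcclimateError(Exception):
    """Base class for all package errors."""

    code = "error"

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context


class DataValidationError(AcclimateError):
    """Malformed input data (bad labels, non-numeric fields, invariant breaks)."""

    code = "invalid_data"


class DesignError(AcclimateError):
    """The experimental design cannot support the requested analysis.

    Raised e.g. when the new-environment control group is absent under the
    dual-control policy: without organisms fully acclimated to the new
    environment there is no estimate of the fully adjusted phenotype, and the
    true rate of plasticity cannot be expressed on the proportional scale.
    """

    code = "design_error"


class NoPlasticResponseError(AcclimateError):
    """|z0 - z_inf| is indistinguishable from noise; D is not identifiable."""

    code = "no_plastic_response"


class EstimatorDomainError(AcclimateError):
    """A single-point estimator was called outside its domain (e.g. D <= 0)."""

    code = "estimator_domain"


class FitError(AcclimateError):
    """Curve fitting failed; ``context`` may carry diagnostics and the best candidate."""

    code = "fit_error"


class NoDeclineError(FitError):
    """All normalized values sit at or above 1: no plastic decline to fit."""

    code = "no_decline"


class BootstrapError(AcclimateError):
    code = "bootstrap_error"


class AcclimateWarning(UserWarning):
    code = "warning"


class DesignWarning(AcclimateWarning):
    """The dataset violates one of the recommended design practices
    (dual controls, several measurement occasions, unidirectional response)."""

    code = "design_warning"


class SingleControlWarning(DesignWarning):
    code = "single_control"


class FewTimePointsWarning(DesignWarning):
    code = "few_time_points"


class NonMonotoneWarning(DesignWarning):
    code = "non_monotone_response"


class OvershootWarning(AcclimateWarning):
    """D crossed below 0 or above 1; retained for fitting, rejected pointwise."""

    code = "d_out_of_range"
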