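"""Spirometry screening and FVC/DI prediction from photogrammetric mobility.

Two published linear models predict forced vital capacity (FVC) and deep
inspiration (DI), both in litres, from height (m), thorax length (cm) and
total volumetric mobility (l):

    FVC = -8.572 + 5.108*height + 0.138*thorax + 0.120*mobility
    DI  = -6.373 + 3.751*height + 0.122*thorax + 0.163*mobility

They ship as read-only JSON fixtures; :func:`fit_model` refits the same
model form to new cohorts by ordinary least squares.  Subjects whose
Tiffeneau index (FEV1/FVC) falls below 0.80 are screened out as showing
airflow obstruction or restriction before any model is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import statsmodels.api as sm

from .errors import ParameterError, SingularFitError

PREDICTOR_NAMES = ("height_m", "thorax_cm", "mobility_l")

RETAINED = "retained"
EXCLUDED = "excluded_obstruction_or_restriction"

_RATIO_ATOL = 1e-9


@dataclass(frozen=True)
class SpirometryRecord:
    """One subject's spirometric outcomes (litres; PEF in l/s)."""

    FEV1: float
    FVC: float
    PEF: float
    DI: float

    def __post_init__(self):
        for name in ("FEV1", "FVC", "PEF", "DI"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def tiffeneau(self) -> float:
        """FEV1/FVC ratio, computed before any rounding."""
        return self.FEV1 / self.FVC


@dataclass(frozen=True)
class RegressionModel:
    """Affine model outcome = intercept + b_h*height + b_t*thorax + b_m*mobility."""

    outcome: str
    intercept: float
    coef_height: float
    coef_thorax: float
    coef_mobility: float
    R: float
    R_squared: float
    SE_estimate: float
    n: int

    def __post_init__(self):
        if self.SE_estimate < 0:
            raise ParameterError("SE of the estimate cannot be negative")

    def validate_r(self, atol: float = 1e-6) -> None:
        """Check R_squared == R^2; published models carry rounded values."""
        if np.isfinite(self.R) and abs(self.R_squared - self.R**2) > atol:
            raise ParameterError(
                f"R_squared {self.R_squared} inconsistent with R {self.R} (atol={atol})"
            )

    def predict(self, height: float, thorax: float, mobility: float) -> float:
        return (
            self.intercept
            + self.coef_height * height
            + self.coef_thorax * thorax
            + self.coef_mobility * mobility
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "outcome": self.outcome,
                "intercept": self.intercept,
                "coef": {
                    "height_m": self.coef_height,
                    "thorax_cm": self.coef_thorax,
                    "mobility_l": self.coef_mobility,
                },
                "R": None if not np.isfinite(self.R) else self.R,
                "R2": None if not np.isfinite(self.R_squared) else self.R_squared,
                "SEE_l": self.SE_estimate,
                "n": self.n,
            },
            indent=2,
        )


def _load_packaged(name: str) -> RegressionModel:
    raw = json.loads(resources.files("respivol.models").joinpath(name).read_text())
    model = RegressionModel(
        outcome=raw["outcome"],
        intercept=raw["intercept"],
        coef_height=raw["coef"]["height_m"],
        coef_thorax=raw["coef"]["thorax_cm"],
        coef_mobility=raw["coef"]["mobility_l"],
        R=raw["R"],
        R_squared=raw["R2"],
        SE_estimate=raw["SEE_l"],
        n=raw["n"],
    )
    # Published R and R2 are reported as printed and are not mutually
    # consistent for the DI model (0.881^2 = 0.776, printed R2 = 0.815),
    # so the R2 == R^2 invariant is enforced only on freshly fitted models.
    return model


FVC_MODEL = _load_packaged("fvc_model.json")
DI_MODEL = _load_packaged("di_model.json")


def screen_subject(
    rec: SpirometryRecord,
    threshold: float = 0.80,
    fvc_lower_limit: float | None = None,
) -> str:
    """Apply the pre-analysis screening rule.

    A subject is excluded when the Tiffeneau index is strictly below the
    threshold (default 0.80, a ratio not percent points), or — when a
    lower limit is supplied — when FVC falls below it (possible
    restriction).  No default FVC limit exists; it must come from a
    reference equation chosen by the user.
    """
    if rec.tiffeneau < threshold - _RATIO_ATOL:
        return EXCLUDED
    if fvc_lower_limit is not None and rec.FVC < fvc_lower_limit:
        return EXCLUDED
    return RETAINED


def predict_fvc(height: float, thorax: float, mobility: float) -> float:
    """Predicted forced vital capacity (l) from the published equation."""
    return FVC_MODEL.predict(height, thorax, mobility)


def predict_di(height: float, thorax: float, mobility: float) -> float:
    """Predicted deep inspiration (l) from the published equation."""
    return DI_MODEL.predict(height, thorax, mobility)


def fit_model(outcomes, predictors, outcome_name: str = "FVC") -> RegressionModel:
    """Refit the three-predictor model form to a new cohort by OLS.

    ``predictors`` is (n, 3): height (m), thorax (cm), mobility (l).
    R is the multiple correlation of fitted vs observed values and the
    standard error of the estimate is sqrt(RSS / (n - 4)).  A constant
    outcome yields zero slopes with undefined (NaN) R, reported with a
    warning rather than an error.
    """
    y = np.asarray(outcomes, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ParameterError("predictors must be an (n, 3) array: height, thorax, mobility")
    n = X.shape[0]
    if n < 5:
        raise ParameterError(f"need at least 5 subjects to fit 4 parameters, got {n}")
    if y.shape[0] != n:
        raise ParameterError("outcomes and predictors must have the same length")

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for j, name in enumerate(PREDICTOR_NAMES):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                raise SingularFitError(
                    f"design matrix is rank deficient: column {name!r} is "
                    "collinear with the remaining predictors",
                    column=name,
                )
        raise SingularFitError("design matrix is rank deficient", column="const")

    res = sm.OLS(y, design).fit()
    see = float(np.sqrt(res.ssr / (n - 4)))
    if np.ptp(y) == 0:
        warnings.warn(
            "constant outcome: multiple correlation is undefined", RuntimeWarning, stacklevel=2
        )
        r2 = float("nan")
        r = float("nan")
    else:
        r2 = float(res.rsquared)
        r = float(np.sqrt(max(r2, 0.0)))

    model = RegressionModel(
        outcome=outcome_name,
        intercept=float(res.params[0]),
        coef_height=float(res.params[1]),
        coef_thorax=float(res.params[2]),
        coef_mobility=float(res.params[3]),
        R=r,
        R_squared=r2,
        SE_estimate=see,
        n=n,
    )
    model.validate_r(atol=1e-6)
    return model
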