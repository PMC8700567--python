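"""Regression models and rank correlations for densitometry metrics.

Two model families: linear (y = a + b*x) and inverse/hyperbola (y = a + b/x).
The inverse model is fit by ordinary least squares on the transformed
predictor 1/x — identical to nonlinear least squares for this family, since
the model is linear in 1/x. r^2 is reported on the original y scale (the
two conventions agree here).

A built-in, versioned reference set ships the published coefficient pairs
for prediction and for noise-free cohort generation.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources

import numpy as np
from scipy import stats

DEFAULT_REFERENCE_SET = "pediatric_inspiratory_v1"


class DegenerateFitError(ValueError):
    """Predictor (or its transform) is constant; the fit is undefined."""


@dataclasses.dataclass(frozen=True)
class ReferenceEquation:
    """A fitted or published model y = a + b*x (linear) or y = a + b/x
    (inverse).

    ``se_intercept``/``se_coefficient`` are OLS standard errors, present
    only on fitted equations (None for published ones).
    """

    form: str
    response: str
    predictor: str
    intercept: float
    coefficient: float
    r_squared: float
    n: int
    se_intercept: float | None = None
    se_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "inverse"):
            raise ValueError(f"unknown form {self.form!r}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float


def fit_linear(
    x, y, response: str = "y", predictor: str = "x"
) -> ReferenceEquation:
    """Ordinary least squares of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be congruent 1D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor is constant")

    res = stats.linregress(x, y)
    # linregress r**2 is undefined-ish for constant y; define r^2 = 0 there.
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 0.0
    else:
        yhat = res.intercept + res.slope * x
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return ReferenceEquation(
        form="linear",
        response=response,
        predictor=predictor,
        intercept=float(res.intercept),
        coefficient=float(res.slope),
        r_squared=min(max(r2, 0.0), 1.0),
        n=int(x.size),
        se_intercept=float(res.intercept_stderr),
        se_coefficient=float(res.stderr),
    )


def fit_inverse(
    x, y, response: str = "y", predictor: str = "x"
) -> ReferenceEquation:
    """OLS of y on 1/x; coefficients are those of y = a + b/x."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("inverse fit requires all x > 0")
    eq = fit_linear(1.0 / x, y, response=response, predictor=predictor)
    return dataclasses.replace(eq, form="inverse")


def predict(eq: ReferenceEquation, x: float) -> float:
    """Evaluate the equation at a predictor value (no rounding)."""
    if eq.form == "inverse":
        if x <= 0:
            raise ValueError("inverse form requires x > 0")
        return eq.intercept + eq.coefficient / x
    return eq.intercept + eq.coefficient * x


def present_hu(value: float, nearest: int = 1) -> int:
    """Round a predicted HU value for presentation, half away from zero,
    optionally to the nearest multiple of ``nearest``."""
    scaled = value / nearest
    return int(np.copysign(np.floor(abs(scaled) + 0.5), scaled)) * nearest


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties and a
    two-sided p-value from the large-sample t approximation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be congruent 1D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), n=int(x.size), p_value=float(res.pvalue))


def load_reference_set(name: str = DEFAULT_REFERENCE_SET) -> dict[str, ReferenceEquation]:
    """Load a built-in equation set, keyed like ``mean_hu_vs_age``."""
    raw = json.loads(
        resources.files("pedct.data").joinpath("reference_equations.json").read_text()
    )
    if name not in raw:
        raise KeyError(
            f"unknown reference set {name!r}; available: {sorted(raw)}"
        )
    return {
        key: ReferenceEquation(
            form=entry["form"],
            response=entry["response"],
            predictor=entry["predictor"],
            intercept=float(entry["intercept"]),
            coefficient=float(entry["coefficient"]),
            r_squared=float(entry["r_squared"]),
            n=int(entry["n"]),
        )
        for key, entry in raw[name]["equations"].items()
    }


def equation_to_dict(eq: ReferenceEquation) -> dict:
    return dataclasses.asdict(eq)
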