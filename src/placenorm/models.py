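"""Candidate gestational-age model forms.

Six closed-form candidates are used to describe the evolution of a scalar
biomarker y(t) across gestational age t (weeks): four nested polynomials, a
four-parameter logistic sigmoid, and the analytic time derivative of the
sigmoid (used for within-pregnancy rate-of-change data).

The sigmoid is parameterised as

    y(t) = p1 / (1 + exp(p2 (t - p3))) + p4

so that with p2 < 0 the curve falls from an early plateau p4 through an
inflection at t = p3 (where y = p1/2 + p4) toward a late plateau p1 + p4.
Its derivative,

    dy/dt = -p1 p2 exp(p2 (t - p3)) / (1 + exp(p2 (t - p3)))^2,

is a three-parameter bump centred at t = p3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["ModelSpec", "MODEL_FORMS", "evaluate_model", "model_gradient"]

#: form name -> number of free parameters
MODEL_FORMS: dict[str, int] = {
    "constant": 1,
    "linear": 2,
    "quadratic": 3,
    "cubic": 4,
    "sigmoid": 4,
    "sigmoid_derivative": 3,
}

#: polynomial forms, fittable by linear least squares
POLYNOMIAL_FORMS = ("constant", "linear", "quadratic", "cubic")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model form and its parameter count."""

    form: str

    def __post_init__(self) -> None:
        if self.form not in MODEL_FORMS:
            raise ValueError(
                f"unknown model form {self.form!r}; expected one of {sorted(MODEL_FORMS)}"
            )

    @property
    def n_params(self) -> int:
        return MODEL_FORMS[self.form]

    @property
    def is_polynomial(self) -> bool:
        return self.form in POLYNOMIAL_FORMS


def evaluate_model(spec: ModelSpec | str, params, t):
    """Evaluate a model form at gestational ages ``t``.

    Overflow-safe: the sigmoid and its derivative are computed through the
    logistic function ``expit``, so arguments of any magnitude are handled.
    """
    form = spec.form if isinstance(spec, ModelSpec) else ModelSpec(spec).form
    params = np.asarray(params, dtype=float)
    k = MODEL_FORMS[form]
    if params.shape != (k,):
        raise ValueError(f"{form} takes {k} parameters, got shape {params.shape}")
    t = np.asarray(t, dtype=float)

    if form == "constant":
        return np.full_like(t, params[0])
    if form == "linear":
        return params[0] + params[1] * t
    if form == "quadratic":
        return params[0] + params[1] * t + params[2] * t**2
    if form == "cubic":
        return params[0] + params[1] * t + params[2] * t**2 + params[3] * t**3
    if form == "sigmoid":
        p1, p2, p3, p4 = params
        # 1/(1+exp(u)) = expit(-u)
        return p1 * expit(-p2 * (t - p3)) + p4
    # sigmoid_derivative
    p1, p2, p3 = params
    u = p2 * (t - p3)
    # exp(u)/(1+exp(u))^2 = expit(u) * expit(-u), bounded in (0, 1/4]
    return -p1 * p2 * expit(u) * expit(-u)


def model_gradient(spec: ModelSpec | str, params, t):
    """Gradient of the model with respect to its parameters, shape (len(t), k).

    Used for Gauss-Newton Jacobians and delta-method confidence bands.
    """
    form = spec.form if isinstance(spec, ModelSpec) else ModelSpec(spec).form
    params = np.asarray(params, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))

    if form == "constant":
        return np.ones((t.size, 1))
    if form == "linear":
        return np.column_stack([np.ones_like(t), t])
    if form == "quadratic":
        return np.column_stack([np.ones_like(t), t, t**2])
    if form == "cubic":
        return np.column_stack([np.ones_like(t), t, t**2, t**3])
    if form == "sigmoid":
        p1, p2, p3, p4 = params
        u = p2 * (t - p3)
        s = expit(-u)          # 1/(1+e^u)
        sprime = s * expit(u)  # e^u/(1+e^u)^2
        return np.column_stack([
            s,                       # d/dp1
            -p1 * sprime * (t - p3),  # d/dp2
            p1 * sprime * p2,        # d/dp3
            np.ones_like(t),         # d/dp4
        ])
    # sigmoid_derivative: f = -p1 p2 g(u), g = e^u/(1+e^u)^2, u = p2(t-p3)
    p1, p2, p3 = params
    u = p2 * (t - p3)
    g = expit(u) * expit(-u)
    # g'(u) = g(u) (1 - 2 expit(u))
    gp = g * (1.0 - 2.0 * expit(u))
    return np.column_stack([
        -p2 * g,                                 # d/dp1
        -p1 * (g + p2 * gp * (t - p3)),          # d/dp2
        p1 * p2 * gp * p2,                       # d/dp3
    ])
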