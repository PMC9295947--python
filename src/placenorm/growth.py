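"""Normative gestational-age modeling.

The central objects are :class:`GestationalModel` (data plus a candidate
model form) and the :class:`GestationalFit` returned by its ``fit`` method,
which carries the least-squares parameter estimates, their covariance,
the RMS residual, the BIC, and methods for prediction, confidence/prediction
bands and serialisation — in the style of statsmodels' Model/Results split.

Fitting conventions
-------------------
* Polynomial forms are solved exactly by linear least squares.
* The sigmoid and its derivative are fitted by Levenberg-Marquardt style
  nonlinear least squares (`scipy.optimize.least_squares`) with analytic
  Jacobians, a data-driven initial guess, and random multistart jitters to
  escape local minima.
* Parameter covariance is ``s^2 (J'J)^{-1}`` with ``s^2 = RSS/(n-k)``.
* The reported RMS residual is ``sqrt(RSS/n)``.
* BIC is ``n ln(RSS/n) + k ln(n)``; additive constants common to all
  candidates are dropped, so only BIC differences are meaningful.
* Confidence bands use the delta method with normal (not t) quantiles;
  prediction bands add the residual variance ``s^2``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import MODEL_FORMS, ModelSpec, evaluate_model, model_gradient

__all__ = [
    "GestationalModel",
    "GestationalFit",
    "Band",
    "fit_model",
    "select_model_bic",
    "confidence_band",
    "band_separation",
    "rate_pairs",
    "fit_rate_model",
    "DEFAULT_GRID",
]

#: default evaluation grid for bands and curve-separation tests: 10..40 weeks
DEFAULT_GRID = np.round(np.arange(10.0, 40.0 + 1e-9, 0.1), 10)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class Band:
    """Pointwise 95% confidence and prediction bounds around a fitted curve."""

    grid_t: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    pi_lo: np.ndarray
    pi_hi: np.ndarray

    def __post_init__(self) -> None:
        ok = (
            np.all(self.pi_lo <= self.ci_lo + 1e-12)
            and np.all(self.ci_lo <= self.mean + 1e-12)
            and np.all(self.mean <= self.ci_hi + 1e-12)
            and np.all(self.ci_hi <= self.pi_hi + 1e-12)
        )
        if not ok:
            raise ValueError("band ordering violated: expect pi_lo <= ci_lo <= mean <= ci_hi <= pi_hi")


def _canonicalize(spec: ModelSpec, params: np.ndarray) -> np.ndarray:
    """Resolve the sigmoid's mirror symmetry toward the p2 < 0 convention.

    The logistic forms are invariant under (p1, p2, p3, p4) ->
    (-p1, -p2, p3, p1 + p4) (sigmoid) and (p1, p2, p3) -> (-p1, -p2, p3)
    (derivative); the published parameterisation uses p2 < 0.
    """
    params = np.asarray(params, dtype=float)
    if params.size and spec.form in ("sigmoid", "sigmoid_derivative") and params[1] > 0:
        if spec.form == "sigmoid":
            p1, p2, p3, p4 = params
            return np.array([-p1, -p2, p3, p1 + p4])
        p1, p2, p3 = params
        return np.array([-p1, -p2, p3])
    return params


class GestationalModel:
    """A biomarker-versus-gestational-age regression model.

    Parameters
    ----------
    t : array-like
        Gestational ages in weeks.
    y : array-like
        Biomarker values (same length as ``t``).
    form : str or ModelSpec
        One of ``constant, linear, quadratic, cubic, sigmoid,
        sigmoid_derivative``.
    """

    def __init__(self, t, y, form: str | ModelSpec = "sigmoid") -> None:
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("t and y must be finite")
        self.spec = form if isinstance(form, ModelSpec) else ModelSpec(form)
        if t.size <= self.spec.n_params + 1:
            raise ValueError(
                f"need more than {self.spec.n_params + 1} observations to fit "
                f"a {self.spec.form} model, got {t.size}"
            )
        self.t = t
        self.y = y

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        y: str = "t2star_ms",
        t: str = "ga_weeks",
        form: str | ModelSpec = "sigmoid",
    ) -> "GestationalModel":
        """Build a model from cohort-table columns, dropping missing rows."""
        sub = df[[t, y]].dropna()
        return cls(sub[t].to_numpy(), sub[y].to_numpy(), form=form)

    # -- fitting ---------------------------------------------------------

    def _initial_guess(self) -> np.ndarray:
        t, y = self.t, self.y
        form = self.spec.form
        if form == "sigmoid":
            early = y[t < 20]
            late = y[t > 34]
            p4 = float(early.mean()) if early.size else float(y.max())
            p1 = (float(late.mean()) if late.size else float(y.min())) - p4
            if p1 == 0.0:
                p1 = float(y.min() - y.max()) or -1.0
            return np.array([p1, -0.2, 30.0, p4])
        # sigmoid_derivative: bump height |p1 p2|/4 at t = p3
        peak = float(y[np.argmax(np.abs(y))])
        p2 = -0.2
        p1 = -4.0 * peak / p2 if peak != 0 else -1.0
        return np.array([p1, p2, 30.0])

    def _nls(self, x0: np.ndarray) -> optimize.OptimizeResult:
        spec = self.spec

        def resid(p):
            return evaluate_model(spec, p, self.t) - self.y

        def jac(p):
            return model_gradient(spec, p, self.t)

        return optimize.least_squares(resid, x0, jac=jac, method="lm", max_nfev=2000)

    def fit(self, multistart: int = 20, random_state: int | None = 0) -> "GestationalFit":
        """Fit by least squares; nonlinear forms use multistart NLS.

        ``multistart`` extra starts jitter the data-driven initial guess
        multiplicatively (lognormal, sigma=0.3) and additively for the
        inflection week; the best sum of squares wins.
        """
        t, y, spec = self.t, self.y, self.spec
        n, k = t.size, spec.n_params

        if spec.is_polynomial:
            X = model_gradient(spec, np.zeros(k), t)
            params, *_ = np.linalg.lstsq(X, y, rcond=None)
            converged = True
        else:
            x0 = self._initial_guess()
            best = None
            starts = [x0]
            rng = np.random.default_rng(random_state)
            for _ in range(max(0, multistart)):
                jitter = x0 * rng.lognormal(0.0, 0.3, size=k) * np.sign(x0)
                jitter = np.where(x0 == 0, rng.normal(0, 1, size=k), jitter)
                # keep the inflection start inside gestation
                jitter[2] = np.clip(x0[2] + rng.normal(0, 4), t.min(), t.max())
                starts.append(jitter)
            for s in starts:
                try:
                    res = self._nls(np.asarray(s, dtype=float))
                except Exception:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
            if best is None:
                raise RuntimeError(f"{spec.form} fit failed from every start")
            params = _canonicalize(spec, best.x)
            converged = bool(best.success)

        fitted = evaluate_model(spec, params, t)
        rss = float(np.sum((y - fitted) ** 2))
        s2 = rss / (n - k)
        J = model_gradient(spec, params, t)
        JtJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JtJ)
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular Jacobian in {spec.form} fit; covariance from pseudo-inverse",
                ConvergenceWarning,
                stacklevel=2,
            )
            cov = s2 * np.linalg.pinv(JtJ)
            converged = False
        cov = (cov + cov.T) / 2.0

        rms = float(np.sqrt(rss / n))
        bic = float(n * np.log(max(rss / n, np.finfo(float).tiny)) + k * np.log(n))
        return GestationalFit(
            spec=spec,
            params=np.asarray(params, dtype=float),
            cov_params=cov,
            rms_residual=rms,
            resid_var=s2,
            nobs=n,
            bic=bic,
            converged=converged,
            model=self,
        )


@dataclass
class GestationalFit:
    """Results of a :class:`GestationalModel` fit."""

    spec: ModelSpec
    params: np.ndarray
    cov_params: np.ndarray
    rms_residual: float
    resid_var: float           # RSS/(n-k), used in covariance and prediction SD
    nobs: int
    bic: float
    converged: bool
    model: GestationalModel | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the parameters."""
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def df_resid(self) -> int:
        return self.nobs - self.spec.n_params

    def predict(self, t):
        """Fitted curve at gestational ages ``t``."""
        return evaluate_model(self.spec, self.params, t)

    def curve_sd(self, t):
        """Delta-method SD of the fitted curve at ``t`` (parameter uncertainty only)."""
        g = model_gradient(self.spec, self.params, t)
        var = np.einsum("ij,jk,ik->i", g, self.cov_params, g)
        if np.any(var < -1e-8 * max(1.0, float(np.abs(var).max()))):
            raise ValueError("parameter covariance is not positive semidefinite")
        return np.sqrt(np.clip(var, 0.0, None))

    def prediction_sd(self, t):
        """SD of a new observation at ``t``: curve variance plus residual variance."""
        return np.sqrt(self.curve_sd(t) ** 2 + self.resid_var)

    def confidence_band(self, grid_t=None, level: float = 0.95) -> Band:
        """Pointwise confidence and prediction band over ``grid_t``."""
        if not self.converged:
            raise ValueError("cannot build bands from a non-converged fit")
        grid_t = DEFAULT_GRID if grid_t is None else np.asarray(grid_t, dtype=float)
        z = stats.norm.ppf(0.5 + level / 2.0)
        mean = self.predict(grid_t)
        c = z * self.curve_sd(grid_t)
        p = z * self.prediction_sd(grid_t)
        return Band(grid_t, mean, mean - c, mean + c, mean - p, mean + p)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "form": self.spec.form,
            "params": [float(v) for v in self.params],
            "cov": [float(v) for v in self.cov_params.ravel()],
            "rms": self.rms_residual,
            "resid_var": self.resid_var,
            "n": int(self.nobs),
            "bic": self.bic,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GestationalFit":
        spec = ModelSpec(d["form"])
        k = spec.n_params
        return cls(
            spec=spec,
            params=np.asarray(d["params"], dtype=float),
            cov_params=np.asarray(d["cov"], dtype=float).reshape(k, k),
            rms_residual=float(d["rms"]),
            resid_var=float(d["resid_var"]),
            nobs=int(d["n"]),
            bic=float(d["bic"]),
            converged=bool(d.get("converged", True)),
        )

    @classmethod
    def from_json(cls, path) -> "GestationalFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            f"Gestational {self.spec.form} model fit",
            "=" * 44,
            f"{'n obs':<22}{self.nobs:>22}",
            f"{'RMS residual':<22}{self.rms_residual:>22.4g}",
            f"{'BIC':<22}{self.bic:>22.4g}",
            f"{'converged':<22}{str(self.converged):>22}",
            "-" * 44,
            f"{'param':<8}{'estimate':>18}{'std err':>18}",
        ]
        for i, (p, se) in enumerate(zip(self.params, self.bse), start=1):
            lines.append(f"p{i:<7}{p:>18.6g}{se:>18.6g}")
        lines.append("=" * 44)
        return "\n".join(lines)


# -- functional surface ---------------------------------------------------

def fit_model(t, y, form: str | ModelSpec, **fit_kw) -> GestationalFit:
    """Fit one candidate form; convenience wrapper over GestationalModel."""
    return GestationalModel(t, y, form=form).fit(**fit_kw)


def select_model_bic(
    t, y, candidates=("constant", "linear", "quadratic", "cubic", "sigmoid"), **fit_kw
) -> tuple[GestationalFit, dict[str, GestationalFit]]:
    """Fit each candidate and return (minimum-BIC fit, all fits).

    Ties in BIC are broken toward the form with fewer parameters;
    non-converged candidates are excluded with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate forms")
    fits: dict[str, GestationalFit] = {}
    for form in candidates:
        try:
            fits[str(form)] = fit_model(t, y, form, **fit_kw)
        except Exception as exc:  # noqa: BLE001 - candidate failure is survivable
            warnings.warn(f"candidate {form!r} failed to fit: {exc}", ConvergenceWarning, stacklevel=2)
    usable = {f: r for f, r in fits.items() if r.converged}
    if not usable:
        raise RuntimeError("no candidate model converged")
    for form, r in fits.items():
        if not r.converged:
            warnings.warn(f"candidate {form!r} did not converge; excluded from selection",
                          ConvergenceWarning, stacklevel=2)
    best = min(usable.values(), key=lambda r: (round(r.bic, 10), r.spec.n_params))
    return best, fits


def confidence_band(fit: GestationalFit, grid_t=None, level: float = 0.95) -> Band:
    return fit.confidence_band(grid_t, level=level)


def band_separation(
    fit_a: GestationalFit, fit_b: GestationalFit, grid_t=None, level: float = 0.95
) -> list[tuple[float, float]]:
    """Gestational intervals where the two fits' CIs do not overlap.

    Returns contiguous ``(t_start, t_end)`` week intervals over the grid at
    which the upper CI of the lower curve lies below the lower CI of the
    higher curve.
    """
    grid_t = DEFAULT_GRID if grid_t is None else np.asarray(grid_t, dtype=float)
    band_a = fit_a.confidence_band(grid_t, level=level)
    band_b = fit_b.confidence_band(grid_t, level=level)
    separated = (band_a.ci_hi < band_b.ci_lo) | (band_b.ci_hi < band_a.ci_lo)
    intervals: list[tuple[float, float]] = []
    start = None
    for i, sep in enumerate(separated):
        if sep and start is None:
            start = grid_t[i]
        elif not sep and start is not None:
            intervals.append((float(start), float(grid_t[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(start), float(grid_t[-1])))
    return intervals


def rate_pairs(ga_weeks, y) -> np.ndarray:
    """Centred finite-difference rate pairs from one subject's serial scans.

    For each consecutive scan pair (t1, y1), (t2, y2) returns
    ``(mid, rate) = ((t1+t2)/2, (y2-y1)/(t2-t1))``; structured as an
    (n-1, 2) array with columns (mid_ga_weeks, rate).
    """
    ga = np.asarray(ga_weeks, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if ga.size != y.size:
        raise ValueError("ga_weeks and y must have the same length")
    if ga.size < 2:
        raise ValueError("need at least two scans to form a rate pair")
    order = np.argsort(ga, kind="stable")
    ga, y = ga[order], y[order]
    dt = np.diff(ga)
    if np.any(dt == 0):
        raise ValueError("duplicate gestational ages: rate undefined")
    mid = (ga[:-1] + ga[1:]) / 2.0
    rate = np.diff(y) / dt
    return np.column_stack([mid, rate])


def cohort_rate_pairs(df: pd.DataFrame, y: str = "t2star_ms") -> np.ndarray:
    """Rate pairs pooled over all multi-scan subjects of a cohort table."""
    out = []
    for _, sub in df.sort_values("ga_weeks").groupby("subject_id"):
        if len(sub) >= 2:
            out.append(rate_pairs(sub["ga_weeks"].to_numpy(), sub[y].to_numpy()))
    if not out:
        return np.empty((0, 2))
    return np.vstack(out)


def fit_rate_model(pairs, **fit_kw) -> GestationalFit:
    """Fit the 3-parameter analytic sigmoid derivative to rate pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (mid_ga, rate)")
    if pairs.shape[0] < 10:
        raise ValueError("need at least 10 rate pairs")
    return fit_model(pairs[:, 0], pairs[:, 1], "sigmoid_derivative", **fit_kw)
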