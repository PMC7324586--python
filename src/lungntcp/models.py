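"""Closed-form NTCP dose-response models in the (D50, gamma50) parameterization.

Four sigmoid normal-tissue complication probability (NTCP) models are
provided, each expressed through the same two parameters:

* ``d50`` -- the dose (Gy) producing 50% of the maximal response;
* ``gamma50`` -- the normalized response gradient at the D50 level,
  i.e. ``D50 * dP/dD`` evaluated at ``D = D50`` (dimensionless).

The models and their closed forms:

lyman
    Probit / cumulative-Gaussian form,
    ``P(D) = 0.5 * (1 - erf[gamma50 * sqrt(pi) * (1 - D/D50)])``.
logit
    Log-logistic ("parallel architecture") form,
    ``P(D) = 1 / (1 + (D50/D)**(4*gamma50))``, with ``P(0) = 0`` by
    continuity.  The conventional steepness exponent ``k`` is never a
    free parameter here; it is tied to the slope as ``k = 4*gamma50``.
poisson
    Poisson cell-kill form, ``P(D) = 2**(-exp[e*gamma50*(1 - D/D50)])``.
weibull
    Modified Weibull form,
    ``P(D) = 1 - exp[-ln2 * (D/D50)**((2/ln2)*gamma50)]``.

All four satisfy ``P(D50) = 1/2`` exactly.  The slope identity
``D50 * P'(D50) = gamma50`` holds exactly for lyman, logit and weibull;
for the poisson form the normalized gradient at D50 is
``(e*ln2/2) * gamma50 ~= 0.9421 * gamma50`` -- its gamma parameter is a
steepness parameter that only approximates the normalized gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "MODEL_IDS",
    "NTCPParams",
    "parse_model_id",
    "evaluate",
    "gradient",
    "param_jacobian",
    "lyman_integral_oracle",
]

#: Canonical model identifiers, lower-case.
MODEL_IDS = ("logit", "lyman", "poisson", "weibull")

_LN2 = np.log(2.0)
_SQRT_PI = np.sqrt(np.pi)

#: Normalized gradient at D50 per unit gamma50: 1 for all models except
#: poisson, whose steepness parameter overshoots the slope slightly.
POISSON_SLOPE_FACTOR = float(np.e * _LN2 / 2.0)


def parse_model_id(name: str) -> str:
    """Normalize a model identifier (case-insensitive) to canonical form."""
    canonical = str(name).strip().lower()
    if canonical not in MODEL_IDS:
        raise ValueError(
            f"unknown NTCP model {name!r}; expected one of {', '.join(MODEL_IDS)}"
        )
    return canonical


@dataclass(frozen=True)
class NTCPParams:
    """Dose-response parameters: D50 in Gy and the normalized slope gamma50."""

    d50: float
    gamma50: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d50) and self.d50 > 0):
            raise ValueError(f"d50 must be finite and > 0, got {self.d50}")
        if not (np.isfinite(self.gamma50) and self.gamma50 > 0):
            raise ValueError(f"gamma50 must be finite and > 0, got {self.gamma50}")

    def as_array(self) -> np.ndarray:
        return np.array([self.d50, self.gamma50], dtype=float)


def _check_dose(dose, positive: bool = False) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dose values must be finite")
    if positive:
        if np.any(d <= 0):
            raise ValueError("dose values must be > 0")
    elif np.any(d < 0):
        raise ValueError("dose values must be >= 0")
    return d


def _evaluate_raw(model: str, d50: float, g50: float, d: np.ndarray) -> np.ndarray:
    if model == "lyman":
        return 0.5 * (1.0 - special.erf(g50 * _SQRT_PI * (1.0 - d / d50)))
    if model == "logit":
        # expit(4*g50*log(D/D50)) -> 0 as D -> 0+, defining P(0) = 0.
        with np.errstate(divide="ignore"):
            logratio = np.log(np.where(d > 0, d, np.nan) / d50)
        p = special.expit(4.0 * g50 * np.where(d > 0, logratio, -np.inf))
        return np.where(d > 0, p, 0.0)
    if model == "poisson":
        with np.errstate(over="ignore", under="ignore"):
            return np.exp2(-np.exp(np.e * g50 * (1.0 - d / d50)))
    if model == "weibull":
        m = (2.0 / _LN2) * g50
        with np.errstate(over="ignore", under="ignore"):
            return -np.expm1(-_LN2 * (d / d50) ** m)
    raise AssertionError(model)


def evaluate(model: str, params: NTCPParams, dose) -> np.ndarray | float:
    """Response probability P(D) for one model; vectorized over dose (Gy >= 0)."""
    model = parse_model_id(model)
    d = _check_dose(dose)
    p = _evaluate_raw(model, params.d50, params.gamma50, d)
    return float(p) if np.isscalar(dose) or np.ndim(dose) == 0 else p


def gradient(model: str, params: NTCPParams, dose) -> np.ndarray | float:
    """Analytic derivative dP/dD in 1/Gy; requires dose > 0."""
    model = parse_model_id(model)
    d = _check_dose(dose, positive=True)
    d50, g50 = params.d50, params.gamma50
    if model == "lyman":
        z = g50 * _SQRT_PI * (1.0 - d / d50)
        out = (g50 / d50) * np.exp(-(z**2))
    elif model == "logit":
        p = _evaluate_raw(model, d50, g50, d)
        out = 4.0 * g50 * p * (1.0 - p) / d
    elif model == "poisson":
        with np.errstate(over="ignore", under="ignore"):
            u = np.exp(np.e * g50 * (1.0 - d / d50))
            p = np.exp2(-u)
            out = p * _LN2 * u * np.e * g50 / d50
            out = np.where(np.isfinite(out), out, 0.0)
    elif model == "weibull":
        m = (2.0 / _LN2) * g50
        t = d / d50
        with np.errstate(over="ignore", under="ignore"):
            out = np.exp(-_LN2 * t**m) * _LN2 * m * t ** (m - 1.0) / d50
            out = np.where(np.isfinite(out), out, 0.0)
    else:  # pragma: no cover
        raise AssertionError(model)
    return float(out) if np.isscalar(dose) or np.ndim(dose) == 0 else out


def param_jacobian(model: str, params: NTCPParams, dose) -> np.ndarray:
    """Jacobian of P w.r.t. (d50, gamma50), shape (n, 2). Used by the fitter."""
    model = parse_model_id(model)
    d = np.atleast_1d(_check_dose(dose))
    d50, g50 = params.d50, params.gamma50
    jac = np.zeros((d.size, 2))
    pos = d > 0
    dp = d[pos]
    if model == "lyman":
        z = g50 * _SQRT_PI * (1.0 - d / d50)
        dPdz = -np.exp(-(z**2)) / _SQRT_PI
        jac[:, 0] = dPdz * (g50 * _SQRT_PI * d / d50**2)
        jac[:, 1] = dPdz * (_SQRT_PI * (1.0 - d / d50))
    elif model == "logit":
        p = _evaluate_raw(model, d50, g50, d)[pos]
        w = p * (1.0 - p)
        jac[pos, 0] = w * (-4.0 * g50 / d50)
        jac[pos, 1] = w * 4.0 * np.log(dp / d50)
    elif model == "poisson":
        with np.errstate(over="ignore", under="ignore"):
            u = np.exp(np.e * g50 * (1.0 - d / d50))
            p = np.exp2(-u)
            common = -_LN2 * u * p
            jac[:, 0] = common * (np.e * g50 * d / d50**2)
            jac[:, 1] = common * (np.e * (1.0 - d / d50))
            jac[~np.isfinite(jac)] = 0.0
    elif model == "weibull":
        m = (2.0 / _LN2) * g50
        t = dp / d50
        with np.errstate(over="ignore", under="ignore"):
            s = np.exp(-_LN2 * t**m)
            jac[pos, 0] = -s * _LN2 * m * t**m / d50
            jac[pos, 1] = 2.0 * s * t**m * np.log(t)
            jac[~np.isfinite(jac)] = 0.0
    else:  # pragma: no cover
        raise AssertionError(model)
    return jac


def lyman_integral_oracle(params: NTCPParams, dose: float, tol: float = 1e-9) -> float:
    """Lyman response by adaptive quadrature of its Gaussian integral form.

    Integrates ``(gamma50/D50) * exp(-pi * [gamma50*(x - D50)/D50]**2)``
    from 0 to ``dose``.  With this normalization the integral over the
    whole real line equals 1, so the quadrature agrees with the erf
    closed form up to the truncated mass below D = 0,
    ``0.5*(1 - erf(gamma50*sqrt(pi)))``.

    This routine exists as an independent numerical cross-check of
    :func:`evaluate`; it is never used in fitting.
    """
    if not (0 < tol <= 1e-3):
        raise ValueError("tol must be in (0, 1e-3]")
    d = float(_check_dose(dose))
    if d == 0.0:
        return 0.0
    d50, g50 = params.d50, params.gamma50

    def integrand(x: float) -> float:
        z = g50 * (x - d50) / d50
        return (g50 / d50) * np.exp(-np.pi * z * z)

    value, abserr = integrate.quad(
        integrand, 0.0, d, epsabs=tol, epsrel=tol, points=[d50] if d > d50 else None,
        limit=200,
    )
    if abserr > 10 * tol + 1e-12:
        raise ArithmeticError(
            f"quadrature did not converge: abserr={abserr:.3e} > tol={tol:.3e}"
        )
    return float(value)
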