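"""Exposure–response relative-risk models for ambient PM2.5.

This module implements the two curve families used in global comparative
risk assessments of fine particulate matter:

* the **integrated exposure–response** (IER) family — per-cause relative
  risk curves of the form ``RR(z) = 1 + α·(1 − exp(−γ·(z − z_cf)^δ))``
  above a counterfactual concentration ``z_cf`` and exactly 1 at or
  below it, and
* the **Global Exposure Mortality Model** (GEMM) — a single hazard-ratio
  curve for non-communicable disease plus lower-respiratory-infection
  mortality, ``HR(z) = exp(θ·log(1 + Δ/α)·ω(Δ))`` with
  ``Δ = max(z − z_cf, 0)`` and logistic weight
  ``ω(Δ) = 1/(1 + exp(−(Δ − μ)/ν))``.

Relative risks convert to population attributable fractions via
``PAF = (RR − 1)/RR``.  Curves never return sub-unity risk: below the
counterfactual the risk is clamped to exactly 1 (no extrapolated
benefit), which is standard comparative-risk-assessment practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CAUSES",
    "ADULT_CAUSES",
    "RiskCurveDraw",
    "GemmCurveDraw",
    "evaluate_ier",
    "evaluate_gemm",
    "paf",
]

#: The five causes of death modelled for ambient PM2.5.
CAUSES: tuple[str, ...] = ("IHD", "stroke", "COPD", "lung_cancer", "LRI")

#: Causes restricted to ages above 25 years (LRI applies at all ages).
ADULT_CAUSES: tuple[str, ...] = ("IHD", "stroke", "COPD", "lung_cancer")


def _check_param(name: str, value: float, minimum: float, strict: bool = False) -> None:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if strict:
        if not value > minimum:
            raise ValueError(f"{name} must be > {minimum}, got {value!r}")
    elif not value >= minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {value!r}")


@dataclass(frozen=True)
class RiskCurveDraw:
    """One sampled IER parameter set for a cause/age stratum.

    Parameters
    ----------
    cause
        One of :data:`CAUSES`.
    age_group
        Age-band label.  IHD and stroke curves are typically supplied
        per age band; the other causes use a single band.  A degenerate
        single band is accepted for every cause.
    alpha, gamma, delta
        Shape parameters of the IER form: ``alpha`` is the asymptotic
        excess risk (so ``RR ≤ 1 + alpha``), ``gamma`` the rate and
        ``delta`` the power on the excess concentration.
    z_cf
        Counterfactual concentration (μg/m³) for this draw; the curve
        attributes no risk at or below it.
    draw_id
        Index of the draw within its Monte-Carlo parameter set.
    """

    cause: str
    age_group: str
    alpha: float
    gamma: float
    delta: float
    z_cf: float
    draw_id: int = 0

    def __post_init__(self) -> None:
        if self.cause not in CAUSES:
            raise ValueError(
                f"cause must be one of {CAUSES}, got {self.cause!r}"
            )
        _check_param("alpha", self.alpha, 0.0)
        _check_param("gamma", self.gamma, 0.0)
        _check_param("delta", self.delta, 0.0, strict=True)
        _check_param("z_cf", self.z_cf, 0.0)


@dataclass(frozen=True)
class GemmCurveDraw:
    """One GEMM hazard-ratio parameter set (NCD + LRI mortality).

    ``theta`` is the log-hazard coefficient with standard error
    ``se_theta``; ``knot_alpha`` (μg/m³) scales the log term; ``mu`` and
    ``nu`` (μg/m³) centre and widen the logistic weight.  ``z_cf`` is
    fixed at the model's counterfactual — the lowest concentration
    observed in the fitting cohorts (2.4 μg/m³ in the published model) —
    rather than drawn from a TMREL distribution.
    """

    theta: float
    se_theta: float
    knot_alpha: float
    mu: float
    nu: float
    z_cf: float = 2.4
    cause_group: str = "NCD_LRI"
    draw_id: int = 0

    def __post_init__(self) -> None:
        _check_param("theta", self.theta, -np.inf)
        _check_param("se_theta", self.se_theta, 0.0)
        _check_param("knot_alpha", self.knot_alpha, 0.0, strict=True)
        _check_param("mu", self.mu, -np.inf)
        if not np.isfinite(self.nu) or self.nu == 0:
            raise ValueError(
                f"nu must be finite and non-zero (degenerate logistic weight), got {self.nu!r}"
            )
        _check_param("z_cf", self.z_cf, 0.0)


def _validate_z(z):
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    if np.any(z < 0):
        raise ValueError("z must be >= 0 (concentrations are non-negative)")
    return z


def ier_relative_risk(z, alpha, gamma, delta, z_cf):
    """Vectorised IER relative risk; broadcasts over all arguments.

    Internal workhorse used by the burden engine; prefer
    :func:`evaluate_ier` when working with a single
    :class:`RiskCurveDraw`.
    """
    excess = np.maximum(np.asarray(z, dtype=float) - z_cf, 0.0)
    # -expm1(-x) = 1 - exp(-x), accurate for small gamma·excess^delta
    return 1.0 + alpha * (-np.expm1(-gamma * excess**delta))


def evaluate_ier(z, draw: RiskCurveDraw):
    """Relative risk at concentration ``z`` (μg/m³) under an IER draw.

    Returns 1 exactly for ``z ≤ z_cf``; the curve is continuous and
    non-decreasing in ``z`` with ceiling ``1 + alpha``.  Accepts a
    scalar or array ``z``.
    """
    z = _validate_z(z)
    rr = ier_relative_risk(z, draw.alpha, draw.gamma, draw.delta, draw.z_cf)
    return float(rr) if rr.ndim == 0 else rr


def gemm_hazard_ratio(z, theta, knot_alpha, mu, nu, z_cf):
    """Vectorised GEMM hazard ratio; broadcasts over all arguments."""
    excess = np.maximum(np.asarray(z, dtype=float) - z_cf, 0.0)
    weight = 1.0 / (1.0 + np.exp(-(excess - mu) / nu))
    return np.exp(theta * np.log1p(excess / knot_alpha) * weight)


def evaluate_gemm(z, draw: GemmCurveDraw):
    """Hazard ratio at concentration ``z`` (μg/m³) under a GEMM draw.

    Equals 1 at ``z = z_cf`` and is non-decreasing in ``z`` for
    ``theta > 0``.  Accepts a scalar or array ``z``.
    """
    z = _validate_z(z)
    hr = gemm_hazard_ratio(z, draw.theta, draw.knot_alpha, draw.mu, draw.nu, draw.z_cf)
    return float(hr) if hr.ndim == 0 else hr


def paf(rr):
    """Population attributable fraction ``(RR − 1)/RR`` for ``RR ≥ 1``.

    The curves in this module never return sub-unity risk, so an input
    below 1 signals an upstream bug and is rejected rather than
    silently clamped.
    """
    arr = np.asarray(rr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("rr must be finite")
    if np.any(arr < 1.0):
        raise ValueError(
            f"rr must be >= 1 (got minimum {arr.min()!r}); "
            "risk curves never return sub-unity risk"
        )
    out = (arr - 1.0) / arr
    return float(out) if out.ndim == 0 else out
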