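"""Two-compartment population pharmacokinetics of factor VIII.

The population model is the published two-compartment IV-bolus model for
a conventional FVIII concentrate (BAY 81-8973): elimination clearance CL
and central volume V1 scale with lean body weight through power
functions, intercompartmental clearance Q and peripheral volume V2 are
size-independent, and between-subject variability (BSV) on CL and V1 is
lognormal.  Units throughout: clearances dL·h⁻¹, volumes dL, time h,
doses IU, activity IU·dL⁻¹ (no hidden conversions).

Typical values at the reference lean body weight of 51.1 kg:

========  ========  ==========================  =========
quantity  estimate  covariate effect            BSV (%CV)
========  ========  ==========================  =========
CL        1.88      θ_CL · (LBW/51.1)^0.610     37.0
Q         1.90      —                           —
V1        30.0      θ_V1 · (LBW/51.1)^0.950     11.2
V2        6.37      —                           —
========  ========  ==========================  =========

Residual unexplained variability (proportional 26.7 %CV, additive
1.10 IU·dL⁻¹) is carried as metadata only: simulated activities are
*true* levels and safety criteria are evaluated on true levels.

Activity after IV boluses is evaluated analytically.  The unit-dose
impulse response is the bi-exponential ``A·e^(−αt) + B·e^(−βt)``; a dose
history is superposed dose by dose on top of an additive endogenous
baseline.  Numerical ODE integration is used only as an independent test
oracle, never as the production path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "PKModelSpec",
    "IndividualPKParameters",
    "DoseEvent",
    "MacroConstants",
    "typical_parameters",
    "sample_individual_parameters",
    "sample_cohort_parameters",
    "macro_constants",
    "concentration_profile",
]


@dataclass(frozen=True)
class PKModelSpec:
    """Population PK constants (defaults: published FVIII model).

    ``ruv_proportional_cv`` and ``ruv_additive`` document the model's
    residual-error magnitudes but are never applied to simulated levels.
    """

    cl_typical: float = 1.88  # dL/h at reference LBW
    q_typical: float = 1.90  # dL/h
    v1_typical: float = 30.0  # dL at reference LBW
    v2_typical: float = 6.37  # dL
    lbw_reference: float = 51.1  # kg
    cl_lbw_exponent: float = 0.610
    v1_lbw_exponent: float = 0.950
    bsv_cl_cv: float = 0.370  # fractional CV
    bsv_v1_cv: float = 0.112
    ruv_proportional_cv: float = 0.267  # metadata only
    ruv_additive: float = 1.10  # IU/dL, metadata only

    def __post_init__(self) -> None:
        for name in (
            "cl_typical",
            "q_typical",
            "v1_typical",
            "v2_typical",
            "lbw_reference",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bsv_cl_cv < 0 or self.bsv_v1_cv < 0:
            raise ValueError("BSV coefficients of variation must be non-negative")


@dataclass(frozen=True)
class IndividualPKParameters:
    """Per-subject PK parameters after covariate scaling and BSV."""

    cl: float  # dL/h
    q: float  # dL/h
    v1: float  # dL
    v2: float  # dL
    eta_cl: float = 0.0
    eta_v1: float = 0.0

    def __post_init__(self) -> None:
        if min(self.cl, self.q, self.v1, self.v2) <= 0:
            raise ValueError("cl, q, v1 and v2 must all be positive")


@dataclass(frozen=True)
class DoseEvent:
    """One IV bolus: ``amount_iu`` given instantaneously at ``time_h``."""

    time_h: float
    amount_iu: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")
        if self.amount_iu < 0:
            raise ValueError("amount_iu must be non-negative")


class MacroConstants(NamedTuple):
    """Bi-exponential macro constants of the unit-dose impulse response.

    ``C(t) = coef_a·e^(−alpha·t) + coef_b·e^(−beta·t)`` per IU dosed, with
    ``alpha > beta > 0``.  ``one_compartment`` flags the degenerate
    ``alpha == beta`` fallback where the response collapses to a single
    exponential.
    """

    alpha: float
    beta: float
    coef_a: float
    coef_b: float
    one_compartment: bool = False


def typical_parameters(spec: PKModelSpec, lbw_kg: float) -> IndividualPKParameters:
    """Population-typical parameters at a given lean body weight.

    ``CL = CL_typ·(LBW/LBW_ref)^0.610`` and ``V1 = V1_typ·(LBW/LBW_ref)^0.950``;
    Q and V2 carry no covariate.
    """
    if lbw_kg <= 0:
        raise ValueError(f"lbw_kg must be positive, got {lbw_kg}")
    ratio = lbw_kg / spec.lbw_reference
    return IndividualPKParameters(
        cl=spec.cl_typical * ratio**spec.cl_lbw_exponent,
        q=spec.q_typical,
        v1=spec.v1_typical * ratio**spec.v1_lbw_exponent,
        v2=spec.v2_typical,
    )


def _omega(cv: float) -> float:
    # lognormal SD on the log scale reproducing a fractional CV
    return math.sqrt(math.log1p(cv * cv))


def sample_individual_parameters(
    spec: PKModelSpec, lbw_kg: float, rng: np.random.Generator
) -> IndividualPKParameters:
    """Draw one subject's parameters with lognormal BSV on CL and V1.

    ``CL = CL_typ(LBW)·exp(η_CL)`` with ``η ~ N(0, ω²)``, ``ω² = ln(1+CV²)``,
    so the median equals the typical value and the distribution's
    fractional CV equals the stated %CV.  Q and V2 carry no BSV.  η_CL is
    drawn before η_V1 (fixed order keeps cohorts reproducible).
    """
    typ = typical_parameters(spec, lbw_kg)
    eta_cl = float(rng.normal(0.0, _omega(spec.bsv_cl_cv))) if spec.bsv_cl_cv > 0 else 0.0
    eta_v1 = float(rng.normal(0.0, _omega(spec.bsv_v1_cv))) if spec.bsv_v1_cv > 0 else 0.0
    return IndividualPKParameters(
        cl=typ.cl * math.exp(eta_cl),
        q=typ.q,
        v1=typ.v1 * math.exp(eta_v1),
        v2=typ.v2,
        eta_cl=eta_cl,
        eta_v1=eta_v1,
    )


def sample_cohort_parameters(
    spec: PKModelSpec, lbw_values: Sequence[float], rng: np.random.Generator
) -> list[IndividualPKParameters]:
    """Sample one parameter set per subject, in the given order."""
    return [sample_individual_parameters(spec, lbw, rng) for lbw in lbw_values]


def macro_constants(p: IndividualPKParameters) -> MacroConstants:
    """Convert micro parameters to bi-exponential macro constants.

    With ``k10 = CL/V1``, ``k12 = Q/V1``, ``k21 = Q/V2``: α and β are the
    roots of ``x² − (k10+k12+k21)x + k10·k21``, and
    ``A = (α−k21)/(V1(α−β))``, ``B = (k21−β)/(V1(α−β))`` so that the
    unit-dose response is ``A·e^(−αt) + B·e^(−βt)`` with ``A+B = 1/V1``.
    """
    k10 = p.cl / p.v1
    k12 = p.q / p.v1
    k21 = p.q / p.v2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    if disc <= 0.0:
        # exactly repeated root: mono-exponential limit C = (D/V1)·e^(−k10·t)
        return MacroConstants(
            alpha=k10, beta=k10, coef_a=1.0 / p.v1, coef_b=0.0, one_compartment=True
        )
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = k10 * k21 / alpha  # Vieta; numerically stabler than (s − root)/2
    denom = p.v1 * (alpha - beta)
    return MacroConstants(
        alpha=alpha,
        beta=beta,
        coef_a=(alpha - k21) / denom,
        coef_b=(k21 - beta) / denom,
    )


def concentration_profile(
    p: IndividualPKParameters,
    doses: Sequence[DoseEvent],
    baseline: float,
    time_grid: Sequence[float],
    *,
    predose_at_dose_times: bool = False,
) -> np.ndarray:
    """FVIII activity (IU·dL⁻¹) on ``time_grid`` under a bolus history.

    ``level(t) = baseline + Σ_d amount_d·[A·e^(−α(t−t_d)) + B·e^(−β(t−t_d))]``
    over doses with ``t_d ≤ t``.  A bolus appears instantaneously: by
    default the level *at* ``t_d`` includes that dose; with
    ``predose_at_dose_times=True`` the dose contributes only for
    ``t > t_d``, which yields the pre-dose (trough) value at dose
    instants.  The baseline is an additive constant.

    ``time_grid`` must be sorted ascending and ``doses`` sorted by time.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1:
        raise ValueError("time_grid must be one-dimensional")
    if grid.size > 1 and np.any(np.diff(grid) < 0):
        raise ValueError("time_grid must be sorted ascending")
    times = [d.time_h for d in doses]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("doses must be sorted by time")

    mc = macro_constants(p)
    out = np.full(grid.shape, float(baseline))
    # grid points within 1e-9 h of a dose time count as "at" that dose
    shift = 1e-9 if predose_at_dose_times else -1e-9
    for d in doses:
        if d.amount_iu == 0.0:
            continue
        start = int(np.searchsorted(grid, d.time_h + shift, side="left"))
        if start >= grid.size:
            continue
        dt = grid[start:] - d.time_h
        out[start:] += d.amount_iu * (
            mc.coef_a * np.exp(-mc.alpha * dt) + mc.coef_b * np.exp(-mc.beta * dt)
        )
    return out
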