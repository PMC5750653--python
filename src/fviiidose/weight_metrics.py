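"""Alternative body-size metrics for per-kilogram factor VIII dosing.

Per-kg dosing of FVIII is conventionally based on total body weight (TBW).
Because FVIII distributes into a volume close to plasma volume — which
scales with lean rather than total mass — TBW-based per-kg doses overdose
overweight and obese patients.  This module implements the standard
alternative mass bases used when individualising doses:

* **LBW** — lean body weight, Janmahasatian semi-mechanistic model
  (male form): ``LBW = 9270·TBW / (6680 + 216·BMI)``.
* **IBW** — ideal body weight, Lorentz formula (male form):
  ``IBW = HT − 100 − (HT − 150)/4`` with height in cm.  IBW depends on
  height only, never on TBW or BMI.
* **ABW** — adjusted body weight: IBW plus a fraction of the excess
  weight above IBW, ``ABW_f = IBW + f·(TBW − IBW)``.  The 25% and 40%
  correction factors are in common pharmacokinetic use.

Hemophilia A is X-linked, so the simulated population is male and only
the male constants are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "METRIC_NAMES",
    "Anthropometrics",
    "WeightMetrics",
    "lean_body_weight",
    "ideal_body_weight",
    "adjusted_body_weight",
    "compute_all_metrics",
]

#: Names of the mass bases a per-kg dose may refer to.
METRIC_NAMES = ("TBW", "LBW", "IBW", "ABW25", "ABW40")

# Janmahasatian male LBW constants.
_LBW_NUMERATOR = 9270.0
_LBW_DENOM_CONST = 6680.0
_LBW_DENOM_BMI = 216.0

# TBW must equal BMI·(HT/100)^2; tolerance admits inputs rounded to ~0.01 kg.
_TBW_CONSISTENCY_TOL = 0.01


@dataclass(frozen=True)
class Anthropometrics:
    """Body measurements of one adult male subject.

    The three fields are redundant (``tbw_kg = bmi * (height_cm/100)**2``);
    the constructor enforces that consistency so downstream formulas can
    use whichever representation is convenient.
    """

    height_cm: float
    bmi: float
    tbw_kg: float

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.bmi <= 0 or self.tbw_kg <= 0:
            raise ValueError(
                "height_cm, bmi and tbw_kg must all be positive, got "
                f"height_cm={self.height_cm}, bmi={self.bmi}, tbw_kg={self.tbw_kg}"
            )
        expected = self.bmi * (self.height_cm / 100.0) ** 2
        if abs(self.tbw_kg - expected) > _TBW_CONSISTENCY_TOL:
            raise ValueError(
                f"inconsistent anthropometrics: tbw_kg={self.tbw_kg} but "
                f"bmi*(height/100)^2={expected:.4f}"
            )

    @classmethod
    def from_height_bmi(cls, height_cm: float, bmi: float) -> "Anthropometrics":
        """Construct with TBW derived exactly from height and BMI."""
        return cls(height_cm=height_cm, bmi=bmi, tbw_kg=bmi * (height_cm / 100.0) ** 2)


@dataclass(frozen=True)
class WeightMetrics:
    """All mass bases (kg) derived from one subject's anthropometrics."""

    tbw_kg: float
    lbw_kg: float
    ibw_kg: float
    abw25_kg: float
    abw40_kg: float

    def __post_init__(self) -> None:
        for name in ("tbw_kg", "lbw_kg", "ibw_kg", "abw25_kg", "abw40_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def value_for(self, metric: str) -> float:
        """Return the mass (kg) for a named metric ("TBW", "LBW", ...)."""
        try:
            return {
                "TBW": self.tbw_kg,
                "LBW": self.lbw_kg,
                "IBW": self.ibw_kg,
                "ABW25": self.abw25_kg,
                "ABW40": self.abw40_kg,
            }[metric]
        except KeyError:
            raise KeyError(
                f"unknown weight metric {metric!r}; expected one of {METRIC_NAMES}"
            ) from None


def lean_body_weight(a: Anthropometrics) -> float:
    """Janmahasatian lean body weight (kg), male form.

    ``LBW = 9270·TBW / (6680 + 216·BMI)``.  Strictly increasing in TBW at
    fixed BMI and strictly decreasing in BMI at fixed TBW; below TBW for
    any BMI above ~12 kg·m⁻² (hence throughout the study range).
    """
    return _LBW_NUMERATOR * a.tbw_kg / (_LBW_DENOM_CONST + _LBW_DENOM_BMI * a.bmi)


def ideal_body_weight(height_cm: float) -> float:
    """Lorentz ideal body weight (kg) for an adult male.

    ``IBW = HT − 100 − (HT − 150)/4``; a pure function of height, which is
    what decouples IBW-based doses from adiposity.
    """
    if height_cm <= 0:
        raise ValueError(f"height_cm must be positive, got {height_cm}")
    return height_cm - 100.0 - (height_cm - 150.0) / 4.0


def adjusted_body_weight(tbw_kg: float, ibw_kg: float, fraction: float) -> float:
    """Adjusted body weight ``IBW + fraction·(TBW − IBW)`` (kg).

    ``fraction`` is the correction factor in [0, 1]; 0 recovers IBW and 1
    recovers TBW exactly.
    """
    if tbw_kg <= 0 or ibw_kg <= 0:
        raise ValueError("tbw_kg and ibw_kg must be positive")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    return ibw_kg + fraction * (tbw_kg - ibw_kg)


def compute_all_metrics(a: Anthropometrics) -> WeightMetrics:
    """Bundle TBW, LBW, IBW, ABW25 and ABW40 for one subject."""
    ibw = ideal_body_weight(a.height_cm)
    return WeightMetrics(
        tbw_kg=a.tbw_kg,
        lbw_kg=lean_body_weight(a),
        ibw_kg=ibw,
        abw25_kg=adjusted_body_weight(a.tbw_kg, ibw, 0.25),
        abw40_kg=adjusted_body_weight(a.tbw_kg, ibw, 0.40),
    )
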