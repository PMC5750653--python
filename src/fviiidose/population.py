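"""Synthetic cohorts of virtual adult hemophilia A patients.

Two BMI-stratified groups are generated: a normal-weight group (BMI
uniform on [20.3, 29.6) kg·m⁻²) and an overweight/obese group (BMI
uniform on [29.6, 40.0) kg·m⁻²), the cut-offs that best separate FVIII
in-vivo recovery in adults.  Heights are drawn independently from a
truncated normal emulating the NHANES adult-male distribution, and total
body weight is computed exactly as ``BMI · (height/100)²``.  Each subject
carries the full set of derived mass bases (LBW, IBW, ABW25, ABW40) so a
cohort generated once can be dosed per kg of any metric.

BMI bins are half-open ``[low, high)`` so the shared 29.6 boundary is
unambiguous.  Generation is fully deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .weight_metrics import (
    METRIC_NAMES,
    Anthropometrics,
    WeightMetrics,
    compute_all_metrics,
)

__all__ = [
    "GROUPS",
    "HeightDistribution",
    "PopulationSpec",
    "VirtualPatient",
    "generate_population",
    "population_to_dataframe",
    "write_cohort_csv",
    "summarize_population",
]

#: Group labels, in generation order.
GROUPS = ("normal", "overweight_obese")

_CSV_COLUMNS = [
    "patient_id",
    "group",
    "height_cm",
    "bmi",
    "tbw_kg",
    "lbw_kg",
    "ibw_kg",
    "abw25_kg",
    "abw40_kg",
]


@dataclass(frozen=True)
class HeightDistribution:
    """Truncated normal height model (cm) for adult males.

    Defaults approximate the NHANES adult-male distribution: mean 175.7 cm,
    SD 7.4 cm, truncated to the physiological range [150, 200] cm.
    ``sd_cm = 0`` degenerates to every subject at ``mean_cm``.
    """

    mean_cm: float = 175.7
    sd_cm: float = 7.4
    lower_cm: float = 150.0
    upper_cm: float = 200.0

    def __post_init__(self) -> None:
        if self.sd_cm < 0:
            raise ValueError("sd_cm must be non-negative")
        if not self.lower_cm < self.upper_cm:
            raise ValueError("lower_cm must be below upper_cm")
        if not self.lower_cm <= self.mean_cm <= self.upper_cm:
            raise ValueError("mean_cm must lie within the truncation bounds")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` heights (cm)."""
        if self.sd_cm == 0.0:
            return np.full(n, self.mean_cm)
        a = (self.lower_cm - self.mean_cm) / self.sd_cm
        b = (self.upper_cm - self.mean_cm) / self.sd_cm
        return stats.truncnorm.rvs(
            a, b, loc=self.mean_cm, scale=self.sd_cm, size=n, random_state=rng
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one two-group virtual population."""

    n_per_group: int = 1000
    bmi_normal_range: tuple[float, float] = (20.3, 29.6)
    bmi_high_range: tuple[float, float] = (29.6, 40.0)
    height: HeightDistribution = field(default_factory=HeightDistribution)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        for name, (lo, hi) in (
            ("bmi_normal_range", self.bmi_normal_range),
            ("bmi_high_range", self.bmi_high_range),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got {(lo, hi)}")


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated subject with all derived mass bases."""

    patient_id: str
    group: str
    anthropometrics: Anthropometrics
    metrics: WeightMetrics


def _bmi_range_for(spec: PopulationSpec, group: str) -> tuple[float, float]:
    return spec.bmi_normal_range if group == "normal" else spec.bmi_high_range


def generate_population(spec: PopulationSpec) -> list[VirtualPatient]:
    """Generate ``2 × n_per_group`` virtual patients, normal group first.

    Heights and BMI are sampled independently; within each group BMI is
    uniform on its half-open range.  Same spec (including seed) yields a
    bit-identical population.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    children = root.spawn(len(GROUPS))
    patients: list[VirtualPatient] = []
    for group, child in zip(GROUPS, children):
        rng = np.random.default_rng(child)
        heights = spec.height.sample(spec.n_per_group, rng)
        lo, hi = _bmi_range_for(spec, group)
        bmis = rng.uniform(lo, hi, spec.n_per_group) if lo < hi else np.full(spec.n_per_group, lo)
        for i in range(spec.n_per_group):
            a = Anthropometrics.from_height_bmi(float(heights[i]), float(bmis[i]))
            patients.append(
                VirtualPatient(
                    patient_id=f"{group}-{i:04d}",
                    group=group,
                    anthropometrics=a,
                    metrics=compute_all_metrics(a),
                )
            )
    return patients


def population_to_dataframe(patients: Sequence[VirtualPatient]) -> pd.DataFrame:
    """Flatten a cohort to one row per patient."""
    if len(patients) == 0:
        raise ValueError("empty patient collection")
    rows = [
        {
            "patient_id": p.patient_id,
            "group": p.group,
            "height_cm": p.anthropometrics.height_cm,
            "bmi": p.anthropometrics.bmi,
            "tbw_kg": p.metrics.tbw_kg,
            "lbw_kg": p.metrics.lbw_kg,
            "ibw_kg": p.metrics.ibw_kg,
            "abw25_kg": p.metrics.abw25_kg,
            "abw40_kg": p.metrics.abw40_kg,
        }
        for p in patients
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort_csv(patients: Sequence[VirtualPatient], path) -> None:
    """Write the flattened cohort table to ``path`` as CSV."""
    population_to_dataframe(patients).to_csv(path, index=False)


def summarize_population(patients: Iterable[VirtualPatient]) -> pd.DataFrame:
    """Per-group mean and median of every mass base.

    Returns a long-format table with columns ``group``, ``metric``,
    ``mean_kg`` and ``median_kg``.
    """
    patients = list(patients)
    df = population_to_dataframe(patients)
    metric_cols = {m: f"{m.lower()}_kg" for m in METRIC_NAMES}
    records = []
    for group, sub in df.groupby("group", sort=False):
        for metric, col in metric_cols.items():
            records.append(
                {
                    "group": group,
                    "metric": metric,
                    "mean_kg": sub[col].mean(),
                    "median_kg": sub[col].median(),
                }
            )
    return pd.DataFrame(records)
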