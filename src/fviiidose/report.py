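"""Study outputs: per-table CSVs, a reproducibility manifest, and plots.

CSV layout mirrors the study's summary tables: one file per
(baseline, schedule) with one row per (group, metric) giving the optimal
dose, the safe ratio and median trough at that dose, the mean weekly
factor consumption, and its difference from TBW-based dosing within the
same group.  The manifest records the master seed, a configuration hash
and the package version — enough to regenerate every CSV byte for byte.
Decimal separator is "."; no thousands separators; no timestamps (so
reruns are byte-identical).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .config import StudyConfig, config_hash
from .dose_search import SteadyStateEngine, StudyResult, safety_curve

__all__ = ["emit_report", "plot_safety_curves"]


def emit_report(result: StudyResult, config: StudyConfig, out_dir) -> list[Path]:
    """Write one CSV per (baseline, schedule) plus ``manifest.json``.

    Returns the paths written, manifest last.
    """
    if len(result.table) == 0:
        raise ValueError("cannot emit a report for an empty study result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (baseline, schedule), sub in result.table.groupby(["baseline", "schedule"]):
        path = out / f"doses_{schedule}_baseline{baseline:g}.csv"
        sub.drop(columns=["baseline", "schedule"]).to_csv(
            path, index=False, float_format="%.6g"
        )
        written.append(path)
    manifest = {
        "master_seed": result.master_seed,
        "n_patients": result.n_patients,
        "config_sha256": config_hash(config),
        "package_version": __version__,
        "tables": [p.name for p in written],
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def plot_safety_curves(
    engine: SteadyStateEngine,
    schedule: str,
    baseline: float,
    metrics: Sequence[str],
    doses: Sequence[float],
    path,
    base_dose_per_kg: Optional[float] = None,
) -> Path:
    """Plot safe ratio versus dose for each metric and save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    doses = np.asarray(doses, dtype=float)
    for metric in metrics:
        ratios = safety_curve(engine, schedule, metric, baseline, doses, base_dose_per_kg)
        ax.plot(doses, 100.0 * ratios, label=metric)
    ax.axhline(95.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("dose (IU per kg of metric)")
    ax.set_ylabel("patients with Cmin ≥ 1 IU/dL (%)")
    ax.set_title(f"{schedule}, baseline {baseline:g} IU/dL")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
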