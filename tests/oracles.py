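"""Independent numerical oracles used by the tests.

These deliberately avoid the package's analytic superposition path:
profiles come from stiff ODE integration of the two-compartment mass
balances, and steady-state troughs from closed-form geometric-series
sums.  They exist only to cross-check the implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from fviiidose.pk_model import (
    DoseEvent,
    IndividualPKParameters,
    macro_constants,
)


def ode_concentration_profile(
    p: IndividualPKParameters,
    doses: list[DoseEvent],
    baseline: float,
    time_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Profile via piecewise ODE integration with bolus state jumps.

    dA1/dt = −(k10+k12)·A1 + k21·A2,  dA2/dt = k12·A1 − k21·A2,
    C = A1/V1 + baseline.  Grid points at a dose time take the post-dose
    value, matching the analytic path's default convention.
    """
    k10 = p.cl / p.v1
    k12 = p.q / p.v1
    k21 = p.q / p.v2

    def rhs(_t, y):
        a1, a2 = y
        return [-(k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    grid = np.asarray(time_grid, dtype=float)
    out = np.full(grid.shape, np.nan)
    state = np.zeros(2)
    events_by_time: dict[float, float] = {}
    for d in doses:
        events_by_time[d.time_h] = events_by_time.get(d.time_h, 0.0) + d.amount_iu

    edges = sorted(set(events_by_time) | {float(grid[0]), float(grid[-1])})
    for i, seg_start in enumerate(edges):
        if seg_start in events_by_time:
            state[0] += events_by_time.pop(seg_start)
        last = i + 1 >= len(edges)
        seg_end = grid[-1] if last else edges[i + 1]
        if last:
            sel = grid >= seg_start - 1e-9
        else:
            sel = (grid >= seg_start - 1e-9) & (grid < seg_end - 1e-9)
        t_eval = grid[sel]
        if t_eval.size:
            # points coinciding with the segment start take the current state
            at_start = np.abs(t_eval - seg_start) < 1e-9
            if at_start.all():
                out[sel] = state[0] / p.v1 + baseline
            else:
                sol = solve_ivp(
                    rhs,
                    (seg_start, max(seg_end, t_eval[-1])),
                    state,
                    method="LSODA",
                    t_eval=t_eval,
                    rtol=rtol,
                    atol=atol,
                )
                assert sol.success
                out[sel] = sol.y[0] / p.v1 + baseline
        if not last and seg_end > seg_start:
            sol = solve_ivp(
                rhs, (seg_start, seg_end), state, method="LSODA", rtol=rtol, atol=atol
            )
            assert sol.success
            state = sol.y[:, -1]
    assert not np.isnan(out).any()
    return out


def _unit_response(p: IndividualPKParameters, t: float) -> float:
    mc = macro_constants(p)
    return mc.coef_a * math.exp(-mc.alpha * t) + mc.coef_b * math.exp(-mc.beta * t)


def steady_state_trough_q48(
    p: IndividualPKParameters, dose_iu: float, baseline: float = 0.0, tau: float = 48.0
) -> float:
    """Closed-form pre-dose trough at steady state under equal doses every tau h.

    Geometric-series sum of the bi-exponential over an infinite history:
    ``D·[A·r_a/(1−r_a) + B·r_b/(1−r_b)]`` with ``r = e^(−λτ)``.
    """
    mc = macro_constants(p)
    ra = math.exp(-mc.alpha * tau)
    rb = math.exp(-mc.beta * tau)
    return baseline + dose_iu * (mc.coef_a * ra / (1 - ra) + mc.coef_b * rb / (1 - rb))


def steady_state_cmin_mwf(
    p: IndividualPKParameters,
    base_iu: float,
    friday_iu: float,
    baseline: float = 0.0,
) -> float:
    """Closed-form weekly minimum trough at steady state on the M-W-F calendar.

    Doses ``base`` at hours 0 and 48 and ``friday`` at hour 96 of each
    168 h cycle.  The weekly minimum is the smallest of the three
    pre-dose troughs (pre-Monday after the 72 h gap, pre-Wednesday,
    pre-Friday), each summed as a geometric series over past cycles.
    """
    mc = macro_constants(p)
    cycle = 168.0

    def series(elapsed_mon: float, elapsed_wed: float, elapsed_fri: float) -> float:
        total = 0.0
        for coef, lam in ((mc.coef_a, mc.alpha), (mc.coef_b, mc.beta)):
            r = math.exp(-lam * cycle)
            num = (
                base_iu * math.exp(-lam * elapsed_mon)
                + base_iu * math.exp(-lam * elapsed_wed)
                + friday_iu * math.exp(-lam * elapsed_fri)
            )
            total += coef * num / (1 - r)
        return total

    pre_monday = series(168.0, 120.0, 72.0)
    pre_wednesday = series(48.0, 168.0, 120.0)
    pre_friday = series(96.0, 48.0, 168.0)
    return baseline + min(pre_monday, pre_wednesday, pre_friday)


def lowest_grid_dose(doses: np.ndarray, critical: float) -> float:
    """Smallest grid dose at or above a critical (exact) dose."""
    passing = doses[doses >= critical - 1e-9]
    if passing.size == 0:
        raise ValueError("criterion unreachable on this grid")
    return float(passing[0])
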