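"""Real-time upward PEEP titration during lateral positioning.

At the start of each lateral position PEEP is raised in fixed increments
(default 2 cmH2O from an initial 10 cmH2O) until all of the following hold:

a. global EELI stops decreasing;
b. EELI of the dependent lung stops decreasing, sustained over a
   stabilization window (default 2 min) that restarts after every PEEP
   change;
c. the cumulative dependent-lung EELI drop since lateral onset does not
   exceed a configurable multiple (0.5-1.0) of the dependent lung's tidal
   impedance variation measured in the preceding supine epoch.

"Stops decreasing" is operationalized on per-breath end-expiratory points
as BOTH a least-squares slope above a tolerance AND a bounded drop from the
window maximum - the drop detector catches a single-unit derecruitment
landing at the edge of the window, where the slope estimate is blind.
A safety cap terminates an otherwise unbounded upward titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import TitrationError
from .sim import BreathObs

__all__ = ["TitrationCriteria", "TitrationRecord", "TitrationTrace",
           "eeli_slope", "titrate"]


@dataclass(frozen=True)
class TitrationCriteria:
    """Numeric operationalization of the three titration criteria.

    Tolerances are expressed as fractions of the pre-lateralization
    dependent-lung tidal impedance (the reference dZ), so they scale with
    signal calibration: ``slope_tolerance_frac`` per minute for the
    "stops decreasing" slopes and ``drop_tolerance_frac`` for the
    window-max drop detector.  ``dz_multiple`` is criterion (c)'s
    allowance, between 0.5 and 1.0 times the reference dZ.
    """

    slope_tolerance_frac: float = 0.002  # of reference dZ, per minute
    drop_tolerance_frac: float = 0.002  # of reference dZ
    dependent_window: float = 2.0  # minutes
    global_window: float = 1.0  # minutes
    dz_multiple: float = 1.0
    step_size: float = 2.0  # cmH2O
    max_peep: float = 24.0  # cmH2O
    warmup_s: float = 15.0  # observation before slopes are trusted

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.dependent_window <= 0:
            raise ValueError("dependent_window must be positive")
        if not 0.5 <= self.dz_multiple <= 1.0:
            raise ValueError("dz_multiple must lie in [0.5, 1.0]")
        if self.max_peep <= 0:
            raise ValueError("max_peep must be positive")


@dataclass(frozen=True)
class TitrationRecord:
    """One criteria evaluation."""

    time: float  # s since lateral onset
    peep: float
    global_slope: float | None  # A.U./min (None during warmup)
    dependent_slope: float | None
    cumulative_drop: float  # A.U. below the onset dependent EELI
    crit_a: bool
    crit_b: bool
    crit_c: bool


@dataclass
class TitrationTrace:
    """Full record of one titration run."""

    records: list[TitrationRecord] = field(default_factory=list)
    peep_steps: list[tuple[float, float]] = field(default_factory=list)
    final_peep: float = float("nan")
    terminated_by: str = ""  # 'all_criteria_met' or 'max_peep_reached'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def eeli_slope(times_s: np.ndarray, values: np.ndarray, window_min: float | None = None) -> float:
    """Least-squares EELI slope in A.U. per minute.

    With ``window_min`` given, only the last ``window_min`` minutes of the
    series are used.  Requires at least three end-expiratory points.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if window_min is not None and t.size:
        sel = t >= t[-1] - 60.0 * window_min
        t, v = t[sel], v[sel]
    if t.size < 3:
        raise TitrationError("need at least three end-expiratory points")
    return 60.0 * float(np.polyfit(t, v, 1)[0])


def titrate(
    stream: Iterable[BreathObs],
    dz_reference: float,
    criteria: TitrationCriteria = TitrationCriteria(),
    set_peep: Callable[[float], None] | None = None,
    initial_peep: float = 10.0,
    max_time_s: float = 1800.0,
) -> TitrationTrace:
    """Run the upward titration over a per-breath EELI stream.

    ``stream`` yields :class:`BreathObs` beginning at the lateral-position
    onset; ``set_peep`` is the ventilator controller callback (the same
    engine drives the simulator or a replayed recording).  ``dz_reference``
    is the dependent lung's tidal impedance from the preceding supine epoch
    and must be positive.  Evaluation happens once per breath; on any
    criterion failure PEEP is raised one step and the stabilization window
    restarts.  Termination: all criteria fulfilled, or a failure at the
    safety cap (flagged ``max_peep_reached``), or stream/time exhaustion
    (also flagged ``max_peep_reached`` semantics do not apply - an
    exhausted stream raises).
    """
    if not np.isfinite(dz_reference) or dz_reference <= 0:
        raise TitrationError("missing or non-positive dZ reference")
    slope_tol = criteria.slope_tolerance_frac * dz_reference
    drop_tol = criteria.drop_tolerance_frac * dz_reference
    allowance = criteria.dz_multiple * dz_reference

    trace = TitrationTrace()
    peep = float(initial_peep)
    if set_peep is not None:
        set_peep(peep)
    trace.peep_steps.append((0.0, peep))

    times: list[float] = []
    g_vals: list[float] = []
    d_vals: list[float] = []
    t_change = 0.0
    dep_onset: float | None = None
    n_obs = 0

    def window_arrays(vals: list[float], window_min: float):
        t = np.asarray(times)
        v = np.asarray(vals)
        sel = t >= max(t_change, (t[-1] - 60.0 * window_min) if t.size else 0.0)
        return t[sel], v[sel]

    it: Iterator[BreathObs] = iter(stream)
    for obs in it:
        n_obs += 1
        if dep_onset is None:
            dep_onset = obs.dependent_eeli
        times.append(obs.time)
        g_vals.append(obs.global_eeli)
        d_vals.append(obs.dependent_eeli)

        elapsed = obs.time - t_change
        cum_drop = dep_onset - obs.dependent_eeli
        crit_c = cum_drop <= allowance

        g_slope = d_slope = None
        decreasing = False
        if elapsed >= criteria.warmup_s:
            tg, vg = window_arrays(g_vals, criteria.global_window)
            td, vd = window_arrays(d_vals, criteria.dependent_window)
            if tg.size >= 3:
                g_slope = 60.0 * float(np.polyfit(tg, vg, 1)[0])
            if td.size >= 3:
                d_slope = 60.0 * float(np.polyfit(td, vd, 1)[0])
            g_drop = float(vg.max() - vg[-1]) if tg.size else 0.0
            d_drop = float(vd.max() - vd[-1]) if td.size else 0.0
            decreasing = (
                (g_slope is not None and g_slope < -slope_tol)
                or (d_slope is not None and d_slope < -slope_tol)
                or g_drop > drop_tol
                or d_drop > drop_tol
            )
        crit_a = g_slope is not None and g_slope >= -slope_tol and not decreasing
        crit_b = (
            d_slope is not None
            and d_slope >= -slope_tol
            and elapsed >= 60.0 * criteria.dependent_window
            and not decreasing
        )
        trace.records.append(
            TitrationRecord(obs.time, peep, g_slope, d_slope, cum_drop,
                            crit_a, crit_b, crit_c)
        )

        if crit_a and crit_b and crit_c:
            trace.final_peep = peep
            trace.terminated_by = "all_criteria_met"
            return trace
        if decreasing or not crit_c:
            if peep + criteria.step_size > criteria.max_peep + 1e-9:
                trace.final_peep = peep
                trace.terminated_by = "max_peep_reached"
                return trace
            peep += criteria.step_size
            if set_peep is not None:
                set_peep(peep)
            t_change = obs.time
            trace.peep_steps.append((obs.time, peep))
        if obs.time > max_time_s:
            trace.final_peep = peep
            trace.terminated_by = "max_peep_reached"
            return trace
    if n_obs == 0 or not trace.records:
        raise TitrationError("stream shorter than one evaluation window")
    raise TitrationError("stream ended before titration terminated")
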