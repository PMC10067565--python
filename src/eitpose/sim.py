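"""Compartmental gravitational lung simulator.

The thorax is an ellipse (anterior-posterior span shorter than the
right-left span, as in a real chest).  Each lung pixel of the 32 x 32 EIT
grid holds one lung unit with a compliance coefficient, opening and closing
pressures, and a perfusion weight.  Pleural pressure increases linearly with
gravitational depth; posture only rotates the gravity axis, pixel
coordinates stay body-fixed.  The transpulmonary pressure of a unit is

    P_L = airway pressure - (pleural offset + gradient * gravitational depth)

Recruitment follows a hysteresis rule evaluated breath by breath: a closed
unit opens when its end-inspiratory P_L exceeds its opening pressure, an
open unit closes when its end-expiratory P_L falls below its closing
pressure (optionally after a per-unit delay of a few breaths, which spreads
derecruitment over time the way real lungs derecruit), and otherwise the
state persists.  Driving pressure is emergent: dP = V_T / sum of open-unit
compliances.  The shunt fraction is the perfusion fraction of collapsed
units and maps to a PaO2/FiO2-like oxygenation surrogate.

Rendering composes, per pixel: an end-expiratory baseline proportional to
the unit's aeration, a tidal component shaped by an I:E-aware breath
waveform, a cardiac oscillation proportional to the unit's perfusion
fraction, white sensor noise, and - during apnea - a gamma-variate
first-pass dilution transient after a saline bolus (saline lowers
impedance, so the deflection is negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from . import io as eio
from .errors import DegenerateLungError, EventError
from .io import Event, FrameSequence, ROIMask, default_roi_mask

__all__ = [
    "Posture",
    "SUPINE",
    "LATERAL_LEFT",
    "LATERAL_RIGHT",
    "VentSettings",
    "SimConfig",
    "LungUnit",
    "LungModel",
    "PhysioState",
    "build_lung_model",
    "initialize_state",
    "gravitational_depth",
    "pleural_pressure",
    "transpulmonary_pressure",
    "driving_pressure",
    "step_state",
    "perfusion_fractions",
    "aeration",
    "tidal_amplitudes",
    "oxygenation_surrogate",
    "breath_waveform",
    "Segment",
    "render_frames",
    "make_titration_stream",
    "BreathObs",
    "model_with_ventilation_fractions",
    "model_with_perfusion_fractions",
]


# ----------------------------------------------------------------------
# Configuration types
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Posture:
    """Body position: supine or 30-degree lateral decubitus.

    ``lateral_left`` means the animal lies toward its LEFT side, i.e. the
    left lung is gravitationally dependent (and mirror-wise for
    ``lateral_right``).
    """

    label: str
    tilt_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("supine", "lateral_left", "lateral_right"):
            raise ValueError(f"unknown posture label {self.label!r}")
        if not 0.0 <= self.tilt_angle <= 90.0:
            raise ValueError("tilt_angle must lie in [0, 90] degrees")
        if self.label == "supine" and self.tilt_angle != 0.0:
            raise ValueError("supine posture must have tilt_angle 0")
        if self.label != "supine" and self.tilt_angle == 0.0:
            raise ValueError("lateral posture needs a nonzero tilt angle")


SUPINE = Posture("supine", 0.0)
LATERAL_LEFT = Posture("lateral_left", 30.0)
LATERAL_RIGHT = Posture("lateral_right", 30.0)


@dataclass
class VentSettings:
    """Volume-controlled ventilation settings.

    ``ie_ratio`` is inspiratory:expiratory time as a single number
    (0.5 means 1:2).
    """

    tidal_volume: float = 350.0  # mL
    respiratory_rate: float = 30.0  # breaths/min
    peep: float = 10.0  # cmH2O
    fio2: float = 1.0
    ie_ratio: float = 0.5
    mode: str = "VCV"

    def __post_init__(self) -> None:
        if self.tidal_volume <= 0:
            raise ValueError("tidal_volume must be positive")
        if self.respiratory_rate <= 0:
            raise ValueError("respiratory_rate must be positive")
        if self.peep < 0:
            raise ValueError("peep must be non-negative")
        if not 0.0 < self.fio2 <= 1.0:
            raise ValueError("fio2 must lie in (0, 1]")
        if self.ie_ratio <= 0:
            raise ValueError("ie_ratio must be positive")

    @property
    def breath_period(self) -> float:
        """Seconds per breath."""
        return 60.0 / self.respiratory_rate


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs.

    Geometry and pleural mechanics
    ------------------------------
    thorax_ap_cm / thorax_rl_cm : thorax spans; the right-left span must
        exceed the anterior-posterior one (a chest is wider than deep, which
        is what makes the lateral transpulmonary-pressure spread larger).
    pleural_gradient : cmH2O of pleural pressure per cm of gravitational
        depth (posture-independent slope).
    pleural_offset : pleural pressure at the uppermost thorax point, cmH2O.

    Injury model
    ------------
    injury_severity in [0, 1] interpolates opening/closing pressures between
    a healthy lung (opening <= 0: everything stays open at any PEEP >= 0)
    and a surfactant-depleted lung whose thresholds rise with
    ventral-to-dorsal anatomical depth.  ``collapse_delay_breaths`` spreads
    derecruitment of eligible units over up to that many breaths (0 =
    immediate rule).

    Signal model
    ------------
    z_per_ml calibrates impedance to volume (A.U. per mL); frc_pressure sets
    how much aeration an open unit holds at zero end-expiratory P_L;
    cardiac_amplitude is the summed cardiac oscillation over the whole lung;
    noise_sd is white per-pixel sensor noise; the bolus_* fields parametrize
    the gamma-variate first-pass dilution kernel.

    Perfusion model
    ---------------
    Per-unit weight = base x (1 + gravity_perfusion_slope * depth) x HPV
    factor, where collapsed units are scaled by ``hpv_factor`` (hypoxic
    vasoconstriction) and open units by a conductance term linear in
    end-expiratory P_L (slope ``aeration_perfusion_slope`` around
    ``perfusion_pl_ref``); weights are renormalized to sum to 1.
    """

    seed: int = 0
    frame_rate: float = 50.0
    thorax_ap_cm: float = 22.0
    thorax_rl_cm: float = 30.0
    pleural_gradient: float = 0.7
    pleural_offset: float = -3.0
    injury_severity: float = 1.0
    cardiac_rate: float = 83.0  # beats/min
    cardiac_amplitude: float = 30.0  # A.U., summed over the lung
    noise_sd: float = 0.05  # A.U. per pixel per frame
    hpv_factor: float = 0.6
    gravity_perfusion_slope: float = 0.015  # per cm
    aeration_perfusion_slope: float = 0.16  # per cmH2O
    perfusion_pl_ref: float = 5.0  # cmH2O
    # injury pressure distributions (cmH2O; depth measured from the ventral
    # thorax surface in cm)
    closing_base: float = 3.0
    closing_slope: float = 0.05
    opening_base: float = 21.0
    opening_slope: float = 0.42
    pressure_noise_sd: float = 0.8
    healthy_opening: float = -2.0
    healthy_closing: float = -60.0
    collapse_delay_breaths: int = 40
    # mechanics and signal calibration
    compliance_total: float = 26.0  # mL/cmH2O with every unit open
    compliance_jitter_sd: float = 0.10
    frc_pressure: float = 5.0  # cmH2O
    z_per_ml: float = 1.0
    # oxygenation surrogate
    oxy_ceiling: float = 500.0
    oxy_floor: float = 40.0
    oxy_steepness: float = 20.0
    oxy_midpoint: float = 0.05
    # saline bolus / dilution kernel
    bolus_amplitude: float = 150.0  # A.U., summed over the lung
    bolus_delay_s: float = 1.0
    bolus_time_to_peak_s: float = 2.5
    bolus_shape: float = 3.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.thorax_ap_cm <= 0 or self.thorax_rl_cm <= 0:
            raise ValueError("thorax spans must be positive")
        if self.thorax_rl_cm <= self.thorax_ap_cm:
            raise ValueError(
                "right-left span must exceed the anterior-posterior span"
            )
        if not 0.0 <= self.injury_severity <= 1.0:
            raise ValueError("injury_severity must lie in [0, 1]")
        if not 0.0 <= self.hpv_factor <= 1.0:
            raise ValueError("hpv_factor must lie in [0, 1]")
        for name in ("cardiac_amplitude", "noise_sd", "bolus_amplitude",
                     "compliance_total", "z_per_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.collapse_delay_breaths < 0:
            raise ValueError("collapse_delay_breaths must be >= 0")


# ----------------------------------------------------------------------
# Lung model
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LungUnit:
    """Read-only view of one lung unit (compartment behind one pixel)."""

    pixel_index: int
    compliance_coeff: float  # mL/cmH2O
    opening_pressure: float  # cmH2O
    closing_pressure: float  # cmH2O
    perfusion_weight: float
    is_open: bool
    anatomical_position: tuple[float, float]  # (ventral-dorsal cm, right-left cm)


@dataclass
class LungModel:
    """Array-of-fields collection of lung units (one per lung pixel)."""

    pixel_index: np.ndarray  # (n,) int
    d_ap: np.ndarray  # cm from thorax center, + = dorsal
    rl: np.ndarray  # cm from midline, + = animal's left
    compliance: np.ndarray  # mL/cmH2O
    opening: np.ndarray  # cmH2O
    closing: np.ndarray  # cmH2O
    perfusion_base: np.ndarray
    side: np.ndarray  # 'right_lung' / 'left_lung'
    is_open: np.ndarray  # bool
    collapse_delay: np.ndarray  # breaths until an eligible unit closes
    depth_anat: np.ndarray = field(default=None)  # cm from ventral surface
    countdown: np.ndarray = field(default=None)  # -1 = inactive

    def __post_init__(self) -> None:
        if self.countdown is None:
            self.countdown = np.full(self.n_units, -1, dtype=int)
        if self.depth_anat is None:
            self.depth_anat = self.d_ap - self.d_ap.min()

    @property
    def n_units(self) -> int:
        return self.pixel_index.size

    def unit(self, i: int) -> LungUnit:
        return LungUnit(
            int(self.pixel_index[i]),
            float(self.compliance[i]),
            float(self.opening[i]),
            float(self.closing[i]),
            float(self.perfusion_base[i]),
            bool(self.is_open[i]),
            (float(self.d_ap[i]), float(self.rl[i])),
        )

    def copy(self) -> "LungModel":
        return LungModel(
            self.pixel_index.copy(), self.d_ap.copy(), self.rl.copy(),
            self.compliance.copy(), self.opening.copy(), self.closing.copy(),
            self.perfusion_base.copy(), self.side.copy(), self.is_open.copy(),
            self.collapse_delay.copy(), self.depth_anat.copy(),
            self.countdown.copy(),
        )

    def scatter(self, values: np.ndarray) -> np.ndarray:
        """Spread per-unit values onto the full 1024-pixel vector."""
        out = np.zeros(eio.N_PIXELS)
        out[self.pixel_index] = values
        return out


@dataclass(frozen=True)
class PhysioState:
    """Emergent whole-lung state after a simulation step."""

    driving_pressure: float  # cmH2O
    shunt_fraction: float
    pf_surrogate: float  # mmHg-like
    n_open: int
    open_compliance: float  # mL/cmH2O

    @property
    def plateau(self) -> float:  # pragma: no cover - convenience
        raise AttributeError("plateau depends on PEEP; use peep + driving_pressure")


def build_lung_model(config: SimConfig, roi: ROIMask | None = None) -> LungModel:
    """Instantiate lung units for every lung-mask pixel.

    Deterministic for a fixed ``config.seed``.  Opening and closing
    pressures interpolate between healthy values (opening <= 0) and
    depth-increasing injured means according to ``injury_severity``; the
    per-unit noise is scaled by injury severity as well.  All units start
    open; call :func:`initialize_state` to impose a collapse pattern.
    """
    roi = roi if roi is not None else default_roi_mask()
    pixels = roi.lung_pixels
    n = pixels.size
    rows, cols = pixels // eio.GRID_SIZE, pixels % eio.GRID_SIZE
    ap, rl_span = config.thorax_ap_cm, config.thorax_rl_cm
    d_ap = (rows + 0.5) * ap / eio.GRID_SIZE - ap / 2.0
    rl = (cols + 0.5) * rl_span / eio.GRID_SIZE - rl_span / 2.0
    depth_surface = d_ap + ap / 2.0  # cm from the ventral thorax surface

    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x1C0DE])
    rng = np.random.default_rng(ss)
    inj = config.injury_severity
    noise_c = rng.normal(0.0, config.pressure_noise_sd, n)
    noise_o = rng.normal(0.0, config.pressure_noise_sd, n)
    closing = (1 - inj) * config.healthy_closing + inj * (
        config.closing_base + config.closing_slope * depth_surface + noise_c
    )
    opening = (1 - inj) * config.healthy_opening + inj * (
        config.opening_base + config.opening_slope * depth_surface + noise_o
    )
    opening = np.maximum(opening, closing)  # hysteresis never negative

    weights = np.clip(1.0 + rng.normal(0.0, config.compliance_jitter_sd, n), 0.2, None)
    compliance = config.compliance_total * weights / weights.sum()
    perfusion_base = np.clip(1.0 + rng.normal(0.0, 0.10, n), 0.2, None)
    if config.collapse_delay_breaths > 0:
        # derecruitment at marginal pressures takes tens of seconds; the
        # floor keeps the fastest unit slower than one evaluation window
        lo = max(config.collapse_delay_breaths // 3, 1)
        delays = rng.integers(lo, config.collapse_delay_breaths + 1, n)
    else:
        delays = np.ones(n, dtype=int)

    model = LungModel(
        pixel_index=pixels,
        d_ap=d_ap,
        rl=rl,
        compliance=compliance,
        opening=opening,
        closing=closing,
        perfusion_base=perfusion_base,
        side=roi.side[pixels].copy(),
        is_open=np.ones(n, dtype=bool),
        collapse_delay=delays,
        depth_anat=depth_surface,
    )
    return model


# ----------------------------------------------------------------------
# Pressures
# ----------------------------------------------------------------------

def _gravity_vector(posture: Posture) -> tuple[float, float]:
    """(anterior->posterior, right->left) components of the gravity axis."""
    theta = math.radians(posture.tilt_angle)
    if posture.label == "supine":
        return 1.0, 0.0
    sign = 1.0 if posture.label == "lateral_left" else -1.0
    return math.cos(theta), sign * math.sin(theta)


def gravitational_depth(
    d_ap: np.ndarray | float,
    rl: np.ndarray | float,
    posture: Posture,
    config: SimConfig,
) -> np.ndarray | float:
    """Depth below the uppermost thorax-ellipse point along gravity (cm)."""
    u_ap, u_rl = _gravity_vector(posture)
    a, b = config.thorax_ap_cm / 2.0, config.thorax_rl_cm / 2.0
    support = math.hypot(a * u_ap, b * u_rl)
    return support + u_ap * np.asarray(d_ap) + u_rl * np.asarray(rl)


def pleural_pressure(
    d_ap, rl, posture: Posture, config: SimConfig
) -> np.ndarray | float:
    depth = gravitational_depth(d_ap, rl, posture, config)
    return config.pleural_offset + config.pleural_gradient * depth


def transpulmonary_pressure(
    unit: LungUnit | LungModel,
    airway_pressure: float,
    posture: Posture,
    config: SimConfig,
) -> np.ndarray | float:
    """P_L = airway pressure minus pleural pressure at the unit's depth."""
    if isinstance(unit, LungUnit):
        d_ap, rl = unit.anatomical_position
    else:
        d_ap, rl = unit.d_ap, unit.rl
    return airway_pressure - pleural_pressure(d_ap, rl, posture, config)


def driving_pressure(model: LungModel, vent: VentSettings) -> float:
    """Emergent dP = V_T / total open-unit compliance."""
    c_open = float(model.compliance[model.is_open].sum())
    if c_open <= 0.0:
        raise DegenerateLungError("all lung units collapsed: dP undefined")
    return vent.tidal_volume / c_open


def initialize_state(
    model: LungModel,
    vent: VentSettings,
    posture: Posture,
    config: SimConfig,
    peak_pressure: float | None = None,
) -> LungModel:
    """Impose the initial open/collapsed pattern (in place).

    A unit starts collapsed when its end-inspiratory transpulmonary
    pressure at the given peak pressure stays below its opening pressure
    (the lung is assumed to arrive from a period of injurious ventilation
    with the dependent regions de-aerated).  With ``peak_pressure`` omitted
    it is ``PEEP + V_T / total compliance``.
    """
    if peak_pressure is None:
        peak_pressure = vent.peep + vent.tidal_volume / model.compliance.sum()
    pl_ei = transpulmonary_pressure(model, peak_pressure, posture, config)
    model.is_open = np.asarray(pl_ei > model.opening)
    model.countdown[:] = -1
    if not model.is_open.any():
        raise DegenerateLungError("initial state has no open units")
    return model


# ----------------------------------------------------------------------
# Breath-by-breath dynamics
# ----------------------------------------------------------------------

def step_state(
    model: LungModel,
    vent: VentSettings,
    posture: Posture,
    config: SimConfig,
    n_breaths: int = 1,
) -> PhysioState:
    """Advance the recruitment/derecruitment state by ``n_breaths``.

    Per breath: driving pressure is recomputed from the open-unit
    compliance; closed units with end-inspiratory P_L above their opening
    pressure open; open units with end-expiratory P_L below their closing
    pressure close - immediately when ``collapse_delay_breaths`` is 0,
    otherwise after their per-unit delay (the countdown resets whenever the
    unit is supported again, e.g. after a PEEP increase).  The model is
    modified in place; the returned :class:`PhysioState` reflects the final
    breath.
    """
    pl_pleural = pleural_pressure(model.d_ap, model.rl, posture, config)
    immediate = config.collapse_delay_breaths == 0
    for _ in range(n_breaths):
        dp = driving_pressure(model, vent)
        pl_ei = vent.peep + dp - pl_pleural
        pl_ee = vent.peep - pl_pleural
        opening_now = ~model.is_open & (pl_ei > model.opening)
        model.is_open[opening_now] = True
        model.countdown[opening_now] = -1

        eligible = model.is_open & (pl_ee < model.closing)
        supported = model.is_open & ~eligible
        model.countdown[supported] = -1
        if immediate:
            model.is_open[eligible] = False
        else:
            fresh = eligible & (model.countdown < 0)
            model.countdown[fresh] = model.collapse_delay[fresh]
            model.countdown[eligible] -= 1
            closing_now = eligible & (model.countdown <= 0)
            model.is_open[closing_now] = False
            model.countdown[closing_now] = -1
    return physio_state(model, vent, posture, config)


def physio_state(
    model: LungModel, vent: VentSettings, posture: Posture, config: SimConfig
) -> PhysioState:
    dp = driving_pressure(model, vent)
    q = perfusion_fractions(model, vent, posture, config)
    shunt = float(q[~model.is_open].sum())
    return PhysioState(
        driving_pressure=dp,
        shunt_fraction=shunt,
        pf_surrogate=oxygenation_surrogate(
            shunt, config.oxy_ceiling, config.oxy_floor,
            config.oxy_steepness, config.oxy_midpoint,
        ),
        n_open=int(model.is_open.sum()),
        open_compliance=float(model.compliance[model.is_open].sum()),
    )


def perfusion_fractions(
    model: LungModel, vent: VentSettings, posture: Posture, config: SimConfig
) -> np.ndarray:
    """Per-unit pulmonary blood-flow fractions (sum to 1).

    Weight = base x gravity preference x vascular factor.  Collapsed units
    are attenuated by the hypoxic-vasoconstriction factor; open units carry
    a conductance linear in end-expiratory P_L, which shifts flow toward
    whichever lung moves up (and gains P_L) in lateral posture.
    """
    depth = gravitational_depth(model.d_ap, model.rl, posture, config)
    pl_ee = vent.peep - pleural_pressure(model.d_ap, model.rl, posture, config)
    factor = np.where(
        model.is_open,
        np.clip(
            1.0
            + config.aeration_perfusion_slope * (pl_ee - config.perfusion_pl_ref),
            0.05,
            None,
        ),
        config.hpv_factor,
    )
    w = model.perfusion_base * (1.0 + config.gravity_perfusion_slope * depth) * factor
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise DegenerateLungError("total perfusion weight is zero")
    return w / total


def aeration(
    model: LungModel, vent: VentSettings, posture: Posture, config: SimConfig
) -> np.ndarray:
    """Per-unit end-expiratory aeration signal (A.U.); zero when collapsed.

    A unit part-way through derecruitment (countdown running) de-aerates
    progressively: its level declines linearly with the remaining countdown
    fraction, reaching zero when it closes.  This is what makes an
    impending collapse visible to the EELI criteria before the unit is
    lost; a PEEP step taken in time restores it.
    """
    pl_ee = vent.peep - pleural_pressure(model.d_ap, model.rl, posture, config)
    level = config.z_per_ml * model.compliance * np.clip(
        config.frc_pressure + pl_ee, 0.0, None
    )
    fading = model.countdown >= 0
    frac = np.ones(model.n_units)
    frac[fading] = model.countdown[fading] / np.maximum(
        model.collapse_delay[fading], 1
    )
    return np.where(model.is_open, level * frac, 0.0)


def tidal_amplitudes(
    model: LungModel, vent: VentSettings, config: SimConfig
) -> np.ndarray:
    """Per-unit tidal impedance amplitude (A.U.); zero when collapsed."""
    dp = driving_pressure(model, vent)
    return np.where(model.is_open, config.z_per_ml * model.compliance * dp, 0.0)


def oxygenation_surrogate(
    shunt_fraction: float,
    ceiling: float = 500.0,
    floor: float = 40.0,
    steepness: float = 20.0,
    midpoint: float = 0.05,
) -> float:
    """Map shunt fraction to a PaO2/FiO2-like index (mmHg).

    A normalized logistic interpolation: exactly ``ceiling`` at shunt 0,
    exactly ``floor`` at shunt 1, strictly decreasing in between, with the
    steep part around ``midpoint`` (oxygenation is most sensitive at
    moderate shunt).  Purely a qualitative surrogate - no blood-gas physics
    is claimed.
    """
    s = float(shunt_fraction)
    if not 0.0 <= s <= 1.0:
        raise ValueError("shunt_fraction must lie in [0, 1]")

    def sig(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-x))

    k = steepness
    lo, hi = sig(k * (0.0 - midpoint)), sig(k * (1.0 - midpoint))
    g = (sig(k * (s - midpoint)) - lo) / (hi - lo)
    return ceiling - (ceiling - floor) * g


# ----------------------------------------------------------------------
# Frame rendering
# ----------------------------------------------------------------------

def breath_waveform(phase: np.ndarray, ie_ratio: float) -> np.ndarray:
    """Raised-cosine breath shape on phase in [0, 1): 0 at end-expiration,
    1 at end-inspiration (reached after the inspiratory fraction)."""
    ti = ie_ratio / (1.0 + ie_ratio)
    phase = np.asarray(phase) % 1.0
    insp = phase < ti
    w = np.empty_like(phase, dtype=float)
    w[insp] = 0.5 * (1.0 - np.cos(np.pi * phase[insp] / ti))
    w[~insp] = 0.5 * (1.0 + np.cos(np.pi * (phase[~insp] - ti) / (1.0 - ti)))
    return w


def _gamma_kernel(tau: np.ndarray, config: SimConfig) -> np.ndarray:
    """Gamma-variate first-pass dilution kernel, unit peak at the
    configured time-to-peak."""
    tp, alpha = config.bolus_time_to_peak_s, config.bolus_shape
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / tp
    out[pos] = x**alpha * np.exp(alpha * (1.0 - x))
    return out


@dataclass
class Segment:
    """One homogeneous stretch of rendered signal.

    The lung state is frozen for the duration of the segment (rendering
    assumes a settled state; dynamics happen in the coarse breath loop
    between segments).  ``bolus_time`` is relative to the segment start and
    only legal in apnea segments.  ``extra_events`` are (relative time,
    Event-kind, payload) tuples emitted into the output log.
    """

    model: LungModel
    vent: VentSettings
    posture: Posture
    duration: float  # s
    kind: str = "breathing"  # or "apnea"
    bolus_time: float | None = None
    perfusion: np.ndarray | None = None  # override fractions (ground truth)
    extra_events: Sequence[tuple[float, str, dict]] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("breathing", "apnea"):
            raise ValueError("segment kind must be 'breathing' or 'apnea'")
        if self.bolus_time is not None and self.kind != "apnea":
            raise EventError("bolus event outside an apnea window")
        if self.bolus_time is not None and not (
            0.0 <= self.bolus_time < self.duration
        ):
            raise EventError("bolus time must fall inside the apnea segment")


def render_frames(
    segments: Sequence[Segment],
    config: SimConfig,
    metadata: Mapping | None = None,
    noise_salt: int = 0,
) -> FrameSequence:
    """Render a contiguous :class:`FrameSequence` from scheduled segments.

    Frame count per segment is ``round(duration * frame_rate)``; segments
    butt up against each other so the global time axis stays uniform.  The
    cardiac oscillation is phase-continuous across segments.  Identical
    inputs (and salt) render bit-identical output.
    """
    if not segments:
        raise ValueError("render_frames needs at least one segment")
    fr = config.frame_rate
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0xF4A3, noise_salt])
    )
    chunks: list[np.ndarray] = []
    events: list[Event] = []
    t_start = 0.0
    f_card = config.cardiac_rate / 60.0
    for seg in segments:
        n = int(round(seg.duration * fr))
        t = t_start + np.arange(n) / fr
        model, vent = seg.model, seg.vent
        q = (
            seg.perfusion
            if seg.perfusion is not None
            else perfusion_fractions(model, vent, seg.posture, config)
        )
        baseline = aeration(model, vent, seg.posture, config)
        frames = np.tile(model.scatter(baseline), (n, 1))
        if seg.kind == "breathing":
            amp = tidal_amplitudes(model, vent, config)
            phase = (t - t_start) / vent.breath_period
            frames += np.outer(
                breath_waveform(phase, vent.ie_ratio), model.scatter(amp)
            )
        else:
            events.append(Event(t_start, "apnea_start"))
            if seg.bolus_time is not None:
                tb = t_start + seg.bolus_time
                events.append(
                    Event(tb, "bolus_injection",
                          {"volume_ml": 10.0, "nacl_pct": 10.0})
                )
                tau = t - tb - config.bolus_delay_s
                frames -= np.outer(
                    config.bolus_amplitude * _gamma_kernel(tau, config),
                    model.scatter(q),
                )
            events.append(Event(t_start + seg.duration, "apnea_end"))
        if config.cardiac_amplitude > 0:
            frames += np.outer(
                0.5 * (1.0 - np.cos(2.0 * np.pi * f_card * t)),
                config.cardiac_amplitude * model.scatter(q),
            )
        if config.noise_sd > 0:
            frames += rng.normal(0.0, config.noise_sd, frames.shape)
        for rel_t, kind, payload in seg.extra_events:
            events.append(Event(t_start + rel_t, kind, dict(payload)))
        chunks.append(frames)
        t_start += n / fr
    events.sort(key=lambda e: e.time)
    return FrameSequence(
        fr, np.vstack(chunks), events, metadata or {}, t0=0.0
    )


# ----------------------------------------------------------------------
# Per-breath observation stream (for PEEP titration)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BreathObs:
    """One end-expiratory observation of the simulated lung."""

    time: float  # s since stream start
    global_eeli: float  # A.U.
    dependent_eeli: float  # A.U.


def make_titration_stream(
    model: LungModel,
    vent: VentSettings,
    posture: Posture,
    config: SimConfig,
    dependent_side: str | None = None,
):
    """Breath-by-breath EELI stream from the simulator.

    Returns ``(stream, set_peep)``: an infinite generator of
    :class:`BreathObs` (advancing the model one breath per item) and a
    callback that changes PEEP for subsequent breaths - the programmatic
    controller interface the titration engine drives.
    """
    side = dependent_side or eio.dependent_lung(posture)
    dep = model.side == side

    def set_peep(value: float) -> None:
        vent.peep = float(value)
        # a ventilator change restarts the derecruitment clock of units that
        # are still open: a PEEP step taken in time rescues them
        model.countdown[model.is_open] = -1

    def stream() -> Iterator[BreathObs]:
        t = 0.0
        while True:
            step_state(model, vent, posture, config, n_breaths=1)
            a = aeration(model, vent, posture, config)
            t += vent.breath_period
            yield BreathObs(t, float(a.sum()), float(a[dep].sum()))

    return stream(), set_peep


def dependent_dz_reference(
    model: LungModel, vent: VentSettings, side: str, config: SimConfig
) -> float:
    """Dependent-lung tidal impedance (A.U.) prior to lateralization."""
    amp = tidal_amplitudes(model, vent, config)
    return float(amp[model.side == side].sum())


# ----------------------------------------------------------------------
# Ground-truth scenario constructors
# ----------------------------------------------------------------------

def model_with_ventilation_fractions(
    config: SimConfig,
    fractions: Mapping[str, float],
    roi: ROIMask | None = None,
) -> LungModel:
    """Healthy-lung model whose ROI tidal shares equal ``fractions`` exactly.

    ``fractions`` maps labels of one ROI scheme (quadrants or halves) to
    shares summing to 1; compliance is spread uniformly within each region,
    so the true tidal distribution is known by construction.
    """
    roi = roi if roi is not None else default_roi_mask()
    model = build_lung_model(replace(config, injury_severity=0.0), roi)
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    scheme = "half" if set(fractions) <= set(eio.HALF_LABELS) else "quadrant"
    labels = getattr(roi, scheme)[model.pixel_index]
    comp = np.zeros(model.n_units)
    for lab, frac in fractions.items():
        sel = labels == lab
        if not sel.any():
            raise ValueError(f"no lung pixels in region {lab!r}")
        comp[sel] = frac * config.compliance_total / sel.sum()
    model.compliance = comp
    return model


def model_with_perfusion_fractions(
    config: SimConfig,
    fractions: Mapping[str, float],
    roi: ROIMask | None = None,
) -> tuple[LungModel, np.ndarray]:
    """Healthy-lung model plus exact per-unit perfusion fractions.

    Returns ``(model, q)`` where ``q`` distributes each region's share
    uniformly over its pixels; pass ``q`` as ``Segment.perfusion`` so the
    rendered dilution transient carries a known ground truth.
    """
    roi = roi if roi is not None else default_roi_mask()
    model = build_lung_model(replace(config, injury_severity=0.0), roi)
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    scheme = "half" if set(fractions) <= set(eio.HALF_LABELS) else "quadrant"
    labels = getattr(roi, scheme)[model.pixel_index]
    q = np.zeros(model.n_units)
    for lab, frac in fractions.items():
        sel = labels == lab
        if not sel.any():
            raise ValueError(f"no lung pixels in region {lab!r}")
        q[sel] = frac / sel.sum()
    return model, q
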