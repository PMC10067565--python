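"""Five-position sequential lateral-positioning protocol.

Executes Supine 1 -> Lateral Left -> Supine 2 -> Lateral Right -> Supine 3
on the simulator, invokes the PEEP titration at each lateral onset (PEEP is
carried over when returning to supine), renders a measurement epoch at the
end of each step, and summarizes each step with the ventilation-side
metrics, optional bolus perfusion distribution, and the oxygenation
surrogate.  Cohort runs (independent seeds with jittered model parameters)
feed the paired-comparison statistics: per-quadrant end-expiratory
lung-impedance and perfusion changes of each lateral position against the
immediately preceding supine position.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import breaths as bra
from . import perfusion as perf
from . import sim as simcore
from .errors import AnalysisError, EITPoseError
from .io import FrameSequence, ROIMask, default_roi_mask, dependent_lung
from .titration import TitrationCriteria, TitrationTrace, titrate

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolStep", "PROTOCOL_STEPS", "StepSummary", "ScenarioConfig",
    "ProtocolResult", "run_protocol", "run_cohort", "summaries_frame",
    "PairedComparison", "paired_t", "quadrant_change_report",
    "load_scenario", "save_scenario",
]


@dataclass(frozen=True)
class ProtocolStep:
    label: str
    posture: simcore.Posture
    duration_min: float = 15.0


PROTOCOL_STEPS: tuple[ProtocolStep, ...] = (
    ProtocolStep("Supine1", simcore.SUPINE),
    ProtocolStep("LateralLeft", simcore.LATERAL_LEFT),
    ProtocolStep("Supine2", simcore.SUPINE),
    ProtocolStep("LateralRight", simcore.LATERAL_RIGHT),
    ProtocolStep("Supine3", simcore.SUPINE),
)


@dataclass
class StepSummary:
    """End-of-step measurements (epoch-averaged)."""

    label: str
    posture: str
    peep: float  # cmH2O
    tidal_volume: float  # mL
    driving_pressure: float  # cmH2O
    respiratory_system_compliance: float  # mL/cmH2O = V_T / dP
    ventilation_half: dict  # % of total ventilation
    ventilation_quadrant: dict
    cz_half: dict  # mL/cmH2O
    eeli_quadrant: dict  # A.U.
    pf_surrogate: float
    shunt_fraction: float
    perfusion_quadrant: dict | None = None  # fractions of 1.0


@dataclass
class ScenarioConfig:
    """Everything needed to run the protocol on the simulator.

    Step durations are simulated as ``settle_breaths`` coarse breaths (the
    recruitment state is what matters, not wall clock); the rendered
    measurement epoch mirrors the end-of-step acquisition.  With
    ``peep_policy='schedule'``, lateral PEEP comes from
    ``scheduled_peep[label]`` instead of the titration engine.
    """

    sim: simcore.SimConfig = field(default_factory=simcore.SimConfig)
    vent: simcore.VentSettings = field(default_factory=simcore.VentSettings)
    criteria: TitrationCriteria = field(default_factory=TitrationCriteria)
    settle_breaths: int = 450  # 15 min at 30 breaths/min
    epoch_s: float = 60.0  # rendered breathing epoch per step
    perfusion_enabled: bool = False
    apnea_s: float = 20.0
    bolus_offset_s: float = 3.0
    peep_policy: str = "titrate"  # or "schedule"
    scheduled_peep: dict = field(default_factory=dict)
    # peak airway pressure of the preceding (injurious-ventilation) phase,
    # used to set the initial open/collapsed pattern
    initial_peak_pressure: float | None = 40.0
    # cohort jitter (fractional / additive spreads of subject parameters)
    jitter_compliance: float = 0.08
    jitter_vt: float = 0.08
    jitter_closing: float = 0.3
    jitter_opening: float = 0.5

    def __post_init__(self) -> None:
        if self.peep_policy not in ("titrate", "schedule"):
            raise ValueError("peep_policy must be 'titrate' or 'schedule'")
        if self.epoch_s <= 0 or self.settle_breaths < 0:
            raise ValueError("invalid step timing")


@dataclass
class ProtocolResult:
    summaries: list[StepSummary]
    sequence: FrameSequence
    titration_traces: dict[str, TitrationTrace]
    model: simcore.LungModel


def run_protocol(
    scenario: ScenarioConfig,
    seed: int | None = None,
    roi: ROIMask | None = None,
) -> ProtocolResult:
    """Run the five-step protocol once.

    Steps execute in the fixed order; titration (or the PEEP schedule) is
    applied at each lateral onset and the resulting PEEP carries over into
    the following supine step.  Summaries are computed by the analysis
    modules on the rendered end-of-step epochs - the pipeline consumes its
    own rendered frames, not simulator internals, except for driving
    pressure and the oxygenation surrogate which are ventilator/physiology
    readings.
    """
    config = scenario.sim if seed is None else replace(scenario.sim, seed=int(seed))
    roi = roi if roi is not None else default_roi_mask()
    model = simcore.build_lung_model(config, roi)
    vent = copy.deepcopy(scenario.vent)
    simcore.initialize_state(model, vent, simcore.SUPINE, config,
                             peak_pressure=scenario.initial_peak_pressure)

    segments: list[simcore.Segment] = []
    step_meta: list[dict] = []
    traces: dict[str, TitrationTrace] = {}
    fr = config.frame_rate
    t_cursor = 0.0

    for step in PROTOCOL_STEPS:
        posture = step.posture
        extra = [(0.0, "position_change",
                  {"label": posture.label, "tilt_deg": posture.tilt_angle})]
        if posture.label != "supine":
            side = dependent_lung(posture)
            dz_ref = simcore.dependent_dz_reference(model, vent, side, config)
            if scenario.peep_policy == "titrate":
                stream, set_peep = simcore.make_titration_stream(
                    model, vent, posture, config, dependent_side=side
                )
                trace = titrate(
                    stream, dz_ref, scenario.criteria, set_peep,
                    initial_peep=vent.peep,
                )
                traces[step.label] = trace
                vent.peep = trace.final_peep
            else:
                vent.peep = float(
                    scenario.scheduled_peep.get(step.label, vent.peep)
                )
            extra.append((0.0, "peep_change", {"peep": vent.peep}))
        physio = simcore.step_state(
            model, vent, posture, config, n_breaths=max(scenario.settle_breaths, 1)
        )

        seg = simcore.Segment(
            model.copy(), copy.deepcopy(vent), posture, scenario.epoch_s,
            kind="breathing",
            extra_events=extra + [(0.0, "step_measurement", {"step": step.label})],
        )
        segments.append(seg)
        meta = {
            "step": step.label,
            "posture": posture.label,
            "peep": vent.peep,
            "physio": physio,
            "vent": copy.deepcopy(vent),
            "t_epoch": (t_cursor, t_cursor + scenario.epoch_s),
            "t_bolus": None,
            "t_apnea": None,
        }
        t_cursor += round(scenario.epoch_s * fr) / fr
        if scenario.perfusion_enabled:
            segments.append(
                simcore.Segment(
                    model.copy(), copy.deepcopy(vent), posture,
                    scenario.apnea_s, kind="apnea",
                    bolus_time=scenario.bolus_offset_s,
                )
            )
            meta["t_apnea"] = (t_cursor, t_cursor + scenario.apnea_s)
            meta["t_bolus"] = t_cursor + scenario.bolus_offset_s
            t_cursor += round(scenario.apnea_s * fr) / fr
        step_meta.append(meta)

    seq = simcore.render_frames(
        segments, config,
        metadata={"scenario": "five-step sequential lateral positioning",
                  "seed": int(config.seed)},
    )

    summaries = [
        _summarize_step(seq, meta, roi, config, scenario) for meta in step_meta
    ]
    return ProtocolResult(summaries, seq, traces, model)


def _summarize_step(
    seq: FrameSequence, meta: dict, roi: ROIMask,
    config: simcore.SimConfig, scenario: ScenarioConfig,
) -> StepSummary:
    vent: simcore.VentSettings = meta["vent"]
    physio: simcore.PhysioState = meta["physio"]
    summary = bra.epoch_ventilation_summary(
        seq, roi, vent.respiratory_rate, epoch=meta["t_epoch"]
    )
    dp = physio.driving_pressure
    vtr_half = bra.regional_tidal_volume(
        summary["distribution_half"], vent.tidal_volume
    )
    cz_half = bra.regional_compliance(vtr_half, dp)
    perfusion_q = None
    if meta["t_bolus"] is not None:
        try:
            curves = perf.extract_dilution_curves(
                seq, meta["t_bolus"], meta["t_apnea"], roi,
                cardiac_rate_hz=config.cardiac_rate / 60.0,
            )
            perfusion_q = perf.regional_perfusion(curves, roi, "quadrant").to_dict()
        except (AnalysisError, EITPoseError) as exc:
            logger.warning(
                "perfusion analysis unavailable for %s: %s", meta["step"], exc
            )
    return StepSummary(
        label=meta["step"],
        posture=meta["posture"],
        peep=meta["peep"],
        tidal_volume=vent.tidal_volume,
        driving_pressure=dp,
        respiratory_system_compliance=vent.tidal_volume / dp,
        ventilation_half=summary["distribution_half"].to_dict(),
        ventilation_quadrant=summary["distribution_quadrant"].to_dict(),
        cz_half=cz_half.to_dict(),
        eeli_quadrant=summary["eeli_quadrant"].to_dict(),
        pf_surrogate=physio.pf_surrogate,
        shunt_fraction=physio.shunt_fraction,
        perfusion_quadrant=perfusion_q,
    )


# ----------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------

def run_cohort(
    scenario: ScenarioConfig,
    n_subjects: int = 7,
    seed: int = 0,
    keep_sequences: bool = False,
) -> list[ProtocolResult]:
    """Run the protocol on ``n_subjects`` jittered subjects.

    Each subject gets an independent simulator seed and modest jitter on
    total compliance, tidal volume, and injury pressure offsets, mirroring
    between-animal variability.  Sequences are dropped by default to bound
    memory on long cohorts.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC047])
    )
    results = []
    for k in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = scenario.sim
        cfg = replace(
            cfg,
            seed=sub_seed,
            compliance_total=cfg.compliance_total
            * float(1.0 + rng.uniform(-scenario.jitter_compliance,
                                      scenario.jitter_compliance)),
            closing_base=cfg.closing_base
            + float(rng.normal(0.0, scenario.jitter_closing)),
            opening_base=cfg.opening_base
            + float(rng.normal(0.0, scenario.jitter_opening)),
        )
        vent = copy.deepcopy(scenario.vent)
        vent.tidal_volume *= float(
            1.0 + rng.uniform(-scenario.jitter_vt, scenario.jitter_vt)
        )
        sub_scenario = copy.deepcopy(scenario)
        sub_scenario.sim = cfg
        sub_scenario.vent = vent
        res = run_protocol(sub_scenario)
        if not keep_sequences:
            res.sequence = None  # type: ignore[assignment]
        results.append(res)
    return results


def summaries_frame(results: Sequence[ProtocolResult]) -> pd.DataFrame:
    """Tidy per-subject, per-step table of the scalar metrics."""
    rows = []
    for k, res in enumerate(results):
        for s in res.summaries:
            row = {
                "subject": k,
                "step": s.label,
                "posture": s.posture,
                "peep": s.peep,
                "tidal_volume": s.tidal_volume,
                "driving_pressure": s.driving_pressure,
                "crs": s.respiratory_system_compliance,
                "pf_surrogate": s.pf_surrogate,
                "shunt_fraction": s.shunt_fraction,
                "dorsal_share_pct": s.ventilation_half["dorsal"],
                "ventral_share_pct": s.ventilation_half["ventral"],
                "cz_dorsal": s.cz_half["dorsal"],
                "cz_ventral": s.cz_half["ventral"],
            }
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Paired statistics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PairedComparison:
    """Paired-samples t-test summary for one metric."""

    n: int
    mean_difference: float
    sd_difference: float
    se: float
    t: float
    df: int
    p_value: float


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> PairedComparison:
    """Paired-samples t-test of mean(a - b) against zero.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``df = n - 1`` and a
    two-sided p-value.  Raises on unequal lengths, n < 2, or zero
    difference variance (degenerate input).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AnalysisError("paired samples must be equal-length vectors")
    n = a.size
    if n < 2:
        raise AnalysisError("paired t-test needs n >= 2")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise AnalysisError("zero difference variance: t undefined")
    mean = float(d.mean())
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * float(sstats.t.sf(abs(t), n - 1))
    return PairedComparison(n, mean, sd, se, t, n - 1, p)


def quadrant_change_report(
    results: Sequence[ProtocolResult],
    lateral_label: str,
) -> dict[str, pd.DataFrame]:
    """Per-quadrant changes of a lateral step vs the preceding supine step.

    For each subject the difference (lateral - preceding supine) of the
    per-quadrant EELI epoch means and, when available, of the perfusion
    shares is computed; across subjects a paired t-test summarizes each
    quadrant.  Quadrants are additionally labeled dependent /
    non-dependent for the given posture.  The perfusion table is omitted
    (with a log notice) when no subject carries perfusion data.
    """
    order = [s.label for s in PROTOCOL_STEPS]
    idx = order.index(lateral_label)
    if idx == 0 or "Lateral" not in lateral_label:
        raise AnalysisError("lateral_label must name a lateral step")
    prev_label = order[idx - 1]
    posture = PROTOCOL_STEPS[idx].posture
    dep_side = dependent_lung(posture)
    side_of = {
        "upper_right": "right_lung", "lower_right": "right_lung",
        "upper_left": "left_lung", "lower_left": "left_lung",
    }

    def get(res: ProtocolResult, label: str) -> StepSummary:
        return next(s for s in res.summaries if s.label == label)

    report: dict[str, pd.DataFrame] = {}
    for metric, attr in (("eeli", "eeli_quadrant"),
                         ("perfusion", "perfusion_quadrant")):
        lat, sup = [], []
        for res in results:
            va = getattr(get(res, lateral_label), attr)
            vb = getattr(get(res, prev_label), attr)
            if va is None or vb is None:
                continue
            lat.append(va)
            sup.append(vb)
        if not lat:
            if metric == "perfusion":
                logger.info("no perfusion data: perfusion table omitted")
                continue
            raise AnalysisError("no subjects with EELI data")
        rows = []
        for quad in ("upper_right", "upper_left", "lower_right", "lower_left"):
            a = [v[quad] for v in lat]
            b = [v[quad] for v in sup]
            diffs = np.asarray(a) - np.asarray(b)
            row = {
                "quadrant": quad,
                "lung": "dependent" if side_of[quad] == dep_side else "non_dependent",
                "mean_difference": float(diffs.mean()),
                "n": len(diffs),
            }
            if len(diffs) >= 2 and np.std(diffs, ddof=1) > 0:
                cmp_ = paired_t(a, b)
                row.update(se=cmp_.se, t=cmp_.t, df=cmp_.df, p_value=cmp_.p_value)
            rows.append(row)
        report[metric] = pd.DataFrame(rows).set_index("quadrant")
    return report


# ----------------------------------------------------------------------
# Scenario files
# ----------------------------------------------------------------------

def save_scenario(scenario: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as YAML (all SimConfig/VentSettings/criteria fields)."""
    data = {
        "sim": asdict(scenario.sim),
        "vent": asdict(scenario.vent),
        "criteria": asdict(scenario.criteria),
        "protocol": {
            k: getattr(scenario, k)
            for k in ("settle_breaths", "epoch_s", "perfusion_enabled",
                      "apnea_s", "bolus_offset_s", "peep_policy",
                      "scheduled_peep", "initial_peak_pressure",
                      "jitter_compliance", "jitter_vt",
                      "jitter_closing", "jitter_opening")
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_scenario(path: str | Path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ScenarioConfig(
        sim=simcore.SimConfig(**data.get("sim", {})),
        vent=simcore.VentSettings(**data.get("vent", {})),
        criteria=TitrationCriteria(**data.get("criteria", {})),
        **data.get("protocol", {}),
    )
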