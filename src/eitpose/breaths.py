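"""Breath segmentation and ventilation-side EIT metrics.

Per breath the tidal impedance variation dZ (end-inspiration minus
end-expiration) is read from the raw pixel values at indices found on a
band-limited copy of the global curve: filtering locates timing robustly
but must not bias amplitudes.  From regional dZ follow the ventilation
distribution (regional dZ / total dZ, in percent), the estimated regional
tidal volume V_Tr = share x V_T, and the regional compliance
C_Z = V_Tr / dP.  End-expiratory lung impedance (EELI) is read at the same
end-expiration indices and compared between epochs as a surrogate of
end-expiratory lung-volume change.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import AnalysisError, NoBreathsError
from .io import FrameSequence, ROIMask

logger = logging.getLogger(__name__)

__all__ = [
    "detect_breaths",
    "regional_delta_z",
    "ventilation_distribution",
    "regional_tidal_volume",
    "regional_compliance",
    "eeli_series",
    "delta_eeli",
    "epoch_ventilation_summary",
]


def detect_breaths(
    global_signal: np.ndarray,
    frame_rate: float,
    respiratory_rate_hint: float,
    exclude_windows: Sequence[tuple[float, float]] = (),
    t0: float = 0.0,
) -> pd.DataFrame:
    """Locate breaths on the global impedance curve.

    Returns a breath table (DataFrame) with sample indices ``start`` (the
    pre-inspiratory minimum = end-expiration), ``peak`` (end-inspiration)
    and ``end`` (next end-expiration); each breath spans minimum to next
    minimum.  ``respiratory_rate_hint`` is in breaths/min.
    ``exclude_windows`` (seconds, same clock as ``t0``) drops breaths that
    overlap apnea periods.
    """
    x = np.asarray(global_signal, dtype=float)
    if x.ndim != 1:
        raise AnalysisError("global_signal must be one-dimensional")
    f_r = respiratory_rate_hint / 60.0
    min_len = int(3 * frame_rate / f_r)
    if x.size < min_len:
        raise NoBreathsError("signal shorter than three breath periods")

    nyq = frame_rate / 2.0
    lo, hi = 0.3 * f_r, min(2.5 * f_r, 0.9 * nyq)
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    filt = sps.sosfiltfilt(sos, x)

    amp = float(np.std(filt))
    raw_scale = max(float(np.ptp(x)), 1e-12)
    if amp < 1e-9 * max(raw_scale, 1.0) or np.ptp(filt) < 1e-12:
        raise NoBreathsError("no ventilatory oscillation detected")

    # warn when the spectrum disagrees grossly with the hint
    freqs, psd = sps.periodogram(x - x.mean(), fs=frame_rate)
    band = (freqs > 0.05 * f_r) & (freqs < 10 * f_r)
    if band.any():
        f_dom = float(freqs[band][np.argmax(psd[band])])
        if not 0.5 * f_r <= f_dom <= 2.0 * f_r:
            logger.warning(
                "dominant frequency %.3f Hz inconsistent with hint %.3f Hz",
                f_dom, f_r,
            )

    distance = max(int(0.6 * frame_rate / f_r), 1)
    prominence = 0.5 * amp
    troughs, _ = sps.find_peaks(-filt, distance=distance, prominence=prominence)
    if troughs.size < 2:
        raise NoBreathsError("fewer than two end-expiratory minima found")

    # Filtering the asymmetric breath waveform shifts its extrema and the
    # raw trough is too flat for a pointwise minimum under noise, so each
    # breath is aligned to the ensemble-average breath by least squares
    # (template matching): the filtered curve finds the breaths, the
    # matched template fixes their timing.
    troughs = _align_to_template(x, troughs, frame_rate / f_r)

    rows = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        peak = a + int(np.argmax(filt[a : b + 1]))
        if not a < peak < b:
            continue  # no interior maximum: not a breath
        t_a, t_b = t0 + a / frame_rate, t0 + b / frame_rate
        if any(t_a < w1 and t_b > w0 for w0, w1 in exclude_windows):
            continue
        rows.append((a, peak, b))
    if not rows:
        raise NoBreathsError("no complete breaths detected")
    df = pd.DataFrame(rows, columns=["start", "peak", "end"])
    df.attrs["frame_rate"] = frame_rate
    df.attrs["t0"] = t0
    return df


def _align_to_template(
    x: np.ndarray, troughs: np.ndarray, period_samples: float,
    max_shift: int = 10, n_iter: int = 2,
) -> np.ndarray:
    """Refine trough indices by aligning each breath to the ensemble mean.

    The average cycle over all detected breaths serves as a matched
    template; each trough is shifted (within ``max_shift`` samples) to
    minimize the squared distance between its neighborhood and the
    template.  Averaging concentrates the full breath energy into the
    timing estimate, which a pointwise minimum of the flat end-expiratory
    trough cannot do under noise.
    """
    w = int(0.4 * period_samples)
    if w < 3 or troughs.size < 3:
        return troughs
    offsets = np.arange(-w, w + 1)
    for _ in range(n_iter):
        usable = troughs[(troughs - w - max_shift >= 0)
                         & (troughs + w + max_shift < x.size)]
        if usable.size < 2:
            return troughs
        segments = x[usable[:, None] + offsets[None, :]]
        template = segments.mean(axis=0) - segments.mean()
        refined = []
        for t in troughs:
            if t - w - max_shift < 0 or t + w + max_shift >= x.size:
                refined.append(t)
                continue
            shifts = np.arange(-max_shift, max_shift + 1)
            seg = x[(t + shifts[:, None]) + offsets[None, :]]
            seg = seg - seg.mean(axis=1, keepdims=True)
            score = ((seg - template[None, :]) ** 2).sum(axis=1)
            refined.append(t + int(shifts[np.argmin(score)]))
        troughs = np.unique(refined)
    # the template inherits any systematic shift of the initial filtered
    # troughs; relocate its (low-noise, breath-averaged) minimum and move
    # every trough by that correction
    usable = troughs[(troughs - w >= 0) & (troughs + w < x.size)]
    if usable.size >= 2:
        template = x[usable[:, None] + offsets[None, :]].mean(axis=0)
        k = int(np.argmin(template))
        if 0 < k < template.size - 1:  # parabolic sub-sample interpolation
            y0, y1, y2 = template[k - 1 : k + 2]
            denom = y0 - 2.0 * y1 + y2
            if denom > 0:
                k = k + 0.5 * (y0 - y2) / denom
        correction = int(round(k - w))
        if correction != 0:
            troughs = np.unique(
                np.clip(troughs + correction, 0, x.size - 1)
            )
    return troughs


def _roi_partition(roi: ROIMask, scheme: str) -> dict[str, np.ndarray]:
    part = {lab: roi.pixels(scheme, lab) for lab in roi.labels(scheme)}
    for lab, px in part.items():
        if px.size == 0:
            raise AnalysisError(f"empty ROI {lab!r}")
    return part


def regional_delta_z(
    frames: np.ndarray | FrameSequence,
    breaths: pd.DataFrame,
    roi: ROIMask,
    scheme: str = "quadrant",
) -> pd.DataFrame:
    """Per-breath regional dZ: sum over ROI pixels of (end-inspiration -
    end-expiration) raw pixel values.  Additive over disjoint ROIs, so the
    scheme columns sum to the ``global`` column exactly.
    """
    fr = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    part = _roi_partition(roi, scheme)
    diff = fr[breaths["peak"].to_numpy()] - fr[breaths["start"].to_numpy()]
    out = pd.DataFrame(index=breaths.index)
    for lab, px in part.items():
        out[lab] = diff[:, px].sum(axis=1)
    out["global"] = diff[:, roi.lung_pixels].sum(axis=1)
    return out


def ventilation_distribution(
    dz_by_roi: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Regional share of total tidal ventilation, percent (sums to 100).

    Small negative regional dZ (out-of-phase pixels under noise) is clipped
    to zero before normalization; the clipped mass is logged.
    """
    s = pd.Series(dict(dz_by_roi), dtype=float)
    s = s.drop(labels=["global"], errors="ignore")
    clipped = float(-s[s < 0].sum())
    if clipped > 0:
        logger.info("clipped negative regional dZ mass: %.4g A.U.", clipped)
    s = s.clip(lower=0.0)
    total = float(s.sum())
    if total <= 0.0:
        raise AnalysisError("total tidal impedance variation is zero")
    return 100.0 * s / total


def regional_tidal_volume(
    distribution_pct: pd.Series | Mapping[str, float], tidal_volume: float
) -> pd.Series:
    """Estimated regional V_T in mL: share x total V_T (sums to V_T)."""
    if tidal_volume <= 0:
        raise AnalysisError("tidal_volume must be positive")
    return pd.Series(dict(distribution_pct), dtype=float) / 100.0 * tidal_volume


def regional_compliance(
    v_tr: pd.Series | Mapping[str, float] | float, driving_pressure: float
):
    """Regional compliance C_Z = V_Tr / dP (mL/cmH2O).

    Over a partition the regional values sum to the respiratory-system
    compliance V_T / dP.
    """
    if driving_pressure <= 0:
        raise AnalysisError("driving_pressure must be positive")
    if isinstance(v_tr, (int, float)):
        return float(v_tr) / driving_pressure
    return pd.Series(dict(v_tr), dtype=float) / driving_pressure


def eeli_series(
    frames: np.ndarray | FrameSequence,
    breaths: pd.DataFrame,
    roi: ROIMask,
    scheme: str = "quadrant",
) -> pd.DataFrame:
    """Global and per-ROI EELI at each breath's end-expiration sample.

    Values are read from the raw (unfiltered) frames; the returned table
    has a ``time`` column (seconds) plus one column per label and
    ``global``.
    """
    fr = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    part = _roi_partition(roi, scheme)
    idx = breaths["start"].to_numpy()
    frame_rate = breaths.attrs.get("frame_rate", 1.0)
    t0 = breaths.attrs.get("t0", 0.0)
    out = pd.DataFrame({"time": t0 + idx / frame_rate}, index=breaths.index)
    ee = fr[idx]
    for lab, px in part.items():
        out[lab] = ee[:, px].sum(axis=1)
    out["global"] = ee[:, roi.lung_pixels].sum(axis=1)
    return out


def delta_eeli(
    series: pd.DataFrame,
    epoch_a: tuple[float, float],
    epoch_b: tuple[float, float],
) -> pd.Series:
    """Change in mean EELI from epoch A to epoch B, per column (A.U.).

    Alongside the difference, a slow linear drift (A.U./min, least squares
    over each epoch's end-expiratory points) is reported in
    ``result.attrs['drift_a']`` / ``['drift_b']``; the drift is not
    subtracted - the EELI change is itself the quantity of interest.
    """
    t = series["time"].to_numpy()
    cols = [c for c in series.columns if c != "time"]
    sel_a = (t >= epoch_a[0]) & (t < epoch_a[1])
    sel_b = (t >= epoch_b[0]) & (t < epoch_b[1])
    if not sel_a.any() or not sel_b.any():
        raise AnalysisError("epoch contains no end-expiration samples")
    out = pd.Series(
        {c: series[c][sel_b].mean() - series[c][sel_a].mean() for c in cols}
    )
    for name, sel in (("drift_a", sel_a), ("drift_b", sel_b)):
        if sel.sum() >= 3:
            out.attrs[name] = {
                c: 60.0 * np.polyfit(t[sel], series[c][sel].to_numpy(), 1)[0]
                for c in cols
            }
    return out


def epoch_ventilation_summary(
    seq: FrameSequence,
    roi: ROIMask,
    respiratory_rate_hint: float,
    epoch: tuple[float, float] | None = None,
    drop_edge_breaths: int = 1,
) -> dict:
    """Breath-averaged ventilation metrics over one epoch of a sequence.

    Detects breaths on the epoch slice, drops ``drop_edge_breaths`` at each
    boundary (filter edge effects), and averages regional dZ over the
    remaining breaths.  Returns a dict with the mean distributions for
    halves and quadrants, the mean global dZ, and the per-quadrant/global
    EELI epoch means.
    """
    sub = seq.slice(*epoch) if epoch is not None else seq
    x = sub.frames[:, roi.lung_pixels].sum(axis=1)
    breaths = detect_breaths(
        x, sub.frame_rate, respiratory_rate_hint,
        exclude_windows=sub.apnea_windows(), t0=sub.t0,
    )
    if drop_edge_breaths and len(breaths) > 2 * drop_edge_breaths:
        breaths = breaths.iloc[drop_edge_breaths:-drop_edge_breaths]
    dz_q = regional_delta_z(sub, breaths, roi, "quadrant")
    dz_h = regional_delta_z(sub, breaths, roi, "half")
    eeli_q = eeli_series(sub, breaths, roi, "quadrant")
    return {
        "n_breaths": len(breaths),
        "dz_global": float(dz_q["global"].mean()),
        "distribution_quadrant": ventilation_distribution(
            dz_q.drop(columns="global").mean()
        ),
        "distribution_half": ventilation_distribution(
            dz_h.drop(columns="global").mean()
        ),
        "eeli_quadrant": eeli_q.drop(columns="time").mean(),
    }
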