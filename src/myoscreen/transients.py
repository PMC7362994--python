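"""Extraction of contraction and Ca2+ transient parameters from single-cell traces.

The pipeline is: segment the paced record into beats (stimulus-locked, with a
pre-trigger window for the diastolic baseline), average the beats, then fit the
averaged beat for baseline, peak, % shortening (or % Ca amplitude), the rising
10%->90% interval (TTP90), the 90%-recovery interval from the peak (TTB90) and
single/double exponential relaxation time constants. Cells whose peak
deflection does not clear the noise floor are flagged non-contractile; their
kinetic parameters are reported missing, and % shortening is set to zero so
they still enter population averages without bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: Fraction of the pacing period taken before each stimulus as the baseline
#: (pre-trigger) window when segmenting beats.
PRETRIGGER_FRAC = 0.1

#: A beat is contractile when its peak deflection exceeds
#: max(NOISE_FLOOR_FRAC * baseline, 3 * pre-onset residual SD).
NOISE_FLOOR_FRAC = 0.005

SIGNAL_KINDS = ("sarcomere_length", "cell_length", "ca_ratio")


@dataclass
class Transient:
    """One cell's time series (sarcomere length, cell length or Fura ratio)."""

    time_s: np.ndarray
    signal: np.ndarray
    signal_kind: str = "sarcomere_length"
    pacing_hz: float | None = None
    stimulus_times_s: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape:
            raise ValueError("time_s and signal must have equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        if self.stimulus_times_s is not None:
            self.stimulus_times_s = np.asarray(self.stimulus_times_s, dtype=float)

    @property
    def sample_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    @property
    def polarity(self) -> str:
        return "upward" if self.signal_kind == "ca_ratio" else "downward"


@dataclass
class Beat:
    """One segmented beat; ``time_s`` is relative to the stimulus (onset at 0)."""

    time_s: np.ndarray
    signal: np.ndarray


@dataclass
class TransientParams:
    """Beat-averaged measures for one cell."""

    baseline: float = np.nan
    peak: float = np.nan
    percent_shortening: float = np.nan   # % Ca amplitude for ca_ratio traces
    ttp90_s: float = np.nan
    ttb90_s: float = np.nan
    tau_single_s: float = np.nan
    tau_double: tuple = ()               # (a1, tau1, a2, tau2) when retained
    f_over_f0: float = np.nan            # ca_ratio only
    n_beats_averaged: int = 0
    contractile: bool = False


def segment_beats(transient: Transient) -> list[Beat]:
    """Split a paced record into stimulus-locked beats.

    Each beat spans one pacing period starting ``PRETRIGGER_FRAC`` of a period
    before its stimulus, so the averaged beat carries a pre-onset baseline
    window. When stimulus times are absent the onset phase is estimated from
    the period-folded mean waveform (steepest deflection away from baseline);
    a flat record folds into period-length slices from the start.
    """
    if transient.stimulus_times_s is not None and transient.pacing_hz is None:
        stims = np.asarray(transient.stimulus_times_s, dtype=float)
        period = float(np.median(np.diff(stims))) if stims.size > 1 else \
            float(transient.time_s[-1] - stims[0])
    elif transient.pacing_hz is not None:
        period = 1.0 / transient.pacing_hz
        stims = transient.stimulus_times_s
    else:
        period = estimate_period(transient.time_s, transient.signal)
        stims = None

    t, y = transient.time_s, transient.signal
    dt = 1.0 / transient.sample_hz
    if stims is None:
        stims = _estimate_stimuli(t, y, period, transient.polarity)

    pre = PRETRIGGER_FRAC * period
    beats = []
    for ts in stims:
        lo, hi = ts - pre, ts - pre + period
        sel = (t >= lo - 0.5 * dt) & (t < hi - 0.5 * dt)
        if t[sel].size < 2:
            continue
        # keep only complete windows (full period within the record)
        if t[sel][0] > lo + 1.5 * dt or t[sel][-1] < hi - 2.5 * dt:
            continue
        beats.append(Beat(time_s=t[sel] - ts, signal=y[sel].copy()))
    if len(beats) < 2:
        warnings.warn("fewer than 2 complete beats detected", stacklevel=2)
    return beats


def estimate_period(t: np.ndarray, y: np.ndarray, min_period_s: float = 0.2) -> float:
    """Pacing period from the autocorrelation peak of the mean-removed signal.

    Used when a record carries neither pacing metadata nor stimulus times
    (e.g. traces round-tripped through the tidy CSV format). Raises when the
    record has no periodic content.
    """
    dt = float(np.median(np.diff(t)))
    x = y - np.mean(y)
    if float(np.max(np.abs(x))) < 1e-12:
        raise ValueError("cannot estimate pacing from a flat record")
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    ac = np.fft.irfft(spec)[:n]
    lo = max(int(min_period_s / dt), 2)
    hi = n // 2
    if hi <= lo:
        raise ValueError("record too short to estimate pacing")
    lag = lo + int(np.argmax(ac[lo:hi]))
    if ac[lag] <= 0.1 * ac[0]:
        raise ValueError("no periodic pacing structure detected")
    return lag * dt


def _estimate_stimuli(t, y, period, polarity) -> np.ndarray:
    """Onset phase from the period-folded mean waveform."""
    dt = float(np.median(np.diff(t)))
    nper = max(int(round(period / dt)), 2)
    nfold = (len(y) // nper) * nper
    if nfold == 0:
        return np.array([t[0]])
    folded = y[:nfold].reshape(-1, nper).mean(axis=0)
    dev = folded - np.median(folded)
    if polarity == "downward":
        dev = -dev
    if dev.max() - dev.min() < 1e-12:           # flat record: slice from start
        phase_idx = 0
    else:
        slope = np.gradient(dev)
        ext = int(np.argmax(dev))
        # steepest rise toward the extremum marks the upstroke; back off to
        # the last sub-10% sample before it as the onset
        upstroke = int(np.argmax(slope[: ext + 1])) if ext > 0 else 0
        below = np.nonzero(dev[: upstroke + 1] < 0.05 * dev[ext])[0]
        phase_idx = int(below[-1]) if below.size else upstroke
    t_first = t[0] + phase_idx * dt
    n_beats = int(np.floor((t[-1] - t_first) / period)) + 1
    return t_first + period * np.arange(n_beats)


def average_beats(beats: list[Beat]) -> Beat:
    """Pointwise mean of stimulus-aligned beats, truncated to the shortest."""
    if not beats:
        raise ValueError("average_beats requires at least one beat")
    nmin = min(b.signal.size for b in beats)
    sig = np.mean([b.signal[:nmin] for b in beats], axis=0)
    return Beat(time_s=beats[0].time_s[:nmin], signal=sig)


def _interp_crossing(tseg, yseg, level, rising):
    """First crossing of ``level`` in a segment, linear interp between samples."""
    if rising:
        hit = np.nonzero(yseg >= level)[0]
    else:
        hit = np.nonzero(yseg <= level)[0]
    if hit.size == 0:
        return np.nan
    i = int(hit[0])
    if i == 0:
        return float(tseg[0])
    y0, y1 = yseg[i - 1], yseg[i]
    if y1 == y0:
        return float(tseg[i])
    f = (level - y0) / (y1 - y0)
    return float(tseg[i - 1] + f * (tseg[i] - tseg[i - 1]))


def _parabolic_peak(tseg, yseg, idx):
    """Sub-sample extremum from a parabola through the 5 samples around idx."""
    lo = max(idx - 2, 0)
    hi = min(idx + 3, len(yseg))
    tt, yy = tseg[lo:hi], yseg[lo:hi]
    if tt.size < 3:
        return float(tseg[idx]), float(yseg[idx])
    coef = np.polyfit(tt - tt.mean(), yy, 2)
    if coef[0] == 0:
        return float(tseg[idx]), float(yseg[idx])
    tv = -coef[1] / (2 * coef[0])
    # constrain the vertex to the fitted window
    tv = float(np.clip(tv, tt[0] - tt.mean(), tt[-1] - tt.mean()))
    yv = float(np.polyval(coef, tv))
    return tv + float(tt.mean()), yv


def fit_transient(avg_beat: Beat, signal_kind: str = "sarcomere_length") -> TransientParams:
    """Extract all beat parameters from an averaged, stimulus-aligned beat.

    The beat's time axis must have the stimulus at t=0 with a pre-onset
    baseline window at negative times (as produced by :func:`segment_beats`).
    """
    t, y = avg_beat.time_s, avg_beat.signal
    params = TransientParams()
    pre = t < 0
    if not np.any(pre):        # fall back: first 10% of the window
        pre = np.arange(len(t)) < max(int(0.1 * len(t)), 2)
    baseline = float(np.mean(y[pre]))
    resid_sd = float(np.std(y[pre], ddof=1)) if np.sum(pre) > 1 else 0.0
    params.baseline = baseline

    upward = signal_kind == "ca_ratio"
    dev = (y - baseline) if upward else (baseline - y)
    post = t >= 0
    tpost, dpost = t[post], dev[post]
    idx = int(np.argmax(dpost))
    t_peak, amp = _parabolic_peak(tpost, dpost, idx)
    amp = max(amp, 0.0)
    params.peak = baseline + amp if upward else baseline - amp

    threshold = max(NOISE_FLOOR_FRAC * baseline, 3.0 * resid_sd)
    if amp < threshold:
        params.contractile = False
        params.percent_shortening = 0.0
        if upward:
            params.f_over_f0 = 1.0
        return params

    params.contractile = True
    params.percent_shortening = 100.0 * amp / baseline
    if upward:
        params.f_over_f0 = params.peak / baseline

    # rising-phase 10% -> 90% crossings
    rise_t, rise_d = tpost[: idx + 1], dpost[: idx + 1]
    t10 = _interp_crossing(rise_t, rise_d, 0.10 * amp, rising=True)
    t90 = _interp_crossing(rise_t, rise_d, 0.90 * amp, rising=True)
    if np.isfinite(t10) and np.isfinite(t90):
        params.ttp90_s = t90 - t10

    # recovery: peak -> within 10% of peak amplitude of baseline
    fall_t, fall_d = tpost[idx:], dpost[idx:]
    t_rec = _interp_crossing(fall_t, fall_d, 0.10 * amp, rising=False)
    if np.isfinite(t_rec):
        params.ttb90_s = t_rec - t_peak

    _fit_relaxation(params, fall_t, fall_d, t_peak, amp, t_rec)
    return params


def _fit_relaxation(params, fall_t, fall_d, t_peak, amp, t_rec):
    """Single/double exponential fits to the peak->90%-recovery segment.

    The double-exponential is retained only when it reduces the SSE of the
    single fit by at least 5%.
    """
    hi = fall_t <= (t_rec if np.isfinite(t_rec) else fall_t[-1])
    # the refined peak time may sit past the first sample; clamp at 0 so the
    # exponential models never see negative times
    ts, ds = np.maximum(fall_t[hi] - t_peak, 0.0), fall_d[hi]
    if ts.size < 5:
        return
    tau0 = max((ts[-1] - ts[0]) / 2.3, 1e-4)

    def single(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        p1, _ = curve_fit(single, ts, ds, p0=[amp, tau0],
                          bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=2000)
    except RuntimeError:
        return
    params.tau_single_s = float(p1[1])
    sse1 = float(np.sum((ds - single(ts, *p1)) ** 2))

    def double(tt, a1, tau1, a2, tau2):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    try:
        p2, _ = curve_fit(double, ts, ds,
                          p0=[p1[0] * 0.7, p1[1] * 0.5, p1[0] * 0.3, p1[1] * 2.0],
                          bounds=(0, np.inf), maxfev=5000)
        sse2 = float(np.sum((ds - double(ts, *p2)) ** 2))
        if sse1 > 0 and sse2 <= 0.95 * sse1:
            params.tau_double = tuple(float(v) for v in p2)
    except RuntimeError:
        pass


def analyze_transient(transient: Transient) -> TransientParams:
    """segment -> average -> fit for a single cell record."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beats = segment_beats(transient)
    if not beats:
        return TransientParams()
    avg = average_beats(beats)
    params = fit_transient(avg, transient.signal_kind)
    params.n_beats_averaged = len(beats)
    return params


PARAM_COLUMNS = [
    "cell_id", "prep_id", "condition", "dose_um", "baseline", "peak",
    "pct_shortening", "ttp90_s", "ttb90_s", "tau_s", "f_over_f0",
    "contractile", "n_beats", "error",
]


def analyze_record(records: list[tuple[dict, Transient]]) -> pd.DataFrame:
    """Batch analysis of one dish/condition: one row of parameters per cell.

    Trace-level failures are recorded in the ``error`` column and never abort
    the batch. Logs the count of non-contractile cells.
    """
    if not records:
        warnings.warn("analyze_record called with no traces", stacklevel=2)
        return pd.DataFrame(columns=PARAM_COLUMNS)
    rows = []
    for meta, tr in records:
        row = {
            "cell_id": meta.get("cell_id"),
            "prep_id": meta.get("prep_id"),
            "condition": meta.get("condition", "baseline"),
            "dose_um": meta.get("dose_um", 0.0),
            "error": "",
        }
        try:
            p = analyze_transient(tr)
            row.update(
                baseline=p.baseline, peak=p.peak,
                pct_shortening=p.percent_shortening,
                ttp90_s=p.ttp90_s, ttb90_s=p.ttb90_s, tau_s=p.tau_single_s,
                f_over_f0=p.f_over_f0, contractile=p.contractile,
                n_beats=p.n_beats_averaged,
            )
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            row.update(error=f"{type(exc).__name__}: {exc}", contractile=False,
                       pct_shortening=np.nan, n_beats=0)
        rows.append(row)
    table = pd.DataFrame(rows, columns=PARAM_COLUMNS)
    n_noncontr = int((~table["contractile"].fillna(False).astype(bool)).sum())
    logger.info("analyze_record: %d cells, %d non-contractile", len(table), n_noncontr)
    return table
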