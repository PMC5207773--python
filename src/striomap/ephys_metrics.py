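"""Synaptic-physiology metrics for optogenetically evoked EPSC traces.

Traces are whole-cell voltage-clamp currents (pA, negative-going EPSCs)
with known photostimulus onsets.  The metrics follow the conventions of
striatal channelrhodopsin mapping experiments:

* responder detection: any post-stimulus peak exceeding 6x the baseline SD,
* amplitude / 10-90% rise / 90-10% decay kinetics, with the decay measured
  against the post-EPSC plateau so a sustained slow current does not
  inflate it,
* paired-pulse ratio (two stimuli 50 ms apart), the second amplitude
  measured from the extrapolated exponential tail of the first EPSC,
* 20 Hz train dynamics: per-stimulus amplitudes and 50 ms charge transfers
  normalized to the first stimulus, and the slow sustained current
  (10 ms window before the 10th stimulus vs before the 1st, normalized to
  the first EPSC peak),
* the cell-inclusion rule (first evoked EPSC of at most -100 pA).

All metrics are invariant to a constant holding-current offset.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

RESPONDER_SD_FACTOR = 6.0
INCLUSION_FLOOR_PA = -100.0
#: absolute responder floor (pA) used when the baseline is noiseless
DEGENERATE_BASELINE_FLOOR_PA = 5.0


class TraceError(ValueError):
    """Raised for malformed traces or windows falling off the trace."""


@dataclasses.dataclass
class EPSCTrace:
    """A current trace with stimulus metadata (and optional ground truth)."""

    current: np.ndarray  # pA, negative-going EPSCs
    sampling_khz: float
    stimulus_times_ms: list[float]
    ground_truth: dict | None = None

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=np.float64)
        if self.current.ndim != 1:
            raise TraceError("current must be a 1D time series")
        if self.sampling_khz <= 0:
            raise TraceError("sampling rate must be positive")
        t = np.asarray(self.stimulus_times_ms, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise TraceError("stimulus times must be nonempty and strictly increasing")
        if t[0] < 0 or t[-1] >= self.duration_ms:
            raise TraceError("stimulus times must lie within the trace")
        self.stimulus_times_ms = t.tolist()

    @property
    def duration_ms(self) -> float:
        return self.current.size / self.sampling_khz

    def index(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_khz))

    def window(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        i0, i1 = self.index(t0_ms), self.index(t1_ms)
        if i0 < 0 or i1 > self.current.size or i1 <= i0:
            raise TraceError(f"window [{t0_ms}, {t1_ms}) ms falls outside the trace")
        return self.current[i0:i1]


def _stim_windows(trace: EPSCTrace, default_ms: float = 50.0):
    """Per-stimulus peak-search windows [onset, onset + inter-stimulus interval)."""
    times = trace.stimulus_times_ms
    out = []
    for k, t in enumerate(times):
        if k + 1 < len(times):
            end = times[k + 1]
        else:
            end = min(t + default_ms, trace.duration_ms)
        out.append((t, end))
    return out


def baseline_stats(trace: EPSCTrace, window_ms=None):
    """(mean, sd) of the pre-stimulus baseline."""
    if window_ms is None:
        window_ms = (0.0, trace.stimulus_times_ms[0])
    if window_ms[1] > trace.stimulus_times_ms[0] + 1e-9:
        raise TraceError("baseline window must precede the first stimulus")
    seg = trace.window(*window_ms)
    return float(seg.mean()), float(seg.std())


def detect_responder(trace: EPSCTrace, baseline_window_ms=None,
                     degenerate_floor_pa: float = DEGENERATE_BASELINE_FLOOR_PA) -> bool:
    """True iff any post-stimulus EPSC peak magnitude strictly exceeds 6x baseline SD.

    A zero-variance (noiseless) baseline is degenerate; the absolute floor
    ``degenerate_floor_pa`` is used as the threshold instead.
    """
    mean, sd = baseline_stats(trace, baseline_window_ms)
    threshold = RESPONDER_SD_FACTOR * sd if sd > 0 else degenerate_floor_pa
    for t0, t1 in _stim_windows(trace):
        peak = mean - trace.window(t0, t1).min()  # EPSCs are negative-going
        if peak > threshold:
            return True
    return False


def _crossing_time(t, y, level, rising: bool):
    """First time y crosses `level` (interpolated); None if never."""
    if rising:
        hit = np.nonzero(y >= level)[0]
    else:
        hit = np.nonzero(y <= level)[0]
    if hit.size == 0:
        return None
    i = hit[0]
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def epsc_kinetics(trace: EPSCTrace, stimulus_index: int = 0):
    """(amplitude pA, rise ms, decay ms) of one evoked EPSC.

    Amplitude is peak minus the 10 ms pre-stimulus baseline (negative for
    an inward EPSC).  Rise is the 10%-to-90% interval of the falling edge;
    decay is the 90%-to-10% interval measured relative to the post-EPSC
    plateau (mean over the last 10 ms of the peak window), which subtracts
    any slow sustained component.  Rise/decay are None when the respective
    crossings are not reached within the window.
    """
    windows = _stim_windows(trace)
    if not 0 <= stimulus_index < len(windows):
        raise TraceError(f"no stimulus with index {stimulus_index}")
    t0, t1 = windows[stimulus_index]
    pre0 = max(0.0, t0 - 10.0)
    baseline = float(trace.window(pre0, t0).mean()) if t0 > pre0 else 0.0
    seg = trace.window(t0, t1)
    tt = t0 + np.arange(seg.size) / trace.sampling_khz
    i_peak = int(seg.argmin())
    peak = float(seg[i_peak])
    amplitude = peak - baseline
    if amplitude >= 0:
        return amplitude, None, None
    lvl10 = baseline + 0.1 * amplitude
    lvl90 = baseline + 0.9 * amplitude
    t10 = _crossing_time(tt[: i_peak + 1], seg[: i_peak + 1], lvl10, rising=False)
    t90 = _crossing_time(tt[: i_peak + 1], seg[: i_peak + 1], lvl90, rising=False)
    rise = (t90 - t10) if (t10 is not None and t90 is not None) else None
    plateau = float(trace.window(max(t0, t1 - 10.0), t1).mean())
    drop = peak - plateau
    decay = None
    if drop < 0:
        d90 = plateau + 0.9 * drop
        d10 = plateau + 0.1 * drop
        td90 = _crossing_time(tt[i_peak:], seg[i_peak:], d90, rising=True)
        td10 = _crossing_time(tt[i_peak:], seg[i_peak:], d10, rising=True)
        if td90 is not None and td10 is not None:
            decay = td10 - td90
    return amplitude, rise, decay


def _exp_tail_baseline(trace: EPSCTrace, onset1: float, onset2: float):
    """Extrapolated single-exponential tail of EPSC1 over the EPSC2 window."""
    fit0 = onset1 + 20.0
    seg = trace.window(fit0, onset2)
    t = np.arange(seg.size) / trace.sampling_khz

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    c0 = float(seg[-1])
    a0 = float(seg[0] - c0) or -1.0
    try:
        popt, _ = curve_fit(model, t, seg, p0=(a0, 10.0, c0), maxfev=5000)
        a, tau, c = popt
        if tau <= 0:
            raise RuntimeError
    except Exception:
        # fall back to the mean of the last 5 ms before the second stimulus
        tail = float(trace.window(onset2 - 5.0, onset2).mean())
        return lambda t_ms: np.full_like(np.asarray(t_ms, dtype=float), tail)
    return lambda t_ms: model(np.asarray(t_ms, dtype=float) - fit0, a, tau, c)


def paired_pulse_ratio(trace: EPSCTrace, baseline_mode: str = "exp_tail",
                       enforce_inclusion: bool = True):
    """PPR = amplitude(EPSC2) / amplitude(EPSC1) for two stimuli 50 ms apart.

    EPSC2 is measured against the decayed tail of EPSC1: by default a
    single-exponential fit on [onset1 + 20 ms, onset2) extrapolated under
    the second peak (``baseline_mode='prestim'`` switches to the simple
    mean of the 5 ms before the second stimulus).  Returns None when the
    first EPSC fails the -100 pA inclusion rule and ``enforce_inclusion``.
    """
    if len(trace.stimulus_times_ms) != 2:
        raise TraceError("paired-pulse ratio requires exactly 2 stimuli")
    onset1, onset2 = trace.stimulus_times_ms
    amp1, _, _ = epsc_kinetics(trace, 0)
    if enforce_inclusion and not include_cell(amp1):
        return None
    if baseline_mode == "exp_tail":
        base_fn = _exp_tail_baseline(trace, onset1, onset2)
    elif baseline_mode == "prestim":
        tail = float(trace.window(onset2 - 5.0, onset2).mean())
        base_fn = lambda t_ms: np.full_like(np.asarray(t_ms, dtype=float), tail)
    else:
        raise TraceError(f"unknown baseline mode {baseline_mode!r}")
    end2 = min(onset2 + (onset2 - onset1), trace.duration_ms)
    seg2 = trace.window(onset2, end2)
    tt2 = onset2 + np.arange(seg2.size) / trace.sampling_khz
    resid = seg2 - base_fn(tt2)
    amp2 = float(resid.min())
    return amp2 / amp1


def train_dynamics(trace: EPSCTrace):
    """Relative amplitudes, relative 50 ms charges and slow-current fraction.

    Requires 10 stimuli at 50 ms spacing.  Per-stimulus amplitude is the
    window minimum against the mean of the 2 ms immediately pre-stimulus
    (so the slowly building plateau is subtracted); charge is the integral
    of (current - pre-train baseline) over [onset, onset + 50 ms); both
    are normalized to the first stimulus.  The slow current is the change
    in mean current (10 ms windows) before the 10th vs before the 1st
    stimulus, normalized to the first EPSC peak.
    """
    times = trace.stimulus_times_ms
    if len(times) != 10:
        raise TraceError("train dynamics requires 10 stimuli")
    if not np.allclose(np.diff(times), 50.0, atol=1e-6):
        raise TraceError("train stimuli must be 50 ms apart (20 Hz)")
    if times[-1] + 50.0 > trace.duration_ms + 1e-9:
        raise TraceError("trace ends before the last 50 ms stimulus window")
    base0 = float(trace.window(times[0] - 10.0, times[0]).mean())
    amps = []
    charges = []
    dt_ms = 1.0 / trace.sampling_khz
    for t in times:
        pre = float(trace.window(t - 2.0, t).mean())
        seg = trace.window(t, min(t + 50.0, trace.duration_ms))
        amps.append(float(seg.min()) - pre)
        charges.append(float((seg - base0).sum() * dt_ms))  # pA*ms
    amps = np.asarray(amps)
    charges = np.asarray(charges)
    if amps[0] == 0 or charges[0] == 0:
        raise TraceError("first stimulus evoked no measurable EPSC")
    rel_amps = amps / amps[0]
    rel_charges = charges / charges[0]
    pre10 = float(trace.window(times[-1] - 10.0, times[-1]).mean())
    slow = (pre10 - base0) / amps[0]  # both negative for inward currents
    return rel_amps, rel_charges, float(slow)


def include_cell(first_epsc_amplitude_pa: float) -> bool:
    """Cell-inclusion rule: first evoked EPSC of at most -100 pA (inclusive)."""
    return first_epsc_amplitude_pa <= INCLUSION_FLOOR_PA


# ---------------------------------------------------------------------------
# Trace IO: CSV (time_ms, current_pA) with a JSON sidecar
# ---------------------------------------------------------------------------

def save_trace(trace: EPSCTrace, path) -> None:
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    t = np.arange(trace.current.size) / trace.sampling_khz
    pd.DataFrame({"time_ms": t, "current_pA": trace.current}).to_csv(path, index=False)
    sidecar = {
        "sampling_khz": trace.sampling_khz,
        "stimulus_times_ms": trace.stimulus_times_ms,
        "ground_truth": trace.ground_truth,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_trace(path) -> EPSCTrace:
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EPSCTrace(
        df["current_pA"].to_numpy(),
        sidecar["sampling_khz"],
        sidecar["stimulus_times_ms"],
        ground_truth=sidecar.get("ground_truth"),
    )
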