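"""Named experiment protocols and the spike-train measurement layer.

Segmentation taxonomy (three classes of silence, by length):

* cf_pause  — short (~tens of ms) gap immediately after a CF-evoked
  complex spike;
* quiescent — gap above 500 ms, covering both CF-toggled down states
  (~1 s) and pump-generated silences (>> 1 s);
* firing epochs between them split into *burst* stretches (somatic spikes
  accompanied by a dendritic Ca spike within 50 ms) and *tonic* remainder.

The detection constants (spike threshold -20 mV, 2 ms refractory, 500 ms
quiescence gap, 50 ms burst-association window, 5/15 ms complex-spike
windows) are scale choices fixed from the waveforms the model produces;
all are overridable keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .config import ModelConfig
from .engine import ProtocolSpec, Trace, simulate

SPIKE_THRESHOLD = -20.0       # mV
SPIKE_REFRACTORY = 2.0        # ms
QUIESCENT_GAP = 500.0         # ms
BURST_WINDOW = 50.0           # ms
CS_ONSET_WINDOW = 5.0         # ms after a CF event
CS_SPAN = 15.0                # ms for >= 2 spikes
CF_PAUSE_MAX = 100.0          # ms
DEND_SPIKE_THRESHOLD = -30.0  # mV


class AnalysisError(ValueError):
    """Missing channel or malformed inputs to the measurement layer."""


# ---------------------------------------------------------------------------
# spike detection on sampled traces (the engine also records full-rate
# crossings; this operates on any uniformly sampled voltage channel)
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, compartment: int = 0,
                  threshold: float = SPIKE_THRESHOLD,
                  refractory: float = SPIKE_REFRACTORY) -> np.ndarray:
    """Peak-aligned upward threshold crossings of one voltage channel."""
    if trace.v.ndim != 2 or compartment >= trace.v.shape[1]:
        raise AnalysisError(f"no voltage channel for compartment {compartment}")
    v = trace.v[:, compartment]
    t = trace.t
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -np.inf
    for i in crossings:
        if t[i] - last < refractory:
            continue
        # align to the local peak while the trace stays above threshold
        j = i
        while j + 1 < len(v) and v[j + 1] >= v[j] and above[j + 1]:
            j += 1
        times.append(t[j])
        last = t[i]
    return np.asarray(times)


def detect_complex_spikes(spikes: np.ndarray, cf_events: np.ndarray,
                          dend_spikes: np.ndarray | None = None,
                          onset: float = CS_ONSET_WINDOW,
                          span: float = CS_SPAN) -> np.ndarray:
    """Times of CF-evoked complex spikes.

    A complex spike is a somatic multi-spike event (>= 2 spikes within
    ``span`` ms) beginning within ``onset`` ms of a CF event and, when
    dendritic spike times are supplied, co-incident with a dendritic Ca
    spike.  Bursts without a CF event are excluded by construction.
    """
    spikes = np.asarray(spikes)
    out = []
    for e in np.asarray(cf_events):
        first = spikes[(spikes >= e) & (spikes <= e + onset)]
        if len(first) == 0:
            continue
        t0 = first[0]
        n_in_span = np.sum((spikes >= t0) & (spikes <= t0 + span))
        if n_in_span < 2:
            continue
        if dend_spikes is not None and len(dend_spikes) > 0:
            if not np.any((dend_spikes >= e - 1.0)
                          & (dend_spikes <= e + 10.0)):
                continue
        elif dend_spikes is not None:
            continue
        out.append(t0)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# mode segmentation
# ---------------------------------------------------------------------------

@dataclass
class ModeSegmentation:
    """Non-overlapping labeled intervals tiling the analysis window."""

    intervals: list[tuple[float, float, str]]

    def total(self, label: str) -> float:
        return sum(e - s for s, e, lab in self.intervals if lab == label)

    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.intervals]

    def of_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


@dataclass
class SpikeTrainSummary:
    """Headline numbers of one simulated protocol."""

    spike_times: np.ndarray
    complex_spike_times: np.ndarray
    dend_spike_times: np.ndarray
    tonic_rate_hz: float
    firing_length_ms: float
    repeat_length_ms: float
    up_durations_ms: list[float] = field(default_factory=list)
    down_durations_ms: list[float] = field(default_factory=list)


def segment_modes(spikes: Sequence[float], ca_spikes: Sequence[float],
                  window: tuple[float, float],
                  complex_spikes: Sequence[float] = (),
                  quiescent_gap: float = QUIESCENT_GAP,
                  burst_window: float = BURST_WINDOW,
                  cf_pause_max: float = CF_PAUSE_MAX) -> ModeSegmentation:
    """Tile ``window`` with tonic / burst / quiescent / cf_pause intervals."""
    t0, t1 = window
    spikes = np.asarray([s for s in spikes if t0 <= s <= t1])
    ca_spikes = np.asarray(ca_spikes)
    complex_spikes = np.asarray(complex_spikes)
    if len(spikes) == 0:
        return ModeSegmentation([(t0, t1, "quiescent")])

    # label each spike tonic/burst by Ca-spike association
    if len(ca_spikes):
        d = np.min(np.abs(spikes[:, None] - ca_spikes[None, :]), axis=1)
        burst_flag = d <= burst_window
    else:
        burst_flag = np.zeros(len(spikes), dtype=bool)

    intervals: list[tuple[float, float, str]] = []
    if spikes[0] - t0 > quiescent_gap:
        intervals.append((t0, spikes[0], "quiescent"))
        seg_start = spikes[0]
    else:
        seg_start = t0
    cur_label = "burst" if burst_flag[0] else "tonic"

    def is_cf_pause(gap_start: float, gap: float) -> bool:
        if gap > cf_pause_max or len(complex_spikes) == 0:
            return False
        return bool(np.any(np.abs(complex_spikes - gap_start) <= CS_SPAN + 1))

    for i in range(len(spikes) - 1):
        gap = spikes[i + 1] - spikes[i]
        nxt_label = "burst" if burst_flag[i + 1] else "tonic"
        if gap > quiescent_gap:
            intervals.append((seg_start, spikes[i], cur_label))
            intervals.append((spikes[i], spikes[i + 1], "quiescent"))
            seg_start = spikes[i + 1]
            cur_label = nxt_label
        elif is_cf_pause(spikes[i], gap):
            intervals.append((seg_start, spikes[i], cur_label))
            intervals.append((spikes[i], spikes[i + 1], "cf_pause"))
            seg_start = spikes[i + 1]
            cur_label = nxt_label
        elif nxt_label != cur_label:
            mid = 0.5 * (spikes[i] + spikes[i + 1])
            intervals.append((seg_start, mid, cur_label))
            seg_start = mid
            cur_label = nxt_label
    intervals.append((seg_start, spikes[-1], cur_label))
    if t1 - spikes[-1] > quiescent_gap:
        intervals.append((spikes[-1], t1, "quiescent"))
    elif t1 > spikes[-1]:
        intervals.append((spikes[-1], t1, cur_label))

    # merge contiguous same-label intervals and drop empty ones
    merged: list[tuple[float, float, str]] = []
    for s, e, lab in intervals:
        if e <= s:
            continue
        if merged and merged[-1][2] == lab and abs(merged[-1][1] - s) < 1e-9:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return ModeSegmentation(merged)


def tonic_frequency(seg: ModeSegmentation, spikes: Sequence[float],
                    complex_spikes: Sequence[float] = ()) -> float:
    """Pooled mean rate over tonic intervals, Hz, excluding the spikelets
    of complex spikes (and their pauses, which are not tonic intervals)."""
    spikes = np.asarray(spikes)
    complex_spikes = np.asarray(complex_spikes)
    count = 0
    dur = 0.0
    for s, e in seg.of_label("tonic"):
        sel = (spikes >= s) & (spikes <= e)
        if len(complex_spikes):
            d = np.min(np.abs(spikes[:, None] - complex_spikes[None, :]),
                       axis=1)
            sel &= d > CS_SPAN
        count += int(np.sum(sel))
        dur += e - s
    if dur <= 0:
        raise AnalysisError("no tonic interval in segmentation")
    return count / dur * 1000.0


# ---------------------------------------------------------------------------
# toggle statistics
# ---------------------------------------------------------------------------

@dataclass
class ToggleStats:
    up_durations_ms: list[float]
    down_durations_ms: list[float]
    flip_fraction: float
    n_cf: int
    n_flips: int
    pump_silences: list[tuple[float, float]]
    states: list[str]


def toggle_statistics(spikes: Sequence[float], cf_events: Sequence[float],
                      min_up_spikes: int = 3,
                      silence_span: int = 3) -> ToggleStats:
    """Classify each inter-CF interval as up (firing) or down (quiescent),
    report state durations, the CF flip fraction (outside pump silences)
    and pump silences (down runs spanning > ``silence_span`` CF events)."""
    spikes = np.asarray(spikes)
    cf = np.sort(np.asarray(cf_events))
    if len(cf) < 2:
        raise AnalysisError("need at least two CF events")
    states: list[str] = []
    for i in range(len(cf) - 1):
        # ignore the complex spike itself (first 30 ms after the CF event)
        lo, hi = cf[i] + 30.0, cf[i + 1]
        n = int(np.sum((spikes > lo) & (spikes < hi)))
        states.append("up" if n >= min_up_spikes else "down")

    # pump silences: > silence_span consecutive down intervals
    silences: list[tuple[float, float]] = []
    in_silence = np.zeros(len(states), dtype=bool)
    i = 0
    while i < len(states):
        if states[i] == "down":
            j = i
            while j < len(states) and states[j] == "down":
                j += 1
            if j - i > silence_span:
                silences.append((float(cf[i]), float(cf[j])))
                in_silence[i:j] = True
            i = j
        else:
            i += 1

    flips = 0
    considered = 0
    for i in range(1, len(states)):
        if in_silence[i] or in_silence[i - 1]:
            continue
        considered += 1
        if states[i] != states[i - 1]:
            flips += 1
    frac = flips / considered if considered else 0.0

    ups, downs = [], []
    i = 0
    while i < len(states):
        j = i
        while j < len(states) and states[j] == states[i]:
            j += 1
        dur = float(cf[j] - cf[i])
        if states[i] == "up":
            ups.append(dur)
        elif not in_silence[i]:
            downs.append(dur)
        i = j
    return ToggleStats(ups, downs, frac, len(cf), flips, silences, states)


# ---------------------------------------------------------------------------
# protocol presets and the experiment runner
# ---------------------------------------------------------------------------

def preset(name: str, duration: float | None = None,
           pf_seed: int = 0) -> ProtocolSpec:
    """Named protocols with the published parameter choices."""
    presets: dict[str, ProtocolSpec] = {
        "trimodal": ProtocolSpec("trimodal", 25000.0),
        "trimodal_k02": ProtocolSpec("trimodal_k02", 25000.0, k=0.2),
        "pf_only": ProtocolSpec("pf_only", 25000.0, pf_on=True,
                                pf_rate=100.0, pf_seed=pf_seed),
        "cf_toggle": ProtocolSpec("cf_toggle", 40000.0, cf_on=True,
                                  cf_freq=1.0, g_sk=0.72),
        "cf_pause": ProtocolSpec("cf_pause", 15000.0, cf_on=True,
                                 cf_freq=1.0, g_sk=0.62),
        "cf_pf_gain": ProtocolSpec("cf_pf_gain", 15000.0, cf_on=True,
                                   cf_freq=1.0, g_sk=0.62, pf_on=True,
                                   pf_rate=100.0, pf_seed=pf_seed),
        "ih_block": ProtocolSpec("ih_block", 20000.0, cf_on=True,
                                 g_sk=0.72, g_ih_soma=0.0),
        "ih_mask": ProtocolSpec("ih_mask", 20000.0, cf_on=True,
                                g_sk=0.72, g_ih_soma=5.0),
        "ih_rescue_85": ProtocolSpec("ih_rescue_85", 20000.0, cf_on=True,
                                     g_sk=0.85, g_ih_soma=5.0),
        "ih_rescue_88": ProtocolSpec("ih_rescue_88", 20000.0, cf_on=True,
                                     g_sk=0.88, g_ih_soma=5.0),
    }
    if name not in presets:
        raise AnalysisError(
            f"unknown protocol {name!r}; choose from {sorted(presets)}")
    p = presets[name]
    if duration is not None:
        p.duration = duration
    return p


def summarize(trace: Trace, cf_events: np.ndarray | None = None
              ) -> SpikeTrainSummary:
    """Full measurement pass over one protocol trace."""
    spikes = trace.soma_spikes
    dend = trace.dend_spikes
    window = (0.0, trace.meta.get("duration_ms", trace.t[-1]
                                  if len(trace.t) else 0.0))
    cs = (detect_complex_spikes(spikes, cf_events, dend)
          if cf_events is not None and len(cf_events) else np.zeros(0))
    seg = segment_modes(spikes, dend, window, complex_spikes=cs)
    try:
        rate = tonic_frequency(seg, spikes, cs)
    except AnalysisError:
        rate = float("nan")

    # firing epochs: contiguous non-quiescent spans
    firing, repeats = firing_epochs(seg)
    ups, downs = [], []
    if cf_events is not None and len(cf_events) >= 2:
        ts = toggle_statistics(spikes, cf_events)
        ups, downs = ts.up_durations_ms, ts.down_durations_ms
    return SpikeTrainSummary(
        spike_times=spikes, complex_spike_times=cs, dend_spike_times=dend,
        tonic_rate_hz=rate,
        firing_length_ms=float(np.mean(firing)) if firing else float("nan"),
        repeat_length_ms=float(np.mean(repeats)) if repeats else float("nan"),
        up_durations_ms=ups, down_durations_ms=downs)


def firing_epochs(seg: ModeSegmentation) -> tuple[list[float], list[float]]:
    """(firing-epoch lengths, trimodal repeat lengths).

    A firing epoch is a maximal contiguous non-quiescent span; the repeat
    length is the time between successive quiescent-to-firing transitions.
    """
    firing: list[float] = []
    starts: list[float] = []
    cur = None
    prev_label = None
    for s, e, lab in seg.intervals:
        if lab == "quiescent":
            if cur is not None:
                firing.append(cur[1] - cur[0])
                cur = None
        else:
            if cur is None:
                cur = [s, e]
                if prev_label == "quiescent":
                    starts.append(s)
            else:
                cur[1] = e
        prev_label = lab
    if cur is not None:
        firing.append(cur[1] - cur[0])
    repeats = list(np.diff(starts)) if len(starts) >= 2 else []
    return firing, repeats


def run_experiment(name: str, config: ModelConfig | None = None,
                   duration: float | None = None,
                   pf_seed: int = 0) -> dict[str, Any]:
    """Execute a preset protocol and return a machine-readable report."""
    proto = preset(name, duration, pf_seed)
    trace = simulate(config or ModelConfig(), proto)
    cf_events = None
    if proto.cf_on:
        cf_events = np.arange(0.0, proto.duration, 1000.0 / proto.cf_freq)
    s = summarize(trace, cf_events)
    report: dict[str, Any] = {
        "protocol": name,
        "n_spikes": int(len(s.spike_times)),
        "n_complex_spikes": int(len(s.complex_spike_times)),
        "tonic_rate_hz": s.tonic_rate_hz,
        "firing_length_ms": s.firing_length_ms,
        "repeat_length_ms": s.repeat_length_ms,
        "up_durations_ms": s.up_durations_ms,
        "down_durations_ms": s.down_durations_ms,
    }
    if cf_events is not None and len(cf_events) >= 2 \
            and len(s.spike_times):
        ts = toggle_statistics(s.spike_times, cf_events)
        report["flip_fraction"] = ts.flip_fraction
        report["pump_silences_s"] = [(b - a) / 1000.0
                                     for a, b in ts.pump_silences]
        if len(s.complex_spike_times):
            pauses = complex_spike_pauses(s.spike_times,
                                          s.complex_spike_times)
            report["cs_pause_ms"] = (float(np.median(pauses))
                                     if len(pauses) else float("nan"))
    return report


def complex_spike_pauses(spikes: Sequence[float],
                         complex_spikes: Sequence[float],
                         span: float = CS_SPAN) -> np.ndarray:
    """Gap from the last spikelet of each complex spike to the next simple
    spike, ms (the CF-evoked after-pause)."""
    spikes = np.asarray(spikes)
    out = []
    for c in np.asarray(complex_spikes):
        burst = spikes[(spikes >= c) & (spikes <= c + span)]
        if len(burst) == 0:
            continue
        later = spikes[spikes > burst[-1]]
        if len(later):
            out.append(float(later[0] - burst[-1]))
    return np.asarray(out)
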