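"""RF amplitude bookkeeping: RMS RF integrals as a SAR proxy.

Hard pulses are rectangular with a fixed duration (default 1 ms), so a 90
degree pulse runs at 0.25/duration Hz (250 Hz at 1 ms) and a 180 at twice
that; SL segments run at the nominal SL amplitude f_SL for their share of
TSL.  The RMS integral over a window W is sqrt(sum(amp^2 * dur) / W), which
depends only on the amplitude histogram, not the event order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modules import HardPulse, SLModuleSpec, SLSegment

__all__ = ["RFTimeline", "rf_timeline", "rms_rf", "relative_increase", "rf_report"]


@dataclass
class RFTimeline:
    """Ordered (amplitude Hz, duration s) pairs for every event of a module."""

    events: tuple  # of (amplitude_hz, duration_s)

    def __post_init__(self):
        for amp, dur in self.events:
            if dur <= 0:
                raise ValueError("event durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.events))

    @property
    def sum_amp2_dur(self) -> float:
        return float(sum(a * a * d for a, d in self.events))


def rf_timeline(
    spec: SLModuleSpec, f_sl: float, t_sl: float, pulse_dur: float = 1e-3
) -> RFTimeline:
    """Amplitude/duration timeline of one module execution."""
    if f_sl <= 0 or t_sl <= 0 or pulse_dur <= 0:
        raise ValueError("f_sl, t_sl and pulse_dur must be positive")
    events = []
    for ev in spec.events:
        if isinstance(ev, HardPulse):
            flip_turns = 0.25 if ev.kind == "excite90" else 0.5  # fraction of a full turn
            events.append((flip_turns / pulse_dur, pulse_dur))
        elif isinstance(ev, SLSegment):
            events.append((float(f_sl), ev.fraction * t_sl))
    return RFTimeline(events=tuple(events))


def rms_rf(timeline: RFTimeline, window="module") -> float:
    """RMS RF amplitude in Hz: sqrt(sum(amp^2*dur)/W).

    ``window='module'`` uses the timeline's own duration; a float gives a
    fixed window in seconds (must cover the timeline).
    """
    if window == "module":
        w = timeline.total_duration
    else:
        w = float(window)
        if w <= 0:
            raise ValueError("window must be positive")
        if w < timeline.total_duration:
            raise ValueError("fixed window shorter than the timeline")
    return float(np.sqrt(timeline.sum_amp2_dur / w))


def relative_increase(rms_a: float, rms_b: float) -> float:
    """(rms_a / rms_b - 1) * 100, percent."""
    return (rms_a / rms_b - 1.0) * 100.0


def rf_report(specs, f_sl_list, t_sl_list, pulse_dur: float = 1e-3, reference: str = "CSL"):
    """RMS table over a grid of f_SL and TSL, with the percent increase of
    each module over the reference module.

    Modules are compared inside a common fixed window (the longest module
    duration at that TSL), so the comparison reflects deposited RF energy
    rather than slightly different module lengths.
    """
    import pandas as pd

    from .modules import build_preset

    specs = [s if isinstance(s, SLModuleSpec) else build_preset(s) for s in specs]
    names = [s.name for s in specs]
    if reference not in names:
        raise ValueError(f"reference module {reference!r} not among {names}")
    rows = []
    for t_sl in t_sl_list:
        for f_sl in f_sl_list:
            tls = {s.name: rf_timeline(s, f_sl, t_sl, pulse_dur) for s in specs}
            window = max(tl.total_duration for tl in tls.values())
            ref_rms = rms_rf(tls[reference], window)
            for name, tl in tls.items():
                rows.append(
                    {
                        "module": name,
                        "f_sl": f_sl,
                        "t_sl": t_sl,
                        "rms_hz": rms_rf(tl, window),
                        "rms_module_window_hz": rms_rf(tl, "module"),
                        "increase_vs_ref_pct": relative_increase(rms_rf(tl, window), ref_rms),
                    }
                )
    return pd.DataFrame(rows)
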