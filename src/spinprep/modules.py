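"""Declarative spin-lock preparation modules and their full propagators.

A module is an ordered list of events *in temporal order*: hard pulses
(90 degree excitation / 180 degree refocusing, with a phase sign) and SL
segments (phase sign and a fraction of the total lock time TSL).  The full
propagator multiplies the per-event propagators in reverse temporal order so
that the first event is the rightmost factor.

Presets
-------
C-SL   rotary-echo composite lock: one refocusing pulse between two
       phase-alternated SL halves; prepared magnetization ends on -z.
B-SL   balanced lock: two refocusing pulses of opposite phase, SL split
       1/4, 1/2, 1/4; ends on +z.
TR-SL  triple-refocused: three refocusing pulses (+y/+y/-y in time), four
       equal SL quarters; ends on -z.
QR-SL  quadruple-refocused: four refocusing pulses with phases +y/+y/-y/-y
       in time and five phase-cycled SL segments with fractions
       1/8, 1/4, 1/4, 1/4, 1/8; ends on +z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import (
    GROUND_STATE,
    FieldConditions,
    RelaxationParams,
    hard_pulse,
    sl_propagator,
)

__all__ = [
    "HardPulse",
    "SLSegment",
    "SLModuleSpec",
    "PRESET_NAMES",
    "build_preset",
    "build_n_refocused",
    "module_propagator",
    "mz_after_prep",
]


@dataclass(frozen=True)
class HardPulse:
    """Instantaneous pulse event: kind 'excite90' or 'refocus180', sign +-1."""

    kind: str
    sign: int

    def __post_init__(self):
        if self.kind not in ("excite90", "refocus180"):
            raise ValueError(f"unknown pulse kind {self.kind!r}")
        if self.sign not in (1, -1):
            raise ValueError("pulse sign must be +1 or -1")


@dataclass(frozen=True)
class SLSegment:
    """Spin-lock segment: phase sign +-1 and its fraction of the total TSL."""

    phase_sign: int
    fraction: float

    def __post_init__(self):
        if self.phase_sign not in (1, -1):
            raise ValueError("SL phase sign must be +1 or -1")
        if not 0 < self.fraction <= 1:
            raise ValueError("SL fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SLModuleSpec:
    """An ordered preparation-module program in temporal order."""

    name: str
    events: tuple

    def __post_init__(self):
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if len(events) < 3:
            raise ValueError("a module needs at least 90 - SL - 90")
        if not (
            isinstance(events[0], HardPulse)
            and events[0].kind == "excite90"
            and isinstance(events[-1], HardPulse)
            and events[-1].kind == "excite90"
        ):
            raise ValueError("first and last events must be 90-degree pulses")
        fractions = [e.fraction for e in events if isinstance(e, SLSegment)]
        if not fractions:
            raise ValueError("module contains no SL segment")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"SL fractions must sum to 1, got {sum(fractions)}")
        for i, ev in enumerate(events):
            if isinstance(ev, HardPulse) and ev.kind == "refocus180":
                if not (
                    0 < i < len(events) - 1
                    and isinstance(events[i - 1], SLSegment)
                    and isinstance(events[i + 1], SLSegment)
                ):
                    raise ValueError("refocusing pulses must sit between SL segments")

    @property
    def sl_segments(self):
        return tuple(e for e in self.events if isinstance(e, SLSegment))

    @property
    def n_refocus(self) -> int:
        return sum(1 for e in self.events if isinstance(e, HardPulse) and e.kind == "refocus180")

    @property
    def fractions(self):
        return tuple(e.fraction for e in self.sl_segments)

    def total_lock_rotation(self, f_sl: float, t_sl: float) -> float:
        """Nominal total rotation Theta_y = 2*pi*f_SL*TSL during the lock, rad."""
        return 2.0 * np.pi * f_sl * t_sl

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        evs = []
        for e in self.events:
            if isinstance(e, HardPulse):
                evs.append({"type": "pulse", "kind": e.kind, "sign": e.sign})
            else:
                evs.append({"type": "sl", "phase_sign": e.phase_sign, "fraction": e.fraction})
        return {"name": self.name, "events": evs}

    @classmethod
    def from_dict(cls, d: dict) -> "SLModuleSpec":
        events = []
        for e in d["events"]:
            if e["type"] == "pulse":
                events.append(HardPulse(e["kind"], int(e["sign"])))
            elif e["type"] == "sl":
                events.append(SLSegment(int(e["phase_sign"]), float(e["fraction"])))
            else:
                raise ValueError(f"unknown event type {e['type']!r}")
        return cls(name=d.get("name", "custom"), events=tuple(events))

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "SLModuleSpec":
        return cls.from_dict(json.loads(s))


def _p90(sign=1):
    return HardPulse("excite90", sign)


def _p180(sign=1):
    return HardPulse("refocus180", sign)


def _preset_events(name):
    if name == "CSL":
        return (
            _p90(+1),
            SLSegment(+1, 0.5),
            _p180(+1),
            SLSegment(-1, 0.5),
            _p90(+1),
        )
    if name == "BSL":
        return (
            _p90(+1),
            SLSegment(+1, 0.25),
            _p180(+1),
            SLSegment(-1, 0.5),
            _p180(-1),
            SLSegment(+1, 0.25),
            _p90(-1),
        )
    if name == "TRSL":
        return (
            _p90(+1),
            SLSegment(+1, 0.25),
            _p180(+1),
            SLSegment(-1, 0.25),
            _p180(+1),
            SLSegment(+1, 0.25),
            _p180(-1),
            SLSegment(-1, 0.25),
            _p90(+1),
        )
    if name == "QRSL":
        return (
            _p90(+1),
            SLSegment(+1, 0.125),
            _p180(+1),
            SLSegment(-1, 0.25),
            _p180(+1),
            SLSegment(+1, 0.25),
            _p180(-1),
            SLSegment(-1, 0.25),
            _p180(-1),
            SLSegment(+1, 0.125),
            _p90(-1),
        )
    raise KeyError(name)


PRESET_NAMES = ("CSL", "BSL", "TRSL", "QRSL")

_ALIASES = {
    "CSL": "CSL", "C-SL": "CSL", "C_SL": "CSL",
    "BSL": "BSL", "B-SL": "BSL", "B_SL": "BSL",
    "TRSL": "TRSL", "TR-SL": "TRSL", "TR_SL": "TRSL",
    "QRSL": "QRSL", "QR-SL": "QRSL", "QR_SL": "QRSL",
}


def canonical_preset_name(name: str) -> str:
    key = _ALIASES.get(str(name).upper())
    if key is None:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    return key


def build_preset(name: str) -> SLModuleSpec:
    """Return the event list of one of the four published preparation modules."""
    key = canonical_preset_name(name)
    return SLModuleSpec(name=key, events=_preset_events(key))


def build_n_refocused(
    n_refocus: int,
    refocus_phases,
    sl_phase_start: int = 1,
    final_90_sign: int = 1,
    fractions=None,
    name: str | None = None,
) -> SLModuleSpec:
    """Generic n-refocused rotary-echo module.

    ``n_refocus + 1`` SL segments; unless ``fractions`` is given, the end
    segments get 1/(2n) of TSL and interior segments 1/n (for n=1 this is the
    rotary-echo 1/2 + 1/2 split).  SL phases alternate starting from
    ``sl_phase_start``; refocusing phases are given explicitly.  The QR-SL
    preset is recovered with n=4, phases (+,+,-,-), final 90 sign -1.
    """
    n_refocus = int(n_refocus)
    if n_refocus < 0:
        raise ValueError("n_refocus must be >= 0")
    refocus_phases = tuple(int(p) for p in refocus_phases)
    if len(refocus_phases) != n_refocus:
        raise ValueError("need exactly one phase sign per refocusing pulse")
    n_seg = n_refocus + 1
    if fractions is None:
        if n_refocus == 0:
            fractions = (1.0,)
        else:
            inner = 1.0 / n_refocus
            fractions = (inner / 2,) + (inner,) * (n_refocus - 1) + (inner / 2,)
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != n_seg:
        raise ValueError("need one fraction per SL segment")
    events = [_p90(+1)]
    phase = int(sl_phase_start)
    for i in range(n_seg):
        events.append(SLSegment(phase, fractions[i]))
        if i < n_refocus:
            events.append(_p180(refocus_phases[i]))
        phase = -phase
    events.append(_p90(int(final_90_sign)))
    if name is None:
        pat = "".join("+" if p > 0 else "-" for p in refocus_phases)
        name = f"n{n_refocus}refocused[{pat}]"
    return SLModuleSpec(name=name, events=tuple(events))


def module_propagator(
    spec: SLModuleSpec,
    t_sl,
    fields: FieldConditions,
    relax: RelaxationParams,
    angle_mode: str = "effective",
) -> np.ndarray:
    """Full module propagator B for lock duration(s) ``t_sl`` seconds.

    Broadcasts over arrays of ``t_sl`` and/or array-valued field conditions;
    returns shape ``broadcast + (3, 3)``.
    """
    t_sl = np.asarray(t_sl, dtype=float)
    if np.any(t_sl < 0):
        raise ValueError("TSL must be non-negative")
    b = np.eye(3)
    for ev in spec.events:
        if isinstance(ev, HardPulse):
            p = hard_pulse(ev.kind, ev.sign, fields)
        else:
            p = sl_propagator(ev.phase_sign, ev.fraction * t_sl, fields, relax, angle_mode)
        b = p @ b
    return b


def mz_after_prep(
    spec: SLModuleSpec,
    t_sl,
    fields: FieldConditions,
    relax: RelaxationParams,
    angle_mode: str = "effective",
) -> np.ndarray:
    """z-component of the prepared magnetization, B . (0, 0, 1)."""
    b = module_propagator(spec, t_sl, fields, relax, angle_mode)
    return (b @ GROUND_STATE)[..., 2]
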