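"""Closed-form prepared Mz in the two limiting cases, as an independent oracle.

These expressions are transcribed directly (not derived from the numeric
propagators) so that they can serve as a genuinely independent check:

B1-only (theta = 0, arbitrary flip angles alpha, beta):
    C-SL / TR-SL : Mz = -E1 sin^2(alpha) + E2 cos^2(alpha) cos(beta)
    B-SL / QR-SL : Mz = +E1 sin^2(alpha) + E2 cos^2(alpha)

B0-only (alpha = pi/2, beta = pi, arbitrary tilt theta):
    C-SL / TR-SL : Mz = -(E1 cos^2(theta) + E2 sin^2(theta))
    B-SL / QR-SL : Mz = +(E1 cos^2(theta) + E2 sin^2(theta))

with E1 = exp(-TSL/T1rho), E2 = exp(-TSL/T2rho).  The modules with an even
number of refocusing pulses (B-SL, QR-SL) carry no beta dependence at
theta = 0; the odd-count modules (C-SL, TR-SL) depend on beta through
cos(beta).  All eight forms reduce to +-exp(-TSL/T1rho) at the ideal values.
"""

from __future__ import annotations

import numpy as np

from .core import FieldConditions, RelaxationParams
from .modules import SLModuleSpec, canonical_preset_name, mz_after_prep

__all__ = ["mz_closed_form", "oracle_check"]

_SIGN = {"CSL": -1.0, "TRSL": -1.0, "BSL": 1.0, "QRSL": 1.0}


def mz_closed_form(
    preset: str,
    case: str,
    t_sl,
    relax: RelaxationParams,
    alpha: float = np.pi / 2,
    beta: float = np.pi,
    theta: float = 0.0,
):
    """Evaluate the limiting-case closed form for one preset.

    ``case='b1_only'`` requires theta = 0 and uses (alpha, beta);
    ``case='b0_only'`` requires alpha = pi/2 and beta = pi and uses theta.
    """
    key = canonical_preset_name(preset)
    sign = _SIGN[key]
    t_sl = np.asarray(t_sl, dtype=float)
    e1 = np.exp(-t_sl / relax.t1rho) if relax.enabled else np.ones_like(t_sl)
    e2 = np.exp(-t_sl / relax.t2rho) if relax.enabled else np.ones_like(t_sl)
    if case == "b1_only":
        if not np.isclose(theta, 0.0, atol=1e-12):
            raise ValueError("b1_only case requires theta = 0")
        if sign < 0:  # odd refocusing count: beta-dependent
            return -e1 * np.sin(alpha) ** 2 + e2 * np.cos(alpha) ** 2 * np.cos(beta)
        return e1 * np.sin(alpha) ** 2 + e2 * np.cos(alpha) ** 2
    if case == "b0_only":
        if not (np.isclose(alpha, np.pi / 2, atol=1e-12) and np.isclose(beta, np.pi, atol=1e-12)):
            raise ValueError("b0_only case requires alpha = pi/2 and beta = pi")
        return sign * (e1 * np.cos(theta) ** 2 + e2 * np.sin(theta) ** 2)
    raise ValueError(f"unknown case {case!r}; expected 'b1_only' or 'b0_only'")


def oracle_check(
    preset: str,
    case: str,
    fields: FieldConditions,
    relax: RelaxationParams,
    t_sl_grid,
    angle_mode: str = "effective",
) -> float:
    """Max |numeric Mz - closed form| over a TSL grid for one limiting case.

    The field conditions must be consistent with the case: ``b1_only`` needs
    delta_f0 = 0 (any b1_scale); ``b0_only`` needs b1_scale = 1.
    """
    from .modules import build_preset

    spec = preset if isinstance(preset, SLModuleSpec) else build_preset(preset)
    t_sl_grid = np.asarray(t_sl_grid, dtype=float)
    if case == "b1_only":
        if not np.allclose(np.asarray(fields.delta_f0), 0.0):
            raise ValueError("b1_only oracle needs delta_f0 = 0")
        alpha = (np.pi / 2) * float(np.asarray(fields.b1_scale))
        beta = np.pi * float(np.asarray(fields.b1_scale))
        ref = mz_closed_form(spec.name, case, t_sl_grid, relax, alpha=alpha, beta=beta)
    elif case == "b0_only":
        if not np.allclose(np.asarray(fields.b1_scale), 1.0):
            raise ValueError("b0_only oracle needs b1_scale = 1")
        ref = mz_closed_form(spec.name, case, t_sl_grid, relax, theta=float(fields.theta))
    else:
        raise ValueError(f"unknown case {case!r}")
    num = mz_after_prep(spec, t_sl_grid, fields, relax, angle_mode)
    return float(np.max(np.abs(num - ref)))
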