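"""Elementary 3x3 propagators for spin-lock preparation modules.

Magnetization is a unit-scaled vector ``(mx, my, mz)`` in the rotating frame
with ground state ``(0, 0, 1)``.  All propagators are real 3x3 matrices acting
by left multiplication; products are written right-to-left, so the rightmost
factor acts first in time.

Conventions
-----------
* Rotations are *clockwise* in a *left-handed* frame:
  ``Rx(psi) = [[1,0,0],[0,c,s],[0,-s,c]]`` and analogously for y/z.  All
  downstream closed forms depend on this convention; do not "fix" it to the
  right-handed one.
* The spin-lock (SL) pulse is applied along +y; rotating-frame relaxation is
  diagonal with the T1rho decay on the y entry and T2rho on x/z.
* Angles are radians internally; frequencies are Hz at the API boundary and
  converted to angular frequencies (rad/s) internally.

All constructors broadcast over numpy arrays, so a whole grid of durations or
field conditions can be propagated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GROUND_STATE",
    "FieldConditions",
    "RelaxationParams",
    "rotation_matrix",
    "relaxation_matrix",
    "hard_pulse",
    "sl_propagator",
    "tilt_angle",
    "effective_frequency",
]

#: Equilibrium magnetization (0, 0, 1), the state every module starts from.
GROUND_STATE = np.array([0.0, 0.0, 1.0])

ANGLE_MODES = ("effective", "literal")


def rotation_matrix(axis: str, psi) -> np.ndarray:
    """Clockwise rotation by ``psi`` (radians) about a lab axis.

    Parameters
    ----------
    axis : {'x', 'y', 'z'}
    psi : float or array_like
        Rotation angle(s); the result broadcasts to ``psi.shape + (3, 3)``.
    """
    psi = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(psi), np.sin(psi)
    one, zero = np.ones_like(c), np.zeros_like(c)
    if axis == "x":
        rows = ((one, zero, zero), (zero, c, s), (zero, -s, c))
    elif axis == "y":
        rows = ((c, zero, -s), (zero, one, zero), (s, zero, c))
    elif axis == "z":
        rows = ((c, s, zero), (-s, c, zero), (zero, zero, one))
    else:
        raise ValueError(f"unknown rotation axis {axis!r}; expected 'x', 'y' or 'z'")
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


@dataclass(frozen=True)
class RelaxationParams:
    """Rotating-frame decay constants.

    t1rho : float or array
        Decay constant (s) of magnetization parallel to the SL axis.
    t2rho : float or array
        Decay constant (s) perpendicular to the SL axis.
    enabled : bool
        When False every relaxation matrix is the identity (pure rotations).
    """

    t1rho: float
    t2rho: float
    enabled: bool = True

    def __post_init__(self):
        if np.any(np.asarray(self.t1rho) <= 0) or np.any(np.asarray(self.t2rho) <= 0):
            raise ValueError("relaxation times must be positive")

    @classmethod
    def from_ratio(cls, t1rho: float, ratio: float, enabled: bool = True) -> "RelaxationParams":
        """Build from T1rho and the ratio T1rho:T2rho (ratio 2 -> T2rho = T1rho/2)."""
        return cls(t1rho=t1rho, t2rho=t1rho / ratio, enabled=enabled)

    @property
    def ratio(self):
        return self.t1rho / self.t2rho

    @classmethod
    def disabled(cls) -> "RelaxationParams":
        return cls(t1rho=1.0, t2rho=1.0, enabled=False)


def relaxation_matrix(tau, relax: RelaxationParams) -> np.ndarray:
    """diag(e^{-tau/T2rho}, e^{-tau/T1rho}, e^{-tau/T2rho}) for an SL along y."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("relaxation interval must be non-negative")
    if not relax.enabled:
        shape = np.broadcast_shapes(tau.shape)
        return np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    e1 = np.exp(-tau / np.asarray(relax.t1rho, dtype=float))
    e2 = np.exp(-tau / np.asarray(relax.t2rho, dtype=float))
    e1, e2 = np.broadcast_arrays(e1, e2)
    zero = np.zeros_like(e1)
    rows = ((e2, zero, zero), (zero, e1, zero), (zero, zero, e2))
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


@dataclass(frozen=True)
class FieldConditions:
    """Off-resonance and B1-scale state of one voxel (or a grid of them).

    Parameters
    ----------
    f_sl_nominal : float
        Nominal spin-lock amplitude f_SL in Hz (gamma*B_SL/2pi).
    delta_f0 : float or array
        Off-resonance Delta f0 in Hz (B0 inhomogeneity).
    b1_scale : float or array
        Multiplicative B1 factor 1 + dB1 (0.75 for a -25% deviation).  Always
        scales the nominal 90/180 flip angles.
    couple_sl_amplitude : bool
        When True (default) the B1 factor also scales the SL amplitude, hence
        the tilt angle and effective frequency.  When False the B1 error only
        perturbs the hard-pulse flip angles, which is how grid simulations
        that sweep alpha/beta directly treat it.

    Derived quantities: ``delta_omega0`` = 2*pi*delta_f0, ``omega_sl_eff`` the
    (possibly B1-scaled) SL angular frequency, the tilt angle
    ``theta = arctan(delta_omega0/omega_sl_eff)`` of the effective field away
    from the lock axis, and ``omega_e = sqrt(omega_sl_eff^2 + delta_omega0^2)``
    the effective-field magnitude in angular-frequency units.
    """

    f_sl_nominal: float
    delta_f0: float = 0.0
    b1_scale: float = 1.0
    couple_sl_amplitude: bool = True

    def __post_init__(self):
        if np.any(np.asarray(self.f_sl_nominal) <= 0):
            raise ValueError("nominal SL frequency must be positive")

    @property
    def delta_omega0(self):
        return 2.0 * np.pi * np.asarray(self.delta_f0, dtype=float)

    @property
    def omega_sl_eff(self):
        scale = np.asarray(self.b1_scale, dtype=float) if self.couple_sl_amplitude else 1.0
        return 2.0 * np.pi * self.f_sl_nominal * scale

    @property
    def theta(self):
        """Tilt of the effective SL field from the lock axis, in (-pi/2, pi/2)."""
        w = np.asarray(self.omega_sl_eff)
        if np.any(w <= 0):
            raise ValueError("tilt angle undefined for zero effective SL amplitude")
        return np.arctan(self.delta_omega0 / w)

    @property
    def omega_e(self):
        return np.sqrt(np.asarray(self.omega_sl_eff) ** 2 + self.delta_omega0**2)

    @property
    def f_e(self):
        return self.omega_e / (2.0 * np.pi)

    def replace(self, **kw) -> "FieldConditions":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def tilt_angle(fields: FieldConditions):
    """Tilt angle theta = arctan(delta_omega0 / omega_sl_eff), radians."""
    return fields.theta


def effective_frequency(fields: FieldConditions):
    """Effective-field magnitude f_e = sqrt(f_sl_eff^2 + delta_f0^2), Hz."""
    return fields.f_e


def hard_pulse(kind: str, sign: int, fields: FieldConditions) -> np.ndarray:
    """Instantaneous hard pulse; relaxation during the pulse is neglected.

    ``excite90`` rotates about x by sign * (pi/2) * b1_scale;
    ``refocus180`` rotates about y by sign * pi * b1_scale.
    """
    if sign not in (1, -1):
        raise ValueError("pulse sign must be +1 or -1")
    scale = np.asarray(fields.b1_scale, dtype=float)
    if kind == "excite90":
        return rotation_matrix("x", sign * (np.pi / 2.0) * scale)
    if kind == "refocus180":
        return rotation_matrix("y", sign * np.pi * scale)
    raise ValueError(f"unknown hard pulse kind {kind!r}")


def sl_propagator(
    phase_sign: int,
    tau,
    fields: FieldConditions,
    relax: RelaxationParams,
    angle_mode: str = "effective",
) -> np.ndarray:
    """Propagator of one spin-lock segment of duration ``tau`` seconds.

    The off-resonance tilt is handled in the tilted rotating frame:

        SL+(tau) = Rx(-theta) . E_rho(tau) . Ry(w*tau) . Rx(theta)
        SL-(tau) = Rx(theta - pi) . E_rho(tau) . Ry(w*tau) . Rx(pi - theta)

    where the in-lock rotation rate ``w`` is the effective frequency
    ``omega_e`` for ``angle_mode='effective'`` or the (B1-scaled) nominal
    ``omega_sl_eff`` for ``angle_mode='literal'``.  The two coincide exactly
    when ``delta_f0 = 0``.
    """
    if phase_sign not in (1, -1):
        raise ValueError("phase sign must be +1 or -1")
    if angle_mode not in ANGLE_MODES:
        raise ValueError(f"angle_mode must be one of {ANGLE_MODES}")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("SL duration must be non-negative")
    theta = np.asarray(fields.theta)
    omega = np.asarray(fields.omega_e if angle_mode == "effective" else fields.omega_sl_eff)
    psi = omega * tau
    e_rho = relaxation_matrix(tau, relax)
    if phase_sign == 1:
        return (
            rotation_matrix("x", -theta)
            @ e_rho
            @ rotation_matrix("y", psi)
            @ rotation_matrix("x", theta)
        )
    return (
        rotation_matrix("x", theta - np.pi)
        @ e_rho
        @ rotation_matrix("y", psi)
        @ rotation_matrix("x", np.pi - theta)
    )
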