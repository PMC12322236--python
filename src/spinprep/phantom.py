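"""Digital twin of the tube-phantom validation experiment.

A 2-D label map of circular agarose-like tubes, spatial B0/B1 field maps,
voxel-wise synthesis of T1rho-weighted image series from the module
propagators, and the two standard field-map estimators (dual-TE B0 map,
double-angle B1 map).

Geometry convention: voxel centers on FOV-centered axes, x increasing with
the column index, units mm; the NIfTI affine records the voxel size.

The default per-tube T1rho values are *synthetic* plausible values for 2-6%
agarose gels at 3 T; they are package defaults, not measured reference data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import FieldConditions, RelaxationParams
from .modules import SLModuleSpec, mz_after_prep

__all__ = [
    "DigitalPhantom",
    "FieldMaps",
    "make_tube_phantom",
    "make_field_maps",
    "synthesize_weighted_series",
    "b0_map_dual_te",
    "b0_unambiguous_range_hz",
    "b1_map_double_angle",
    "save_stack_nifti",
    "load_stack_nifti",
]

#: Synthetic defaults (s) emulating 2%..6% agarose tubes: stiffer gel, shorter T1rho.
DEFAULT_TUBE_T1RHO = (0.120, 0.095, 0.075, 0.060, 0.050)

#: Quincunx tube centers (mm) for five 20-mm tubes in a 120-mm FOV.
DEFAULT_TUBE_CENTERS = ((0.0, 0.0), (-30.0, 0.0), (30.0, 0.0), (0.0, -30.0), (0.0, 30.0))


@dataclass
class DigitalPhantom:
    """Label map plus per-label relaxation parameters and proton density.

    ``labels`` is 0 for background and 1..n_tubes inside the tubes;
    ``t1rho``/``t2rho``/``proton_density`` are indexed by label-1.
    """

    labels: np.ndarray
    t1rho: np.ndarray
    t2rho: np.ndarray
    proton_density: np.ndarray
    fov_mm: float

    def __post_init__(self):
        if np.any(self.t1rho <= 0) or np.any(self.t2rho <= 0):
            raise ValueError("relaxation parameters must be positive")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def shape(self):
        return self.labels.shape

    def _per_voxel(self, values):
        out = np.full(self.shape, np.nan)
        out[self.mask] = np.asarray(values)[self.labels[self.mask] - 1]
        return out

    @property
    def t1rho_map(self) -> np.ndarray:
        return self._per_voxel(self.t1rho)

    @property
    def t2rho_map(self) -> np.ndarray:
        return self._per_voxel(self.t2rho)


@dataclass
class FieldMaps:
    """Per-voxel off-resonance (Hz) and B1 scale (dimensionless)."""

    delta_f0: np.ndarray
    b1_scale: np.ndarray

    def __post_init__(self):
        if self.delta_f0.shape != self.b1_scale.shape:
            raise ValueError("field maps must share a geometry")
        if not (np.all(np.isfinite(self.delta_f0)) and np.all(np.isfinite(self.b1_scale))):
            raise ValueError("field maps must be finite")

    @property
    def shape(self):
        return self.delta_f0.shape


def _voxel_axes(matrix: int, fov_mm: float):
    """FOV-centered voxel-center coordinates, mm."""
    delta = fov_mm / matrix
    return (np.arange(matrix) - (matrix - 1) / 2.0) * delta


def make_tube_phantom(
    matrix: int = 200,
    fov_mm: float = 120.0,
    tube_diameter_mm: float = 20.0,
    centers_mm=DEFAULT_TUBE_CENTERS,
    t1rho=None,
    t2rho=None,
    proton_density=None,
) -> DigitalPhantom:
    """Rasterize disjoint circular tubes on a square matrix.

    Defaults follow the validation setup: five 20-mm tubes on a 200x200
    matrix over a 120x120 mm FOV.  Overlapping tubes are rejected.
    """
    centers = [tuple(map(float, c)) for c in centers_mm]
    n = len(centers)
    radius = tube_diameter_mm / 2.0
    half = fov_mm / 2.0
    for cx, cy in centers:
        if abs(cx) + radius > half or abs(cy) + radius > half:
            raise ValueError(f"tube at ({cx}, {cy}) extends beyond the FOV")
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < tube_diameter_mm:
                raise ValueError("tubes overlap")
    if t1rho is None:
        t1rho = DEFAULT_TUBE_T1RHO[:n] if n <= len(DEFAULT_TUBE_T1RHO) else None
        if t1rho is None:
            raise ValueError("give per-tube t1rho for more than 5 tubes")
    t1rho = np.asarray(t1rho, dtype=float)
    if t1rho.size != n:
        raise ValueError("need one t1rho per tube")
    t2rho = t1rho.copy() if t2rho is None else np.asarray(t2rho, dtype=float)
    if t2rho.size != n:
        raise ValueError("need one t2rho per tube")
    proton_density = (
        np.ones(n) if proton_density is None else np.asarray(proton_density, dtype=float)
    )
    ax = _voxel_axes(matrix, fov_mm)
    xx, yy = np.meshgrid(ax, ax, indexing="xy")  # row=y, col=x
    labels = np.zeros((matrix, matrix), dtype=int)
    for k, (cx, cy) in enumerate(centers, start=1):
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        labels[inside] = k
    return DigitalPhantom(
        labels=labels, t1rho=t1rho, t2rho=t2rho, proton_density=proton_density, fov_mm=fov_mm
    )


def make_field_maps(
    matrix: int = 200,
    fov_mm: float = 120.0,
    b0_mode: str = "x_gradient",
    b0_span_hz: float | None = 116.0,
    gradient_hz_per_cm: float | None = None,
    b1_scale: float = 0.8,
) -> FieldMaps:
    """Spatial field-deviation maps for the digital twin.

    ``x_gradient`` mode produces a linear off-resonance along x, zero at the
    FOV center; give either the total span across the FOV (default 116 Hz,
    i.e. -58..+58 Hz edge to edge) or a gradient in Hz/cm.  ``uniform`` mode
    is zero off-resonance everywhere.  The B1 scale map is uniform.
    """
    if b0_mode == "uniform":
        f0 = np.zeros((matrix, matrix))
    elif b0_mode == "x_gradient":
        if gradient_hz_per_cm is not None:
            x = _voxel_axes(matrix, fov_mm)  # mm
            row = x * gradient_hz_per_cm / 10.0
        elif b0_span_hz is not None:
            row = np.linspace(-b0_span_hz / 2.0, b0_span_hz / 2.0, matrix)
        else:
            raise ValueError("give b0_span_hz or gradient_hz_per_cm")
        f0 = np.broadcast_to(row, (matrix, matrix)).copy()
    else:
        raise ValueError("b0_mode must be 'uniform' or 'x_gradient'")
    return FieldMaps(delta_f0=f0, b1_scale=np.full((matrix, matrix), float(b1_scale)))


def synthesize_weighted_series(
    phantom: DigitalPhantom,
    spec: SLModuleSpec,
    tsl_list,
    maps: FieldMaps | None,
    f_sl: float,
    noise_sigma: float = 0.0,
    rng=None,
    angle_mode: str = "effective",
    couple_sl_amplitude: bool = True,
) -> np.ndarray:
    """T1rho-weighted image stack, one volume per TSL, shape (ny, nx, n_tsl).

    Per voxel the signal is proton_density * |Mz| after the module under the
    voxel's field conditions; the readout is an ideal sampler.  When
    ``noise_sigma`` > 0, complex Gaussian noise of that standard deviation is
    added on two quadrature channels and the magnitude taken (Rician noise).
    """
    tsl_list = np.asarray(tsl_list, dtype=float)
    if tsl_list.size == 0:
        raise ValueError("empty TSL list")
    if maps is None:
        maps = FieldMaps(
            delta_f0=np.zeros(phantom.shape), b1_scale=np.ones(phantom.shape)
        )
    if maps.shape != phantom.shape:
        raise ValueError("field-map geometry does not match the phantom")
    mask = phantom.mask
    lab = phantom.labels[mask] - 1
    relax = RelaxationParams(t1rho=phantom.t1rho[lab], t2rho=phantom.t2rho[lab])
    fields = FieldConditions(
        f_sl_nominal=f_sl,
        delta_f0=maps.delta_f0[mask],
        b1_scale=maps.b1_scale[mask],
        couple_sl_amplitude=couple_sl_amplitude,
    )
    pd_vox = phantom.proton_density[lab]
    stack = np.zeros(phantom.shape + (tsl_list.size,))
    for k, tsl in enumerate(tsl_list):
        mz = mz_after_prep(spec, float(tsl), fields, relax, angle_mode)
        vol = np.zeros(phantom.shape)
        vol[mask] = pd_vox * np.abs(mz)
        stack[..., k] = vol
    if noise_sigma > 0:
        gen = np.random.default_rng(rng)
        re = stack + gen.normal(0.0, noise_sigma, stack.shape)
        im = gen.normal(0.0, noise_sigma, stack.shape)
        stack = np.hypot(re, im)
    return stack


def b0_unambiguous_range_hz(te1: float, te2: float) -> float:
    """Half-width of the alias-free off-resonance range, 1/(2*(TE2-TE1)) Hz."""
    return 1.0 / (2.0 * (te2 - te1))


def b0_map_dual_te(phase_te1, phase_te2, te1: float = 2.5e-3, te2: float = 3.5e-3):
    """Off-resonance map from the phase difference of two echoes.

    delta_f0 = wrap(phi2 - phi1) / (2*pi*(TE2 - TE1)), with the difference
    wrapped to (-pi, pi]; values beyond the unambiguous range alias and are
    not unwrapped here.
    """
    if te2 <= te1:
        raise ValueError("need TE2 > TE1")
    dphi = np.asarray(phase_te2, dtype=float) - np.asarray(phase_te1, dtype=float)
    wrapped = np.angle(np.exp(1j * dphi))
    return wrapped / (2.0 * np.pi * (te2 - te1))


def b1_map_double_angle(s1, s2, fa1_deg: float = 60.0):
    """B1 scale map from the double-angle method (FA2 = 2*FA1).

    actual angle = arccos(s2 / (2*s1)); scale = actual/nominal FA1.  Voxels
    with |s2/(2*s1)| > 1, non-positive s1, or a degenerate zero actual angle
    are flagged invalid (NaN scale).  Returns ``(scale_map, valid_mask)``.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s2 / (2.0 * s1)
    valid = (s1 > 0) & np.isfinite(ratio) & (np.abs(ratio) <= 1.0) & (ratio < 1.0)
    scale = np.full(np.broadcast(s1, s2).shape, np.nan)
    alpha_act = np.arccos(np.clip(ratio, -1.0, 1.0))
    scale = np.where(valid, alpha_act / np.deg2rad(fa1_deg), np.nan)
    return scale, valid


# ---------------------------------------------------------------------------
# NIfTI I/O with a JSON sidecar (TSL list in ms plus provenance)
# ---------------------------------------------------------------------------

def save_stack_nifti(path, stack: np.ndarray, voxel_mm: float, tsl_s=None, meta: dict | None = None):
    """Write a (ny, nx[, n_tsl]) array as NIfTI plus a JSON sidecar."""
    path = Path(path)
    data = np.asarray(stack, dtype=np.float64)
    if data.ndim == 3:  # store TSL on the 4th NIfTI axis
        data = data[:, :, None, :]
    affine = np.diag([voxel_mm, voxel_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = dict(meta or {})
    if tsl_s is not None:
        sidecar["tsl_ms"] = [1e3 * float(t) for t in np.asarray(tsl_s).ravel()]
    side_path = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path
    side_path = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    side_path.write_text(json.dumps(sidecar, indent=1))


def load_stack_nifti(path):
    """Read a stack written by :func:`save_stack_nifti`; returns (array, sidecar)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[2] == 1:
        data = data[:, :, 0, :]
    side_path = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    meta = json.loads(side_path.read_text()) if side_path.exists() else {}
    return data, meta
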