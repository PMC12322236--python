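"""Grid sweeps over B0/B1 deviations, SL frequencies and relaxation ratios.

Every cell of a sweep runs the random-TSL quantification protocol (shared
draws across cells and modules, so module comparisons are seed-paired) plus
the dense-trajectory RSS, and the summary reports the proportion of cells
meeting the accuracy criteria |DQ| < 1% and RSS < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FieldConditions, RelaxationParams
from .modules import SLModuleSpec, build_n_refocused, build_preset
from .quantify import fit_monoexponential_batch
from .modules import mz_after_prep

__all__ = [
    "SweepResult",
    "inhomogeneity_sweep",
    "proportion_within",
    "fsl_sweep",
    "ratio_sweep",
    "phase_combination_study",
    "SIX_QR_PHASE_COMBOS",
]

#: The six self-compensating refocusing-phase patterns of a 4-refocused module.
SIX_QR_PHASE_COMBOS = (
    (1, 1, -1, -1),
    (-1, -1, 1, 1),
    (1, -1, -1, 1),
    (-1, 1, 1, -1),
    (1, -1, 1, -1),
    (-1, 1, -1, 1),
)


@dataclass
class SweepResult:
    """Per-cell quantification errors over a B0 x B1 deviation grid."""

    delta_f0: np.ndarray          # (n_b0,) Hz
    b1_scale: np.ndarray          # (n_b1,) dimensionless
    dq_abs: np.ndarray            # (n_b0, n_b1) mean |dq|
    dq_signed: np.ndarray         # (n_b0, n_b1) signed mean dq
    dq_s0_abs: np.ndarray         # (n_b0, n_b1) mean |amplitude error|
    rss: np.ndarray               # (n_b0, n_b1) dense-trajectory RSS (raw sum)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.dq_abs.shape


def _tsl_draws(n_reps, n_points, t1rho, seed):
    rng = np.random.default_rng(seed)
    return np.sort(rng.uniform(0.0, 2.0 * t1rho, size=(n_reps, n_points)), axis=1)


def inhomogeneity_sweep(
    spec: SLModuleSpec,
    f_sl: float,
    relax: RelaxationParams,
    b0_range: float = 600.0,
    b1_range: float = 0.5,
    steps=(100, 100),
    n_reps: int = 100,
    n_points: int = 8,
    n_dense: int = 200,
    seed=0,
    angle_mode: str = "effective",
    couple_sl_amplitude: bool = True,
) -> SweepResult:
    """Sweep delta_f0 in [-b0_range, +b0_range] Hz x b1_scale in 1 +- b1_range.

    Endpoints are included; with an odd step count the ideal cell (0 Hz,
    scale 1) lies exactly on the grid.  The TSL draws are generated once from
    ``seed`` and reused for every cell, so sweeps of different modules with
    the same seed are exactly paired.
    """
    if min(steps) < 2:
        raise ValueError("need at least 2 steps per axis")
    t1rho = float(np.asarray(relax.t1rho))
    b0_axis = np.linspace(-b0_range, b0_range, steps[0])
    b1_axis = np.linspace(1.0 - b1_range, 1.0 + b1_range, steps[1])
    draws = _tsl_draws(n_reps, n_points, t1rho, seed)
    t_dense = np.linspace(0.0, 2.0 * t1rho, n_dense)

    n_b0, n_b1 = steps
    dq_abs = np.empty((n_b0, n_b1))
    dq_signed = np.empty((n_b0, n_b1))
    dq_s0_abs = np.empty((n_b0, n_b1))
    rss = np.empty((n_b0, n_b1))

    # chunk over b0 rows to bound the propagator workspace
    max_cells = max(1, 1_000_000 // ((n_reps * n_points + n_dense) * n_b1))
    for i0 in range(0, n_b0, max_cells):
        sl = slice(i0, min(i0 + max_cells, n_b0))
        nb = sl.stop - sl.start
        fields = FieldConditions(
            f_sl_nominal=f_sl,
            delta_f0=b0_axis[sl, None, None, None],
            b1_scale=b1_axis[None, :, None, None],
            couple_sl_amplitude=couple_sl_amplitude,
        )
        mz = mz_after_prep(spec, draws[None, None, :, :], fields, relax, angle_mode)
        y = np.abs(mz).reshape(nb * n_b1 * n_reps, n_points)
        t = np.broadcast_to(draws, (nb * n_b1, n_reps, n_points)).reshape(-1, n_points)
        s0, t1_fit, ok = fit_monoexponential_batch(t, y)
        dq = np.where(ok, t1_fit / t1rho - 1.0, np.nan).reshape(nb, n_b1, n_reps)
        dqs0 = np.where(ok, s0 - 1.0, np.nan).reshape(nb, n_b1, n_reps)
        with np.errstate(invalid="ignore"):
            dq_abs[sl] = np.nanmean(np.abs(dq), axis=-1)
            dq_signed[sl] = np.nanmean(dq, axis=-1)
            dq_s0_abs[sl] = np.nanmean(np.abs(dqs0), axis=-1)
        # dense trajectory per cell
        fields_d = FieldConditions(
            f_sl_nominal=f_sl,
            delta_f0=b0_axis[sl, None, None],
            b1_scale=b1_axis[None, :, None],
            couple_sl_amplitude=couple_sl_amplitude,
        )
        yd = np.abs(mz_after_prep(spec, t_dense[None, None, :], fields_d, relax, angle_mode))
        yd = yd.reshape(nb * n_b1, n_dense)
        s0d, t1d, okd = fit_monoexponential_batch(t_dense, yd)
        model = s0d[:, None] * np.exp(-t_dense[None, :] / np.where(np.isfinite(t1d), t1d, 1.0)[:, None])
        r = np.sum((yd - model) ** 2, axis=1)
        rss[sl] = np.where(okd, r, np.nan).reshape(nb, n_b1)

    return SweepResult(
        delta_f0=b0_axis,
        b1_scale=b1_axis,
        dq_abs=dq_abs,
        dq_signed=dq_signed,
        dq_s0_abs=dq_s0_abs,
        rss=rss,
        meta={
            "module": spec.name,
            "f_sl": f_sl,
            "t1rho": t1rho,
            "ratio": float(relax.ratio),
            "n_reps": n_reps,
            "n_points": n_points,
            "n_dense": n_dense,
            "seed": seed,
            "angle_mode": angle_mode,
            "couple_sl_amplitude": couple_sl_amplitude,
            "tsl_checksum": float(np.sum(draws)),
        },
    )


def proportion_within(
    sweep: SweepResult,
    criterion: str = "delta_q",
    threshold: float = 0.01,
    signed: bool = False,
) -> float:
    """Fraction of grid cells meeting ``|DQ| < threshold`` or ``RSS < threshold``."""
    if criterion == "delta_q":
        grid = np.abs(sweep.dq_signed) if signed else sweep.dq_abs
    elif criterion == "rss":
        grid = sweep.rss
    else:
        raise ValueError("criterion must be 'delta_q' or 'rss'")
    with np.errstate(invalid="ignore"):
        return float(np.mean(grid < threshold))


def _as_specs(specs):
    out = []
    for s in specs:
        out.append(s if isinstance(s, SLModuleSpec) else build_preset(s))
    return out


def fsl_sweep(
    specs,
    f_sl_list,
    relax: RelaxationParams,
    **sweep_kw,
) -> pd.DataFrame:
    """Proportion curves versus SL frequency, one row per (module, f_SL)."""
    f_sl_list = list(f_sl_list)
    if len(f_sl_list) < 1:
        raise ValueError("need at least one SL frequency")
    rows = []
    for f_sl in f_sl_list:
        for spec in _as_specs(specs):
            sw = inhomogeneity_sweep(spec, f_sl, relax, **sweep_kw)
            rows.append(
                {
                    "module": spec.name,
                    "f_sl": f_sl,
                    "ratio": float(relax.ratio),
                    "prop_dq": proportion_within(sw, "delta_q", 0.01),
                    "prop_rss": proportion_within(sw, "rss", 0.01),
                    "mean_dq_abs": float(np.nanmean(sw.dq_abs)),
                    "mean_rss": float(np.nanmean(sw.rss)),
                }
            )
    return pd.DataFrame(rows)


def ratio_sweep(
    specs,
    ratios,
    f_sl: float = 500.0,
    t1rho: float = 0.05,
    **sweep_kw,
) -> pd.DataFrame:
    """Proportion curves versus the T1rho:T2rho ratio at fixed f_SL."""
    rows = []
    for ratio in ratios:
        relax = RelaxationParams.from_ratio(t1rho, ratio)
        for spec in _as_specs(specs):
            sw = inhomogeneity_sweep(spec, f_sl, relax, **sweep_kw)
            rows.append(
                {
                    "module": spec.name,
                    "f_sl": f_sl,
                    "ratio": ratio,
                    "prop_dq": proportion_within(sw, "delta_q", 0.01),
                    "prop_rss": proportion_within(sw, "rss", 0.01),
                    "mean_dq_abs": float(np.nanmean(sw.dq_abs)),
                    "mean_rss": float(np.nanmean(sw.rss)),
                }
            )
    return pd.DataFrame(rows)


def phase_combination_study(
    combos=SIX_QR_PHASE_COMBOS,
    f_sl: float = 500.0,
    relax: RelaxationParams | None = None,
    **sweep_kw,
) -> pd.DataFrame:
    """Grid-mean |DQ| and RSS for 4-refocused modules with the given
    refocusing-phase patterns, ranked by grid-mean RSS (shared seeds)."""
    if relax is None:
        relax = RelaxationParams.from_ratio(0.05, 1.0)
    rows = []
    for combo in combos:
        spec = build_n_refocused(4, combo, sl_phase_start=1, final_90_sign=-1)
        sw = inhomogeneity_sweep(spec, f_sl, relax, **sweep_kw)
        rows.append(
            {
                "phases": "".join("+" if p > 0 else "-" for p in combo),
                "mean_dq_abs": float(np.nanmean(sw.dq_abs)),
                "mean_rss": float(np.nanmean(sw.rss)),
                "prop_dq": proportion_within(sw, "delta_q", 0.01),
                "prop_rss": proportion_within(sw, "rss", 0.01),
            }
        )
    df = pd.DataFrame(rows).sort_values("mean_rss", ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
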