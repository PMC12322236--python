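# spinprep

Simulation and quantification toolkit for **spin-lock T1ρ preparation
modules** in quantitative MRI.

T1ρ — the longitudinal relaxation time in the rotating frame — is measured by
locking the magnetization along a long, low-amplitude RF pulse (the spin-lock,
amplitude f_SL = γB_SL/2π) for a duration TSL, and fitting the resulting image
series to the mono-exponential signal model

    S(TSL) = S0 · exp(−TSL / T1ρ).

In practice both the static field (B0, off-resonance Δf0) and the RF field
(B1, a flip-angle/amplitude scale error) deviate from nominal.  The effective
lock axis then tilts by θ = arctan(Δω0/ω_SL) and the prepared magnetization
oscillates instead of decaying cleanly, producing banding artifacts and T1ρ
quantification errors.  Composite preparation modules fight this with
rotary-echo phase cycling of the lock and with 180° refocusing pulses:

| module | refocusing pulses | SL segments (fractions of TSL) |
|--------|-------------------|--------------------------------|
| C-SL   | 1 (+y)            | 1/2, 1/2 |
| B-SL   | 2 (+y, −y)        | 1/4, 1/2, 1/4 |
| TR-SL  | 3 (+y, +y, −y)    | 1/4 × 4 |
| QR-SL  | 4 (+y, +y, −y, −y)| 1/8, 1/4, 1/4, 1/4, 1/8 |

`spinprep` builds each module as a chain of 3×3 rotation and rotating-frame
relaxation matrices (propagators are multiplied right-to-left; the spin-lock
segment in the tilted frame is `Rx(−θ)·Eρ(τ)·Ry(ωτ)·Rx(θ)`), and provides:

* **propagation core** (`spinprep.core`) — rotations, relaxation, hard pulses,
  tilted-frame SL segments; everything broadcasts over numpy arrays.
* **module library** (`spinprep.modules`) — the four presets plus a generic
  n-refocused builder and JSON (de)serialization of custom modules.
* **closed forms** (`spinprep.closed_forms`) — analytic Mz for the B1-only and
  B0-only limiting cases, used as an independent oracle.
* **quantification** (`spinprep.quantify`) — mono-exponential fitting (scalar
  and vectorized), the per-trial error Δq = T1ρ,fit/T1ρ,true − 1, its
  repetition average ΔQ, dense-trajectory RSS, pixel-wise T1ρ mapping, and
  relative residual maps.
* **sweep engine** (`spinprep.sweeps`) — ΔQ/RSS grids over ±600 Hz × ±50%
  field deviations with seed-paired module comparisons, f_SL and
  T1ρ:T2ρ-ratio curves, and the refocusing-phase combination study.
* **digital phantom** (`spinprep.phantom`) — five 20-mm tubes in a 120-mm
  field of view (200×200 matrix), linear-gradient B0 maps, uniform B1 scale,
  T1ρ-weighted series synthesis with optional Rician noise, and the standard
  dual-TE B0 / double-angle B1 map estimators.
* **RF metrics** (`spinprep.rf`) — RMS RF integrals per module as a SAR proxy.
* **CLI** (`spinprep`) — `simulate`, `sweep`, `phase-study`, `phantom`,
  `map`, `rf` subcommands with deterministic, provenance-stamped outputs.

## Worked example

Quantification errors of all four modules at f_SL = 500 Hz with an
off-resonance of 350 Hz and a −25% B1 error (100 repetitions of 8-point
random-TSL fitting, identical TSL draws for every module):

```sh
$ spinprep simulate --module all --fsl 500 --db0 350 --db1 -0.25 \
      --reps 100 --seed 7 --out sim.csv
$ cat sim.csv
# spinprep 0.1.0 config=5efa9e5051c8 seed=7
module,f_sl,delta_f0,db1,dq_signed_pct,dq_abs_pct,dq_s0_abs_pct,rss,n_failed
CSL,500.0,350.0,-0.25,-0.814...,4.013...,9.617...,0.0844...,0
BSL,500.0,350.0,-0.25,-1.096...,13.886...,16.717...,0.8301...,0
TRSL,500.0,350.0,-0.25,-1.335...,5.792...,8.242...,0.1957...,0
QRSL,500.0,350.0,-0.25,-0.542...,5.495...,6.955...,0.1308...,0
```

Reading the columns: `dq_abs_pct` is the mean |ΔQ| of the fitted T1ρ in
percent (here ~4% for C-SL versus ~14% for B-SL — the double-refocused module
suffers most at this off-resonance), `dq_s0_abs_pct` is the corresponding
error of the fitted amplitude against the true initial magnetization, and
`rss` is the residual sum of squares of the densely sampled |Mz| trajectory
around its mono-exponential fit (the banding-artifact score; the
quadruple-refocused module oscillates least among the refocused variants).
The same quantities come straight from the library:

```python
from spinprep import (FieldConditions, RelaxationParams, build_preset,
                      mean_delta_q)

fields = FieldConditions(f_sl_nominal=500.0, delta_f0=350.0, b1_scale=0.75,
                         couple_sl_amplitude=False)
relax = RelaxationParams.from_ratio(0.05, 1.0)       # T1rho 50 ms, ratio 1
res = mean_delta_q(build_preset("QRSL"), fields, relax, n_reps=100, rng=7)
print(f"{100 * res.abs_mean:.2f} %")                 # -> 5.50 %
```

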