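# Methods

## Unit system

All internal quantities are in piconewtons, nanometres and seconds; spring
constants are pN/nm, stresses and moduli pN/nm² (= 1 MPa exactly). Public
converters take and return SI pascals, stiffness sweeps are specified in
kPa, and flow speeds are nm/s (1 nm/s = 0.06 μm/min). Slip-bond and talin
force coefficients are stored in 1/N, the units their published constants
carry, and rescaled at evaluation time. Working in pN/nm keeps the ~1e11
1/N exponential coefficients at order 0.1/pN and avoids overflow-prone
intermediate values.

## Rigid-actin clutch engine

A zero-dimensional ensemble of `nf` integrin–fibronectin clutches couples a
rigidly treadmilling filament to an elastic substrate
(`ksub = 4π·ra·E/9`, adhesion radius `ra`). Per fixed step `dt`:

1. unbound clutches bind with probability `kon·dt`, engaging at the current
   substrate position (zero extension); `kon = kont·dint_eff` rises with
   vinculin-driven reinforcement;
2. bound clutches unbind with probability `koff(Fc)·dt`, where
   `koff = koff_scale · a·exp(b·Fc)` with `(a,b) = (0.1905 s⁻¹,
   2.333e11 N⁻¹)` below 13.2 pN and `(0.04527 s⁻¹, 7.251e10 N⁻¹)` from
   13.2 pN on. The second branch is extrapolated beyond its stated 30 pN
   range (continuity of the high-force slip regime; forces rarely reach it
   at the defaults). The two branches are kept exactly as published — the
   law is discontinuous at 13.2 pN, dropping ~33-fold, which creates a
   kinetically protected high-force state that loading can reach only by
   crossing the fast-unbinding 8–13 pN window quickly;
3. bound talin unfolds/refolds with the published exponential rates
   (`pt = 0.073` of the clutch force on talin); unfolded talin binds
   vinculin (probability-capped, occupancy capped at 1 per clutch), each
   event adding `dint_increment` to the effective integrin density and
   reverting when the clutch unbinds. At the default operating forces
   (1–10 pN per clutch) unfolding is rare and reinforcement is essentially
   dormant; the machinery is present and tested but does not shape the
   default curves;
4. bound clutch positions advance by `vf·dt`;
5. `Fsub = ksub·kc·Σxᵢ/(ksub + n_bound·kc)` (series force balance, held to
   1e-9 relative as a tested invariant);
6. `vf` is recomputed from the two clamped linear force–velocity terms.

The integration is fixed-step Monte Carlo rather than exact event-driven
simulation because the propensities change continuously with the flow; a
guard warns when any binding/unbinding probability per step exceeds 0.1.
The talin-refold and vinculin rates (e^13.07 s⁻¹, 1e8 s⁻¹) are saturating
by construction and excluded from the guard. Default `dt` = 5e-4 s;
runs start all-unbound and unloaded, and summary statistics drop the first
20% of samples (configurable).

## Viscoelastic actin-network engine

The lamellipodial network is a serial chain of mesoscale units (per-unit
spring `kactin`, count `Ntot`, damper `η`) growing at a rigid membrane
wall by `Nn = Nn_max(1 − Fc_max/Fs_actin)` units of rest length `L` per
step, where `Fc_max` is the largest single-clutch force. Clutches grip the
chain's rear end; the rear position obeys

    η dXc/dt = kactin(Ladd − Xc)/Ntot − Fadh,

integrated by explicit Euler. Integration uses the translation-invariant
variables `comp = Ladd − Xc` (net compression, clamped ≥ 0: the chain
pushes but cannot pull) and per-clutch spring extensions `eᵢ`, which all
evolve at the common rate `dXc/dt − dXsub/dt` with the substrate following
quasi-statically (`dXsub/dt = Nc·kc·(dXc/dt)/(ks + Nc·kc)`, the rate form
of the printed lumped balance). This formulation is exactly equivalent to
the absolute-coordinate equations on any engagement epoch but has no
growing coordinates, so arbitrarily long runs stay well-conditioned.

Clutches bind at zero extension and unbind by the same slip-bond law as
the rigid engine (a `koff_mode="constant"` switch uses `koff_scale` as a
bare rate instead). When a clutch releases, the substrate recoils and the
released load redistributes instantly onto the survivors — the
failure-cascade mechanism that terminates each loading cycle. When the
last clutch releases, the stored compression relaxes freely through the
damper (`release_mode="relax"`; `"reset"` discards it). The rearward flow
speed is the largest clutch displacement rate — zero while disengaged — so
each full release drops the speed to zero and each re-engagement of the
still-compressed chain produces a drag spike. (The network's free
relaxation is real motion, but the reported speed follows the
clutch-displacement definition; this is why release events appear as drops
rather than spikes in the traces.)

Two emergent behaviors carry the physics: (i) traction rises with
substrate stiffness because stiffer substrates load clutches faster, both
pushing individual bonds across the 13.2 pN branch point into the
long-lived state and shortening the low-force rebuild phase of each cycle;
(ii) lowering `kactin` (Arp2/3 inhibition) softens the chain, so a larger
fraction of each growth increment is stored as compression instead of
loading the clutches — force rebuild after every release slows by the
factor `Ntot/kactin`, cutting the duty cycle and the transmitted traction
while leaving the long-run flow (pinned to the growth rate) much less
affected.

## Condition presets

`make_preset(name, base, model)` applies the pharmacological conditions.
All inhibited conditions zero the myosin velocity term. The viscoelastic
presets differ only in network mechanics — kactin = 11000 (BBS), 1500
(CK666-BBS), 1150 (SMIFH2-BBS), 1000 (LatA-BBS), with η = 0.175 except
SMIFH2 (1.08) and LatA (0.8) — so the BBS/CK666-BBS comparison isolates
kactin exactly. In the rigid engine, CK666-BBS instead halves the actin
stall force and raises the unclutching-rate magnitude to 6 (vs 0.5 for the
other inhibited conditions), the adjustment used for that model variant.
The preset overrides are engine-dependent because the two published
comparisons parameterize the conditions differently.

## Parameter defaults and provenance

Constants fixed by measurement or the source models: `δ` = 2.7 nm,
`Ccrit` = 0.12 μM, `C` = 100 μM, `T` = 310 K (37 °C culture), the koff
branch constants, the talin/vinculin rate constants, `pt` = 0.073,
`konv` = 1e8 s⁻¹, kactin/η presets, and the actin:myosin stall ratio of
one third (`Fs_actin` = 50 pN against `nm·Fm` = 150 pN in the rigid
engine).

The remaining ensemble parameters are not fixed by published values; they
were chosen once, per engine, to place each model in its intended operating
regime (traction of order 1–30 Pa and flow of order 0.05–1 μm/min on the
0.6–12.7 kPa gel set, with load-and-fail cycling in the viscoelastic
model), and are shipped as the documented defaults:

- shared: `ra` = 1000 nm, `nm` = 75, `Fm` = 2 pN;
- rigid engine: `nf` = 10, `kc` = 1 pN/nm, `kon` = 0.45 s⁻¹,
  `Va` = 9 nm/s, `vactin_max` = 6.5 nm/s (unloaded WT flow
  ≈ 0.93 μm/min and unloaded inhibited flow ≈ 0.39 μm/min, the fitted
  intercepts of the corresponding flow curves);
- viscoelastic engine: `kc` = 5 pN/nm, `kon` = 0.05 s⁻¹ (a sparse, stiff
  ensemble whose cascade failures produce full-release cycling),
  `N0` = 5000 units, `L` = 10 nm, `Nn_max` = 2.5e-4 units/step (growth
  5 nm/s at the default dt), `Fs_actin` = 40 pN.

`Nn_max` is defined per step, as in the unit-addition rule; holding the
growth *rate* fixed while changing `dt` requires rescaling it, which the
convergence test does.

## Sweeps, fits, spectra

`run_sweep` runs `n_reps` independent seeded simulations per stiffness
(default 20; child seeds derive deterministically from one base seed) and
summarizes each run by its post-burn-in time averages. Fits are unweighted
nonlinear least squares (`scipy.optimize.curve_fit`): the power law is
initialized from a log-log regression, the negative exponential from
`(Vmax − Vmin, −1/median(E), Vmin)`; `adj_R²
= 1 − (1−R²)(n−1)/(n−p−1)`.

Spectra are mean-subtracted one-sided periodograms (boxcar by default, Hann
optional; no tapering is the appropriate default for the short 31-frame
traces of windowed flow fields sampled at 6 s). The DC bin is excluded from
normalization, band powers, and the power-weighted mean frequency (a
spectral-peak mode is available); total boxcar power equals the trace
variance (Parseval, tested at 1e-6). Simulated traces are resampled to
~1 s before spectral summaries so the cycle structure (periods of seconds
to tens of seconds) is resolved; 6-s resampling is used when emulating
flow-field windows. "Unclutching events" are full network releases — the
velocity-drop-to-zero events of the traces — logged separately from
individual bond releases, whose rate is binding-limited and carries no
stiffness signal.

## Synthetic generators

`gen_sawtooth` emulates load-and-fail flow traces: a baseline speed,
release spikes with exponential decay, and Gaussian noise. Event gaps are
gamma-distributed with mean rate `lambda_fail` and shape `regularity`
(default 4): the quasi-periodic cycling of real load-and-fail traces, for
which the spectral mean frequency rises with the event rate. Shape 1
recovers a Poisson process — for which the normalized shot-noise spectrum
is rate-invariant, so no spectral trend exists; this is why the default is
quasi-periodic. `gen_flow_grid` stacks independent windows with a
stiffness-dependent rate; `gen_response` draws from either fit form with
multiplicative lognormal noise (log-residuals exactly normal). Generators
are seed-deterministic. They emulate trace morphology and summary-curve
shapes only — no spatial correlation between windows, no photometric or
tracking noise, no drift — so tests built on them validate the analysis
chain, not the microscopy.

## Numerical choices

- Explicit Euler with `dt` = 5e-4 s for both engines; the stiffest
  relaxation rate at the defaults is ~10² s⁻¹, giving λ·dt ≲ 0.06.
  Convergence is verified in a deterministic configuration (instant
  binding, no unbinding), where halving `dt` moves the post-burn-in means
  by well under 2%; in stochastic runs the seed-to-seed spread (~20% per
  300-s run) dominates any integrator bias.
- Event probabilities are `rate·dt` capped at 1; the dt guard warns at
  0.1 for the binding/unbinding channels.
- Forces feeding the slip bond are clamped at ≥ 0; flow terms clamp at
  zero unless `allow_reversal` is set.
- Both engines have a pure-Python reference step (`step_rigid`,
  `step_visco`) and a numba kernel that consume identical random streams;
  a test asserts trajectory-level agreement, so the compiled path is
  cross-validated against the readable one. Fixed seeds give bit-identical
  reruns.

## Known limitations

- The BBS : CK666-BBS traction fold-change, the flow-speed difference, and
  the traction power-law exponents trade off against each other along a
  frontier controlled by the free ensemble parameters; the shipped
  calibration yields a fold-change near 1.6–1.9, a flow difference near
  40%, and exponents near 0.10 (BBS) / 0.02–0.13 (CK666-BBS, the noisiest
  of the summaries), rather than the published ~4-fold / ~20% / 0.173 /
  0.106 combination, which we could not realize simultaneously at the
  published kactin, η and slip-bond constants. (The published fitted
  curves themselves imply a ~2.3–2.9-fold traction contrast.)
- In the rigid engine, WT dominance in traction and the decaying-flow fit
  for the inhibited condition are mutually exclusive at the published koff
  constants: the inhibited condition's bonds are 2× longer-lived
  (koff_scale 0.5 vs 1), so wherever its traction genuinely rises toward
  the bond ceiling it overtakes WT at the stiff end, and talin
  reinforcement — the mechanism that would rescue WT — activates only
  above ~40 pN per clutch, far above the operating forces. The defaults
  keep WT dominance and the ~3-fold flow contrast; inhibited-condition
  traction is then stiffness-flat and its flow nearly so.
- The models are zero-dimensional: no spatial structure along the leading
  edge, no membrane degree of freedom (rigid wall), no coupling of η to
  stiffness or time.
- Reported traction prefactors depend on the adhesion radius `ra` through
  the force-to-stress conversion and are order-of-magnitude only;
  exponents, ratios and trends are the meaningful outputs.
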