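# Methods

## Scope and model

`afoflex` simulates one leg wearing an ankle-foot orthosis (AFO) over a gait
cycle in the sagittal plane. The pelvis, thigh and shank follow prescribed
(recorded or synthetic) kinematics; the dynamic subsystem comprises six free
generalized coordinates:

| coordinate     | meaning                                            |
|----------------|----------------------------------------------------|
| `ankle_rz`     | ankle dorsi-/plantarflexion angle (dorsiflexion +) |
| `aux_tx,ty,tz` | translations of the auxiliary body carrying the device axis |
| `footshell_rz` | foot-shell rotation about the device axis          |
| `calfshell_rz` | calf-shell rotation about the device axis          |

The frame convention is x anterior, y up, z the flexion axis (right-handed).
The auxiliary body attaches at the ankle center plus an optional
misalignment offset; its joint is free in translation and locked in
rotation, so shell rotation cannot be produced by auxiliary-body spin. Both
shells pin to the auxiliary body about z. Four viscoelastic interface
elements (two per region) couple the shells to foot and shank; each element
applies the per-axis law `F = -(K dx + C dx')`, `M = -(Kr dth + Cr dth')`
in an element frame fixed on the body-segment side, with the reaction
negated on the other body. Rotational deviations use a fixed-order
small-angle convention, adequate for the few-degree relative rotations the
element represents; stiffness is symmetric in sign (direction-dependent
tissue stiffness is a known, deliberate omission).

Shell-side anchor and marker geometry is stored in neutral-state
coordinates, so the elements are unloaded and the marker pairs coincident at
assembly *for every misalignment*: shifting the device axis changes the
lever arms about the pin, not the donned fit. This matches how a misaligned
brace is actually worn.

## Equations of motion and integrator

The EOM are written in the shank-attached frame with the complete planar
fictitious-force set of the moving frame (frame-origin acceleration,
centrifugal, Euler and Coriolis terms, plus the frame angular acceleration
on each body's rotary inertia), making the free-subsystem dynamics exact
given the prescribed base motion. The mass matrix couples the auxiliary
translations with the shell rotations through the shells' center-of-mass
offsets.

The interface makes the system numerically stiff: 1e4 N/m on the 1e-05 kg
auxiliary body gives characteristic rates of ~3e4 1/s, far beyond any
explicit scheme at a usable step. Time stepping is therefore a fixed-step
linearly-implicit theta scheme (default theta 0.6, slightly damped; the
energy-audit runs use 0.5 for minimal numerical dissipation) at dt = 1 ms,
with force Jacobians obtained by finite differences and refreshed every 10
steps — the interface geometry rotates slowly, so mildly stale Jacobians
affect only the stability margin, never the solution. A singular mass
matrix (possible only with degenerate user mass properties) is rejected
with the condition number in the diagnostic.

## Tracking controller

A computed-muscle-control-style loop tracks the reference ankle angle
(weight 10; the knee is a prescribed coordinate of the base motion and is by
construction reproduced exactly, honoring its weight-10 task trivially).
Per control step:

1. desired acceleration `qdd_des = qdd_ref + k_v (qd_ref - qd) + k_p (q_ref - q)`
   with defaults `k_p = 100 1/s^2`, `k_v = 20 1/s` (critically damped pair;
   config-exposed);
2. a strictly convex QP distributes the tasked accelerations over muscle
   activations and reserve actuators: weighted task error plus
   activation-squared cost plus a reserve penalty that makes reserves ~100x
   more expensive than muscles. The QP is solved by an exact active-set
   iteration with KKT-gradient constraint release;
3. activation bounds in the per-step solve are the range *reachable* under
   first-order activation/deactivation dynamics (tau_act = 10 ms,
   tau_deact = 30 ms), and the excitation applies the one-step inverse of
   the activation filter, so the realized activation equals the optimum
   unless the physiological rate limit binds — without this lookahead
   compensation the realized muscle moment lags every demand ramp and
   tracking degrades. The one-shot `cmc_step` API instead exposes the plain
   [0, 1]-bounded optimization.

Reserves are recorded per coordinate as the residual-actuator usage. Because
the base kinematics are prescribed exactly, translational base residuals
vanish identically; the informative residual of this formulation is the
ankle reserve moment. The plausibility check accepts residual forces up to
5% of the peak ground-reaction magnitude and reserve moments up to 25 Nm — a
conservative fraction of the residual-moment magnitudes conventionally
accepted in gait simulation practice (boundary values inclusive).

## Bootstrap ("initial CMC")

Gait simulations start from a settled state produced by a bootstrap run: the
tasked angles ramp linearly from the standard (anatomical neutral) pose to
the gait-initial pose over 10 knots (default 20 ms each), external gait
forces excluded, base floating on virtual supports, followed by a 0.5 s
settle. The bootstrap always runs on the unweakened model, so every
weakening level and misalignment starts a speed/direction cell from the same
body pose; residual interface motion above 1e-3 m/s (rad/s) at the end is
flagged on the returned state.

## Synthetic gait generator

The generator emulates a motion-lab data set that is not available; it is a
first-class, tested component, not a fixture.

* **Kinematics.** Hip/knee/ankle angles are truncated-Fourier templates
  (3 harmonics) least-squares-fitted to fixed normative control points,
  with speed-scaled cycle duration (slow/medium/fast = 1.25/1.05/0.90 s),
  amplitude scale (0.95/1.00/1.08), and seeded two-harmonic jitter
  (0.7 deg RMS) — smooth by construction, so no non-physiological
  accelerations.
* **Ground reaction.** A double-bump vertical profile (flat-topped envelope
  minus a mid-stance valley term) tapered to zero over the final ~0.18 s of
  stance: push-off unloading takes roughly constant wall time across
  speeds, so the taper occupies a larger phase fraction of fast cycles; a
  per-speed amplitude factor compensates the taper's area loss and keeps
  the single-limb stance impulse near 0.92 body weight x stance duration.
  The center of pressure sweeps heel to toe with an excursion bounded by
  foot length, hence only weakly speed-dependent.
* **Support curves.** The companion assistance-as-needed identification is
  emulated, not re-derived. The inverse-dynamics ankle demand is split into
  the healthy plantarflexor share — the demand-implied activation passed
  through the activation filter, *including its deactivation tail after
  push-off* — and the dorsiflexor remainder. The device supplies the full
  dorsiflexor share (dorsiflexors are paralyzed in every patient variant)
  plus the fraction (1 - w) of the plantarflexor share lost to weakness.
  This yields a late-stance plantarflexion lobe scaling with weakness, a
  toe-off catch, and a small gravity-hold swing lobe. The deactivation
  constant of 30 ms (fast end of the published Hill-model range) together
  with the unloading taper keeps the toe-off lobe — which necessarily
  scales *with* residual strength, as it counters the patient's own
  lingering plantarflexor moment — below the PF75 stance lobe, so the peak
  support magnitude is monotone non-increasing from PF25 to PF100.
* **Reference activation.** The healthy plantarflexor curve is the same
  filtered demand-implied activation; simulated activations are compared
  against it over the stance window.

What the generator does **not** reproduce: inter-subject anthropometric
variation, 3D kinematics, double-support force sharing, measured EMG, or
the numeric magnitudes of any specific cohort. Passing grid properties
therefore demonstrate the mechanistic orderings (weakness, speed,
misalignment) under controlled synthetic conditions, not agreement with any
particular experimental data set.

## Outcome measures

* **Relative movement**: shell-marker minus segment-marker displacement in
  the segment frame, resampled to 101 points of the heel-strike-to-heel-
  strike cycle. The weakening-ordering measure is the dominant *negative*
  stance y-excursion of the foot pair (device pressing into the instep);
  the unsigned peak can be contaminated by the positive toe-off catch.
* **Activation deviation**: mean absolute difference between simulated and
  reference plantarflexor activation, in percentage points, over the stance
  window (vertical ground reaction above 2% of its peak — the cycle is
  reported per-phase but the stance boundary is never standardized, so the
  2% threshold is fixed here once).
* **Residual plausibility**: per-coordinate pass/fail with margins, as
  above.
* **Aggregation**: mean of per-subject means (subjects = generator seeds).

## Problem sizes

The default study grid is 4 weakening levels x 3 speeds x 7 alignment
conditions = 84 simulations per synthetic subject at dt = 1 ms (~1,250 steps
per cycle plus a ~700-step bootstrap shared by the four levels of each
speed/direction cell); one subject suffices for every ordering property and
runs in about a minute on one CPU. The analytic oracles run at dt = 0.2 ms.

## Known limitations

* Magnitudes are qualitative: support curves and gait are synthetic, so
  millimeter and percent values characterize this model world, not a
  clinical cohort.
* Symmetric per-axis stiffness; no direction-dependent tissue response, no
  strap contact mechanics, no finite-element tissue field.
* The controller optimizes per step (no receding horizon); reserve spikes
  at toe-off reflect the interface transmission lag and the activation
  rate limit, both physical, but their size depends on the support
  calibration.
* In-plane prescribed motion makes the out-of-plane (z) interface response
  identically zero under aligned axes; the z channel is exercised only by
  inside/outside misalignment, and then only trivially (the z-translation
  of the auxiliary body is load-free in this geometry).
* The zero-load/zero-motion identity holds exactly for an inertial base;
  during gait the accelerating base shakes the shells on their soft springs
  by a few millimeters even without gravity and support — a genuine
  inertial response, an order of magnitude below loaded excursions.
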