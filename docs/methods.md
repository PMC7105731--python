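# Methods

This note records the models implemented, the defaults and why they were
chosen, the desk-scale substitutions, and what the tests do and do not
demonstrate. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Membrane models

**Detailed model.** The ten Tusscher–Panfilov (2006) human ventricular
myocyte: 19 state variables, the full current set (I_Na, I_K1, I_to,
I_Kr, I_Ks, I_CaL, I_NaCa, I_NaK, I_pCa, I_pK, I_bNa, I_bCa), dyadic
subspace calcium with I_xfer, and SR release/leak/uptake. Parameters are
the published table; transmural variants differ in g_to (epi/M 0.294,
endo 0.073 mS/uF) and g_Ks (epi/endo 0.392, M 0.098 mS/uF). The
experiment dial is a dimensionless multiplier on the baseline
g_Ks = 0.392 × 1.3 mS/uF; the epicardial variant is the default.
Integration: Rush–Larsen for gates, forward Euler for voltage and
concentrations, dt = 0.02 ms. Step-halving agreement (dt vs dt/10) is
better than 1 mV over a paced beat (tested).

With pacing at 600 ms to steady state, APD90 falls monotonically from
~280 ms (multiplier 1) to ~64 ms (multiplier 100) for the epicardial
cell. The reported reference value for the ×100 condition is ~90 ms; an
isolated epicardial cell lands below it and an isolated mid-myocardial
cell above it (~104 ms). A transmurally heterogeneous coupled ventricle —
which electrotonically averages these — is the likely source of the
intermediate value; reproducing it would require the 3D heterogeneous
tissue this package deliberately replaces with sheets. This is the one
acceptance quantity the desk build reports honestly out of band
(`scripts/acceptance.py` prints what the stated single-cell setup
actually produces).

**Reduced model.** A three-current excitable model (fast inward, slow
outward, slow inward; Fenton–Karma class) plus a first-order
phenomenological calcium variable relaxing toward the normalized
depolarization (tau = 30 ms, diastolic 0.1 uM, peak ~1 uM — chosen to
match the detailed model's transient scale). Two departures from the
classic parameter set, both needed at desk resolution (h = 0.5 mm):

* u_csi lowered 0.85 → 0.5 so that *propagated* upstrokes — whose peak
  is reduced on coarse grids — still recruit the slow inward current;
  otherwise tissue APs collapse to ~40 ms spikes while stimulated cells
  show full APs;
* the APD dial acts only on the plateau decay of the slow gate w
  (tau_w+ / gain, gain = 1.55 · m^0.453, calibrated once so paced APD90
  spans ~250 ms at multiplier 1 down to ~74 ms at 100). Scaling current
  magnitudes instead produces an all-or-nothing plateau collapse, and
  scaling the fast system changes the propagation threshold; the w-decay
  dial leaves the upstroke, the excitation threshold and hence conduction
  exactly multiplier-independent (verified: cable CV varies < 1% across
  the ladder at fixed D).

## Tissue

Monodomain on regular grids: per-axis effective diffusion D (mm²/ms)
absorbs resistivity, surface-to-volume ratio and capacitance, which the
source experiment never reports separately — only conduction velocities.
Calibration to CV is therefore the contract: bisection (geometric mean
steps, since CV ≈ const·√D) on an 80-node cable until the planar-wave
speed is within 2% of target. Spatial operator: second-order central
differences with finite-volume no-flux boundaries (ghost node = boundary
node), which conserves the spatial mean exactly; the interior operator
matches the analytic heat kernel to < 1% RMS. Operator splitting
(reaction then diffusion), explicit, with the stability bound
dt ≤ h²/(2 Σ D_axis) checked up front. Movies are recorded at exactly
10 ms frames regardless of the internal step.

**S1–S2 protocol.** Three S1 pulses 600 ms apart at the left edge, then
one S2 over a half or quadrant region (the sheet analogues of whole-LV,
lower-LV, whole-RV, lower-RV delivery). S2 fires when the wave tail of
the last S1 has cleared the stimulated region: the trigger monitor is the
region node the S1 wave reaches last (clamped to the sheet midline so
refractory tissue always remains beyond it), and it fires at
repolarization below −80 mV. The depth matters: a threshold scan on the
64×64 reduced sheet showed sustained induction only for crossings in
[−75, −82] mV — shallower firing hits tissue that is still
post-repolarization refractory; −80 mV is the center of that window and
was frozen before the final grid was run.

**Desk-scale caveat.** On a 32 mm sheet the induced rotor is sustained
for the lower-left-quadrant S2 at multipliers ≥ 4 and transient (1–2
rotations) for the other sites: with a planar S1 wave, a half-sheet S2
region cannot create a free phase-singularity end (the block line spans
the full height), and right-side regions fire when little refractory
tissue remains. This is a genuine domain-size/geometry limit, not a
detector artifact; the full-heart geometry the study used gives all four
sites complex sustained patterns. Consequently the desk grid's variance
in DF and PS comes mostly from the inducing site, and the statistics
stage is validated separately on synthetic tables with the reference
correlation structure.

## Excitation–contraction and circulation

One-way coupling. Per node: Ca_i → troponin occupancy TCa (single-site
on/off ODE, kon = 50 /mM/ms, koff = 0.02 /ms) → four-state cross-bridge
chain N ⇌ P ⇌ XB_PreR ⇌ XB_PostR with regulatory rates
K_np·TCa^7.5 and K_pn·TCa^−7.5 (the diverging backward rate capped at
0.5 /ms; occupancies renormalized each step, conserved to 1e−10). Rates
(1/ms): f_aapT 0.05, g_aapT 0.01, h_fT 0.02, h_bT 0.004, g_xbT 0.012 —
a reduced parameterization giving ~100 ms twitch rise; T_max = 30 kPa
puts peak twitch tension at O(10 kPa). ampTens uses the population SD
over time per node (its definition), while the statistics stage uses
sample SDs — the two conventions are deliberate and documented.

The ventricles feed a closed 8-compartment loop (LA, LV, systemic artery
and vein, RA, RV, pulmonary artery and vein) with diode valves.
Ventricular pressure is P = C(y_v)⁻¹(V − V_rest(y_v)) with compliance
interpolating C_min → C_max and rest volume V_rest,d → V_rest,s as the
activation y_v goes 0 → 1; y_v comes from the spatial-mean tension. For
a single record it is min–max normalized; grid cases instead divide by a
fixed 10 kPa reference (clipped to [0, 1]), because per-case min–max
rescaling hands weakly contracting, fused-tension cases a full-range
activation and thereby *larger* stroke volumes than strongly twitching
ones — inverting the tension–ejection coupling that cross-case
statistics are supposed to measure. The activated-state rest-volume offset uses the *systolic* rest
volume for both ventricles; the printed source formula mixes a diastolic
right-ventricular entry, which is dimensionally consistent but
physiologically asymmetric — both variants are implemented
(`literal_rest_vector`), the symmetric one is the default. How the
activation was computed during arrhythmia in the source pipeline is
unstated; the tension-mean rule here is an explicit assumption. Total
blood volume is conserved to 1e−6 relative over 20 s (tested). The
parameter defaults are a compact working set tuned once to eject a few
tens of mL per cycle at 1 Hz; stroke volume is *only* meaningful
relatively, across conditions — no finite-element mechanics stands
behind it, which is the largest fidelity gap of the build.

## Metrics

* APD90: onset at maximal upstroke dV/dt, end at V_rest + 0.1(V_peak −
  V_rest) on the falling limb with linear interpolation; beats segmented
  at upward −40 mV crossings.
* DF: mean-detrended signals zero-padded to ≤ 0.01 Hz bins (the stated
  0.01 Hz read as spectral resolution — the movie cadence is 10 ms, so it
  cannot be a sampling rate), argmax of power in 0.5–30 Hz; nodes with
  < 1 mV peak-to-peak excluded from the tissue mean (count logged).
* Phase: delay embedding with tau = one 10 ms frame, per-frame spatial
  mean as origin; range exactly [−π, π) (the +π boundary maps to −π so
  the wrap rule's output range is half-open).
* PS: the four wrapped phase differences around each 2×2 plaquette sum
  to an exact multiple of 2π (the wraps telescope), so detection is a
  question of counting ±2π plaquettes; the 0.1 rad tolerance guards
  float noise only.
* Filaments: an element is on the filament when the 4-corner
  interpolated potential attains V_iso at frames n and n+1 — the
  iso-surface intersects the element at both times, which is precisely
  where the surface does not move over a frame (the discrete
  dV/dt = 0 + iso-potential condition) and marks the rotation axis. A
  strict centroid-proximity variant (p = q = r = 0.5 weights, tolerance
  epsilon) is available; as the *sole* criterion it fails its own
  ground-truth contract (a rigidly rotating scroll sweeps the iso-line
  more than any reasonable epsilon per 10 ms frame except at the core
  itself), so the crossing form is the default. V_iso per frame is the
  mean potential over surface-slice PS locations clamped to
  [−75, −10] mV, falling back to −40 mV.
* Connected components: 26-connectivity; the per-case scalar is the
  time-averaged element count (component count kept as a diagnostic).
  On uniform scrolls elements live on layer *pairs*, so the count scales
  with nz − 1.

## Desk grid and analysis windows

The default grid preset is the reduced model on a 64×64 sheet at
h = 0.5 mm: 12 multipliers × 4 S2 sites, generation 2.6 s at 20 cm/s,
maintenance 1.0 s at 68.5 cm/s (the full-study durations of 10 s + 20 s
scale down proportionally; sizes chosen so the whole grid runs in
minutes). Electrical metrics are computed on the post-S2 window
(arrhythmic episode; ≥ 2 s by construction); when the episode dies
before re-exciting the center probe twice, the case APD falls back to
the probe's final paced beat before the S2 transient. Mechanics integrate the whole case record:
at sheet scale the alternative — mechanics on a possibly quiescent
post-S2 window — would reduce stroke volume to an uninformative zero for
every non-inducing case. Passing grid tests therefore demonstrate the
*directional* structure (APD falling along the g_Ks ladder; DF
negatively associated with SV and ampTens), not the published effect
sizes, which required the full-resolution heart.

## Synthetic generators

Spiral/scroll movies are pure phase fields V = V₀ + A·cos(Σᵢ χᵢ
atan2(y−yᵢ, x−xᵢ) − 2πt/T + k·r) mapped into [−86, +34] mV (multi-vortex
fields superpose phases, not voltages; r is distance to the nearest
core). They have exactly known singularity tracks, chirality, and DF,
but rigid rotation, no meander, no breakup and no restitution — so
detector tests on them validate geometry and counting, not robustness to
fibrillatory complexity. Plane-wave movies are piecewise-linear in time
(30 ms upstroke) so threshold crossings interpolated between 10 ms
frames recover CV exactly. Correlated tables use Cholesky of the target
correlation matrix (eigenvalue clipping at 1e−8 with diagonal rescaling
repairs printed matrices that are marginally indefinite; the repair is
recorded), scaled to target moments, count columns rounded to
nonnegative integers.

## Statistics

Sample SD (n−1) throughout, matching standard practice. Two pathways —
raw-table OLS (statsmodels) and the closed form from summary statistics —
agree to 1e−8 and both match an explicit normal-equations solve (tested).
The packaged reference summary is 3-decimal rounded, which bounds
achievable agreement with the published regression tables at roughly
0.1–0.6% relative; the 4-predictor models inherit the APD–DF r = −0.991
near-singularity (VIF ≈ 79, printed-precision-sensitive) and are
computed but flagged, never used as anchors. Durbin–Watson needs a case
ordering: the convention is g_Ks ascending within S2 site (the source
ordering is unknown), and it is reported only for raw-table fits.

## Known limitations

* No finite-element passive mechanics, no mechano-electrical feedback,
  no patient geometry, no fiber anisotropy, no bidomain.
* Reduced-model grid cases: rotor sustainment depends on sheet size and
  S2 site (see above); PS counts on coarse simulated (as opposed to
  analytic) fields include transient front-edge pairs.
* The circulation surrogate's absolute volumes and pressures are not
  calibrated to a patient; only condition-to-condition contrasts are
  interpretable.
* Dynamic troponin-buffer feedback onto the electrical model is
  deliberately absent (one-way coupling).
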