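# Methods

## Scope and model

`raffsim` implements rotating-frame relaxometry with RAFFn irradiation
(Relaxation Along a Fictitious Field in the rotating frame of rank n) for
characterizing myocardial infarction: pulse construction, a two-pool
Bloch-McConnell simulator of signal decay under pulse trains, the
dual-polarity steady-state relaxation fit, pixel-wise mapping on a
synthetic short-axis cardiac phantom, and the RRTD contrast statistic.

### RAFF2 pulses and the stretching factor

The rank-2 pulse uses sine/cosine amplitude and frequency modulation,

    omega_1(t) = omega_1^max sin(omega_1^max t),
    d_omega(t) = omega_1^max cos(omega_1^max t),

which keeps the first-frame effective field at constant magnitude
omega_1^max while sweeping its tilt at the constant rate omega_1^max.  In
the second rotating frame the fictitious field is then stationary at
alpha_2 = 45 deg with magnitude sqrt(2) omega_1^max.  The refocusing
element duration, T_e = pi / (sqrt(2) omega_1^max), is exactly the time
for a pi rotation about that fictitious field; four elements
P, P_pi^-1, P_pi, P^-1 (time-reversed sample order with negated frequency
offset for the inverses; a pi phase shift on the middle pair) build the
rotary-echo P-packet of 4 pi / (sqrt(2) omega_1^max) = 2.26 ms at the
625 Hz design power.  With this pairing the packet is an *algebraically
exact* rotary echo: the propagator of P_pi^-1 is the matrix inverse of the
propagator of P sample for sample, so an on-resonance magnetization
returns to its starting point at any discretization (verified to machine
precision in the tests).

**Stretching.** The stretching factor TL in [0.6, 2.0] rescales the
element duration only; the modulation frequency stays at the nominal
design value.  The sweep angle covered by one element therefore grows in
proportion to TL (127 deg x TL), while the fictitious-field tilt remains
45 deg at every TL.  The design was genuinely open here: the alternative
convention co-scales the sweep rate as omega_1^max / TL, preserving the
sweep range and tilting the fictitious field to arctan(1/TL).  We adopted
the fixed-sweep-rate reading because it alone reproduces the reference
steady-state fractions across the whole TL series (the co-scaled reading
errs by up to 0.11 at TL 2.0, far outside the printed precision), while
both conventions satisfy the published packet-duration table.  Timing is
keyed to the 625 Hz nominal design frequency even when the played
amplitude differs (the TL0.6 instrument preset is 608 Hz with an
unchanged 1.35 ms packet).

Waveforms default to 128 samples per packet (32 per element), midpoint
piecewise-constant.  Midpoint sampling is the resolution-converged choice:
fitted observables are identical at 32 and 64 samples per element, whereas
edge-sampled grids carry a non-converged discretization residue.

**Higher ranks.** Rank 1 is the constant 45-deg effective field with
equal amplitude and offset (peak power 625 Hz).  Ranks 3-5 descend the
frame recursion from a stationary 45-deg top-frame fictitious field of
magnitude sqrt(2) omega_1^max whose sub-frame tilt is swept at rate
omega_1^max: E_{k-1}(t) = E_k(t) cos(alpha_k(t)), alpha_{k-1}' =
E_k(t) sin(alpha_k(t)).  Under this recursion the peak played amplitude
is non-increasing in rank (625, 625, 361, 34, 7 Hz for ranks 1-5); the
exact normalization used in earlier hardware implementations is not
recoverable from published material, so only the monotone property is
asserted.

### Two-pool Bloch-McConnell system

Pool A is the dilute solute (fibronectin Fn1 or periostin hydroxyl
protons), pool B tissue water.  Fractions follow molar concentrations
(P_A = c_solute / 80 mol/l; healthy Fn1 1.2e-6 mol/l, upregulated
1.2e-5 mol/l, so P_A = 1.5e-8 or 1.5e-7).  The 500 Hz chemical-shift
difference is split population-weighted: Delta_A = 2 pi P_B 500,
Delta_B = 2 pi P_A 500 rad/s, putting the carrier at the population
average and water essentially on resonance.  Both pools share the
dipolar R1 and R2 of two identical spins with a single correlation time:

    b  = (mu0 / 4 pi) hbar gamma^2 / r^3,  J(w) = tau_c / (1 + w^2 tau_c^2)
    R1 = (3/10) b^2 [J(w0) + 4 J(2 w0)]
    R2 = (3/20) b^2 [3 J(0) + 5 J(w0) + 2 J(2 w0)]

At tau_c = 10 ps, B0 = 9.4 T, r = 158 pm this gives R1 = 0.5480 and
R2 = 0.5487 1/s -- extreme narrowing (w0 tau_c = 0.025), so R1 and R2
agree to 0.13 %.  The exchange constant "0.001" is read as a rate
k_ex = 0.001 1/s by default (a time-constant reading, k_ex = 1000 1/s, is
available as `tau_ex_as_rate=False`); with a solute fraction of 1.5e-8
either reading leaves every observable unchanged, which is also why the
upregulated scenario is indistinguishable from the healthy one.
Exchange is split by detailed balance, k_AB = k_ex P_B, k_BA = k_ex P_A.

### Propagation

Waveform samples act as piecewise-constant RF with the frequency offset
as a longitudinal field.  Over one dwell the Bloch-McConnell generator is
constant, so the per-dwell matrix exponential of the augmented 7x7 system
is the exact propagator; a packet composes 128 of them, and a 64-packet
train is a matrix power.  An adaptive RK45 path (rtol 1e-8, atol 1e-10),
restarted at every dwell so the solver never steps across a field
discontinuity, serves as the independent oracle; the two agree to 1e-7 on
all six magnetization components.

### Decay curves and the steady-state fit

Signal is the pool-summed Mz at packet boundaries; trains of 0-64 packets
sampled at 33 evenly spaced lengths, started from +z and from -z.  The
joint model

    SI_{+/-Z}(t) = SI_{0,+/-Z} e^{-R t} - S_SS (1 - e^{-R t})

shares R *and the asymptote* between the polarities: the driven steady
state of the dynamics does not depend on the initial condition, so
-S_SS is one common plateau (internally the fit parameterizes the plateau
P_inf = -S_SS; the reported steady-state fraction is SS = P_inf /
SI_{0,+Z}).  Fitting is deterministic: bounded least squares with a
log-linear rate initialization plus a fixed small multi-start ladder,
R constrained to [0, 1e4] 1/s.  A mirrored-plateau reading of the model
(each polarity levelling at its own sign) cannot fit simulated +/-Z pairs
and was rejected.

### What the simulation reproduces, and what it cannot

With these parameters the simulated steady-state fractions across the
stretching series are, at the published operating point (64 packets,
33 time points):

    TL    0.6    0.8    1.0    1.2    1.4    1.6    1.8    2.0
    SS    0.940  0.848  0.716  0.571  0.442  0.342  0.271  0.217

a strictly decreasing series matching the reference two-digit values
within 1-5 %; rank-1 and rank-4 pulses give SS = 0.50 and 1.00.  The
fitted rate, by contrast, is R ~ 0.548 1/s for *every* scheme, rising
only microscopically with TL (0.54804 to 0.54843) through the tiny
R1/R2 anisotropy sampled along the trajectory.  This is forced by the
physics: with R1 ~ R2, negligible exchange and a 1.5e-8 solute fraction,
every eigen-rate of the exact propagator equals the dipolar rate, and the
exact rotary echo leaves no coherent decay at packet boundaries.
Published reference rates of 2-8 1/s for this same parameter set scale
with the packet length and are reproduced in magnitude and trend when the
train is re-integrated with a loose-tolerance adaptive solver, identifying
them as numerical damping of the fast intrapacket precession rather than a
property of the model.  `raffsim` integrates exactly and reports the exact
value; the monotone-trend and invariance properties are the meaningful
desk-scale checks on the rate column.

## Phantom and contrast pipeline

The phantom is a 192 x 192 short-axis slice (row-major, 0-based; angles
counterclockwise from +x): a myocardial annulus (radii 38/68 px) with an
anterolateral MI sector, a septal remote sector, and healthy myocardium
elsewhere.  Default ground truth uses a remote relaxation time of 50 ms
(ex vivo rotating-frame scale) and MI/remote time ratios of 1.182, 1.170
and 1.123, chosen so the pipeline reproduces contrast magnitudes of
18.2 %, 17.0 % and 12.3 % RRTD -- the published effect sizes for the
compressed-packet schemes, used here as constructed targets, not as
re-derivations of animal data.  Steady-state fractions of 0.25 (MI) and
0.30 (remote/healthy) echo the elevated-SS-in-MI pattern.  Image series
are the steady-state forward model at the requested train lengths;
noise is Gaussian on the signal or Rician (Gaussian on quadrature
channels before a signed magnitude), with the seed part of the spec so
phantoms are bit-reproducible.  The phantom emulates region geometry,
effect sizes and noise floors; it has no motion, partial-volume mixing,
B0/B1 inhomogeneity or anatomical texture, so passing tests demonstrate
correctness of the estimation pipeline, not robustness to those real-data
effects.

Mapping fits each pixel independently (no spatial regularization);
failed or out-of-mask pixels are NaN with a validity flag.  ROI summaries
are means and SDs over valid pixels; RRTD = (T_MI - T_remote) /
T_remote x 100 % from ROI means of relaxation times.  The report computes
RRTD from averaged times per map; replicate-level aggregation is left to
the caller (both orderings are easily composed from `roi_stats`).
Group hypothesis testing is deliberately outside the computational core.

## Numerical choices and degenerate inputs

- Fit tolerances: xtol = ftol = gtol = 1e-14; an early exit stops the
  multi-start ladder once a machine-level residual is reached.
- Monoexponential fits require positive signals and >= 3 points; a
  constant signal returns a time constant far beyond the sampled window
  or a non-converged flag.
- The B1 nutation fit seeds its frequency from a zero-padded spectrum and
  refines by least squares; it needs >= 4 samples spanning about half a
  period (design grid: 0-1.0 ms in 0.125 ms steps).
- Curve containers enforce strictly increasing times starting at zero and
  finite signals; propagation rejects record times beyond the train.
- Shape files round-trip through text at 12 significant digits (~1e-12
  relative); the normalized dialect stores wrapped phase in degrees.

## Problem sizes used in the checked examples

Simulation checks run the full published operating point (12 schemes,
64 packets, 128-sample waveforms) in seconds.  Phantom pipeline checks
run on a 48 x 48 phantom with 17 time points and on 500-pixel noise
ensembles; these sizes give sub-percent estimator noise and are the
package's default verification scale.

## Known limitations

- The published rate column for this simulation set-up is not recoverable
  by exact integration (see above); only its trend properties are.
- Ranks 3-5 use the package's own frame-recursion normalization; peak
  powers below rank 2 differ from earlier hardware presets.
- The -Z acquisition is treated as signed; magnitude-valued input is
  supported only through the phantom's signed-magnitude Rician option.
- Readout physics (fast spin echo timing, B0 artifact correction) is
  recorded as metadata only and never simulated.
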