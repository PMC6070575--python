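# Methods

## The problem

In triple-resonance backbone-assignment experiments (HNCA and relatives),
the Cα resonance recorded during the indirect evolution period t1 is split
by one-bond scalar couplings to the carbonyl carbon (CO, ~55 Hz) and the
side-chain Cβ (33–42 Hz).  Collapsing these multiplets doubles sensitivity,
but the standard remedy — band-selective inversion pulses applied to the
coupling partners during t1 — irradiates off resonance from the Cα band and
therefore drags the observed Cα frequencies away from their true positions
(the Bloch–Siegert shift) and distorts phases.

The method implemented here designs shaped pulses with two simultaneous
properties:

1. **Partner inversion** — longitudinal magnetization of CO and of a chosen
   Cβ band is inverted (Iz → −Iz), so the corresponding J coupling changes
   sign at the midpoint of t1 and refocuses by its end.
2. **Contracted Cα encoding** — over the whole Cα band, the pulse acts as a
   *universal rotation* about z with angle 2π·ω·aT: every Cα spin accrues
   chemical-shift phase as if it had evolved freely for the contracted time
   T′ = aT (a ≤ 1, T the pulse duration).  Because the contraction is the
   same constant a for every offset, inserting the pulse between two delays
   d0 = (t1 − aT)/2 encodes exactly t1 of evolution for every spin — no
   offset-dependent frequency error remains, which is precisely the absence
   of a Bloch–Siegert shift.  The price is a fixed real-time overhead
   (1 − a)·T per increment and a minimum encoded time t1 = aT; shorter
   increments skip the pulse (free evolution only).

## Spin model and conventions

Magnetization is propagated classically on the Bloch sphere (spin-1/2, no
relaxation).  A shaped pulse is piecewise-constant: segment k applies the
effective-field vector n = (ν1 cos φ, ν1 sin φ, Δν) in Hz and rotates the
magnetization about n̂ by 2π·|n|·dt — an exact axis–angle rotation, so there
is no time-stepping error at any segment length.  The global sign
convention, fixed once: a positive offset rotates +x toward +y (right-handed
about +z); the target universal rotation uses the same convention.  A
fine-step Runge–Kutta integrator exists only as an independent test oracle.

The coupled two-spin system (observed Cα + partner) is propagated as an
exact 4×4 density matrix under the secular (weak-coupling) Hamiltonian
H/2π = Δ_A·Iz + Δ_B·Sz + J·IzSz, with the RF term acting on both spins at
their respective offsets.  The detected signal is ⟨I⁺⟩ of the observed
spin.  With an ideal instantaneous π on the partner at the midpoint of t1,
the interferogram is exactly J-independent (the refocusing identity, one of
the test-suite invariants).  Strong-coupling terms, relaxation, radiation
damping, >2-spin systems and heteronuclear channels are all out of scope.

## Pulse variants

All values quoted at 800 MHz (1H); durations and amplitude ceilings scale
with the field so that band edges in p.p.m. and flip angles are preserved.

| variant  | T (ms) | ceiling (kHz) | a    | rotation band (p.p.m.) | inverted bands (p.p.m.)    |
|----------|--------|---------------|------|------------------------|----------------------------|
| GOODCOP  | 0.15   | 15.00         | 0.90 | 35–75                  | 165–185                    |
| BADCOP1  | 1.0    | 5.94          | 0.91 | 40–72                  | 165–185, 5–37              |
| BADCOP2  | 1.0    | 4.87          | 0.91 | 40–72                  | 165–185, 28–35 (preserve 5–26) |
| BADCOP3  | 1.0    | 7.22          | 0.91 | 47–72                  | 165–185, 10–45             |

GOODCOP decouples CO only (contracted time aT = 135 µs, overhead 15 µs);
the BADCOP variants additionally invert Cβ bands (aT = 910 µs, overhead
90 µs).  BADCOP3's rotation band starts at 47 p.p.m., which excludes the
glycine Cα (~45.4 p.p.m.): glycines come out attenuated and/or mis-phased
("perturbed") under that variant.  Two bounds for the upper edge of
BADCOP3's Cβ inversion band are in circulation (45 vs 43 p.p.m.); the
45 p.p.m. version is the default and the 43 p.p.m. version is available as
the `BADCOP3_ALT` preset.  For BADCOP2 the preserved band is [5, 26] p.p.m.
with 2 p.p.m. unconstrained guard bands around the [28, 35] inversion band;
band-edge behavior cannot be made arbitrarily sharp by a 1 ms pulse, and
leaving the guard bands unconstrained keeps the optimizer from fighting the
physics at the edges.

The 13C carrier defaults to 55 p.p.m. (mid-Cα, the conventional placement;
it keeps Cα offsets small) and is configurable.  1 p.p.m. equals
proton_frequency × 0.25145 Hz (γC/γH), i.e. 201.16 Hz at 800 MHz.

## Optimization targets

Per variant: 100 chemical shifts uniformly spaced over the rotation band,
initial states alternating Ix/Iy with sample parity, desired states equal
to the initial state rotated about z by 2π·ω·aT (by linearity of rotations,
correctness on two orthogonal transverse states implies correctness for
every transverse state, and a z-axis net rotation preserves Iz as well);
30 shifts over the CO band and, for the BADCOP variants, 30–60 over the Cβ
band(s) with Iz → −Iz; BADCOP2 additionally carries 40 explicit Iz → +Iz
preservation targets, since variants that must *not* invert a band are
optimized for preservation rather than relying on the mere absence of
inversion targets.  All weights default to 1.

## GRAPE optimizer

The objective is the weighted mean Bloch overlap Φ = Σ wⱼ⟨Mⱼ(T), dⱼ⟩ / Σ wⱼ
— the standard state-transfer fidelity for spin-1/2 at the Bloch level;
Φ = 1 iff every target is met exactly.  Note that, being a weighted *mean*,
Φ and its gradient are invariant under uniform rescaling of all weights.

Controls are Cartesian per-segment amplitudes (u_x, u_y); the hard RF
ceiling |u| ≤ ν1max is enforced by radial projection of each segment onto
the feasible disc after every accepted step — the exported pulse can never
violate the published ceiling, by construction.  Gradients are exact: the
derivative of each segment's rotation matrix with respect to its control
components uses the closed-form derivative of the SO(3) exponential map
(Gallego & Yezzi 2015), assembled into ∂Φ/∂u by one forward and one
backward sweep per target (adjoint method; cost linear in
n_segments × n_targets).  Agreement with central finite differences to
better than 1e−4 relative is a test-suite requirement and holds at
arbitrary per-segment rotation angles.

The ascent is a projected quasi-Newton method: L-BFGS two-loop directions
(memory 12) over the projected iterates with a monotone backtracking line
search, falling back to the raw gradient direction (and a cleared curvature
memory) when projection spoils the quasi-Newton model.  Accepted fidelity
is therefore non-decreasing, and the ceiling holds at every accepted point.

Numerical choices:

- **Initial shape** — uniform random Cartesian controls in ±0.5 × ceiling
  from a seeded generator (default seed 20180801).  Much weaker starts sit
  on a nearly flat region of the landscape for the far-off-resonance
  inversion targets (22–26 kHz from the carrier) and stall.
- **Multi-start** — the landscape has occasional poor basins; by default 3
  pilot ascents of 150 iterations from seeds (seed, seed+1, seed+2) run
  first and the best continues for the remaining budget.  Fully
  deterministic given the seed.
- **Discretization** — control segments default to 0.5 µs for GOODCOP
  (300 segments) and 1 µs for the BADCOP variants (1000 segments),
  configurable; the tests and the acceptance run use 128 segments, which
  keeps the control Nyquist bandwidth (±64 kHz at dt = 7.8 µs) well beyond
  the outermost target offsets while fitting the optimizations in seconds
  to a couple of minutes on one CPU.
- **Convergence** — stop when fidelity improves by < 1e−10 for 10
  consecutive iterations, when no improving step exists, or at the
  iteration cap (reported as `converged=False`, not an exception).
- An optional quadratic smoothness penalty λ Σ|u_{k+1}−u_k|²/ν1max² on
  control differences is available (`smoothness_weight`, off by default)
  for hardware that dislikes abrupt amplitude or phase jumps; it shapes
  the optimizer's objective only and reported per-target fidelities stay
  pure overlaps.

Typical converged results with 128 segments: GOODCOP mean fidelity ≈ 0.9997,
BADCOP1 ≈ 0.983 with residual infidelity confined to the physically
unavoidable ~3 p.p.m. transition between the Cβ inversion edge (37 p.p.m.)
and the rotation band (40 p.p.m.).  Profile-plateau assertions therefore
inset band edges by 1–2 p.p.m. (the Cβ check band ends at 35 p.p.m., the Cα
check band starts at 41 p.p.m.), mirroring the finite transition widths any
band-selective pulse of this duration must have.

## Validation pipeline

- **Spectra** — synthetic interferograms are cosine-squared apodized
  (first point halved), zero-filled ×4 (×8 for shift measurement), Fourier
  transformed; peaks are local maxima above 5% of the global maximum with
  3-point parabolic sub-bin interpolation.  These processing defaults were
  chosen for peak-position fidelity; both spectra of a ratio measurement
  always share them.
- **Bloch–Siegert measurement** — for each offset, the d0–pulse–d0
  interferogram of an uncoupled spin is transformed and the interpolated
  peak position compared with the intrinsic offset; the phase error is the
  complex argument at the interpolated peak frequency (evaluated as a DTFT
  to avoid bin quantization).  The analytically ideal contracted pulse
  (net effect exactly exp(−iω·aT·Iz)) nulls both to numerical precision —
  the module's null test.  The t1 grid uses 100 µs increments (±5 kHz
  spectral width, covering the Cα band at 800 MHz) and 256 increments.
- **The effect being removed** — continuous irradiation at ν1 = 1 kHz
  placed 10 kHz off resonance with naive timing reproduces the classic
  second-order shift ν1²/(2Δ) = 50 Hz within 10% over ν1/Δ ∈ [0.05, 0.15].
- **Sensitivity** — ideal midpoint inversion vs no decoupling at J = 35 Hz
  gives a peak-height ratio of 2.00 under identical processing; a partner
  at the inversion-band edge gives a ratio strictly between 1 and 2.
- **Secondary peaks** — any peak above 5% of the main peak within ±2 kHz
  is labeled a sideband in the peak list.

## Synthetic strips and pattern logic

`patterns` predicts, per variant, whether a residue's Cα appears as a
singlet, doublet, partial multiplet, or perturbed peak: the partner's final
Mz at the residue's mean Cβ shift (simulated profile when an optimized
pulse is supplied, ideal band profile otherwise) is thresholded at ±0.8 —
a value inside the simulated transition widths; residues whose Cα falls
outside the variant's rotation band are "perturbed", and glycine (no Cβ)
is always a singlet.  Mean Cα/Cβ shifts are a fixed 20-residue table of
standard BMRB-style averages (no network lookups).

Synthetic strip sets emulate multi-variant HNCA planes: per residue and
variant, the Cα interferogram (two-spin propagation for optimized pulses;
a closed-form contracted-encoding/partner-inversion model for idealized
variants, with out-of-band Cα modeled as 0.3× amplitude and a 1 rad phase
error) is processed into a real trace on a common frequency axis, plus
seeded Gaussian noise.  They deliberately do *not* model: amide/15N
dimensions, sequential (i−1) peak intensity asymmetry, secondary-structure
shift deviations from the mean table, relaxation-dependent linewidths, or
NUS sampling artifacts.  Passing tests therefore demonstrate the decoupling
and matching *logic*, not performance on real spectra.

Matching follows the intersective rule: Pearson correlation between ±60 Hz
windows (spanning a full 42 Hz doublet plus linewidth) centered on each
strip's own peak, per variant; a candidate must reach the threshold
(default 0.9) in *every* variant — one exception implies different Cβ
environments and excludes the match.  Adding variants can only shrink the
surviving candidate set.

## Problem sizes used by the shipped tests and acceptance run

GRAPE runs use 128 segments with the full published target sets (130 for
GOODCOP, 190 for BADCOP1); shift measurements use 9–17 offsets × 256
increments; two-spin spectra 256–512 increments; strip sets ≤ 12 residues ×
4 variants.  These sizes make the whole suite run in minutes on a single
CPU while exercising every stage at full physical fidelity (the propagation
is exact at any segment count).

## Known limitations

- No relaxation or RF-inhomogeneity robustness ensembles; a miscalibrated
  B1 will degrade the inversion bands.
- Band-edge transitions are ~2–3 p.p.m. wide for the 1 ms variants;
  residues whose Cβ falls in a transition show partial patterns.
- The idealized strip generator is a logic fixture, not a spectrum
  emulator (see above).
- The optimizer is local; the multi-start default makes bad basins
  unlikely, not impossible.  Check `GrapeResult.converged` and the
  per-target fidelities before exporting a pulse for use.
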