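# decop

Optimal-control design, simulation and validation of **band-selective
homonuclear decoupling pulses** for protein backbone NMR — shaped pulses
that invert CO and selected Cβ bands while the Cα spins keep accruing
chemical-shift phase at a uniformly contracted rate, collapsing Cα
multiplets in HNCA-type experiments **without Bloch–Siegert shifts**.

## Who this is for

NMR spectroscopists and methods developers who want to (re)generate the
GOODCOP/BADCOP family of decoupling pulses for their own field strength,
verify a pulse's inversion profile and frequency fidelity by simulation
before burning spectrometer time, compute the timing bookkeeping needed to
insert such a pulse into an indirect evolution period, or prototype the
multi-variant line-shape logic used for sequential assignment.

## The method in brief

During the indirect evolution time t1 the observed Cα magnetization
evolves under its offset ω and the scalar couplings to CO (~55 Hz) and Cβ
(33–42 Hz).  A shaped pulse of duration T is optimized (GRAPE, exact
adjoint gradients) so that simultaneously:

- CO and chosen Cβ bands undergo a point-to-point inversion
  Iz → −Iz, so the coupling changes sign mid-t1 and refocuses; and
- every Cα offset undergoes the *universal rotation*
  U = exp(−i ω·aT·Iz), i.e. the pulse encodes exactly T′ = aT of
  chemical-shift evolution, with the same contraction factor a for all
  offsets.

Sandwiching the pulse between two delays d0 = (t1 − aT)/2 then encodes
exactly t1 for every spin: no offset-dependent frequency error (no
Bloch–Siegert shift), at the cost of a fixed overhead (1 − a)·T and a
minimum encoded time t1 = aT (shorter increments skip the pulse).  Four
variants are built in (parameters at 800 MHz; they rescale to any field):

| variant  | decouples                  | T (ms) | max RF (kHz) | a    |
|----------|----------------------------|--------|--------------|------|
| GOODCOP  | CO                         | 0.15   | 15.00        | 0.90 |
| BADCOP1  | CO + Cβ < 35 p.p.m.        | 1      | 5.94         | 0.91 |
| BADCOP2  | CO + Cβ ≈ 28–35 p.p.m.     | 1      | 4.87         | 0.91 |
| BADCOP3  | CO + Cβ < 43–45 p.p.m.     | 1      | 7.22         | 0.91 |

Because each variant collapses a different subset of Cα doublets,
recording several HNCA planes gives residue-type information (e.g. alanine
is a singlet under BADCOP1 but a doublet under BADCOP2; only Ser/Thr stay
split under BADCOP3) that resolves ambiguities in sequential strip
matching.  See `docs/methods.md` for the full model, conventions and
numerical choices.

## Worked example

Timing bookkeeping for inserting GOODCOP into a 10 ms increment:

```text
$ decop timing --variant GOODCOP --t1 10ms
GOODCOP: contracted time 135.000 us, overhead 15.000 us, minimum t1 135.000 us
t1    10000.000 us: d0    4932.5000 us, pulse on, elapsed    10015.000 us
```

The pulse encodes 135 µs of Cα evolution in 150 µs of real time, so a
10 ms increment needs two 4.9325 ms delays around it and costs 15 µs of
real-time overhead.

Design a reduced-resolution GOODCOP pulse and export it as a Bruker
JCAMP-DX shape file:

```text
$ decop design optimize --variant GOODCOP --segments 64 --max-iterations 150 \
      --out good.shp --log good.json
GOODCOP: fidelity 0.999879 after 150 iterations (converged=False); max amplitude 15000.0 Hz -> good.shp
```

Mean Bloch overlap 0.9999 over 130 targets (100 Cα universal-rotation
targets over 35–75 p.p.m. + 30 CO inversion targets over 165–185 p.p.m.);
the 15 kHz amplitude ceiling is enforced by construction.  The doublet
collapse a midpoint inversion buys:

```text
$ decop validate sensitivity
J = 35 Hz: peak-height ratio 2.0000 (2.0 = full doublet collapse)
```

i.e. collapsing a 35 Hz doublet into a singlet doubles the peak height
under identical processing.  `decop validate bs-shift` measures the
residual frequency error across the Cα band with the pulse in place
(≤ 0.4 Hz for the optimized pulses here, versus the 50 Hz shift that 1 kHz
of naive CW irradiation 10 kHz off resonance produces), `decop simulate
profile` traces the inversion bands, and `decop strips generate/match`
runs the multi-variant assignment logic on synthetic data.

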