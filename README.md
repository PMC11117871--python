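# stressfit

Parametric logistic stress–stretch analysis of compressive load tests on
vertebral bone.

## The problem

Compression tests on whole vertebrae (the motivating data are canine lumbar
vertebrae L1–L7) produce either cyclic hysteresis loops — repeated
compression–relaxation cycles at a fixed load — or a single monotone ramp to
fracture. Classical hyperelastic laws (neo-Hookean, Mooney–Rivlin, Ogden, …)
fit only parts of the stretch range of such curves. A four-parameter
*modified logistic* function fits the whole range, from the start of loading
to the ultimate strength:

σ(t) = C₀ + C₁ / (1 + exp(−C₂ · (t − C₃)))

where C₀ shifts the sigmoid along the stress axis, C₀ + C₁ is the upper
asymptote (a theoretical limit of the ultimate strength), C₂ is the
exponential rise/fall scale, and C₃ the curve midpoint. The stretch
λ = (L − l)/L (specimen length L, crosshead displacement l; λ = 1 at rest,
decreasing under compression) is modelled per half-cycle as a quadratic
λ(t) = D₂t² + D₁t + D₀. Together the two curves give the stress–stretch
relation in parametric form; when λ is linear in time the pair collapses to
a logistic *of stretch* with transformed coefficients C₂′ = C₂/D₁,
C₃′ = D₀ + D₁C₃. The slope at the midpoint is tan(α) = C₁C₂/4.

`stressfit` implements the full pipeline for this analysis:

1. **mechanics** — convert machine output (force N, displacement mm) to
   stress σ = F/S (MPa) and stretch λ = (L − l)/L using specimen geometry;
2. **segmentation** — detect stress extrema (prominence-based) and split the
   trace into loading (valley→peak) and unloading (peak→valley) half-cycles;
3. **fitting** — per half-cycle nonlinear least squares for the logistic and
   ordinary least squares for the quadratic, with R² = 1 − SSres/SStot;
4. **uncertainty** — Student-t confidence half-widths (t·s/√n) for geometry
   measurements and quadrature error propagation to stress and stretch;
5. **synthetic** — generators for cyclic and fracture records built from
   packaged published reference coefficients, for testing and simulation.

It is aimed at biomechanics labs running micro-compression tests who want
reproducible per-cycle coefficient tables rather than hand-driven curve fits.

## Worked example

```python
import stressfit as sf

# synthetic 3-cycle test built on the published L3 loading coefficients,
# with realistic instrument noise
spec = sf.default_cyclic_spec(n_cycles=3, noise_sd_stress_mpa=0.036,
                              noise_sd_displacement_mm=0.005, seed=42)
record = sf.generate_cyclic(spec)          # or CompressionTest.from_csv(...)
results = sf.CompressionTest.from_record(record).fit()
print(results.summary())
```

prints

```
Compression test fit — specimen SYN
Experiment: cyclic
Mode: time-domain logistic stress + quadratic stretch
Samples: 1944   Half-cycles fitted: 6

cyc dir            C0         C1         C2         C3        R2    tan(a)
--------------------------------------------------------------------------
  1 load       0.1122      7.168       1.47      3.161   0.99985     2.634
  1 unload     0.1077      7.168     -1.469      3.242   0.99982    -2.633
  2 load       0.1031      7.177      1.462      3.258   0.99981     2.623
  2 unload     0.1181      7.151     -1.479      3.541   0.99984    -2.644
  3 load       0.1089      7.165      1.463      2.998   0.99981      2.62
  3 unload    0.09699       7.18     -1.463      3.323   0.99982    -2.625

cyc dir            D2         D1         D0        R2
-----------------------------------------------------
  1 down    5.974e-06   -0.02318     0.9981   0.99997
  1 up        0.00267   0.005842     0.8498   0.99996
  2 down    1.292e-07   -0.02314          1   0.99996
  2 up       0.002628   0.004143     0.8493   0.99840
  3 down   -1.831e-06   -0.02315     0.9944   0.99997
  3 up       0.002689    0.00529     0.8496   0.99995

Error budget: relative stress error 0.01005 (dF = 0.7313 N, dS = 1 mm^2); stretch error 2.5e-05 (dl = 0.01 mm)
```

Each half-cycle gets its own logistic stress fit (C₀…C₃, on the segment's
re-zeroed clock; unloading segments carry C₂ < 0 since stress falls on
forward time) and quadratic stretch fit (D₂, D₁, D₀; "down" = compression,
"up" = recovery). The generating amplitude C₁ = 7.163 MPa and rate
C₂ = 1.4699 s⁻¹ are recovered to a few parts per thousand under noise, with
R² ≈ 0.9998 — the near-0.999 regime typical of these tests. `tan(a)` is the
midpoint slope C₁C₂/4; the error budget applies the machine precisions
(±0.1% force, ±0.01 mm displacement) and the recorded geometry
uncertainties.

`results.frame()` returns the same table as a DataFrame,
`results.to_csv(path)` writes the coefficient table,
`results.stretch_domain_models()` gives the stress-vs-stretch logistic for
cycles whose stretch is linear in time, and `results.plot()` overlays the
fitted curves on the observed hysteresis loops.

The same pipeline runs from a shell:

```sh
stressfit simulate --cycles 10 --seed 7 --output trace.csv
stressfit fit-cycles --input trace.csv --geometry trace.geometry.toml --output coeffs.csv
stressfit fit-fracture --input frac.csv --length-mm 20 --surface-mm2 100
stressfit report --input trace.csv --length-mm 20 --surface-mm2 100
```

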