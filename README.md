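# kinquant

Quantitative-fluorescence estimation of the DNA content of a kinetochore —
the chromatin packaged beneath a GFP-marked centromere protein domain — in
kilobases, calibrated against bacteriophage particles of known genome size
imaged in the same field of view.

## The measurement

Mitotic kinetochores sit on centromeric chromatin that cannot normally be
distinguished from the surrounding chromosome. When condensin (SMC2) is
depleted, kinetochores are occasionally stretched away from the chromosome
body ("excursions"), spatially isolating their chromatin. With the DNA
stained by DAPI and the kinetochore marked by CENP-A–GFP or CENP-H–GFP, the
amount of DNA inside the kinetochore domain can be read off an internal
standard curve:

1. **Standards.** Bacteriophages T4 (168 kb), P1 (90 kb) and λ (48 kb) are
   fixed, DAPI-stained and mixed onto the same slide. Each particle is
   measured on its best single focal plane: the sum intensity *S* inside an
   ROI covering the particle, minus the sum *B* of the same ROI moved 5–10 px
   onto empty background, gives the net intensity *I = S − B*.
2. **Standard curve.** Ordinary least squares of net intensity on genome
   size, *I = β₀ + β₁·kb*, one curve per imaging session.
3. **Unknowns.** The GFP image defines an envelope ROI around each stretched
   kinetochore; net DAPI intensity inside that envelope, measured on a sum
   projection of the planes carrying GFP signal, is converted by inverse
   prediction, *kb = (I − β₀)/β₁*, with a 95 % interval from the
   delta method (Fieller bounds optional).

Because no raw image data accompany the protocol, the package includes a
first-class synthetic-image simulator: two-channel 3-D stacks
(1,024 × 1,024 px planes, 200 nm z-step, 65 nm pixels) containing Gaussian
phage point sources and extended kinetochore blobs with Poisson shot noise,
Gaussian read noise and a ground-truth manifest, so the entire pipeline is
validated by parameter recovery.

## Worked example

```python
from kinquant import SimConfig, simulate_field, analyze_field, summarize_cohort

cfg = SimConfig(field_shape=(21, 512, 512), seed=11)   # 3+3+3 phages, 5 kinetochores
field, manifest = simulate_field(cfg)
analysis = analyze_field(field, session="demo")

fit = analysis.fit
print(f"standard curve: slope={fit.slope:.2f} photons/kb, "
      f"intercept={fit.intercept:.1f}, r2={fit.r_squared:.4f}")
print(summarize_cohort(analysis.records, include_flagged=True).to_text())
```

prints

```
standard curve: slope=199.31 photons/kb, intercept=44.4, r2=0.9999
n = 5
mean_kb = 63.1
sd_kb = 30.4
min_kb = 30.9
max_kb = 101.3
```

The slope is the recovered photon yield per kilobase (the simulation used
200 photons/kb), the near-zero intercept shows the background subtraction is
working, and the five kb estimates recover the manifest's true values
(43.3, 87.4, 99.6, 31.4, 45.6 kb) to a few percent each.

The same stages are available from a shell:

```sh
kinquant simulate --seed 11 --out sim/
kinquant quantify --field sim/ --seeds auto --out results/
kinquant summarize --records results/records.csv
```

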