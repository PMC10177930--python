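# sfdikit

Spatial-frequency domain imaging (SFDI) shines sinusoidally patterned light
on a turbid sample and demodulates the reflected patterns into a planar
(DC) and a modulation-amplitude (AC) image. Because modulated light
attenuates with the frequency-dependent effective depth
δ′_eff = 1/√(μ_eff² + (2πf_x)²), higher frequencies interrogate shallower
tissue — the property that lets SFDI map sub-surface optical properties and
detect early-stage bruises in fruit. The practical question this package
addresses: **how deep does the detected light actually sample in apple
flesh, and down to what cover depth does a bruise stay visible?**

`sfdikit` is a library + CLI for scientists working on structured-light
inspection of fruit (or turbid media generally). It provides:

* **`sfdikit.optics`** — diffusion-theory formulas: μ_eff = √(3μ_a(μ_a+μ_s′)),
  penetration depth δ = 1/μ_eff, its modulated generalisation δ′_eff, mean
  free path, exponential fluence decay; plus the packaged apple
  optical-property table (six wavelengths, 550–730 nm).
* **`sfdikit.demodulation`** — three-phase pattern synthesis and
  demodulation (I_DC = (I₁+I₂+I₃)/3,
  I_AC = (√2/3)√((I₁−I₂)²+(I₁−I₃)²+(I₂−I₃)²)), whiteboard flat-field
  correction, TIFF/PNG stack I/O.
* **`sfdikit.mc`** — Monte Carlo photon transport in a semi-infinite or
  two-layer medium (Henyey–Greenstein scattering, Fresnel boundary,
  Russian roulette) with photon-wise Hankel-transform reflectance
  R(f) = Σ wᵢJ₀(2πf ρᵢ)/N and detected-light sampling-depth quantiles.
* **`sfdikit.inversion`** — diffusion forward model of modulated diffuse
  reflectance, reflectance calibration, and two-frequency lookup-table
  inversion to per-pixel (μ_a, μ_s′) maps.
* **`sfdikit.contrast`** — Michelson contrast, peak-to-valley ratio (PVR),
  the PVR ≥ 1.2 penetration decision rule, and contrast-vs-thickness fits.
* **`sfdikit.scenes`** — seeded synthetic phantoms (uniform slab, buried
  ink-filled cylinders, bar target under a tissue slice, bruise under a
  cover slab) with exact ground truth, camera noise and 8-bit quantization.
* **`sfdikit.pipeline` / CLI** — end-to-end experiment analogs.

See `docs/methods.md` for models, defaults, numerical choices, and what
the synthetic scenes do and do not emulate.

## Worked example

How deep does detected light sample apple flesh at 550 nm?

```python
from sfdikit.optics import apple_properties, penetration_depth, effective_penetration_depth
from sfdikit.mc import TransportConfig, run_transport, sampling_depth_quantiles
from sfdikit.inversion import diffusion_rd

props = apple_properties(550)          # mu_a = 0.0302, mu_s' = 1.286 mm^-1
print(f"diffuse penetration depth at 550 nm: {penetration_depth(props):.2f} mm")
print(f"effective depth at fx = 0.1 /mm:     {effective_penetration_depth(props, 0.1):.2f} mm")
print(f"diffusion reflectance Rd(0):         {diffusion_rd(props, 0.0):.3f}")

result = run_transport(TransportConfig(medium=props, n_photons=200_000, seed=20230425))
sd = sampling_depth_quantiles(result, fx=0.0)
print(f"MC reflectance R(0):                 {sd.reflectance:.3f}")
print(f"detected-light depth quantiles:      "
      f"q25 = {sd.depth_q25:.2f} mm, q50 = {sd.depth_q50:.2f} mm, q75 = {sd.depth_q75:.2f} mm")
```

```
diffuse penetration depth at 550 nm: 2.90 mm
effective depth at fx = 0.1 /mm:     1.39 mm
diffusion reflectance Rd(0):         0.512
MC reflectance R(0):                 0.502
detected-light depth quantiles:      q25 = 0.56 mm, q50 = 1.09 mm, q75 = 2.00 mm
```

Reading the numbers: diffusion theory puts the nominal penetration depth
near 2.9 mm, but the backscattered light a camera actually detects mostly
stayed much shallower — half of it within ~1.1 mm, three quarters within
~2.0 mm of the surface. The Monte Carlo and diffusion reflectances agree
to ~2%, a consistency check between the two independent models. Modulating
at 0.1 cycles/mm pulls the effective depth down to 1.4 mm, which is why
high-frequency AC images emphasise shallow structure.

The same analyses from the shell:

```bash
sfdikit simulate-depth --out runs/depth            # per-wavelength depth table
sfdikit experiment2 --wavelength 630 --out runs/e2 # covered-target PVR sweep
sfdikit experiment3 --thicknesses 0,1,2,4,8 --out runs/e3  # bruise visibility
```

Every command writes its resolved configuration (`run_config.yaml`) next
to its outputs and refuses to overwrite without `--force`.

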