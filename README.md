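# lightpatch

Ray-optics design model for **tapered-fiber, air-gap photonic patches** —
implantable light-delivery devices in which a flexible optical fiber with a
micrometre-scale tapered tip is embedded in a thin, transparent,
high-refractive-index polymer patch (PMCL, n = 1.49) and then retracted by a
few micrometres, leaving an air-filled cavity between the fiber tip and the
patch.  The two refracting interfaces of that cavity convert forward,
flashlight-like fiber emission into bulb-like, laterally spread illumination,
so a patch glued onto an organ can light a large, deep tissue area without
puncturing it.

The package is for device designers and modellers who want to reproduce and
explore the optics behind the design: why a pull distance *d* in the 5–25 um
window maximizes lateral scattering, how much energy ends up on the tissue
side of the patch, and how the device compares with clinical flat-end,
matt-tip and side-glow fibers.

## The model

* **Interface optics** (`lightpatch.optics`): Snell refraction, total
  internal reflection with the tie-break "at the critical angle = TIR", and
  unpolarized Fresnel power coefficients (s/p average),
  `theta_c = arcsin(n_out / n_in)`.
* **Geometry** (`lightpatch.geometry`): the cavity is the exact mold of the
  taper profile `F(z) = r_tip + (r_base - r_tip)(z/L)^p` (defaults
  0.5 um -> 50 um over L = 280 um, p = 2, injectable), retracted by `d`.
* **Transport** (`lightpatch.engine`): power-weighted Monte Carlo rays from a
  point source at the tip (cone half-angle 65 deg, uniform per solid angle),
  deterministic two-branch Fresnel splitting, strict energy ledgers at every
  stage; then slab transport to the patch's tissue/air/edge faces.
* **Statistics** (`lightpatch.metrics`): the lateral power fraction
  `P_s/P` — power leaving the *forward propagation region*, the spatial cone
  of half-angle 43 deg with vertex at the fiber tip — the pull-distance
  design curve, divergence angles from angular distributions and from
  synthetic light-path images, footprint and tissue/air split.
* **Tissue** (`lightpatch.tissue`): Beer–Lambert penetration,
  `depth = -ln(threshold)/mu_eff`, and closed-form illuminated volumes for
  the four device classes (cone, hemisphere, column, disk+outskirt).

## Worked example

```python
import lightpatch as lp

device = lp.default_device()                    # 280 um taper, d = 15 um
spec = lp.EmissionSpec(n_rays=100_000, seed=7)

table = lp.sweep_d(device, [0.5, 2, 5, 15, 25, 60, 120], spec)
print(table[["d_um", "ps_over_p"]].to_string(index=False))

dist, exits, ledger = lp.simulate_device(device, spec)
tissue, air, edge = lp.side_split(exits)
print(f"tissue {tissue:.2f}  air {air:.2f}  ledger total {sum(ledger.values()):.6f}")
```

prints

```
 d_um  ps_over_p
  0.5   0.488853
  2.0   0.916147
  5.0   0.968872
 15.0   0.990750
 25.0   0.988615
 60.0   0.957028
120.0   0.856564
tissue 0.59  air 0.14  ledger total 1.000000
```

Reading the numbers: the lateral power fraction P_s/P rises steeply below
d = 5 um (at d = 0.5 um half the light still exits through the flat cavity
apex and stays forward), holds a plateau above 96% across the 5–25 um design
window, and falls off again toward d = 120 um, where light leaves the long
cavity near the axis and ahead of the tip — this is what makes 5–25 um the
target range for the fiber pull. Of all emitted power, 59% exits on the
tissue side versus 14% on the air side, because the patch/tissue critical
angle (70 deg) is much larger than patch/air (42 deg); the energy ledger
closes exactly.

The same pipeline is scriptable from a shell:

```bash
lightpatch simulate --rays 100000 --seed 7 --out runs/base
lightpatch sweep-d --rays 100000 --seed 1234 --out runs/sweep
lightpatch divergence --image beam.tiff --out runs/div
lightpatch compare-devices --out runs/volumes
```

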